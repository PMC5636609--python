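"""Intrinsic excitability from current-clamp step families.

Metrics follow the standard slice-electrophysiology conventions:
input resistance is the OLS slope of steady-state voltage deflection
against injected current over the hyperpolarizing steps; the F-I gain
is the OLS slope of mean firing rate (spike count over the step) versus
injected current across the depolarizing steps; resting potential is
the pre-step baseline corrected once for the liquid junction potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_io import Trace
from . import stats as _stats


@dataclass
class StepFamily:
    """A family of current-step sweeps from one neuron.

    ``sweeps`` holds ``(injected_current_pA, voltage Trace)`` pairs with
    strictly increasing currents; ``step_window`` is the (start, end) of
    the current step in seconds from the beginning of each sweep.
    """

    sweeps: list  # list[(float, Trace)]
    step_window: tuple[float, float]
    neuron_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        currents = [c for c, _ in self.sweeps]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValueError("sweep currents must be strictly increasing")
        if self.step_window[1] <= self.step_window[0]:
            raise ValueError("empty step window")

    def currents(self) -> np.ndarray:
        return np.array([c for c, _ in self.sweeps])


@dataclass
class SpikeConfig:
    threshold_mv: float = 0.0     # upward crossing level
    refractory_ms: float = 2.0
    takeoff_dvdt: float = 20.0    # mV/ms, defines the spike take-off point
    qc_amp_mv: float = 50.0       # amplitude below this is flagged


@dataclass
class SpikeTrain:
    times: np.ndarray        # s
    amplitudes: np.ndarray   # mV, peak minus take-off voltage
    below_qc: np.ndarray     # bool per spike

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FIResult:
    currents: np.ndarray     # pA, steps used (>= 0)
    rates: np.ndarray        # Hz, count over the step duration
    gain: float              # Hz/pA
    rheobase: float | None   # pA, first step with >= 1 spike
    zero_activity: bool = False


def _window_slice(trace: Trace, start: float, end: float) -> slice:
    fs = trace.sampling_rate
    return slice(int(round(start * fs)), int(round(end * fs)))


def input_resistance(family: StepFamily, steady_ms: float = 100.0) -> float:
    """Input resistance (MOhm) from the non-positive current steps.

    Steady-state deflection = mean over the last ``steady_ms`` of the
    step minus the pre-step baseline; the V-I slope (mV/pA) converts to
    MOhm by a factor of 1000.  Offsetting every sweep by a constant
    leaves the result unchanged.
    """
    t0, t1 = family.step_window
    pairs = [(c, tr) for c, tr in family.sweeps if c <= 0]
    if len(pairs) < 2 or not any(c < 0 for c, _ in pairs):
        raise ValueError("need at least two non-positive steps including a negative one")
    currents, deflections = [], []
    for c, tr in pairs:
        base = float(np.mean(tr.samples[_window_slice(tr, max(0.0, t0 - 0.1), t0)]))
        steady = float(np.mean(
            tr.samples[_window_slice(tr, t1 - steady_ms * 1e-3, t1)]))
        currents.append(c)
        deflections.append(steady - base)
    slope = np.polyfit(currents, deflections, 1)[0]  # mV/pA
    return float(slope * 1e3)  # MOhm


def detect_spikes(trace: Trace, config: SpikeConfig | None = None) -> SpikeTrain:
    """Threshold-crossing spike detection on a voltage trace.

    A spike is an upward crossing of ``threshold_mv`` (default 0 mV —
    robust for >50 mV spikes from a ~-60 mV rest) honoring a 2 ms
    refractory.  Amplitude is the peak minus the take-off voltage, the
    last point before the peak where dV/dt stays below
    ``takeoff_dvdt``; spikes smaller than the QC criterion are flagged,
    not dropped.
    """
    if trace.channel_role != "cclamp_voltage":
        raise ValueError(f"expected cclamp_voltage trace, got {trace.channel_role}")
    config = config or SpikeConfig()
    v = trace.samples
    fs = trace.sampling_rate
    above = v >= config.threshold_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    refr = max(1, int(round(config.refractory_ms * 1e-3 * fs)))
    times, amps = [], []
    last = -refr - 1
    dvdt = np.diff(v, prepend=v[0]) * fs * 1e-3  # mV/ms
    for i in crossings:
        if i - last < refr:
            continue
        last = i
        j1 = min(v.size, i + refr)
        peak_rel = int(np.argmax(v[i:j1]))
        peak = i + peak_rel
        # walk back to the take-off point
        k = i
        lo = max(0, i - refr)
        while k > lo and dvdt[k] > config.takeoff_dvdt:
            k -= 1
        times.append(trace.t0 + peak / fs)
        amps.append(float(v[peak] - v[k]))
    times = np.asarray(times)
    amps = np.asarray(amps)
    return SpikeTrain(times=times, amplitudes=amps,
                      below_qc=amps < config.qc_amp_mv)


def fi_gain(
    family: StepFamily,
    spike_config: SpikeConfig | None = None,
    suprathreshold_only: bool = False,
) -> FIResult:
    """Firing rate per step and the F-I gain (Hz/pA).

    Rate = spike count within the step window divided by the step
    duration; the gain is the OLS slope of rate versus current over the
    non-negative steps (optionally only the spiking ones).  An entirely
    silent family yields gain 0 with ``zero_activity`` set.
    """
    t0, t1 = family.step_window
    dur = t1 - t0
    currents, rates = [], []
    rheobase = None
    for c, tr in family.sweeps:
        if c < 0:
            continue
        spikes = detect_spikes(tr, spike_config)
        in_step = np.sum((spikes.times >= tr.t0 + t0) & (spikes.times < tr.t0 + t1))
        currents.append(c)
        rates.append(in_step / dur)
        if rheobase is None and in_step > 0:
            rheobase = c
    currents = np.asarray(currents, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.all(rates == 0):
        return FIResult(currents=currents, rates=rates, gain=0.0,
                        rheobase=None, zero_activity=True)
    sel = rates > 0 if suprathreshold_only else np.ones_like(rates, bool)
    gain = float(np.polyfit(currents[sel], rates[sel], 1)[0])
    return FIResult(currents=currents, rates=rates, gain=gain, rheobase=rheobase)


def compare_fi_slopes(
    group_a: Sequence[StepFamily],
    group_b: Sequence[StepFamily],
    labels: tuple[str, str] = ("a", "b"),
    spike_config: SpikeConfig | None = None,
) -> dict:
    """Compare F-I relationships between two groups of neurons.

    Returns the homogeneity-of-slopes ANCOVA (rate ~ current * group,
    interaction F-test) on the pooled per-step rates, plus an unpaired t
    test on the per-neuron gains and the group mean gains.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two neurons per group")
    series = {labels[0]: [], labels[1]: []}
    gains = {labels[0]: [], labels[1]: []}
    for label, group in zip(labels, (group_a, group_b)):
        for fam in group:
            res = fi_gain(fam, spike_config)
            series[label].append((res.currents, res.rates))
            gains[label].append(res.gain)
    ancova = _stats.ancova_slopes(series)
    ttest = _stats.unpaired_t(gains[labels[0]], gains[labels[1]])
    return {
        "ancova": ancova,
        "gain_t": ttest,
        "mean_gains": {k: float(np.mean(v)) for k, v in gains.items()},
        "gains": {k: list(map(float, v)) for k, v in gains.items()},
    }


DEFAULT_LJP_MV = -12.0


def resting_potential(
    trace: Trace,
    step_start: float | None = None,
    ljp: float = DEFAULT_LJP_MV,
    baseline_s: float = 0.1,
) -> float:
    """Resting membrane potential at the start of the step protocol (mV).

    Mean of the pre-step baseline plus the liquid junction potential
    correction (pipette relative to bath; reported = measured + ljp).
    The correction is applied exactly once: a trace whose metadata marks
    it already corrected is refused.
    """
    if trace.metadata.get("ljp_corrected"):
        raise ValueError("trace already LJP-corrected; refusing to correct twice")
    if step_start is None:
        step_start = trace.metadata.get("step_start_s", baseline_s)
    if step_start < baseline_s:
        raise ValueError("need at least %.0f ms of pre-step baseline" % (baseline_s * 1e3))
    sl = _window_slice(trace, step_start - baseline_s, step_start)
    return float(np.mean(trace.samples[sl]) + ljp)
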