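"""Ground-truth-labeled synthetic recordings.

This module emulates the three kinds of raw data the analysis pipeline
consumes, with fully known ground truth so each downstream stage can be
certified against what was actually injected:

* voltage-clamp traces carrying Poisson-timed miniature EPSCs
  (biexponential kernels, right-skewed amplitudes, Gaussian noise);
* current-clamp step families from a leaky integrate-and-fire neuron,
  whose firing rate has a closed analytic form;
* two-channel integrated neurograms with near-synchronous ~1 s bursts
  whose amplitude and frequency change across drug epochs.

Seed policy: every generator takes one seed (or an existing
``numpy.random.Generator``); multi-neuron generators derive independent
per-neuron streams from the master seed with ``SeedSequence.spawn``, so
a fixed master seed yields bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trace_io import Trace


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class MiniTraceParams:
    """Generative settings for one minute-style mEPSC recording.

    Amplitudes follow a lognormal law parameterized by its median (pA)
    and log-scale sigma.  Defaults put <2% of the amplitude mass below
    the 7.5 pA detection threshold, so threshold truncation contributes
    negligible bias in recovery experiments.  Events are inward
    (downward) deflections, as for AMPA currents clamped at -80 mV, but
    ground-truth amplitudes are stored as positive magnitudes.
    """

    duration: float = 60.0          # s
    sampling_rate: float = 100_000.0  # Hz
    event_rate: float = 1.5         # events/s (Poisson)
    amp_median: float = 18.0        # pA
    amp_sigma: float = 0.40         # lognormal log-scale
    rise_tau: float = 1.0           # ms
    decay_tau: float = 8.0          # ms
    noise_sd: float = 2.0           # pA
    baseline: float = 0.0           # pA holding current offset
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("duration", "sampling_rate", "amp_median",
                     "rise_tau", "decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("event_rate", "amp_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")


@dataclass
class GroundTruth:
    """What was actually injected into a synthetic recording."""

    event_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    neuron_params: dict = field(default_factory=dict)
    burst_windows: dict = field(default_factory=dict)   # channel -> (n, 2) array, s
    burst_coincident: np.ndarray | None = None
    burst_amplitudes: dict = field(default_factory=dict)
    epoch_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_onsets = np.asarray(self.event_onsets, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if np.any(np.diff(self.event_onsets) < 0):
            raise ValueError("event onsets must be sorted")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("event amplitudes must be positive")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# mEPSC traces
# --------------------------------------------------------------------------

def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time-to-peak (ms) of the biexponential kernel."""
    return math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def mepsc_kernel(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials, ``t_ms >= 0`` in milliseconds."""
    tp = kernel_peak_time(rise_tau, decay_tau)
    norm = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    y = np.exp(-t_ms / decay_tau) - np.exp(-t_ms / rise_tau)
    return y / norm


def generate_mepsc_trace(
    params: MiniTraceParams,
    rng: np.random.Generator | None = None,
    events: Sequence[tuple[float, float]] | None = None,
) -> tuple[Trace, GroundTruth]:
    """Synthesize one voltage-clamp trace of miniature EPSCs.

    The trace is ``baseline + noise - sum of events``; each event is a
    unit-peak biexponential scaled by its drawn amplitude, so the
    extremum of an isolated event sits exactly ``amplitude`` below
    baseline.  Overlapping events sum; that is physiology, not an error.

    Parameters
    ----------
    events:
        Optional explicit ``(onset_s, amplitude_pA)`` pairs, bypassing
        the Poisson/lognormal draw (used to force exact fixtures).
    """
    rng = _rng(rng if rng is not None else params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))

    if events is None:
        n_ev = rng.poisson(params.event_rate * params.duration)
        onsets = np.sort(rng.uniform(0.0, params.duration, n_ev))
        amps = rng.lognormal(math.log(params.amp_median), params.amp_sigma, n_ev)
    else:
        pairs = sorted(events)
        onsets = np.array([p[0] for p in pairs], dtype=float)
        amps = np.array([p[1] for p in pairs], dtype=float)

    samples = np.full(n, params.baseline)
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, n)

    # kernel support capped at 10 decay time constants
    k_len = int(round(10 * params.decay_tau * 1e-3 * fs))
    t_ms = np.arange(k_len) / fs * 1e3
    kern = mepsc_kernel(t_ms, params.rise_tau, params.decay_tau)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        if i0 >= n:
            continue
        i1 = min(i0 + k_len, n)
        samples[i0:i1] -= amp * kern[: i1 - i0]

    trace = Trace(samples, fs, channel_role="vclamp_current",
                  metadata={"baseline_pA": params.baseline})
    truth = GroundTruth(event_onsets=onsets, event_amplitudes=amps)
    return trace, truth


def generate_scaled_cohorts(
    control: MiniTraceParams,
    factor: float,
    n_neurons: int,
    seed: int | None = None,
) -> tuple[list[tuple[Trace, GroundTruth]], list[tuple[Trace, GroundTruth]]]:
    """Generate a control cohort and a multiplicatively scaled cohort.

    The treated cohort is generated by the identical process except that
    every drawn amplitude is multiplied by ``factor`` before trace
    synthesis — the generative definition of multiplicative synaptic
    scaling.  Event times are independent between cohorts.
    """
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(2 * n_neurons)
    cohorts: list[list[tuple[Trace, GroundTruth]]] = [[], []]
    for g, amp_factor in enumerate((1.0, factor)):
        params = control if amp_factor == 1.0 else replace(
            control, amp_median=control.amp_median * amp_factor)
        for j in range(n_neurons):
            rng = np.random.default_rng(streams[g * n_neurons + j])
            trace, truth = generate_mepsc_trace(params, rng=rng)
            trace.metadata.update(
                neuron_id=f"{'ctrl' if g == 0 else 'treat'}{j:02d}",
                group="control" if g == 0 else "treated",
            )
            cohorts[g].append((trace, truth))
    return cohorts[0], cohorts[1]


# --------------------------------------------------------------------------
# current-clamp step families (leaky integrate-and-fire)
# --------------------------------------------------------------------------

@dataclass
class LIFParams:
    """Leaky integrate-and-fire neuron with an absolute refractory period.

    Chosen as the spiking model because its F-I curve has a closed form,
    f(I) = 1 / (t_ref + tau_m * ln(dV_inf / (dV_inf - dV_th))) above
    rheobase, giving an exact oracle for gain-recovery tests.
    """

    R_in: float = 150.0      # MOhm
    tau_m: float = 20.0      # ms
    V_rest: float = -60.0    # mV
    V_thresh: float = -30.0  # mV
    t_ref: float = 5.0       # ms
    spike_peak: float = 25.0  # mV, painted spike apex (>50 mV above threshold)

    def rheobase(self) -> float:
        """Smallest current (pA) that reaches threshold in steady state."""
        return (self.V_thresh - self.V_rest) / self.R_in * 1e3

    def analytic_rate(self, current_pA: float) -> float:
        """Steady-state firing rate (Hz) at a sustained current step."""
        dv_inf = current_pA * self.R_in * 1e-3  # mV
        dv_th = self.V_thresh - self.V_rest
        if dv_inf <= dv_th:
            return 0.0
        isi_ms = self.t_ref + self.tau_m * math.log(dv_inf / (dv_inf - dv_th))
        return 1e3 / isi_ms


def default_step_currents() -> np.ndarray:
    """The standard 24-step protocol: -150 pA to 1000 pA in 50 pA steps."""
    return np.arange(-150.0, 1000.0 + 1, 50.0)


def generate_fi_sweeps(
    neuron: LIFParams,
    steps: Sequence[float] | None = None,
    step_dur: float = 0.5,
    sampling_rate: float = 10_000.0,
    pre_dur: float = 0.2,
    post_dur: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Simulate a current-step family and return an excitability.StepFamily.

    Sub-threshold sweeps follow exact exponential charging toward
    ``V_rest + I*R_in``; supra-threshold sweeps paint a stereotyped
    one-sample spike to ``spike_peak`` followed by reset to rest and an
    absolute refractory hold.  Deterministic given the seed.
    """
    from .excitability import StepFamily

    if steps is None:
        steps = default_step_currents()
    steps = np.asarray(steps, dtype=float)
    if not np.all(np.isfinite(steps)):
        raise ValueError("step currents must be finite")
    if step_dur <= 0:
        raise ValueError("step_dur must be positive")
    rng = _rng(seed)
    fs = sampling_rate
    dt_ms = 1e3 / fs
    decay = math.exp(-dt_ms / neuron.tau_m)
    n_pre = int(round(pre_dur * fs))
    n_step = int(round(step_dur * fs))
    n_post = int(round(post_dur * fs))
    n_ref = max(1, int(round(neuron.t_ref / dt_ms)))

    sweeps = []
    for current in steps:
        v_inf = neuron.V_rest + current * neuron.R_in * 1e-3
        v = np.empty(n_pre + n_step + n_post)
        v[:n_pre] = neuron.V_rest
        vm = neuron.V_rest
        i = n_pre
        end_step = n_pre + n_step
        while i < end_step:
            vm = v_inf + (vm - v_inf) * decay
            if vm >= neuron.V_thresh:
                v[i] = neuron.spike_peak
                hold = min(n_ref, end_step - i - 1)
                v[i + 1: i + 1 + hold] = neuron.V_rest
                i += 1 + hold
                vm = neuron.V_rest
            else:
                v[i] = vm
                i += 1
        v[end_step:] = neuron.V_rest
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, v.size)
        trace = Trace(
            v, fs, channel_role="cclamp_voltage",
            metadata={"current_pA": float(current)},
        )
        sweeps.append((float(current), trace))

    return StepFamily(
        sweeps=sweeps,
        step_window=(pre_dur, pre_dur + step_dur),
        neuron_params=vars(neuron).copy(),
    )


# --------------------------------------------------------------------------
# two-channel integrated neurograms
# --------------------------------------------------------------------------

DEFAULT_EPOCH_EFFECTS = {
    "baseline": {"amplitude": 1.0, "frequency": 1.0},
    "drug": {"amplitude": 0.6, "frequency": 0.2},
    "washout": {"amplitude": 0.9, "frequency": 0.8},
}


def generate_neurogram(
    burst_rate: float = 10.0,          # bursts/min in baseline
    burst_dur: float = 1.0,            # s
    burst_amp: float = 5.0,            # integrated units above baseline
    channel_lag: float = 0.1,          # s, snii onset lead relative to cnx
    epochs: dict | None = None,        # name -> (start_s, end_s)
    epoch_effects: dict | None = None,  # name -> {amplitude, frequency}
    noise_sd: float = 0.05,
    baseline_level: float = 1.0,
    amp_jitter_sigma: float = 0.10,    # lognormal jitter on burst height
    sampling_rate: float = 50.0,
    solo_bursts_cnx: Sequence[float] = (),
    seed: int | None = None,
) -> tuple[Trace, Trace, GroundTruth]:
    """Synthesize paired integrated nerve-root traces with shared bursts.

    Both channels carry positive half-sine burst envelopes at shared
    event times (the snii channel offset by ``channel_lag``) over a
    noisy positive baseline, emulating fictive breaths recorded
    simultaneously from the vagal root and the hypoglossal nerve.
    Per-epoch amplitude and frequency multipliers model the drug
    response.  ``solo_bursts_cnx`` injects bursts on the cnx channel
    only; ground truth marks them non-coincident.
    """
    if not (0.1 <= burst_dur <= 5.0):
        raise ValueError("burst_dur out of plausible range")
    if epochs is None:
        epochs = {"baseline": (0.0, 600.0), "drug": (600.0, 1200.0),
                  "washout": (1200.0, 1800.0)}
    if epoch_effects is None:
        epoch_effects = DEFAULT_EPOCH_EFFECTS
    rng = _rng(seed)
    duration = max(end for _, end in epochs.values())
    fs = sampling_rate
    n = int(round(duration * fs))

    onsets: list[float] = []
    heights: list[float] = []
    min_gap = burst_dur + 1.5  # leave a clean pre-burst baseline second
    for name, (start, end) in epochs.items():
        eff = epoch_effects.get(name, {"amplitude": 1.0, "frequency": 1.0})
        rate_hz = burst_rate / 60.0 * eff["frequency"]
        if rate_hz > 0 and 1.0 / rate_hz <= min_gap:
            raise ValueError(
                f"epoch {name!r}: burst rate {rate_hz * 60:.1f}/min too high for "
                f"the {min_gap:.1f} s inter-burst refractory")
        t = start
        while True:
            if rate_hz <= 0:
                break
            # renewal gaps of mean exactly 1/rate: refractory + exponential tail,
            # so realized epoch frequency matches the configured multiplier
            t += min_gap + rng.exponential(1.0 / rate_hz - min_gap)
            if t + burst_dur > end:
                break
            onsets.append(t)
            heights.append(
                burst_amp * eff["amplitude"]
                * rng.lognormal(0.0, amp_jitter_sigma)
            )

    coincident = [True] * len(onsets)
    for t in solo_bursts_cnx:
        onsets.append(float(t))
        heights.append(burst_amp)
        coincident.append(False)
    order = np.argsort(onsets)
    onsets_a = np.asarray(onsets)[order]
    heights_a = np.asarray(heights)[order]
    coincident_a = np.asarray(coincident)[order]

    def paint(lagged: bool, shared_only: bool) -> np.ndarray:
        y = np.full(n, baseline_level)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd, n)
        for t, h, co in zip(onsets_a, heights_a, coincident_a):
            if shared_only and not co:
                continue
            start = t + (channel_lag if lagged else 0.0)
            i0 = int(round(start * fs))
            i1 = min(i0 + int(round(burst_dur * fs)), n)
            if i0 >= n:
                continue
            phase = np.arange(i1 - i0) / (burst_dur * fs)
            y[i0:i1] += h * np.sin(np.pi * phase)
        return np.clip(y, 0.0, None)

    cnx = Trace(paint(False, False), fs, channel_role="neurogram_cnx")
    snii = Trace(paint(True, True), fs, channel_role="neurogram_snii")

    windows_cnx = np.column_stack([onsets_a, onsets_a + burst_dur])
    windows_snii = windows_cnx[coincident_a] + channel_lag
    truth = GroundTruth(
        burst_windows={"cnx": windows_cnx, "snii": windows_snii},
        burst_coincident=coincident_a,
        burst_amplitudes={"cnx": heights_a},
        epoch_effects={k: dict(v) for k, v in epoch_effects.items()},
    )
    return cnx, snii, truth
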