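"""Respiratory burst analysis of two-channel integrated neurograms.

Fictive breaths are bursts of motoneuron population discharge recorded
from cut nerve roots of a rhythmic brainstem preparation.  A burst on
the vagal channel counts as respiratory only when it occurs
near-synchronously with a hypoglossal burst and lasts on the order of a
second — coactivation of both outflows is the signature of the
respiratory central pattern generator, distinguishing lung-related
bursts from other discharge.

Because absolute amplitudes from suction-electrode recordings are not
comparable across preparations, epoch comparisons are expressed as
percent of the baseline epoch only; this module provides no
cross-preparation absolute comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .detection import running_median
from .trace_io import Trace


@dataclass
class ConditioningConfig:
    """Raw-nerve-signal conditioning: band-pass, rectify, integrate."""

    band: tuple[float, float] = (100.0, 1000.0)  # Hz
    integrate_tau_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.integrate_tau_ms <= 0:
            raise ValueError("integrator time constant must be positive")
        if self.band[0] >= self.band[1] or self.band[0] <= 0:
            raise ValueError("invalid band")


@dataclass
class BurstConfig:
    k_mad_enter: float = 4.0     # threshold = baseline + k * MAD
    k_mad_exit: float = 2.0      # hysteresis exit level
    duration_range: tuple[float, float] = (0.3, 3.0)  # s, "~1 s" bursts
    coincidence_tol: float = 0.5  # s, "near-synchronous" window
    baseline_window_s: float = 60.0
    pre_baseline_s: float = 1.0  # metric baseline, mean of this much pre-onset


@dataclass
class Burst:
    channel: str
    onset: float        # s
    offset: float       # s
    amplitude: float    # integrated units, peak minus pre-onset baseline
    area: float         # units*s above baseline
    coincident: bool = False
    baseline_flagged: bool = False  # baseline estimated from a short prefix

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EpochSummary:
    epoch: str
    window: tuple[float, float]
    n_bursts: int
    frequency: float                 # bursts/min
    mean_amplitude: float | None
    mean_area: float | None
    percent_of_baseline: dict = field(default_factory=dict)
    flagged: bool = False


def leaky_integrate(x: np.ndarray, fs: float, tau_ms: float) -> np.ndarray:
    """First-order leaky integrator; unit step reaches 63.2% at one tau."""
    alpha = np.exp(-1e3 / (fs * tau_ms))
    return signal.lfilter([1 - alpha], [1, -alpha], x)


def condition_neurogram(raw: Trace, config: ConditioningConfig | None = None) -> Trace:
    """Band-pass, full-wave rectify, and integrate a raw nerve signal."""
    config = config or ConditioningConfig()
    fs = raw.sampling_rate
    if fs < 2000:
        raise ValueError("raw neurogram must be sampled at >= 2 kHz")
    if config.band[1] >= fs / 2:
        raise ValueError(f"band {config.band} exceeds Nyquist ({fs / 2} Hz)")
    sos = signal.butter(4, config.band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, raw.samples)  # causal, like the acquisition chain
    y = np.abs(y)
    y = leaky_integrate(y, fs, config.integrate_tau_ms)
    meta = dict(raw.metadata, integrated=True)
    return Trace(y, fs, channel_role=raw.channel_role, t0=raw.t0, metadata=meta)


def _channel_bursts(trace: Trace, config: BurstConfig) -> list[Burst]:
    x = trace.samples
    fs = trace.sampling_rate
    w = int(round(config.baseline_window_s * fs))
    base = running_median(x, w, max(1, w // 8))
    mad = float(np.median(np.abs(x - base)))
    if mad == 0:
        mad = max(1e-12, 1e-6 * float(np.max(np.abs(x)) or 1.0))
    enter = base + config.k_mad_enter * mad
    exit_ = base + config.k_mad_exit * mad

    above = x > enter
    if not np.any(above):
        return []
    starts = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    below_exit = x <= exit_
    bursts: list[Burst] = []
    last_end = -1
    for s in starts:
        if s <= last_end:
            continue
        # hysteresis: extend to the exit level on both sides
        pre = np.nonzero(below_exit[:s])[0]
        onset = pre[-1] + 1 if pre.size else 0
        post = np.nonzero(below_exit[s:])[0]
        end = s + post[0] if post.size else x.size
        last_end = end
        dur = (end - onset) / fs
        if not (config.duration_range[0] <= dur <= config.duration_range[1]):
            continue
        amp, area, flagged = burst_metrics(
            trace, trace.t0 + onset / fs, trace.t0 + end / fs,
            pre_baseline_s=config.pre_baseline_s)
        if amp <= 0:
            continue
        bursts.append(Burst(
            channel=trace.channel_role, onset=trace.t0 + onset / fs,
            offset=trace.t0 + end / fs, amplitude=amp, area=area,
            baseline_flagged=flagged))
    return bursts


def burst_metrics(trace: Trace, onset: float, offset: float,
                  pre_baseline_s: float = 1.0) -> tuple[float, float, bool]:
    """Amplitude and area of one burst window, relative to local baseline.

    Baseline = mean over the second preceding onset (a shorter prefix is
    used, and flagged, at the start of the trace).  Amplitude = maximum
    within the window minus baseline; area = integral of the
    baseline-subtracted trace over the window, negative excursions
    clipped at zero.  Both are invariant to adding any constant offset.
    """
    fs = trace.sampling_rate
    i0 = int(round((onset - trace.t0) * fs))
    i1 = int(round((offset - trace.t0) * fs))
    if i1 <= i0:
        raise ValueError("empty burst window")
    b0 = i0 - int(round(pre_baseline_s * fs))
    flagged = b0 < 0
    b0 = max(0, b0)
    if i0 == 0:
        raise ValueError("burst window starts at the very first sample")
    baseline = float(np.mean(trace.samples[b0:i0]))
    seg = trace.samples[i0:i1] - baseline
    amplitude = float(np.max(seg))
    area = float(np.trapezoid(np.clip(seg, 0.0, None)) / fs)
    return amplitude, area, flagged


def detect_bursts(cnx: Trace, snii: Trace, config: BurstConfig | None = None
                  ) -> list[Burst]:
    """Detect bursts on the vagal channel and classify by coincidence.

    Candidate bursts are supra-threshold excursions (adaptive threshold:
    rolling-median baseline + 4 MAD, hysteresis exit at +2 MAD) with
    duration inside ``duration_range``.  A cnx burst is ``coincident``
    — and hence respiratory — iff some snii burst onset lies within
    ``coincidence_tol`` of its onset.  Returns cnx bursts (all
    candidates, flagged); use :func:`respiratory_bursts` to keep only
    the coincident ones.
    """
    config = config or BurstConfig()
    t_lo = max(cnx.t0, snii.t0)
    t_hi = min(cnx.t0 + cnx.duration, snii.t0 + snii.duration)
    if t_hi <= t_lo:
        raise ValueError("cnx and snii traces do not overlap in time")
    cnx_bursts = _channel_bursts(cnx, config)
    snii_bursts = _channel_bursts(snii, config)
    snii_onsets = np.array([b.onset for b in snii_bursts])
    for b in cnx_bursts:
        b.coincident = bool(
            snii_onsets.size
            and np.min(np.abs(snii_onsets - b.onset)) <= config.coincidence_tol)
    return cnx_bursts


def respiratory_bursts(bursts) -> list[Burst]:
    """Only the coincident (respiratory) bursts."""
    return [b for b in bursts if b.coincident]


def epoch_compare(bursts, epochs: dict, baseline: str = "baseline"
                  ) -> list[EpochSummary]:
    """Per-epoch burst frequency / amplitude / area as percent of baseline.

    ``epochs`` maps epoch name to a ``(start_s, end_s)`` window; the
    baseline epoch must be present.  Metrics for the baseline epoch are
    100% of themselves by construction.  A baseline epoch with zero
    bursts leaves the percentages undefined (None) and flags every
    summary.
    """
    if baseline not in epochs:
        raise ValueError(f"baseline epoch {baseline!r} missing from epochs")
    summaries = []
    per_epoch = {}
    for name, (start, end) in epochs.items():
        inside = [b for b in bursts if start <= b.onset < end]
        minutes = (end - start) / 60.0
        per_epoch[name] = {
            "n": len(inside),
            "frequency": len(inside) / minutes,
            "amplitude": float(np.mean([b.amplitude for b in inside])) if inside else None,
            "area": float(np.mean([b.area for b in inside])) if inside else None,
        }
    ref = per_epoch[baseline]
    degenerate = ref["n"] == 0
    for name, (start, end) in epochs.items():
        cur = per_epoch[name]
        pct = {}
        for metric in ("frequency", "amplitude", "area"):
            if degenerate or cur[metric] is None or not ref[metric]:
                pct[metric] = None
            else:
                pct[metric] = 100.0 * cur[metric] / ref[metric]
        summaries.append(EpochSummary(
            epoch=name, window=(start, end), n_bursts=cur["n"],
            frequency=cur["frequency"], mean_amplitude=cur["amplitude"],
            mean_area=cur["area"], percent_of_baseline=pct,
            flagged=degenerate))
    return summaries
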