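"""Miniature EPSC detection and per-neuron quantification.

The detector is deliberately simple and certifiable: low-pass smooth,
subtract a running-median baseline, find inward peaks that exceed the
rejection threshold (default 7.5 pA, roughly twice the background noise
of the recordings this emulates), and backtrack each peak to its last
baseline crossing for the onset.  Rise time is onset-to-peak — note
this is NOT the 10-90% convention.  Events are reported as positive
amplitude magnitudes even though the underlying deflections are inward
(downward) at a -80 mV holding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .trace_io import Trace


class ChannelRoleError(ValueError):
    """Operation applied to a trace with the wrong channel role."""


@dataclass
class DetectionConfig:
    threshold: float = 7.5            # pA; events below are rejected
    baseline_window_ms: float = 200.0  # running-median window
    smoothing_cutoff_hz: float = 1000.0  # low-pass corner; None disables
    merge_refractory_ms: float = 5.0  # min peak separation
    polarity: str = "inward"
    # return-to-baseline tolerance, as a fraction of the event amplitude
    # (2.5% = 0.5 pA on a 20 pA event); relative so that charge scales
    # exactly linearly with the deflection
    charge_return_frac: float = 0.025
    charge_cap_ms: float = 100.0      # hard cap on the integration window
    onset_search_ms: float = 50.0     # how far back to look for the onset

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.polarity != "inward":
            raise ValueError("only inward (downward) events are supported")


@dataclass
class MiniEvent:
    """One detected miniature EPSC."""

    onset: float        # s
    peak_time: float    # s
    amplitude: float    # pA, baseline-to-peak magnitude
    charge: float       # pA*ms, integral of baseline-subtracted current
    rise_time: float    # ms, onset to peak
    overlapped: bool = False


@dataclass
class NeuronRecord:
    """Per-neuron summary metrics plus quality-control fields."""

    neuron_id: str = ""
    group: str = ""
    mean_amplitude: float | None = None   # pA
    mean_charge: float | None = None      # pA*ms
    frequency: float = 0.0                # events/min
    mean_rise_time: float | None = None   # ms
    n_events: int = 0
    no_events: bool = False
    R_in: float | None = None             # MOhm
    V_rest: float | None = None           # mV
    fi_gain: float | None = None          # Hz/pA
    ap_amplitude: float | None = None     # mV
    Rs_start: float | None = None         # MOhm
    Rs_end: float | None = None           # MOhm
    qc_pass: bool | None = None


def running_median(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Median over centered windows evaluated every ``step`` samples,
    linearly interpolated back to the full grid.  O(n * window / step)."""
    n = x.size
    window = max(3, min(window, n))
    step = max(1, step)
    centers = np.arange(0, n, step)
    med = np.empty(centers.size)
    half = window // 2
    for j, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(n, c + half)
        med[j] = np.median(x[lo:hi])
    return np.interp(np.arange(n), centers, med)


def _smooth(x: np.ndarray, fs: float, cutoff: float | None) -> np.ndarray:
    if cutoff is None or cutoff >= 0.45 * fs:
        return x
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_events(trace: Trace, config: DetectionConfig | None = None) -> list[MiniEvent]:
    """Detect mEPSCs in a voltage-clamp trace.

    Returns events sorted by onset; every reported amplitude is at or
    above ``config.threshold``.  An event whose onset does not return to
    baseline (it rides the decaying tail of the previous event) is
    measured from the local pre-event level and flagged ``overlapped``.
    """
    if trace.channel_role != "vclamp_current":
        raise ChannelRoleError(
            f"detect_events needs a vclamp_current trace, got {trace.channel_role}")
    if trace.duration < 1.0:
        raise ValueError("trace shorter than 1 s; record at least one second")
    config = config or DetectionConfig()
    fs = trace.sampling_rate
    dt = trace.dt

    smoothed = _smooth(trace.samples, fs, config.smoothing_cutoff_hz)
    w = int(round(config.baseline_window_ms * 1e-3 * fs))
    baseline = running_median(smoothed, w, max(1, w // 4))
    # dev is positive where the current deflects inward (downward)
    dev = baseline - smoothed

    distance = max(1, int(round(config.merge_refractory_ms * 1e-3 * fs)))
    peaks, _ = signal.find_peaks(dev, height=config.threshold, distance=distance)

    search = int(round(config.onset_search_ms * 1e-3 * fs))
    cap = int(round(config.charge_cap_ms * 1e-3 * fs))
    events: list[MiniEvent] = []
    prev_peak = -1
    for p in peaks:
        lo = max(0, p - search)
        if prev_peak >= 0:
            lo = max(lo, prev_peak)
        seg = dev[lo:p]
        below = np.nonzero(seg <= 0)[0]
        if below.size:
            onset = lo + below[-1]
            local = 0.0
            overlapped = False
        else:
            onset = lo + int(np.argmin(seg)) if seg.size else p
            local = max(dev[onset], 0.0)
            overlapped = True
        amplitude = dev[p] - local
        if amplitude < config.threshold:
            prev_peak = p
            continue
        # charge: integrate until first return within charge_return_frac of
        # the local baseline level, capped
        hi = min(dev.size, onset + cap)
        tail = dev[p:hi]
        back = np.nonzero(tail <= local + config.charge_return_frac * amplitude)[0]
        end = p + back[0] if back.size else hi
        window = dev[onset:end + 1] - local
        charge = float(np.trapezoid(np.clip(window, 0.0, None)) * dt * 1e3)
        events.append(MiniEvent(
            onset=trace.t0 + onset * dt,
            peak_time=trace.t0 + p * dt,
            amplitude=float(amplitude),
            charge=charge,
            rise_time=float((p - onset) * dt * 1e3),
            overlapped=overlapped,
        ))
        prev_peak = p
    return events


def summarize_neuron(
    events: Sequence[MiniEvent],
    window: float = 60.0,
    record: NeuronRecord | None = None,
) -> NeuronRecord:
    """Average event metrics over an analysis window (default 1 min).

    Frequency is reported per minute regardless of the window length.
    With zero events the means are undefined (left as None and flagged);
    this is a valid outcome, not an error.
    """
    record = replace(record) if record is not None else NeuronRecord()
    t_start = min((e.onset for e in events), default=0.0)
    inside = [e for e in events if e.onset <= t_start + window]
    record.n_events = len(inside)
    record.frequency = len(inside) / (window / 60.0)
    if inside:
        record.mean_amplitude = float(np.mean([e.amplitude for e in inside]))
        record.mean_charge = float(np.mean([e.charge for e in inside]))
        record.mean_rise_time = float(np.mean([e.rise_time for e in inside]))
        record.no_events = False
    else:
        record.no_events = True
    return record


@dataclass
class FirstN:
    amplitudes: np.ndarray
    shortfall: bool

    def __iter__(self):
        return iter((self.amplitudes, self.shortfall))


def first_n_amplitudes(events: Sequence[MiniEvent], n: int = 50) -> FirstN:
    """Amplitudes of the earliest ``n`` events by onset.

    Mirrors the sampling convention of rank-order analyses that pool an
    equal event count per neuron.  If fewer than ``n`` events exist all
    are returned with ``shortfall=True``.
    """
    ordered = sorted(events, key=lambda e: e.onset)
    amps = np.array([e.amplitude for e in ordered[:n]], dtype=float)
    return FirstN(amps, shortfall=len(ordered) < n)


@dataclass
class QCResult:
    status: str                 # "pass" | "fail" | "incomplete"
    reasons: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.status == "pass"


#: recording-quality limits: resting potential, action-potential height,
#: absolute series resistance, and relative series-resistance drift
QC_V_REST_MAX = -45.0      # mV, must be more negative
QC_AP_MIN = 50.0           # mV
QC_RS_MAX = 25.0           # MOhm
QC_RS_DRIFT_MAX = 0.20     # fraction


def qc_filter(record: NeuronRecord) -> QCResult:
    """Apply the recording quality criteria and enumerate failures."""
    required = {
        "V_rest": record.V_rest,
        "ap_amplitude": record.ap_amplitude,
        "Rs_start": record.Rs_start,
        "Rs_end": record.Rs_end,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        record.qc_pass = None
        return QCResult("incomplete", [f"missing:{k}" for k in missing])
    reasons = []
    if not record.V_rest < QC_V_REST_MAX:
        reasons.append("v_rest_depolarized")
    if not record.ap_amplitude > QC_AP_MIN:
        reasons.append("ap_small")
    if record.Rs_end > QC_RS_MAX:
        reasons.append("rs_high")
    if abs(record.Rs_end - record.Rs_start) / record.Rs_start > QC_RS_DRIFT_MAX:
        reasons.append("rs_drift")
    record.qc_pass = not reasons
    return QCResult("pass" if not reasons else "fail", reasons)
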