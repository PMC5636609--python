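"""Rank-order analysis of multiplicative synaptic scaling.

Under homeostatic synaptic scaling every measurable excitatory synapse
changes strength by a common multiplicative factor.  On a rank-order
plot — equal-count quantile pairing of two mEPSC amplitude
distributions sorted ascending — pure multiplicative scaling appears as
a straight line whose slope IS the scaling factor, whereas
synapse-specific potentiation (LTP-like plasticity) bends the relation
toward an exponential.  The procedure implemented here:

1. pool an equal number of amplitudes per neuron from each group,
2. rank order and pair by index,
3. fit both a linear and an exponential model and compare fits,
4. down-scale the treated distribution by the fitted slope, dropping
   scaled values that fall below the detection threshold (they cannot
   appear in the control distribution and would bias the comparison),
5. compare raw and down-scaled distributions to control with
   two-sample Kolmogorov-Smirnov tests (exact p for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats


class FitError(ValueError):
    """Degenerate input makes the requested regression undefined."""


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float


@dataclass
class ExponentialFit:
    a: float
    b: float
    r2: float
    converged: bool = True
    message: str = ""


@dataclass
class KSResult:
    D: float
    p: float
    mode_used: str


@dataclass
class RankOrderResult:
    ranked_control: np.ndarray
    ranked_treated: np.ndarray
    linear: LinearFit
    exponential: ExponentialFit
    n_points: int

    @property
    def scaling_factor(self) -> float:
        """The multiplicative scaling factor = slope of the linear fit."""
        return self.linear.slope


@dataclass
class ScalingVerdict:
    ks_raw: KSResult
    ks_downscaled: KSResult
    n_excluded_below_threshold: int
    multiplicative: bool
    alpha: float = 0.05


@dataclass
class ScalingConfig:
    n_per_neuron: int = 50
    threshold: float = 7.5   # pA detection floor
    alpha: float = 0.05
    ks_mode: str = "auto"
    # default: only the down-scaled treated distribution is filtered at
    # the threshold.  The alternative convention also truncates the
    # CONTROL distribution for the down-scaled comparison, making both
    # sides of the KS test subject to the same floor.
    truncate_control: bool = False


def rank_order(control_amps, treated_amps) -> tuple[np.ndarray, np.ndarray]:
    """Sort both amplitude sets ascending and pair them by rank index.

    Lengths must match exactly; equal-count sampling (e.g. first 50
    events per neuron) is the caller's job and is never done silently
    here.  Ties keep their original order (stable sort) — irrelevant to
    any fit, but documented for reproducibility.
    """
    a = np.asarray(control_amps, dtype=float)
    b = np.asarray(treated_amps, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("amplitude lists must be non-empty")
    if a.size != b.size:
        raise ValueError(
            f"rank_order requires equal lengths, got {a.size} vs {b.size}")
    return np.sort(a, kind="stable"), np.sort(b, kind="stable")


def fit_rank_linear(ranked_control, ranked_treated) -> LinearFit:
    """Ordinary least squares of treated (y) on control (x).

    A slope above 1 means up-scaling.  The intercept is fitted freely;
    under pure multiplicative scaling it should land near zero.
    """
    x = np.asarray(ranked_control, dtype=float)
    y = np.asarray(ranked_treated, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 rank pairs")
    if np.ptp(x) == 0:
        raise FitError("control amplitudes have zero variance")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue ** 2))


def fit_rank_exponential(ranked_control, ranked_treated) -> ExponentialFit:
    """Nonlinear least squares of ``y = a * exp(b * x)``.

    Initialized from the log-linear fit ``ln y = ln a + b x`` (valid
    because amplitudes are positive); r^2 is computed on the original
    scale so it is directly comparable with the linear fit's.
    Non-convergence is reported in the result, not raised.
    """
    x = np.asarray(ranked_control, dtype=float)
    y = np.asarray(ranked_treated, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 rank pairs")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive amplitudes")
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y,
            p0=(np.exp(loga0), b0), maxfev=10_000)
    except RuntimeError as err:
        return ExponentialFit(a=float(np.exp(loga0)), b=float(b0), r2=float("nan"),
                              converged=False, message=str(err))
    a, b = popt
    resid = y - a * np.exp(b * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ExponentialFit(a=float(a), b=float(b), r2=r2)


def downscale(treated_amps, factor: float, threshold: float = 7.5
              ) -> tuple[np.ndarray, int]:
    """Divide amplitudes by the scaling factor, dropping sub-threshold values.

    Scaled values below the detection floor cannot be present in the
    control distribution, so keeping them would bias the distribution
    comparison; they are removed and counted.
    """
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    scaled = np.asarray(treated_amps, dtype=float) / factor
    keep = scaled >= threshold
    return scaled[keep], int(np.sum(~keep))


def ks_compare(a, b, mode: str = "auto") -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison.

    ``D = sup |ECDF_a - ECDF_b|``.  Under ``auto``, the exact p-value is
    used when ``n_a * n_b <= 10_000`` and the asymptotic approximation
    otherwise; the mode actually used is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires non-empty samples")
    if mode not in ("exact", "asymptotic", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        used = "exact" if a.size * b.size <= 10_000 else "asymptotic"
    else:
        used = mode
    method = {"exact": "exact", "asymptotic": "asymp"}[used]
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(D=float(res.statistic), p=float(res.pvalue), mode_used=used)


def scaling_pipeline(
    control_amps_by_neuron: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    treated_amps_by_neuron: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    config: ScalingConfig | None = None,
) -> tuple[RankOrderResult, ScalingVerdict]:
    """Run the full rank-order scaling procedure on per-neuron amplitudes.

    Each neuron contributes its first ``n_per_neuron`` amplitudes (the
    inputs are assumed time-ordered); pooled counts must end up equal
    between groups.  The verdict's ``multiplicative`` flag is true iff
    the linear fit beats the exponential fit AND the raw distributions
    differ (KS p < alpha) AND the down-scaled treated distribution is
    indistinguishable from control (KS p >= alpha).
    """
    config = config or ScalingConfig()

    def pool(groups) -> np.ndarray:
        lists = groups.values() if isinstance(groups, Mapping) else groups
        return np.concatenate([
            np.asarray(v, dtype=float)[: config.n_per_neuron] for v in lists])

    control = pool(control_amps_by_neuron)
    treated = pool(treated_amps_by_neuron)
    if control.size != treated.size:
        raise ValueError(
            f"pooled counts differ ({control.size} vs {treated.size}); "
            "equal-count sampling per neuron is required")

    xc, yt = rank_order(control, treated)
    lin = fit_rank_linear(xc, yt)
    expo = fit_rank_exponential(xc, yt)
    result = RankOrderResult(ranked_control=xc, ranked_treated=yt,
                             linear=lin, exponential=expo, n_points=xc.size)

    scaled, n_excl = downscale(treated, lin.slope, config.threshold)
    ks_raw = ks_compare(control, treated, config.ks_mode)
    control_for_down = (control[control >= config.threshold]
                        if config.truncate_control else control)
    ks_down = ks_compare(control_for_down, scaled, config.ks_mode)
    # a failed exponential fit cannot beat the linear one
    linear_wins = np.isnan(expo.r2) or lin.r2 > expo.r2
    verdict = ScalingVerdict(
        ks_raw=ks_raw,
        ks_downscaled=ks_down,
        n_excluded_below_threshold=n_excl,
        multiplicative=bool(linear_wins and ks_raw.p < config.alpha
                            and ks_down.p >= config.alpha),
        alpha=config.alpha,
    )
    return result, verdict
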