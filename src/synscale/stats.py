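"""Group-comparison statistics used across the pipeline.

Thin, explicit wrappers around scipy/statsmodels that pin down the
conventions this package reports: two-tailed p-values, explicit
Welch-vs-Student choice (never silently automatic), exact small-sample
Mann-Whitney, and the homogeneity-of-slopes ANCOVA formulated as the
interaction term of ``y ~ x * group``.  No multiple-testing correction
is applied anywhere; results are reported per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple | None
    p: float
    tails: int = 2
    n: tuple = ()
    notes: str = ""


def _arr(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def unpaired_t(a, b, welch: bool | str = False) -> TestResult:
    """Two-tailed unpaired t test; Welch's correction on request.

    ``welch`` may also be ``"auto"``: apply the correction when a
    two-sided F test of the variance ratio rejects equality at 0.05.
    Auto is never a default anywhere in the package — the choice is
    recorded so analyses stay reproducible.  With equal group sizes and
    equal variances the Welch statistic coincides with Student's.  Two
    zero-variance groups with equal means are reported as t=0, p=1 by
    convention.
    """
    a, b = _arr(a), _arr(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    auto_note = ""
    if welch == "auto":
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va > 0 and vb > 0:
            f = va / vb
            p_var = 2 * min(sps.f.cdf(f, a.size - 1, b.size - 1),
                            sps.f.sf(f, a.size - 1, b.size - 1))
            welch = p_var < 0.05
        else:
            welch = va != vb
        auto_note = f"; auto variance check chose {'Welch' if welch else 'Student'}"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t" if welch else "student_t", 0.0,
                              float(a.size + b.size - 2), 1.0,
                              n=(a.size, b.size),
                              notes="zero variance in both groups, equal means")
        return TestResult("welch_t" if welch else "student_t", float("inf"),
                          float(a.size + b.size - 2), 0.0, n=(a.size, b.size),
                          notes="zero variance in both groups, unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        name="welch_t" if welch else "student_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=(a.size, b.size),
        notes=("Welch-Satterthwaite df" if welch else "pooled-variance df")
        + auto_note,
    )


#: per-group size at or below which the exact Mann-Whitney null is used
MW_EXACT_MAX_N = 8


def mann_whitney(a, b) -> TestResult:
    """Two-tailed Mann-Whitney U test on ranked data.

    Exact p when both groups have at most 8 observations and no ties
    span the groups; otherwise the normal approximation with tie and
    continuity corrections.  The mode used is recorded in ``notes``.
    """
    a, b = _arr(a), _arr(b)
    if a.size < 1 or b.size < 1:
        raise ValueError("need n >= 1 per group")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = max(a.size, b.size) <= MW_EXACT_MAX_N and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(
        name="mann_whitney",
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        n=(a.size, b.size),
        notes="exact" if exact else "normal approximation, tie-corrected",
    )


def paired_t(before, after) -> TestResult:
    """Two-tailed paired t test on the within-pair differences."""
    before, after = _arr(before), _arr(after)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("need at least two pairs")
    d = after - before
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult("paired_t", 0.0, float(n - 1), 1.0, n=(n,),
                              notes="all differences zero")
        return TestResult("paired_t", float("inf") * np.sign(d.mean()),
                          float(n - 1), float("nan"), n=(n,),
                          notes="degenerate: zero-variance nonzero differences")
    res = sps.ttest_rel(after, before)
    return TestResult("paired_t", float(res.statistic), float(n - 1),
                      float(res.pvalue), n=(n,))


def ancova_slopes(groups: dict) -> TestResult:
    """Homogeneity-of-slopes ANCOVA across two or more groups.

    ``groups`` maps a label to a list of per-neuron ``(x, y)`` series;
    all points are pooled into the linear model
    ``y ~ x + group + x:group`` and the slope difference is read from
    the F test of the interaction term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    for label, series in groups.items():
        if len(series) < 2:
            raise ValueError(f"group {label!r} needs at least two series")
        for x, y in series:
            x, y = _arr(x), _arr(y)
            rows.append(pd.DataFrame({"x": x, "y": y, "group": label}))
    df = pd.concat(rows, ignore_index=True)
    if df["x"].nunique() < 2:
        raise ValueError("covariate has no variation; singular design")
    model = smf.ols("y ~ x * C(group)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("collinear design matrix")
    table = anova_lm(model, typ=2)
    inter = table.loc["x:C(group)"]
    return TestResult(
        name="ancova_interaction",
        statistic=float(inter["F"]),
        df=(float(inter["df"]), float(table.loc["Residual", "df"])),
        p=float(inter["PR(>F)"]),
        n=tuple(int(np.sum(df["group"] == g)) for g in groups),
        notes="F test of x:group interaction in y ~ x * group",
    )
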