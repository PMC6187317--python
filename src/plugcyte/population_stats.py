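"""Population dispersion statistics and one-way ANOVA.

Per-population summaries report the sample mean, the n-1 standard deviation,
the coefficient of variation CV = sd/mean, type-7 (linearly interpolated)
quartiles, and the quartile coefficient of dispersion
QCD = (Q3 - Q1)/(Q3 + Q1) — a robust relative-spread measure well suited to
right-skewed copy-number distributions.  The one-way ANOVA F statistic is
computed from explicit between/within sums of squares, with the p-value from
the upper tail of the F distribution and the field's significance convention
of p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import SummaryStats

__all__ = ["summarize", "anova_oneway", "AnovaResult", "P_SIGNIFICANT"]

#: Significance threshold used throughout (the "*" convention).
P_SIGNIFICANT = 0.01


def summarize(values, quantile_method: str = "linear") -> SummaryStats:
    """Summary statistics for one population of positive values.

    Requires at least 4 observations; all values must be strictly positive
    so that the QCD is well defined.  ``quantile_method`` is passed to
    ``numpy.quantile`` (default "linear" = classical type-7).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.any(x <= 0):
        raise ValueError("values must be strictly positive for the QCD")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    q1, q2, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75],
                                                method=quantile_method))
    return SummaryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv=sd / mean,
        q1=q1, q2=q2, q3=q3,
        qcd=(q3 - q1) / (q3 + q1),
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < P_SIGNIFICANT


def anova_oneway(groups: list) -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    ``groups`` is a list of >= 2 samples, each with >= 2 observations.
    ``F = (SSB/df_b) / (SSW/df_w)``; when every group is constant and the
    means coincide (0/0), F is defined as 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)
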