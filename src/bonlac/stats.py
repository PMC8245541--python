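"""Validation statistics: blot normalization, pooled t-tests, OLS regression.

Western-blot band densities are normalized in-lane to total protein and
expressed relative to the wild-type mean within each blot, so values are
comparable across blots. Group comparisons use the Student pooled-variance
two-sample t-test (df = n1 + n2 − 2) reported figure-legend style: t, df,
two-tailed p, 95% CI of the mean difference, and the effect as the
difference of group means ± its standard error. The de novo vs. total
protein relationship is summarized by ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "RegressionResult",
    "StatsError",
    "normalize_blot",
    "unpaired_t_test",
    "p_from_t",
    "format_p",
    "linear_regression",
]

#: reported in place of p when both groups are constant but unequal
P_FLOOR = 1e-300


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t-test reported figure-legend style.

    ``effect`` is mean(b) − mean(a) and ``t`` carries its sign, so that
    calling with (control, affected) reports the affected-relative-to-control
    shift. ``degenerate`` flags the both-groups-constant-but-unequal case,
    where p is reported at a floor.
    """

    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    effect: float
    effect_se: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "p_formatted": format_p(self.p),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "effect": self.effect,
            "effect_se": self.effect_se,
        }


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p": self.p,
            "p_formatted": format_p(self.p),
        }


def normalize_blot(table: pd.DataFrame) -> pd.Series:
    """Per-lane relative expression from a blot table.

    ``table`` needs columns ``lane_id``, ``group`` (``WT``/``TG``),
    ``band_density``, ``total_density`` and ``blot_id``. Within each blot,
    the lane's band density is divided by its total-protein density and then
    by the mean of that quantity over the blot's WT lanes, so the WT group
    mean is exactly 1 and values are comparable across blots.
    """
    required = {"lane_id", "group", "band_density", "total_density", "blot_id"}
    if not required.issubset(table.columns):
        raise StatsError(f"blot table needs columns {sorted(required)}")
    if (table["total_density"] <= 0).any():
        raise StatsError("total-protein densities must be positive")
    if (table["band_density"] <= 0).any():
        raise StatsError("band densities must be positive")

    out = pd.Series(np.nan, index=table.index, name="relative_expression")
    for _, blot in table.groupby("blot_id"):
        in_lane = blot["band_density"] / blot["total_density"]
        wt = in_lane[blot["group"] == "WT"]
        if len(wt) == 0:
            raise StatsError("each blot needs at least one WT lane")
        out.loc[blot.index] = in_lane / wt.mean()
    return out


def unpaired_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Student's pooled-variance two-sample t-test of b against a.

    The effect (and the sign of t) is mean(b) − mean(a); the 95% CI comes
    from the pooled standard error and the central-t quantile at
    n1 + n2 − 2 degrees of freedom. Two constant equal groups give t = 0,
    p = 1; two constant unequal groups are degenerate and report p at a
    floor with the ``degenerate`` flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("groups must be finite")

    n1, n2 = a.size, b.size
    df = int(n1 + n2 - 2)
    diff = float(b.mean() - a.mean())
    pooled_var = (
        (n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)
    ) / df
    se = math.sqrt(pooled_var * (1 / n1 + 1 / n2))

    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0, 0.0, 0.0, 0.0)
        t = math.copysign(math.inf, diff)
        return TTestResult(t, df, P_FLOOR, diff, diff, diff, 0.0, degenerate=True)

    t = diff / se
    p = p_from_t(t, df)
    tq = float(sps.t.ppf(0.975, df))
    return TTestResult(
        t=t,
        df=df,
        p=p,
        ci_low=diff - tq * se,
        ci_high=diff + tq * se,
        effect=diff,
        effect_se=se,
    )


def p_from_t(t: float, df: float) -> float:
    """Two-tailed p under the central t distribution: 2 · P(T ≥ |t|)."""
    if not math.isfinite(t):
        raise StatsError("t must be finite")
    if df < 1:
        raise StatsError(f"df must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def format_p(p: float) -> str:
    """Legend-style p: half-up to 4 decimals; below 0.0001 as '< 0.0001'."""
    if not 0 <= p <= 1:
        raise StatsError(f"p must be in [0, 1], got {p}")
    if p < 0.0001:
        return "< 0.0001"
    return str(Decimal(repr(p)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of y on x with the slope's two-tailed p.

    r² = 1 − SSres/SStot; the p-value tests a zero slope with n − 2 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must be the same length")
    if x.size < 3:
        raise StatsError("need at least 3 paired points")
    if np.var(x) == 0:
        raise StatsError("x has zero variance")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
    )
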