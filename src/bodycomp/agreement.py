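"""Method-comparison battery and multi-metric ranking of predictors.

Every comparison is between a reference series (deuterium dilution) and a
predicted series, with differences taken as reference - predicted
throughout. The battery covers Bland-Altman bias and 1.96*sd limits of
agreement with a proportional-bias regression, Pearson and Lin concordance
correlations, Cohen's d for paired samples, Passing-Bablok structural
regression with its residual SD, the median absolute percentage error
(MAPE), the minimum symmetric TOST equivalence bound (% of the grand mean),
and the range-normalized Gower similarity index. Equations are ranked by
mean rank over MAPE (ascending), TOST bound (ascending) and Gower
(descending).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "lin_ccc",
    "cohens_d_paired",
    "passing_bablok",
    "mape",
    "tost_min_equivalence",
    "gower_index",
    "compare_arrays",
    "compare_method",
    "rank_equations",
    "LOA_MULTIPLIER",
]

#: Limits-of-agreement multiplier (1.96, the 95% Gaussian quantile).
LOA_MULTIPLIER = 1.96

_PB_MIN_N = 10


@dataclass(frozen=True)
class AgreementReport:
    """Full comparison battery between a predictor and the reference."""

    label: str
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    lin_ccc: float
    cohen_d_paired: Optional[float]
    paired_t_p: Optional[float]
    pb_slope: Optional[float]
    pb_intercept: Optional[float]
    pb_rsd: Optional[float]
    mape_pct: float
    tost_bound_pct: float
    gower: float
    prop_bias_slope: float
    prop_bias_p: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(**d)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    return x, y


def bland_altman(reference, predicted
                 ) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Bland-Altman analysis of reference - predicted differences.

    Returns (bias, sd_diff, (loa_low, loa_high), (prop_slope, prop_p)),
    where the proportional-bias term is the slope of the differences on the
    pair means with its t-test p-value.
    """
    ref, pred = _paired(reference, predicted)
    if len(ref) < 3:
        raise ValueError("need at least 3 pairs")
    d = ref - pred
    means = (ref + pred) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)
    if sd == 0 or means.std(ddof=1) == 0:
        slope, p = 0.0, 1.0
    else:
        res = stats.linregress(means, d)
        slope, p = float(res.slope), float(res.pvalue)
    return bias, sd, loa, (slope, p)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation, population (1/n) moments.

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2); agreement with
    the identity line, bounded by the Pearson correlation in magnitude.
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("constant input")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def cohens_d_paired(x, y) -> float:
    """Cohen's d for paired samples: mean(x-y)/sd(x-y)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    return float(d.mean() / sd)


def passing_bablok(x, y) -> tuple[float, float, float]:
    """Passing-Bablok structural regression of y on x.

    The slope is the shifted median of all pairwise slopes (slopes equal to
    -1 are discarded; the median index is offset by the count of slopes
    below -1, per the original procedure), the intercept is
    median(y - slope*x), and the residual SD is the sample SD of the
    vertical residuals y - (intercept + slope*x).
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < _PB_MIN_N:
        raise ValueError(f"need at least {_PB_MIN_N} pairs")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    slopes = []
    for a, b in zip(dx, dy):
        if a == 0:
            if b == 0:
                continue  # identical points carry no slope information
            slopes.append(math.inf if b > 0 else -math.inf)
        else:
            s = b / a
            if s != -1.0:
                slopes.append(s)
    if len(slopes) < 1:
        raise ValueError("too few distinct pairs")
    slopes = np.sort(np.asarray(slopes, dtype=float))
    N = len(slopes)
    K = int(np.sum(slopes < -1.0))
    if N % 2 == 1:
        b = slopes[(N + 1) // 2 + K - 1]
    else:
        b = 0.5 * (slopes[N // 2 + K - 1] + slopes[N // 2 + K])
    a = float(np.median(y - b * x))
    resid = y - (a + b * x)
    rsd = float(resid.std(ddof=1))
    return float(b), a, rsd


def mape(reference, predicted) -> float:
    """Median absolute percentage error, in percent of the reference."""
    ref, pred = _paired(reference, predicted)
    if np.any(ref == 0):
        raise ValueError("reference contains zero entries")
    return float(np.median(100.0 * np.abs(ref - pred) / np.abs(ref)))


def tost_min_equivalence(x, y, alpha: float = 0.05,
                         resolution_pct: float = 0.01) -> float:
    """Minimum symmetric TOST equivalence bound, % of the grand mean.

    Bisects for the smallest delta (expressed as a percentage of the mean
    of all values of x and y) such that both one-sided paired t tests
    against +/-delta reject at ``alpha``. The closed-form limit is
    |mean difference| + t_crit * SE.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    dbar = d.mean()
    se = d.std(ddof=1) / math.sqrt(n)
    gm = float(np.mean(np.concatenate([x, y])))
    if gm == 0:
        raise ValueError("grand mean is zero")
    if se == 0:
        return abs(dbar) / abs(gm) * 100.0
    tcrit = stats.t.ppf(1 - alpha, n - 1)

    def equivalent(delta_pct: float) -> bool:
        delta = delta_pct / 100.0 * abs(gm)
        t_lower = (dbar + delta) / se
        t_upper = (delta - dbar) / se
        return t_lower >= tcrit and t_upper >= tcrit

    lo = 0.0
    hi = (abs(dbar) + tcrit * se) / abs(gm) * 100.0 * 2.0 + 1.0
    while not equivalent(hi):
        hi *= 2.0
    while hi - lo > resolution_pct:
        mid = (lo + hi) / 2.0
        if equivalent(mid):
            hi = mid
        else:
            lo = mid
    return hi


def gower_index(x, y) -> float:
    """Range-normalized similarity: 1 - mean|x-y| / pooled range, in [0,1]."""
    x, y = _paired(x, y)
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    pooled = np.concatenate([x, y])
    rng = float(pooled.max() - pooled.min())
    if rng == 0:
        raise ValueError("zero pooled range")
    g = 1.0 - float(np.mean(np.abs(x - y))) / rng
    return min(max(g, 0.0), 1.0)


def compare_arrays(reference, predicted, label: str = "") -> AgreementReport:
    """Full agreement battery between two paired series."""
    ref, pred = _paired(reference, predicted)
    bias, sd, loa, (pb_slope_d, pb_p_d) = bland_altman(ref, pred)
    d = ref - pred
    if sd > 0:
        t_p = float(stats.ttest_rel(ref, pred).pvalue)
        cohen = float(d.mean() / sd)
    else:
        t_p = None
        cohen = None
    if ref.std() > 0 and pred.std() > 0:
        pearson = float(stats.pearsonr(ref, pred).statistic)
        ccc = lin_ccc(ref, pred)
    else:
        pearson = 1.0 if sd == 0 else 0.0
        ccc = 1.0 if (sd == 0 and bias == 0) else 0.0
    if len(ref) >= _PB_MIN_N:
        slope, intercept, rsd = passing_bablok(pred, ref)
    else:
        warnings.warn(f"{label or 'comparison'}: fewer than {_PB_MIN_N} "
                      "pairs; Passing-Bablok omitted")
        slope = intercept = rsd = None
    return AgreementReport(
        label=label, n=len(ref), bias=bias, sd_diff=sd,
        loa_low=loa[0], loa_high=loa[1], pearson_r=pearson, lin_ccc=ccc,
        cohen_d_paired=cohen, paired_t_p=t_p,
        pb_slope=slope, pb_intercept=intercept, pb_rsd=rsd,
        mape_pct=mape(ref, pred),
        tost_bound_pct=tost_min_equivalence(ref, pred),
        gower=gower_index(ref, pred),
        prop_bias_slope=pb_slope_d, prop_bias_p=pb_p_d)


_QUANTITIES = ("tbw_l", "ffm_kg", "fm_kg", "pbf")


def compare_method(reference_composition: Sequence,
                   predicted_composition: Sequence,
                   quantity: str = "ffm_kg",
                   label: str = "") -> AgreementReport:
    """Agreement battery on one body-composition quantity.

    ``quantity`` selects the field compared (tbw_l, ffm_kg, fm_kg or pbf);
    the series must be matched subject-for-subject.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}")
    if len(reference_composition) != len(predicted_composition):
        raise ValueError("mismatched subject counts")
    ref = np.array([getattr(c, quantity) for c in reference_composition])
    pred = np.array([getattr(c, quantity) for c in predicted_composition])
    return compare_arrays(ref, pred, label=label or quantity)


def rank_equations(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Combined ranking: MAPE asc, TOST bound asc, Gower desc, mean rank.

    Ties in the combined rank break by MAPE then label. Input order does
    not affect the result.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to rank")
    df = pd.DataFrame({
        "eq_id": [r.label for r in reports],
        "mape_pct": [r.mape_pct for r in reports],
        "tost_bound_pct": [r.tost_bound_pct for r in reports],
        "gower": [r.gower for r in reports],
    })
    df["rank_mape"] = stats.rankdata(df["mape_pct"])
    df["rank_tost"] = stats.rankdata(df["tost_bound_pct"])
    df["rank_gower"] = stats.rankdata(-df["gower"].to_numpy())
    df["mean_rank"] = df[["rank_mape", "rank_tost", "rank_gower"]].mean(axis=1)
    df = df.sort_values(["mean_rank", "mape_pct", "eq_id"],
                        kind="mergesort").reset_index(drop=True)
    df["overall_rank"] = np.arange(1, len(df) + 1)
    return df
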