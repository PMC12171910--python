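"""Equation development: regression, diagnostics, double cross-validation.

Implements the development protocol used for both predictor families:
ordinary least squares with the full diagnostic set (SE of estimate as
sqrt(MSE), R^2, Gaussian AIC, Mallows' Cp, PRESS via the hat matrix, VIF
from auxiliary regressions), stepwise selection with alpha-to-enter /
alpha-to-remove, a randomized sex-stratified 50:50 split, double
cross-validation with a covariance-analysis homogeneity test of the
reference-vs-predicted slopes and intercepts, pooling when homogeneous with
leave-one-out error, plus Kolmogorov-Smirnov normality and generalized ESD
outlier screens.

Diagnostics are computed from first principles (hat matrix, auxiliary R^2)
rather than delegated, so they can be audited directly; tests cross-check
them against statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import AgreementReport, compare_arrays

__all__ = [
    "RegressionFit",
    "CrossValReport",
    "fit_linear",
    "stepwise_select",
    "split_cohort",
    "split_indices",
    "double_cross_validate",
    "ks_normality",
    "esd_outliers",
]


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit (intercept first) with its diagnostic battery."""

    response: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray            # [intercept, b1, ...]
    standard_errors: np.ndarray
    p_values: np.ndarray
    r2: float
    rmse: float                         # SE of estimate = sqrt(MSE)
    aic: float
    mallows_cp: float
    press: float
    vif: dict = field(default_factory=dict)
    n: int = 0
    sse: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coefficients[0] + X @ self.coefficients[1:]

    def coef_dict(self) -> dict:
        names = ("intercept",) + self.predictors
        return dict(zip(names, self.coefficients.tolist()))

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "r2": self.r2, "rmse": self.rmse, "aic": self.aic,
            "mallows_cp": self.mallows_cp, "press": self.press,
            "vif": self.vif, "n": self.n,
        }


@dataclass(frozen=True)
class CrossValReport:
    """Double cross-validation outcome for one candidate model."""

    group1_fit: RegressionFit
    group2_fit: RegressionFit
    crossed_agreement: tuple[AgreementReport, AgreementReport]
    homogeneity_F: float
    homogeneity_p: float
    homogeneous: bool
    pooled_fit: Optional[RegressionFit]
    loocv_rmse: Optional[float]
    r2_pred: Optional[float]

    def to_dict(self) -> dict:
        return {
            "group1_fit": self.group1_fit.to_dict(),
            "group2_fit": self.group2_fit.to_dict(),
            "crossed_agreement": [a.to_dict() for a in self.crossed_agreement],
            "homogeneity_F": self.homogeneity_F,
            "homogeneity_p": self.homogeneity_p,
            "homogeneous": self.homogeneous,
            "pooled_fit": None if self.pooled_fit is None
            else self.pooled_fit.to_dict(),
            "loocv_rmse": self.loocv_rmse,
            "r2_pred": self.r2_pred,
        }


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(len(X)), X])


def fit_linear(y, X, labels: Sequence[str], response: str = "y",
               sigma2_full: Optional[float] = None) -> RegressionFit:
    """OLS with first-principles diagnostics.

    PRESS uses the hat-matrix identity sum((e_i/(1-h_ii))^2); VIF comes from
    the auxiliary R^2 of each predictor on the others; Cp is evaluated
    against ``sigma2_full`` (the fullest candidate model's MSE) when given,
    otherwise against the model's own MSE; AIC is the Gaussian-likelihood
    form (comparable across models of the same response only).
    """
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    n, p1 = Xd.shape
    labels = tuple(labels)
    if len(labels) != p1 - 1:
        raise ValueError("labels must match predictor columns")
    if n <= p1:
        raise ValueError(f"need n > p+1 (n={n}, p={p1 - 1})")

    rank = np.linalg.matrix_rank(Xd)
    if rank < p1:
        # name the columns implicated via the QR diagonal
        q, r = np.linalg.qr(Xd)
        bad = [labels[j - 1] for j in range(1, p1)
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ y
    fitted = Xd @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    dof = n - p1
    mse = sse / dof if dof > 0 else 0.0
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * mse, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    h = np.einsum("ij,jk,ik->i", Xd, XtX_inv, Xd)
    press = float(np.sum((resid / (1.0 - h)) ** 2))

    vif = {}
    for j, lab in enumerate(labels):
        xj = Xd[:, j + 1]
        others = np.delete(Xd, j + 1, axis=1)
        bj, *_ = np.linalg.lstsq(others, xj, rcond=None)
        rj = xj - others @ bj
        ssj = float(np.sum((xj - xj.mean()) ** 2))
        aux_r2 = 1.0 - float(rj @ rj) / ssj if ssj > 0 else 0.0
        vif[lab] = float("inf") if aux_r2 >= 1.0 else 1.0 / (1.0 - aux_r2)

    sigma2_hat = sse / n
    if sigma2_hat > 0:
        aic = n * math.log(2 * math.pi * sigma2_hat) + n + 2 * (p1 + 1)
    else:
        aic = -math.inf
    s2f = mse if sigma2_full is None else sigma2_full
    cp = sse / s2f - n + 2 * p1 if s2f > 0 else float(p1)

    return RegressionFit(
        response=response, predictors=labels, coefficients=beta,
        standard_errors=se, p_values=pvals, r2=r2,
        rmse=math.sqrt(mse), aic=aic, mallows_cp=cp, press=press,
        vif=vif, n=n, sse=sse)


def stepwise_select(y, X, labels: Sequence[str],
                    alpha_enter: float = 0.05,
                    alpha_remove: float = 0.10,
                    response: str = "y",
                    ) -> tuple[RegressionFit, list[dict]]:
    """Forward-entry / backward-removal stepwise OLS.

    Enters the candidate with the smallest partial-t p-value below
    ``alpha_enter``; after each entry removes any in-model predictor whose
    p-value has risen above ``alpha_remove``. Deterministic given the data.
    Returns the selected fit (intercept-only never occurs as a RegressionFit
    here: an empty selection yields an intercept-only surrogate) plus the
    selection trace.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = list(labels)
    if not labels:
        raise ValueError("candidate set is empty")
    selected: list[int] = []
    trace: list[dict] = []

    sigma2_full = fit_linear(y, X, labels, response=response).rmse ** 2

    while True:
        changed = False
        remaining = [j for j in range(len(labels)) if j not in selected]
        best = None
        for j in remaining:
            cols = selected + [j]
            fit = fit_linear(y, X[:, cols], [labels[k] for k in cols],
                             response=response)
            p = fit.p_values[-1]
            if best is None or p < best[1]:
                best = (j, p)
        if best is not None and best[1] < alpha_enter:
            selected.append(best[0])
            trace.append({"action": "enter", "predictor": labels[best[0]],
                          "p": float(best[1])})
            changed = True
        # backward pass
        while len(selected) > 0:
            fit = fit_linear(y, X[:, selected],
                             [labels[k] for k in selected],
                             response=response)
            worst_idx = int(np.argmax(fit.p_values[1:]))
            worst_p = float(fit.p_values[1 + worst_idx])
            if worst_p > alpha_remove:
                removed = selected.pop(worst_idx)
                trace.append({"action": "remove",
                              "predictor": labels[removed], "p": worst_p})
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        import warnings

        warnings.warn("no predictor met alpha-to-enter; "
                      "returning intercept-only model")
        beta = np.array([y.mean()])
        resid = y - beta[0]
        sse = float(resid @ resid)
        n = len(y)
        mse = sse / (n - 1)
        fit = RegressionFit(
            response=response, predictors=(), coefficients=beta,
            standard_errors=np.array([math.sqrt(mse / n)]),
            p_values=np.array([0.0]), r2=0.0, rmse=math.sqrt(mse),
            aic=n * math.log(2 * math.pi * sse / n) + n + 4,
            mallows_cp=1.0, press=float(np.sum((resid / (1 - 1 / n)) ** 2)),
            vif={}, n=n, sse=sse)
        return fit, trace

    fit = fit_linear(y, X[:, selected], [labels[k] for k in selected],
                     response=response, sigma2_full=sigma2_full)
    return fit, trace


def split_indices(sex: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomized sex-stratified 50:50 split; returns index arrays.

    Within each sex stratum subjects are shuffled and halved; when a stratum
    is odd the extra member goes to group 1 or 2 by one seeded coin flip per
    stratum, so group sizes differ by at most one per stratum.
    """
    sex = np.asarray(sex)
    rng = np.random.default_rng(seed)
    g1, g2 = [], []
    for s in np.unique(sex):
        idx = np.flatnonzero(sex == s)
        if len(idx) < 2:
            raise ValueError(f"stratum sex={s} has fewer than 2 subjects")
        perm = rng.permutation(idx)
        half = len(perm) // 2
        extra_to_g1 = bool(rng.integers(0, 2)) if len(perm) % 2 else False
        cut = half + (1 if extra_to_g1 else 0)
        g1.append(perm[:cut])
        g2.append(perm[cut:])
    return np.sort(np.concatenate(g1)), np.sort(np.concatenate(g2))


def split_cohort(records: Sequence, seed: int) -> tuple[list, list]:
    """Sex-stratified 50:50 split of subject records."""
    sex = np.array([r.sex for r in records])
    i1, i2 = split_indices(sex, seed)
    return [records[i] for i in i1], [records[i] for i in i2]


def _homogeneity_test(y1, X1, y2, X2, labels) -> tuple[float, float]:
    """Covariance-analysis test of regression equality across groups.

    Pools the two development regressions with a group indicator and its
    interactions with every predictor; the F test of the extra terms
    against the common model tests intercept and slope equality jointly
    (exact at level alpha under the shared-model null).
    """
    y = np.concatenate([y1, y2])
    X = np.vstack([X1, X2])
    grp = np.concatenate([np.zeros(len(y1)), np.ones(len(y2))])
    X_full = np.column_stack([X, grp, grp[:, None] * X])
    labels_full = (list(labels) + ["group"]
                   + [f"group_x_{l}" for l in labels])
    full = fit_linear(y, X_full, labels_full)
    reduced = fit_linear(y, X, list(labels))
    df_num = X.shape[1] + 1
    df_den = len(y) - X_full.shape[1] - 1
    if full.sse <= 0:
        return 0.0, 1.0
    F = ((reduced.sse - full.sse) / df_num) / (full.sse / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), p


def double_cross_validate(df: pd.DataFrame, response: str,
                          predictors: Sequence[str], seed: int,
                          alpha: float = 0.05,
                          stratify_on: str = "sex") -> CrossValReport:
    """Split-sample double cross-validation of a linear predictor.

    Fits the model in each half of a sex-stratified split, applies each
    equation to the opposite half (agreement of reference vs predicted),
    tests homogeneity of the two reference-vs-predicted lines, and - when
    not significant at ``alpha`` - fits the pooled model, reporting the
    leave-one-out RMSE (sqrt(PRESS/n)) and PRESS-based R^2_pred.
    """
    predictors = list(predictors)
    i1, i2 = split_indices(df[stratify_on].to_numpy(), seed)
    halves = [df.iloc[i1], df.iloc[i2]]
    fits = []
    for half in halves:
        fits.append(fit_linear(half[response].to_numpy(),
                               half[predictors].to_numpy(),
                               predictors, response=response))
    # apply each group's equation to the opposite group
    preds = [fits[0].predict(halves[1][predictors].to_numpy()),
             fits[1].predict(halves[0][predictors].to_numpy())]
    refs = [halves[1][response].to_numpy(), halves[0][response].to_numpy()]
    agreements = (
        compare_arrays(refs[0], preds[0], label="group1_eq_on_group2"),
        compare_arrays(refs[1], preds[1], label="group2_eq_on_group1"),
    )
    F, p = _homogeneity_test(
        halves[0][response].to_numpy(), halves[0][predictors].to_numpy(),
        halves[1][response].to_numpy(), halves[1][predictors].to_numpy(),
        predictors)
    homogeneous = p >= alpha
    pooled = loocv_rmse = r2_pred = None
    if homogeneous:
        y = df[response].to_numpy()
        pooled = fit_linear(y, df[predictors].to_numpy(), predictors,
                            response=response)
        loocv_rmse = math.sqrt(pooled.press / pooled.n)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2_pred = 1.0 - pooled.press / sst if sst > 0 else None
    return CrossValReport(
        group1_fit=fits[0], group2_fit=fits[1],
        crossed_agreement=agreements, homogeneity_F=F, homogeneity_p=p,
        homogeneous=homogeneous, pooled_fit=pooled,
        loocv_rmse=loocv_rmse, r2_pred=r2_pred)


def ks_normality(x, lilliefors: bool = False) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality with fitted mean and SD.

    The asymptotic p-value is conservative because the Gaussian parameters
    are estimated from the data; set ``lilliefors=True`` for the corrected
    null distribution.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def esd_outliers(x, alpha: float = 0.05, max_k: int = 5) -> np.ndarray:
    """Rosner's generalized extreme studentized deviate outlier test.

    Iteratively removes the most extreme studentized value up to ``max_k``
    times, compares each R_i with its critical value lambda_i, and flags
    the largest i for which R_i > lambda_i (all the first i removals).
    Returns indices into x, possibly empty.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= max_k + 2:
        raise ValueError("need n > max_k + 2")
    vals = x.copy()
    idx = np.arange(n)
    removed: list[int] = []
    exceed = 0
    for i in range(1, max_k + 1):
        m = vals.mean()
        s = vals.std(ddof=1)
        if s == 0:
            raise ValueError("degenerate variance during ESD iteration")
        j = int(np.argmax(np.abs(vals - m)))
        R = abs(vals[j] - m) / s
        ni = n - i + 1
        pcrit = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(pcrit, ni - 2)
        lam = (ni - 1) * t / math.sqrt((ni - 2 + t ** 2) * ni)
        removed.append(int(idx[j]))
        if R > lam:
            exceed = i
        vals = np.delete(vals, j)
        idx = np.delete(idx, j)
    return np.array(removed[:exceed], dtype=int)
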