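"""Collinearity filtering, forward model selection and GLM fitting.

Two country-level regressions are supported: richness (count of
established non-native species) under a negative-binomial GLM with log
link, and the per-country reporting-trend statistic, which can be negative
and therefore defaults to a Gaussian identity-link model.  Predictors are
screened first by iterative VIF removal (threshold 10), then entered by
forward selection under AICc.  Diagnostics cover a Pearson overdispersion
test against the Poisson baseline, k-fold cross-validated deviance and
leverage/Cook-style influence per country.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import PredictorTable

__all__ = [
    "CollinearityReport",
    "SelectionTrace",
    "GlmFit",
    "CvResult",
    "filter_collinear",
    "forward_select",
    "fit_glm",
    "fit_nb_glm",
    "overdispersion_test",
    "kfold_cv",
    "influence_diagnostics",
    "standardize",
]

logger = logging.getLogger(__name__)

FAMILIES = ("negative_binomial", "poisson", "gaussian")


@dataclass
class CollinearityReport:
    vif: dict[str, float]  # VIF of every retained predictor after filtering
    removed: list[tuple[str, float]]  # (name, VIF at removal), in order
    threshold: float


@dataclass
class SelectionTrace:
    steps: list[tuple[str, float]]  # (predictor added, criterion after adding)
    final_predictors: list[str]
    criterion: str


@dataclass
class GlmFit:
    coefficients: pd.DataFrame  # index: term; estimate, std_error, p_value
    theta: float | None  # NB dispersion (variance = mu + mu^2/theta); None otherwise
    criterion_value: float
    family: str
    converged: bool
    n: int
    _result: object = field(repr=False, default=None)  # statsmodels results


@dataclass
class CvResult:
    k: int
    per_fold_deviance: list[float]
    mean_deviance: float


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score predictors so coefficient magnitudes are comparable."""
    sd = frame.std(ddof=0).replace(0.0, 1.0)
    return (frame - frame.mean()) / sd


# ---------------------------------------------------------------------------
# collinearity

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) of its OLS on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return np.inf
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def filter_collinear(
    predictors: PredictorTable | pd.DataFrame, threshold: float = 10.0
) -> tuple[PredictorTable | pd.DataFrame, CollinearityReport]:
    """Iteratively drop the highest-VIF predictor until all VIF < threshold.

    Perfectly collinear columns show unbounded VIF and go first.  Ties are
    broken lexicographically by name so the outcome does not depend on the
    column order of the input.
    """
    is_table = isinstance(predictors, PredictorTable)
    frame = predictors.data if is_table else predictors
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 predictors for a VIF analysis")
    cols = list(frame.columns)
    removed: list[tuple[str, float]] = []
    while len(cols) >= 2:
        X = frame[cols].to_numpy(dtype=float)
        vifs = {name: _vif_one(X, j) for j, name in enumerate(cols)}
        worst_value = max(vifs.values())
        # among equal VIFs pick the alphabetically first (order independence)
        worst = sorted(c for c in cols if vifs[c] == worst_value)[0]
        if vifs[worst] < threshold:
            break
        removed.append((worst, float(vifs[worst])))
        cols.remove(worst)
    X = frame[cols].to_numpy(dtype=float)
    final_vif = (
        {name: float(_vif_one(X, j)) for j, name in enumerate(cols)}
        if len(cols) >= 2
        else {name: 1.0 for name in cols}
    )
    report = CollinearityReport(vif=final_vif, removed=removed, threshold=threshold)
    if is_table:
        return predictors.drop([name for name, _ in removed]), report
    return frame[cols].copy(), report


# ---------------------------------------------------------------------------
# GLM fitting

def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _fit_raw(y: np.ndarray, design: np.ndarray, family: str):
    """Fit one model; returns (statsmodels results, llf, k_params)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "negative_binomial":
            model = sm.NegativeBinomial(y, design)
            try:
                res = model.fit(disp=0, maxiter=200)
                ok = _converged(res, family) and np.all(np.isfinite(res.bse))
            except Exception:  # Newton can blow up on extreme counts
                ok = False
            if not ok:
                # restart from an IRLS Poisson solution with a robust optimizer
                try:
                    irls = sm.GLM(y, design, family=sm.families.Poisson()).fit()
                    start = np.append(np.asarray(irls.params), 0.5)
                except Exception:
                    start = np.zeros(design.shape[1] + 1)
                    start[0] = np.log(max(y.mean(), 1e-8))
                    start[-1] = 0.5
                res = model.fit(start_params=start, method="bfgs", disp=0, maxiter=500)
            return res, float(res.llf), design.shape[1] + 1  # + alpha
        if family == "poisson":
            model = sm.Poisson(y, design)
            res = model.fit(disp=0, maxiter=200)
            return res, float(res.llf), design.shape[1]
        if family == "gaussian":
            res = sm.OLS(y, design).fit()
            return res, float(res.llf), design.shape[1] + 1  # + sigma^2
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _criterion(llf: float, k: int, n: int, which: str) -> float:
    aic = 2 * k - 2 * llf
    if which.lower() == "aic":
        return aic
    if which.lower() == "aicc":
        if n - k - 1 <= 0:
            return np.inf
        return aic + 2 * k * (k + 1) / (n - k - 1)
    raise ValueError(f"unknown criterion {which!r}")


def _converged(res, family: str) -> bool:
    if family == "gaussian":
        return True
    retvals = getattr(res, "mle_retvals", None)
    return bool(retvals.get("converged", True)) if retvals else True


def fit_glm(
    response: pd.Series | np.ndarray,
    design: pd.DataFrame,
    family: str = "negative_binomial",
    criterion: str = "aicc",
) -> GlmFit:
    """Fit one GLM on an intercept-plus-predictors design.

    Negative binomial (NB2, log link) estimates its dispersion alpha by
    maximum likelihood; ``theta`` is reported as 1/alpha.  Negative
    responses are rejected for the count families with a pointer to the
    gaussian override.
    """
    y = np.asarray(response, dtype=float)
    if design.isna().to_numpy().any():
        raise ValueError("design matrix contains missing values")
    if family in ("negative_binomial", "poisson") and np.any(y < 0):
        raise ValueError(
            f"negative responses are impossible under {family}; "
            "use family='gaussian' (identity link) instead"
        )
    X = _design(design)
    res, llf, k = _fit_raw(y, X, family)
    if not _converged(res, family):
        raise RuntimeError(
            f"{family} fit did not converge: {getattr(res, 'mle_retvals', {})}"
        )
    names = ["intercept"] + list(design.columns)
    params = np.asarray(res.params)[: len(names)]
    bse = np.asarray(res.bse)[: len(names)]
    pvals = np.asarray(res.pvalues)[: len(names)]
    coefficients = pd.DataFrame(
        {"estimate": params, "std_error": bse, "p_value": pvals}, index=names
    )
    theta = None
    if family == "negative_binomial":
        alpha = float(np.asarray(res.params)[-1])
        theta = np.inf if alpha <= 0 else 1.0 / alpha
    return GlmFit(
        coefficients=coefficients,
        theta=theta,
        criterion_value=_criterion(llf, k, len(y), criterion),
        family=family,
        converged=True,
        n=len(y),
        _result=res,
    )


def fit_nb_glm(response, design: pd.DataFrame, family: str = "negative_binomial") -> GlmFit:
    """Convenience alias used by the pipeline (family overridable)."""
    return fit_glm(response, design, family=family)


def forward_select(
    response: pd.Series | np.ndarray,
    predictors: PredictorTable | pd.DataFrame,
    family: str = "negative_binomial",
    criterion: str = "aicc",
) -> SelectionTrace:
    """Forward stepwise selection from the intercept-only model.

    At each step the candidate that minimizes the criterion is added;
    selection stops when no candidate improves on the current value.  Ties
    are broken lexicographically; candidates whose fit fails to converge
    are skipped with a warning, never silently accepted.
    """
    frame = predictors.data if isinstance(predictors, PredictorTable) else predictors
    y = np.asarray(response, dtype=float)
    n = len(y)
    empty = pd.DataFrame(index=frame.index)
    _, llf0, k0 = _fit_raw(y, _design(empty), family)
    best = _criterion(llf0, k0, n, criterion)
    chosen: list[str] = []
    steps: list[tuple[str, float]] = []
    remaining = sorted(frame.columns)
    while remaining:
        scores: dict[str, float] = {}
        for cand in remaining:
            try:
                res, llf, k = _fit_raw(y, _design(frame[chosen + [cand]]), family)
                if not _converged(res, family):
                    raise RuntimeError("non-convergence")
            except Exception as exc:  # noqa: BLE001 - candidate-level guard
                logger.warning("candidate %s skipped: %s", cand, exc)
                continue
            scores[cand] = _criterion(llf, k, n, criterion)
        if not scores:
            break
        winner = min(sorted(scores), key=scores.get)
        if scores[winner] >= best:
            break
        best = scores[winner]
        chosen.append(winner)
        remaining.remove(winner)
        steps.append((winner, best))
    return SelectionTrace(steps=steps, final_predictors=chosen, criterion=criterion)


# ---------------------------------------------------------------------------
# diagnostics

def overdispersion_test(
    response: pd.Series | np.ndarray, design: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Pearson chi-square overdispersion test on the Poisson baseline.

    Returns (dispersion, p_value, overdispersed): the dispersion is the
    Pearson statistic over its residual df; the one-sided p-value comes
    from the chi-square reference distribution of the Pearson statistic
    under equidispersion.
    """
    y = np.asarray(response, dtype=float)
    X = _design(design)
    res, _, _ = _fit_raw(y, X, "poisson")
    mu = np.asarray(res.predict(X))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    df = len(y) - X.shape[1]
    dispersion = pearson / df
    p = float(stats.chi2.sf(pearson, df))
    return dispersion, p, p < alpha


def _deviance(y: np.ndarray, mu: np.ndarray, family: str, theta: float | None) -> float:
    if family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2 * np.sum(term - (y - mu)))
    if family == "negative_binomial":
        t = np.inf if theta is None else theta
        if not np.isfinite(t):
            return _deviance(y, mu, "poisson", None)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + t) * np.log((y + t) / (mu + t))
        return float(2 * np.sum(term - term2))
    raise ValueError(f"unknown family {family!r}")


def kfold_cv(
    response: pd.Series | np.ndarray,
    design: pd.DataFrame,
    family: str = "negative_binomial",
    k: int = 5,
    seed: int = 0,
) -> CvResult:
    """k-fold cross-validated held-out deviance.

    Folds are a seeded random partition (disjoint, exhaustive).  A fold
    whose training response loses all variation is flagged, excluded from
    the mean and logged.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("k must lie in [2, n]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    devs: list[float] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        y_tr = y[train_idx]
        if np.all(y_tr == y_tr[0]):
            logger.warning("fold %d: training response has no variation; skipped", fi)
            devs.append(np.nan)
            continue
        X_tr = design.iloc[train_idx]
        X_te = design.iloc[test_idx]
        fit = fit_glm(y_tr, X_tr, family=family)
        mu = np.asarray(fit._result.predict(_design(X_te)))
        devs.append(_deviance(y[test_idx], mu, family, fit.theta))
    valid = [d for d in devs if np.isfinite(d)]
    return CvResult(k=k, per_fold_deviance=devs, mean_deviance=float(np.mean(valid)))


def influence_diagnostics(fit: GlmFit, design: pd.DataFrame) -> pd.DataFrame:
    """Pearson residuals, leverage and Cook-style influence per country.

    Leverage comes from the weighted hat matrix H = W^.5 X (X'WX)^-1 X' W^.5
    (W = IRLS working weights; identity for gaussian); influence is Cook's
    distance D_i = r_i^2 h_i / (p (1-h_i)); countries with D_i > 4/n are
    flagged.
    """
    res = fit._result
    y = np.asarray(res.model.endog, dtype=float)
    X = _design(design)
    beta = np.asarray(res.params)[: X.shape[1]]
    eta = X @ beta
    if fit.family == "gaussian":
        mu = eta
        var = np.full_like(mu, float(np.sum((y - mu) ** 2) / max(len(y) - X.shape[1], 1)))
        w = np.ones_like(mu)
    elif fit.family == "poisson":
        mu = np.exp(eta)
        var = mu
        w = mu
    else:  # negative binomial, log link
        mu = np.exp(eta)
        t = fit.theta if fit.theta and np.isfinite(fit.theta) else np.inf
        var = mu + (0.0 if not np.isfinite(t) else mu**2 / t)
        w = mu**2 / var
    WX = X * np.sqrt(w)[:, None]
    hat = WX @ np.linalg.pinv(WX.T @ WX) @ WX.T
    leverage = np.clip(np.diag(hat), 0.0, 1.0 - 1e-12)
    pearson = (y - mu) / np.sqrt(var)
    p = X.shape[1]
    cooks = pearson**2 * leverage / (p * (1.0 - leverage))
    return pd.DataFrame(
        {
            "country": list(design.index),
            "pearson_residual": pearson,
            "leverage": leverage,
            "influence": cooks,
            "flagged": cooks > 4.0 / len(y),
        }
    )
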