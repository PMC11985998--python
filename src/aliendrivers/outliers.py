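"""Per-predictor null models with Bonferroni-adjusted count envelopes.

For each national predictor, the null expectation is that established
non-native species distribute across countries in proportion to the
predictor: expected_i = total * x_i / sum(x).  Around that expectation an
acceptance envelope is drawn from count-distribution quantiles: exact
Poisson when the data are equidispersed, otherwise a negative binomial
matched to mean mu and variance phi*mu (the quasi-Poisson family has no
quantile function, so the matched NB supplies one; it reduces to the
Poisson at phi = 1).  Coverage per country is (1 - alpha/m_i) with m_i the
country's established-species count — richer countries get stricter
thresholds — split equally between the two tails.  Countries above the
upper bound are over-represented, below the lower bound under-represented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NullEnvelope",
    "OutlierResult",
    "null_expected_counts",
    "estimate_dispersion",
    "envelope_bounds",
    "build_envelope",
    "classify_outliers",
    "outlier_table",
]


@dataclass
class NullEnvelope:
    predictor: str
    countries: list[str]
    expected: np.ndarray
    dispersion_phi: float
    alpha: float
    m: np.ndarray  # per-country Bonferroni divisor (established species count)
    lower: np.ndarray  # int
    upper: np.ndarray  # int


@dataclass(frozen=True)
class OutlierResult:
    country: str
    predictor: str
    observed: int
    status: str  # over | under | within


def null_expected_counts(
    predictor_values: np.ndarray | pd.Series, total_species: int
) -> np.ndarray:
    """Proportional-allocation null expectation.

    expected_i = total_species * x_i / sum(x); the expectations conserve the
    total.  This is the minimal model under which the species distribution
    mirrors the predictor distribution; a log-link GLM alternative is
    available via :func:`build_envelope`.
    """
    x = np.asarray(predictor_values, dtype=float)
    if np.any(x < 0):
        raise ValueError("predictor values must be non-negative")
    s = x.sum()
    if s == 0:
        raise ValueError("all-zero predictor has no proportional allocation")
    return total_species * x / s


def estimate_dispersion(
    observed: np.ndarray | pd.Series, expected: np.ndarray | pd.Series
) -> float:
    """Pearson dispersion: sum((obs-exp)^2 / exp) / (n - 1), floored at 1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if len(obs) < 2:
        raise ValueError("dispersion needs at least 2 countries")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be strictly positive")
    phi = float(np.sum((obs - exp) ** 2 / exp) / (len(obs) - 1))
    return max(phi, 1.0)


def raw_dispersion(observed, expected) -> float:
    """Unfloored Pearson dispersion (for reporting)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    return float(np.sum((obs - exp) ** 2 / exp) / (len(obs) - 1))


def envelope_bounds(
    expected_i: float, phi: float, alpha: float, m_i: int
) -> tuple[int, int]:
    """Two-sided count bounds covering (1 - alpha/m_i) of the null.

    Each tail holds (alpha/m_i)/2.  phi = 1 gives exact Poisson quantiles
    of mean ``expected_i``; phi > 1 gives quantiles of the negative
    binomial with the same mean and variance phi * expected_i
    (size = mu / (phi - 1), p = 1/phi).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_i < 1:
        raise ValueError("Bonferroni divisor m must be >= 1")
    tail = (alpha / m_i) / 2.0
    if phi <= 1.0:
        lower = stats.poisson.ppf(tail, expected_i)
        upper = stats.poisson.ppf(1.0 - tail, expected_i)
    else:
        size = expected_i / (phi - 1.0)
        p = 1.0 / phi
        lower = stats.nbinom.ppf(tail, size, p)
        upper = stats.nbinom.ppf(1.0 - tail, size, p)
    return int(lower), int(upper)


def build_envelope(
    predictor_name: str,
    predictor_values: pd.Series,
    observed: pd.Series,
    alpha: float = 0.05,
    method: str = "proportional",
) -> NullEnvelope:
    """Full envelope for one predictor over all countries.

    ``observed`` doubles as the per-country Bonferroni divisor m.  With
    ``method='glm'`` the null expectation comes from a log-link Poisson
    regression of observed counts on log1p(predictor) instead of pure
    proportional allocation (exposes the intercept-fitting alternative).
    """
    if not predictor_values.index.equals(observed.index):
        raise ValueError("predictor and observed country sets are misaligned")
    total = int(observed.sum())
    if method == "proportional":
        expected = null_expected_counts(predictor_values, total)
    elif method == "glm":
        import statsmodels.api as sm

        X = sm.add_constant(np.log1p(predictor_values.to_numpy(dtype=float)))
        fit = sm.GLM(
            observed.to_numpy(dtype=float), X, family=sm.families.Poisson()
        ).fit()
        expected = np.asarray(fit.fittedvalues)
    else:
        raise ValueError(f"unknown null-model method {method!r}")
    phi = estimate_dispersion(observed, expected)
    m = observed.to_numpy(dtype=int)
    bounds = [
        envelope_bounds(e, phi, alpha, max(int(mi), 1))
        for e, mi in zip(expected, m)
    ]
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    return NullEnvelope(
        predictor=predictor_name,
        countries=list(observed.index),
        expected=np.asarray(expected, dtype=float),
        dispersion_phi=phi,
        alpha=alpha,
        m=m,
        lower=lower,
        upper=upper,
    )


def classify_outliers(
    observed: pd.Series, envelope: NullEnvelope
) -> list[OutlierResult]:
    """Classify every country against the envelope.

    Restricted to countries with at least one established species; a
    country is *over* iff observed > upper, *under* iff observed < lower.
    """
    if list(observed.index) != envelope.countries:
        extra = set(observed.index).symmetric_difference(envelope.countries)
        raise ValueError(f"country sets misaligned: {sorted(extra)}")
    results = []
    for i, country in enumerate(envelope.countries):
        obs = int(observed.iloc[i])
        if obs < 1:
            continue
        if obs > envelope.upper[i]:
            status = "over"
        elif obs < envelope.lower[i]:
            status = "under"
        else:
            status = "within"
        results.append(
            OutlierResult(
                country=country,
                predictor=envelope.predictor,
                observed=obs,
                status=status,
            )
        )
    return results


def outlier_table(
    predictors: pd.DataFrame,
    observed: pd.Series,
    alpha: float = 0.05,
    method: str = "proportional",
) -> pd.DataFrame:
    """Long-format envelope + classification over every predictor column."""
    rows = []
    for name in predictors.columns:
        x = predictors[name]
        if (x < 0).any() or x.sum() == 0:
            continue  # predictor unusable as an allocation weight
        env = build_envelope(name, x, observed, alpha=alpha, method=method)
        status = {r.country: r.status for r in classify_outliers(observed, env)}
        for i, country in enumerate(env.countries):
            rows.append(
                {
                    "country": country,
                    "predictor": name,
                    "observed": int(observed.iloc[i]),
                    "expected": env.expected[i],
                    "lower": int(env.lower[i]),
                    "upper": int(env.upper[i]),
                    "phi": env.dispersion_phi,
                    "status": status.get(country, "excluded"),
                }
            )
    return pd.DataFrame(rows)
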