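"""Variance partitioning of one response over four predictor blocks.

The explained variance of a linear model is decomposed across the four
driver categories (research, economy, environment & culture, land use) by
adjusted R²: the marginal adjusted R² is computed for every non-empty union
of blocks (15 of them), and the 15 Venn cells follow by Möbius inversion,

    cell(T) = sum over W ⊆ T of (-1)^(|T|-|W|+1) · R²adj(union of B \\ W),

whose singleton cells equal the familiar unique fractions
R²adj(all) − R²adj(all minus X).  The cells plus the residual
1 − R²adj(all) sum to one exactly.  Adjusted R² uses the Ezekiel
correction, so individual cells can be negative — a known and accepted
property of this decomposition.  Significance of marginal and unique
fractions is assessed by permutation: response rows are permuted for
marginal fractions; for unique fractions the residuals of the
reduced model (all blocks minus the focal one) are permuted and added back
to its fitted values, the standard residual-permutation scheme for partial
tests.  Shared cells get no p-values; they are not testable quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "AdjustedR2",
    "VarpartResult",
    "adjusted_r2",
    "partition_four_blocks",
    "permutation_test",
]


@dataclass
class AdjustedR2:
    r2: float
    r2_adj: float
    n: int
    p: int


@dataclass
class VarpartResult:
    blocks: list[str]
    marginal_r2adj: dict[frozenset, float]  # 15 unions
    venn_fractions: dict[frozenset, float]  # 15 cells
    residual: float
    p_values: dict[str, float]
    n_permutations: int

    def unique_fraction(self, block: str) -> float:
        return self.venn_fractions[frozenset([block])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.marginal_r2adj, key=lambda s: (len(s), sorted(s))):
            label = "+".join(sorted(subset))
            rows.append(
                {
                    "fraction": f"marginal:{label}",
                    "value": self.marginal_r2adj[subset],
                    "p_value": self.p_values.get(f"marginal:{label}", np.nan),
                }
            )
        for subset in sorted(self.venn_fractions, key=lambda s: (len(s), sorted(s))):
            label = "&".join(sorted(subset))
            key = f"unique:{label}" if len(subset) == 1 else None
            rows.append(
                {
                    "fraction": f"venn:{label}",
                    "value": self.venn_fractions[subset],
                    "p_value": self.p_values.get(key, np.nan) if key else np.nan,
                }
            )
        rows.append({"fraction": "residual", "value": self.residual, "p_value": np.nan})
        return pd.DataFrame(rows)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """R² of OLS with intercept; returns (r2, rank of the design)."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has no variance")
    return 1.0 - float(np.sum(resid**2)) / sst, int(rank)


def adjusted_r2(response: pd.Series | np.ndarray, design: pd.DataFrame) -> AdjustedR2:
    """OLS R² with the Ezekiel adjustment 1 − (1−R²)(n−1)/(n−p−1)."""
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    r2, rank = _ols_r2(y, X)
    if rank < p + 1:
        # name the dependent columns via QR pivoting on the centred design
        q, r = np.linalg.qr(X - X.mean(axis=0))
        dep = [design.columns[j] for j in range(p) if abs(r[j, j]) < 1e-10] if r.shape[0] >= p else list(design.columns)
        raise ValueError(f"rank-deficient design; dependent columns near: {dep}")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return AdjustedR2(r2=r2, r2_adj=r2_adj, n=n, p=p)


def _union_design(blocks: dict[str, pd.DataFrame], subset: frozenset) -> pd.DataFrame:
    parts = [blocks[b] for b in sorted(subset)]
    return pd.concat(parts, axis=1)


def _all_subsets(labels: list[str]):
    for k in range(1, len(labels) + 1):
        for combo in combinations(sorted(labels), k):
            yield frozenset(combo)


def partition_four_blocks(
    response: pd.Series | np.ndarray, blocks: dict[str, pd.DataFrame]
) -> VarpartResult:
    """Marginal adjusted R² for all block unions plus the Venn-cell fractions."""
    labels = sorted(blocks)
    if len(labels) < 2:
        raise ValueError("need at least 2 blocks to partition")
    cols: set[str] = set()
    for label, frame in blocks.items():
        if frame.shape[1] == 0:
            raise ValueError(f"block {label!r} is empty")
        overlap = cols & set(frame.columns)
        if overlap:
            raise ValueError(f"blocks share predictors: {sorted(overlap)}")
        cols |= set(frame.columns)
    y = np.asarray(response, dtype=float)

    marginal: dict[frozenset, float] = {}
    for subset in _all_subsets(labels):
        marginal[subset] = adjusted_r2(y, _union_design(blocks, subset)).r2_adj

    full = frozenset(labels)

    def R(subset: frozenset) -> float:
        return marginal[subset] if subset else 0.0

    venn: dict[frozenset, float] = {}
    for T in _all_subsets(labels):
        cell = 0.0
        for k in range(len(T) + 1):
            for W in combinations(sorted(T), k):
                cell += (-1) ** (len(T) - len(W) + 1) * R(full - frozenset(W))
        venn[T] = cell

    residual = 1.0 - marginal[full]
    return VarpartResult(
        blocks=labels,
        marginal_r2adj=marginal,
        venn_fractions=venn,
        residual=residual,
        p_values={},
        n_permutations=0,
    )


def _marginal_stat_factory(y: np.ndarray, X: pd.DataFrame):
    """Fast permuted adjusted R² via an orthonormal basis of the design."""
    n, p = len(y), X.shape[1]
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    q, _ = np.linalg.qr(design)

    def stat(yv: np.ndarray) -> float:
        sst = float(np.sum((yv - yv.mean()) ** 2))
        proj = q.T @ yv
        sse = float(np.sum(yv**2) - np.sum(proj**2))
        r2 = 1.0 - sse / sst
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    return stat


def permutation_test(
    response: pd.Series | np.ndarray,
    blocks: dict[str, pd.DataFrame],
    fraction_id: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for a marginal or unique fraction.

    ``fraction_id`` is ``"marginal:<block>[+<block>...]"`` or
    ``"unique:<block>"``.  p = (1 + #{perm ≥ obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives too coarse a p-value resolution")
    kind, _, label = fraction_id.partition(":")
    y = np.asarray(response, dtype=float)
    rng = np.random.default_rng(seed)
    labels = sorted(blocks)
    full = frozenset(labels)

    if kind == "marginal":
        subset = frozenset(label.split("+"))
        unknown = subset - full
        if unknown:
            raise ValueError(f"unknown blocks in fraction id: {sorted(unknown)}")
        stat = _marginal_stat_factory(y, _union_design(blocks, subset))
        observed = stat(y)
        count = sum(stat(rng.permutation(y)) >= observed for _ in range(n_perm))
        return (1 + count) / (n_perm + 1)

    if kind == "unique":
        if label not in blocks:
            raise ValueError(f"unknown block {label!r}")
        reduced_set = full - {label}
        stat_full = _marginal_stat_factory(y, _union_design(blocks, full))
        stat_red = _marginal_stat_factory(y, _union_design(blocks, reduced_set))
        observed = stat_full(y) - stat_red(y)
        # residual permutation under the reduced model
        Xr = np.column_stack(
            [np.ones(len(y)), _union_design(blocks, reduced_set).to_numpy(dtype=float)]
        )
        coef, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        fitted = Xr @ coef
        resid = y - fitted
        count = 0
        for _ in range(n_perm):
            y_star = fitted + rng.permutation(resid)
            if stat_full(y_star) - stat_red(y_star) >= observed:
                count += 1
        return (1 + count) / (n_perm + 1)

    raise ValueError("fraction_id must start with 'marginal:' or 'unique:'")


def partition_with_tests(
    response: pd.Series | np.ndarray,
    blocks: dict[str, pd.DataFrame],
    n_perm: int = 10_000,
    seed: int = 0,
) -> VarpartResult:
    """Partition plus permutation p-values for the single-block marginal and
    unique fractions (the testable ones)."""
    result = partition_four_blocks(response, blocks)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * len(blocks))]
    p_values: dict[str, float] = {}
    for i, label in enumerate(sorted(blocks)):
        p_values[f"marginal:{label}"] = permutation_test(
            response, blocks, f"marginal:{label}", n_perm, seeds[2 * i]
        )
        p_values[f"unique:{label}"] = permutation_test(
            response, blocks, f"unique:{label}", n_perm, seeds[2 * i + 1]
        )
    result.p_values = p_values
    result.n_permutations = n_perm
    return result
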