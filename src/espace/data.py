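"""Core data containers shared across the estimators.

The central object is :class:`ExpressionMatrix`, an n-samples x p-genes
matrix of (log-)expression values assumed, after preprocessing, to have
mean-zero columns.  Partial-correlation estimates are stored as a flat
vector over the p(p-1)/2 unordered gene pairs in row-major upper-triangle
order (0,1), (0,2), ..., (0,p-1), (1,2), ..., (p-2,p-1); this ordering is
fixed so that output files are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "HubSet",
    "FitConfig",
    "PartialCorrSolution",
    "pair_index",
    "pair_list",
    "preprocess",
]


def pair_list(p: int) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), i < j, in row-major upper-triangle order."""
    iu, ju = np.triu_indices(p, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def pair_index(i: int, j: int, p: int) -> int:
    """Flat index of the unordered pair (i, j) in the canonical ordering."""
    if i == j:
        raise ValueError("self-pairs have no index")
    if i > j:
        i, j = j, i
    if not (0 <= i < j < p):
        raise ValueError(f"pair ({i},{j}) out of range for p={p}")
    return i * (2 * p - i - 3) // 2 + j - 1


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-expression data: ``values[k, i]`` is gene i in sample k."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, p = vals.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 genes, got {n}x{p}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains missing or non-finite values")
        gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(gene_ids) != p:
            raise ValueError(f"{len(gene_ids)} gene ids for {p} columns")
        if len(set(gene_ids)) != p:
            raise ValueError("gene ids must be unique")
        sample_ids = tuple(str(s) for s in self.sample_ids) if self.sample_ids else tuple(
            f"sample{k}" for k in range(n)
        )
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} rows")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @classmethod
    def from_array(cls, values: np.ndarray, gene_ids: Sequence[str] | None = None) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[1])]
        return cls(values=values, gene_ids=tuple(gene_ids))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def is_centered(self, tol: float = 1e-10) -> bool:
        return bool(np.max(np.abs(self.values.mean(axis=0))) <= tol)


def preprocess(X: ExpressionMatrix, scale: bool = True) -> ExpressionMatrix:
    """Mean-center each gene column; optionally scale to unit variance.

    Scaling (population variance, divisor n) makes λ grids transferable
    between datasets.  Zero-variance genes make the pairwise regressions
    degenerate and are rejected here.
    """
    vals = X.values - X.values.mean(axis=0)
    sd = np.sqrt((vals**2).mean(axis=0))
    if np.any(sd == 0):
        bad = [X.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene column(s): {bad}")
    if scale:
        vals = vals / sd
    return replace(X, values=vals)


@dataclass(frozen=True)
class HubSet:
    """Indices of genes known a priori to be network hubs (may be empty)."""

    members: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        members = frozenset(int(i) for i in self.members)
        if any(i < 0 for i in members):
            raise ValueError("hub indices must be nonnegative")
        object.__setattr__(self, "members", members)

    @classmethod
    def from_ids(cls, hub_ids: Iterable[str], gene_ids: Sequence[str]) -> tuple["HubSet", list[str]]:
        """Map identifiers to column indices; returns (hubs, unmatched_ids)."""
        lookup = {g: i for i, g in enumerate(gene_ids)}
        matched, unmatched = set(), []
        for h in hub_ids:
            if h in lookup:
                matched.add(lookup[h])
            else:
                unmatched.append(h)
        return cls(frozenset(matched)), unmatched

    def validate(self, p: int) -> None:
        if any(i >= p for i in self.members):
            raise ValueError(f"hub index out of range for p={p}")

    def mask(self, p: int) -> np.ndarray:
        self.validate(p)
        m = np.zeros(p, dtype=bool)
        m[list(self.members)] = True
        return m

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, i: int) -> bool:
        return i in self.members


@dataclass(frozen=True)
class FitConfig:
    """Tuning parameters and numerical controls for the pairwise estimator.

    lam
        Overall ℓ1 penalty λ ≥ 0 (λ = 0 only allowed when n > p).
    alpha
        Hub relaxation factor α ∈ (0, 1]; edges touching a known hub are
        penalized by αλ instead of λ.  α = 1 recovers the plain estimator.
    weights
        Per-gene nonnegative weights on the squared-error losses
        (all ones by default, as in the reference formulation).
    tol
        Convergence tolerance τ for the coordinate-descent sweeps.
    """

    lam: float
    alpha: float = 1.0
    weights: np.ndarray | None = None
    tol: float = 1e-6
    max_inner_iter: int = 1000
    max_sweep_iter: int = 100
    max_omega_iter: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lam >= 0:
            raise ValueError("lam must be nonnegative")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        for name in ("max_inner_iter", "max_sweep_iter", "max_omega_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            object.__setattr__(self, "weights", w)

    def resolved_weights(self, p: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(p)
        if self.weights.shape != (p,):
            raise ValueError(f"weights must have length p={p}")
        return self.weights


@dataclass(frozen=True)
class PartialCorrSolution:
    """Estimated partial correlations and diagonal precision entries.

    ``rho[k]`` is the estimate for the k-th pair in canonical order;
    ``omega_diag[i]`` estimates ω_ii, the reciprocal residual variance of
    gene i's regression on all other genes.
    """

    rho: np.ndarray
    omega_diag: np.ndarray
    n_omega_iters: int
    n_sweeps: int
    converged: bool
    objective_value: float

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        om = np.asarray(self.omega_diag, dtype=float)
        p = om.shape[0]
        if rho.shape != (p * (p - 1) // 2,):
            raise ValueError("rho length inconsistent with omega_diag")
        if np.any(np.abs(rho) > 1 + 1e-9):
            raise ValueError("partial correlations must lie in [-1, 1]")
        if np.any(om <= 0):
            raise ValueError("omega_diag must be strictly positive")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "omega_diag", om)

    @property
    def p(self) -> int:
        return self.omega_diag.shape[0]

    def rho_matrix(self) -> np.ndarray:
        """Symmetric p x p matrix of partial correlations (unit diagonal)."""
        p = self.p
        m = np.eye(p)
        iu, ju = np.triu_indices(p, k=1)
        m[iu, ju] = self.rho
        m[ju, iu] = self.rho
        return m
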