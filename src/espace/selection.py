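"""Tuning-parameter selection by a GIC-type information criterion.

For a fitted partial-correlation model the criterion is

    GIC(λ, α) = Σ_{i=1}^p { n·log RSS_i + log(log n)·log(p−1)·df_i },

where RSS_i = ‖X_i − Σ_{j≠i} ρ̂^{ij}√(ω̂_jj/ω̂_ii) X_j‖² is the residual
sum of squares of gene i's regression and df_i = #{j ≠ i : ρ̂^{ij} ≠ 0}
counts its selected neighbors.  Each edge therefore contributes to the
dimension penalty at both endpoints.  The grid search fits every (λ, α)
combination and returns the argmin, breaking ties toward larger λ and
then larger α (the sparser, less hub-relaxed model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import core
from .data import ExpressionMatrix, FitConfig, HubSet, PartialCorrSolution

__all__ = ["TuningGrid", "SelectionResult", "SelectionError", "gic", "select", "default_grid"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


class SelectionError(RuntimeError):
    """No candidate on the grid produced a converged fit."""


@dataclass(frozen=True)
class TuningGrid:
    """Candidate λ values (positive, sorted) and α values (must include 1)."""

    lambdas: tuple[float, ...]
    alphas: tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self) -> None:
        lambdas = tuple(sorted(float(x) for x in self.lambdas))
        alphas = tuple(sorted(float(a) for a in self.alphas))
        if not lambdas:
            raise ValueError("lambda grid is empty")
        if any(l <= 0 for l in lambdas):
            raise ValueError("lambda grid entries must be positive")
        if not alphas or any(not (0 < a <= 1) for a in alphas):
            raise ValueError("alpha grid entries must lie in (0, 1]")
        if 1.0 not in alphas:
            raise ValueError("alpha grid must include 1 (the no-relaxation model)")
        object.__setattr__(self, "lambdas", lambdas)
        object.__setattr__(self, "alphas", alphas)


@dataclass(frozen=True)
class SelectionResult:
    lam_star: float
    alpha_star: float
    gic_table: dict[tuple[float, float], float]
    best_fit: PartialCorrSolution


def default_grid(
    X: ExpressionMatrix,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 0.05,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> TuningGrid:
    """Log-spaced λ grid from λ_max (empty model at α=1) down to its 5%."""
    lmax = core.lambda_max(X)
    lambdas = np.geomspace(lambda_min_ratio * lmax, lmax, n_lambdas)
    return TuningGrid(lambdas=tuple(lambdas), alphas=alphas)


def residual_sums_of_squares(X: ExpressionMatrix, sol: PartialCorrSolution) -> np.ndarray:
    """Per-gene RSS_i at the fitted (ρ̂, ω̂)."""
    # the residual map ignores the diagonal of the rho matrix
    R = core._residual_matrix(X.values, sol.rho_matrix(), sol.omega_diag)
    return (R**2).sum(axis=0)


def gic(X: ExpressionMatrix, sol: PartialCorrSolution) -> float:
    """GIC-type criterion of a fitted solution on the data it was fit to."""
    n = X.n_samples
    p = X.n_genes
    if n <= 2:
        raise ValueError("GIC requires n >= 3 (log log n must be defined)")
    if sol.p != p:
        raise ValueError("solution dimension inconsistent with data")
    rss = residual_sums_of_squares(X, sol)
    if np.any(rss == 0):
        raise ValueError("degenerate fit: zero residual sum of squares")
    nz = sol.rho_matrix() - np.eye(p) != 0
    df = nz.sum(axis=1)  # neighbors of each gene; edges counted at both endpoints
    return float(np.sum(n * np.log(rss) + np.log(np.log(n)) * np.log(p - 1) * df))


def select(
    X: ExpressionMatrix,
    hubs: HubSet,
    grid: TuningGrid | None = None,
    config: FitConfig | None = None,
    warm_start: bool = True,
) -> SelectionResult:
    """Fit every grid point and return the GIC argmin.

    λ is swept in descending order within each α, warm-starting the ω
    diagonal from the previous fit (the ρ vector is re-initialized by the
    marginal soft-threshold regardless, so warm starts only accelerate the
    ω fixed point and leave results unchanged to solver tolerance).
    """
    if grid is None:
        grid = default_grid(X)
    if config is None:
        config = FitConfig(lam=grid.lambdas[0])
    table: dict[tuple[float, float], float] = {}
    fits: dict[tuple[float, float], PartialCorrSolution] = {}
    any_converged = False
    for alpha in grid.alphas:
        omega0 = None
        for lam in reversed(grid.lambdas):
            cfg = replace(config, lam=lam, alpha=alpha)
            sol = core.fit(X, hubs, cfg, omega_init=omega0 if warm_start else None)
            fits[(lam, alpha)] = sol
            table[(lam, alpha)] = gic(X, sol)
            if sol.converged:
                any_converged = True
                omega0 = sol.omega_diag
    if not any_converged:
        raise SelectionError("no (lambda, alpha) candidate converged")
    # argmin over converged fits; ties toward larger lambda, then larger alpha
    best_key = None
    best_val = np.inf
    for lam in grid.lambdas:
        for alpha in grid.alphas:
            key = (lam, alpha)
            if not fits[key].converged:
                continue
            val = table[key]
            if val < best_val or (
                val == best_val
                and best_key is not None
                and (lam, alpha) > best_key
            ):
                best_val = val
                best_key = key
    lam_star, alpha_star = best_key
    return SelectionResult(
        lam_star=lam_star,
        alpha_star=alpha_star,
        gic_table=table,
        best_fit=fits[best_key],
    )
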