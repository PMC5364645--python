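"""Hub-aware sparse partial-correlation estimation (ESPACE).

The estimator solves the joint ℓ1-penalized regression

    min_ρ  (1/2) Σ_i w_i Σ_k ( X_i^k − Σ_{j≠i} ρ^{ij} √(ω_jj/ω_ii) X_j^k )²
           + αλ Σ_{i<j, hub-adjacent} |ρ^{ij}|  +  λ Σ_{i<j, both non-hub} |ρ^{ij}|

over the p(p−1)/2 partial correlations ρ^{ij}, where 0 < α ≤ 1 relaxes the
penalty on edges touching a previously known hub gene.  With α = 1 or an
empty hub set this is the plain SPACE estimator.  The diagonal precision
entries ω_ii are not penalized; they are re-estimated from residual
variances in an outer fixed-point loop.

The solver is an "active shooting" coordinate descent: after a marginal
soft-threshold initialization it cycles intensively over the currently
nonzero coordinates, then performs full sweeps over all pairs, and repeats
until the largest coordinate change falls below the tolerance τ and the
exact subgradient (KKT) residual is below 10τ.  Residuals are maintained
incrementally so each coordinate update costs O(n).
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

from .data import ExpressionMatrix, FitConfig, HubSet, PartialCorrSolution

__all__ = [
    "soft_threshold",
    "pair_gram",
    "penalty_vector",
    "objective",
    "kkt_residuals",
    "fit",
    "edges_from_solution",
    "Edge",
    "lambda_max",
]

logger = logging.getLogger(__name__)


def soft_threshold(x: float, t: float) -> float:
    """sign(x) · max(|x| − t, 0), the scalar ℓ1 proximal map."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    ax = abs(x) - t
    if ax <= 0:
        return 0.0
    return ax if x > 0 else -ax


def pair_gram(Xi: np.ndarray, Xj: np.ndarray, wii: float, wjj: float) -> tuple[float, float]:
    """Inner products of the stacked pair design with the stacked response.

    For the pair (i, j) the stacked regressor places √(ω_jj/ω_ii)·X_j in
    block i and √(ω_ii/ω_jj)·X_i in block j of an np-vector.  Both inner
    products collapse to O(n) sums and are returned without materializing
    the stacked vectors:

        cross   = (√(ω_jj/ω_ii) + √(ω_ii/ω_jj)) Σ_k X_i^k X_j^k
        norm_sq = (ω_jj/ω_ii) Σ_k (X_j^k)² + (ω_ii/ω_jj) Σ_k (X_i^k)²
    """
    Xi = np.asarray(Xi, dtype=float)
    Xj = np.asarray(Xj, dtype=float)
    if Xi.size == 0 or Xj.size == 0:
        raise ValueError("empty expression vectors")
    if Xi.shape != Xj.shape:
        raise ValueError("Xi and Xj must have the same length")
    if not (wii > 0 and wjj > 0):
        raise ValueError("omega diagonal entries must be positive")
    r = np.sqrt(wjj / wii)
    cross = (r + 1.0 / r) * float(Xi @ Xj)
    norm_sq = (wjj / wii) * float(Xj @ Xj) + (wii / wjj) * float(Xi @ Xi)
    return cross, norm_sq


def penalty_vector(p: int, hubs: HubSet, lam: float, alpha: float) -> np.ndarray:
    """Per-pair ℓ1 penalty: αλ for hub-adjacent pairs, λ otherwise."""
    hub_mask = hubs.mask(p)
    iu, ju = np.triu_indices(p, k=1)
    pen = np.where(hub_mask[iu] | hub_mask[ju], alpha * lam, lam)
    return pen


def _residual_matrix(Xc: np.ndarray, rho_mat: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """n x p matrix of per-gene regression residuals r_i = X_i − Σ_j β_ij X_j."""
    sw = np.sqrt(omega)
    B = rho_mat * (sw[np.newaxis, :] / sw[:, np.newaxis])  # B[i, j] = ρ^{ij}√(ω_jj/ω_ii)
    np.fill_diagonal(B, 0.0)
    return Xc - Xc @ B.T


def objective(
    X: ExpressionMatrix,
    rho: np.ndarray,
    omega_diag: np.ndarray,
    hubs: HubSet,
    lam: float,
    alpha: float,
    weights: np.ndarray | None = None,
) -> float:
    """Penalized squared-error objective at a given (ρ, ω) point."""
    p = X.n_genes
    omega_diag = np.asarray(omega_diag, dtype=float)
    if np.any(omega_diag <= 0):
        raise ValueError("omega_diag must be strictly positive")
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (p * (p - 1) // 2,):
        raise ValueError("rho has wrong length")
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    rho_mat = np.zeros((p, p))
    iu, ju = np.triu_indices(p, k=1)
    rho_mat[iu, ju] = rho
    rho_mat[ju, iu] = rho
    R = _residual_matrix(X.values, rho_mat, omega_diag)
    loss = 0.5 * float(w @ (R**2).sum(axis=0))
    pen = penalty_vector(p, hubs, lam, alpha)
    return loss + float(pen @ np.abs(rho))


def kkt_residuals(
    X: ExpressionMatrix,
    rho: np.ndarray,
    omega_diag: np.ndarray,
    hubs: HubSet,
    lam: float,
    alpha: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Subgradient optimality residual per pair, at fixed omega_diag.

    For a zero coordinate the residual is (|∂loss/∂ρ| − penalty)_+; for a
    nonzero coordinate it is |∂loss/∂ρ + penalty·sign(ρ)|.  A minimizer has
    all residuals equal to zero.
    """
    p = X.n_genes
    n = X.n_samples
    rho = np.asarray(rho, dtype=float)
    omega = np.asarray(omega_diag, dtype=float)
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    iu, ju = np.triu_indices(p, k=1)
    rho_mat = np.zeros((p, p))
    rho_mat[iu, ju] = rho
    rho_mat[ju, iu] = rho
    R = _residual_matrix(X.values, rho_mat, omega)
    sw = np.sqrt(omega)
    M = X.values.T @ R  # M[a, b] = X_a · r_b
    # full-residual correlate c_full[i,j]; gradient of the loss is −c_full
    c_full = (w[iu] * (sw[ju] / sw[iu]) * M[ju, iu]
              + w[ju] * (sw[iu] / sw[ju]) * M[iu, ju])
    grad = -c_full
    pen = penalty_vector(p, hubs, lam, alpha)
    nz = rho != 0
    res = np.empty_like(rho)
    res[~nz] = np.maximum(np.abs(grad[~nz]) - pen[~nz], 0.0)
    res[nz] = np.abs(grad[nz] + pen[nz] * np.sign(rho[nz]))
    return res


@njit(cache=True, fastmath=True)
def _update_pair(i, j, Xt, R, rho, sw, lw, Gd, pen_ij):  # pragma: no cover - jitted
    n = Xt.shape[1]
    sji = sw[j] / sw[i]  # multiplies X_j inside r_i
    sij = sw[i] / sw[j]
    old = rho[i, j]
    if old != 0.0:
        for k in range(n):
            R[i, k] += old * sji * Xt[j, k]
            R[j, k] += old * sij * Xt[i, k]
    c = 0.0
    for k in range(n):
        c += lw[i] * sji * Xt[j, k] * R[i, k] + lw[j] * sij * Xt[i, k] * R[j, k]
    curv = lw[i] * sji * sji * Gd[j] + lw[j] * sij * sij * Gd[i]
    ac = abs(c) - pen_ij
    if ac <= 0.0:
        new = 0.0
    else:
        new = ac / curv if c > 0 else -ac / curv
    if new != 0.0:
        for k in range(n):
            R[i, k] -= new * sji * Xt[j, k]
            R[j, k] -= new * sij * Xt[i, k]
    rho[i, j] = new
    rho[j, i] = new
    return abs(new - old)


@njit(cache=True, fastmath=True)
def _solve_rho(Xt, omega, lw, pen, tol, max_inner, max_sweep):  # pragma: no cover - jitted
    """Active-shooting coordinate descent at fixed omega diagonal.

    Returns (rho matrix, residual matrix, sweeps used, kkt-ish max change,
    converged flag).  pen is the p x p penalty matrix (upper triangle used).
    """
    p, n = Xt.shape
    sw = np.sqrt(omega)
    Gd = np.empty(p)
    for i in range(p):
        s = 0.0
        for k in range(n):
            s += Xt[i, k] * Xt[i, k]
        Gd[i] = s
    rho = np.zeros((p, p))
    R = Xt.copy()
    # marginal soft-threshold initialization over all pairs
    for i in range(p - 1):
        for j in range(i + 1, p):
            sji = sw[j] / sw[i]
            sij = sw[i] / sw[j]
            d = 0.0
            for k in range(n):
                d += Xt[i, k] * Xt[j, k]
            c = (lw[i] * sji + lw[j] * sij) * d
            curv = lw[i] * sji * sji * Gd[j] + lw[j] * sij * sij * Gd[i]
            ac = abs(c) - pen[i, j]
            if ac > 0.0:
                v = ac / curv if c > 0 else -ac / curv
                rho[i, j] = v
                rho[j, i] = v
                for k in range(n):
                    R[i, k] -= v * sji * Xt[j, k]
                    R[j, k] -= v * sij * Xt[i, k]
    m = p * (p - 1) // 2
    ai = np.empty(m, dtype=np.int64)
    aj = np.empty(m, dtype=np.int64)
    n_sweeps = 0
    converged = False
    last_delta = np.inf
    for _sweep in range(max_sweep):
        # collect active set
        na = 0
        for i in range(p - 1):
            for j in range(i + 1, p):
                if rho[i, j] != 0.0:
                    ai[na] = i
                    aj[na] = j
                    na += 1
        # intensive cycles over the active set; drop zeroed coordinates
        for _it in range(max_inner):
            maxd = 0.0
            q = 0
            while q < na:
                i = ai[q]
                j = aj[q]
                d = _update_pair(i, j, Xt, R, rho, sw, lw, Gd, pen[i, j])
                if d > maxd:
                    maxd = d
                if rho[i, j] == 0.0:
                    na -= 1
                    ai[q] = ai[na]
                    aj[q] = aj[na]
                else:
                    q += 1
            if maxd < tol:
                break
        # one full sweep over all pairs
        maxd_full = 0.0
        for i in range(p - 1):
            for j in range(i + 1, p):
                d = _update_pair(i, j, Xt, R, rho, sw, lw, Gd, pen[i, j])
                if d > maxd_full:
                    maxd_full = d
        n_sweeps += 1
        last_delta = maxd_full
        if maxd_full < tol:
            converged = True
            break
    return rho, R, n_sweeps, last_delta, converged


def lambda_max(X: ExpressionMatrix, weights: np.ndarray | None = None) -> float:
    """Smallest λ for which the α = 1 marginal initialization is all-zero.

    Evaluated at the starting point ω_ii = 1, where the correlate of pair
    (i, j) is (w_i + w_j)·X_i·X_j; any λ at or above the largest absolute
    correlate yields an empty model.
    """
    p = X.n_genes
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    G = X.values.T @ X.values
    iu, ju = np.triu_indices(p, k=1)
    return float(np.max(np.abs((w[iu] + w[ju]) * G[iu, ju])))


def fit(
    X: ExpressionMatrix,
    hubs: HubSet,
    config: FitConfig,
    omega_init: np.ndarray | None = None,
) -> PartialCorrSolution:
    """Estimate sparse partial correlations by active-shooting descent.

    The outer loop alternates a full ρ solve at fixed ω (re-initialized by
    the marginal soft-threshold each time) with the residual-variance
    update 1/ω_ii = (1/n)‖r_i‖², applied Jacobi-style (all ω updated from
    the previous iterate), until the ω fixed point stabilizes.  The
    returned ρ is the minimizer at the returned ω, so the KKT certificate
    holds at the reported solution.

    omega_init optionally warm-starts the ω diagonal (used when sweeping a
    λ grid); the default is the all-ones start.
    """
    p = X.n_genes
    n = X.n_samples
    if p < 2:
        raise ValueError("need at least two genes")
    if not X.is_centered(tol=1e-8):
        raise ValueError("expression matrix must be mean-centered; apply preprocess() first")
    hubs.validate(p)
    if config.lam == 0 and n <= p:
        raise ValueError("lam=0 requires n > p (otherwise the problem is ill-posed)")
    col_ss = (X.values**2).sum(axis=0)
    if np.any(col_ss == 0):
        raise ValueError("zero-variance gene column")

    lw = config.resolved_weights(p)
    pen_vec = penalty_vector(p, hubs, config.lam, config.alpha)
    iu, ju = np.triu_indices(p, k=1)
    pen = np.zeros((p, p))
    pen[iu, ju] = pen_vec
    pen[ju, iu] = pen_vec
    Xt = np.ascontiguousarray(X.values.T)

    omega = np.ones(p) if omega_init is None else np.asarray(omega_init, dtype=float).copy()
    omega_rtol = config.tol  # relative fixed-point tolerance on the omega map
    total_sweeps = 0
    rho_converged = False
    omega_converged = False
    rho_mat = np.zeros((p, p))
    R = Xt.copy()
    n_omega_iters = 0
    # Steffensen bookkeeping: a pair of consecutive plain updates yields a
    # secant estimate of the linear contraction rate, which is used to
    # extrapolate to the fixed point (r < 0 damps oscillatory updates).
    prev_omega: np.ndarray | None = None
    prev_F: np.ndarray | None = None
    best_delta = np.inf
    best_iter = 0
    delta_rel = np.inf
    tight = False
    for _s in range(config.max_omega_iter):
        # intermediate omega iterates only steer the fixed point, so their
        # rho solves may run at a relaxed tolerance; convergence is only
        # ever declared from a full-tolerance ("tight") solve
        tight = delta_rel < 100 * omega_rtol or _s == config.max_omega_iter - 1
        inner_tol = config.tol if tight else min(1e-4, max(config.tol, 1e-3 * delta_rel))
        rho_mat, R, sweeps, last_delta, rho_converged = _solve_rho(
            Xt, omega, lw, pen, inner_tol, config.max_inner_iter, config.max_sweep_iter
        )
        # enforce the subgradient certificate, not just small coordinate
        # steps, tightening the inner tolerance geometrically if needed
        if tight and rho_converged:
            for _extra in range(4):
                res = _kkt_from_state(Xt, R, rho_mat, omega, lw, pen_vec, iu, ju)
                if res <= 10 * config.tol:
                    break
                inner_tol /= 10.0
                rho_mat, R, sweeps2, last_delta, rho_converged = _solve_rho(
                    Xt, omega, lw, pen, inner_tol, config.max_inner_iter,
                    config.max_sweep_iter,
                )
                sweeps += sweeps2
        total_sweeps += sweeps
        n_omega_iters += 1
        F = n / (R**2).sum(axis=1)
        delta = F - omega
        delta_rel = float(np.max(np.abs(delta) / omega))
        if tight and delta_rel < omega_rtol:
            omega_converged = True
            break  # keep omega: rho is the minimizer at this omega
        if delta_rel < best_delta:
            best_delta = delta_rel
            best_iter = _s
        elif _s - best_iter >= 6:
            # the omega map is cycling rather than contracting (it has no
            # attracting fixed point in the dense/overfit regime); stop
            # early and report the non-converged solution
            break
        if _s == config.max_omega_iter - 1:
            break  # keep the omega the final rho solve used
        if prev_omega is not None:
            d1 = prev_F - prev_omega
            d2 = F - prev_F
            den = float(d1 @ d1)
            r = float(d2 @ d1) / den if den > 0 else 0.0
            prev_omega = prev_F = None
            if -0.999 < r < 0.98:
                cand = F + (r / (1.0 - r)) * d2
                if np.all(cand > 1e-12):
                    omega = cand
                    continue
            omega = F
        else:
            prev_omega = omega
            prev_F = F
            omega = F

    converged = bool(rho_converged and omega_converged)
    if not converged:
        logger.warning(
            "fit did not converge (rho_converged=%s, omega_converged=%s, "
            "omega_iters=%d, sweeps=%d)", rho_converged, omega_converged,
            n_omega_iters, total_sweeps,
        )
    rho_vec = rho_mat[iu, ju]
    obj = objective(X, rho_vec, omega, hubs, config.lam, config.alpha, lw)
    return PartialCorrSolution(
        rho=rho_vec,
        omega_diag=omega,
        n_omega_iters=n_omega_iters,
        n_sweeps=total_sweeps,
        converged=converged,
        objective_value=obj,
    )


def _kkt_from_state(Xt, R, rho_mat, omega, lw, pen_vec, iu, ju) -> float:
    """Max subgradient residual from the solver's incremental state."""
    sw = np.sqrt(omega)
    M = Xt @ R.T  # M[a, b] = X_a · r_b
    c_full = (lw[iu] * (sw[ju] / sw[iu]) * M[ju, iu]
              + lw[ju] * (sw[iu] / sw[ju]) * M[iu, ju])
    rho = rho_mat[iu, ju]
    nz = rho != 0
    res = np.where(
        nz,
        np.abs(-c_full + pen_vec * np.sign(rho)),
        np.maximum(np.abs(c_full) - pen_vec, 0.0),
    )
    return float(res.max()) if res.size else 0.0


class Edge(tuple):
    """(gene_a, gene_b, partial_correlation, hub_adjacent) record."""

    __slots__ = ()

    def __new__(cls, gene_a: str, gene_b: str, rho: float, hub_adjacent: bool):
        return super().__new__(cls, (gene_a, gene_b, float(rho), bool(hub_adjacent)))

    @property
    def gene_a(self) -> str:
        return self[0]

    @property
    def gene_b(self) -> str:
        return self[1]

    @property
    def rho(self) -> float:
        return self[2]

    @property
    def hub_adjacent(self) -> bool:
        return self[3]


def edges_from_solution(
    sol: PartialCorrSolution,
    gene_ids: list[str] | tuple[str, ...],
    hubs: HubSet = HubSet(),
) -> list[Edge]:
    """One record per exactly-nonzero partial correlation.

    Coordinate descent produces exact zeros, so the zero test is exact;
    edges appear in the canonical pair order.
    """
    p = sol.p
    if len(gene_ids) != p:
        raise ValueError("gene_ids length inconsistent with solution")
    hub_mask = hubs.mask(p)
    iu, ju = np.triu_indices(p, k=1)
    edges = []
    for i, j, r in zip(iu.tolist(), ju.tolist(), sol.rho.tolist()):
        if r != 0.0:
            edges.append(Edge(gene_ids[i], gene_ids[j], r, bool(hub_mask[i] or hub_mask[j])))
    return edges
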