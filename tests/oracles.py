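"""Independent reference implementations used only by the test suite.

Each oracle solves the same mathematical problem as the package by a
different route (explicit stacked designs, generic smooth optimization,
proximal gradient, exhaustive enumeration), so agreement is evidence of
correctness rather than self-confirmation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def stacked_design(Xc: np.ndarray, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the np-dimensional stacked response Y and design X̃.

    Y concatenates the gene columns X_1, ..., X_p.  The column of X̃ for
    pair (i, j) holds √(ω_jj/ω_ii)·X_j in block i and √(ω_ii/ω_jj)·X_i in
    block j, zeros elsewhere.  Deliberately the naive O(np · m)
    construction the fast solver avoids.
    """
    n, p = Xc.shape
    Y = Xc.T.reshape(-1).astype(float)
    cols = []
    for i in range(p - 1):
        for j in range(i + 1, p):
            v = np.zeros(n * p)
            v[i * n:(i + 1) * n] = np.sqrt(omega[j] / omega[i]) * Xc[:, j]
            v[j * n:(j + 1) * n] = np.sqrt(omega[i] / omega[j]) * Xc[:, i]
            cols.append(v)
    return Y, np.column_stack(cols)


def pair_penalties(p: int, hub_indices: set[int], lam: float, alpha: float) -> np.ndarray:
    pen = []
    for i in range(p - 1):
        for j in range(i + 1, p):
            pen.append(alpha * lam if (i in hub_indices or j in hub_indices) else lam)
    return np.array(pen)


def lasso_lbfgs(A: np.ndarray, y: np.ndarray, pen: np.ndarray) -> np.ndarray:
    """min_x ½‖y − Ax‖² + Σ pen_k|x_k| via the positive/negative split.

    Writing x = u − v with u, v ≥ 0 turns the ℓ1 term into a linear one,
    leaving a smooth bound-constrained problem for L-BFGS-B.
    """
    m = A.shape[1]
    AtA = A.T @ A
    Aty = A.T @ y
    yty = float(y @ y)

    def fun(z):
        u, v = z[:m], z[m:]
        x = u - v
        g_smooth = AtA @ x - Aty
        f = 0.5 * (x @ AtA @ x) - float(Aty @ x) + 0.5 * yty + float(pen @ (u + v))
        grad = np.concatenate([g_smooth + pen, -g_smooth + pen])
        return f, grad

    z0 = np.zeros(2 * m)
    res = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * m),
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[:m] - res.x[m:]


def espace_fixed_omega(Xc: np.ndarray, omega: np.ndarray, hub_indices: set[int],
                       lam: float, alpha: float) -> np.ndarray:
    """Minimizer of the pairwise objective at fixed omega, by generic solver."""
    Y, A = stacked_design(Xc, omega)
    pen = pair_penalties(Xc.shape[1], hub_indices, lam, alpha)
    return lasso_lbfgs(A, Y, pen)


def glasso_penalized_loglik(Omega: np.ndarray, S: np.ndarray, P: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return -np.inf
    off = np.sum(np.triu(P, 1) * np.abs(np.triu(Omega, 1)))
    diag = float(np.diag(P) @ np.abs(np.diag(Omega)))
    return float(logdet - np.trace(S @ Omega) - 2.0 * off - diag)


def glasso_ista(S: np.ndarray, P: np.ndarray, max_iter: int = 50000,
                tol: float = 1e-11) -> np.ndarray:
    """Proximal-gradient (ISTA) maximizer of the penalized log-likelihood.

    Gradient step on −log|Ω| + tr(SΩ) followed by elementwise
    soft-thresholding at the penalty matrix P, with backtracking to keep
    the iterate positive definite and ascending.
    """
    p = S.shape[0]
    Omega = np.diag(1.0 / (np.diag(S) + np.diag(P)))
    f = glasso_penalized_loglik(Omega, S, P)
    t = 1.0
    for _ in range(max_iter):
        grad = np.linalg.inv(Omega) - S  # ascent direction of the smooth part
        stepped = False
        while t > 1e-14:
            Z = Omega + t * grad
            cand = np.sign(Z) * np.maximum(np.abs(Z) - t * P, 0.0)
            cand = 0.5 * (cand + cand.T)
            f_cand = glasso_penalized_loglik(cand, S, P)
            if np.isfinite(f_cand) and f_cand >= f - 1e-15:
                stepped = True
                break
            t *= 0.5
        if not stepped:
            break
        delta = np.max(np.abs(cand - Omega))
        Omega, f = cand, f_cand
        t = min(t * 1.5, 10.0)
        if delta < tol:
            break
    return Omega


def confusion_bruteforce(true_edges, est_edges, p):
    """Exhaustive enumeration over all unordered pairs."""
    t = {(min(i, j), max(i, j)) for i, j in true_edges}
    e = {(min(i, j), max(i, j)) for i, j in est_edges}
    tp = fp = fn = tn = 0
    for i in range(p - 1):
        for j in range(i + 1, p):
            in_t, in_e = (i, j) in t, (i, j) in e
            if in_t and in_e:
                tp += 1
            elif in_e:
                fp += 1
            elif in_t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
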