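"""Synthetic hub-structured networks and Gaussian expression data.

The generator mirrors the standard benchmark recipe for Gaussian
graphical-model recovery studies:

1. build a sparse undirected network in which a few designated hub nodes
   carry degree ≥ 8 while background nodes keep degrees in the 0–3 range;
2. turn the edge set into a positive-definite precision matrix by drawing
   edge weights from Unif([−1,−0.5] ∪ [0.5,1]), row-normalizing by 1.5×
   the absolute row sum, symmetrizing, resetting the diagonal to one and
   flooring tiny surviving entries at magnitude 0.1;
3. standardize the implied covariance to unit diagonal,
   Σ_ij = (Ω⁻¹)_ij / √((Ω⁻¹)_ii (Ω⁻¹)_jj);
4. sample i.i.d. multivariate-normal expression rows, optionally adding
   independent measurement noise Z = X + ε, ε ~ N(0, σ_ε² I).

A 3-gene worked example with closed-form covariance is included to show
how additive noise creates spurious conditional dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .data import ExpressionMatrix, HubSet

__all__ = [
    "NetworkStructure",
    "NoiseConfig",
    "generate_precision",
    "precision_to_covariance",
    "sample_expression",
    "add_noise",
    "worked_example",
    "hub_network",
]


@dataclass(frozen=True)
class NetworkStructure:
    """An undirected graph on nodes 0..p−1 given by its edge set."""

    p: int
    edges: frozenset[tuple[int, int]]
    hubs: HubSet = HubSet()

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be positive")
        norm = set()
        for i, j in self.edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < self.p and 0 <= j < self.p):
                raise ValueError(f"edge ({i},{j}) out of range for p={self.p}")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))
        self.hubs.validate(self.p)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.p, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass(frozen=True)
class NoiseConfig:
    """Variance σ_ε² of i.i.d. additive measurement noise, plus its seed."""

    sigma_eps_sq: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_eps_sq < 0:
            raise ValueError("noise variance must be nonnegative")


def _draw_edge_weight(rng: np.random.Generator) -> float:
    """Unif on [−1,−0.5] ∪ [0.5,1], each half-interval with probability ½."""
    mag = rng.uniform(0.5, 1.0)
    return mag if rng.random() < 0.5 else -mag


def generate_precision(net: NetworkStructure, seed: int, max_attempts: int = 100) -> np.ndarray:
    """Positive-definite precision matrix supported on the given edge set.

    Edge weights are drawn from Unif([−1,−0.5]∪[0.5,1]); rows are scaled
    by 1/(1.5·Σ_k |ω̃_ik|) (isolated nodes contribute zero rows and the
    division is skipped), the result symmetrized as (A + Aᵀ)/2, the
    diagonal reset to 1, and entries with 0 < |ω_ij| < 0.1 floored to
    0.1·sign(ω_ij).  Non-positive-definite draws are resampled with an
    incremented seed, up to ``max_attempts``.
    """
    p = net.p
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        Om_t = np.eye(p)
        for i, j in sorted(net.edges):
            w = _draw_edge_weight(rng)
            Om_t[i, j] = w
            Om_t[j, i] = w
        d = np.abs(Om_t).sum(axis=1) - 1.0  # off-diagonal absolute row sums
        A = np.zeros((p, p))
        for i in range(p):
            if d[i] > 0:
                A[i, :] = Om_t[i, :] / (1.5 * d[i])
            # isolated node: row contributes zeros
        Om = 0.5 * (A + A.T)
        np.fill_diagonal(Om, 1.0)
        small = (np.abs(Om) > 0) & (np.abs(Om) < 0.1)
        np.fill_diagonal(small, False)
        Om[small] = 0.1 * np.sign(Om[small])
        try:
            np.linalg.cholesky(Om)
        except np.linalg.LinAlgError:
            continue
        return Om
    raise RuntimeError(f"no positive-definite precision matrix in {max_attempts} attempts")


def precision_to_covariance(Om: np.ndarray) -> np.ndarray:
    """Correlation-standardized inverse: Σ_ij = (Ω⁻¹)_ij/√((Ω⁻¹)_ii(Ω⁻¹)_jj)."""
    Om = np.asarray(Om, dtype=float)
    inv = np.linalg.inv(Om)
    s = np.sqrt(np.diag(inv))
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise np.linalg.LinAlgError("inverse has nonpositive diagonal")
    Sigma = inv / np.outer(s, s)
    np.fill_diagonal(Sigma, 1.0)
    return 0.5 * (Sigma + Sigma.T)


def sample_expression(
    Sigma: np.ndarray,
    n: int,
    seed: int,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """n i.i.d. rows from N(0, Σ), deterministic per seed."""
    Sigma = np.asarray(Sigma, dtype=float)
    if n < 2:
        raise ValueError("need at least two samples")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, Sigma.shape[0]))
    return ExpressionMatrix.from_array(Z @ L.T, gene_ids)


def add_noise(X: ExpressionMatrix, cfg: NoiseConfig) -> ExpressionMatrix:
    """Observed data Z = X + ε with ε rows i.i.d. N(0, σ_ε² I)."""
    if cfg.sigma_eps_sq == 0:
        return X
    rng = np.random.default_rng(cfg.seed)
    eps = np.sqrt(cfg.sigma_eps_sq) * rng.standard_normal(X.values.shape)
    return ExpressionMatrix(values=X.values + eps, gene_ids=X.gene_ids, sample_ids=X.sample_ids)


def worked_example() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The 3-gene noise illustration: (Σ, Σ_Z, Σ⁻¹, Σ_Z⁻¹), σ_ε² = 0.5.

    X has a chain conditional-dependence structure — genes 1 and 3 are
    conditionally independent given gene 2 (zero (1,3) precision entry) —
    but the noisy observation Z = X + ε does not: its precision matrix has
    a nonzero (1,3) entry.  The inverses are computed, not hard-coded.
    """
    Sigma = np.array(
        [
            [Fraction(15, 11), Fraction(-8, 11), Fraction(2, 11)],
            [Fraction(-8, 11), Fraction(16, 11), Fraction(-4, 11)],
            [Fraction(2, 11), Fraction(-4, 11), Fraction(12, 11)],
        ],
        dtype=float,
    )
    SigmaZ = Sigma + 0.5 * np.eye(3)
    return Sigma, SigmaZ, np.linalg.inv(Sigma), np.linalg.inv(SigmaZ)


def hub_network(
    p: int,
    n_hubs: int,
    hub_degree_range: tuple[int, int] = (8, 12),
    background_degree_mean: float = 1.5,
    seed: int = 0,
    max_attempts: int = 50,
) -> NetworkStructure:
    """Random sparse network with ``n_hubs`` designated high-degree nodes.

    Hub nodes receive degrees drawn uniformly from ``hub_degree_range``
    (minimum 8, so they exceed the degree-7 hub rule); all other nodes
    keep small degrees (mean ≈ ``background_degree_mean``, capped at 5 so
    no background node can be mistaken for a hub).  The designated hub
    indices are recorded on the returned structure.
    """
    lo, hi = hub_degree_range
    if lo < 8:
        raise ValueError("hub degrees must be at least 8 to satisfy the hub rule")
    if n_hubs < 0 or n_hubs > p:
        raise ValueError("invalid number of hubs")
    if n_hubs > 0 and (p - 1) < lo:
        raise ValueError("p too small for the requested hub degrees")
    if n_hubs * lo > p * (p - 1) // 2:
        raise ValueError("infeasible hub degree demand")
    bg_cap = 5
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        hubs = rng.choice(p, size=n_hubs, replace=False) if n_hubs else np.empty(0, dtype=int)
        hub_set = set(int(h) for h in hubs)
        deg = np.zeros(p, dtype=int)
        edges: set[tuple[int, int]] = set()

        def try_add(a: int, b: int) -> bool:
            if a == b:
                return False
            e = (min(a, b), max(a, b))
            if e in edges:
                return False
            for v in (a, b):
                cap = hi if v in hub_set else bg_cap
                if deg[v] + 1 > cap:
                    return False
            edges.add(e)
            deg[a] += 1
            deg[b] += 1
            return True

        ok = True
        for h in hub_set:
            target = int(rng.integers(lo, hi + 1))
            others = rng.permutation(p)
            for v in others:
                if deg[h] >= target:
                    break
                try_add(int(h), int(v))
            if deg[h] < lo:
                ok = False
                break
        if not ok:
            continue
        # background edges among non-hub pairs until the mean degree target
        non_hubs = [v for v in range(p) if v not in hub_set]
        n_bg_target = max(0, int(round(background_degree_mean * len(non_hubs) / 2)) - 0)
        budget = n_bg_target - sum(deg[v] for v in non_hubs) // 2
        trials = 0
        while budget > 0 and trials < 50 * p:
            a, b = rng.choice(len(non_hubs), size=2, replace=False)
            if try_add(non_hubs[int(a)], non_hubs[int(b)]):
                budget -= 1
            trials += 1
        net = NetworkStructure(p=p, edges=frozenset(edges), hubs=HubSet(frozenset(hub_set)))
        d = net.degrees()
        if n_hubs and (min(d[list(hub_set)]) < 8):
            continue
        if any(d[v] > 7 for v in non_hubs):
            continue
        return net
    raise RuntimeError("could not generate a hub network with the requested parameters")
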