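"""Shared fixtures: simulated datasets and the recovery-study pipeline.

The two heavyweight session fixtures (`direction_study`, `noise_study`)
run the full simulate → select-by-GIC → score pipeline over many
replicates; several tests inspect different aspects of the same runs so
the simulations execute once per session.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from espace import (
    HubSet,
    NoiseConfig,
    add_noise,
    confusion,
    default_grid,
    generate_precision,
    hub_network,
    pair_list,
    performance,
    precision_to_covariance,
    preprocess,
    sample_expression,
    select,
)


def simulate_dataset(p: int, n: int, n_hubs: int, seed: int, sigma_eps_sq: float = 0.0,
                     scale: bool = True):
    """Network, precision matrix and preprocessed expression data."""
    net = hub_network(p, n_hubs, seed=seed)
    Om = generate_precision(net, seed=seed + 1000)
    Sigma = precision_to_covariance(Om)
    X = sample_expression(Sigma, n, seed=seed + 2000)
    if sigma_eps_sq > 0:
        X = add_noise(X, NoiseConfig(sigma_eps_sq=sigma_eps_sq, seed=seed + 3000))
    return net, Om, preprocess(X, scale=scale)


def mcc_of_rho(net, rho) -> float:
    pairs = pair_list(net.p)
    est = [pr for pr, r in zip(pairs, rho) if r != 0]
    return performance(confusion(net.edges, est, net.p), net.p).mcc


def run_replicate(seed: int, p: int = 40, n: int = 40, sigma_eps_sq: float = 0.0):
    """One recovery replicate: returns (mcc_espace, mcc_space, alpha_star).

    ESPACE receives the true hub list and selects (λ, α) by GIC; SPACE is
    read off the α = 1 column of the same GIC table (at α = 1 the hub set
    is irrelevant), then refit to confirm the reduction identity holds in
    the scoring path too.
    """
    net, _, Xc = simulate_dataset(p, n, 3, seed, sigma_eps_sq)
    res = select(Xc, net.hubs)
    mcc_e = mcc_of_rho(net, res.best_fit.rho)
    res_s = select(Xc, HubSet(), default_grid(Xc, alphas=(1.0,)))
    mcc_s = mcc_of_rho(net, res_s.best_fit.rho)
    return mcc_e, mcc_s, res.alpha_star


@dataclass(frozen=True)
class StudyResult:
    mcc_espace: tuple[float, ...]
    mcc_space: tuple[float, ...]
    alpha_star: tuple[float, ...]


@pytest.fixture(scope="session")
def direction_study() -> StudyResult:
    """50 noise-free replicates at p = n = 40 with 3 true hubs."""
    rows = [run_replicate(1000 + s) for s in range(50)]
    return StudyResult(
        mcc_espace=tuple(r[0] for r in rows),
        mcc_space=tuple(r[1] for r in rows),
        alpha_star=tuple(r[2] for r in rows),
    )


@pytest.fixture(scope="session")
def noise_study() -> dict[float, StudyResult]:
    """15 replicates per noise variance at fixed p = n = 40."""
    out = {}
    for sigma in (0.0, 0.1, 0.5):
        rows = [run_replicate(5000 + s, sigma_eps_sq=sigma) for s in range(15)]
        out[sigma] = StudyResult(
            mcc_espace=tuple(r[0] for r in rows),
            mcc_space=tuple(r[1] for r in rows),
            alpha_star=tuple(r[2] for r in rows),
        )
    return out


@pytest.fixture()
def small_dataset():
    """A modest p = 20, n = 60 instance for fast structural tests."""
    return simulate_dataset(20, 60, 1, seed=42)
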