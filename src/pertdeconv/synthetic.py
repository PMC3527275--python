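"""Synthetic reference sets and heterogeneous mixtures with known truth.

The generator inverts the multinomial-mixture view of deconvolution: draw
K reference gene distributions from a Dirichlet, draw per-sample mixing
weights theta* on the simplex, optionally apply a shared log-normal
multiplicative perturbation rho* and/or inject a hidden population absent
from the references, then sample N discrete observations per sample. With
rho_sigma = 0 and hidden_fraction = 0 this is exactly the matched-reference
generative model, so every fitter has a scenario where its assumptions hold
by construction.

Defaults are desk-scale: K=8 populations, G=2000 genes, D=4 samples and
N=1e6 observations per sample (scaled down from study-scale K=118,
G=22215, N~1.7e7). rho_sigma=0.5 puts ~16% of genes past the 2-fold
threshold, a plausible magnitude for a culture effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    DigitalMixture,
    GeneIndex,
    ReferenceDistributions,
    ValidationError,
)
from .models import MixtureProportions, NEW_POPULATION_NAME

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_references",
    "simulate_mixture",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    K: int = 8
    G: int = 2000
    D: int = 4
    N: int = 1_000_000
    theta_concentration: float = 1.0
    reference_concentration: float = 0.5
    rho_sigma: float = 0.0
    hidden_fraction: float = 0.0
    hidden_min_tv: float = 0.2  # min total-variation distance to each reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.G < 2 or self.D < 1 or self.N < 1:
            raise ValidationError("require K >= 1, G >= 2, D >= 1, N >= 1")
        if not (0.0 <= self.hidden_fraction < 1.0):
            raise ValidationError("hidden_fraction must lie in [0, 1)")
        if self.rho_sigma < 0:
            raise ValidationError("rho_sigma must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic study (theta* includes the hidden
    population as its last column when one was injected)."""

    beta_star: ReferenceDistributions
    theta_star: MixtureProportions
    rho_star: np.ndarray  # unit vector when rho_sigma = 0
    hidden_profile: np.ndarray | None
    counts: DigitalMixture
    seed: int


def _gene_index(G: int) -> GeneIndex:
    return GeneIndex(tuple(f"gene{i + 1}" for i in range(G)))


def simulate_references(
    K: int, G: int, reference_concentration: float = 0.5, seed: int = 0
) -> ReferenceDistributions:
    """K independent Dirichlet(c * 1_G) gene distributions."""
    if K < 1 or G < 2:
        raise ValidationError("require K >= 1 and G >= 2")
    rng = np.random.default_rng(seed)
    beta = rng.dirichlet(np.full(G, reference_concentration), size=K)
    beta /= beta.sum(axis=1, keepdims=True)
    return ReferenceDistributions(
        genes=_gene_index(G),
        population_names=tuple(f"pop{k + 1}" for k in range(K)),
        beta=beta,
        totals=np.full(K, 1e7),
    )


def _perturbed(beta: np.ndarray, rho: np.ndarray | None) -> np.ndarray:
    if rho is None:
        return beta
    prod = beta * rho[None, :]
    return prod / prod.sum(axis=1, keepdims=True)


def simulate_mixture(
    beta: ReferenceDistributions | np.ndarray,
    theta_row: np.ndarray,
    N: int,
    rho: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One sample: N multinomial observations from sum_k theta_k*gamma_k(rho)."""
    B = beta.beta if isinstance(beta, ReferenceDistributions) else np.asarray(beta, float)
    theta_row = np.asarray(theta_row, dtype=float)
    if theta_row.ndim != 1 or theta_row.size != B.shape[0]:
        raise ValidationError("theta_row length must equal the number of populations")
    if np.any(theta_row < 0) or abs(theta_row.sum() - 1.0) > 1e-8:
        raise ValidationError("theta_row must lie on the simplex")
    if N < 1:
        raise ValidationError("N must be >= 1")
    p = theta_row @ _perturbed(B, rho)
    p = np.maximum(p, 0)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(N), p)


def _draw_hidden_profile(rng, beta: np.ndarray, concentration: float,
                         min_tv: float, max_tries: int = 200) -> np.ndarray:
    G = beta.shape[1]
    for _ in range(max_tries):
        cand = rng.dirichlet(np.full(G, concentration))
        tv = 0.5 * np.abs(beta - cand[None, :]).sum(axis=1)
        if np.all(tv >= min_tv):
            return cand
    raise ValidationError(
        f"could not draw a hidden profile at total-variation distance "
        f">= {min_tv} from every reference"
    )


def simulate_study(config: SimulationConfig) -> SimulationTruth:
    """Full synthetic study: references, truth, and per-sample counts.

    rho* is log-normal(0, rho_sigma^2), anchored so its beta-weighted mean
    is 1 (matching the fitter's reporting convention); the hidden
    population, when requested, takes ``hidden_fraction`` of every sample,
    removed proportionally from the reference populations' weights. The
    perturbation applies to the reference populations (it maps reference to
    constituent condition); the hidden profile is already a constituent.
    """
    rng = np.random.default_rng(config.seed)
    refs = simulate_references(
        config.K, config.G, config.reference_concentration,
        seed=int(rng.integers(2**31)),
    )
    beta = refs.beta

    hidden = None
    if config.hidden_fraction > 0:
        hidden = _draw_hidden_profile(
            rng, beta, config.reference_concentration, config.hidden_min_tv
        )

    theta_ref = rng.dirichlet(np.full(config.K, config.theta_concentration),
                              size=config.D)
    if hidden is not None:
        theta = np.hstack([
            theta_ref * (1.0 - config.hidden_fraction),
            np.full((config.D, 1), config.hidden_fraction),
        ])
        pop_names = tuple(refs.population_names) + (NEW_POPULATION_NAME,)
    else:
        theta = theta_ref
        pop_names = refs.population_names

    if config.rho_sigma > 0:
        rho = rng.lognormal(mean=0.0, sigma=config.rho_sigma, size=config.G)
        rho /= float(beta.mean(axis=0) @ rho)
    else:
        rho = np.ones(config.G)

    constituents = _perturbed(beta, rho if config.rho_sigma > 0 else None)
    if hidden is not None:
        constituents = np.vstack([constituents, hidden])

    counts = np.empty((config.D, config.G), dtype=np.int64)
    for d in range(config.D):
        p = theta[d] @ constituents
        counts[d] = rng.multinomial(config.N, p / p.sum())

    return SimulationTruth(
        beta_star=refs,
        theta_star=MixtureProportions(
            theta=theta, population_names=pop_names,
            sample_names=tuple(f"sample{d + 1}" for d in range(config.D)),
        ),
        rho_star=rho,
        hidden_profile=hidden,
        counts=DigitalMixture(
            genes=refs.genes,
            sample_names=tuple(f"sample{d + 1}" for d in range(config.D)),
            counts=counts,
        ),
        seed=config.seed,
    )
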