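"""Deconvolution fitters: NNLS, NNML, NNML-np and PERT.

All four models estimate, for each heterogeneous sample d, the proportions
theta[d, k] of K reference cell populations. NNLS works on log2-scale
intensities with an additive-Gaussian noise model; the other three treat a
sample's expression as N_d ~ 1e7 discrete observations, each drawn from one
population's gene distribution beta_k, i.e. a multinomial mixture whose
noise variance scales with the mean — the LDA-style view of deconvolution.

NNML-np adds one latent population gamma (a distribution over genes, given
a Dirichlet prior centred on a convex combination of the references) to
absorb expression the provided references cannot explain. PERT instead
replaces every reference distribution beta_k by a perturbed constituent
distribution

    gamma[k, g] = rho[g] * beta[k, g] / sum_g' rho[g'] * beta[k, g'],

where a single positive vector rho of gene-wise fold changes is shared by
all populations and all samples; rho captures systematic transcriptional
shifts (e.g. cell-culture effects) between the conditions under which the
references and the mixtures were collected. rho carries a Gamma prior with
mean 1 and strength kappa so it introduces as few deviations as possible.

The latent per-observation population labels are never materialised: every
update uses the gene-level marginalised likelihood

    l(theta) = sum_d sum_g x[d, g] * ln( sum_k theta[d, k] * B[k, g] ),

which is mathematically identical and keeps memory at desk scale.
Optimisation is block coordinate ascent with closed-form EM updates for
theta and L-BFGS for rho; the penalized objective is non-decreasing across
iterations by construction (every block is guarded).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import gammaln, digamma

from .data_io import (
    DigitalMixture,
    ExpressionTable,
    ReferenceDistributions,
    ValidationError,
)

__all__ = [
    "MixtureProportions",
    "PerturbationEstimate",
    "NewPopulationEstimate",
    "FitOptions",
    "Responsibilities",
    "FitResult",
    "nnls_deconvolve",
    "nnml_loglik",
    "nnml_fit",
    "nnml_np_fit",
    "pert_fit",
    "perturb_reference",
    "responsibilities",
    "rho_log_objective",
]

_THETA_FLOOR = 1e-12
NEW_POPULATION_NAME = "new_population"


@dataclass
class MixtureProportions:
    """Estimated theta: rows (one per sample) on the simplex."""

    theta: np.ndarray  # (D, M)
    population_names: tuple[str, ...]
    sample_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.sample_names), len(self.population_names)):
            raise ValidationError("theta must have shape (D, M)")
        if np.any(self.theta < -1e-12) or np.any(self.theta > 1 + 1e-12):
            raise ValidationError("theta entries must lie in [0, 1]")
        if not np.allclose(self.theta.sum(axis=1), 1.0, rtol=0, atol=1e-8):
            raise ValidationError("theta rows must sum to 1 within 1e-8")


@dataclass
class PerturbationEstimate:
    """Shared gene-wise multiplicative perturbation rho (fold-change units).

    rho[g] > 1: gene g up-regulated in the mixtures' condition relative to
    the references; rho[g] < 1: down-regulated. Reported rho is anchored so
    that its reference-weighted mean, sum_g mean_k(beta[k, g]) * rho[g],
    equals 1 (the constituent distributions are invariant to rho's scale).
    """

    rho: np.ndarray
    kappa: float
    gene_ids: tuple[str, ...] | None = None
    anchor: str = "beta_weighted_mean"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.rho <= 0) or not np.all(np.isfinite(self.rho)):
            raise ValidationError("all rho entries must be positive and finite")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")


@dataclass
class NewPopulationEstimate:
    """Latent extra population: gene distribution gamma with its prior.

    The prior on gamma is Dirichlet with mean sum_k omega[k] * beta_k
    (omega convex) and concentration kappa * G.
    """

    gamma: np.ndarray
    omega: np.ndarray
    kappa: float
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if abs(self.gamma.sum() - 1.0) > 1e-10:
            raise ValidationError("gamma must sum to 1 within 1e-10")
        if np.any(self.omega < -1e-12) or abs(self.omega.sum() - 1.0) > 1e-8:
            raise ValidationError("omega must lie on the simplex")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")


@dataclass
class FitOptions:
    """Optimisation schedule shared by the probability-model fitters.

    alpha is a per-sample scalar symmetric-Dirichlet concentration on
    theta_d; it is constrained to alpha >= 1 so the prior stays proper on
    the closed simplex and the MAP-EM theta update remains monotone.
    kappa is the strength of the gamma-prior (NNML-np) or rho-prior (PERT),
    estimated by bounded search on a log scale within kappa_bounds.
    """

    max_iter: int = 2000
    rel_tol: float = 1e-8
    seed: int = 0
    optimizer: str = "em"
    alpha_mode: str = "per_sample"
    kappa_bounds: tuple[float, float] = (1e-2, 1e4)
    kappa_start: float = 10.0
    alpha_start: float = 1.0
    alpha_bounds: tuple[float, float] = (1.0, 1e6)
    estimate_kappa: bool = True
    estimate_alpha: bool = True
    inner_max_iter: int = 25

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValidationError("rel_tol must be positive")
        if self.kappa_bounds[0] <= 0 or self.kappa_bounds[0] >= self.kappa_bounds[1]:
            raise ValidationError("kappa_bounds must be an increasing positive pair")


@dataclass
class Responsibilities:
    """r[d, g, m]: posterior probability that an observed unit of gene g in
    sample d originated from population m (the marginalised latent labels)."""

    r: np.ndarray  # (D, G, M)


@dataclass
class FitResult:
    model: str
    proportions: MixtureProportions
    loglik: float
    logpost: float
    n_iter: int
    converged: bool
    n_obs: int
    perturbation: PerturbationEstimate | None = None
    new_population: NewPopulationEstimate | None = None
    kappa: float | None = None
    alpha: np.ndarray | None = None
    seed: int | None = None
    objective_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shared kernels


def _as_beta_array(beta) -> np.ndarray:
    if isinstance(beta, ReferenceDistributions):
        return beta.beta
    return np.asarray(beta, dtype=float)


def _check_dims(counts: DigitalMixture, B: np.ndarray) -> None:
    if counts.counts.shape[1] != B.shape[1]:
        raise ValidationError(
            f"counts have {counts.counts.shape[1]} genes but reference "
            f"distributions have {B.shape[1]}"
        )
    if B.shape[0] < 1:
        raise ValidationError("reference set must contain at least one population")


def _data_loglik(x: np.ndarray, probs: np.ndarray) -> float:
    """sum_dg x * ln(probs) over entries with x > 0; -inf is signalled."""
    mask = x > 0
    if np.any(probs[mask] <= 0):
        raise FloatingPointError(
            "zero mixture probability for a gene with positive count "
            "(use a positive zero_floor when building reference distributions)"
        )
    out = np.zeros_like(probs)
    np.log(probs, out=out, where=mask)
    return float(np.sum(x * out))


def nnml_loglik(counts: DigitalMixture, beta, theta) -> float:
    """Marginal multinomial-mixture log-likelihood (natural log).

    l = sum_d sum_g x[d,g] * ln( sum_k theta[d,k] * beta[k,g] ); identical
    to the complete likelihood with the per-observation labels summed out.
    """
    B = _as_beta_array(beta)
    th = theta.theta if isinstance(theta, MixtureProportions) else np.asarray(theta, float)
    th = np.atleast_2d(th)
    _check_dims(counts, B)
    if th.shape[1] != B.shape[0]:
        raise ValidationError("theta population dimension does not match beta")
    probs = th @ B
    return _data_loglik(counts.counts.astype(float), probs)


def responsibilities(counts: DigitalMixture, beta_or_gamma, theta) -> Responsibilities:
    """Posterior population assignment per unit of expression (Bayes rule):
    r[d,g,m] = theta[d,m]*B[m,g] / sum_j theta[d,j]*B[j,g]."""
    B = _as_beta_array(beta_or_gamma)
    th = theta.theta if isinstance(theta, MixtureProportions) else np.asarray(theta, float)
    th = np.atleast_2d(th)
    _check_dims(counts, B)
    num = th[:, None, :] * B.T[None, :, :]  # (D, G, M)
    den = num.sum(axis=2, keepdims=True)
    bad = (den[..., 0] <= 0) & (counts.counts > 0)
    if np.any(bad):
        raise ValidationError("zero posterior denominator for a positive count")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0 / th.shape[1])
    return Responsibilities(r=r)


def _sym_dirichlet_logpdf(theta_row: np.ndarray, alpha: float) -> float:
    m = theta_row.size
    safe = np.maximum(theta_row, _THETA_FLOOR)
    return float(gammaln(m * alpha) - m * gammaln(alpha) + (alpha - 1.0) * np.sum(np.log(safe)))


def _dirichlet_logpdf(gamma: np.ndarray, a: np.ndarray) -> float:
    safe = np.maximum(gamma, _THETA_FLOOR**2)
    return float(gammaln(a.sum()) - gammaln(a).sum() + np.sum((a - 1.0) * np.log(safe)))


def _em_theta_step(x: np.ndarray, B: np.ndarray, theta: np.ndarray,
                   alpha: np.ndarray, fixed_zero_last: bool = False) -> np.ndarray:
    """One MAP-EM update of theta for all samples (monotone for alpha >= 1)."""
    D, M = theta.shape
    probs = theta @ B  # (D, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(probs > 0, x / np.where(probs > 0, probs, 1.0), 0.0)
    n_dk = theta * (ratio @ B.T)  # expected counts per population
    num = n_dk + (alpha[:, None] - 1.0)
    if fixed_zero_last:
        num[:, -1] = 0.0
    num = np.maximum(num, 0.0)
    new = num / num.sum(axis=1, keepdims=True)
    new = np.maximum(new, _THETA_FLOOR if not fixed_zero_last else 0.0)
    if not fixed_zero_last:
        new /= new.sum(axis=1, keepdims=True)
    return new


def _optimize_theta(x, B, theta, alpha, opts: FitOptions,
                    fixed_zero_last: bool = False) -> np.ndarray:
    prev = None
    for _ in range(opts.inner_max_iter):
        theta = _em_theta_step(x, B, theta, alpha, fixed_zero_last)
        obj = _data_loglik(x, theta @ B) + sum(
            _sym_dirichlet_logpdf(theta[d], alpha[d]) for d in range(theta.shape[0])
        )
        if prev is not None and abs(obj - prev) <= opts.rel_tol * (abs(prev) + 1.0):
            break
        prev = obj
    return theta


def _estimate_alpha_row(theta_row: np.ndarray, bounds: tuple[float, float]) -> float:
    """Empirical-Bayes scalar concentration for one sample's theta."""
    m = theta_row.size
    logsum = float(np.sum(np.log(np.maximum(theta_row, _THETA_FLOOR))))

    def neg(log_a: float) -> float:
        a = np.exp(log_a)
        return -(gammaln(m * a) - m * gammaln(a) + (a - 1.0) * logsum)

    res = scipy.optimize.minimize_scalar(
        neg, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# NNLS


def nnls_deconvolve(
    mixture_log2: ExpressionTable, reference_log2: ExpressionTable
) -> MixtureProportions:
    """Non-negative least squares deconvolution on log2-scale data.

    Each mixed profile is modelled as a non-negatively weighted sum of the
    reference profiles under additive Gaussian noise; weights are found by
    the Lawson-Hanson active-set algorithm and rescaled to sum to one. An
    all-zero weight vector falls back to uniform proportions with a warning.
    """
    if not (mixture_log2.is_log2 and reference_log2.is_log2):
        raise ValidationError(
            "nnls_deconvolve requires log2-scale tables (see log2_transform)"
        )
    if mixture_log2.genes.ids != reference_log2.genes.ids:
        raise ValidationError("inputs must be gene-aligned (see align_genes)")
    V = reference_log2.values  # (G, K)
    K = V.shape[1]
    theta = np.empty((mixture_log2.n_samples, K))
    for d in range(mixture_log2.n_samples):
        w, _ = scipy.optimize.nnls(V, mixture_log2.values[:, d])
        s = w.sum()
        if s <= 0:
            warnings.warn(
                f"all-zero NNLS solution for sample "
                f"{mixture_log2.sample_names[d]!r}; returning uniform proportions"
            )
            theta[d] = 1.0 / K
        else:
            theta[d] = w / s
    return MixtureProportions(
        theta=theta,
        population_names=reference_log2.sample_names,
        sample_names=mixture_log2.sample_names,
    )


# ---------------------------------------------------------------------------
# NNML


def nnml_fit(counts: DigitalMixture, beta: ReferenceDistributions,
             opts: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood multinomial-mixture deconvolution via EM.

    theta starts uniform at 1/K; each EM step is a closed-form update
    through the responsibilities and never decreases the likelihood.
    """
    opts = opts or FitOptions()
    B = beta.beta
    _check_dims(counts, B)
    x = counts.counts.astype(float)
    D, K = x.shape[0], B.shape[0]
    theta = np.full((D, K), 1.0 / K)
    alpha = np.ones(D)  # flat prior: pure maximum likelihood
    trace = [_data_loglik(x, theta @ B)]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        theta = _em_theta_step(x, B, theta, alpha)
        ll = _data_loglik(x, theta @ B)
        if abs(ll - trace[-1]) <= opts.rel_tol * (abs(trace[-1]) + 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    props = MixtureProportions(
        theta=theta,
        population_names=beta.population_names,
        sample_names=counts.sample_names,
    )
    ll = trace[-1]
    return FitResult(
        model="nnml", proportions=props, loglik=ll, logpost=ll, n_iter=it,
        converged=converged, n_obs=int(counts.totals.sum()), seed=opts.seed,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# NNML-np


def nnml_np_fit(counts: DigitalMixture, beta: ReferenceDistributions,
                opts: FitOptions | None = None, *,
                fix_new_population_at_zero: bool = False) -> FitResult:
    """NNML with one latent extra population (ISOLATE-style).

    theta gains a (K+1)-th column for a population whose gene distribution
    gamma is estimated under a Dirichlet prior centred on the convex
    combination sum_k omega[k] * beta_k with concentration kappa * G; omega,
    kappa and the per-sample theta concentrations alpha are estimated from
    the data. Block coordinate ascent cycles theta -> gamma ->
    (omega, kappa, alpha); the penalized objective never decreases.
    """
    opts = opts or FitOptions()
    Bref = beta.beta
    _check_dims(counts, Bref)
    x = counts.counts.astype(float)
    D, G = x.shape
    K = Bref.shape[0]
    M = K + 1

    theta = np.full((D, M), 1.0 / M)
    if fix_new_population_at_zero:
        theta = np.zeros((D, M))
        theta[:, :K] = 1.0 / K
    omega = np.full(K, 1.0 / K)
    gamma = omega @ Bref
    kappa = float(opts.kappa_start)
    alpha = np.full(D, float(opts.alpha_start))

    def objective(theta, gamma, omega, kappa, alpha) -> float:
        B = np.vstack([Bref, gamma])
        obj = _data_loglik(x, theta @ B)
        obj += _dirichlet_logpdf(gamma, kappa * G * (omega @ Bref))
        obj += sum(_sym_dirichlet_logpdf(theta[d], alpha[d]) for d in range(D))
        return obj

    trace = [objective(theta, gamma, omega, kappa, alpha)]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # theta block
        B = np.vstack([Bref, gamma])
        theta = _optimize_theta(x, B, theta, alpha, opts,
                                fixed_zero_last=fix_new_population_at_zero)
        # gamma block: MAP-EM update from counts assigned to the new population
        a = kappa * G * (omega @ Bref)
        probs = theta @ np.vstack([Bref, gamma])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(probs > 0, x / np.where(probs > 0, probs, 1.0), 0.0)
        n_new = gamma * (theta[:, -1:] .T @ ratio).ravel()  # (G,)
        cand = np.maximum(n_new + a - 1.0, _THETA_FLOOR)
        cand /= cand.sum()
        before = objective(theta, gamma, omega, kappa, alpha)
        if objective(theta, cand, omega, kappa, alpha) >= before:
            gamma = cand

        # omega block: fit the prior mean to gamma (L-BFGS on softmax logits)
        def neg_omega(z: np.ndarray) -> tuple[float, np.ndarray]:
            w = np.exp(z - z.max())
            w /= w.sum()
            a_w = kappa * G * (w @ Bref)
            val = _dirichlet_logpdf(gamma, a_w)
            dm = kappa * G * (np.log(np.maximum(gamma, _THETA_FLOOR**2)) - digamma(a_w))
            gk = Bref @ dm
            grad = w * (gk - np.dot(w, gk))
            return -val, -grad

        res = scipy.optimize.minimize(
            neg_omega, np.log(np.maximum(omega, 1e-8)), jac=True,
            method="L-BFGS-B", options={"maxiter": opts.inner_max_iter},
        )
        w = np.exp(res.x - res.x.max())
        cand_omega = w / w.sum()
        if objective(theta, gamma, cand_omega, kappa, alpha) >= objective(
            theta, gamma, omega, kappa, alpha
        ):
            omega = cand_omega

        # kappa block: bounded 1-D search on log kappa
        if opts.estimate_kappa:
            mean = omega @ Bref

            def neg_kappa(log_k: float) -> float:
                return -_dirichlet_logpdf(gamma, np.exp(log_k) * G * mean)

            res = scipy.optimize.minimize_scalar(
                neg_kappa,
                bounds=(np.log(opts.kappa_bounds[0]), np.log(opts.kappa_bounds[1])),
                method="bounded",
            )
            cand_k = float(np.exp(res.x))
            if objective(theta, gamma, omega, cand_k, alpha) >= objective(
                theta, gamma, omega, kappa, alpha
            ):
                kappa = cand_k

        # alpha block
        if opts.estimate_alpha:
            for d in range(D):
                cand_a = _estimate_alpha_row(theta[d], opts.alpha_bounds)
                if _sym_dirichlet_logpdf(theta[d], cand_a) >= _sym_dirichlet_logpdf(
                    theta[d], alpha[d]
                ):
                    alpha[d] = cand_a

        obj = objective(theta, gamma, omega, kappa, alpha)
        if obj < trace[-1] - 1e-9 * abs(trace[-1]):
            # guarded blocks should prevent this; keep the trace honest
            warnings.warn("objective decreased in nnml_np_fit cycle")
        if abs(obj - trace[-1]) <= opts.rel_tol * (abs(trace[-1]) + 1.0):
            trace.append(obj)
            converged = True
            break
        trace.append(obj)

    B = np.vstack([Bref, gamma])
    props = MixtureProportions(
        theta=theta,
        population_names=tuple(beta.population_names) + (NEW_POPULATION_NAME,),
        sample_names=counts.sample_names,
    )
    return FitResult(
        model="nnml_np", proportions=props,
        loglik=_data_loglik(x, theta @ B), logpost=trace[-1],
        n_iter=it, converged=converged, n_obs=int(counts.totals.sum()),
        new_population=NewPopulationEstimate(
            gamma=gamma, omega=omega, kappa=kappa, gene_ids=beta.genes.ids
        ),
        kappa=kappa, alpha=alpha.copy(), seed=opts.seed, objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# PERT


def _perturbed_distributions(Bref: np.ndarray, rho: np.ndarray) -> np.ndarray:
    s = Bref @ rho  # (K,)
    return (Bref * rho[None, :]) / s[:, None]


def rho_log_objective(x: np.ndarray, Bref: np.ndarray, theta: np.ndarray,
                      u: np.ndarray, kappa: float) -> tuple[float, np.ndarray]:
    """Penalized objective and analytic gradient for the rho block, as a
    function of u = ln(rho) with theta held fixed.

    Objective: data log-likelihood with constituent distributions
    gamma_k(rho) plus the Gamma(kappa, kappa) log-prior on each rho[g]
    (normalisation constants dropped). Exposed for gradient validation
    against central differences.
    """
    u = np.clip(u, -30.0, 30.0)  # keep exp() and downstream sums finite
    rho = np.exp(u)
    s = Bref @ rho  # (K,)
    gamma = (Bref * rho[None, :]) / s[:, None]
    probs = theta @ gamma
    ll = _data_loglik(x, probs)
    prior = float(np.sum((kappa - 1.0) * u - kappa * rho))
    # gradient: d ll / d rho_g = X_g / rho_g - sum_k (C_k / s_k) * B_kg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(probs > 0, x / np.where(probs > 0, probs, 1.0), 0.0)
    n_dk = theta * (ratio @ gamma.T)  # expected counts per (d, k)
    C = n_dk.sum(axis=0)  # (K,)
    X = x.sum(axis=0)  # (G,)
    grad_rho = X / rho - (C / s) @ Bref + (kappa - 1.0) / rho - kappa
    return ll + prior, grad_rho * rho


def pert_fit(counts: DigitalMixture, beta: ReferenceDistributions,
             opts: FitOptions | None = None, *, fix_rho: bool = False) -> FitResult:
    """Deconvolution with a shared multiplicative perturbation of the
    references.

    Estimates per-sample proportions theta and one positive vector rho of
    gene-wise fold changes, shared across samples and populations, that
    transports every reference distribution beta_k into the constituent
    distribution gamma_k = rho*beta_k / sum(rho*beta_k). rho has a
    Gamma(kappa, kappa) prior (mean 1, variance 1/kappa); kappa and the
    per-sample theta concentrations alpha are estimated. Block coordinate
    ascent cycles theta -> rho -> (kappa, alpha) and the penalized
    objective never decreases. The reported rho is anchored so its
    beta-weighted mean is 1 (gamma_k is invariant to rho's overall scale).
    """
    opts = opts or FitOptions()
    Bref = beta.beta
    _check_dims(counts, Bref)
    x = counts.counts.astype(float)
    D, G = x.shape
    K = Bref.shape[0]

    theta = np.full((D, K), 1.0 / K)
    u = np.zeros(G)  # ln rho
    kappa = float(opts.kappa_start)
    alpha = np.full(D, float(opts.alpha_start))

    def gamma_prior(u: np.ndarray, kappa: float) -> float:
        # full Gamma(kappa, kappa) log-density, constants included
        rho = np.exp(u)
        return float(
            np.sum(kappa * np.log(kappa) - gammaln(kappa)
                   + (kappa - 1.0) * u - kappa * rho)
        )

    def objective(theta, u, kappa, alpha) -> float:
        gam = _perturbed_distributions(Bref, np.exp(u))
        obj = _data_loglik(x, theta @ gam)
        obj += gamma_prior(u, kappa)
        obj += sum(_sym_dirichlet_logpdf(theta[d], alpha[d]) for d in range(D))
        return obj

    trace = [objective(theta, u, kappa, alpha)]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # theta block
        gam = _perturbed_distributions(Bref, np.exp(u))
        theta = _optimize_theta(x, gam, theta, alpha, opts)

        # rho block: L-BFGS on u = ln rho with the analytic gradient
        if not fix_rho:
            def neg(u_):
                val, grad = rho_log_objective(x, Bref, theta, u_, kappa)
                return -val, -grad

            # bound ln(rho) to keep exp() finite; 1e-13..1e13 fold changes
            res = scipy.optimize.minimize(
                neg, u, jac=True, method="L-BFGS-B",
                bounds=[(-30.0, 30.0)] * G,
                options={"maxiter": opts.inner_max_iter},
            )
            val_new, _ = rho_log_objective(x, Bref, theta, res.x, kappa)
            val_old, _ = rho_log_objective(x, Bref, theta, u, kappa)
            if val_new >= val_old:
                u = res.x

            # kappa block: maximize the Gamma(kappa, kappa) log-density of rho
            if opts.estimate_kappa:
                def neg_kappa(log_k: float) -> float:
                    return -gamma_prior(u, float(np.exp(log_k)))

                res = scipy.optimize.minimize_scalar(
                    neg_kappa,
                    bounds=(np.log(opts.kappa_bounds[0]),
                            np.log(opts.kappa_bounds[1])),
                    method="bounded",
                )
                cand_k = float(np.exp(res.x))
                if gamma_prior(u, cand_k) >= gamma_prior(u, kappa):
                    kappa = cand_k

        # alpha block
        if opts.estimate_alpha:
            for d in range(D):
                cand_a = _estimate_alpha_row(theta[d], opts.alpha_bounds)
                if _sym_dirichlet_logpdf(theta[d], cand_a) >= _sym_dirichlet_logpdf(
                    theta[d], alpha[d]
                ):
                    alpha[d] = cand_a

        obj = objective(theta, u, kappa, alpha)
        if obj < trace[-1] - 1e-9 * abs(trace[-1]):
            warnings.warn("objective decreased in pert_fit cycle")
        if abs(obj - trace[-1]) <= opts.rel_tol * (abs(trace[-1]) + 1.0):
            trace.append(obj)
            converged = True
            break
        trace.append(obj)

    rho = np.exp(u)
    # anchor the reported rho: beta-weighted mean of rho equals 1
    weights = Bref.mean(axis=0)
    rho_anchored = rho / float(weights @ rho)
    gam = _perturbed_distributions(Bref, rho)
    props = MixtureProportions(
        theta=theta,
        population_names=beta.population_names,
        sample_names=counts.sample_names,
    )
    return FitResult(
        model="pert", proportions=props,
        loglik=_data_loglik(x, theta @ gam), logpost=trace[-1],
        n_iter=it, converged=converged, n_obs=int(counts.totals.sum()),
        perturbation=PerturbationEstimate(
            rho=rho_anchored, kappa=kappa, gene_ids=beta.genes.ids
        ),
        kappa=kappa, alpha=alpha.copy(), seed=opts.seed, objective_trace=trace,
    )


def perturb_reference(beta_row: np.ndarray, rho) -> np.ndarray:
    """Transport a reference profile into the perturbed condition:
    rho*beta / sum(rho*beta). Invariant to rho's overall scale."""
    if isinstance(rho, PerturbationEstimate):
        rho = rho.rho
    rho = np.asarray(rho, dtype=float)
    beta_row = np.asarray(beta_row, dtype=float)
    if rho.shape != beta_row.shape:
        raise ValidationError("rho and beta_row must have the same length")
    if np.any(rho <= 0):
        raise ValidationError("rho must be positive")
    prod = rho * beta_row
    s = prod.sum()
    if s <= 0:
        raise ValidationError("rho * beta sums to zero; cannot normalise")
    return prod / s
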