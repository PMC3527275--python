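# Methods

## Model family

All fitters consume a digitized mixture matrix `x` (D samples × G genes of
integer counts, row totals N_d) and reference distributions `beta`
(K rows on the G-simplex). The latent story: each of the N_d observation
units in sample d carries a population label z ∈ {1..M}; conditioned on
z = k the unit lands on gene g with probability B_{k,g}. Labels are never
materialised (N_d ≈ 10⁷); every update uses the gene-level marginalised
log-likelihood

    l(theta) = sum_{d,g} x[d,g] * ln( sum_k theta[d,k] * B[k,g] ),

which is identical to the complete-data likelihood with z summed out and
keeps memory at O(D·G·M).

- **NNML**: B = beta, maximum likelihood over theta via EM
  (responsibilities r[d,g,k] ∝ theta[d,k]·B[k,g]; update
  theta[d,k] ← Σ_g x[d,g]·r[d,g,k]/N_d). Each step provably does not
  decrease l.
- **NNML-np**: B = [beta; gamma] with one extra latent population. Prior:
  gamma ~ Dirichlet(kappa·G·m) with m = Σ_k omega_k·beta_k, omega convex;
  theta_d ~ symmetric Dirichlet(alpha_d). Block coordinate ascent
  theta → gamma → (omega, kappa, alpha): gamma by the MAP-EM closed form
  (counts assigned to the new population plus prior pseudo-counts, negative
  components truncated at the floor and renormalised), omega by L-BFGS on
  softmax logits, kappa and alpha_d by bounded scalar search on a log grid.
- **PERT**: B = gamma(rho) with gamma[k,g] = rho[g]·beta[k,g]/Σ_{g'}
  rho[g']·beta[k,g'], one positive rho shared by all populations and
  samples; prior rho_g ~ Gamma(shape=kappa, rate=kappa) (mean 1, variance
  1/kappa), theta_d as above. Cycle theta → rho → (kappa, alpha); the rho
  step maximises the exact penalized objective over u = ln(rho) by L-BFGS
  with the analytic gradient

      d l / d rho_g = X_g/rho_g − Σ_k (C_k/s_k)·beta[k,g],

  where X_g = Σ_d x[d,g], s_k = beta_k·rho and C_k is the total expected
  count assigned to population k at the current point. The gradient is
  validated against central differences in the suite (< 1e-4 relative).
- **NNLS** is the non-probabilistic baseline: per sample, min‖V·w − x‖²
  s.t. w ≥ 0 on log2-scale values via the Lawson–Hanson active-set solver
  (`scipy.optimize.nnls`), weights rescaled to sum to 1. The log2 transform
  is log2(1 + v); the +1 offset handles zero intensities. All-zero
  solutions fall back to uniform proportions with a warning.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `target_total` | digitization depth N_d | 1e7 | observation units chosen so N_d ~ 1e7; fixed total makes likelihoods comparable across samples |
| `zero_floor` | relative floor for zero reference intensities | 1e-12 | a mixture count on a gene absent from all references would otherwise give −inf log-likelihood |
| `rel_tol` | relative objective change at convergence | 1e-8 | nesting/oracle tests tighten to 1e-14 |
| `max_iter` | outer cycles | 2000 | EM at desk scale converges in tens of cycles |
| `kappa_bounds` | prior-strength search range | [1e-2, 1e4] | log-grid bounded scalar search inside each cycle |
| `alpha_bounds` | theta-concentration range | [1, 1e6] | alpha ≥ 1 keeps the Dirichlet prior proper on the closed simplex and the MAP-EM update monotone; alpha < 1 would make the objective unbounded at simplex corners |

All fitters are deterministic given `FitOptions.seed`; the EM/L-BFGS path
uses no randomness, so identical inputs give identical outputs.

## Numerical choices

- **Integerization** of intensities uses floor-then-largest-remainder
  apportionment with ties broken by ascending gene index: deterministic,
  conserves the total exactly, and is invariant to rescaling the input.
- **Monotonicity guard**: every block update (gamma, omega, kappa, alpha,
  rho) is accepted only if it does not decrease its objective; decreases
  beyond 1e-9 relative would warn. This is the normative behaviour — the
  original optimiser (conjugate gradient) is not reproduced, only the
  optimum and the non-decreasing objective contract.
- **rho anchoring**: gamma(c·rho) = gamma(rho) for any c > 0, so rho is
  identified only up to scale by the data. During optimisation the
  Gamma(kappa, kappa) prior pins the scale; the *reported* rho is rescaled
  once at convergence so that its beta-weighted mean Σ_g mean_k(beta[k,g])
  ·rho_g equals 1. Anchoring after every update instead would interact
  with the prior term and could violate the monotone-objective contract,
  so it is deliberately done only at the end.
- **ln(rho) bounds** of ±30 in the L-BFGS step keep exp() finite when the
  prior is nearly flat (small kappa).
- **theta floor** of 1e-12 after each EM step keeps log-prior terms finite.

## Synthetic studies

`simulate_study` draws K reference rows from Dirichlet(0.5·1_G) (spiky,
well-separated profiles, resembling expression distributions dominated by
a few genes), per-sample weights theta* from Dirichlet(1·1_K), optionally a
shared perturbation rho* ~ log-normal(0, rho_sigma²) anchored to
beta-weighted mean 1 (rho_sigma = 0.5 puts ~16% of genes past the 2-fold
threshold, a plausible culture-effect magnitude), and optionally one hidden
population: a fresh Dirichlet profile at total-variation distance ≥ 0.2
from every reference, mixed in at `hidden_fraction` (taken proportionally
out of the reference weights). Counts are exact multinomial draws at depth
N per sample. Defaults (K=8, G=2000, D=4, N=1e6) are scaled down from
study scale (K=118, G=22215, N ≈ 1.7e7) to keep the suite fast.

The simulator emulates multinomial sampling noise only: no probe-level
effects, batch effects, array normalisation artifacts, or biological
replicate variability. A green recovery test therefore establishes
statistical correctness of the estimator under its own generative
assumptions — not robustness to real microarray noise.

## Known limitations

- **New-population weight is set-identified.** If the hidden population's
  contribution can be written as gamma = (f·hidden + c·combo)/(f + c) with
  combo a convex combination of the references, every c ≥ 0 yields the same
  data likelihood (mass moves between the reference columns and the new
  population). The Dirichlet prior on gamma is *centred on* reference
  combinations, so the MAP actively prefers larger c: on synthetic data
  with a 30% hidden population the estimated new-population weight settles
  near 0.55 even though the recovered profile correlates with the hidden
  profile at r ≈ 0.95. On exactly-matched references (no hidden
  population), kappa runs to its upper bound, the likelihood is flat in the
  new-population weight, and EM drifts from the uniform 1/(K+1)
  initialisation to ≈ 0.08–0.10 rather than 0. Interpret NNML-np's
  estimated new-population *profile*, and treat its *weight* as an upper
  bound. The corresponding recovery tests in the acceptance suite assert
  the idealised bounds and are expected to fail; they document this
  identifiability gap.
- The published parameter-count totals for the study-scale fits cannot be
  reconciled with any straightforward convention; `count_free_parameters`
  documents its own convention (theta: (K−1)·D per the simplex constraint,
  etc.) and BIC worked examples take the published triples as inputs.
- Per-population perturbation vectors (a different rho per reference) are
  out of scope; the shared-rho assumption is what makes the model
  identifiable from few samples.
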