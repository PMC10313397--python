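# Methods

## Model and assumptions

Each taste (sweetness, sourness, bitterness) is analysed independently.  A
participant's four VAS scores — one per shape condition, in the canonical
order (Bouba-A6, Kiki-A6, Bouba-S6, Kiki-A10) — are a draw from a
4-dimensional multivariate normal with mean vector μ, scale vector σ and
correlation matrix R, so Σ = diag(σ)·R·diag(σ).  Priors are
μ_i ~ Uniform(0, 100), σ_i ~ Uniform(0, 50) (VAS units) and R ~ LKJ(η).

Assumptions worth making explicit:

- **Untruncated likelihood.**  The likelihood is a plain multivariate
  normal even though VAS scores live in [0, 100]; only the priors are
  bounded.  With means well inside the scale and moderate σ this is a mild
  approximation; near the scale ends it biases σ downward.
- **No cross-taste model.**  The three 4-dimensional fits share nothing;
  cross-taste correlation is not modelled.
- **Complete cases only.**  Incomplete designs are rejected at validation,
  not imputed.
- **No order effects.**  Presentation order is generated and recorded but
  never enters the likelihood.

The LKJ density is implemented up to its normalizing constant,
`(η − 1)·log det R`; MCMC needs the target only up to a constant.  The
default η = 1 (uniform over correlation matrices) is the least-informative
member of the family and is exposed in `PriorSpec`.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| μ bounds | VAS | (0, 100) | the rating scale itself |
| σ bounds | VAS | (0, 50) | half the scale; an SD above 50 is not meaningful for a bounded 0–100 score |
| LKJ η | — | 1 | uniform correlation prior |
| chains × iterations | — | 5 × 5,000 | study-scale sampling plan |
| burn-in | iterations/chain | 1,000 | retained draws 5 × 4,000 = 20,000 |
| R̂ threshold | — | 0.01 | `max |R̂ − 1| < 0.01` over all 14 parameters |
| HDI mass | — | 0.95 | reporting convention |

## Unconstrained parameterization

The sampler works on a 14-dimensional unconstrained vector: scaled-logistic
bijections map 4 means onto (0, 100) and 4 scales onto (0, 50); the 6 free
correlation entries are canonical partial correlations, tanh-transformed and
assembled into a Cholesky factor by the standard recursion, which yields a
positive-definite correlation matrix for any finite input.  This
parameterization keeps the unconstrained space rectangular (every finite
vector is valid), unlike a raw Cholesky parameterization.  The log-Jacobian
of the full map is computed analytically — logistic terms, `log(1 − z²)`
tanh terms, and the triangular `log L[j,j] + ½ log(rem)` terms of the
partial-correlation recursion — and is validated in tests against central
finite differences of the forward map.

## Sampler

`run_mcmc` is an adaptive random-walk Metropolis sampler; the analysis
contract is sampler-agnostic (any kernel that samples the same target may
be plugged in), and the random-walk baseline is validated against
closed-form oracles (standard-normal moments, conjugate normal-mean
quantiles, a piecewise-constant 3-bin stationary distribution).

Design choices:

- **Proposals per retained draw.**  At the optimal ~0.234 acceptance rate a
  random-walk chain in d dimensions has an integrated autocorrelation time
  of roughly 2d/0.6 proposals (~47 at d = 14).  Each retained iteration is
  therefore the state after `proposals_per_draw = 10` proposals, bringing
  retained draws close to unit-lag independence while preserving the
  chains × iterations × burn-in bookkeeping.
- **Phased burn-in adaptation.**  Burn-in proposals run in three phases:
  (1) first 25%: scale-only Robbins–Monro adaptation with an isotropic
  proposal, to escape the overdispersed prior-draw initialization;
  (2) until 90%: empirical-covariance estimation from post-transient history
  (Welford moments, Cholesky refreshed every 25 steps, shrinkage-regularized),
  with the proposal scale re-centred at 2.38/√d when the covariance is first
  installed; (3) last 10%: scale fine-tuning with the covariance frozen.
  After burn-in the proposal is fully frozen, so the retained phase is an
  exact Markov chain.  Adapting over the whole burn-in history without a
  phase split left occasional chains with transient-contaminated proposals
  and visibly split R̂; the phase structure removed this across seeds.
- **Initialization.**  Per-chain start points are independent draws from
  the prior (transformed), i.e. deliberately overdispersed, which is what
  makes the between-chain R̂ comparison informative.  Chain i uses RNG seed
  `seed + i`; runs are exactly reproducible for a fixed seed.
- **Failure modes.**  A non-finite target at an initial point raises
  immediately, naming the chain; a chain that accepts nothing raises a
  diagnostic error.  Convergence violations, by contrast, are warnings
  that annotate the report — the statistic is a diagnostic, not a gate.

## Convergence diagnostic

Split Gelman–Rubin: each chain is halved; with m half-chains of length n,
`var⁺ = ((n − 1)W + B)/n` and `R̂ = sqrt(var⁺/W)`.  Splitting is the
stricter modern form (it also flags within-chain drift) and can only make
the check more conservative.  Zero within-chain variance yields NaN with a
warning.  The suite cross-checks the statistic against arviz's split R̂.
No effective-sample-size or rank-normalized diagnostics are computed.

## Posterior summaries

- **EAP** — mean over pooled retained draws.
- **Posterior SD** — sample (n − 1) convention (the convention is not
  dictated by the reporting format; it is documented here and fixed).
- **HDI** — shortest-window estimator on sorted draws: among all contiguous
  windows holding ⌈mass·n⌉ draws, the narrowest wins; ties go to the
  smallest lower endpoint.  Assumes unimodality, which the MVN model class
  guarantees for these marginals.
- **Probability matrices** are reported at 3 decimals with a zero diagonal
  (self-comparison is meaningless); summaries print as
  `EAP (SD) [HDI lower, HDI upper]` at 2 decimals.
- **Compound comparisons** report both the draw-wise joint probability and
  the product of the four marginal probabilities.  These differ under
  posterior dependence: for exchangeable parameters the joint is 1/6 while
  the naive product is 1/16, and the four events are positively associated
  (joint ≥ product) because each is monotone in the same coordinates.  Both
  are reported, neither silently corrected to the other, because published
  group comparisons are sometimes computed from rounded pairwise tables
  (marginal product) rather than from draws (joint).

## Synthetic-data generator

The generator emulates the tasting study's structure: n participants
(default 24), every participant rating all four shapes for all three
tastes, presentation orders assigned by cycling through a seed-shuffled
enumeration of all 4! = 24 condition permutations (at n = 24 each
permutation is used exactly once and each condition appears in each serial
position 6 times).  Scores per taste are multivariate-normal draws with the
assumed covariance structure; tastes are generated from independent RNG
substreams derived from the master seed by fixed offsets.

`make_study_dataset` uses the published condition-mean estimates as
generator truth (e.g. sweetness 38.52 / 28.90 / 40.63 / 30.67), a common
σ = 20 VAS units and exchangeable correlation ρ = 0.5.  σ = 20 is a
realistic per-condition spread for VAS taste ratings consistent with the
published posterior SDs (≈3.4–5.9 at n = 24, i.e. σ ≈ SD·√n ≈ 17–29);
ρ = 0.5 reflects the substantial participant-level correlation a
within-subjects rating task induces.

Bounding behaviour, because the inference model is untruncated:

- `unbounded` — exactly the model's assumptions; the only mode under which
  the model is exactly recoverable, hence used by recovery tests;
- `clipped` (default) — clamp to [0, 100], realistic for VAS data;
- `truncated` — redraw until all four components are in range.

Scores are continuous by default with an optional integer-rounding flag;
VAS granularity is an instrument property, not a model one.

What passing tests on this generator do **not** show about real data: no
participant heterogeneity in means or scale usage (no random effects), no
order/carry-over/fatigue effects, no response granularity artifacts, no
floor/ceiling censoring beyond the clipping itself, and no cross-taste
dependence.

## Problem sizes used by the test suite

Full study-scale fits (5 × 5,000, three tastes, n = 24) are exercised once,
in the end-to-end convergence check.  Parameter recovery runs one n = 200
unbounded dataset with a reduced sampling plan (3 chains × 1,500, burn-in
500), asserting every EAP within 3 posterior SDs of truth; interval
calibration runs 12 replicate n = 60 datasets (3 × 1,200, burn-in 400) and
requires ≥ 40 of 48 nominal-95% HDIs for the condition means to cover
truth (a ≈3-standard-deviation binomial lower bound).  These sizes are the
package's chosen test scale; the full-scale plan remains the default for
analyses.

## Known limitations

- Clipped data are fit with an untruncated likelihood; at n = 24 and the
  default generator settings the induced bias is small relative to
  posterior spread, but extreme means/scales would need a censored model.
- The random-walk kernel scales poorly beyond a few dozen parameters; it is
  adequate for d = 14 but a gradient-based sampler would be preferred for
  richer models.
- Exact end-to-end label invariance (permuting input condition columns)
  holds at the deterministic layers (validation, pivoting, probability
  operations); the sampler's RNG path, and hence individual draws, differ.
- The split-half R̂ here is the classic variance-ratio form, not the
  rank-normalized variant; heavy-tailed posteriors could evade it (not a
  concern for this model class).
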