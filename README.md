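# shapetaste

Bayesian within-subjects analysis of visual-analogue-scale (VAS) taste
ratings for chocolate pieces of four shapes — two rounded ("Bouba") and two
angular ("Kiki") variants.  The crossmodal-correspondence question is
whether shape alone shifts perceived sweetness, sourness and bitterness
when every participant eats all four shapes and rates each taste on a
0–100 VAS.

`shapetaste` is for sensory/psychophysics researchers who want this analysis
as a tested, reusable pipeline: a synthetic-data generator that emulates the
counterbalanced tasting design, the Bayesian rating model, an MCMC engine
with convergence diagnostics, and posterior summaries down to the
directional and compound hypothesis probabilities.

## Model

For one taste, participant `p`'s four scores form a vector
`y_p ∈ R^4` modelled as

```
y_p ~ MVN(μ, Σ),   Σ = diag(σ) R diag(σ)
μ_i ~ Uniform(0, 100)        i = 1..4   (VAS units)
σ_i ~ Uniform(0, 50)
R   ~ LKJ(η),  η = 1 by default (uniform over correlation matrices)
```

with conditions ordered `(Bouba-A6, Kiki-A6, Bouba-S6, Kiki-A10) = (μ1, μ2,
μ3, μ4)`.  The three tastes are fit independently.  Posteriors are sampled
with 5 chains × 5,000 iterations (per-chain burn-in 1,000, hence 20,000
retained draws) using an adaptive random-walk Metropolis kernel on an
unconstrained reparameterization; convergence requires `|R̂ − 1| < 0.01`
for every parameter (split Gelman–Rubin).

A directional hypothesis `μ_i > μ_j` is scored as the posterior mean of the
draw-wise indicator `1{μ_i(t) > μ_j(t)}`.  The compound shape-family
comparison "(both Bouba) > (both Kiki)" is scored two ways: the draw-wise
joint indicator product (dependence-respecting), and the plain product of
the four marginal pairwise probabilities (the arithmetic used with published
pairwise tables).

## Worked example

```python
from shapetaste import ChainConfig, build_report, fit_all_tastes, make_study_dataset

table = make_study_dataset(seed=1)            # 24 participants x 4 shapes x 3 tastes
fits = fit_all_tastes(table, chains=ChainConfig(seed=1))
bundle = build_report(fits, seed=1)
print(bundle.to_markdown())
```

On this synthetic dataset (generator means set to the published
condition-mean estimates, common σ = 20, exchangeable ρ = 0.5) the sweetness
summaries print as `EAP (posterior SD) [95% HDI]`:

```
mu[Bouba-A6] -> 39.25 (4.58) [30.25, 48.14]
mu[Kiki-A6]  -> 26.05 (4.74) [16.70, 35.62]
mu[Bouba-S6] -> 44.39 (4.58) [35.52, 53.58]
mu[Kiki-A10] -> 29.66 (3.51) [23.00, 36.79]
```

All three fits converge (max `|R̂ − 1|` of 0.0025 / 0.0034 / 0.0029 for
sweetness / sourness / bitterness).  The directional hypotheses evaluate to

```
H1 sweetness  Bouba-A6 > Kiki-A6   0.977
H2 sourness   Kiki-A6  > Bouba-A6  0.910
H3 bitterness Kiki-A6  > Bouba-A6  0.582
H4 sweetness  Bouba-S6 > Bouba-A6  0.844
H5 sourness   Kiki-A10 > Kiki-A6   0.016
H6 bitterness Kiki-A10 > Kiki-A6   0.387
```

i.e. with these generator settings the rounded shapes are credibly sweeter
(H1 ≈ 0.98), and the compound sweetness comparison
`(Bouba-A6 & Bouba-S6) > (Kiki-A6 & Kiki-A10)` has joint posterior
probability 0.960 (marginal product 0.952).  Exact numbers vary with the
seed; the structure (which hypotheses are near 1 or near 0) is stable.

The same pipeline runs from a shell:

```
shapetaste simulate --n 24 --seed 1 --out ratings.csv
shapetaste fit --data ratings.csv --taste all --out draws/
shapetaste report --draws draws/ --out report.json
```

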