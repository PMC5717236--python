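# Methods

This note documents the statistical model behind `prefperf`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Data model

The unit design is a complete bipartite assay of a fly roster over a host
catalogue. Oviposition is recorded per replicate: no-choice assays expose 5
females to one fruit substrate for 24 h (6 replicates per species × fruit
cell); choice assays expose 10 females to 8 substrates at once (12
replicates per species). Larval performance is recorded per cup — one
neonate larva on a fruit-based diet, pupation as a binary outcome, 30–50
cups per cell — and aggregated on demand to the cell proportion. Storing
survival per cup rather than as a proportion supports both the resampling
unit (5 cups per draw) and the cell-level covariate without information
loss.

Egg matrices use no-choice records only; the choice assay serves purely to
validate that the no-choice hierarchy is a faithful preference measure.
Unobserved egg cells are filled with 0 and logged (the design is complete,
so absence means an unrecorded zero); unobserved survival cells are left
NaN — zero trials is not 0 % survival — and excluded downstream.

## Diet breadth

A species' degree of specialisation is the Hill number of order q = 1 of
its host-use profile: D = exp(−Σ p_j ln p_j), the effective number of
equally common hosts. Entropy is in nats; numbers equivalents are
base-free. Zero weights are dropped before any exponent sum (0·ln 0 = 0,
and p^q at q < 1 would otherwise be ill-defined), and the q = 1 branch is
taken within |q − 1| < 1e−9; the q-continuity test bounds the branch seam at
1e−4. Per-species values are column-wise Hill numbers of the interaction
matrix; a community-level alpha under multiplicative partitioning (weighted
geometric mean of the per-species values at q = 1) is provided for
completeness but is not the covariate — the degree of specialisation must
vary by species.

## Resampling

B = 1000 matrices by default, each built by sampling, per cell, one
oviposition replicate and five survival cups. Sampling is without
replacement within a cell (replicates are experimental units), independent
across cells and matrices. Matrix m draws from the substream
`SeedSequence(seed, spawn_key=(m,))`, so enlarging B never reshuffles
earlier matrices and fixed seeds give byte-identical output. Cells with
fewer cups than requested fall back to all available cups (logged); a
species whose sampled egg profile comes out all-zero is redrawn up to 100
times and otherwise dropped from that matrix and logged — diversity is
undefined on an empty profile, and dropping keeps the remaining sample
honest rather than imputing.

Classification is diagnostic: species are split at the largest gap in mean
preference diet breadth, and the separation score is the fraction of
resampled matrices in which every high-group species exceeds every
low-group species. The a-priori guild labels remain the covariate in the
guild-contrast model; the classification output reports agreement rather
than replacing them.

## Correlation analyses

All Pearson tests are two-sided with p from the t distribution on n − 2 df.
The choice/no-choice consistency analysis pairs each choice-replicate count
with the species' no-choice per-fruit mean (12 × 8 = 96 pairs). This
replicate-level pairing is a reconstruction: back-computing the t statistic
from published-style (r, p) pairs such as r = 0.12 → p ≈ 0.24 and r = 0.29
→ p ≈ 0.004 is consistent with n ≈ 96 and not with n = 8; the fruit-level
alternative (8 pairs of means) remains available via `level="fruit"`.

## Quasi-Poisson deviance models

The fitter is plain IRLS on the log link: weights μ, working response
η + (y − μ)/μ, weighted least squares via `numpy.linalg.lstsq`, convergence
when the deviance's relative change falls below 1e−10 (max 100 iterations;
non-convergence is flagged on the result, never silent). Fitted means are
floored at 1e−10 against separation-like divergence, with the floor's
activation flagged. Deviance is the Poisson deviance with y ln(y/μ) = 0 at
y = 0; responses may be non-integral (quasi-likelihood), which the
mean-response option of the cell table uses.

Analysis of deviance is sequential (type-I) in the declared term order.
Each term's F statistic divides the per-df deviance drop by the Pearson
dispersion φ̂ of the fullest model in its sequence — standard
quasi-likelihood ANOVA practice — and is referred to F(Δdf, df_residual of
the fullest model). Rows report the residual df remaining after the term
enters, matching the usual Δdev_{Δdf, df} presentation. A scaled chi-square
flavour is available by flag. Observation units: the fruit × diet-breadth
model is replicate-level (one row per no-choice replicate, 1044 rows on the
default design); all survival models are cell-level, one row per species ×
fruit with the summed egg count as response (an integer, hence a valid
Poisson response; the mean response is a sensitivity option). The
diet-breadth covariate is the species' resampling mean, constant within
species.

The zero-removal refits drop cells with zero survival, zero eggs, or
either, then refit eggs ~ survival on specialists only; they guard against
the survival effect being an artefact of the many structural zeros in
specialist profiles.

## Synthetic communities

Preference weights per species are Dirichlet draws: concentration 2.0 on
the six-fruit Cucurbitaceae block and 0.05 elsewhere for specialists
(≈ 91 % of mass on the block, true diet breadth ≈ 5–8), flat 1.0 for
generalists (≈ 17–22). Weights are floored at 1e−8 and renormalised so log
weights stay finite. Egg counts are gamma-mixed Poisson (negative binomial)
with size λ/(φ − 1), giving Var = φ·mean exactly — quasi-Poisson prescribes
only this variance law, and the negative binomial is its natural generative
representative; φ = 1 falls back to Poisson. Survival is
logit(s) = a_g + b_g·z + ε with z the species-standardised log preference
weight, so the coupling slope b_g is comparable across species of different
breadths; cups are Bernoulli(s), cup counts uniform on 30–50.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `egg_scale` | 400 | total 24-h laying capacity of 5 peak-fecundity females (~80 eggs/female); also keeps single-replicate profiles count-rich enough that the plug-in Hill estimate is nearly unbiased (see below) |
| `overdispersion_phi` | 2.0 | moderate overdispersion typical of egg-count assays |
| `coupling_b_specialist` / `generalist` | 3.0 / 0.0 | the contrast under study: strong coupling in specialists, none in generalists |
| `survival_intercept` spec/gen | −2.0 / 0.0 | specialists survive well only on preferred (cucurbit) hosts; generalists near 50 % everywhere |
| `noise_sd` | 0.5 | biological scatter on the logit scale |
| replicate counts, cups | 6 / 12 / 30–50 | the real assay design |

A known property of the pipeline, visible in simulation: the plug-in Hill
estimate from a single replicate's counts is biased low by roughly a factor
exp(−φ(k − 1)/2N) for a species using k hosts with N total eggs. At the
default scale this is ~6 % for generalists and ~2 % for specialists, within
the 10 % recovery band the tests enforce; at much lower count scales or
higher dispersion the bias would grow, which is worth remembering before
applying the method to sparse real data.

What the generator does **not** emulate: temporal fruit availability,
interspecific competition, female depletion across the 24 h window (counts
are exchangeable across replicates), correlation between a cell's egg and
survival noise beyond the latent coupling, and performance components other
than survival (development time, pupal weight). Passing recovery tests
therefore show the estimators are consistent under the stated sampling
model, not that real communities satisfy that model.

## Test scale choices

The recovery and power experiments use 200 simulated communities with
B = 100 resampled matrices each (the resampling mean is stable well below
B = 1000), and the quasi-F size calibration uses 1000 null simulations per
dispersion level at n = 150 observations, a size at which the F
approximation should be expected to hold. The acceptance script runs the
full B = 1000 pipeline once.

## Known limitations

* Sequential (type-I) deviance decomposition only; marginal (type-III)
  tests are out of scope.
* No analytic or jackknife variance for diversity — uncertainty is purely
  the matrix-resampling distribution.
* The IRLS fitter has no step-halving; on pathological designs it flags
  non-convergence rather than recovering.
* The largest-gap classifier is a one-dimensional heuristic; with more than
  two genuine guilds it will still force a two-way split (flagged degenerate
  only when all means coincide).
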