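# prefperf

Preference–performance analysis for a phytophagous insect community.

Phytophagous insect larvae usually cannot choose their host: the mother's
oviposition decision fixes it. The *mother-knows-best* hypothesis predicts
that female oviposition preference should correlate with offspring
performance — and that the correlation should be stronger for diet
specialists, which survive on few hosts, than for generalists, for which a
poor choice costs little. `prefperf` implements the complete statistical
pipeline for testing this within one insect community assayed on a common
host panel: a six-species tephritid fruit-fly community (two Cucurbitaceae
specialists, four generalists) offered 29 fruit species from 15 plant
families in no-choice and choice oviposition assays and single-larva
survival trials.

It is a library for ecologists and biostatisticians working with bipartite
host-use data; a thin `prefperf` command-line front end covers the common
runs, and `examples/` holds short narrative scripts, one per capability.

## The statistics

**Diet breadth** of species *i* is the numbers equivalent (Hill number) of
the Shannon entropy of its host-use proportions *p·ᵢ*:

    D_i = exp(H_i),   H_i = − Σ_j p_ji ln p_ji

the "effective number of equally common host plants". Uncertainty comes
from rebuilding the 29 × 6 plants × species interaction matrix B = 1000
times, sampling one oviposition replicate (or five survival cups) per cell,
and taking the mean and variance of D_i over the resampled matrices.

**Preference vs performance** is tested three ways with Pearson's *r* (two
sided, t reference with n − 2 df): diet breadth on eggs vs diet breadth on
survival across species; per-fruit mean eggs vs survival within each
species; and choice vs no-choice consistency (each of the 12 × 8 choice
replicate counts paired with the species' no-choice fruit mean, n = 96).

**Deviance models**: egg counts are overdispersed, so oviposition is
modelled with quasi-Poisson log-linear GLMs (log μ = Xβ, Var = φμ) and
tested by sequential analysis of deviance, F = (Δdev/Δdf)/φ̂ with φ̂ the
Pearson dispersion of the fullest model. The suite fits
eggs ~ fruit × diet-breadth at replicate level, eggs ~ survival × guild and
within-guild eggs ~ survival × species at cell level, plus the three
zero-removal sensitivity refits for specialists. The IRLS fitter is part of
the package and is cross-checked against statsmodels in the test-suite.

**Synthetic communities** with known ground truth (Dirichlet preference
weights per guild, negative-binomial egg counts with Var = φ·mean, binomial
survival with a tunable logit-linear preference–performance coupling per
guild) drive all recovery and calibration tests.

## Worked example

```python
from prefperf import (ResamplingPlan, alpha_distributions, classify_by_alpha,
                      generate_community)

dataset, truth = generate_community(seed=7)
estimates = alpha_distributions(dataset, ResamplingPlan(n_matrices=500, seed=1))
for e in estimates:
    if e.measure == "eggs":
        print(f"{e.species:24s} {e.mean_alpha:6.2f} (truth {truth.alpha[e.species]:5.2f})")
print(classify_by_alpha(estimates, dataset.roster).agreement)
```

prints

```
Dacus demmerezi            5.96 (truth  5.80)
Zeugodacus cucurbitae      5.81 (truth  6.01)
Ceratitis catoirii        17.69 (truth 18.86)
Ceratitis capitata        18.33 (truth 19.78)
Ceratitis quilicii        15.70 (truth 17.40)
Bactrocera zonata         18.30 (truth 19.03)
True
```

— the two specialists' effective host numbers sit near 6 (the Cucurbitaceae
block), the generalists' near 18–20, the resampling means recover the
ground truth, and the largest-gap classification agrees with the a-priori
guilds. `examples/03_preference_performance.py` then shows the headline
pattern: per-species preference–performance correlations around r ≈ +0.65
(p < 0.001) for the specialists and scattered around zero for the
generalists, and `examples/04_deviance_models.py` prints the deviance
tables, e.g. the guild contrast row `Ddev_1,170` testing whether the
preference–performance slope differs between guilds.

The same pipeline runs from the shell:

```sh
prefperf run --seed 7 --out results/       # simulate + full analysis
prefperf simulate --seed 7 --out data/     # tables + ground truth only
prefperf run --in data/ --out results/     # analyse observed tables
```

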