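"""Pearson-correlation analyses of the preference-performance question.

Three analyses share one statistic:

1. across species, the correlation between diet breadth measured on
   oviposition (preference) and on larval survival (performance);
2. per species, the correlation over the 29 fruits between mean no-choice
   egg counts and survival proportions — the mother-knows-best test;
3. per species, the consistency between choice and no-choice assays, pairing
   each choice-replicate egg count with the species' no-choice per-fruit mean.

P-values are two-sided, from the t reference distribution with n - 2 degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CommunityDataset, build_interaction_matrix
from .resampling import DiversityEstimate

__all__ = [
    "CorrelationResult",
    "pearson_test",
    "alpha_pref_perf_correlation",
    "species_pref_perf_correlation",
    "choice_nochoice_consistency",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_two_sided: float


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t test.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` is reported alongside the p-value;
    at |r| = 1 the t statistic is infinite and p is 0. Constant input or
    n < 3 raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson test needs n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0 - 1e-15:
        t = float("inf") if r > 0 else float("-inf")
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return CorrelationResult(r=r, n=n, t_statistic=float(t), p_two_sided=float(res.pvalue))


def alpha_pref_perf_correlation(
    pref_estimates: list[DiversityEstimate],
    perf_estimates: list[DiversityEstimate],
) -> CorrelationResult:
    """Across-species correlation of preference vs performance diet breadth.

    Pairs each species' mean resampled diversity on eggs with its mean on
    survival; both lists must cover the same species.
    """
    pref = {e.species: e.mean_alpha for e in pref_estimates if e.measure == "eggs"}
    perf = {e.species: e.mean_alpha for e in perf_estimates if e.measure == "survival"}
    if set(pref) != set(perf):
        raise ValueError(
            f"species mismatch: preference {sorted(pref)} vs performance {sorted(perf)}"
        )
    species = sorted(pref)
    return pearson_test([pref[s] for s in species], [perf[s] for s in species])


def species_pref_perf_correlation(
    dataset: CommunityDataset, species: str
) -> CorrelationResult:
    """One species' preference-performance correlation over the full catalogue.

    Pairs the per-fruit mean no-choice egg count with the per-fruit survival
    proportion (29 pairs on the full design).
    """
    if species not in dataset.species:
        raise ValueError(f"unknown species {species!r}")
    eggs = build_interaction_matrix(dataset, "eggs", "mean").column(species)
    surv = build_interaction_matrix(dataset, "survival").column(species)
    keep = ~np.isnan(surv)
    if keep.sum() < 3:
        raise ValueError(f"species {species!r}: fewer than 3 fruits with survival data")
    return pearson_test(eggs[keep], surv[keep])


def choice_nochoice_consistency(
    dataset: CommunityDataset, species: str, level: str = "replicate"
) -> CorrelationResult:
    """Consistency of the choice and no-choice preference hierarchies.

    ``level="replicate"`` (default) pairs every choice-replicate egg count on
    a subset fruit with the species' no-choice mean for that fruit (12
    replicates x 8 fruits = 96 pairs on the full design). ``level="fruit"``
    collapses choice counts to per-fruit means first (8 pairs).
    """
    if level not in ("replicate", "fruit"):
        raise ValueError(f"unknown level {level!r}")
    subset = set(dataset.catalog.loc[dataset.catalog["in_choice_subset"], "fruit_id"])
    ovi = dataset.oviposition
    choice = ovi[
        (ovi["species"] == species)
        & (ovi["assay"] == "choice")
        & (ovi["fruit_id"].isin(subset))
    ]
    nc = ovi[
        (ovi["species"] == species)
        & (ovi["assay"] == "no_choice")
        & (ovi["fruit_id"].isin(subset))
    ]
    covered = set(choice["fruit_id"]) & set(nc["fruit_id"])
    if covered != subset:
        raise ValueError(
            f"species {species!r}: choice subset not fully covered, "
            f"missing fruits {sorted(subset - covered)}"
        )
    nc_mean = nc.groupby("fruit_id")["eggs"].mean()
    if level == "fruit":
        ch = choice.groupby("fruit_id")["eggs"].mean()
        fruits = sorted(subset)
        return pearson_test([ch[f] for f in fruits], [nc_mean[f] for f in fruits])
    return pearson_test(
        choice["eggs"].to_numpy(dtype=float),
        nc_mean.loc[choice["fruit_id"]].to_numpy(),
    )
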