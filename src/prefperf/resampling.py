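"""Resampling of interaction matrices and diet-breadth classification.

To attach uncertainty to each species' diet breadth, the analysis rebuilds
the plants x species interaction matrix many times (default B = 1000), each
time sampling — without replacement, independently across cells and matrices
— one oviposition replicate per cell and five survival cups per cell. The
Hill diversity of every species column in every resampled matrix yields a
per-species distribution of diet breadth, summarised by its mean and
variance.

Randomness is driven by one master seed; matrix ``m`` uses the substream
``SeedSequence(seed, spawn_key=(m,))``, so enlarging B extends the sequence
without reshuffling earlier matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import CommunityDataset, InteractionMatrix
from .diversity import hill_diversity

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingPlan",
    "DiversityEstimate",
    "GuildAssignment",
    "ClassificationResult",
    "resample_matrices",
    "alpha_distributions",
    "classify_by_alpha",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class ResamplingPlan:
    """How to resample: B matrices, k replicates per cell, master seed."""

    n_matrices: int = 1000
    k_oviposition: int = 1
    k_survival: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrices < 1:
            raise ValueError("n_matrices must be >= 1")
        if self.k_oviposition < 1 or self.k_survival < 1:
            raise ValueError("k values must be >= 1")


@dataclass
class DiversityEstimate:
    """Resampling distribution of one species' diet breadth for one measure."""

    species: str
    measure: str
    mean_alpha: float
    var_alpha: float
    samples: np.ndarray  # length n_matrices; NaN where the draw was degenerate
    n_dropped: int = 0


@dataclass
class GuildAssignment:
    species: str
    a_priori_guild: str
    assigned_guild: str
    mean_alpha: float
    separation_score: float


@dataclass
class ClassificationResult:
    assignments: list[GuildAssignment]
    degenerate: bool
    separation_score: float
    agreement: bool = field(default=False)


# ---------------------------------------------------------------------------


class _CellPools:
    """Per-cell replicate pools in a fixed (species-major) cell order."""

    def __init__(self, dataset: CommunityDataset):
        self.fruit_ids = dataset.fruit_ids
        self.species = dataset.species
        nc = dataset.oviposition[dataset.oviposition["assay"] == "no_choice"]
        self.eggs: dict[tuple[str, int], np.ndarray] = {
            key: grp["eggs"].to_numpy()
            for key, grp in nc.groupby(["species", "fruit_id"], sort=False)
        }
        self.cups: dict[tuple[str, int], np.ndarray] = {
            key: grp["pupated"].to_numpy()
            for key, grp in dataset.survival.groupby(["species", "fruit_id"], sort=False)
        }

    def check(self, plan: ResamplingPlan) -> None:
        empty = [
            (s, f)
            for s in self.species
            for f in self.fruit_ids
            if (s, f) not in self.cups
        ]
        if empty:
            logger.warning("%d survival cells have no cups; left NaN in resamples", len(empty))
        short = [
            (key, len(v)) for key, v in self.cups.items() if len(v) < plan.k_survival
        ]
        if short:
            logger.warning(
                "%d survival cells have fewer than k=%d cups; all available cups used",
                len(short),
                plan.k_survival,
            )


def _draw_pair(rng: np.random.Generator, pools: _CellPools, plan: ResamplingPlan):
    """Draw one (eggs, survival) matrix pair. Cell order is fixed: all egg
    cells species-major, then all survival cells."""
    n_r, n_c = len(pools.fruit_ids), len(pools.species)
    row_of = {f: i for i, f in enumerate(pools.fruit_ids)}
    eggs = np.zeros((n_r, n_c))
    for j, sp in enumerate(pools.species):
        for fr in pools.fruit_ids:
            pool = pools.eggs.get((sp, fr))
            if pool is None:
                continue
            eggs[row_of[fr], j] = _draw_eggs_cell(rng, pool, plan.k_oviposition)
    surv = np.full((n_r, n_c), np.nan)
    for j, sp in enumerate(pools.species):
        for fr in pools.fruit_ids:
            pool = pools.cups.get((sp, fr))
            if pool is None:
                continue
            k = min(plan.k_survival, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            surv[row_of[fr], j] = pool[idx].mean()
    return eggs, surv


def _draw_eggs_cell(rng: np.random.Generator, pool: np.ndarray, k: int) -> float:
    k = min(k, len(pool))
    if k == 1:
        return float(pool[rng.integers(len(pool))])
    idx = rng.choice(len(pool), size=k, replace=False)
    return float(pool[idx].sum())


def _matrix_rng(seed: int, m: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(m,)))


def resample_matrices(
    dataset: CommunityDataset, plan: ResamplingPlan
) -> list[tuple[InteractionMatrix, InteractionMatrix]]:
    """Build ``plan.n_matrices`` resampled (eggs, survival) matrix pairs.

    Every pair has the full catalogue x roster shape. Oviposition cells carry
    the egg count of ``k_oviposition`` sampled no-choice replicates (default
    one); survival cells carry the pupation proportion among ``k_survival``
    sampled cups. Fully reproducible from ``plan.seed``.
    """
    pools = _CellPools(dataset)
    pools.check(plan)
    out = []
    for m in range(plan.n_matrices):
        eggs, surv = _draw_pair(_matrix_rng(plan.seed, m), pools, plan)
        out.append(
            (
                InteractionMatrix(eggs, pools.fruit_ids, pools.species, "eggs"),
                InteractionMatrix(surv, pools.fruit_ids, pools.species, "survival"),
            )
        )
    return out


def alpha_distributions(
    dataset: CommunityDataset,
    plan: ResamplingPlan,
    measures: tuple[str, ...] = ("eggs", "survival"),
) -> list[DiversityEstimate]:
    """Per-species resampling distributions of Hill (q=1) diet breadth.

    For each resampled matrix and species, the species column's Hill
    diversity is recorded. A species column that comes out all-zero in a
    draw is redrawn (that species' cells only, up to 100 times); if still
    degenerate its sample is dropped from that matrix (NaN) and counted in
    ``n_dropped``.
    """
    pools = _CellPools(dataset)
    pools.check(plan)
    row_of = {f: i for i, f in enumerate(pools.fruit_ids)}
    n_sp = len(pools.species)
    samples = {meas: np.full((plan.n_matrices, n_sp), np.nan) for meas in measures}
    for m in range(plan.n_matrices):
        rng = _matrix_rng(plan.seed, m)
        eggs, surv = _draw_pair(rng, pools, plan)
        mats = {"eggs": eggs, "survival": surv}
        for measure in measures:
            mat = mats[measure]
            for j, sp in enumerate(pools.species):
                col = mat[:, j]
                if measure == "eggs":
                    col = _redraw_zero_column(rng, pools, plan, sp, col, row_of)
                    if col is None:
                        continue
                finite = col[~np.isnan(col)]
                if finite.size == 0 or finite.sum() <= 0:
                    continue  # dropped; counted below
                samples[measure][m, j] = hill_diversity(col, 1.0)
    estimates = []
    for measure in measures:
        arr = samples[measure]
        for j, sp in enumerate(pools.species):
            col = arr[:, j]
            n_dropped = int(np.isnan(col).sum())
            if n_dropped == plan.n_matrices:
                raise ValueError(
                    f"species {sp!r}: every {measure} resample degenerate (all-zero column)"
                )
            if n_dropped:
                logger.warning(
                    "species %s (%s): %d degenerate resamples dropped", sp, measure, n_dropped
                )
            mean = float(np.nanmean(col))
            if plan.n_matrices - n_dropped <= 1 or np.nanmax(col) == np.nanmin(col):
                var = 0.0  # constant samples: exactly zero, no summation jitter
            else:
                var = float(np.nanvar(col, ddof=1))
            estimates.append(
                DiversityEstimate(
                    species=sp,
                    measure=measure,
                    mean_alpha=mean,
                    var_alpha=var,
                    samples=col,
                    n_dropped=n_dropped,
                )
            )
    return estimates


def _redraw_zero_column(rng, pools, plan, species, col, row_of):
    """If a species' sampled egg profile is all-zero, redraw its cells.

    Returns the (possibly redrawn) column, or None if still all-zero after
    the redraw budget — alpha is undefined on an empty profile.
    """
    if np.nansum(col) > 0:
        return col
    # a species whose pools are all-zero can never yield a positive draw
    if all(
        pool.sum() == 0 for (sp, _), pool in pools.eggs.items() if sp == species
    ):
        return None
    for _ in range(_MAX_REDRAWS):
        new = np.array(col)
        for fr in pools.fruit_ids:
            pool = pools.eggs.get((species, fr))
            if pool is None:
                continue
            new[row_of[fr]] = _draw_eggs_cell(rng, pool, plan.k_oviposition)
        if np.nansum(new) > 0:
            return new
    return None


# ---------------------------------------------------------------------------


def classify_by_alpha(
    estimates: list[DiversityEstimate],
    roster=None,
    measure: str = "eggs",
) -> ClassificationResult:
    """Split species into specialists and generalists by their mean diet breadth.

    Species are ordered by mean preference diversity and split at the largest
    gap: the low side is called specialist, the high side generalist. The
    ``separation_score`` is the fraction of resampled matrices in which every
    assigned generalist's diversity exceeds every assigned specialist's — a
    paired, distribution-level check that the two guilds really separate.
    The a-priori roster (when given) is reported against, not overridden.
    """
    ests = [e for e in estimates if e.measure == measure]
    if len(ests) < 2:
        raise ValueError("classification needs at least two species")
    ests = sorted(ests, key=lambda e: e.mean_alpha)
    means = np.array([e.mean_alpha for e in ests])
    gaps = np.diff(means)
    degenerate = bool(gaps.max() <= 0)
    split = int(np.argmax(gaps)) + 1
    guild_of = {
        e.species: ("specialist" if i < split else "generalist") for i, e in enumerate(ests)
    }
    spec_samples = np.array([e.samples for e in ests[:split]])
    gen_samples = np.array([e.samples for e in ests[split:]])
    ok = ~(
        np.isnan(spec_samples).any(axis=0) | np.isnan(gen_samples).any(axis=0)
    )
    if ok.sum() == 0:
        separation = float("nan")
    else:
        separation = float(
            (gen_samples[:, ok].min(axis=0) > spec_samples[:, ok].max(axis=0)).mean()
        )
    a_priori = {}
    if roster is not None:
        a_priori = dict(zip(roster["species"], roster["guild"]))
    assignments = [
        GuildAssignment(
            species=e.species,
            a_priori_guild=a_priori.get(e.species, ""),
            assigned_guild=guild_of[e.species],
            mean_alpha=e.mean_alpha,
            separation_score=separation,
        )
        for e in ests
    ]
    agreement = bool(a_priori) and all(
        a.assigned_guild == a.a_priori_guild for a in assignments
    )
    if degenerate:
        logger.warning("classification degenerate: all mean alphas equal")
    return ClassificationResult(
        assignments=assignments,
        degenerate=degenerate,
        separation_score=separation,
        agreement=agreement,
    )
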