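"""Synthetic fruit-fly communities with known diet breadth and known
preference-performance coupling.

The generator mirrors the real assay design — a 29-fruit catalogue in 15
family blocks (one 6-fruit Cucurbitaceae block), 6 fly species (2 Cucurbitaceae
specialists, 4 generalists), 6 no-choice replicates per cell, 12 choice
replicates on an 8-fruit subset, and 30-50 single-larva survival cups per
cell — while every latent quantity is known exactly:

* preference weights ``w_i`` per species drawn from a block-weighted
  Dirichlet (specialists concentrated on the Cucurbitaceae block);
* expected eggs per replicate ``lambda_ij = egg_scale * w_ij`` with
  gamma-mixed Poisson (negative binomial) counts calibrated so that
  ``Var = phi * mean`` — the quasi-Poisson variance law;
* survival probabilities ``logit(s_ij) = a_g + b_g * z_ij + eps`` where
  ``z_ij`` is the species-standardised log preference weight: the coupling
  slope ``b_g`` is the ground-truth strength of the mother-knows-best
  relationship per guild (defaults: strong for specialists, zero for
  generalists).

``true_alpha`` — the Hill (q=1) diversity of ``w_i`` — is the ground truth
that the estimation pipeline is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CommunityDataset, load_catalog, load_roster

__all__ = ["CommunityConfig", "SyntheticTruth", "generate_community", "true_alpha"]

# family block sizes of the real catalogue, in fruit_id order
_DEFAULT_BLOCKS = [1, 1, 1, 1, 1, 6, 1, 1, 1, 4, 1, 3, 1, 1, 5]
_CUCURBIT_BLOCK_INDEX = 5  # the 6-fruit specialist block (fruit ids 6-11)


@dataclass(frozen=True)
class CommunityConfig:
    """Study-design constants and ground-truth distribution parameters.

    Dirichlet concentrations set diet breadth: specialists put mass on the
    Cucurbitaceae block (``specialist_block_conc`` on-block against
    ``specialist_offblock_conc`` off-block), generalists spread diffusely
    (``generalist_conc`` everywhere). ``egg_scale`` is the expected total
    eggs a replicate's females lay across a hypothetical full fruit set in
    24 h; ``overdispersion_phi`` the quasi-Poisson variance inflation;
    ``coupling_b_*`` the per-guild preference-performance slopes on the
    logit-survival scale.
    """

    n_fruits: int = 29
    family_blocks: tuple[int, ...] = tuple(_DEFAULT_BLOCKS)
    specialist_block: int = _CUCURBIT_BLOCK_INDEX
    n_specialists: int = 2
    n_generalists: int = 4
    specialist_block_conc: float = 2.0
    specialist_offblock_conc: float = 0.05
    generalist_conc: float = 1.0
    egg_scale: float = 400.0
    overdispersion_phi: float = 2.0
    coupling_b_specialist: float = 3.0
    coupling_b_generalist: float = 0.0
    survival_intercept_specialist: float = -2.0
    survival_intercept_generalist: float = 0.0
    noise_sd: float = 0.5
    n_nochoice_reps: int = 6
    n_choice_reps: int = 12
    choice_subset_size: int = 8
    n_females_nochoice: int = 5
    n_females_choice: int = 10
    survival_cups_min: int = 30
    survival_cups_max: int = 50
    replicate_overrides: dict = field(default_factory=dict)  # (species_idx, fruit_id) -> n reps
    seed: int = 0

    def validate(self) -> None:
        if sum(self.family_blocks) != self.n_fruits:
            raise ValueError("family blocks must partition the fruit set")
        if not (0 <= self.specialist_block < len(self.family_blocks)):
            raise ValueError("specialist_block out of range")
        if self.n_specialists < 1 or self.n_generalists < 1:
            raise ValueError("both guilds must be non-empty")
        if self.overdispersion_phi < 1:
            raise ValueError("overdispersion_phi must be >= 1")
        if min(
            self.specialist_block_conc,
            self.specialist_offblock_conc,
            self.generalist_conc,
        ) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.egg_scale <= 0 or self.noise_sd < 0:
            raise ValueError("egg_scale must be positive and noise_sd non-negative")
        if not (1 <= self.choice_subset_size <= self.n_fruits):
            raise ValueError("choice subset must be within the fruit set")
        if not (1 <= self.survival_cups_min <= self.survival_cups_max):
            raise ValueError("invalid survival cup range")
        if min(self.n_nochoice_reps, self.n_choice_reps) < 1:
            raise ValueError("replicate counts must be positive")


@dataclass
class SyntheticTruth:
    """Latent ground truth behind a generated community."""

    species: list[str]
    guilds: dict[str, str]
    fruit_ids: list[int]
    preference_weights: pd.DataFrame  # species x fruit_id, rows on the simplex
    survival_probs: pd.DataFrame  # species x fruit_id, in (0,1)
    alpha: dict[str, float]
    config: CommunityConfig


def true_alpha(truth: SyntheticTruth) -> dict[str, float]:
    """Effective host number per species: exp of the Shannon entropy of
    its true preference weights."""
    out = {}
    for sp in truth.species:
        w = truth.preference_weights.loc[sp].to_numpy()
        w = w[w > 0]
        out[sp] = float(np.exp(-(w * np.log(w)).sum()))
    return out


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, phi: float) -> np.ndarray:
    """Counts with mean lam and variance phi*lam (Poisson at phi = 1)."""
    lam = np.asarray(lam, dtype=float)
    if phi <= 1.0 + 1e-12:
        return rng.poisson(lam)
    size = lam / (phi - 1.0)  # Var = lam + lam^2/size = phi*lam
    out = np.zeros(lam.shape, dtype=int)
    pos = lam > 0
    out[pos] = rng.negative_binomial(size[pos], size[pos] / (size[pos] + lam[pos]))
    return out


def _guild_weights(rng: np.random.Generator, config: CommunityConfig, guild: str) -> np.ndarray:
    conc = np.full(config.n_fruits, config.generalist_conc)
    if guild == "specialist":
        conc[:] = config.specialist_offblock_conc
        start = sum(config.family_blocks[: config.specialist_block])
        stop = start + config.family_blocks[config.specialist_block]
        conc[start:stop] = config.specialist_block_conc
    w = rng.dirichlet(conc)
    # numerical floor: tiny-concentration draws can underflow; keeps log w finite
    w = np.clip(w, 1e-8, None)
    return w / w.sum()


def generate_community(
    config: CommunityConfig | None = None, seed: int | None = None
) -> tuple[CommunityDataset, SyntheticTruth]:
    """Draw one synthetic community dataset plus its ground truth.

    With the default 29-fruit / 6-species design the embedded catalogue and
    roster are used verbatim, so outputs are drop-in replacements for the
    real tables. All draws flow from one generator seeded by ``seed``
    (default ``config.seed``) in a fixed order, so outputs are reproducible.
    """
    config = config or CommunityConfig()
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    default_design = (
        config.n_fruits == 29
        and tuple(config.family_blocks) == tuple(_DEFAULT_BLOCKS)
        and config.n_specialists == 2
        and config.n_generalists == 4
    )
    if default_design:
        catalog = load_catalog()
        roster = load_roster()
    else:
        families = [f"family_{i + 1:02d}" for i in range(len(config.family_blocks))]
        rows = []
        fid = 0
        for fam, size in zip(families, config.family_blocks):
            for k in range(size):
                fid += 1
                rows.append((fid, fam, f"{fam} sp. {k + 1}", f"fruit_{fid:02d}", False))
        catalog = pd.DataFrame(
            rows,
            columns=["fruit_id", "family", "scientific_name", "common_name", "in_choice_subset"],
        )
        subset = np.sort(
            rng.choice(config.n_fruits, size=config.choice_subset_size, replace=False) + 1
        )
        catalog["in_choice_subset"] = catalog["fruit_id"].isin(subset)
        roster = pd.DataFrame(
            [(f"specialist_{i + 1}", "specialist") for i in range(config.n_specialists)]
            + [(f"generalist_{i + 1}", "generalist") for i in range(config.n_generalists)],
            columns=["species", "guild"],
        )

    species = list(roster["species"])
    guilds = dict(zip(roster["species"], roster["guild"]))
    fruit_ids = list(catalog["fruit_id"])
    subset_ids = list(catalog.loc[catalog["in_choice_subset"], "fruit_id"])

    # latent truth
    W = np.vstack([_guild_weights(rng, config, guilds[sp]) for sp in species])
    S = np.zeros_like(W)
    for i, sp in enumerate(species):
        g = guilds[sp]
        a = (
            config.survival_intercept_specialist
            if g == "specialist"
            else config.survival_intercept_generalist
        )
        b = (
            config.coupling_b_specialist
            if g == "specialist"
            else config.coupling_b_generalist
        )
        logw = np.log(W[i])
        z = (logw - logw.mean()) / (logw.std() if logw.std() > 0 else 1.0)
        eps = rng.normal(0.0, config.noise_sd, size=config.n_fruits)
        S[i] = 1.0 / (1.0 + np.exp(-(a + b * z + eps)))

    # oviposition: no-choice then choice, species-major, fruit-minor
    ovi_rows = []
    for i, sp in enumerate(species):
        for j, fr in enumerate(fruit_ids):
            n_reps = config.replicate_overrides.get((i, fr), config.n_nochoice_reps)
            lam = np.full(n_reps, config.egg_scale * W[i, j])
            counts = _nb_counts(rng, lam, config.overdispersion_phi)
            for r, c in enumerate(counts, start=1):
                ovi_rows.append(
                    (sp, fr, "no_choice", r, config.n_females_nochoice, int(c))
                )
    female_ratio = config.n_females_choice / config.n_females_nochoice
    for i, sp in enumerate(species):
        # females allocate among offered fruits by the same latent weights
        w_sub = np.array([W[i, fruit_ids.index(fr)] for fr in subset_ids])
        lam_sub = config.egg_scale * female_ratio * w_sub
        for r in range(1, config.n_choice_reps + 1):
            counts = _nb_counts(rng, lam_sub, config.overdispersion_phi)
            for fr, c in zip(subset_ids, counts):
                ovi_rows.append((sp, fr, "choice", r, config.n_females_choice, int(c)))
    oviposition = pd.DataFrame(
        ovi_rows,
        columns=["species", "fruit_id", "assay", "replicate", "n_females", "eggs"],
    )

    # survival cups
    surv_rows = []
    for i, sp in enumerate(species):
        for j, fr in enumerate(fruit_ids):
            n_cups = int(
                rng.integers(config.survival_cups_min, config.survival_cups_max + 1)
            )
            outcomes = rng.random(n_cups) < S[i, j]
            for cup, pup in enumerate(outcomes, start=1):
                surv_rows.append((sp, fr, cup, int(pup)))
    survival = pd.DataFrame(surv_rows, columns=["species", "fruit_id", "cup", "pupated"])

    dataset = CommunityDataset(
        catalog=catalog, roster=roster, oviposition=oviposition, survival=survival
    )
    truth = SyntheticTruth(
        species=species,
        guilds=guilds,
        fruit_ids=fruit_ids,
        preference_weights=pd.DataFrame(W, index=species, columns=fruit_ids),
        survival_probs=pd.DataFrame(S, index=species, columns=fruit_ids),
        alpha={},
        config=config,
    )
    truth.alpha = true_alpha(truth)
    return dataset, truth


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Emit the per-(species, fruit) ground truth as a tidy TSV."""
    rows = []
    for sp in truth.species:
        for fr in truth.fruit_ids:
            rows.append(
                {
                    "species": sp,
                    "fruit_id": fr,
                    "w": truth.preference_weights.loc[sp, fr],
                    "s": truth.survival_probs.loc[sp, fr],
                    "true_alpha": truth.alpha[sp],
                    "guild": truth.guilds[sp],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
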