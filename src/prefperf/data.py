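"""Data model and tidy-table IO for the fruit-fly / host-plant community.

The study design is a complete bipartite assay: each tephritid species in the
roster is exposed to each fruit of a 29-fruit host catalogue, in

* **no-choice oviposition assays** — 5 females caged with a single fruit
  substrate for 24 h, eggs counted; 6 replicates per (species, fruit) cell;
* **choice oviposition assays** — 10 females with substrates of 8 fruits
  simultaneously, 12 replicates per species;
* **larval survival trials** — one neonate larva per cup on a fruit-based
  diet, 30-50 cups per (species, fruit) cell; survival is the proportion of
  cups that yield a pupa.

Records live in tidy ``pandas`` tables, one observation per row; all on-disk
formats are UTF-8 tab-separated text with a mandatory header so that a
write/read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "InteractionMatrix",
    "CommunityDataset",
    "load_catalog",
    "load_roster",
    "read_oviposition_table",
    "write_oviposition_table",
    "read_survival_table",
    "write_survival_table",
    "read_roster_table",
    "write_roster_table",
    "read_catalog_table",
    "write_catalog_table",
    "aggregate_survival",
    "build_interaction_matrix",
    "validate_dataset",
]


class ValidationError(ValueError):
    """A table or dataset violated the data contract; message lists offending rows."""


# The 29-fruit host catalogue used in the assays: (fruit_id, family,
# scientific name, common name, offered in the 8-fruit choice assay).
_CATALOG_ROWS = [
    (1, "Anacardiaceae", "Mangifera indica", "Mango", True),
    (2, "Annonaceae", "Annona reticulata", "Custard apple", False),
    (3, "Cactaceae", "Hylocereus undatus", "Dragon fruit", False),
    (4, "Caricaceae", "Carica papaya", "Papaya", False),
    (5, "Combretaceae", "Terminalia catappa", "Indian almond", True),
    (6, "Cucurbitaceae", "Citrullus lanatus", "Watermelon", False),
    (7, "Cucurbitaceae", "Cucumis melo", "Melon", True),
    (8, "Cucurbitaceae", "Cucumis sativus", "Cucumber", False),
    (9, "Cucurbitaceae", "Cucurbita maxima", "Pumpkin", True),
    (10, "Cucurbitaceae", "Cucurbita pepo", "Zucchini", False),
    (11, "Cucurbitaceae", "Sechium edule", "Chayote", False),
    (12, "Lauraceae", "Persea americana", "Avocado", False),
    (13, "Lythraceae", "Punica granatum", "Pomegranate", False),
    (14, "Moraceae", "Ficus carica", "Fig", False),
    (15, "Myrtaceae", "Psidium cattleyanum", "Strawberry guava", True),
    (16, "Myrtaceae", "Psidium guajava", "Guava", True),
    (17, "Myrtaceae", "Syzygium jambos", "Rose apple", False),
    (18, "Myrtaceae", "Syzygium samarangense", "Java apple", False),
    (19, "Oxalidaceae", "Averrhoa carambola", "Star fruit", False),
    (20, "Rosaceae", "Eriobotrya japonica", "Loquat", False),
    (21, "Rosaceae", "Prunus domestica", "Plum", False),
    (22, "Rosaceae", "Prunus persica", "Peach", False),
    (23, "Rubiaceae", "Coffea arabica", "Coffee", False),
    (24, "Rutaceae", "Citrus reticulata x Citrus sinensis", "Tangor", False),
    (25, "Solanaceae", "Capsicum annum", "Chili", True),
    (26, "Solanaceae", "Solanum betaceum", "Tree tomato", False),
    (27, "Solanaceae", "Solanum lycopersicum", "Tomato", True),
    (28, "Solanaceae", "Solanum mauritianum", "Bugweed", False),
    (29, "Solanaceae", "Solanum melongena", "Eggplant", False),
]

# The six-species community of La Reunion: two Cucurbitaceae specialists,
# four polyphagous generalists. Guilds are assigned a priori from reported
# field host ranges; the pipeline re-checks them against estimated diet breadth.
_ROSTER_ROWS = [
    ("Dacus demmerezi", "specialist"),
    ("Zeugodacus cucurbitae", "specialist"),
    ("Ceratitis catoirii", "generalist"),
    ("Ceratitis capitata", "generalist"),
    ("Ceratitis quilicii", "generalist"),
    ("Bactrocera zonata", "generalist"),
]

CATALOG_COLUMNS = ["fruit_id", "family", "scientific_name", "common_name", "in_choice_subset"]
ROSTER_COLUMNS = ["species", "guild"]
OVIPOSITION_COLUMNS = ["species", "fruit_id", "assay", "replicate", "n_females", "eggs"]
SURVIVAL_COLUMNS = ["species", "fruit_id", "cup", "pupated"]

ASSAYS = ("no_choice", "choice")
GUILDS = ("specialist", "generalist")


def load_catalog() -> pd.DataFrame:
    """Return the embedded 29-fruit host catalogue.

    Columns: ``fruit_id`` (1..29), ``family``, ``scientific_name``,
    ``common_name``, ``in_choice_subset`` (bool; 8 fruits flagged).
    """
    return pd.DataFrame(_CATALOG_ROWS, columns=CATALOG_COLUMNS)


def load_roster() -> pd.DataFrame:
    """Return the embedded six-species roster with a-priori guilds."""
    return pd.DataFrame(_ROSTER_ROWS, columns=ROSTER_COLUMNS)


# ---------------------------------------------------------------------------
# tidy-table IO


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing} (found {list(df.columns)})")


def _report_rows(mask: pd.Series, df: pd.DataFrame, msg: str, errors: list[str]) -> None:
    # +2: header line plus 1-based numbering, so numbers match the text file.
    for idx in df.index[mask]:
        errors.append(f"line {idx + 2}: {msg}: {df.loc[idx].to_dict()}")


def read_oviposition_table(
    path: str | Path,
    *,
    catalog: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a tidy oviposition table (TSV).

    Expected columns: species, fruit_id, assay {no_choice|choice}, replicate,
    n_females, eggs. Malformed rows are reported with their line number in the
    file; unknown species/fruits (against *roster*/*catalog* when given) and
    negative egg counts raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "assay": str})
    _check_columns(df, OVIPOSITION_COLUMNS, f"oviposition table {path}")
    df = df[OVIPOSITION_COLUMNS].copy()
    if df.empty:
        return df.astype(
            {"fruit_id": int, "replicate": int, "n_females": int, "eggs": int},
            errors="ignore",
        )
    errors: list[str] = []
    _report_rows(~df["assay"].isin(ASSAYS), df, "unknown assay", errors)
    for col in ("fruit_id", "replicate", "n_females", "eggs"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        _report_rows(bad, df, f"non-numeric {col}", errors)
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if not errors:
        _report_rows(df["eggs"] < 0, df, "negative egg count", errors)
        if catalog is not None:
            _report_rows(~df["fruit_id"].isin(catalog["fruit_id"]), df, "unknown fruit_id", errors)
        if roster is not None:
            _report_rows(~df["species"].isin(roster["species"]), df, "unknown species", errors)
        dup = df.duplicated(subset=["species", "fruit_id", "assay", "replicate"], keep=False)
        _report_rows(dup & ~df.duplicated(subset=["species", "fruit_id", "assay", "replicate"]),
                     df, "duplicate (species, fruit, assay, replicate)", errors)
    if errors:
        raise ValidationError("invalid oviposition table:\n" + "\n".join(errors))
    return df.astype({"fruit_id": int, "replicate": int, "n_females": int, "eggs": int})


def write_oviposition_table(df: pd.DataFrame, path: str | Path) -> None:
    df[OVIPOSITION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_survival_table(
    path: str | Path,
    *,
    catalog: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a per-cup survival table (TSV).

    Expected columns: species, fruit_id, cup, pupated {0|1}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    _check_columns(df, SURVIVAL_COLUMNS, f"survival table {path}")
    df = df[SURVIVAL_COLUMNS].copy()
    if df.empty:
        return df
    errors: list[str] = []
    for col in ("fruit_id", "cup", "pupated"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        _report_rows(bad, df, f"non-numeric {col}", errors)
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if not errors:
        _report_rows(~df["pupated"].isin((0, 1)), df, "pupated not in {0,1}", errors)
        if catalog is not None:
            _report_rows(~df["fruit_id"].isin(catalog["fruit_id"]), df, "unknown fruit_id", errors)
        if roster is not None:
            _report_rows(~df["species"].isin(roster["species"]), df, "unknown species", errors)
    if errors:
        raise ValidationError("invalid survival table:\n" + "\n".join(errors))
    return df.astype({"fruit_id": int, "cup": int, "pupated": int})


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_roster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, ROSTER_COLUMNS, f"roster table {path}")
    df = df[ROSTER_COLUMNS].copy()
    bad = ~df["guild"].isin(GUILDS)
    if bad.any():
        raise ValidationError(f"invalid roster table: unknown guilds {sorted(df.loc[bad, 'guild'])}")
    return df


def write_roster_table(df: pd.DataFrame, path: str | Path) -> None:
    df[ROSTER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_catalog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, CATALOG_COLUMNS, f"catalog table {path}")
    df = df[CATALOG_COLUMNS].copy()
    df["in_choice_subset"] = df["in_choice_subset"].astype(int).astype(bool)
    ids = df["fruit_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(1, len(df) + 1)):
        raise ValidationError("catalog fruit_id values must be unique and contiguous from 1")
    return df


def write_catalog_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CATALOG_COLUMNS].copy()
    out["in_choice_subset"] = out["in_choice_subset"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class CommunityDataset:
    """A complete community study: catalogue, roster and replicate-level records."""

    catalog: pd.DataFrame
    roster: pd.DataFrame
    oviposition: pd.DataFrame
    survival: pd.DataFrame

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CommunityDataset":
        """Load ``hosts.tsv``, ``roster.tsv``, ``oviposition.tsv`` and
        ``survival.tsv`` from *directory*."""
        d = Path(directory)
        catalog = read_catalog_table(d / "hosts.tsv")
        roster = read_roster_table(d / "roster.tsv")
        return cls(
            catalog=catalog,
            roster=roster,
            oviposition=read_oviposition_table(d / "oviposition.tsv", catalog=catalog, roster=roster),
            survival=read_survival_table(d / "survival.tsv", catalog=catalog, roster=roster),
        )

    def to_dir(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_catalog_table(self.catalog, d / "hosts.tsv")
        write_roster_table(self.roster, d / "roster.tsv")
        write_oviposition_table(self.oviposition, d / "oviposition.tsv")
        write_survival_table(self.survival, d / "survival.tsv")

    @property
    def species(self) -> list[str]:
        return list(self.roster["species"])

    @property
    def fruit_ids(self) -> list[int]:
        return list(self.catalog["fruit_id"])


def validate_dataset(dataset: CommunityDataset) -> dict:
    """Cross-check all record references and enumerate unobserved design cells.

    Returns a report dict (never raises for incompleteness): keys
    ``unknown_species``, ``unknown_fruits``, ``missing_oviposition_cells``,
    ``missing_survival_cells``, ``survival_cup_range_exceptions``.
    """
    report: dict = {}
    species = set(dataset.roster["species"])
    fruits = set(dataset.catalog["fruit_id"])
    ovi, surv = dataset.oviposition, dataset.survival
    report["unknown_species"] = sorted(
        (set(ovi["species"]) | set(surv["species"])) - species
    )
    report["unknown_fruits"] = sorted(
        (set(ovi["fruit_id"]) | set(surv["fruit_id"])) - fruits
    )
    nc = ovi[ovi["assay"] == "no_choice"]
    have_ovi = set(zip(nc["species"], nc["fruit_id"]))
    have_surv = set(zip(surv["species"], surv["fruit_id"]))
    full = {(s, f) for s in species for f in fruits}
    report["missing_oviposition_cells"] = sorted(full - have_ovi)
    report["missing_survival_cells"] = sorted(full - have_surv)
    counts = surv.groupby(["species", "fruit_id"]).size()
    exceptions = counts[(counts < 30) | (counts > 50)]
    report["survival_cup_range_exceptions"] = {
        key: int(n) for key, n in exceptions.items()
    }
    for key, value in report.items():
        if value:
            logger.warning("dataset validation: %s: %s", key, value)
    return report


def aggregate_survival(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-cup Bernoulli outcomes into per-cell survival proportions.

    Returns one row per observed (species, fruit_id) with ``n_trials``,
    ``n_pupae`` and ``survival`` = n_pupae / n_trials. Cells with zero trials
    are simply absent (0 trials is not 0% survival).
    """
    if trials.empty:
        return pd.DataFrame(columns=["species", "fruit_id", "n_trials", "n_pupae", "survival"])
    g = trials.groupby(["species", "fruit_id"], as_index=False).agg(
        n_trials=("pupated", "size"), n_pupae=("pupated", "sum")
    )
    g["survival"] = g["n_pupae"] / g["n_trials"]
    return g


# ---------------------------------------------------------------------------
# interaction matrix


@dataclass
class InteractionMatrix:
    """Plants x fly-species matrix of interaction strengths (eggs or survival).

    ``values[i, j]`` is the strength for ``row_labels[i]`` (fruit_id) and
    ``col_labels[j]`` (species). Unobserved survival cells are NaN and listed
    in ``missing_cells``; unobserved egg cells are 0 (the design is complete,
    a missing egg cell is logged as a warning).
    """

    values: np.ndarray
    row_labels: list[int]
    col_labels: list[str]
    measure: str
    missing_cells: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("interaction strengths must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, species: str) -> np.ndarray:
        return self.values[:, self.col_labels.index(species)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


def build_interaction_matrix(
    dataset: CommunityDataset, measure: str = "eggs", statistic: str = "sum"
) -> InteractionMatrix:
    """Build the full plants x species interaction matrix.

    For ``measure="eggs"`` only no-choice records are used (the study's
    preference measure) and each cell is the *statistic* (``sum`` or ``mean``)
    of its replicate egg counts; unobserved cells become 0 with a warning.
    For ``measure="survival"`` each cell is the pupation proportion over all
    cups; unobserved cells become NaN and are listed in ``missing_cells``.
    """
    if measure not in ("eggs", "survival"):
        raise ValueError(f"unknown measure {measure!r}")
    if statistic not in ("sum", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if dataset.oviposition.empty and dataset.survival.empty:
        raise ValidationError("empty dataset: no oviposition or survival records")
    fruit_ids = dataset.fruit_ids
    species = dataset.species
    row_index = {f: i for i, f in enumerate(fruit_ids)}
    col_index = {s: j for j, s in enumerate(species)}
    missing: list[tuple[str, int]] = []
    if measure == "eggs":
        values = np.zeros((len(fruit_ids), len(species)))
        nc = dataset.oviposition[dataset.oviposition["assay"] == "no_choice"]
        agg = nc.groupby(["species", "fruit_id"])["eggs"].agg(statistic)
        for (sp, fr), v in agg.items():
            values[row_index[fr], col_index[sp]] = v
        observed = set(agg.index)
        unobserved = [(s, f) for s in species for f in fruit_ids if (s, f) not in observed]
        if unobserved:
            logger.warning(
                "%d unobserved egg cells set to 0 (first: %s)", len(unobserved), unobserved[0]
            )
    else:
        values = np.full((len(fruit_ids), len(species)), np.nan)
        cells = aggregate_survival(dataset.survival)
        for _, row in cells.iterrows():
            if row["species"] in col_index and row["fruit_id"] in row_index:
                values[row_index[row["fruit_id"]], col_index[row["species"]]] = row["survival"]
        missing = [
            (s, f)
            for s in species
            for f in fruit_ids
            if np.isnan(values[row_index[f], col_index[s]])
        ]
        if missing:
            logger.warning("%d survival cells unobserved (flagged NaN)", len(missing))
    return InteractionMatrix(
        values=values,
        row_labels=fruit_ids,
        col_labels=species,
        measure=measure,
        missing_cells=missing,
    )
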