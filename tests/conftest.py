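import numpy as np
import pandas as pd
import pytest

from prefperf import CommunityConfig, CommunityDataset, generate_community, load_catalog, load_roster


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community with its ground truth (fixed seed)."""
    return generate_community(CommunityConfig(), seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_community):
    return default_community[0]


@pytest.fixture(scope="session")
def default_truth(default_community):
    return default_community[1]


def tiny_dataset(
    egg_cells: dict[tuple[str, int], list[int]],
    cup_cells: dict[tuple[str, int], list[int]],
    guilds: dict[str, str] | None = None,
    n_fruits: int | None = None,
) -> CommunityDataset:
    """Hand-built minimal dataset from per-cell replicate lists."""
    species = sorted({sp for sp, _ in list(egg_cells) + list(cup_cells)})
    fruits = sorted({f for _, f in list(egg_cells) + list(cup_cells)})
    n_fruits = n_fruits or max(fruits)
    catalog = pd.DataFrame(
        {
            "fruit_id": range(1, n_fruits + 1),
            "family": [f"fam{i}" for i in range(1, n_fruits + 1)],
            "scientific_name": [f"Plantus num{i}" for i in range(1, n_fruits + 1)],
            "common_name": [f"fruit{i}" for i in range(1, n_fruits + 1)],
            "in_choice_subset": False,
        }
    )
    guilds = guilds or {}
    roster = pd.DataFrame(
        {"species": species, "guild": [guilds.get(s, "generalist") for s in species]}
    )
    ovi_rows = [
        (sp, f, "no_choice", r + 1, 5, e)
        for (sp, f), reps in egg_cells.items()
        for r, e in enumerate(reps)
    ]
    surv_rows = [
        (sp, f, c + 1, int(p))
        for (sp, f), cups in cup_cells.items()
        for c, p in enumerate(cups)
    ]
    return CommunityDataset(
        catalog=catalog,
        roster=roster,
        oviposition=pd.DataFrame(
            ovi_rows, columns=["species", "fruit_id", "assay", "replicate", "n_females", "eggs"]
        ),
        survival=pd.DataFrame(surv_rows, columns=["species", "fruit_id", "cup", "pupated"]),
    )
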