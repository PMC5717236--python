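"""End-to-end orchestration: data in, tidy result tables out.

``run_pipeline`` chains the full analysis — simulate or ingest, resample
interaction matrices, estimate per-species diet breadth, classify guilds,
run the correlation analyses and the deviance-model suite — and writes six
deterministic TSV outputs plus a JSON manifest. Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    alpha_pref_perf_correlation,
    choice_nochoice_consistency,
    species_pref_perf_correlation,
)
from .data import CommunityDataset, validate_dataset
from .glm import model_suite
from .resampling import ResamplingPlan, alpha_distributions, classify_by_alpha
from .simulate import CommunityConfig, generate_community, write_truth_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs. Exactly one of ``input_dir`` /
    ``simulation`` drives the data stage."""

    input_dir: str | None = None
    simulation: CommunityConfig | None = None
    plan: ResamplingPlan = field(default_factory=ResamplingPlan)
    test: str = "F"  # deviance test flavour: F or chi2
    cell_response: str = "sum"  # cell-level egg response: sum or mean of replicates
    consistency_level: str = "replicate"  # choice/no-choice pairing level
    out_dir: str = "prefperf_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_dir or simulation")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML mapping.

    Top-level keys mirror the dataclass fields; ``simulation`` and ``plan``
    are nested mappings of :class:`CommunityConfig` / :class:`ResamplingPlan`
    fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "family_blocks" in sim:
            sim["family_blocks"] = tuple(sim["family_blocks"])
        sim = CommunityConfig(**sim)
    plan = ResamplingPlan(**raw.pop("plan", {}))
    return PipelineConfig(simulation=sim, plan=plan, **raw)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if echo.get("simulation") and isinstance(echo["simulation"].get("replicate_overrides"), dict):
        echo["simulation"]["replicate_overrides"] = {
            str(k): v for k, v in echo["simulation"]["replicate_overrides"].items()
        }
    return echo


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Outputs: ``diversity_estimates.tsv``, ``alpha_samples.tsv``,
    ``classification.tsv``, ``correlations.tsv``, ``deviance_tables.tsv``,
    ``manifest.json`` (plus the four input tables and ``truth.tsv`` when
    simulating). Returns a dict with the in-memory stage results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("prefperf").addHandler(collector)
    try:
        return _run(config, out, collector)
    finally:
        logging.getLogger("prefperf").removeHandler(collector)


def _run(config: PipelineConfig, out: Path, collector: _WarningCollector) -> dict:
    # --- stage: data
    if config.simulation is not None:
        sim_config = replace(config.simulation, seed=config.seed)
        dataset, truth = generate_community(sim_config)
        dataset.to_dir(out)
        write_truth_table(truth, out / "truth.tsv")
    else:
        dataset, truth = CommunityDataset.from_dir(config.input_dir), None
    validation = validate_dataset(dataset)

    # --- stage: resampling + diversity
    plan = replace(config.plan, seed=config.seed + 1)
    estimates = alpha_distributions(dataset, plan)
    div_rows = [
        {
            "species": e.species,
            "measure": e.measure,
            "q": 1.0,
            "mean_alpha": e.mean_alpha,
            "var_alpha": e.var_alpha,
            "n_resamples": plan.n_matrices - e.n_dropped,
        }
        for e in estimates
    ]
    pd.DataFrame(div_rows).to_csv(
        out / "diversity_estimates.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    sample_rows = []
    for e in estimates:
        for m, a in enumerate(e.samples):
            if not np.isnan(a):
                sample_rows.append(
                    {"matrix_index": m, "species": e.species, "measure": e.measure, "alpha": a}
                )
    pd.DataFrame(sample_rows).to_csv(
        out / "alpha_samples.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- stage: classification
    classification = classify_by_alpha(estimates, dataset.roster)
    pd.DataFrame(
        [
            {
                "species": a.species,
                "a_priori_guild": a.a_priori_guild,
                "assigned_guild": a.assigned_guild,
                "mean_alpha": a.mean_alpha,
                "separation_score": a.separation_score,
            }
            for a in classification.assignments
        ]
    ).to_csv(out / "classification.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # --- stage: correlations
    corr_rows = []
    community = alpha_pref_perf_correlation(estimates, estimates)
    corr_rows.append(_corr_row("alpha_pref_perf", "community", community))
    for sp in dataset.species:
        corr_rows.append(
            _corr_row("species_pref_perf", sp, species_pref_perf_correlation(dataset, sp))
        )
    for sp in dataset.species:
        try:
            res = choice_nochoice_consistency(dataset, sp, config.consistency_level)
        except ValueError as exc:
            logger.warning("choice consistency skipped for %s: %s", sp, exc)
            continue
        corr_rows.append(_corr_row("choice_consistency", sp, res))
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- stage: deviance models
    alpha_by_species = {
        e.species: e.mean_alpha for e in estimates if e.measure == "eggs"
    }
    suite = model_suite(
        dataset, alpha_by_species, test=config.test, cell_response=config.cell_response
    )
    dev_rows = []
    for model_id, table in suite.items():
        for _, row in table.rows.iterrows():
            dev_rows.append(
                {
                    "model_id": model_id,
                    "term": row["term"],
                    "delta_dev": row["delta_dev"],
                    "delta_df": int(row["delta_df"]),
                    "df_residual": int(row["df_residual"]),
                    "F": row["F"],
                    "p": row["p"],
                    "dispersion": table.dispersion,
                    "n_obs": table.n_obs,
                }
            )
    pd.DataFrame(dev_rows).to_csv(
        out / "deviance_tables.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- manifest
    manifest = {
        "package": "prefperf",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "validation": {k: _jsonable(v) for k, v in validation.items()},
        "warnings": collector.messages,
        "outputs": [
            "diversity_estimates.tsv",
            "alpha_samples.tsv",
            "classification.tsv",
            "correlations.tsv",
            "deviance_tables.tsv",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    return {
        "dataset": dataset,
        "truth": truth,
        "estimates": estimates,
        "classification": classification,
        "correlations": correlations,
        "suite": suite,
        "validation": validation,
    }


def _corr_row(analysis: str, species: str, res) -> dict:
    return {
        "analysis": analysis,
        "species": species,
        "r": res.r,
        "n": res.n,
        "t": res.t_statistic,
        "p": res.p_two_sided,
    }


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
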