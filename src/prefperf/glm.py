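"""Quasi-Poisson log-linear models and sequential analysis of deviance.

Egg counts are modelled on the log scale, ``log mu = X beta``, with the
Poisson deviance ``D = 2 sum[y log(y/mu) - (y - mu)]`` and a dispersion
parameter ``phi`` estimated as Pearson chi-square over residual degrees of
freedom — the quasi-Poisson treatment of overdispersed counts. Terms are
tested sequentially (type-I): each added term's deviance drop is scaled to
an F statistic ``F = (Ddev/Ddf) / phi`` using the dispersion of the fullest
model in the sequence, with p from ``F(Ddf, df_residual of fullest)``.

Fitting is iteratively reweighted least squares written against numpy /
scipy directly, so its agreement with an independent GLM implementation can
serve as a genuine cross-check in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CommunityDataset, aggregate_survival

logger = logging.getLogger(__name__)

__all__ = [
    "FittedGLM",
    "DevianceTable",
    "build_design_matrix",
    "fit_quasipoisson",
    "sequential_deviance",
    "zero_filter",
    "make_replicate_table",
    "make_cell_table",
    "model_suite",
]

_MU_FLOOR = 1e-10


@dataclass
class FittedGLM:
    coefficients: np.ndarray
    column_names: list[str]
    fitted_means: np.ndarray
    deviance: float
    df_residual: int
    pearson_chi2: float
    dispersion: float
    converged: bool
    n_iterations: int
    mu_floored: bool = False


@dataclass
class DevianceTable:
    """Sequential analysis-of-deviance rows for one model.

    ``df_residual`` per row is the residual df after adding that term (the
    convention of printed Ddev_{Ddf, df} signatures); F p-values use the
    fullest model's dispersion and residual df.
    """

    model_id: str
    rows: pd.DataFrame  # term, delta_dev, delta_df, df_residual, F, p
    dispersion: float
    n_obs: int
    df_residual_full: int = 0

    def row(self, term: str) -> pd.Series:
        return self.rows.set_index("term").loc[term]


# ---------------------------------------------------------------------------
# design matrices


def _encode_factor(values: pd.Series) -> tuple[np.ndarray, list[str], str]:
    """Treatment-code a factor: reference = first declared (or first-seen) level."""
    if isinstance(values.dtype, pd.CategoricalDtype):
        levels = list(values.cat.categories)
    else:
        levels = list(pd.unique(values))
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} has a single level")
    cols = np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])
    names = [f"{values.name}[{lv}]" for lv in levels[1:]]
    return cols, names, str(levels[0])


def _term_block(data: pd.DataFrame, term: str, factors: set[str]):
    """Columns for one term: a factor's dummies, a covariate, or an
    interaction built as column-wise products of its components."""
    parts = term.split(":")
    block = np.ones((len(data), 1))
    names = [""]
    for part in parts:
        if part not in data.columns:
            raise ValueError(f"term component {part!r} not in data")
        if part in factors:
            cols, cnames, _ = _encode_factor(data[part])
        else:
            cols = data[part].to_numpy(float)[:, None]
            cnames = [part]
        block = np.repeat(block, cols.shape[1], axis=1) * np.tile(cols, (1, len(names)))
        names = [
            (f"{old}:{new}" if old else new)
            for old in names
            for new in cnames
        ]
    return block, names


def build_design_matrix(
    data: pd.DataFrame, terms: list[str], factors: list[str] | None = None
):
    """Assemble a full-rank design matrix with an intercept.

    ``terms`` are column names or ``a:b`` interactions, in testing order.
    Columns aliased with earlier ones (rank-deficient) are dropped and
    logged. Returns ``(X, term_slices, column_names)`` where ``term_slices``
    maps each term (and "intercept") to its column indices in X.
    """
    if factors is None:
        factors = [
            c for c in data.columns if not pd.api.types.is_numeric_dtype(data[c])
        ]
    factor_set = set(factors)
    X = np.ones((len(data), 1))
    names = ["intercept"]
    term_cols: dict[str, list[int]] = {"intercept": [0]}
    dropped: list[str] = []
    for term in terms:
        block, bnames = _term_block(data, term, factor_set)
        idx: list[int] = []
        for col, cname in zip(block.T, bnames):
            cand = np.column_stack([X, col])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                X = cand
                idx.append(X.shape[1] - 1)
                names.append(cname)
            else:
                dropped.append(cname)
        if not idx:
            raise ValueError(f"term {term!r} is entirely aliased with earlier terms")
        term_cols[term] = idx
    if dropped:
        logger.warning("dropped %d aliased design columns: %s", len(dropped), dropped)
    return X, term_cols, names


# ---------------------------------------------------------------------------
# IRLS fitting


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_quasipoisson(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    column_names: list[str] | None = None,
) -> FittedGLM:
    """Fit a Poisson log-linear model by IRLS; dispersion from Pearson X^2.

    Quasi-likelihood: *y* may be any non-negative reals (e.g. cell means).
    Convergence is stationarity of the deviance (relative change < *tol*);
    non-convergence and mean-floor activation are flagged, never silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    n, p = X.shape
    if n <= 0 or p == 0:
        raise ValueError("empty design")
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.5 + 0.1
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(p)
    converged = False
    floored = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        eta = X @ beta
        mu = np.exp(np.clip(eta, np.log(_MU_FLOOR), 700.0))
        if np.any(mu <= _MU_FLOOR * 1.0001):
            floored = True
        mu = np.maximum(mu, _MU_FLOOR)
        new_dev = _poisson_deviance(y, mu)
        if abs(new_dev - dev) <= tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        logger.warning("IRLS did not converge in %d iterations (deviance %.6g)", max_iter, dev)
    df_resid = n - p
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / df_resid if df_resid > 0 else float("nan")
    return FittedGLM(
        coefficients=beta,
        column_names=column_names or [f"x{j}" for j in range(p)],
        fitted_means=mu,
        deviance=dev,
        df_residual=df_resid,
        pearson_chi2=pearson,
        dispersion=dispersion,
        converged=converged,
        n_iterations=it,
        mu_floored=floored,
    )


# ---------------------------------------------------------------------------
# sequential analysis of deviance


def sequential_deviance(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    factors: list[str] | None = None,
    model_id: str = "model",
    test: str = "F",
) -> DevianceTable:
    """Type-I (sequential) analysis of deviance for a quasi-Poisson model.

    Fits the nested sequence null, +term1, +term1+term2, ... and reports each
    term's deviance drop. ``test="F"`` (default) scales drops by the fullest
    model's Pearson dispersion into F statistics; ``test="chi2"`` refers
    ``Ddev/phi`` to a chi-square with Ddf degrees of freedom instead.
    """
    if not terms:
        raise ValueError("need at least one term")
    if test not in ("F", "chi2"):
        raise ValueError(f"unknown test {test!r}")
    X_full, term_cols, col_names = build_design_matrix(data, terms, factors)
    y = data[response].to_numpy(float)
    n = len(y)
    fits: list[FittedGLM] = []
    cols: list[int] = list(term_cols["intercept"])
    fits.append(fit_quasipoisson(X_full[:, cols], y))
    for term in terms:
        cols = cols + term_cols[term]
        fits.append(
            fit_quasipoisson(
                X_full[:, cols], y, column_names=[col_names[c] for c in cols]
            )
        )
    full = fits[-1]
    phi = full.dispersion
    rows = []
    for i, term in enumerate(terms):
        prev_fit, fit = fits[i], fits[i + 1]
        delta_dev = prev_fit.deviance - fit.deviance
        if delta_dev < -1e-8:
            logger.warning("negative deviance drop %.3g for term %s", delta_dev, term)
        delta_dev = max(delta_dev, 0.0)
        delta_df = prev_fit.df_residual - fit.df_residual
        if test == "F":
            F = (delta_dev / delta_df) / phi if phi > 0 else float("inf")
            p = float(stats.f.sf(F, delta_df, full.df_residual))
        else:
            F = delta_dev / phi if phi > 0 else float("inf")
            p = float(stats.chi2.sf(F, delta_df))
        rows.append(
            {
                "term": term,
                "delta_dev": delta_dev,
                "delta_df": delta_df,
                "df_residual": fit.df_residual,
                "F": F,
                "p": p,
            }
        )
    return DevianceTable(
        model_id=model_id,
        rows=pd.DataFrame(rows),
        dispersion=phi,
        n_obs=n,
        df_residual_full=full.df_residual,
    )


# ---------------------------------------------------------------------------
# observation tables and the model suite


def make_replicate_table(
    dataset: CommunityDataset, alpha_by_species: dict[str, float]
) -> pd.DataFrame:
    """Replicate-level no-choice observations with the species' mean diet
    breadth attached (the degree-of-specialisation covariate)."""
    nc = dataset.oviposition[dataset.oviposition["assay"] == "no_choice"].copy()
    if nc.empty:
        raise ValueError("no no-choice oviposition records")
    nc["fruit"] = pd.Categorical(
        nc["fruit_id"], categories=dataset.fruit_ids
    )
    nc["alpha"] = nc["species"].map(alpha_by_species)
    if nc["alpha"].isna().any():
        missing = sorted(nc.loc[nc["alpha"].isna(), "species"].unique())
        raise ValueError(f"no alpha estimate for species {missing}")
    return nc


def make_cell_table(
    dataset: CommunityDataset,
    alpha_by_species: dict[str, float] | None = None,
    response: str = "sum",
) -> pd.DataFrame:
    """One row per (species, fruit) cell: total (or mean) no-choice eggs,
    survival proportion, guild, and optionally diet breadth.

    Cells without survival trials are dropped with a warning (0 trials is
    not 0% survival).
    """
    if response not in ("sum", "mean"):
        raise ValueError(f"unknown response {response!r}")
    nc = dataset.oviposition[dataset.oviposition["assay"] == "no_choice"]
    eggs = nc.groupby(["species", "fruit_id"], as_index=False)["eggs"].agg(response)
    cells = eggs.merge(
        aggregate_survival(dataset.survival)[["species", "fruit_id", "survival"]],
        on=["species", "fruit_id"],
        how="left",
    )
    n_missing = int(cells["survival"].isna().sum())
    if n_missing:
        logger.warning("%d cells without survival trials dropped from cell table", n_missing)
        cells = cells.dropna(subset=["survival"])
    cells = cells.merge(dataset.roster, on="species", how="left")
    if alpha_by_species is not None:
        cells["alpha"] = cells["species"].map(alpha_by_species)
    cells["species"] = pd.Categorical(cells["species"], categories=dataset.species)
    cells["guild"] = pd.Categorical(cells["guild"], categories=["specialist", "generalist"])
    return cells.reset_index(drop=True)


def zero_filter(cell_table: pd.DataFrame, mode: str) -> tuple[pd.DataFrame, dict]:
    """Drop zero cells for the sensitivity refits.

    ``mode`` is ``survival_zeros`` (drop survival = 0), ``oviposition_zeros``
    (drop eggs = 0) or ``both`` (drop the union). Returns the filtered table
    and a removal log.
    """
    if mode not in ("survival_zeros", "oviposition_zeros", "both"):
        raise ValueError(f"unknown zero-filter mode {mode!r}")
    surv_zero = cell_table["survival"] == 0
    egg_zero = cell_table["eggs"] == 0
    if mode == "survival_zeros":
        drop = surv_zero
    elif mode == "oviposition_zeros":
        drop = egg_zero
    else:
        drop = surv_zero | egg_zero
    kept = cell_table[~drop].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"zero filter {mode!r} removed every cell")
    log = {
        "mode": mode,
        "n_before": int(len(cell_table)),
        "n_removed": int(drop.sum()),
        "n_after": int(len(kept)),
    }
    return kept, log


def model_suite(
    dataset: CommunityDataset,
    alpha_by_species: dict[str, float],
    test: str = "F",
    cell_response: str = "sum",
) -> dict[str, DevianceTable]:
    """Run the full set of oviposition deviance models.

    * ``preference_fruit_alpha`` — replicate-level eggs ~ fruit + alpha +
      fruit:alpha (does preference depend on fruit and on diet breadth?);
    * ``guild_interaction`` — cell-level eggs ~ survival + guild +
      survival:guild (does the preference-performance slope differ between
      specialists and generalists?);
    * ``generalists_species`` / ``specialists_species`` — within-guild
      cell-level eggs ~ survival + species + survival:species;
    * ``specialists_zero_removed_*`` — specialist-only eggs ~ survival after
      dropping survival zeros, oviposition zeros, or both.
    """
    out: dict[str, DevianceTable] = {}
    rep = make_replicate_table(dataset, alpha_by_species)
    out["preference_fruit_alpha"] = sequential_deviance(
        rep,
        "eggs",
        ["fruit", "alpha", "fruit:alpha"],
        factors=["fruit"],
        model_id="preference_fruit_alpha",
        test=test,
    )
    cells = make_cell_table(dataset, alpha_by_species, response=cell_response)
    out["guild_interaction"] = sequential_deviance(
        cells,
        "eggs",
        ["survival", "guild", "survival:guild"],
        factors=["guild"],
        model_id="guild_interaction",
        test=test,
    )
    for guild in ("generalist", "specialist"):
        sub = cells[cells["guild"] == guild].copy()
        sub["species"] = sub["species"].cat.remove_unused_categories()
        out[f"{guild}s_species"] = sequential_deviance(
            sub,
            "eggs",
            ["survival", "species", "survival:species"],
            factors=["species"],
            model_id=f"{guild}s_species",
            test=test,
        )
    spec_cells = cells[cells["guild"] == "specialist"]
    for mode, label in (
        ("survival_zeros", "specialists_zero_removed_survival"),
        ("oviposition_zeros", "specialists_zero_removed_oviposition"),
        ("both", "specialists_zero_removed_both"),
    ):
        filtered, log = zero_filter(spec_cells, mode)
        logger.info("zero filter: %s", log)
        out[label] = sequential_deviance(
            filtered, "eggs", ["survival"], factors=[], model_id=label, test=test
        )
    return out
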