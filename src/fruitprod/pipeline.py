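"""Glue from tables to fitted analyses.

The three analyses differ in response reduction and data subset:

* ``binom`` — binary reproductive status (any fruit in any period), all
  trees;
* ``amulti`` — maximum fruiting category across periods, all trees, K = 4;
* ``rmulti`` — maximum category among reproductive trees only, relabeled
  1..3 (original 2..4), K = 3.

Species with fewer than ``min_reproductive`` (default 2) reproductive
individuals are excluded from every analysis and logged — one such species
cannot inform species-level effects and destabilizes the hierarchy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fruitprod.covariates import build_design
from fruitprod.data_io import align_response, reduce_max_category, reduce_status
from fruitprod.evaluation import FitResult, fit_result
from fruitprod.inference import McmcConfig, TEST_SCALE, run_mcmc
from fruitprod.model_core import BinomialModel, OrdinalModel, _BaseModel

logger = logging.getLogger(__name__)

ANALYSES = ("binom", "amulti", "rmulti")

__all__ = ["ANALYSES", "build_model", "fit_analysis", "fit_covariate_sets"]


def _exclude_rare_reproducers(trees, fruit, min_reproductive):
    status = reduce_status(fruit)
    merged = trees.merge(
        status.rename("status"), left_on="tree_id", right_index=True,
        how="left",
    )
    n_rep = merged.groupby("species")["status"].sum(min_count=1).fillna(0)
    drop = n_rep[n_rep < min_reproductive].index.tolist()
    if drop:
        logger.info(
            "excluding species with < %d reproductive individuals: %s",
            min_reproductive, drop,
        )
    kept = trees[~trees["species"].isin(drop)].reset_index(drop=True)
    return kept, drop


def build_model(
    trees: pd.DataFrame,
    soil: pd.DataFrame | None,
    fruit: pd.DataFrame,
    analysis: str,
    covariate_set: str,
    kernel: str = "as_printed",
    min_reproductive: int = 2,
    obs_level: bool = False,
    crowding_shapes=None,
    **design_kwargs,
) -> _BaseModel:
    """Assemble the model object for one analysis and covariate set.

    ``obs_level=True`` (ordinal analyses only) fits every per-period
    observation, with periods sharing each tree's random effect, instead of
    the max-category reduction — exact for synthetic data whose periods are
    exchangeable draws.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}")
    trees, _ = _exclude_rare_reproducers(trees, fruit, min_reproductive)
    fruit = fruit[fruit["tree_id"].isin(set(trees["tree_id"]))]

    if analysis == "binom":
        status = reduce_status(fruit)
        kept, y = align_response(trees, status)
        design = build_design(kept, soil, covariate_set, kernel=kernel,
                              **design_kwargs)
        return BinomialModel(design, y, crowding_shapes=crowding_shapes)

    if analysis == "amulti":
        if obs_level:
            kept = trees[trees["tree_id"].isin(set(fruit["tree_id"]))]
            kept = kept.reset_index(drop=True)
            design = build_design(kept, soil, covariate_set, kernel=kernel,
                                  **design_kwargs)
            pos = {t: i for i, t in enumerate(design.tree_id)}
            obs = fruit.reset_index(drop=True)
            oti = obs["tree_id"].map(pos).to_numpy(np.int64)
            return OrdinalModel(design, obs["category"].to_numpy(), K=4,
                                obs_tree_index=oti,
                                crowding_shapes=crowding_shapes)
        fmax = reduce_max_category(fruit)
        kept, y = align_response(trees, fmax)
        design = build_design(kept, soil, covariate_set, kernel=kernel,
                              **design_kwargs)
        return OrdinalModel(design, y, K=4, crowding_shapes=crowding_shapes)

    # rmulti: reproductive individuals only, zero-fruit category dropped
    fmax = reduce_max_category(fruit)
    fmax = fmax[fmax > 1]
    rep_trees = trees[trees["tree_id"].isin(fmax.index)]
    rep_trees, _ = _exclude_rare_reproducers(
        rep_trees, fruit[fruit["tree_id"].isin(fmax.index)], min_reproductive
    )
    kept, y = align_response(rep_trees.reset_index(drop=True), fmax)
    design = build_design(kept, soil, covariate_set, kernel=kernel,
                          **design_kwargs)
    return OrdinalModel(design, y - 1, K=3, crowding_shapes=crowding_shapes)


def fit_analysis(
    trees, soil, fruit,
    analysis: str,
    covariate_set: str,
    config: McmcConfig = TEST_SCALE,
    label: str | None = None,
    with_scores: bool = True,
    **model_kwargs,
) -> tuple[FitResult, _BaseModel]:
    """Build, fit, and score one analysis x covariate set."""
    model = build_model(trees, soil, fruit, analysis, covariate_set,
                        **model_kwargs)
    samples = run_mcmc(model, config)
    res = fit_result(label or f"{analysis}:{covariate_set}", samples, model,
                     with_scores=with_scores)
    return res, model


def fit_covariate_sets(
    trees, soil, fruit,
    analysis: str,
    covariate_sets: list[str],
    config: McmcConfig = TEST_SCALE,
    **model_kwargs,
) -> list[FitResult]:
    """Fit several candidate covariate sets for one analysis.

    Each set gets a distinct chain seed derived from the base config seed
    so fits are independent yet reproducible.
    """
    fits = []
    for i, cs in enumerate(covariate_sets):
        cfg = config.with_seed(config.seed + 1000 * (i + 1))
        res, _ = fit_analysis(trees, soil, fruit, analysis, cs, cfg,
                              **model_kwargs)
        fits.append(res)
    return fits
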