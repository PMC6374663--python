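"""Posterior-derived quantities: reproductive thresholds, threshold-vs-
maximum-size scaling, seed-mass regressions, and prediction curves.

The reproductive threshold D_thres of a species is the DBH at which the
modeled probability of being reproductive is 0.5, i.e. where the linear
predictor crosses zero with all other covariates held at their reference
values (standardized zero = sample means; individual effects at zero, the
population-median curve). Because DBH enters linearly on the standardized
scale the per-draw solution is closed-form; draws with a non-positive DBH
coefficient leave the threshold undefined and are excluded with the
excluded fraction reported.

The interspecific scaling hypothesis D_thres = 1/2 D_max is evaluated on
the log scale: an OLS fit of ln(D_thres) on ln(D_max) plus the coefficient
of determination of the constrained line ln(D_thres) = ln(D_max) - ln 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from fruitprod.inference import PosteriorSamples
from fruitprod.model_core import _BaseModel, cumulative_category_probs

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdEstimate",
    "SpeciesPosteriorCurve",
    "threshold_size",
    "threshold_from_coefs",
    "threshold_vs_dmax",
    "seed_mass_regressions",
    "average_category_probabilities",
    "prediction_curves",
    "plot_curve",
]


@dataclass
class ThresholdEstimate:
    """Posterior summary of one species' reproductive threshold size."""

    species: str
    mean: float
    sd: float
    q2_5: float
    q97_5: float
    dmax: float
    frac_excluded: float
    draws: np.ndarray | None = None


def _reference_crowding(samples, model, species_j, draw_idx):
    """Per-draw species-mean scaled crowding index (the 'sample mean'
    reference for the unstandardizable crowding covariate)."""
    d = model.design
    alpha = samples.flat("alpha")[draw_idx]
    nu = samples.flat("nu")[draw_idx]
    out = np.empty(len(draw_idx))
    for s, i in enumerate(draw_idx):
        out[s] = d.nci_values(species_j, float(alpha[i, species_j]),
                              float(nu[i, species_j])).mean()
    return out


def threshold_from_coefs(
    intercept: float,
    beta_dbh: float,
    dbh_mean: float,
    dbh_sd: float,
    offset: float = 0.0,
    method: str = "closed_form",
) -> float:
    """DBH (cm) where eta = intercept + beta_dbh*z + offset crosses zero.

    ``method="bisection"`` solves the same crossing numerically (used as an
    internal cross-check of the closed form).
    """
    if beta_dbh <= 0:
        raise ValueError("threshold undefined for beta_dbh <= 0")
    if method == "closed_form":
        z = -(intercept + offset) / beta_dbh
        return dbh_mean + dbh_sd * z
    if method == "bisection":
        def f(dbh):
            return intercept + offset + beta_dbh * (dbh - dbh_mean) / dbh_sd

        lo, hi = dbh_mean - 1e3 * dbh_sd, dbh_mean + 1e3 * dbh_sd
        from scipy.optimize import brentq

        return float(brentq(f, lo, hi, xtol=1e-12))
    raise ValueError(f"unknown method {method!r}")


def threshold_size(
    samples: PosteriorSamples,
    model: _BaseModel,
    species: str,
    max_draws: int = 2_000,
    keep_draws: bool = False,
) -> ThresholdEstimate:
    """Posterior threshold size for one species from a binomial fit.

    Solves eta = 0 for DBH draw by draw (closed form on the standardized
    scale, back-transformed through the stored moments). Other covariates
    sit at standardized zero; with a crowding term in the model the
    crowding covariate sits at its per-draw species-mean index value.
    """
    d = model.design
    if "dbh" not in d.columns:
        raise ValueError("threshold requires a model that includes DBH")
    if species not in d.species_names:
        raise ValueError(f"species {species!r} not in fit")
    j = d.species_names.index(species)
    c_dbh = d.columns.index("dbh")
    m, s = d.moments["dbh"]

    beta = samples.flat("beta")
    n_total = beta.shape[0]
    idx = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    b0 = beta[idx, j, 0]
    b_dbh = beta[idx, j, c_dbh]
    offset = np.zeros(len(idx))
    if model.has_crowding:
        crowd_ref = _reference_crowding(samples, model, j, idx)
        offset = beta[idx, j, -1] * crowd_ref

    valid = b_dbh > 0
    frac_excluded = float(1.0 - valid.mean())
    if frac_excluded > 0:
        logger.info(
            "%s: excluding %.1f%% of draws with beta_dbh <= 0",
            species, 100 * frac_excluded,
        )
    if valid.sum() < 2:
        raise ValueError(
            f"{species}: almost no draws with a positive DBH effect; "
            "threshold not estimable"
        )
    thr = m + s * (-(b0[valid] + offset[valid]) / b_dbh[valid])
    dmax = float(d.dbh_cm[d.species_rows(j)].max())
    return ThresholdEstimate(
        species=species,
        mean=float(thr.mean()),
        sd=float(thr.std(ddof=1)),
        q2_5=float(np.quantile(thr, 0.025)),
        q97_5=float(np.quantile(thr, 0.975)),
        dmax=dmax,
        frac_excluded=frac_excluded,
        draws=thr if keep_draws else None,
    )


def thresholds_table(estimates: list[ThresholdEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": e.species, "mean": e.mean, "sd": e.sd,
                "q2.5": e.q2_5, "q97.5": e.q97_5, "dmax": e.dmax,
                "frac_excluded": e.frac_excluded,
            }
            for e in estimates
        ]
    )


@dataclass
class LogScalingResult:
    """ln(D_thres) ~ ln(D_max): OLS fit plus the constrained half-size line."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    constrained_r2: float
    n: int


def threshold_vs_dmax(thresholds, dmax=None) -> LogScalingResult:
    """Regress ln threshold on ln maximum size across species.

    Accepts a thresholds table (columns species/mean/dmax) or two aligned
    arrays. Reports the OLS slope/intercept/R^2 and the R^2 (1 - SSR/SST)
    of the constrained line ln(D_thres) = ln(D_max) - ln 2, i.e. the
    half-maximum-size rule.
    """
    if dmax is None:
        df = thresholds
        thr = df["mean"].to_numpy(float)
        dmx = df["dmax"].to_numpy(float)
    else:
        thr = np.asarray(thresholds, dtype=float)
        dmx = np.asarray(dmax, dtype=float)
    ok = thr > 0
    if (~ok).any():
        logger.info("excluding %d non-positive thresholds", int((~ok).sum()))
    thr, dmx = thr[ok], dmx[ok]
    if len(thr) < 3:
        raise ValueError("need >= 3 species with positive thresholds")
    if np.allclose(dmx, dmx[0]):
        raise ValueError("all species share one D_max; regression undefined")
    lt, lm = np.log(thr), np.log(dmx)
    res = sps.linregress(lm, lt)
    sst = float(np.sum((lt - lt.mean()) ** 2))
    ssr_half = float(np.sum((lt - (lm - np.log(2.0))) ** 2))
    return LogScalingResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        constrained_r2=1.0 - ssr_half / sst if sst > 0 else float("nan"),
        n=len(lt),
    )


def seed_mass_regressions(
    responses: pd.DataFrame,
    seed_mass: pd.Series | dict,
    exclusions: list[str] | None = None,
) -> pd.DataFrame:
    """Simple regressions of posterior-derived responses on dry seed mass.

    ``responses`` is indexed by species with one column per response (e.g.
    threshold size, each category's average probability); ``seed_mass`` maps
    species to dry seed mass (mg). Each response is regressed on seed mass
    with and without the configured exclusion list. Species lacking a seed
    mass are dropped.
    """
    sm = pd.Series(seed_mass, dtype=float).dropna()
    exclusions = list(exclusions or [])
    rows = []
    for excl_label, excluded in (("all", []), ("excluding", exclusions)):
        if excl_label == "excluding" and not exclusions:
            continue
        keep = [s for s in responses.index if s in sm.index
                and s not in excluded]
        if len(keep) < 3:
            raise ValueError(
                f"fewer than 3 species with seed mass after exclusion "
                f"({len(keep)})"
            )
        x = sm.loc[keep].to_numpy()
        for col in responses.columns:
            yv = responses.loc[keep, col].to_numpy(float)
            res = sps.linregress(x, yv)
            rows.append({
                "response": col,
                "subset": excl_label,
                "n": len(keep),
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "p": float(res.pvalue),
            })
    return pd.DataFrame(rows)


def _species_draw_data(samples, model, species, max_draws):
    d = model.design
    if species not in d.species_names:
        raise ValueError(f"species {species!r} not in fit")
    j = d.species_names.index(species)
    beta = samples.flat("beta")
    n_total = beta.shape[0]
    idx = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    gamma = (samples.flat("gamma")[idx]
             if "gamma" in samples.arrays else None)
    return j, idx, beta, gamma


def average_category_probabilities(
    samples: PosteriorSamples,
    model: _BaseModel,
    species: str,
    n_grid: int = 50,
    max_draws: int = 400,
) -> pd.DataFrame:
    """Mean probability of each category over the species' DBH range.

    Per posterior draw, category probabilities are averaged over a uniform
    DBH grid spanning the species' observed range (other covariates at
    reference); the table summarizes those per-draw averages. The K mean
    probabilities sum to 1.
    """
    if not model.is_ordinal:
        raise ValueError("category probabilities need an ordinal fit")
    d = model.design
    j, idx, beta, gamma = _species_draw_data(samples, model, species,
                                             max_draws)
    rows_j = d.species_rows(j)
    dbh = d.dbh_cm[rows_j]
    m, s = d.moments["dbh"]
    grid_z = (np.linspace(dbh.min(), dbh.max(), n_grid) - m) / s
    c_dbh = d.columns.index("dbh")
    K = model.K
    offset = np.zeros(len(idx))
    if model.has_crowding:
        crowd_ref = _reference_crowding(samples, model, j, idx)
        offset = beta[idx, j, -1] * crowd_ref
    avgs = np.empty((len(idx), K))
    for sdx, i in enumerate(idx):
        eta = beta[i, j, 0] + beta[i, j, c_dbh] * grid_z + offset[sdx]
        pi = cumulative_category_probs(eta, gamma[sdx], K)
        avgs[sdx] = pi.mean(axis=0)
    out = pd.DataFrame({
        "category": np.arange(1, K + 1),
        "mean": avgs.mean(axis=0),
        "sd": avgs.std(axis=0, ddof=1),
        "q2.5": np.quantile(avgs, 0.025, axis=0),
        "q97.5": np.quantile(avgs, 0.975, axis=0),
    })
    out.attrs["species"] = species
    return out


@dataclass
class SpeciesPosteriorCurve:
    """Posterior mean and interval band of predicted probabilities.

    For ordinal fits ``mean``/``lo``/``hi`` have shape (grid, K); for
    binomial fits they are the reproduction probability, shape (grid,).
    ``axis`` is "dbh" (grid in cm) or "crowding" (grid in raw index units).
    """

    species: str
    axis: str
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.mean.ndim == 1:
            for g, mn, lo, hi in zip(self.grid, self.mean, self.lo, self.hi):
                rows.append({"species": self.species, "axis": self.axis,
                             "x": g, "category": "reproductive",
                             "mean": mn, "lo": lo, "hi": hi})
        else:
            for gi, g in enumerate(self.grid):
                for k in range(self.mean.shape[1]):
                    rows.append({
                        "species": self.species, "axis": self.axis, "x": g,
                        "category": k + 1, "mean": self.mean[gi, k],
                        "lo": self.lo[gi, k], "hi": self.hi[gi, k],
                    })
        return pd.DataFrame(rows)


def prediction_curves(
    samples: PosteriorSamples,
    model: _BaseModel,
    species: str,
    axis: str = "dbh",
    grid: np.ndarray | None = None,
    n_grid: int = 60,
    max_draws: int = 400,
    band: float = 0.95,
) -> SpeciesPosteriorCurve:
    """Category-probability (or reproduction-probability) curves.

    Along ``axis="dbh"`` the grid spans the species' observed DBH (cm) with
    other covariates at reference. Along ``axis="crowding"`` the raw index
    value is swept directly (each draw divides by the fit's index scale),
    DBH at its mean. Bands are central posterior intervals per grid point.
    """
    d = model.design
    j, idx, beta, gamma = _species_draw_data(samples, model, species,
                                             max_draws)
    rows_j = d.species_rows(j)
    m, s = d.moments.get("dbh", (0.0, 1.0))
    if axis == "dbh":
        if "dbh" not in d.columns:
            raise ValueError("model has no DBH covariate")
        if grid is None:
            dbh = d.dbh_cm[rows_j]
            grid = np.linspace(dbh.min(), dbh.max(), n_grid)
        x_term = (np.asarray(grid) - m) / s
        c_x = d.columns.index("dbh")
    elif axis == "crowding":
        if not model.has_crowding:
            raise ValueError("model has no crowding covariate")
        if grid is None:
            nci_obs = d.nci_values(
                j,
                float(samples.flat("alpha")[:, j].mean()),
                float(samples.flat("nu")[:, j].mean()),
            ) * d.nci_scale
            hi = float(nci_obs.max()) if len(nci_obs) else 1.0
            grid = np.linspace(0.0, max(hi, 1e-6), n_grid)
        x_term = np.asarray(grid) / d.nci_scale
        c_x = None
    else:
        raise ValueError("axis must be 'dbh' or 'crowding'")

    offset = np.zeros(len(idx))
    if model.has_crowding and axis == "dbh":
        crowd_ref = _reference_crowding(samples, model, j, idx)
        offset = beta[idx, j, -1] * crowd_ref
    K = model.K if model.is_ordinal else 2
    curves = []
    for sdx, i in enumerate(idx):
        if axis == "dbh":
            eta = beta[i, j, 0] + beta[i, j, c_x] * x_term + offset[sdx]
        else:
            eta = beta[i, j, 0] + beta[i, j, -1] * x_term
        if model.is_ordinal:
            curves.append(cumulative_category_probs(eta, gamma[sdx], K))
        else:
            from scipy.special import expit

            curves.append(expit(eta))
    arr = np.stack(curves)  # (draws, grid[, K])
    q = (1 - band) / 2
    return SpeciesPosteriorCurve(
        species=species,
        axis=axis,
        grid=np.asarray(grid, dtype=float),
        mean=arr.mean(axis=0),
        lo=np.quantile(arr, q, axis=0),
        hi=np.quantile(arr, 1 - q, axis=0),
    )


def plot_curve(curve: SpeciesPosteriorCurve, ax=None, path=None):
    """Plot a prediction curve (stacked categories or binomial band).

    Requires matplotlib (the optional ``plot`` extra). Ordinal curves are
    drawn as stacked shaded category bands over the axis grid; binomial
    curves as the mean reproduction probability with its interval band.
    Returns the axes; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = curve.grid
    if curve.mean.ndim == 2:
        stacked = np.cumsum(curve.mean, axis=1)
        lower = np.zeros(len(x))
        K = curve.mean.shape[1]
        for k in range(K):
            shade = str(0.85 - 0.7 * k / max(K - 1, 1))
            ax.fill_between(x, lower, stacked[:, k], color=shade,
                            label=f"category {k + 1}")
            lower = stacked[:, k]
        ax.set_ylabel("category probability")
        ax.legend(fontsize=7, loc="center right")
    else:
        ax.fill_between(x, curve.lo, curve.hi, color="0.85")
        ax.plot(x, curve.mean, color="0.1")
        ax.set_ylabel("P(reproductive)")
    ax.set_xlabel("DBH (cm)" if curve.axis == "dbh"
                  else "crowding index")
    ax.set_title(curve.species, fontsize=9)
    ax.set_ylim(0, 1)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
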