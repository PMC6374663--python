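"""Model comparison across candidate covariate sets and effect classification.

DIC is computed in its conditional form (individual random effects in
focus, the default a WinBUGS fit would report): Dbar is the mean of the
recorded deviance trace, D(theta-bar) the deviance at the posterior mean of
every sampled quantity (coefficients, random effects, crowding shapes, cut
points), pD = Dbar - D(theta-bar), and DIC = Dbar + pD.

Proper scoring rules supplement DIC: the Brier and logarithmic scores for
the binomial analysis and the ranked probability score (RPS) for the
ordinal analyses, each evaluated at the posterior-mean predictive
distribution against the observed outcome. Lower is better for all three.

Effects are classified from posterior summaries: *strong* when the 95%
credible interval (mean +/- 2 SD) excludes zero, *moderate* when the 87%
interval (mean +/- 1.5 SD) does, otherwise *weak*; the sign comes from the
posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fruitprod.inference import PosteriorSamples
from fruitprod.model_core import _BaseModel, cumulative_category_probs

__all__ = [
    "FitResult",
    "EffectClass",
    "compute_dic",
    "compute_scores",
    "classify_effect",
    "classify_all_effects",
    "compare_models",
    "fit_result",
]


@dataclass
class FitResult:
    """One fitted covariate set: posterior, DIC decomposition, scores."""

    label: str
    covariate_set: str
    samples: PosteriorSamples
    dbar: float
    p_d: float
    dic: float
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def analysis(self) -> str:
        """Binom / AMulti / RMulti, from model type and category count."""
        meta = self.samples.meta
        if meta["model_type"] == "binomial":
            return "Binom"
        return "AMulti" if meta["K"] == 4 else "RMulti"

    @property
    def fingerprint(self) -> str:
        return self.samples.meta["fingerprint"]

    @property
    def complexity(self) -> int:
        """Coefficients per species plus crowding shapes; tie-break key."""
        meta = self.samples.meta
        n = len(meta["coef_names"])
        if self.samples.arrays.get("alpha") is not None:
            n += 2
        return n


def compute_dic(samples: PosteriorSamples,
                model: _BaseModel) -> tuple[float, float, float]:
    """(Dbar, pD, DIC) from the deviance trace and theta-bar deviance."""
    dev = samples.deviance
    if not np.isfinite(dev).all():
        n_bad = int((~np.isfinite(dev)).sum())
        raise ValueError(
            f"{n_bad} non-finite deviance draws; check convergence and "
            "parameter support before computing DIC"
        )
    dbar = float(dev.mean())
    d_at_mean = model.deviance(samples.posterior_mean_params())
    p_d = dbar - d_at_mean
    return dbar, p_d, dbar + p_d


def _posterior_mean_predictive(
    samples: PosteriorSamples, model: _BaseModel, max_draws: int = 400
) -> np.ndarray:
    """Mean predictive distribution per observation.

    Averages the predictive over an evenly thinned subset of retained draws
    (at most ``max_draws``), with each draw's systematic effects combined
    with the posterior-mean individual effects. Returns per-observation
    success probabilities (binomial) or category probabilities (ordinal).
    """
    beta = samples.flat("beta")
    n_total = beta.shape[0]
    idx = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    alpha = samples.flat("alpha")[idx] if "alpha" in samples.arrays else None
    nu = samples.flat("nu")[idx] if "nu" in samples.arrays else None
    gamma = samples.flat("gamma")[idx] if "gamma" in samples.arrays else None
    oti = model.obs_tree_index
    eps = samples.eps_mean
    base = samples.posterior_mean_params()
    acc = None
    for s, i in enumerate(idx):
        params = base.copy()
        params.beta = beta[i]
        if alpha is not None:
            params.alpha = alpha[s]
            params.nu = nu[s]
        eta = model.systematic_eta(params) + eps
        if model.is_ordinal:
            g = gamma[s]
            pi = cumulative_category_probs(eta[oti], g, model.K)
        else:
            from scipy.special import expit

            pi = expit(eta[oti])
        acc = pi if acc is None else acc + pi
    return acc / len(idx)


def compute_scores(samples: PosteriorSamples, model: _BaseModel,
                   max_draws: int = 400) -> dict[str, float]:
    """Proper scores of the posterior-mean predictive vs the observations.

    Binomial: Brier score mean((p - y)^2) and log score -mean(log p_y).
    Ordinal: ranked probability score, the mean over observations of
    sum_k (P(Y<=k) - 1{y<=k})^2 / (K-1). All are negatively oriented.
    """
    pred = _posterior_mean_predictive(samples, model, max_draws)
    y = model.y
    if model.is_ordinal:
        K = model.K
        cum = np.cumsum(pred, axis=1)[:, : K - 1]
        obs_cum = (y[:, None] <= np.arange(1, K)[None, :]).astype(float)
        rps = float(np.mean(np.sum((cum - obs_cum) ** 2, axis=1) / (K - 1)))
        p_obs = np.clip(pred[np.arange(len(y)), y - 1], 1e-300, None)
        return {"rps": rps, "log": float(-np.mean(np.log(p_obs)))}
    p = pred
    brier = float(np.mean((p - y) ** 2))
    p_obs = np.clip(np.where(y == 1, p, 1 - p), 1e-300, None)
    return {"brier": brier, "log": float(-np.mean(np.log(p_obs)))}


def fit_result(label: str, samples: PosteriorSamples, model: _BaseModel,
               with_scores: bool = True) -> FitResult:
    """Bundle a fitted model into a FitResult (DIC plus optional scores)."""
    dbar, p_d, dic = compute_dic(samples, model)
    scores = compute_scores(samples, model) if with_scores else {}
    return FitResult(
        label=label,
        covariate_set=samples.meta["covariate_set"],
        samples=samples,
        dbar=dbar,
        p_d=p_d,
        dic=dic,
        scores=scores,
    )


@dataclass(frozen=True)
class EffectClass:
    """Direction and strength of one species-level covariate effect."""

    species: str
    covariate: str
    sign: int
    strength: str  # strong | moderate | weak


def classify_effect(mean: float, sd: float, species: str = "",
                    covariate: str = "") -> EffectClass:
    """Strong if 0 outside mean +/- 2 SD; moderate if outside +/- 1.5 SD.

    A degenerate summary (SD 0 and mean 0) classifies as weak.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sign = int(np.sign(mean))
    if sd == 0 and mean == 0:
        return EffectClass(species, covariate, 0, "weak")
    if sd == 0 or abs(mean) > 2 * sd:
        strength = "strong"
    elif abs(mean) > 1.5 * sd:
        strength = "moderate"
    else:
        strength = "weak"
    return EffectClass(species, covariate, sign, strength)


def classify_all_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Classify every non-intercept species coefficient of a fit."""
    beta = samples.flat("beta")  # (draws, J, p)
    species = samples.meta["species"]
    coef = samples.meta["coef_names"]
    rows = []
    for j, sp in enumerate(species):
        for c, name in enumerate(coef):
            if name == "intercept":
                continue
            draws = beta[:, j, c]
            eff = classify_effect(float(draws.mean()),
                                  float(draws.std(ddof=1)), sp, name)
            rows.append({
                "species": sp, "covariate": name,
                "mean": float(draws.mean()), "sd": float(draws.std(ddof=1)),
                "sign": eff.sign, "strength": eff.strength,
            })
    return pd.DataFrame(rows)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """DIC (and scores) per covariate set per analysis, minima flagged.

    All fits within one analysis column must share a data fingerprint
    (same trees, same response reduction); comparison across different
    subsets is refused. Ties within 1e-9 DIC go to the less complex set
    and are flagged.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    for analysis in ("Binom", "AMulti", "RMulti"):
        group = [f for f in fits if f.analysis == analysis]
        if not group:
            continue
        prints = {f.fingerprint for f in group}
        if len(prints) > 1:
            raise ValueError(
                f"{analysis}: fits use different data subsets "
                f"(fingerprints {sorted(prints)}); refusing to compare"
            )
        best = min(group, key=lambda f: (f.dic, f.complexity))
        tied = [f for f in group
                if abs(f.dic - best.dic) <= 1e-9 and f is not best]
        for f in group:
            row = {
                "analysis": analysis,
                "covariate_set": f.covariate_set,
                "dic": f.dic,
                "dbar": f.dbar,
                "p_d": f.p_d,
                "best": f is best,
                "tie": f in tied or (f is best and bool(tied)),
            }
            row.update({f"score_{k}": v for k, v in f.scores.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def comparison_report(table: pd.DataFrame) -> str:
    """Text report mirroring the covariate-set x analysis layout."""
    pivot = table.pivot_table(index="covariate_set", columns="analysis",
                              values="dic")
    best = table[table["best"]]
    lines = ["DIC by covariate set (lowest per analysis marked *)", ""]
    header = "covariate_set".ljust(16) + "".join(
        c.rjust(12) for c in pivot.columns
    )
    lines.append(header)
    for cs in pivot.index:
        cells = []
        for an in pivot.columns:
            v = pivot.loc[cs, an]
            mark = "*" if ((best["analysis"] == an)
                           & (best["covariate_set"] == cs)).any() else " "
            cells.append((f"{v:10.1f}{mark}") if np.isfinite(v) else "  -")
        lines.append(cs.ljust(16) + "".join(c.rjust(12) for c in cells))
    return "\n".join(lines)
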