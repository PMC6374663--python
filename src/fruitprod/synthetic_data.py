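"""Synthetic forest plots, soil surfaces, and fruit observations.

Generates data from the same generative model the inference modules fit, with
known ("true") parameters, so every downstream stage can be validated by
parameter recovery. Defaults emulate the study conditions: five 41 m x 240 m
mapped plots, 17 species with at least 50 stems each and small-DBH-skewed
(truncated lognormal) size distributions, a soil design of 200 composite
samples on a 1-m transect down the plot center plus a 10-m lattice over the
rest of the plot, spatially autocorrelated nutrient fields, and three
observation periods with ordinal fruit categories drawn from the
cumulative-logit model.

Stems are placed uniformly within plots by default; a Thomas cluster process
is available per species. Soil nutrient surfaces are a smooth low-order
trend (sum of two rotated sinusoids per nutrient) plus independent Gaussian
noise, sampled at the design points — enough spatial structure to exercise
interpolation without modeling real pedogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fruitprod.covariates import (
    DEFAULT_NCI_SCALE,
    build_design,
)
from fruitprod.data_io import CategoryScheme
from fruitprod.model_core import ModelParams, cumulative_category_probs

__all__ = [
    "PlotGeometry",
    "SpeciesConfig",
    "SoilConfig",
    "TrueParams",
    "SyntheticDataset",
    "default_species_table",
    "generate_forest",
    "load_config",
    "make_truth",
    "simulate_fruit",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot footprint in meters; default 41 x 240."""

    plot_id: str = "P1"
    width: float = 41.0
    length: float = 240.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("plot width and length must be positive")


@dataclass(frozen=True)
class SpeciesConfig:
    """Abundance and size distribution of one species.

    ``n_total`` stems are spread across all plots. DBH is lognormal
    (``dbh_meanlog``, ``dbh_sdlog``), truncated below at the 5-cm census
    minimum, skewing stands toward small stems. ``cluster`` optionally
    switches placement to a Thomas process: (parents per plot, cluster SD m).
    """

    name: str
    n_total: int
    dbh_meanlog: float = 2.8
    dbh_sdlog: float = 0.6
    cluster: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"species {self.name}: abundance must be >= 1")


@dataclass(frozen=True)
class SoilConfig:
    """Smoothness and level of the synthetic nutrient surfaces.

    ``means`` per raw sample column; incubated N pools default above the
    initial pools so potential N mineralization is positive on average.
    ``trend_amplitude`` scales the smooth spatial trend and ``noise_cv`` the
    white noise, both as fractions of the mean; ``length_scale`` (m) sets
    trend wavelength. Values are clipped at zero (concentrations).
    """

    means: dict[str, float] = field(default_factory=lambda: {
        "no3_i": 4.0, "nh4_i": 6.0, "no3_f": 9.0, "nh4_f": 10.0,
        "p": 5.0, "k": 60.0, "ca": 300.0, "mg": 80.0,
    })
    trend_amplitude: float = 0.35
    noise_cv: float = 0.10
    length_scale: float = 60.0
    transect_spacing: float = 1.0
    lattice_spacing: float = 10.0

    def __post_init__(self) -> None:
        if self.trend_amplitude < 0 or self.noise_cv < 0:
            raise ValueError("soil variances must be >= 0")


@dataclass
class TrueParams:
    """Generative-side parameters of the fruit-production model.

    ``beta`` is (n_species, n_coef) on the standardized-covariate scale used
    by the design matrices (last column = crowding slope when present);
    ``tau`` is the precision of the individual random effects; ``alpha``
    and ``nu`` are the per-species crowding shape parameters; ``gamma`` the
    full cut-point vector (first element 0).
    """

    species: list[str]
    covariate_set: str
    beta: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    tau: float
    alpha: np.ndarray | None = None
    nu: np.ndarray | None = None
    gamma: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.5, 3.0])
    )
    scheme: CategoryScheme = field(default_factory=CategoryScheme)
    kernel: str = "as_printed"
    nci_scale: float = DEFAULT_NCI_SCALE

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gamma[0] != 0 or np.any(np.diff(self.gamma) <= 0):
            raise ValueError("gamma must be increasing with gamma_1 = 0")
        for name in ("alpha", "nu"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if (v <= 0).any():
                    raise ValueError(f"{name} must be positive")
                setattr(self, name, v)

    def as_model_params(self, n_trees: int,
                        eps: np.ndarray | None = None) -> ModelParams:
        return ModelParams(
            beta=self.beta.copy(),
            mu=self.mu.copy(),
            Sigma=self.Sigma.copy(),
            eps=np.zeros(n_trees) if eps is None else eps,
            tau=self.tau,
            alpha=None if self.alpha is None else self.alpha.copy(),
            nu=None if self.nu is None else self.nu.copy(),
            gamma=self.gamma.copy(),
        )


@dataclass
class SyntheticDataset:
    """Generated tables plus the truth that produced them."""

    trees: pd.DataFrame
    soil: pd.DataFrame
    observations: pd.DataFrame
    truth: TrueParams
    seed: int
    counts: pd.DataFrame | None = None
    eps: np.ndarray | None = None

    def __post_init__(self) -> None:
        known = set(self.trees["tree_id"])
        if not set(self.observations["tree_id"]).issubset(known):
            raise ValueError("observation tree_id missing from stem map")


#: Study-like abundances: 17 species, >= 50 stems each, echoing the real
#: census's spread of common canopy and subcanopy species.
DEFAULT_ABUNDANCES = (
    74, 206, 65, 114, 60, 57, 85, 55, 374, 50, 367, 112, 99, 198, 51, 86, 173,
)


def default_species_table(n_species: int = 17) -> list[SpeciesConfig]:
    """Species table matching the study conditions.

    Canopy species (larger ``dbh_meanlog``) alternate with subcanopy ones so
    stands mix size structures; all distributions are skewed toward small
    stems by the lognormal shape and the 5-cm truncation.
    """
    if not 1 <= n_species <= len(DEFAULT_ABUNDANCES):
        raise ValueError(f"n_species must be in 1..{len(DEFAULT_ABUNDANCES)}")
    table = []
    for i in range(n_species):
        meanlog = 2.4 + 0.08 * (i % 7)          # ~11-19 cm median
        sdlog = 0.45 + 0.05 * (i % 4)
        table.append(SpeciesConfig(
            name=f"SP{i + 1:02d}",
            n_total=DEFAULT_ABUNDANCES[i],
            dbh_meanlog=meanlog,
            dbh_sdlog=sdlog,
        ))
    return table


def _truncated_lognormal(rng, meanlog, sdlog, n, lower=5.0):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(meanlog, sdlog, size=2 * (n - filled) + 8)
        draw = draw[draw >= lower]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _soil_design_points(geom: PlotGeometry, cfg: SoilConfig) -> np.ndarray:
    """Sample locations: 1-m center transect composites + 10-m lattice.

    The transect runs down the plot center line (x = width/2) with one
    composite per meter over a 200-m run (or the plot length if shorter),
    sampled at cell midpoints. The lattice covers the whole plot at
    ``lattice_spacing`` starting at the origin.
    """
    x_mid = geom.width / 2.0
    run = min(200.0, geom.length)
    n_t = int(run // cfg.transect_spacing)
    ty = (np.arange(n_t) + 0.5) * cfg.transect_spacing
    transect = np.column_stack([np.full(n_t, x_mid), ty])
    gx = np.arange(0.0, geom.width + 1e-9, cfg.lattice_spacing)
    gy = np.arange(0.0, geom.length + 1e-9, cfg.lattice_spacing)
    lattice = np.column_stack(
        [np.repeat(gx, len(gy)), np.tile(gy, len(gx))]
    )
    return np.vstack([transect, lattice])


def _nutrient_field(rng, xy, mean, cfg: SoilConfig):
    """Smooth rotated-sinusoid trend + white noise, clipped at zero."""
    theta1, theta2 = rng.uniform(0, np.pi, size=2)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    u1 = xy[:, 0] * np.cos(theta1) + xy[:, 1] * np.sin(theta1)
    u2 = xy[:, 0] * np.cos(theta2) + xy[:, 1] * np.sin(theta2)
    trend = 0.5 * (
        np.sin(2 * np.pi * u1 / cfg.length_scale + phase1)
        + np.sin(2 * np.pi * u2 / (2 * cfg.length_scale) + phase2)
    )
    vals = mean * (1.0 + cfg.trend_amplitude * trend)
    vals = vals + rng.normal(0.0, cfg.noise_cv * mean, size=len(xy))
    return np.clip(vals, 0.0, None)


def generate_forest(
    geometry: PlotGeometry | None = None,
    n_plots: int = 5,
    species_table: list[SpeciesConfig] | None = None,
    soil_config: SoilConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the stem map and soil sample tables.

    Returns ``(trees, soil)`` in the data_io schemas. Stems are assigned to
    plots uniformly, placed uniformly (or by a per-species Thomas process)
    inside the plot, and given truncated-lognormal DBH >= 5 cm. Identical
    (config, seed) reproduces identical tables.
    """
    geometry = geometry or PlotGeometry()
    species_table = species_table or default_species_table()
    soil_config = soil_config or SoilConfig()
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    rng = np.random.default_rng(seed)
    plot_ids = [f"P{i + 1}" for i in range(n_plots)]

    rows = []
    tid = 0
    for sp in species_table:
        plot_assign = rng.integers(0, n_plots, size=sp.n_total)
        for p_idx, pid in enumerate(plot_ids):
            n_here = int((plot_assign == p_idx).sum())
            if n_here == 0:
                continue
            if sp.cluster is None:
                x = rng.uniform(0, geometry.width, n_here)
                y = rng.uniform(0, geometry.length, n_here)
            else:
                n_par, csd = sp.cluster
                px = rng.uniform(0, geometry.width, n_par)
                py = rng.uniform(0, geometry.length, n_par)
                parent = rng.integers(0, n_par, n_here)
                x = np.clip(px[parent] + rng.normal(0, csd, n_here),
                            0, geometry.width)
                y = np.clip(py[parent] + rng.normal(0, csd, n_here),
                            0, geometry.length)
            dbh = _truncated_lognormal(rng, sp.dbh_meanlog, sp.dbh_sdlog,
                                       n_here)
            for xi, yi, di in zip(x, y, dbh):
                tid += 1
                rows.append((f"T{tid:05d}", pid, sp.name,
                             round(float(xi), 3), round(float(yi), 3),
                             round(float(di), 2)))
    trees = pd.DataFrame(
        rows, columns=["tree_id", "plot_id", "species", "x_m", "y_m",
                       "dbh_cm"]
    )

    soil_rows = []
    nutrients = list(soil_config.means)
    for pid in plot_ids:
        xy = _soil_design_points(geometry, soil_config)
        cols = {
            n: _nutrient_field(rng, xy, soil_config.means[n], soil_config)
            for n in nutrients
        }
        for i in range(len(xy)):
            soil_rows.append(
                (pid, round(float(xy[i, 0]), 3), round(float(xy[i, 1]), 3))
                + tuple(round(float(cols[n][i]), 4) for n in nutrients)
            )
    soil = pd.DataFrame(
        soil_rows, columns=["plot_id", "x_m", "y_m"] + nutrients
    )
    return trees, soil


def make_truth(
    species: list[str],
    covariate_set: str = "dbh+anci",
    mu: np.ndarray | None = None,
    Sigma: np.ndarray | None = None,
    tau: float = 4.0,
    gamma: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    nu: np.ndarray | None = None,
    kernel: str = "as_printed",
    nci_scale: float = DEFAULT_NCI_SCALE,
    seed: int | None = None,
    beta: np.ndarray | None = None,
) -> TrueParams:
    """Build generative parameters, drawing beta_j ~ MVN(mu, Sigma).

    Defaults give a moderately size-driven, crowding-suppressed community:
    hyper-means (intercept, DBH, [soil...], crowding) = (-1, 1.5, [0...],
    -1), species SDs 0.3-0.5, random-effect precision tau = 4 (eps SD 0.5),
    cut points (0, 1.5, 3). With ``beta`` given, it is used as-is.
    """
    from fruitprod.covariates import COVARIATE_SETS

    fixed, crowding = COVARIATE_SETS[covariate_set]
    p = 1 + len(fixed) + (1 if crowding else 0)
    J = len(species)
    rng = np.random.default_rng(seed)
    if mu is None:
        mu = np.zeros(p)
        mu[0] = -1.0
        if "dbh" in fixed:
            mu[1] = 1.5
        if crowding:
            mu[-1] = -1.0
    mu = np.asarray(mu, dtype=float)
    if Sigma is None:
        sds = np.full(p, 0.3)
        sds[0] = 0.5
        Sigma = np.diag(sds**2)
    Sigma = np.asarray(Sigma, dtype=float)
    if beta is None:
        beta = rng.multivariate_normal(mu, Sigma, size=J)
    if crowding:
        if alpha is None:
            alpha = np.full(J, 1.0)
        if nu is None:
            nu = np.full(J, 1.0)
    return TrueParams(
        species=list(species),
        covariate_set=covariate_set,
        beta=np.asarray(beta, dtype=float),
        mu=mu,
        Sigma=Sigma,
        tau=tau,
        alpha=alpha,
        nu=nu,
        gamma=np.array([0.0, 1.5, 3.0]) if gamma is None else gamma,
        kernel=kernel,
        nci_scale=nci_scale,
    )


def _latent_count(rng, category: int, scheme: CategoryScheme,
                  cap: float = 10_000.0) -> int:
    lo, hi = scheme.bounds[category - 1]
    if hi == 0:
        return 0
    hi = min(hi, cap) if np.isfinite(hi) else cap
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_fruit(
    trees: pd.DataFrame,
    soil: pd.DataFrame | None,
    truth: TrueParams,
    n_periods: int = 3,
    seed: int = 0,
    with_counts: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None, np.ndarray]:
    """Draw ordinal fruit observations from the generative model.

    For each tree, eps_i ~ Normal(0, precision tau) once; each period's
    category is an independent draw from the cumulative-logit probabilities
    at eta_i. Crowding indices are computed from the realized stem map at
    the true (alpha_j, nu_j). Returns ``(fruit, counts, eps)`` where
    ``counts`` (optional) holds a latent fruit count drawn log-uniformly
    within the drawn category's bounds (top category capped at 10,000),
    for validating the count-vs-category utilities.
    """
    unknown = set(trees["species"]) - set(truth.species)
    if unknown:
        raise ValueError(f"species missing from truth: {sorted(unknown)}")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    rng = np.random.default_rng(seed)
    design = build_design(
        trees, soil, truth.covariate_set,
        kernel=truth.kernel, nci_scale=truth.nci_scale,
    )
    # map design species order onto truth rows
    order = [truth.species.index(s) for s in design.species_names]
    beta = truth.beta[order]
    alpha = None if truth.alpha is None else truth.alpha[order]
    nu = None if truth.nu is None else truth.nu[order]
    n = design.n_trees
    eps = rng.normal(0.0, 1.0 / np.sqrt(truth.tau), size=n)
    params = ModelParams(
        beta=beta, mu=truth.mu, Sigma=truth.Sigma, eps=eps, tau=truth.tau,
        alpha=alpha, nu=nu, gamma=truth.gamma,
    )
    from fruitprod.model_core import BinomialModel

    probe = BinomialModel(design, np.zeros(n, dtype=int))
    eta = probe.systematic_eta(params) + eps
    K = truth.scheme.n_categories
    gamma = truth.gamma[: K - 1]
    pi = cumulative_category_probs(eta, gamma, K)        # (n, K)
    cum = np.cumsum(pi, axis=1)
    obs_rows, count_rows = [], []
    tree_ids = design.tree_id
    for period in range(1, n_periods + 1):
        u = rng.uniform(size=n)
        cats = 1 + (u[:, None] > cum).sum(axis=1)
        for i in range(n):
            obs_rows.append((tree_ids[i], period, int(cats[i])))
            if with_counts:
                count_rows.append(
                    (tree_ids[i], period,
                     _latent_count(rng, int(cats[i]), truth.scheme))
                )
    fruit = pd.DataFrame(obs_rows, columns=["tree_id", "period", "category"])
    counts = (
        pd.DataFrame(count_rows, columns=["tree_id", "period", "count"])
        if with_counts else None
    )
    return fruit, counts, eps


def load_config(path) -> dict:
    """Read a simulation configuration from a YAML file.

    Recognized sections (all optional): ``geometry`` (width, length),
    ``n_plots``, ``n_periods``, ``seed``, ``species`` (list of mappings
    with name, n_total, dbh_meanlog, dbh_sdlog, cluster), ``soil``
    (SoilConfig fields), and ``truth`` (covariate_set, tau, mu, gamma,
    kernel, nci_scale). Returns keyword arguments for
    :func:`simulate_dataset`, with the seed recorded so outputs are
    reproducible from the file alone.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "geometry" in raw:
        kwargs["geometry"] = PlotGeometry(**raw["geometry"])
    for key in ("n_plots", "n_periods", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "species" in raw:
        table = []
        for entry in raw["species"]:
            entry = dict(entry)
            if entry.get("cluster") is not None:
                entry["cluster"] = tuple(entry["cluster"])
            table.append(SpeciesConfig(**entry))
        kwargs["species_table"] = table
    if "soil" in raw:
        kwargs["soil_config"] = SoilConfig(**raw["soil"])
    if "truth" in raw:
        t = dict(raw["truth"])
        species = [s.name for s in kwargs.get(
            "species_table", default_species_table()
        )]
        for arr in ("mu", "gamma", "alpha", "nu", "beta", "Sigma"):
            if arr in t:
                t[arr] = np.asarray(t[arr], dtype=float)
        kwargs["truth"] = make_truth(
            species, seed=kwargs.get("seed", 0), **t
        )
    return kwargs


def simulate_dataset(
    geometry: PlotGeometry | None = None,
    n_plots: int = 5,
    species_table: list[SpeciesConfig] | None = None,
    soil_config: SoilConfig | None = None,
    truth: TrueParams | None = None,
    n_periods: int = 3,
    seed: int = 0,
    with_counts: bool = False,
) -> SyntheticDataset:
    """One-call generation of a full synthetic study (forest + fruit)."""
    species_table = species_table or default_species_table()
    trees, soil = generate_forest(
        geometry, n_plots, species_table, soil_config, seed=seed
    )
    if truth is None:
        truth = make_truth([sp.name for sp in species_table], seed=seed)
    fruit, counts, eps = simulate_fruit(
        trees, soil, truth, n_periods=n_periods, seed=seed + 1,
        with_counts=with_counts,
    )
    return SyntheticDataset(
        trees=trees, soil=soil, observations=fruit, truth=truth,
        seed=seed, counts=counts, eps=eps,
    )
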