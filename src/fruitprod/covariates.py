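"""Per-tree model covariates: crowding neighborhoods, soil interpolation,
derived nutrient indices, and standardized design matrices.

The neighborhood crowding index for focal tree f is

    NCI_f = sum_i DBH_i^alpha * g(dist_i; nu)

summed over mapped neighbors i within a 10 m radius (conspecific and
heterospecific alike). The asymmetric variant (ANCI) restricts the sum to
neighbors with DBH strictly greater than the focal tree's, capturing
size-asymmetric (light) competition. Two distance kernels are available:
``"as_printed"`` uses g = exp(-nu/dist), the form this index is
sometimes printed with in the field literature, although it increases
toward 1 with distance; ``"decay"`` uses the
conventional competition kernel g = exp(-nu*dist). Both are kept because
alpha and nu are estimated inside the likelihood, so the choice is a model
variant, not a bug fix to apply silently.

Because alpha and nu are sampled, NCI cannot be z-scored ahead of fitting;
raw index values are divided by a fixed ``nci_scale`` (default 100) so the
crowding coefficient is on a comparable scale to the z-scored covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_M = 10.0
DEFAULT_MIN_DISTANCE_M = 0.1
DEFAULT_NCI_SCALE = 100.0
KERNELS = ("as_printed", "decay")

#: The seven candidate covariate sets compared by model selection. "soil"
#: always means the triple (NMin, P, SBC).
COVARIATE_SETS: dict[str, tuple[tuple[str, ...], str | None]] = {
    "intercept": ((), None),
    "dbh": (("dbh",), None),
    "dbh+soil": (("dbh", "nmin", "p", "sbc"), None),
    "dbh+nci": (("dbh",), "nci"),
    "dbh+anci": (("dbh",), "anci"),
    "dbh+soil+nci": (("dbh", "nmin", "p", "sbc"), "nci"),
    "dbh+soil+anci": (("dbh", "nmin", "p", "sbc"), "anci"),
}


@dataclass
class NeighborList:
    """Ragged per-focal-tree neighbor arrays in CSR layout.

    ``ptr[i]:ptr[i+1]`` slices the flat arrays for focal tree i (in the
    order of the tree table used to build the lists). ``larger`` flags
    neighbors whose DBH strictly exceeds the focal tree's.
    """

    ptr: np.ndarray
    dbh: np.ndarray
    dist: np.ndarray
    larger: np.ndarray

    @property
    def n_focal(self) -> int:
        return len(self.ptr) - 1

    def counts(self) -> np.ndarray:
        return np.diff(self.ptr)

    def for_tree(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e = self.ptr[i], self.ptr[i + 1]
        return self.dbh[s:e], self.dist[s:e], self.larger[s:e]


def find_neighbors(
    trees: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_M,
    min_distance: float = DEFAULT_MIN_DISTANCE_M,
) -> NeighborList:
    """All mapped neighbors within a closed ball of ``radius`` of each tree.

    Neighborhoods never cross plot boundaries and are truncated at plot
    edges (no edge correction). Coincident stems (mapped multi-stem
    artifacts) get their distance clamped to ``min_distance`` so the
    distance kernels stay finite.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if trees["tree_id"].duplicated().any():
        raise ValueError("duplicate tree_id in stem map")
    n = len(trees)
    dbh = trees["dbh_cm"].to_numpy(float)
    xy = trees[["x_m", "y_m"]].to_numpy(float)
    plot = trees["plot_id"].to_numpy()

    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None] = [None] * n
    counts = np.zeros(n, dtype=np.int64)
    n_clamped = 0
    for p in pd.unique(plot):
        idx = np.flatnonzero(plot == p)
        if len(idx) < 2:
            continue
        tree = cKDTree(xy[idx])
        hits = tree.query_ball_point(xy[idx], r=radius)
        for local_i, neigh in enumerate(hits):
            gi = idx[local_i]
            others = np.array([j for j in neigh if j != local_i], dtype=int)
            if len(others) == 0:
                continue
            gj = idx[others]
            d = np.sqrt(((xy[gj] - xy[gi]) ** 2).sum(axis=1))
            n_clamped += int((d < min_distance).sum())
            d = np.maximum(d, min_distance)
            counts[gi] = len(gj)
            blocks[gi] = (dbh[gj], d, dbh[gj] > dbh[gi])
    if n_clamped:
        logger.info("clamped %d neighbor distances to %.2f m", n_clamped,
                    min_distance)
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    filled = [b for b in blocks if b is not None]
    if filled:
        flat_dbh = np.concatenate([b[0] for b in filled])
        flat_dist = np.concatenate([b[1] for b in filled])
        flat_larger = np.concatenate([b[2] for b in filled])
    else:
        flat_dbh = np.empty(0)
        flat_dist = np.empty(0)
        flat_larger = np.empty(0, dtype=bool)
    return NeighborList(ptr=ptr, dbh=flat_dbh, dist=flat_dist,
                        larger=flat_larger)


def _kernel_weight(dist: np.ndarray, nu: float, kernel: str) -> np.ndarray:
    if kernel == "as_printed":
        return np.exp(-nu / dist)
    if kernel == "decay":
        return np.exp(-nu * dist)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def compute_nci(
    neighbor_dbh,
    neighbor_dist,
    alpha: float,
    nu: float,
    asymmetric: bool = False,
    larger=None,
    kernel: str = "as_printed",
) -> float:
    """Crowding index for one focal tree: sum of DBH^alpha * kernel(dist).

    With ``asymmetric=True`` only neighbors flagged ``larger`` (strictly
    greater DBH than the focal tree) contribute. An empty neighbor set
    yields 0.
    """
    if alpha <= 0 and nu < 0:
        raise ValueError("alpha must be > 0 and nu >= 0")
    d = np.asarray(neighbor_dist, dtype=float)
    dbh = np.asarray(neighbor_dbh, dtype=float)
    if (d <= 0).any():
        raise ValueError("neighbor distances must be positive (clamp first)")
    if asymmetric:
        if larger is None:
            raise ValueError("asymmetric NCI needs the larger-DBH flags")
        mask = np.asarray(larger, dtype=bool)
        dbh, d = dbh[mask], d[mask]
    if len(dbh) == 0:
        return 0.0
    return float(np.sum(dbh**alpha * _kernel_weight(d, nu, kernel)))


@dataclass
class SpeciesNeighborSegments:
    """Flattened neighbor arrays for one species' focal trees.

    Precomputed so the sampler can recompute all of a species' crowding
    indices for a proposed (alpha, nu) with a single bincount pass.
    ``seg`` maps each neighbor pair to the position of its focal tree in
    the species' tree list.
    """

    n_focal: int
    seg: np.ndarray
    log_dbh: np.ndarray
    dist: np.ndarray

    def nci(self, alpha: float, nu: float, kernel: str) -> np.ndarray:
        if len(self.seg) == 0:
            return np.zeros(self.n_focal)
        if kernel == "as_printed":
            arg = alpha * self.log_dbh - nu / self.dist
        else:
            arg = alpha * self.log_dbh - nu * self.dist
        # cap the exponent so extreme sampler proposals stay finite (and get
        # rejected on likelihood grounds rather than producing NaNs)
        w = np.exp(np.minimum(arg, 700.0))
        return np.bincount(self.seg, weights=w, minlength=self.n_focal)


def interpolate_soil(
    soil: pd.DataFrame,
    points: pd.DataFrame,
    k: int = 5,
    power: float = 1.0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Inverse-distance-weighted average of the k nearest soil samples.

    ``points`` needs plot_id, x_m, y_m; interpolation never crosses plots.
    A query point coincident with a sample returns that sample's values
    exactly. Plots with fewer than k samples use all available (warned).
    """
    if columns is None:
        columns = [c for c in soil.columns if c not in ("plot_id", "x_m", "y_m")]
    out = np.full((len(points), len(columns)), np.nan)
    pts_plot = points["plot_id"].to_numpy()
    pts_xy = points[["x_m", "y_m"]].to_numpy(float)
    for p in pd.unique(pts_plot):
        samp = soil[soil["plot_id"] == p]
        if samp.empty:
            raise ValueError(f"no soil samples for plot {p!r}")
        kk = min(k, len(samp))
        if kk < k:
            logger.warning(
                "plot %r has %d soil samples (< k=%d); using all", p, kk, k
            )
        tree = cKDTree(samp[["x_m", "y_m"]].to_numpy(float))
        sel = np.flatnonzero(pts_plot == p)
        d, j = tree.query(pts_xy[sel], k=kk)
        d = np.atleast_2d(d.reshape(len(sel), kk))
        j = np.atleast_2d(j.reshape(len(sel), kk))
        vals = samp[columns].to_numpy(float)[j]  # (m, kk, ncol)
        exact = d[:, 0] == 0.0
        with np.errstate(divide="ignore"):
            w = 1.0 / d**power
        w[exact] = 0.0
        w[exact, 0] = 1.0
        w /= w.sum(axis=1, keepdims=True)
        out[sel] = np.einsum("mk,mkc->mc", w, vals)
    return pd.DataFrame(out, columns=columns, index=points.index)


def derive_soil_covariates(values: pd.DataFrame) -> pd.DataFrame:
    """Derive the three model soil covariates from raw sample columns.

    NMin (potential nitrogen mineralization) is the 30-day incubation change
    in the NO3 + NH4 pool; SBC is the sum of the strongly covarying base
    cations K + Ca + Mg; extractable P passes through unchanged.
    """
    needed = ["no3_i", "nh4_i", "no3_f", "nh4_f", "p", "k", "ca", "mg"]
    missing = [c for c in needed if c not in values.columns]
    if missing:
        raise ValueError(f"missing soil constituents: {missing}")
    return pd.DataFrame(
        {
            "nmin": (values["no3_f"] + values["nh4_f"])
            - (values["no3_i"] + values["nh4_i"]),
            "p": values["p"],
            "sbc": values["k"] + values["ca"] + values["mg"],
        },
        index=values.index,
    )


@dataclass
class DesignMatrix:
    """Standardized covariates plus crowding structure for one model fit.

    ``X`` holds the intercept and globally z-scored fixed covariates; the
    crowding index is not a fixed column because its shape parameters are
    sampled — instead per-species neighbor segments support recomputation
    at any (alpha, nu). ``moments`` stores the standardization (mean, sd)
    per raw covariate for back-transformation.
    """

    covariate_set: str
    tree_id: np.ndarray
    species_names: list[str]
    species_index: np.ndarray
    X: np.ndarray
    columns: list[str]
    moments: dict[str, tuple[float, float]]
    dbh_cm: np.ndarray
    crowding: str | None = None
    kernel: str = "as_printed"
    nci_scale: float = DEFAULT_NCI_SCALE
    neighbors: NeighborList | None = None
    segments: list[SpeciesNeighborSegments] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.tree_id)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_coef(self) -> int:
        """Coefficients per species: fixed columns plus crowding slope."""
        return self.X.shape[1] + (1 if self.crowding else 0)

    @property
    def coef_names(self) -> list[str]:
        return self.columns + ([self.crowding] if self.crowding else [])

    def species_rows(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.species_index == j)

    def nci_values(self, j: int, alpha: float, nu: float) -> np.ndarray:
        """Scaled crowding index for species j's trees at (alpha, nu)."""
        return self.segments[j].nci(alpha, nu, self.kernel) / self.nci_scale

    def audit_table(self) -> pd.DataFrame:
        """Per-tree covariate audit: z-scores and neighbor counts."""
        cols = {"tree_id": self.tree_id}
        for name in self.columns[1:]:
            cols[name + "_z"] = self.X[:, self.columns.index(name)]
        if self.neighbors is not None:
            cols["n_neighbors"] = self.neighbors.counts()
            nl = self.neighbors
            cols["n_larger_neighbors"] = np.array(
                [int(nl.larger[nl.ptr[i]:nl.ptr[i + 1]].sum())
                 for i in range(nl.n_focal)]
            )
        return pd.DataFrame(cols)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=0))
    if s == 0:
        raise ValueError("cannot standardize a constant covariate")
    return (x - m) / s, m, s


def build_design(
    trees: pd.DataFrame,
    soil: pd.DataFrame | None,
    covariate_set: str,
    radius: float = DEFAULT_RADIUS_M,
    k_soil: int = 5,
    idw_power: float = 1.0,
    kernel: str = "as_printed",
    nci_scale: float = DEFAULT_NCI_SCALE,
    min_distance: float = DEFAULT_MIN_DISTANCE_M,
    neighbors: NeighborList | None = None,
) -> DesignMatrix:
    """Assemble the design for one of the seven candidate covariate sets.

    Soil covariates are interpolated to each stem (IDW over the k=5 nearest
    samples), reduced to (NMin, P, SBC), and z-scored globally across all
    included trees, as is DBH. When the set includes a crowding term the
    full-census neighbor lists are attached and per-species segments
    precomputed; ``neighbors`` may be passed to reuse lists across sets.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"unknown covariate set {covariate_set!r}; "
            f"choose from {sorted(COVARIATE_SETS)}"
        )
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    fixed, crowding = COVARIATE_SETS[covariate_set]
    trees = trees.reset_index(drop=True)
    n = len(trees)
    species_names = sorted(trees["species"].unique())
    sp_code = {s: j for j, s in enumerate(species_names)}
    species_index = trees["species"].map(sp_code).to_numpy()
    dbh_cm = trees["dbh_cm"].to_numpy(float)

    columns = ["intercept"]
    cols = [np.ones(n)]
    moments: dict[str, tuple[float, float]] = {}
    if "dbh" in fixed:
        z, m, s = _zscore(dbh_cm)
        cols.append(z)
        columns.append("dbh")
        moments["dbh"] = (m, s)
    if "nmin" in fixed:
        if soil is None:
            raise ValueError(f"covariate set {covariate_set!r} needs soil data")
        interp = interpolate_soil(soil, trees, k=k_soil, power=idw_power)
        derived = derive_soil_covariates(interp)
        for name in ("nmin", "p", "sbc"):
            z, m, s = _zscore(derived[name].to_numpy(float))
            cols.append(z)
            columns.append(name)
            moments[name] = (m, s)
    X = np.column_stack(cols)

    nl = None
    segments: list[SpeciesNeighborSegments] = []
    if crowding:
        nl = neighbors if neighbors is not None else find_neighbors(
            trees, radius=radius, min_distance=min_distance
        )
        asym = crowding == "anci"
        for j in range(len(species_names)):
            rows = np.flatnonzero(species_index == j)
            seg_ids, dbh_l, dist_l = [], [], []
            for pos, i in enumerate(rows):
                nd, dd, lg = nl.for_tree(i)
                if asym:
                    nd, dd = nd[lg], dd[lg]
                if len(nd):
                    seg_ids.append(np.full(len(nd), pos, dtype=np.int64))
                    dbh_l.append(nd)
                    dist_l.append(dd)
            if seg_ids:
                segments.append(SpeciesNeighborSegments(
                    n_focal=len(rows),
                    seg=np.concatenate(seg_ids),
                    log_dbh=np.log(np.concatenate(dbh_l)),
                    dist=np.concatenate(dist_l),
                ))
            else:
                segments.append(SpeciesNeighborSegments(
                    n_focal=len(rows),
                    seg=np.empty(0, dtype=np.int64),
                    log_dbh=np.empty(0),
                    dist=np.empty(0),
                ))
    return DesignMatrix(
        covariate_set=covariate_set,
        tree_id=trees["tree_id"].to_numpy(),
        species_names=species_names,
        species_index=species_index,
        X=X,
        columns=columns,
        moments=moments,
        dbh_cm=dbh_cm,
        crowding=crowding,
        kernel=kernel,
        nci_scale=nci_scale,
        neighbors=nl,
        segments=segments,
    )
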