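"""Tabular I/O, observation-reduction rules, and count-vs-category validation.

Three CSV schemas (UTF-8, "." decimal):

``trees.csv``
    tree_id, plot_id, species, x_m, y_m, dbh_cm — one mapped stem per row;
    the census includes all stems with DBH >= 5 cm.
``soil.csv``
    plot_id, x_m, y_m, no3_i, nh4_i, no3_f, nh4_f, p, k, ca, mg — one soil
    sample per row; ``_i`` columns are initial extractions, ``_f`` the same
    pools after a 30-day incubation.
``fruit.csv``
    tree_id, period, category — one ordinal fruiting assessment per tree per
    observation period. Categories are integer codes 1..K (1-based
    everywhere in this package).

An optional ``counts.csv`` (tree_id, branch1, branch2, branch3, n_branches)
feeds the branch-count validation of the ordinal categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREE_COLUMNS = ["tree_id", "plot_id", "species", "x_m", "y_m", "dbh_cm"]
SOIL_COLUMNS = [
    "plot_id", "x_m", "y_m",
    "no3_i", "nh4_i", "no3_f", "nh4_f", "p", "k", "ca", "mg",
]
FRUIT_COLUMNS = ["tree_id", "period", "category"]
COUNT_COLUMNS = ["tree_id", "branch1", "branch2", "branch3", "n_branches"]

MIN_CENSUS_DBH_CM = 5.0


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, contiguous count intervals defining the ordinal categories.

    The default is the four-level field scheme: exactly zero fruit; 1-100;
    101-1,000; more than 1,000. Intervals are closed on both ends except the
    last, which is open above (``upper`` of ``inf``). Category codes are
    1-based.
    """

    bounds: tuple[tuple[float, float], ...] = (
        (0, 0), (1, 100), (101, 1000), (1001, math.inf),
    )

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("scheme needs at least one interval")
        lo0, _ = self.bounds[0]
        if lo0 != 0 or self.bounds[0][1] != 0:
            raise ValueError("first interval must be exactly [0, 0]")
        for (alo, ahi), (blo, bhi) in zip(self.bounds, self.bounds[1:]):
            if alo > ahi or blo > bhi:
                raise ValueError("intervals must be non-empty")
            if blo != ahi + 1:
                raise ValueError("intervals must be contiguous and increasing")

    @property
    def n_categories(self) -> int:
        return len(self.bounds)

    def assign(self, count: float) -> int:
        return assign_category(count, self)


def assign_category(count: float, scheme: CategoryScheme | None = None) -> int:
    """Map a fruit count to its 1-based ordinal category.

    >>> assign_category(0), assign_category(100), assign_category(101)
    (1, 2, 3)
    """
    if scheme is None:
        scheme = CategoryScheme()
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    for code, (lo, hi) in enumerate(scheme.bounds, start=1):
        if lo <= count <= hi:
            return code
    raise ValueError(f"count {count} not covered by scheme {scheme.bounds}")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def read_trees(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TREE_COLUMNS, "trees")
    df = df[TREE_COLUMNS].copy()
    if df["tree_id"].duplicated().any():
        dupes = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()[:5]
        raise SchemaError(f"trees: duplicate tree_id values, e.g. {dupes}")
    bad = df.index[df["dbh_cm"] < MIN_CENSUS_DBH_CM].tolist()
    if bad:
        # +2: 1-based plus header line
        lines = [i + 2 for i in bad[:5]]
        raise SchemaError(
            f"trees: dbh_cm below the {MIN_CENSUS_DBH_CM} cm census minimum "
            f"at line(s) {lines}"
        )
    return df


def read_soil(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SOIL_COLUMNS, "soil")
    df = df[SOIL_COLUMNS].copy()
    conc = SOIL_COLUMNS[3:]
    neg = df.index[(df[conc] < 0).any(axis=1)].tolist()
    if neg:
        lines = [i + 2 for i in neg[:5]]
        raise SchemaError(f"soil: negative concentration at line(s) {lines}")
    return df


def read_fruit(path, scheme: CategoryScheme | None = None) -> pd.DataFrame:
    if scheme is None:
        scheme = CategoryScheme()
    df = pd.read_csv(path)
    _require_columns(df, FRUIT_COLUMNS, "fruit")
    df = df[FRUIT_COLUMNS].copy()
    if len(df):
        ok = df["category"].between(1, scheme.n_categories)
        if not ok.all():
            lines = [i + 2 for i in df.index[~ok].tolist()[:5]]
            raise SchemaError(
                f"fruit: category outside 1..{scheme.n_categories} "
                f"at line(s) {lines}"
            )
        if (df["period"] < 1).any():
            raise SchemaError("fruit: period must be >= 1")
    return df


def read_tables(
    trees_path, soil_path, fruit_path, scheme: CategoryScheme | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three core tables.

    Returns ``(trees, soil, fruit)``. Observations whose tree_id is absent
    from the stem map are rejected; mapped trees never observed are allowed
    here and handled (excluded, logged) at model-building time.
    """
    trees = read_trees(trees_path)
    soil = read_soil(soil_path)
    fruit = read_fruit(fruit_path, scheme)
    unknown = set(fruit["tree_id"]) - set(trees["tree_id"])
    if unknown:
        raise SchemaError(
            f"fruit: {len(unknown)} observation tree_id(s) not in stem map, "
            f"e.g. {sorted(unknown)[:5]}"
        )
    return trees, soil, fruit


def write_tables(dataset, out_dir) -> dict[str, str]:
    """Write a dataset's tables to ``out_dir``; returns {name: path}."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("trees", dataset.trees), ("soil", dataset.soil),
        ("fruit", dataset.observations),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


# ---------------------------------------------------------------------------
# Observation reductions


def reduce_status(fruit: pd.DataFrame) -> pd.Series:
    """Binary reproductive status per tree: 1 if any period's category > 1.

    A tree is called reproductive if fruit was observed at least once across
    the observation periods. Input is the long fruit table; output is a
    Series indexed by tree_id.
    """
    if fruit.empty:
        return pd.Series(dtype=int, name="status")
    status = (
        fruit.groupby("tree_id")["category"].max().gt(1).astype(int)
    )
    status.name = "status"
    return status


def reduce_max_category(fruit: pd.DataFrame) -> pd.Series:
    """Maximum fruiting category per tree across all observation periods.

    Species fruit at different times of year, so the per-tree maximum over
    periods is used as the single ordinal response F.
    """
    if fruit.empty:
        return pd.Series(dtype=int, name="max_category")
    out = fruit.groupby("tree_id")["category"].max()
    out.name = "max_category"
    return out


def align_response(
    trees: pd.DataFrame, response: pd.Series
) -> tuple[pd.DataFrame, np.ndarray]:
    """Align a per-tree response with the stem map, dropping unobserved trees.

    Trees present in the map but absent from the response are excluded from
    model fitting and logged, never silently NA-filled.
    """
    observed = trees["tree_id"].isin(response.index)
    n_drop = int((~observed).sum())
    if n_drop:
        logger.info("excluding %d mapped trees with no observations", n_drop)
    kept = trees.loc[observed].reset_index(drop=True)
    y = response.loc[kept["tree_id"]].to_numpy()
    return kept, y


# ---------------------------------------------------------------------------
# Count-based validation of the ordinal categories


def branch_count_estimate(
    branch_counts, n_reproductive_branches: float
) -> float:
    """Whole-tree fruit count from three per-branch counts.

    The mean of the three branch counts times the number of reproductive
    branches on the tree.
    """
    counts = np.asarray(branch_counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("exactly three branch counts required")
    if (counts < 0).any() or n_reproductive_branches < 0:
        raise ValueError("branch counts and branch number must be >= 0")
    return float(counts.mean() * n_reproductive_branches)


@dataclass
class AgreementResult:
    """Agreement between count-derived and observed ordinal categories."""

    n: int
    agreement: float
    r_all: float | None
    r_nonzero: float | None
    n_nonzero: int
    detail: pd.DataFrame = field(repr=False, default=None)


def category_agreement(
    count_estimates, categories, scheme: CategoryScheme | None = None
) -> AgreementResult:
    """Fraction of agreeing pairs plus Pearson correlations.

    ``agreement`` is the fraction of trees for which the category implied by
    the count estimate equals the observed ordinal category. Correlations of
    count estimate vs category code are reported for all pairs and for the
    subset where both estimates are nonzero; either is ``None`` when
    undefined (fewer than two pairs, or zero variance).
    """
    if scheme is None:
        scheme = CategoryScheme()
    counts = np.asarray(count_estimates, dtype=float)
    cats = np.asarray(categories, dtype=int)
    if counts.shape != cats.shape:
        raise ValueError("count_estimates and categories must be paired")
    derived = np.array([assign_category(c, scheme) for c in counts])
    agree = float(np.mean(derived == cats)) if len(cats) else float("nan")

    def _pearson(x, y):
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return None
        return float(np.corrcoef(x, y)[0, 1])

    nz = (counts > 0) & (cats > 1)
    detail = pd.DataFrame(
        {"count": counts, "derived": derived, "observed": cats}
    )
    return AgreementResult(
        n=len(cats),
        agreement=agree,
        r_all=_pearson(counts, cats),
        r_nonzero=_pearson(counts[nz], cats[nz]),
        n_nonzero=int(nz.sum()),
        detail=detail,
    )
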