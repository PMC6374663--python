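import numpy as np
import pandas as pd
import pytest

from conftest import random_stem_map
from fruitprod.covariates import (
    COVARIATE_SETS,
    build_design,
    compute_nci,
    derive_soil_covariates,
    find_neighbors,
    interpolate_soil,
)


def brute_force_neighbors(trees, radius, min_distance=0.1):
    """All-pairs oracle for the neighborhood search."""
    xy = trees[["x_m", "y_m"]].to_numpy(float)
    dbh = trees["dbh_cm"].to_numpy(float)
    plot = trees["plot_id"].to_numpy()
    out = []
    for i in range(len(trees)):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        mask = (d <= radius) & (plot == plot[i])
        mask[i] = False
        idx = np.flatnonzero(mask)
        out.append((dbh[idx], np.maximum(d[idx], min_distance),
                    dbh[idx] > dbh[i]))
    return out


class TestNeighbors:
    def test_single_tree_has_empty_list(self):
        trees = random_stem_map(np.random.default_rng(0), 1)
        nl = find_neighbors(trees)
        assert nl.counts().tolist() == [0]

    def test_closed_ball_boundary(self):
        trees = pd.DataFrame({
            "tree_id": ["a", "b", "c"], "plot_id": "P1",
            "species": "X", "x_m": [0.0, 9.99, 10.01],
            "y_m": [0.0, 0.0, 0.0], "dbh_cm": [10.0, 12.0, 14.0],
        })
        nl = find_neighbors(trees, radius=10.0)
        dbh_a, dist_a, _ = nl.for_tree(0)
        assert set(dbh_a) == {12.0}          # 9.99 in, 10.01 out
        assert np.isclose(dist_a[0], 9.99)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        trees = random_stem_map(rng, 500)
        nl = find_neighbors(trees, radius=10.0)
        oracle = brute_force_neighbors(trees, 10.0)
        for i in range(len(trees)):
            dbh, dist, larger = nl.for_tree(i)
            o_dbh, o_dist, o_larger = oracle[i]
            order, o_order = np.argsort(dist), np.argsort(o_dist)
            np.testing.assert_allclose(dist[order], o_dist[o_order])
            np.testing.assert_allclose(dbh[order], o_dbh[o_order])
            np.testing.assert_array_equal(larger[order], o_larger[o_order])

    def test_no_cross_plot_pairs(self):
        rng = np.random.default_rng(4)
        a = random_stem_map(rng, 40, plot_id="P1")
        b = random_stem_map(rng, 40, plot_id="P2")
        b = b.assign(tree_id=["U%04d" % i for i in range(40)])
        both = pd.concat([a, b], ignore_index=True)
        nl = find_neighbors(both)
        oracle = brute_force_neighbors(both, 10.0)
        for i in range(len(both)):
            assert len(nl.for_tree(i)[0]) == len(oracle[i][0])

    def test_duplicate_ids_rejected(self):
        trees = random_stem_map(np.random.default_rng(0), 5)
        trees.loc[1, "tree_id"] = trees.loc[0, "tree_id"]
        with pytest.raises(ValueError, match="duplicate"):
            find_neighbors(trees)


class TestNci:
    def test_no_neighbors_zero(self):
        assert compute_nci([], [], alpha=0.5, nu=2.0) == 0.0

    def test_hand_computed_value(self):
        # one neighbor: DBH 20 cm at 4 m, alpha .5, nu 2 -> 20^.5 * e^-.5
        val = compute_nci([20.0], [4.0], alpha=0.5, nu=2.0,
                          kernel="as_printed")
        assert val == pytest.approx(np.sqrt(20) * np.exp(-0.5), abs=1e-12)

    def test_nu_zero_limit_kernel_independent(self):
        for kern in ("as_printed", "decay"):
            assert compute_nci([20.0], [7.3], alpha=1.0, nu=0.0,
                               kernel=kern) == pytest.approx(20.0)

    def test_asymmetric_keeps_strictly_larger_only(self):
        # focal DBH 30: only the 35-cm neighbor contributes
        val = compute_nci(
            [25.0, 35.0, 30.0], [2.0, 2.0, 2.0], alpha=1.0, nu=1.0,
            asymmetric=True, larger=[False, True, False],
        )
        assert val == pytest.approx(35.0 * np.exp(-0.5))

    def test_anci_never_exceeds_nci(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 12)
            dbh = rng.uniform(5, 80, n)
            dist = rng.uniform(0.5, 10, n)
            larger = rng.uniform(size=n) < 0.5
            a, v = rng.uniform(0.2, 2, 2)
            full = compute_nci(dbh, dist, a, v)
            asym = compute_nci(dbh, dist, a, v, asymmetric=True,
                               larger=larger)
            assert asym <= full + 1e-12

    def test_monotone_in_dbh_and_distance_direction_per_kernel(self):
        base = dict(alpha=0.8, nu=1.5)
        lo = compute_nci([20.0], [5.0], **base)
        assert compute_nci([25.0], [5.0], **base) > lo
        # as-printed kernel increases with distance; decay decreases
        assert compute_nci([20.0], [6.0], **base, kernel="as_printed") > lo
        d_lo = compute_nci([20.0], [5.0], **base, kernel="decay")
        assert compute_nci([20.0], [6.0], **base, kernel="decay") < d_lo


class TestSoil:
    def brute_force_idw(self, soil, pt, k, cols):
        d = np.sqrt((soil["x_m"] - pt[0]) ** 2 + (soil["y_m"] - pt[1]) ** 2)
        order = np.argsort(d.to_numpy(), kind="stable")[:k]
        dd = d.to_numpy()[order]
        vals = soil[cols].to_numpy(float)[order]
        if dd[0] == 0:
            return vals[0]
        w = 1.0 / dd
        return (w[:, None] * vals).sum(axis=0) / w.sum()

    def test_coincident_sample_returned_exactly(self, small_forest):
        _, soil = small_forest
        pt = soil.iloc[7]
        res = interpolate_soil(
            soil, pd.DataFrame({"plot_id": [pt["plot_id"]],
                                "x_m": [pt["x_m"]], "y_m": [pt["y_m"]]})
        )
        for col in res.columns:
            assert res.iloc[0][col] == pytest.approx(pt[col], abs=1e-12)

    def test_matches_brute_force_oracle(self, small_forest):
        _, soil = small_forest
        rng = np.random.default_rng(8)
        pts = pd.DataFrame({
            "plot_id": "P1",
            "x_m": rng.uniform(0, 41, 60),
            "y_m": rng.uniform(0, 240, 60),
        })
        cols = [c for c in soil.columns if c not in ("plot_id", "x_m", "y_m")]
        res = interpolate_soil(soil, pts, k=5)
        for i in range(len(pts)):
            exp = self.brute_force_idw(
                soil, (pts.iloc[i]["x_m"], pts.iloc[i]["y_m"]), 5, cols
            )
            np.testing.assert_allclose(res.iloc[i].to_numpy(), exp,
                                       rtol=1e-10)

    def test_constant_field_reproduced_exactly(self):
        soil = pd.DataFrame({
            "plot_id": "P1",
            "x_m": [0, 10, 20, 30, 40, 5],
            "y_m": [0, 5, 10, 15, 20, 30],
            "p": [3.5] * 6,
        })
        pts = pd.DataFrame({"plot_id": ["P1"] * 3, "x_m": [1, 17, 33],
                            "y_m": [2, 12, 28]})
        res = interpolate_soil(soil, pts, k=5, columns=["p"])
        np.testing.assert_allclose(res["p"], 3.5)

    def test_derived_covariates_arithmetic(self):
        df = pd.DataFrame({
            "no3_i": [2.0], "nh4_i": [3.0], "no3_f": [5.0], "nh4_f": [6.0],
            "p": [1.5], "k": [0.0], "ca": [0.0], "mg": [0.0],
        })
        out = derive_soil_covariates(df)
        assert out["nmin"].iloc[0] == 6.0
        assert out["sbc"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.5

    def test_nmin_zero_when_no_incubation_change(self):
        df = pd.DataFrame({
            "no3_i": [4.0], "nh4_i": [1.0], "no3_f": [4.0], "nh4_f": [1.0],
            "p": [1.0], "k": [1.0], "ca": [2.0], "mg": [3.0],
        })
        out = derive_soil_covariates(df)
        assert out["nmin"].iloc[0] == 0.0
        assert out["sbc"].iloc[0] == 6.0


class TestDesign:
    def test_intercept_only(self, small_forest):
        trees, soil = small_forest
        d = build_design(trees, soil, "intercept")
        assert d.columns == ["intercept"]
        np.testing.assert_allclose(d.X[:, 0], 1.0)
        assert d.crowding is None

    def test_dbh_soil_columns_standardized(self, small_forest):
        trees, soil = small_forest
        d = build_design(trees, soil, "dbh+soil")
        assert d.columns == ["intercept", "dbh", "nmin", "p", "sbc"]
        for c in range(1, d.X.shape[1]):
            assert abs(d.X[:, c].mean()) < 1e-10
            assert d.X[:, c].std() == pytest.approx(1.0)
        # moments invert the transform
        m, s = d.moments["dbh"]
        np.testing.assert_allclose(
            d.X[:, 1] * s + m, trees["dbh_cm"], rtol=1e-12
        )

    def test_anci_segments_use_larger_neighbors_only(self, small_forest):
        trees, soil = small_forest
        d_all = build_design(trees, soil, "dbh+nci")
        d_asym = build_design(trees, soil, "dbh+anci")
        for j in range(d_all.n_species):
            nci = d_all.nci_values(j, 1.0, 1.0)
            anci = d_asym.nci_values(j, 1.0, 1.0)
            assert np.all(anci <= nci + 1e-12)

    def test_unknown_set_rejected(self, small_forest):
        trees, soil = small_forest
        with pytest.raises(ValueError, match="unknown covariate set"):
            build_design(trees, soil, "dbh+magic")

    def test_all_seven_sets_build(self, small_forest):
        trees, soil = small_forest
        for cs in COVARIATE_SETS:
            d = build_design(trees, soil, cs)
            assert d.n_coef == d.X.shape[1] + (1 if d.crowding else 0)
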