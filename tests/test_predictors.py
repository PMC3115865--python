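import numpy as np
import pandas as pd
import pytest

from rangediv.popdata import SiteTable
from rangediv.predictors import (
    distance_to_range_margin,
    environmental_marginality,
    merge_expansion_levels,
    predictor_table,
    quantile_grouping,
)


def sites_from_xy(xy_km, lat0=50.0, extra=None):
    """Build a SiteTable whose local projection reproduces ``xy_km``."""
    R = 6371.0
    xy = np.asarray(xy_km, float)
    lat = np.degrees(xy[:, 1] / R)
    lon = np.degrees(xy[:, 0] / (R * np.cos(np.radians(lat0 + lat.mean()))))
    # iterate once so the projection's mean-latitude matches construction
    frame = pd.DataFrame(
        {"lat": lat0 + lat, "lon": lon},
        index=[f"S{i}" for i in range(len(xy))],
    )
    if extra is not None:
        for k, v in extra.items():
            frame[k] = v
    frame["expansion"] = "hol"
    return SiteTable(frame)


class TestRangeMargin:
    def test_hull_vertices_have_zero_distance(self):
        sites = sites_from_xy([[0, 0], [100, 0], [100, 100], [0, 100], [50, 50]])
        lim = distance_to_range_margin(sites)
        assert lim.iloc[:4].max() < 0.5  # vertices, small projection error
        assert lim.iloc[4] == pytest.approx(50.0, rel=0.02)

    def test_interior_point_matches_dense_edge_sampling(self, rng):
        pts = rng.random((12, 2)) * 500
        sites = sites_from_xy(pts)
        lim = distance_to_range_margin(sites)
        # oracle: minimum distance to hull edges sampled at ~1 m resolution
        from scipy.spatial import ConvexHull
        from rangediv.predictors import _project_km

        proj = _project_km(sites)
        hull = ConvexHull(proj)
        verts = proj[hull.vertices]
        for i, p in enumerate(proj):
            best = np.inf
            for a, b in zip(verts, np.roll(verts, -1, axis=0)):
                t = np.linspace(0, 1, int(np.linalg.norm(b - a) * 1000) + 2)
                seg = a[None] + t[:, None] * (b - a)[None]
                best = min(best, np.linalg.norm(seg - p, axis=1).min())
            assert lim.iloc[i] == pytest.approx(best, rel=1e-3, abs=1e-4)

    def test_too_few_or_collinear_sites_rejected(self):
        with pytest.raises(ValueError):
            distance_to_range_margin(sites_from_xy([[0, 0], [1, 1]]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            distance_to_range_margin(sites_from_xy([[0, 0], [1, 1], [2, 2], [3, 3]]))


class TestEnvironmentalMarginality:
    def _sites(self, climate):
        n = len(next(iter(climate.values())))
        frame = pd.DataFrame(
            {"lat": np.linspace(45, 55, n), "lon": np.linspace(0, 10, n), **climate},
            index=[f"S{i}" for i in range(n)],
        )
        frame["expansion"] = "hol"
        return SiteTable(frame)

    def test_site_at_climate_mean_has_zero_marg(self, rng):
        # appending the mean of the other sites puts the last site exactly at
        # the multivariate climate mean, so its z-scores (hence marg) are 0
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        a = np.append(a, a.mean())
        b = np.append(b, b.mean())
        marg, _ = environmental_marginality(
            self._sites({"c1": a, "c2": b}), columns=["c1", "c2"]
        )
        assert marg.iloc[-1] == pytest.approx(0.0, abs=1e-10)

    def test_perfectly_correlated_columns_collapse_to_one_axis(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        marg, rep = environmental_marginality(
            self._sites({"c1": x, "c2": 2 * x}), columns=["c1", "c2"]
        )
        assert rep.n_retained == 1
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(marg.values, np.sqrt(2) * np.abs(z), atol=1e-8)

    def test_kaiser_count_matches_independent_eigendecomposition(self, rng):
        X = rng.standard_normal((80, 35))
        sites = self._sites({f"c{j}": X[:, j] for j in range(35)})
        marg, rep = environmental_marginality(sites, columns=[f"c{j}" for j in range(35)])
        evals_oracle = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
        assert rep.n_retained == int((evals_oracle > 1).sum())

    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        X = rng.standard_normal((30, 6))
        cols = [f"c{j}" for j in range(6)]
        marg, rep = environmental_marginality(self._sites(dict(zip(cols, X.T))), columns=cols)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
        scores_oracle = Z @ Vt[: rep.n_retained].T
        scores = Z @ rep.loadings
        for j in range(rep.n_retained):
            assert (
                np.allclose(scores[:, j], scores_oracle[:, j], atol=1e-8)
                or np.allclose(scores[:, j], -scores_oracle[:, j], atol=1e-8)
            )

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            marg, rep = environmental_marginality(
                self._sites({"c1": np.arange(6.0), "c2": np.ones(6), "c3": np.arange(6.0) ** 2}),
                columns=["c1", "c2", "c3"],
            )
        assert "c2" in rep.dropped_constant


class TestQuantileGrouping:
    def test_hundred_distinct_values_top_fifteen(self):
        v = pd.Series(np.arange(100, dtype=float))
        assert quantile_grouping(v, 0.85).sum() == 15

    def test_median_split_strictly_greater(self):
        v = pd.Series(np.arange(1, 11, dtype=float))
        flag = quantile_grouping(v, 0.5)
        assert flag.sum() == 5  # values > 5.5 -> {6..10}

    def test_ties_fall_below_threshold(self):
        v = pd.Series([1.0, 1, 1, 2, 2, 2])
        flag = quantile_grouping(v, 0.5)
        assert flag.tolist() == [False] * 3 + [True] * 3

    def test_constant_values_empty_group_with_warning(self):
        with pytest.warns(UserWarning, match="empty marginal group"):
            flag = quantile_grouping(pd.Series([3.0] * 8), 0.85)
        assert flag.sum() == 0


class TestMergeExpansion:
    def _setup(self, shift=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        codes = [f"S{i}" for i in range(n)]
        classes = ["ref"] * (n // 3) + ["hol"] * (n // 3) + ["exp"] * (n - 2 * (n // 3))
        he = rng.normal(0.5, 0.1, n)
        he[np.array(classes) == "hol"] += shift
        div = pd.DataFrame({"H_E": he}, index=codes)
        return div, pd.Series(classes, index=codes)

    def test_same_distribution_merges_in_most_replicates(self):
        merged_ct = 0
        for rep in range(60):
            div, exp = self._setup(seed=rep)
            factor, _ = merge_expansion_levels(
                div, exp, measures=("H_E",), n_perm=499,
                rng=np.random.default_rng(rep),
            )
            merged_ct += set(factor) == {"exp", "ref+hol"}
        assert merged_ct >= 54  # >= 90%

    def test_shifted_class_blocks_merge(self):
        blocked = 0
        for rep in range(30):
            div, exp = self._setup(shift=0.3, seed=rep)  # 3 sd shift
            factor, report = merge_expansion_levels(
                div, exp, measures=("H_E",), n_perm=499,
                rng=np.random.default_rng(rep),
            )
            blocked += set(factor) == {"ref", "hol", "exp"}
        assert blocked == 30

    def test_missing_class_is_an_error(self):
        div, exp = self._setup()
        exp = exp.replace("exp", "hol")
        with pytest.raises(ValueError, match="three expansion classes"):
            merge_expansion_levels(div, exp)


class TestPredictorTable:
    def test_assembles_all_columns(self, rng):
        n = 20
        frame = pd.DataFrame(
            {
                "lat": np.linspace(44, 56, n) + rng.normal(0, 0.3, n),
                "lon": np.linspace(-2, 14, n) + rng.normal(0, 0.3, n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
                "bar": rng.integers(0, 2, n),
                "bio": rng.integers(0, 2, n),
                "size": rng.integers(0, 2, n),
                "expansion": ["ref"] * 7 + ["hol"] * 7 + ["exp"] * 6,
            },
            index=[f"S{i}" for i in range(n)],
        )
        pred = predictor_table(SiteTable(frame))
        for col in ("lim_km", "marg", "bar", "bio", "size", "expansion",
                    "lim_group", "marg_group"):
            assert col in pred.columns
        assert (pred["lim_km"] >= 0).all()
        assert (pred["marg"] >= 0).all()

    def test_order_invariance_of_lim_and_marg(self, rng):
        n = 15
        frame = pd.DataFrame(
            {
                "lat": rng.uniform(44, 56, n),
                "lon": rng.uniform(-2, 14, n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
                "expansion": "hol",
            },
            index=[f"S{i}" for i in range(n)],
        )
        p1 = predictor_table(SiteTable(frame))
        p2 = predictor_table(SiteTable(frame.iloc[::-1]))
        assert np.allclose(p1["lim_km"], p2["lim_km"].reindex(p1.index))
        assert np.allclose(p1["marg"], p2["marg"].reindex(p1.index))
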