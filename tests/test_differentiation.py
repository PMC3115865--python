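from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from conftest import make_genotypes

from rangediv.differentiation import (
    EARTH_RADIUS_KM,
    DistanceMatrix,
    category_fst_contrast,
    geo_distance_matrix,
    haplotype_fst,
    linearize_fst,
    mantel_test,
    minimum_spanning_tree,
    pairwise_fst,
    wc_fst,
)
from rangediv.popdata import GenotypeTable, HaplotypeTable, SiteTable
from rangediv.synth import simulate_mixed_mating_population


def dist(codes, values):
    return DistanceMatrix(codes=codes, values=np.asarray(values, float))


class TestWcFst:
    def test_fixed_different_alleles_give_theta_one(self):
        g = make_genotypes(
            {
                "AAA": [[(100, 100)] for _ in range(10)],
                "BBB": [[(104, 104)] for _ in range(10)],
            }
        )
        assert wc_fst(g) == pytest.approx(1.0)

    def test_one_population_split_in_two_gives_theta_near_zero(self):
        g = simulate_mixed_mating_population(100, 0.0, generations=0, seed=5)
        split = GenotypeTable(
            ids=g.ids, sites=["A"] * 50 + ["B"] * 50, loci=g.loci, calls=g.calls
        )
        assert abs(wc_fst(split)) < 0.02

    def test_invariant_to_allele_relabeling_and_site_order(self):
        g = simulate_mixed_mating_population(40, 0.0, generations=0, seed=11)
        split = GenotypeTable(
            ids=g.ids, sites=["A"] * 20 + ["B"] * 20, loci=g.loci, calls=g.calls
        )
        t1 = wc_fst(split)
        shifted = GenotypeTable(
            ids=split.ids, sites=split.sites, loci=split.loci,
            calls=np.where(split.calls > 0, split.calls + 40, 0),
        )
        assert wc_fst(shifted) == pytest.approx(t1, abs=1e-12)
        assert wc_fst(split, ["B", "A"]) == pytest.approx(t1, abs=1e-12)

    def test_no_usable_locus_returns_nan(self):
        g = make_genotypes(
            {"AAA": [[(100, 100)]] * 3, "BBB": [[(100, 100)]] * 3}
        )
        assert np.isnan(wc_fst(g))

    def test_requires_two_sites(self):
        g = make_genotypes({"AAA": [[(100, 102)]] * 3})
        with pytest.raises(ValueError):
            wc_fst(g)


class TestHaplotypeFst:
    def test_disjoint_monomorphic_sites_give_one(self):
        h = HaplotypeTable(counts={"A": {"h1": 10}, "B": {"h2": 10}})
        overall, _ = haplotype_fst(h)
        assert overall == pytest.approx(1.0)

    def test_identical_frequency_vectors_near_zero(self):
        h = HaplotypeTable(
            counts={
                "A": {"h1": 6, "h2": 4},
                "B": {"h1": 6, "h2": 4},
            }
        )
        overall, _ = haplotype_fst(h)
        assert overall < 0.05

    def test_random_split_of_pooled_site_near_zero(self, rng):
        # permutation oracle: pooled haplotypes split at random -> F_ST ~ 0
        pool = np.repeat(np.arange(6), [12, 8, 6, 5, 5, 4])
        vals = []
        for _ in range(40):
            perm = rng.permutation(pool)
            a, b = perm[:20], perm[20:]
            counts = {
                "A": {f"h{i}": int(c) for i, c in zip(*np.unique(a, return_counts=True))},
                "B": {f"h{i}": int(c) for i, c in zip(*np.unique(b, return_counts=True))},
            }
            overall, _ = haplotype_fst(HaplotypeTable(counts=counts))
            vals.append(overall)
        assert abs(np.mean(vals)) < 0.03


class TestLinearize:
    @pytest.mark.parametrize(
        "f,expected", [(0.5, 1.0), (0.0, 0.0), (-0.1, 0.0), (0.368, 0.582)]
    )
    def test_elementwise_transform_with_clamping(self, f, expected):
        m = dist(["a", "b"], [[0, f], [f, 0]])
        assert linearize_fst(m).values[0, 1] == pytest.approx(expected, abs=1e-3)


class TestGeoDistance:
    def _sites(self, rows):
        return SiteTable(
            pd.DataFrame(rows, columns=["lat", "lon"], index=list("abc")[: len(rows)])
        )

    def test_identical_coordinates_give_zero(self):
        m = geo_distance_matrix(self._sites([[50, 8], [50, 8]]))
        assert m.values[0, 1] == pytest.approx(0.0)

    def test_one_degree_longitude_at_equator(self):
        m = geo_distance_matrix(self._sites([[0, 0], [0, 1]]))
        assert m.values[0, 1] == pytest.approx(2 * np.pi * EARTH_RADIUS_KM / 360, rel=1e-6)

    def test_antipodal_points(self):
        m = geo_distance_matrix(self._sites([[0, 0], [0, 180]]))
        assert m.values[0, 1] == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-6)


class TestMantel:
    def _pair(self, rng, n=12):
        pts = rng.random((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        return dist([f"S{i}" for i in range(n)], (d + d.T) / 2)

    def test_perfect_linear_relation(self, rng):
        x = self._pair(rng)
        y = DistanceMatrix(codes=list(x.codes), values=2 * x.values + 3 * (x.values > 0))
        r, p = mantel_test(x, y, n_perm=199, rng=rng)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_negated_matrix_one_sided_p_near_one(self, rng):
        x = self._pair(rng)
        y = DistanceMatrix(codes=list(x.codes), values=-x.values)
        r, p = mantel_test(x, y, n_perm=199, rng=rng)
        assert r == pytest.approx(-1.0)
        assert p > 0.95

    def test_constant_matrix_rejected(self, rng):
        x = self._pair(rng)
        y = DistanceMatrix(codes=list(x.codes), values=np.zeros_like(x.values))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(x, y, rng=rng)

    def test_agrees_with_independent_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        x, y = self._pair(rng), self._pair(rng)
        r, _ = mantel_test(x, y, n_perm=99, rng=rng)
        r_ref = skbio_mantel(
            SkbioDM(x.values, ids=x.codes),
            SkbioDM(y.values, ids=y.codes),
            permutations=0,
        )[0]
        assert r == pytest.approx(float(r_ref), abs=1e-10)


def brute_force_mst_weight(values):
    """Oracle: minimum total weight over all spanning trees (n <= 7)."""
    n = len(values)
    edges = list(combinations(range(n), 2))
    best = np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(values[a, b] for a, b in subset))
    return best


class TestMst:
    def test_three_site_example(self):
        m = dist(["A", "B", "C"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        edges = {(a, b) for a, b, _ in minimum_spanning_tree(m)}
        assert edges == {("A", "B"), ("A", "C")}

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            n = 6
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            m = dist([f"S{i}" for i in range(n)], v)
            mst = minimum_spanning_tree(m)
            assert len(mst) == n - 1
            total = sum(w for *_, w in mst)
            assert total == pytest.approx(brute_force_mst_weight(v), abs=1e-12)

    def test_constant_shift_leaves_edge_set_unchanged(self, rng):
        n = 7
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m1 = dist([f"S{i}" for i in range(n)], v)
        shifted = v + 5.0
        np.fill_diagonal(shifted, 0)
        m2 = dist([f"S{i}" for i in range(n)], shifted)
        e1 = {(a, b) for a, b, _ in minimum_spanning_tree(m1)}
        e2 = {(a, b) for a, b, _ in minimum_spanning_tree(m2)}
        assert e1 == e2

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValueError):
            minimum_spanning_tree(dist(["A"], [[0.0]]))


class TestCategoryContrast:
    def test_constructed_within_category_signal_detected(self, rng):
        n = 42
        v = 0.1 + 0.05 * rng.random((n, n))
        v = (v + v.T) / 2
        cats = rng.choice(n, size=12, replace=False)
        for i in cats:
            for j in cats:
                if i != j:
                    v[i, j] += 0.2
        np.fill_diagonal(v, 0)
        m = dist([f"S{i}" for i in range(n)], v)
        res = category_fst_contrast(
            m, [f"S{i}" for i in cats], n_perm=999, rng=rng
        )
        assert res.observed_diff > 0.15
        assert res.p_one_sided <= 0.01

    def test_category_of_all_but_one_site_rejected(self, rng):
        n = 6
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = dist([f"S{i}" for i in range(n)], v)
        with pytest.raises(ValueError, match="each side"):
            category_fst_contrast(m, [f"S{i}" for i in range(n - 1)], rng=rng)

    def test_p_resolution_matches_permutation_count(self, rng):
        n = 14
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = dist([f"S{i}" for i in range(n)], v)
        res = category_fst_contrast(m, [f"S{i}" for i in range(5)], n_perm=199, rng=rng)
        assert 0 < res.p_one_sided <= 1
        assert res.p_one_sided * 200 == pytest.approx(round(res.p_one_sided * 200))
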