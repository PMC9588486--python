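"""Tests for the topological pipeline: complexes, KDE, persistence,
bottleneck distance and the cloud-comparison machinery.

Persistence is cross-checked against a brute-force oracle that recomputes
barcodes from persistent Betti numbers via F2 linear algebra on every
sub-level complex; the bottleneck distance against exhaustive matching
enumeration.
"""

import numpy as np
import pytest

from _oracles import brute_barcode, brute_bottleneck
from erkin.tda import (
    Barcode,
    DensityEstimate,
    Filtration,
    SimplicialComplex,
    bobrowski_bound,
    bottleneck,
    compare_variants,
    density_filtration,
    empirical_pvalue,
    kde_evaluate,
    persistent_homology,
    ph_of_cloud,
    select_bandwidth,
    vietoris_rips,
)

INF = float("inf")


def random_lower_star_filtration(rng, n_pts=6, dim=2):
    """A small Vietoris–Rips complex filtered by random vertex values."""
    pts = rng.random((n_pts, 2))
    b = float(rng.uniform(0.3, 0.9))
    complex_ = vietoris_rips(pts, b, max_dim=dim)
    vert_vals = rng.integers(0, 4, n_pts).astype(float)
    values = {s: float(np.max(vert_vals[list(s)])) for s in complex_.simplices}
    return Filtration(complex_, values)


class TestComplexes:
    def test_faces_required(self):
        with pytest.raises(ValueError):
            SimplicialComplex([(0,), (1,), (0, 1, 2)])

    def test_collinear_rips(self):
        c = vietoris_rips(np.array([[0.0], [1.0], [2.0]]), 1.0, max_dim=2)
        assert set(c.simplices) == {(0,), (1,), (2,), (0, 1), (1, 2)}

    def test_full_simplex_at_large_scale(self):
        pts = np.random.default_rng(0).random((4, 2))
        c = vietoris_rips(pts, 10.0, max_dim=3)
        assert len(c.simplices) == 15  # 2^4 - 1 subsets

    def test_zero_scale_gives_vertices_only(self):
        pts = np.random.default_rng(0).random((5, 2))
        c = vietoris_rips(pts, 0.0, max_dim=2)
        assert all(len(s) == 1 for s in c.simplices)

    def test_filtration_must_be_monotone(self):
        c = SimplicialComplex([(0,), (1,), (0, 1)])
        with pytest.raises(ValueError):
            Filtration(c, {(0,): 1.0, (1,): 1.0, (0, 1): 0.0})


class TestKDE:
    def test_epanechnikov_peak_1d(self):
        est = DensityEstimate(np.array([[0.0]]), 1.0)
        assert kde_evaluate(est, np.array([0.0])) == pytest.approx(0.75)

    def test_compact_support(self, rng):
        est = DensityEstimate(rng.random((10, 2)), 0.5)
        far = np.full((1, 2), 100.0)
        assert kde_evaluate(est, far)[0] == 0.0

    def test_integrates_to_one_2d(self, rng):
        est = DensityEstimate(rng.random((6, 2)), 0.7)
        g = np.linspace(-1.0, 2.0, 220)
        xx, yy = np.meshgrid(g, g)
        vals = est.evaluate(np.column_stack([xx.ravel(), yy.ravel()]))
        integral = vals.sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, abs=5e-3)

    def test_matches_reference_implementation(self, rng):
        """scikit-learn's Epanechnikov KDE is an independent oracle."""
        sklearn = pytest.importorskip("sklearn.neighbors")
        pts = rng.normal(size=(40, 3))
        b = 0.9
        est = DensityEstimate(pts, b)
        ref = sklearn.KernelDensity(kernel="epanechnikov", bandwidth=b).fit(pts)
        x = rng.normal(size=(25, 3))
        assert np.allclose(est.evaluate(x), np.exp(ref.score_samples(x)), atol=1e-12)


class TestBandwidth:
    def test_scale_equivariance(self, rng):
        pts = rng.normal(size=(60, 2))
        b1 = select_bandwidth(pts, seed=3)
        b2 = select_bandwidth(10.0 * pts, seed=3)
        assert b2 == pytest.approx(10.0 * b1, rel=1e-9)

    def test_shrinks_with_sample_size(self, rng):
        small = select_bandwidth(rng.normal(size=(60, 2)), seed=0)
        large = select_bandwidth(rng.normal(size=(700, 2)), seed=0)
        assert large < small

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.zeros((10, 2)))


class TestDensityFiltration:
    def test_simplex_value_is_negated_min_density(self, rng):
        pts = rng.random((8, 2))
        est = DensityEstimate(pts, 0.8)
        complex_ = vietoris_rips(pts, 0.8, max_dim=2)
        filt = density_filtration(complex_, est)
        dens = est.evaluate(pts)
        for s in complex_.simplices:
            assert filt.values[s] == pytest.approx(-np.min(dens[list(s)]))

    def test_monotone_by_construction(self, rng):
        from itertools import combinations

        pts = rng.random((10, 2))
        est = DensityEstimate(pts, 0.6)
        filt = density_filtration(vietoris_rips(pts, 0.6, 2), est)
        for s, v in filt.values.items():
            for face in combinations(s, len(s) - 1):
                if face:
                    assert filt.values[face] <= v + 1e-12


class TestPersistence:
    def test_single_vertex(self):
        f = Filtration(SimplicialComplex([(0,)]), {(0,): 0.0})
        assert persistent_homology(f, 0)[0].bars == [(0.0, INF)]

    def test_merge_kills_younger_component(self):
        f = Filtration(
            SimplicialComplex([(0,), (1,), (0, 1)]),
            {(0,): 0.0, (1,): 0.0, (0, 1): 1.0},
        )
        bc = persistent_homology(f, 1)
        assert bc[0].bars == [(0.0, 1.0), (0.0, INF)]
        assert bc[1].bars == []

    def test_hollow_triangle_has_a_loop(self):
        tri = SimplicialComplex([(0,), (1,), (2,), (0, 1), (0, 2), (1, 2)])
        f = Filtration(
            tri, {(0,): 0, (1,): 0, (2,): 0, (0, 1): 1, (0, 2): 1, (1, 2): 1}
        )
        bc = persistent_homology(f, 1)
        assert bc[1].bars == [(1.0, INF)]

    def test_against_betti_number_oracle(self, rng):
        """Interval decomposition must match the inclusion-exclusion of
        persistent Betti numbers on random small filtrations."""
        for _ in range(25):
            filt = random_lower_star_filtration(rng)
            mine = persistent_homology(filt, 1)
            for k in (0, 1):
                assert sorted(mine[k].bars) == brute_barcode(filt, k)


class TestBottleneck:
    def test_identical_barcodes(self):
        b = Barcode(0, [(0.0, 1.0), (0.5, 2.0)])
        assert bottleneck(b, Barcode(0, [(0.0, 1.0), (0.5, 2.0)])) == 0.0

    def test_unmatched_bar_pays_half_persistence(self):
        assert bottleneck(Barcode(0, [(0.0, 10.0)]), Barcode(0, [])) == 5.0

    def test_essential_bars_only_match_essential(self):
        a = Barcode(0, [(0.0, INF)])
        b = Barcode(0, [(2.0, INF)])
        assert bottleneck(a, b) == 2.0
        assert bottleneck(a, Barcode(0, [(0.0, 5.0)])) == INF

    def test_against_exhaustive_matching(self, rng):
        for _ in range(60):
            na, nb = rng.integers(0, 5), rng.integers(0, 5)
            def mk(n):
                bars = []
                for _ in range(n):
                    b0 = float(rng.uniform(0, 5))
                    d0 = b0 + float(rng.uniform(0, 5))
                    if rng.random() < 0.15:
                        d0 = INF
                    bars.append((b0, d0))
                return bars
            ba, bb = mk(na), mk(nb)
            assert bottleneck(Barcode(0, ba), Barcode(0, bb)) == pytest.approx(
                brute_bottleneck(ba, bb)
            )

    def test_metric_axioms_on_random_triples(self, rng):
        def mk():
            bars = []
            for _ in range(int(rng.integers(1, 4))):
                b0 = float(rng.uniform(0, 3))
                bars.append((b0, b0 + float(rng.uniform(0, 3))))
            return Barcode(0, bars)

        for _ in range(30):
            x, y, z = mk(), mk(), mk()
            dxy, dyx = bottleneck(x, y), bottleneck(y, x)
            assert dxy == pytest.approx(dyx)
            assert dxy <= bottleneck(x, z) + bottleneck(z, y) + 1e-12

    def test_stability_under_filtration_perturbation(self, rng):
        """Perturbing the filtering function moves the barcode by at most
        the sup-norm of the perturbation."""
        for _ in range(30):
            filt = random_lower_star_filtration(rng)
            eps = rng.uniform(0.05, 0.5)
            noise = {v: float(rng.uniform(-eps, eps)) for v in filt.complex.vertices}
            values2 = {}
            for s in filt.complex.simplices:
                values2[s] = max(
                    filt.values[(v,)] + noise[v] for v in s
                )
            filt2 = Filtration(filt.complex, values2)
            sup = max(
                abs(filt.values[s] - values2[s]) for s in filt.complex.simplices
            )
            for k in (0, 1):
                b1 = persistent_homology(filt, k)[k]
                b2 = persistent_homology(filt2, k)[k]
                assert bottleneck(b1, b2) <= sup + 1e-9


class TestSamplingBound:
    def test_eta_star_ceiling(self):
        # p_max = 1, eta = 0.25: eta* = ceil(1/0.5) = 2 enters the bound
        val = bobrowski_bound(0.25, 10, 0.5, 2, 1.0)
        import math

        assert math.ceil(1.0 / (2 * 0.25)) == 2
        assert 0.0 <= val <= 1.0

    def test_large_samples_guarantee_recovery(self):
        assert bobrowski_bound(0.25, 10**9, 0.5, 2, 1.0) == pytest.approx(1.0)

    def test_monotone_beyond_turning_point(self):
        eta, b, m, p_max = 0.25, 0.5, 2, 1.0
        c_eta = (eta / 2) ** 2 / (3 * p_max + eta / 2)
        n_turn = int(1.0 / (c_eta * b**m)) + 1
        vals = [bobrowski_bound(eta, n, b, m, p_max) for n in
                np.linspace(n_turn, 20 * n_turn, 12, dtype=int)]
        assert all(x <= y + 1e-15 for x, y in zip(vals, vals[1:]))


class TestCloudPipeline:
    def test_unimodal_cloud_has_one_dominant_mode(self, rng):
        cloud = 0.3 * rng.normal(size=(200, 3))
        h0 = ph_of_cloud(cloud, k_max=0)[0]
        pers = sorted((d - b for b, d in h0.bars), reverse=True)
        assert pers[0] > 5.0 * pers[1]

    def test_translation_invariance(self, rng):
        cloud = 0.3 * rng.normal(size=(150, 3))
        a = ph_of_cloud(cloud, k_max=1)
        b = ph_of_cloud(cloud + np.array([5.0, -3.0, 2.0]), k_max=1)
        for x, y in zip(a, b):
            assert np.allclose(np.array(x.bars), np.array(y.bars))

    def test_two_separated_modes(self, rng):
        cloud = np.vstack(
            [0.2 * rng.normal(size=(100, 3)), 0.2 * rng.normal(size=(100, 3)) + 4.0]
        )
        h0 = ph_of_cloud(cloud, k_max=0)[0]
        pers = sorted((d - b for b, d in h0.bars), reverse=True)
        assert pers[1] > 5.0 * (pers[2] if len(pers) > 2 else 1e-12)


class TestEmpiricalPValue:
    def test_self_comparison_is_null(self, rng):
        cloud = 0.3 * rng.normal(size=(120, 3))

        def sampler(r, n):
            return cloud[r.choice(len(cloud), n, replace=False)]

        d, p = empirical_pvalue(
            cloud, cloud, sampler, sampler, beta=19, n=100, k=0, seed=0
        )
        assert d == 0.0
        assert p == 1.0

    def test_pvalue_range(self, rng):
        a = 0.3 * rng.normal(size=(120, 3))
        b = 0.05 * rng.normal(size=(120, 3))

        def mk(cloud):
            def sampler(r, n):
                return cloud[r.choice(len(cloud), n, replace=False)]
            return sampler

        d, p = empirical_pvalue(a, b, mk(a), mk(b), beta=19, n=100, k=0, seed=0)
        assert d > 0
        assert 1 / 20 <= p <= 1.0

    def test_beta_floor(self, rng):
        a = rng.normal(size=(50, 3))
        with pytest.raises(ValueError):
            empirical_pvalue(a, a, None, None, beta=5)


class TestCompareVariants:
    def test_matrix_structure(self, rng):
        clouds = {
            "a": 0.3 * rng.normal(size=(300, 3)),
            "b": 0.3 * rng.normal(size=(300, 3)) + 1.0,
            "c": 0.05 * rng.normal(size=(300, 3)),
        }
        labels, dmat, pmat = compare_variants(clouds, beta=19, n=120, k=0, seed=0)
        assert np.allclose(dmat, dmat.T) and np.allclose(pmat, pmat.T)
        assert np.all(np.diag(dmat) == 0) and np.all(np.diag(pmat) == 1)
        # the tight cloud c has a far taller density peak: it is the outlier
        ci = labels.index("c")
        others = [i for i in range(len(labels)) if i != ci]
        off_diag_c = dmat[ci, others]
        within_others = dmat[np.ix_(others, others)]
        assert off_diag_c.min() > within_others.max()
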