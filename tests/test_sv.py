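"""Local-PCA windows, MDS, clustering, region calling and genotyping."""

import numpy as np
import pytest

from hybridscan.sv import (
    WindowSummary,
    choose_k_silhouette,
    classical_mds,
    ld_heatmap,
    outlier_regions,
    region_pca_genotype,
    window_distance,
    window_distance_matrix,
    window_summaries,
)
from conftest import make_matrix


def random_summary(rng, n_ind=15, ordinal=0):
    q, _ = np.linalg.qr(rng.normal(size=(n_ind, 2)))
    lam = np.sort(np.abs(rng.normal(size=2)))[::-1]
    return WindowSummary("chr1", ordinal * 100 + 1, (ordinal + 1) * 100, ordinal, lam, q, 10)


def explicit_frobenius(a, b):
    """Oracle: materialise the rank-2 reconstructions and take the norm."""
    pa = a.eigenvectors @ np.diag(a.eigenvalues) @ a.eigenvectors.T
    pb = b.eigenvectors @ np.diag(b.eigenvalues) @ b.eigenvectors.T
    return np.linalg.norm(pa - pb)


class TestWindowSummaries:
    def _matrix(self, states, positions):
        return make_matrix(states, positions=positions)

    def test_eigenpairs_match_dense_oracle(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 3, size=(12, 20)).astype(float)
        m = self._matrix(states, positions=np.arange(20) * 1000 + 1)
        (w,) = window_summaries(m, "chr1", window_bp=100_000)
        x = states - states.mean(axis=0)
        cov = x @ x.T / 20
        lam, vec = np.linalg.eigh(cov)
        np.testing.assert_allclose(w.eigenvalues, lam[::-1][:2], atol=1e-8)
        for k in range(2):
            dot = abs(vec[:, ::-1][:, k] @ w.eigenvectors[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_identical_submatrices_identical_summaries(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(10, 8)).astype(float)
        states = np.hstack([block, block])
        pos = np.concatenate([np.arange(8) * 1000 + 1, 100_001 + np.arange(8) * 1000])
        m = self._matrix(states, positions=pos)
        w1, w2 = window_summaries(m, "chr1", window_bp=100_000)
        np.testing.assert_allclose(w1.eigenvalues, w2.eigenvalues, atol=1e-10)

    def test_constant_window_skipped(self):
        states = np.ones((8, 6))
        m = self._matrix(states, positions=np.arange(6) * 1000 + 1)
        assert window_summaries(m, "chr1", window_bp=100_000) == []

    def test_sparse_window_skipped(self):
        rng = np.random.default_rng(2)
        states = rng.integers(0, 3, size=(8, 3)).astype(float)
        m = self._matrix(states, positions=np.arange(3) * 1000 + 1)
        assert window_summaries(m, "chr1", window_bp=100_000, min_loci=5) == []

    def test_missing_data_mean_imputed(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 3, size=(10, 8)).astype(float)
        states[0, 0] = np.nan
        m = self._matrix(states, positions=np.arange(8) * 1000 + 1)
        (w,) = window_summaries(m, "chr1", window_bp=100_000)
        assert np.isfinite(w.eigenvalues).all()


class TestWindowDistance:
    def test_self_distance_zero(self):
        a = random_summary(np.random.default_rng(0))
        assert window_distance(a, a) == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_rank_one_distance(self):
        v1 = np.zeros((4, 2))
        v1[0, 0] = 1.0
        v1[1, 1] = 1.0
        v2 = np.zeros((4, 2))
        v2[2, 0] = 1.0
        v2[3, 1] = 1.0
        a = WindowSummary("c", 1, 2, 0, np.array([1.0, 0.0]), v1, 5)
        b = WindowSummary("c", 3, 4, 1, np.array([1.0, 0.0]), v2, 5)
        assert window_distance(a, b) == pytest.approx(np.sqrt(2.0))

    def test_identity_form_matches_explicit_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = random_summary(rng)
            b = random_summary(rng)
            assert window_distance(a, b) == pytest.approx(
                explicit_frobenius(a, b), abs=1e-10
            )
            assert window_distance(a, b) == pytest.approx(window_distance(b, a))

    def test_mismatched_individual_sets_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            window_distance(random_summary(rng, 10), random_summary(rng, 12))


class TestClassicalMds:
    def test_collinear_points_recovered_on_first_axis(self):
        d = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        coords = classical_mds(d)
        x = coords[:, 0]
        assert abs(x[1] - x[0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(x[2] - x[1]) == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(coords[:, 1], 0.0, atol=1e-8)

    def test_zero_distances_zero_coordinates(self):
        coords = classical_mds(np.zeros((4, 4)))
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)

    def test_exact_euclidean_configuration_reconstructed(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(d)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1], [2, 0]]))


class TestChooseKSilhouette:
    def _clouds(self, centers, n=20, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return np.vstack(
            [c + spread * rng.normal(size=(n, 2)) for c in np.asarray(centers, float)]
        )

    def test_two_separated_clouds(self):
        coords = self._clouds([[0, 0], [10, 0]])
        k, labels = choose_k_silhouette(coords, seed=0)
        assert k == 2

    def test_four_separated_clouds(self):
        coords = self._clouds([[0, 0], [10, 0], [0, 10], [10, 10]])
        k, labels = choose_k_silhouette(coords, seed=0)
        assert k == 4
        assert len(np.unique(labels)) == 4

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            choose_k_silhouette(np.ones((20, 2)), seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            choose_k_silhouette(np.random.default_rng(0).normal(size=(5, 2)))


class TestOutlierRegions:
    def _windows(self, n, chrom="chr1"):
        return [
            WindowSummary(chrom, i * 100 + 1, (i + 1) * 100, i, np.ones(2), np.eye(2), 5)
            for i in range(n)
        ]

    def test_long_run_called_as_one_region(self):
        scores = np.zeros(50)
        scores[10:22] = 5.0
        regs = outlier_regions(scores, self._windows(50))
        assert len(regs) == 1
        assert regs[0].window_ordinals == list(range(10, 22))

    def test_nine_consecutive_not_enough(self):
        scores = np.zeros(50)
        scores[10:19] = 5.0
        assert outlier_regions(scores, self._windows(50)) == []

    def test_alternating_outliers_no_region(self):
        scores = np.zeros(60)
        scores[::2] = 4.0
        assert outlier_regions(scores, self._windows(60)) == []

    def test_gap_in_window_ordinals_breaks_run(self):
        scores = np.zeros(40)
        scores[5:20] = 5.0
        windows = self._windows(40)
        windows = windows[:12] + windows[13:]  # drop one window inside the run
        scores = np.delete(scores, 12)
        regs = outlier_regions(scores, windows, min_run=10)
        assert regs == []  # runs of 7 and 7 remain

    def test_zero_variance_no_regions(self):
        regs = outlier_regions(np.ones(20), self._windows(20))
        assert regs == []


class TestRegionGenotype:
    def test_three_planted_clusters_recovered(self):
        rng = np.random.default_rng(7)
        n_loci = 30
        karyo = np.repeat([0, 1, 2], [20, 30, 25])
        states = np.empty((75, n_loci))
        for i, k in enumerate(karyo):
            base = {0: 0.0, 1: 1.0, 2: 2.0}[k]
            states[i] = base
            flip = rng.random(n_loci) < 0.05
            states[i, flip] = rng.integers(0, 3, flip.sum())
        m = make_matrix(states, positions=np.arange(n_loci) * 100 + 1)
        g = region_pca_genotype(m, "chr1", 1, 10_000, seed=0)
        assert (g.labels == karyo).mean() >= 0.95
        het = g.summary.set_index("cluster")["region_heterozygosity"]
        assert het[1] == het.max()

    def test_two_cluster_cohort_flagged_collapsed(self):
        karyo = np.repeat([0, 2], [30, 30])
        states = np.tile(np.where(karyo == 0, 0.0, 2.0)[:, None], (1, 25))
        m = make_matrix(states, positions=np.arange(states.shape[1]) * 100 + 1)
        g = region_pca_genotype(m, "chr1", 1, 10_000, seed=0)
        # parental-only cohort: no central heterokaryotype cluster exists
        assert g.collapsed

    def test_labels_invariant_to_individual_order(self):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 3, size=(40, 12)).astype(float)
        m = make_matrix(states, positions=np.arange(12) * 100 + 1)
        g1 = region_pca_genotype(m, "chr1", 1, 10_000, seed=0)
        perm = rng.permutation(40)
        g2 = region_pca_genotype(m.subset_individuals(perm), "chr1", 1, 10_000, seed=0)
        assert (g1.labels[perm] == g2.labels).all()


class TestLdHeatmap:
    def test_maf_boundary_inclusive(self):
        # locus 1 has minor-state frequency exactly 0.05
        states = np.zeros((20, 2))
        states[:10, 0] = 2.0
        states[0, 1] = 2.0
        m = make_matrix(states)
        tab = ld_heatmap(m, maf_min=0.05)
        present = set(tab["pos_i"]) | set(tab["pos_j"])
        assert present == {1000, 2000}

    def test_thinning_to_one_locus_gives_empty_pairs(self):
        rng = np.random.default_rng(10)
        states = rng.integers(0, 3, size=(30, 5)).astype(float)
        m = make_matrix(states)
        tab = ld_heatmap(m, thin_bp=10_000_000)
        assert tab.empty

    def test_empty_subset_rejected(self):
        m = make_matrix([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            ld_heatmap(m, individuals=np.array([], dtype=int))
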