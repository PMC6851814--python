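"""Log-IEI distributions, symmetric KL divergence, distance matrices, MDS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import rhythmkit as rk
from rhythmkit.distributions import DistanceMatrix, LogIEIDistribution


def _dist(probs, lo=-1.0, hi=0.0, label=""):
    probs = np.asarray(probs, float)
    edges = np.linspace(lo, hi, probs.size + 1)
    return LogIEIDistribution(edges, probs / probs.sum(), probs.size, 0.0, label=label)


class TestLogIEIDistribution:
    def test_point_mass_occupies_single_bin(self, iso_clean):
        d = rk.log_iei_distribution(rk.intervals(iso_clean), smoothing=0.0)
        assert np.sum(d.probs > 0) == 1
        mode_bin = np.argmax(d.probs)
        assert d.bin_edges[mode_bin] <= np.log10(0.2) <= d.bin_edges[mode_bin + 1]

    def test_probs_sum_to_one_and_are_positive_after_smoothing(self, synthetic_trio_dists):
        for d in synthetic_trio_dists:
            assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(d.probs > 0)

    def test_shared_grid_spans_pooled_range(self, synthetic_trio_dists):
        grids = [d.bin_edges for d in synthetic_trio_dists]
        for g in grids[1:]:
            np.testing.assert_array_equal(g, grids[0])

    def test_jittered_isochronous_has_single_mode_at_the_period(self, synthetic_trio_dists):
        iso = synthetic_trio_dists[0]
        assert rk.count_modes(iso) == 1
        mode_bin = np.argmax(iso.probs)
        assert iso.bin_edges[mode_bin] <= np.log10(0.2) <= iso.bin_edges[mode_bin + 1]

    def test_hierarchical_series_has_three_modes_at_the_three_gaps(self, synthetic_trio_dists):
        hier = synthetic_trio_dists[1]
        assert rk.count_modes(hier) == 3
        locs = rk.mode_locations(hier)
        for truth, found in zip((0.05, 0.20, 0.60), locs):
            assert found == pytest.approx(truth, rel=0.25)

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            rk.log_iei_distribution(np.array([0.2, -0.1]))

    def test_shuffling_intervals_leaves_distribution_unchanged(self, poisson_10s):
        vals = rk.intervals(poisson_10s).values
        rng = np.random.default_rng(0)
        a = rk.log_iei_distribution(vals, range=(-3, 0))
        b = rk.log_iei_distribution(rng.permutation(vals), range=(-3, 0))
        np.testing.assert_array_equal(a.probs, b.probs)


class TestCountModes:
    def test_exhaustive_hand_case(self):
        d = _dist([0.1, 0.3, 0.1, 0.3, 0.2])
        assert rk.count_modes(d, min_prominence=0.05) == 2

    def test_point_mass_counts_one(self):
        d = _dist([0.001, 0.996, 0.001, 0.001, 0.001])
        assert rk.count_modes(d) == 1

    def test_prominence_threshold_suppresses_minor_bumps(self):
        d = _dist([0.1, 0.5, 0.1, 0.12, 0.1])  # second bump prominence 0.02 < 5% of max
        assert rk.count_modes(d, min_prominence=0.05) == 1


class TestSKLDivergence:
    def test_identity_gives_zero(self, synthetic_trio_dists):
        for d in synthetic_trio_dists:
            assert rk.skl_divergence(d, d) == 0.0

    def test_hand_oracle_two_bin_pair(self):
        p, q = _dist([0.5, 0.5]), _dist([0.9, 0.1])
        # KL(p||q) + KL(q||p) evaluated by hand = 0.8789 nats
        assert rk.skl_divergence(p, q) == pytest.approx(0.8789, abs=1e-3)

    def test_symmetry(self, synthetic_trio_dists):
        a, b = synthetic_trio_dists[0], synthetic_trio_dists[2]
        assert rk.skl_divergence(a, b) == rk.skl_divergence(b, a)
        assert rk.skl_divergence(a, b) > 0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            rk.skl_divergence(_dist([0.5, 0.5]), _dist([0.5, 0.5], lo=-2.0))

    def test_divergence_grows_as_periods_move_apart(self):
        # enough jitter for the histograms to overlap, so the divergence
        # tracks the widening separation instead of saturating
        periods = [0.2, 0.25, 0.3, 0.4]
        series = [
            rk.gen_isochronous(rk.IsochronousSpec(p, 50.0, 0.02, 20 + i))
            for i, p in enumerate([0.2] + periods)
        ]
        dists = rk.log_iei_distribution(
            [rk.intervals(s) for s in series],
            labels=["ref"] + [f"p{p}" for p in periods],
        )
        skl = [rk.skl_divergence(dists[0], d) for d in dists[1:]]
        assert np.all(np.diff(skl) > 0)


class TestPairwiseDistances:
    def test_unique_distance_count(self, synthetic_trio_dists):
        dm = rk.pairwise_distances(synthetic_trio_dists)
        assert dm.n_unique == 3
        assert dm.d.shape == (3, 3)
        np.testing.assert_array_equal(dm.d, dm.d.T)
        np.testing.assert_array_equal(np.diag(dm.d), 0)

    def test_identical_distributions_give_zero_matrix(self):
        a, b = _dist([0.3, 0.7], label="a"), _dist([0.3, 0.7], label="b")
        dm = rk.pairwise_distances([a, b])
        np.testing.assert_array_equal(dm.d, np.zeros((2, 2)))

    def test_duplicate_labels_rejected(self):
        a, b = _dist([0.3, 0.7], label="x"), _dist([0.5, 0.5], label="x")
        with pytest.raises(ValueError, match="unique"):
            rk.pairwise_distances([a, b])


class TestMDSEmbed:
    def test_metric_triangle_embeds_exactly(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        emb = rk.mds_embed(dm, seed=0)
        np.testing.assert_allclose(np.sort(pdist(emb.points)), [3, 4, 5], rtol=0.01)
        assert emb.stress < 1e-3

    def test_duplicated_dataset_stays_coincident(self):
        d = np.array(
            [[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]]
        )
        emb = rk.mds_embed(DistanceMatrix(("a", "a2", "b"), d), seed=0)
        diam = pdist(emb.points).max()
        assert np.linalg.norm(emb.points[0] - emb.points[1]) < 0.01 * diam

    def test_all_zero_matrix_gives_coincident_points(self):
        emb = rk.mds_embed(DistanceMatrix(("a", "b"), np.zeros((2, 2))), seed=0)
        assert emb.stress == 0.0
        np.testing.assert_array_equal(emb.points, 0)
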