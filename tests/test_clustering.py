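import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dfstates.clustering import (
    dan_dmn_fc,
    davies_bouldin_correlation,
    homotopic_fc,
    kmeans_correlation,
    modularity_signed,
    select_k,
    state_biomarkers,
    state_sequence,
    _standardize_rows,
)


def planted_rows(rng, n_per, patterns, noise=0.05):
    rows, labels = [], []
    for k, p in enumerate(patterns):
        for _ in range(n_per):
            rows.append(p + noise * rng.standard_normal(p.size))
            labels.append(k)
    return np.asarray(rows), np.asarray(labels)


class TestKMeansCorrelation:
    def test_two_orthogonal_patterns_perfectly_separated(self, rng):
        p1 = np.concatenate([np.ones(10), -np.ones(10)])
        p2 = np.concatenate([-np.ones(10), np.ones(10)]) * np.linspace(0.5, 2, 20)
        F, truth = planted_rows(rng, 40, [p1, p2])
        model = kmeans_correlation(F, 2, replicates=5, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0
        assert set(model.assignments) == {1, 2}

    def test_identical_rows_up_to_scale_do_not_crash(self, rng):
        base = rng.standard_normal(15)
        F = np.outer(np.abs(rng.random(30)) + 0.1, base)
        model = kmeans_correlation(F, 2, replicates=3, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_row_rejected(self, rng):
        F = rng.standard_normal((10, 8))
        F[3] = 2.5
        with pytest.raises(ValueError, match="3"):
            kmeans_correlation(F, 2)

    def test_invariant_to_positive_row_rescaling(self, rng):
        F, _ = planted_rows(
            rng, 20, [rng.standard_normal(12) for _ in range(3)], noise=0.2
        )
        scaled = F * rng.uniform(0.5, 5.0, size=F.shape[0])[:, None]
        m1 = kmeans_correlation(F, 3, replicates=5, seed=7)
        m2 = kmeans_correlation(scaled, 3, replicates=5, seed=7)
        assert adjusted_rand_score(m1.assignments, m2.assignments) == 1.0

    def test_best_replicate_has_lowest_inertia(self, rng):
        F, _ = planted_rows(rng, 15, [rng.standard_normal(10) for _ in range(2)])
        model = kmeans_correlation(F, 2, replicates=10, seed=1)
        assert model.inertia == pytest.approx(model.replicate_inertias.min())


class TestStateSequence:
    def test_rows_equal_centroids_map_to_their_state(self, rng):
        F, _ = planted_rows(rng, 20, [rng.standard_normal(10) for _ in range(3)])
        model = kmeans_correlation(F, 3, replicates=5, seed=2)
        # noise-free centroid copies (any positive scaling) land on that state
        seq = state_sequence(model, 3.7 * model.centroids)
        np.testing.assert_array_equal(seq, [1, 2, 3])

    def test_assignment_matches_training_labels(self, rng):
        F, _ = planted_rows(rng, 25, [rng.standard_normal(10) for _ in range(2)])
        model = kmeans_correlation(F, 2, replicates=5, seed=3)
        np.testing.assert_array_equal(state_sequence(model, F), model.assignments)

    def test_equidistant_tie_breaks_to_lowest_state(self):
        c1 = np.array([1.0, 0.0, -1.0, 0.0])
        c2 = np.array([0.0, 1.0, 0.0, -1.0])
        F = np.vstack([c1, c2, c1, c2, c1, c2])
        model = kmeans_correlation(F, 2, replicates=3, seed=0)
        probe = _standardize_rows((c1 + c2)[None, :] if False else (c1 + c2)[None, :])
        # the probe is exactly equidistant from both centroids
        seq = state_sequence(model, (c1 + c2)[None, :])
        assert seq[0] == 1


class TestSelectK:
    def test_planted_two_clusters(self, rng):
        F, _ = planted_rows(rng, 50, [rng.standard_normal(15) for _ in range(2)], 0.3)
        table, k_rec, models = select_k(F, k_range=(2, 5), replicates=5, seed=0)
        assert k_rec == 2
        assert table.loc[table["k"] == 2, "silhouette"].iloc[0] > 0.5

    def test_planted_five_clusters(self, rng):
        pats = [rng.standard_normal(20) for _ in range(5)]
        F, _ = planted_rows(rng, 30, pats, 0.15)
        _, k_rec, _ = select_k(F, k_range=(2, 7), replicates=5, seed=0)
        assert k_rec == 5

    def test_single_blob_has_low_silhouette(self, rng):
        F = rng.standard_normal((120, 15))
        table, _, _ = select_k(F, k_range=(2, 4), replicates=3, seed=0)
        assert table["silhouette"].max() < 0.2


class TestHomotopicFC:
    def test_constant_pair_entries(self, parcellation):
        n = parcellation.n_regions
        z = np.zeros((n, n))
        for i, j in parcellation.homotopic_pairs():
            z[i, j] = z[j, i] = 0.42
        means = homotopic_fc(z, parcellation)
        assert all(np.isclose(v, 0.42) for v in means.values())
        assert set(means) == set(parcellation.cortical_networks())

    def test_network_without_pairs_excluded(self, tiny_parcellation):
        # tiny parcellation: its only network HAS pairs; build one without
        z = np.zeros((3, 3))
        means = homotopic_fc(z, tiny_parcellation)
        assert "NETA" in means

    def test_matches_pair_enumeration_oracle(self, rng, parcellation):
        n = parcellation.n_regions
        a = rng.standard_normal((n, n))
        z = (a + a.T) / 2
        means = homotopic_fc(z, parcellation)
        for net in parcellation.cortical_networks():
            pairs = parcellation.homotopic_pairs(net)
            assert means[net] == pytest.approx(
                np.mean([z[i, j] for i, j in pairs])
            )


class TestDanDmnFC:
    def test_planted_block_value(self, parcellation):
        n = parcellation.n_regions
        z = np.zeros((n, n))
        dan = parcellation.network_members("DAN")
        dmn = parcellation.network_members("DMN")
        hemi = np.asarray(parcellation.hemisphere)
        for i in dan:
            for j in dmn:
                if hemi[i] == hemi[j]:
                    z[i, j] = z[j, i] = -0.3
        assert dan_dmn_fc(z, parcellation) == pytest.approx(-0.3)

    def test_cross_hemisphere_coupling_ignored(self, parcellation):
        n = parcellation.n_regions
        z = np.zeros((n, n))
        dan = parcellation.network_members("DAN")
        dmn = parcellation.network_members("DMN")
        hemi = np.asarray(parcellation.hemisphere)
        for i in dan:
            for j in dmn:
                if hemi[i] != hemi[j]:
                    z[i, j] = z[j, i] = 0.9
        assert dan_dmn_fc(z, parcellation) == 0.0

    def test_missing_network_rejected(self, tiny_parcellation):
        with pytest.raises(ValueError):
            dan_dmn_fc(np.zeros((3, 3)), tiny_parcellation)


def brute_force_q_signed(W, partition):
    """Direct double-sum evaluation of the signed modularity."""
    n = W.shape[0]
    q = 0.0
    for sign in (1.0, -1.0):
        Wp = np.clip(sign * W, 0, None)
        v = Wp.sum()
        if v <= 0:
            continue
        s = Wp.sum(axis=1)
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if partition[i] == partition[j]:
                    acc += Wp[i, j] - s[i] * s[j] / v
        q += sign * acc / v
    return q


class TestModularitySigned:
    def two_cliques(self):
        W = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                W[i, j] = W[j, i] = 1.0
        part = np.array([0] * 4 + [1] * 4)
        return W, part

    def test_two_cliques_q_half(self):
        W, part = self.two_cliques()
        # density retaining all 12 edges out of 28 possible
        assert modularity_signed(W, part, densities=(1.0,)) == pytest.approx(0.5)

    def test_single_community_q_zero(self):
        W, _ = self.two_cliques()
        assert modularity_signed(W, np.zeros(8), densities=(1.0,)) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_signed_graphs(self, rng):
        for _ in range(10):
            a = rng.standard_normal((8, 8))
            W = (a + a.T) / 2
            np.fill_diagonal(W, 0)
            part = rng.integers(0, 3, size=8)
            got = modularity_signed(W, part, densities=(1.0,))
            assert got == pytest.approx(brute_force_q_signed(W, part))

    def test_planted_partition_is_optimal_over_all_partitions(self, rng):
        W, part = self.two_cliques()
        # flip the inter-block entries negative: community structure strengthens
        W[:4, 4:] = -0.5
        W[4:, :4] = -0.5
        best_q = modularity_signed(W, part, densities=(1.0,))
        # exhaustive search over all 2-colorings of 8 nodes
        for bits in itertools.product([0, 1], repeat=8):
            q = brute_force_q_signed(W, np.asarray(bits))
            assert q <= best_q + 1e-12

    def test_density_thresholding_keeps_largest_magnitudes(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = -0.9
        W[0, 2] = W[2, 0] = 0.1
        part = np.array([0, 0, 1, 1])
        # 2 of 6 possible edges: keeps the +-largest pair, drops the 0.1 edge
        q_sparse = modularity_signed(W, part, densities=(2 / 6,))
        W_kept = np.zeros_like(W)
        W_kept[0, 1] = W_kept[1, 0] = 1.0
        W_kept[2, 3] = W_kept[3, 2] = -0.9
        assert q_sparse == pytest.approx(brute_force_q_signed(W_kept, part))


class TestStateBiomarkers:
    def test_two_state_plant_recovers_homotopic_ordering(self, rng, parcellation):
        n = parcellation.n_regions
        pairs = parcellation.homotopic_pairs()

        def fc(pair_value):
            a = 0.05 * rng.standard_normal((n, n))
            z = (a + a.T) / 2
            for i, j in pairs:
                z[i, j] = z[j, i] = pair_value
            np.fill_diagonal(z, 0)
            return z

        fcs = [fc(0.8) for _ in range(6)] + [fc(0.1) for _ in range(6)]
        from dfstates.clustering import DFSModel

        model = DFSModel(
            k=2,
            centroids=np.zeros((2, 3)),
            assignments=np.array([1] * 6 + [2] * 6),
            inertia=0.0,
        )
        bm = state_biomarkers(model, fcs, parcellation, densities=(0.2,))
        t = bm.table
        homo1 = t[(t.state == 1) & t.metric.str.startswith("homotopic")]["mean"].mean()
        homo2 = t[(t.state == 2) & t.metric.str.startswith("homotopic")]["mean"].mean()
        assert homo1 > homo2
        assert (t["sem"] >= 0).all()

    def test_single_window_state_sem_zero(self, rng, parcellation):
        n = parcellation.n_regions
        a = rng.standard_normal((n, n))
        z = (a + a.T) / 2
        np.fill_diagonal(z, 0)
        from dfstates.clustering import DFSModel

        model = DFSModel(
            k=2, centroids=np.zeros((2, 3)), assignments=np.array([1, 2]), inertia=0.0
        )
        bm = state_biomarkers(model, [z, z], parcellation, densities=(0.2,))
        assert (bm.table["sem"] == 0).all()

    def test_empty_state_flagged(self, rng, parcellation):
        n = parcellation.n_regions
        z = np.zeros((n, n))
        from dfstates.clustering import DFSModel

        model = DFSModel(
            k=3, centroids=np.zeros((3, 3)), assignments=np.array([1, 1]), inertia=0.0
        )
        bm = state_biomarkers(model, [z, z], parcellation, densities=(0.2,))
        assert bm.empty_states == [2, 3]
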