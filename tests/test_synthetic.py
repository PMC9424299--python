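import numpy as np
import pandas as pd
import pytest

from dfstates.core_io import Parcellation
from dfstates.synthetic import (
    BehaviorPlant,
    LesionPlant,
    MarkovPlant,
    StateSpec,
    apply_occupancy_multipliers,
    build_state_covariance,
    sample_state_sequence,
    simulate_cohort,
    stationary_distribution,
    synth_behavior,
    synth_lesion_cohort,
    synth_session,
    synthetic_parcellation,
    CohortSpec,
)


def coupling_frame(labels, values=None):
    n = len(labels)
    m = np.zeros((n, n)) if values is None else np.asarray(values, dtype=float)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=labels, columns=labels)


class TestMarkovChain:
    def test_single_state_constant(self):
        plant = MarkovPlant(np.array([[1.0]]))
        x = sample_state_sequence(plant, 50, 0)
        assert np.all(x == 1)

    def test_symmetric_two_state_occupancy(self):
        plant = MarkovPlant(np.array([[0.9, 0.1], [0.1, 0.9]]))
        x = sample_state_sequence(plant, 10_000, 1)
        occ = (x == 1).mean()
        assert abs(occ - 0.5) <= 0.03
        np.testing.assert_allclose(
            stationary_distribution(plant.transition_matrix), [0.5, 0.5]
        )

    def test_absorbing_state_sticks(self):
        P = np.array([[0.5, 0.5], [0.0, 1.0]])
        x = sample_state_sequence(MarkovPlant(P), 200, 2)
        first2 = np.argmax(x == 2)
        assert np.all(x[first2:] == 2)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            MarkovPlant(np.array([[0.5, 0.4], [0.1, 0.9]]))

    def test_empirical_transitions_match_matrix(self):
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        x = sample_state_sequence(MarkovPlant(P), 30_000, 3)
        emp = np.zeros((3, 3))
        for a, b in zip(x[:-1], x[1:]):
            emp[a - 1, b - 1] += 1
        emp /= emp.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(emp, P, atol=0.02)

    def test_mean_dwell_parameterization(self):
        plant = MarkovPlant.from_mean_dwell(np.array([10.0, 10.0]))
        x = sample_state_sequence(plant, 12_000, 4)
        from dfstates.dynamics import dwell_time

        dwell, _ = dwell_time(x, 2)
        # geometric runs with switch probability q = 0.1 -> mean 1/q
        assert dwell.mean() == pytest.approx(10.0, rel=0.10)

    def test_occupancy_multipliers_bias_stationary(self):
        P = MarkovPlant.from_mean_dwell(np.array([10.0, 10.0, 10.0])).transition_matrix
        Q = apply_occupancy_multipliers(P, np.array([1.0, 3.0, 1.0]))
        pi = stationary_distribution(Q)
        assert pi[1] > 0.4
        np.testing.assert_allclose(Q.sum(axis=1), 1.0)


class TestStateCovariance:
    def test_identity_coupling_gives_scaled_identity(self, parcellation):
        labels = parcellation.cortical_networks() + ["nuclei", "limbic"]
        spec = StateSpec(
            network_coupling=coupling_frame(labels),
            within_network_r=0.0,
            homotopic_boost=0.0,
            noise_sd=1.7,
        )
        sigma = build_state_covariance(spec, parcellation)
        np.testing.assert_allclose(sigma, 1.7**2 * np.eye(parcellation.n_regions))

    def test_equicorrelation_block_closed_form(self):
        # one network of 6 regions, r = 0.5: eigenvalues 1+(n-1)r and 1-r
        parc = Parcellation(
            labels=tuple(f"r{i}" for i in range(6)),
            hemisphere=("L",) * 3 + ("R",) * 3,
            network=("X",) * 6,
            is_subcortical=(False,) * 6,
            homotopic_partner=(-1,) * 6,
        )
        spec = StateSpec(
            network_coupling=coupling_frame(["X"]),
            within_network_r=0.5,
            homotopic_boost=0.0,
        )
        sigma = build_state_covariance(spec, parc)
        w = np.sort(np.linalg.eigvalsh(sigma))
        np.testing.assert_allclose(w, [0.5] * 5 + [1 + 5 * 0.5], atol=1e-8)

    def test_block_averages_match_coupling(self, parcellation):
        labels = parcellation.cortical_networks() + ["nuclei", "limbic"]
        vals = np.zeros((10, 10))
        vals[0, 1] = vals[1, 0] = 0.4
        spec = StateSpec(
            network_coupling=coupling_frame(labels, vals),
            within_network_r=0.3,
            homotopic_boost=0.0,
            noise_sd=1.0,
        )
        sigma = build_state_covariance(spec, parcellation)
        a = parcellation.network_members("VIS")
        b = parcellation.network_members("SMN")
        assert sigma[np.ix_(a, b)].mean() == pytest.approx(0.4, abs=0.05)

    def test_out_of_range_coupling_rejected(self):
        with pytest.raises(ValueError, match="\\[-1, 1\\]"):
            StateSpec(network_coupling=coupling_frame(["A", "B"], [[1, -1.5], [-1.5, 1]]))

    def test_unknown_network_rejected(self, parcellation):
        spec = StateSpec(network_coupling=coupling_frame(["VIS"]))
        with pytest.raises(ValueError, match="missing"):
            build_state_covariance(spec, parcellation)

    def test_homotopic_boost_applied(self, parcellation):
        labels = parcellation.cortical_networks() + ["nuclei", "limbic"]
        spec = StateSpec(
            network_coupling=coupling_frame(labels),
            within_network_r=0.2,
            homotopic_boost=0.3,
        )
        sigma = build_state_covariance(spec, parcellation)
        i, j = parcellation.homotopic_pairs()[0]
        assert sigma[i, j] == pytest.approx(0.5, abs=0.05)

    def test_always_psd(self, parcellation):
        labels = parcellation.cortical_networks() + ["nuclei", "limbic"]
        rng = np.random.default_rng(0)
        a = rng.uniform(-1, 1, (10, 10))
        vals = (a + a.T) / 2
        spec = StateSpec(
            network_coupling=coupling_frame(labels, vals), within_network_r=0.8
        )
        sigma = build_state_covariance(spec, parcellation)
        assert np.linalg.eigvalsh(sigma).min() >= 0


class TestSynthSession:
    def tiny_parc(self):
        return Parcellation(
            labels=("A_L", "A_R"),
            hemisphere=("L", "R"),
            network=("X", "X"),
            is_subcortical=(False, False),
            homotopic_partner=(1, 0),
        )

    def test_independent_regions_uncorrelated(self):
        parc = self.tiny_parc()
        spec = StateSpec(
            network_coupling=coupling_frame(["X"]),
            within_network_r=0.0,
            homotopic_boost=0.0,
        )
        sess = synth_session(parc, [spec], np.ones(10_000, dtype=int), 0.0, 1)
        r = np.corrcoef(sess.data)[0, 1]
        assert abs(r) < 0.05

    def test_planted_pair_correlation_recovered(self):
        parc = self.tiny_parc()
        spec = StateSpec(
            network_coupling=coupling_frame(["X"]),
            within_network_r=0.8,
            homotopic_boost=0.0,
        )
        sess = synth_session(parc, [spec], np.ones(5_000, dtype=int), 0.0, 2)
        z = np.arctanh(np.corrcoef(sess.data)[0, 1])
        assert abs(z - np.arctanh(0.8)) <= 0.1

    def test_ar_coefficient_reproduced(self):
        parc = self.tiny_parc()
        spec = StateSpec(
            network_coupling=coupling_frame(["X"]),
            within_network_r=0.0,
            homotopic_boost=0.0,
        )
        sess = synth_session(parc, [spec], np.ones(20_000, dtype=int), 0.9, 3)
        x = sess.data[0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.9, abs=0.05)

    def test_ar_coef_out_of_range_rejected(self):
        parc = self.tiny_parc()
        spec = StateSpec(network_coupling=coupling_frame(["X"]))
        with pytest.raises(ValueError):
            synth_session(parc, [spec], np.ones(10, dtype=int), 1.0, 0)

    def test_bit_reproducible_under_seed(self, parcellation):
        from dfstates.synthetic import default_state_specs

        specs = default_state_specs(parcellation, 2)
        labels = np.array([1] * 30 + [2] * 30)
        s1 = synth_session(parcellation, specs, labels, 0.3, 42)
        s2 = synth_session(parcellation, specs, labels, 0.3, 42)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestCohort:
    def test_structure_and_reproducibility(self, parcellation):
        spec = CohortSpec(
            n_controls=2, n_patients=2, k=2, n_frames=80, severe_fraction=0.5
        )
        c1 = simulate_cohort(spec, parcellation, seed=9)
        c2 = simulate_cohort(spec, parcellation, seed=9)
        assert len(c1.sessions) == 2 * 2 + 2 * 3
        np.testing.assert_array_equal(c1.sessions[0].data, c2.sessions[0].data)
        assert {s.group for s in c1.sessions} == {"control", "patient"}
        sev = {s.subject_id: s.severity for s in c1.sessions if s.group == "patient"}
        assert set(sev.values()) == {"severe", "mild"}

    def test_severe_patients_over_occupy_state_two(self, parcellation):
        spec = CohortSpec(
            n_controls=0, n_patients=2, k=3, n_frames=3000,
            patient_timepoints=("2wk",), severe_fraction=0.5,
        )
        coh = simulate_cohort(spec, parcellation, seed=3)
        occ = {
            s.severity: (coh.frame_labels[i] == 2).mean()
            for i, s in enumerate(coh.sessions)
        }
        assert occ["severe"] > occ["mild"]


class TestLesionCohort:
    def test_zero_noise_single_voxel_scores_exact(self):
        plant = LesionPlant(
            grid_shape=(6, 6, 6), blob_size_range=(1, 1), score_noise_sd=0.0, snr=None
        )
        masks, scores = synth_lesion_cohort(12, plant, 5)
        for m, s in zip(masks, scores):
            assert m.sum() == 1
            assert s == pytest.approx(plant.w_true[m][0])

    def test_blobs_are_connected(self):
        from scipy.ndimage import label

        plant = LesionPlant(grid_shape=(10, 10, 10), blob_size_range=(30, 60))
        masks, _ = synth_lesion_cohort(10, plant, 6)
        for m in masks:
            _, n_comp = label(m)
            assert n_comp == 1

    def test_all_zero_weight_field_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            LesionPlant(grid_shape=(4, 4, 4), w_true=np.zeros((4, 4, 4)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            synth_lesion_cohort(5, LesionPlant(), 0)


class TestBehaviorPlant:
    def plant(self, coefs):
        return BehaviorPlant(
            coefficients=pd.DataFrame(
                coefs, index=["ST", "dyn1", "dyn2", "dyn3"]
            ),
            noise_sd=pd.Series({k: 0.0 for k in coefs}),
        )

    def test_zero_noise_exact_linear_map(self, rng):
        st = rng.standard_normal(15)
        dyn = rng.standard_normal((15, 3))
        plant = self.plant({"motor": [1.0, 0.5, -0.5, 2.0]})
        table = synth_behavior(st, dyn, plant, 0)
        expect = st * 1.0 + dyn @ [0.5, -0.5, 2.0]
        np.testing.assert_allclose(table["motor"], expect)

    def test_zero_coefficients_pure_noise(self, rng):
        st = rng.standard_normal(200)
        dyn = rng.standard_normal((200, 3))
        plant = self.plant({"lang": [0.0, 0.0, 0.0, 0.0]})
        plant.noise_sd["lang"] = 1.0
        table = synth_behavior(st, dyn, plant, 1)
        assert abs(np.corrcoef(table["lang"], st)[0, 1]) < 0.2

    def test_misaligned_subjects_rejected(self, rng):
        plant = self.plant({"m": [1, 0, 0, 0]})
        with pytest.raises(ValueError):
            synth_behavior(rng.standard_normal(10), rng.standard_normal((9, 3)), plant, 0)
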