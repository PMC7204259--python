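"""HALS NMF, VAF, synergy-count selection, extraction strategies, projection."""

import numpy as np
import pytest
from scipy.optimize import nnls

import wristsyn as ws
from wristsyn.exceptions import DegenerateDataError, SelectionError

from conftest import effective_truth

FAST = ws.HALSConfig(n_restarts=3, seed=0)


def _random_envelope(rng, m=60, n=7):
    return rng.uniform(0.0, 1.0, (m, n))


class TestHALS:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.5, 2.0, (40, 1))
        s = rng.uniform(0.5, 2.0, (1, 6))
        E = m @ s
        M, S, _ = ws.hals_nmf(E, 1, FAST)
        assert ws.vaf(E, M, S) >= 1 - 1e-9

    def test_deterministic_given_config(self):
        rng = np.random.default_rng(1)
        E = _random_envelope(rng)
        M1, S1, _ = ws.hals_nmf(E, 3, FAST)
        M2, S2, _ = ws.hals_nmf(E, 3, FAST)
        np.testing.assert_array_equal(M1, M2)
        np.testing.assert_array_equal(S1, S2)

    def test_objective_monotone_within_restart(self):
        rng = np.random.default_rng(2)
        E = _random_envelope(rng, m=100)
        _, _, info = ws.hals_nmf(E, 4, ws.HALSConfig(n_restarts=1, seed=7))
        h = np.asarray(info["history"])
        assert np.all(np.diff(h) <= 1e-10 * np.maximum(h[:-1], 1.0))

    def test_unit_norm_columns_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        E = _random_envelope(rng)
        M, S, _ = ws.hals_nmf(E, 3, FAST)
        assert np.all(M >= 0) and np.all(S >= 0)
        np.testing.assert_allclose(np.linalg.norm(S, axis=0), 1.0, atol=1e-9)

    def test_vaf_nondecreasing_in_j(self):
        rng = np.random.default_rng(4)
        E = _random_envelope(rng, m=80)
        cfg = ws.HALSConfig(n_restarts=10, seed=0)
        vafs = [
            ws.vaf(E, *ws.hals_nmf(E, j, cfg)[:2]) for j in (1, 2, 3, 4)
        ]
        assert np.all(np.diff(vafs) >= -1e-6)

    def test_scaling_data_scales_activations_only(self):
        rng = np.random.default_rng(5)
        E = _random_envelope(rng)
        cfg = ws.HALSConfig(n_restarts=10, seed=0)
        M1, S1, _ = ws.hals_nmf(E, 2, cfg)
        M2, S2, _ = ws.hals_nmf(3.0 * E, 2, cfg)
        perm, sims = ws.match_synergies(S2, S1)
        assert np.all(sims > 0.999)
        assert np.linalg.norm(M2[:, perm]) / np.linalg.norm(M1) == pytest.approx(
            3.0, rel=0.01
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ws.hals_nmf(np.ones((5, 3)), 0)
        with pytest.raises(DegenerateDataError):
            ws.hals_nmf(np.zeros((5, 3)), 2)

    def test_matches_multiplicative_update_oracle(self):
        # independent NMF oracle: sklearn's multiplicative-update solver
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(6)
        E = _random_envelope(rng, m=50)
        j = 3
        cfg = ws.HALSConfig(n_restarts=5, seed=0)
        M, S, info = ws.hals_nmf(E, j, cfg)
        best_mu = np.inf
        for r in range(5):
            mdl = NMF(
                n_components=j, solver="mu", init="random", max_iter=2000,
                tol=1e-10, random_state=r,
            )
            W = mdl.fit_transform(E)
            best_mu = min(best_mu, np.linalg.norm(E - W @ mdl.components_) ** 2)
        assert info["objective"] <= 1.01 * best_mu


class TestVAF:
    def test_perfect_reconstruction(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        M = E.copy()
        S = np.eye(2)
        assert ws.vaf(E, M, S) == pytest.approx(1.0)

    def test_zero_model(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert ws.vaf(E, np.zeros((2, 1)), np.zeros((2, 1))) == pytest.approx(0.0)

    def test_half_variance_toy(self):
        # E = I2, reconstruction keeps only the (1,1) entry -> VAF = 0.5
        E = np.eye(2)
        M = np.array([[1.0], [0.0]])
        S = np.array([[1.0], [0.0]])
        assert ws.vaf(E, M, S) == pytest.approx(0.5)

    def test_zero_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            ws.vaf(np.zeros((3, 3)), np.zeros((3, 1)), np.zeros((3, 1)))


class TestSelection:
    def test_reported_min_vaf_pattern_selects_four(self):
        # three synergies fail for at least one subject (0.88 < 0.9), four
        # reach 0.9647 -> four wrist synergies are selected
        table = {1: 0.52, 2: 0.74, 3: 0.88, 4: 0.9647, 5: 0.982, 6: 0.991}
        assert ws.select_from_vaf_table(table, threshold=0.9) == 4

    def test_first_qualifier_wins(self):
        assert ws.select_from_vaf_table({1: 0.95}, threshold=0.9) == 1

    def test_no_qualifier_raises_with_table(self):
        with pytest.raises(SelectionError) as err:
            ws.select_from_vaf_table({1: 0.5, 2: 0.6}, threshold=0.9)
        assert err.value.vaf_table == {1: 0.5, 2: 0.6}

    def test_noiseless_synthetic_needs_at_most_four(self, noiseless_trials):
        wrist = [t.E for t in noiseless_trials if t.condition == "comfortable_max"]
        j, table = ws.select_wrist_synergy_number(
            wrist[:1], j_range=range(1, 6), config=FAST
        )
        assert j <= 4
        assert set(table) == set(range(1, 6))


class TestExtraction:
    def test_slrm1_labels_grip_column(self, noiseless_session, noiseless_trials):
        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        grip = [t for t in noiseless_trials if t.condition == "grip_only"]
        syn = ws.extract_slrm1([wrist[0].E, grip[0].E], j_wrist=4, config=FAST)
        assert syn.roles.count("grip") == 1
        S_eff = effective_truth(noiseless_session)
        true_grip = S_eff[:, -1]
        est_grip = syn.S[:, syn.grip_columns[0]]
        assert float(est_grip @ true_grip) >= 0.9

    def test_slrm1_channel_permutation_equivariance(self, noiseless_trials):
        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        grip = [t for t in noiseless_trials if t.condition == "grip_only"]
        perm = [3, 0, 6, 2, 5, 1, 4]
        fingers_perm = (perm.index(5), perm.index(6))
        a = ws.extract_slrm1([wrist[0].E, grip[0].E], 2, config=FAST)
        b = ws.extract_slrm1(
            [wrist[0].E[:, perm], grip[0].E[:, perm]], 2, config=FAST,
            finger_channels=fingers_perm,
        )
        # equivariant up to column order and optimizer tolerance (the
        # random initialization is indexed by channel)
        _, sims = ws.match_synergies(b.S, a.S[perm, :])
        assert np.min(sims) > 0.999

    def test_slrm2_noiseless_recovery(self, noiseless_session, noiseless_trials):
        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        grip = [t for t in noiseless_trials if t.condition == "grip_only"]
        syn = ws.extract_slrm2(wrist[0].E, grip[0].E, 4, 1,
                               ws.HALSConfig(seed=0))
        _, sims = ws.match_synergies(syn.S, effective_truth(noiseless_session))
        assert np.min(sims) >= 0.95

    def test_slrm2_grip_column_is_finger_dominated(self, noiseless_trials):
        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        grip = [t for t in noiseless_trials if t.condition == "grip_only"]
        syn = ws.extract_slrm2(wrist[0].E, grip[0].E, 4, 1, FAST)
        col = syn.S[:, syn.grip_columns[0]]
        assert np.linalg.norm(col[[5, 6]]) >= 0.8 * np.linalg.norm(col)

    def test_zero_wrist_count_rejected(self, noiseless_trials):
        with pytest.raises(ValueError):
            ws.extract_slrm2(
                noiseless_trials[0].E, noiseless_trials[3].E, 0, 1, FAST
            )


class TestProjection:
    def test_recovers_exact_activations(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(0.1, 1.0, (7, 4))
        S /= np.linalg.norm(S, axis=0)
        M0 = rng.uniform(0.0, 2.0, (50, 4))
        E = M0 @ S.T
        M = ws.project_activations(E, S)
        np.testing.assert_allclose(M, M0, atol=1e-6)

    def test_zero_data_gives_zero(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(0.1, 1.0, (7, 3))
        M = ws.project_activations(np.zeros((10, 7)), S)
        assert np.all(M == 0)

    def test_matches_nnls_oracle(self):
        rng = np.random.default_rng(2)
        S = rng.uniform(0.0, 1.0, (7, 4))
        E = rng.uniform(0.0, 1.0, (20, 7))
        M = ws.project_activations(E, S)
        for i in range(E.shape[0]):
            m_ref, _ = nnls(S, E[i])
            np.testing.assert_allclose(M[i], m_ref, atol=1e-6)

    def test_beats_random_candidates(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0.0, 1.0, (7, 3))
        E = rng.uniform(0.0, 1.0, (5, 7))
        M = ws.project_activations(E, S)
        obj = np.linalg.norm(E - M @ S.T)
        for _ in range(100):
            cand = rng.uniform(0.0, 2.0, M.shape)
            assert obj <= np.linalg.norm(E - cand @ S.T) + 1e-12

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            ws.project_activations(np.ones((5, 6)), np.ones((7, 2)))
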