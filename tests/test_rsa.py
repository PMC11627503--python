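"""Unit tests for the representational similarity machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evsynth import rsa


@pytest.fixture()
def pattern_matrix():
    rng = np.random.default_rng(0)
    return rng.normal(size=(12, 30))  # 12 units x 30 trials


class TestSessionProjection:
    def test_within_session_means_zero(self, pattern_matrix):
        sessions = np.repeat([1, 2, 3], 10)
        Yc = rsa.project_out_sessions(pattern_matrix, sessions)
        for s in (1, 2, 3):
            assert np.allclose(Yc[:, sessions == s].mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self, pattern_matrix):
        sessions = np.repeat([1, 2], 15)
        once = rsa.project_out_sessions(pattern_matrix, sessions)
        twice = rsa.project_out_sessions(once, sessions)
        assert np.allclose(once, twice)

    def test_known_offsets_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 8))
        sessions = np.repeat([1, 2], 4)
        Y = base.copy()
        Y[:, sessions == 2] += 7.5  # constant session offset
        Yc = rsa.project_out_sessions(Y, sessions)
        base_c = rsa.project_out_sessions(base, sessions)
        assert np.allclose(Yc, base_c)

    def test_single_session_warns_identity(self, pattern_matrix):
        with pytest.warns(UserWarning):
            out = rsa.project_out_sessions(pattern_matrix, np.ones(30))
        assert np.allclose(out, pattern_matrix)


class TestComputeRdm:
    def test_duplicate_columns_zero(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=5)
        Y = np.column_stack([col, col, rng.normal(size=5)])
        D = rsa.compute_rdm(Y).D
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_two(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=6)
        Y = np.column_stack([col, -col + col.mean() * 2])
        D = rsa.compute_rdm(Y).D
        assert D[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_matches_pairwise_correlation_oracle(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(3, 3))
        D = rsa.compute_rdm(Y).D
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else 1 - np.corrcoef(Y[:, i], Y[:, j])[0, 1]
                assert D[i, j] == pytest.approx(expected)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(8, 10))
        D1 = rsa.compute_rdm(Y).D
        D2 = rsa.compute_rdm(a * Y + b).D
        assert np.allclose(D1, D2, atol=1e-9)

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(5, 4))
        Y[:, 2] = 3.0
        D = rsa.compute_rdm(Y).D
        assert np.all(np.isnan(D[2, [0, 1, 3]]))
        assert D[2, 2] == 0.0


class TestDelayDetrend:
    def test_per_delay_means_zero(self, pattern_matrix):
        rdm = rsa.compute_rdm(pattern_matrix)
        corrected = rsa.delay_detrend(rdm)
        n = corrected.n_trials
        delay = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        off = ~np.eye(n, dtype=bool)
        for d in range(1, n):
            vals = corrected.D[(delay == d) & off]
            assert np.nanmean(vals) == pytest.approx(0.0, abs=1e-12)

    def test_pure_delay_structure_nulled(self):
        n = 20
        delay = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
        rdm = rsa.RDM(D=0.01 * delay)
        corrected = rsa.delay_detrend(rdm)
        assert np.allclose(corrected.D, 0.0, atol=1e-12)

    def test_randomized_gain_structure_survives(self):
        """AR(1) trial noise induces a delay trend; detrending removes it
        while the gain-distance slope (gains randomized over trials) stays
        within 5%."""
        from evsynth.core import trials_to_arrays
        from evsynth import synth

        spec = synth.GroupDesignSpec("narrow", seed=3)
        design = synth.gen_group_design(spec)
        gains, losses, _, sessions = trials_to_arrays(design)
        rng = np.random.default_rng(7)
        # patterns with explicit gain structure
        Z = np.column_stack([
            0.02 * gains + rng.normal(0, 0.3, 256) for _ in range(16)
        ])
        Y = synth.gen_voxel_patterns(Z, n_vox=80, snr=2.0, ar1_coef=0.5, seed=11)
        rdm_raw = rsa.compute_rdm(Y)
        rdm_cor = rsa.delay_detrend(rdm_raw)
        s_raw = rsa.attribute_encoding_strength(rdm_raw, gains, losses).slope_gain
        s_cor = rsa.attribute_encoding_strength(rdm_cor, gains, losses).slope_gain
        assert s_cor == pytest.approx(s_raw, rel=0.05)


class TestEncodingStrength:
    def test_exact_linear_model_recovered(self):
        rng = np.random.default_rng(8)
        n = 25
        gains = rng.uniform(5, 20, n)
        losses = rng.uniform(5, 20, n)
        i, j = np.tril_indices(n, k=-1)
        D = np.zeros((n, n))
        D[i, j] = D[j, i] = (
            0.1 + 0.02 * np.abs(gains[i] - gains[j]) + 0.005 * np.abs(losses[i] - losses[j])
        )
        enc = rsa.attribute_encoding_strength(rsa.RDM(D=D), gains, losses)
        assert enc.slope_gain == pytest.approx(0.02, abs=1e-10)
        assert enc.slope_loss == pytest.approx(0.005, abs=1e-10)

    def test_shuffled_rdm_slopes_null(self):
        rng = np.random.default_rng(9)
        n = 40
        gains = rng.uniform(0, 1, n)
        losses = rng.uniform(0, 1, n)
        D = np.zeros((n, n))
        i, j = np.tril_indices(n, k=-1)
        vals = rng.normal(size=i.size)
        D[i, j] = D[j, i] = vals
        enc = rsa.attribute_encoding_strength(rsa.RDM(D=D), gains, losses)
        assert abs(enc.slope_gain) < 2 * enc.se_gain + 1e-9 or abs(enc.slope_gain) < 0.5

    def test_ev_slope_exact(self):
        rng = np.random.default_rng(10)
        n = 20
        evs = rng.uniform(-5, 5, n)
        D = np.zeros((n, n))
        i, j = np.tril_indices(n, k=-1)
        D[i, j] = D[j, i] = 0.03 * np.abs(evs[i] - evs[j])
        slope, _ = rsa.ev_encoding_strength(rsa.RDM(D=D), evs)
        assert slope == pytest.approx(0.03, abs=1e-10)

    def test_matches_bruteforce_on_small_instance(self):
        """Estimator equals an explicit per-pair regression oracle."""
        rng = np.random.default_rng(11)
        n = 10
        gains = rng.uniform(0, 1, n)
        losses = rng.uniform(0, 1, n)
        Y = rng.normal(size=(6, n))
        rdm = rsa.compute_rdm(Y)
        enc = rsa.attribute_encoding_strength(rdm, gains, losses)
        rows, ys = [], []
        for a in range(n):
            for b in range(a):
                ys.append(rdm.D[a, b])
                rows.append([1.0, abs(gains[a] - gains[b]), abs(losses[a] - losses[b])])
        beta, *_ = np.linalg.lstsq(np.array(rows), np.array(ys), rcond=None)
        assert enc.slope_gain == pytest.approx(beta[1], rel=1e-8)
        assert enc.slope_loss == pytest.approx(beta[2], rel=1e-8)


class TestBinnedRdm:
    def test_sixteen_levels_shape(self):
        from evsynth import synth
        from evsynth.core import trials_to_arrays

        spec = synth.GroupDesignSpec("narrow", seed=0)
        design = synth.gen_group_design(spec)
        gains, _, _, _ = trials_to_arrays(design)
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(10, 256))
        out = rsa.binned_rdm(rsa.compute_rdm(Y), gains)
        assert out.shape == (16, 16)
        assert np.all(np.isfinite(out))

    def test_one_trial_per_level_is_relabeled_rdm(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(6, 5))
        rdm = rsa.compute_rdm(Y)
        values = np.array([3, 1, 4, 0, 2])
        out = rsa.binned_rdm(rdm, values)
        order = np.argsort(values)
        expected = rdm.D[np.ix_(order, order)].copy()
        np.fill_diagonal(expected, np.nan)  # no within-level pairs
        assert np.allclose(out[~np.isnan(out)], expected[~np.isnan(expected)])

    def test_invariant_to_within_level_order(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(size=(6, 12))
        values = np.repeat([0, 1, 2], 4)
        rdm = rsa.compute_rdm(Y)
        a = rsa.binned_rdm(rdm, values)
        perm = np.concatenate([rng.permutation(np.flatnonzero(values == v))
                               for v in (0, 1, 2)])
        rdm2 = rsa.RDM(D=rdm.D[np.ix_(perm, perm)])
        b = rsa.binned_rdm(rdm2, values[perm])
        assert np.allclose(a, b)


class TestRdmSimilarity:
    def test_identical_rdms_r_one(self, pattern_matrix):
        rdm = rsa.compute_rdm(pattern_matrix)
        r, z = rsa.rdm_similarity(rdm, rdm)
        assert r == pytest.approx(1.0)

    def test_independent_rdms_null(self):
        rs = []
        for s in range(1000):
            rng = np.random.default_rng(s)
            D1 = rsa.compute_rdm(rng.normal(size=(6, 50)))
            D2 = rsa.compute_rdm(rng.normal(size=(6, 50)))
            r, _ = rsa.rdm_similarity(D1, D2)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.005

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            rsa.rdm_similarity(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_group_test_detects_positive_shift(self):
        rng = np.random.default_rng(15)
        z = rng.normal(0.5, 0.1, 20)
        t, p, dof = rsa.group_level_test(z)
        assert dof == 19
        assert p < 1e-6 and t > 0
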