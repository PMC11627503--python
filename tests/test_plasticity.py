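"""Unit tests for the anti-Hebbian infomax plasticity rule."""

import numpy as np
import pytest

from evsynth.core import forward_trial, make_network
from evsynth.engine import run_sequence
from evsynth.plasticity import (
    PlasticityParams,
    PlasticityState,
    adapt_sequence,
    attribute_adaptation_step,
    infomax_innovation,
    information_loss,
    plasticity_step,
)
from evsynth.simulation import RangeCondition, make_factorial_design


def _log_steepness(C, x_flat, z_mu, z_sigma):
    """sum_k ln|df_z/dv(k)| for given connectivity, at one attribute pattern."""
    v = C.T @ x_flat
    z = 1 / (1 + np.exp((z_mu - v) / z_sigma))
    return np.sum(np.log(z * (1 - z) / z_sigma))


class TestInfomaxInnovation:
    def test_vanishes_at_half_activation(self, small_net):
        act = forward_trial(small_net, (0.5, 0.5))
        g = infomax_innovation(act, small_net.z_sigma)
        # manually zero one unit's (1-2z) factor
        act2 = type(act)(x=act.x, v=act.v, z=np.full_like(act.z, 0.5), V=act.V)
        g2 = infomax_innovation(act2, small_net.z_sigma)
        assert np.allclose(g2, 0.0)
        assert g.shape == small_net.C.shape

    def test_closed_form_entry(self, small_net):
        act = forward_trial(small_net, (0.5, 0.5))
        z = act.z.copy()
        z[1] = 0.75
        act2 = type(act)(x=act.x, v=act.v, z=z, V=act.V)
        x = act.x.ravel()
        g = infomax_innovation(act2, small_net.z_sigma)
        k = 1
        expected = (1 - 2 * 0.75) / small_net.z_sigma[k] * x
        assert np.allclose(g[:, k], expected)

    def test_matches_finite_differences(self):
        """Gradient-oracle equivalence on a random small net."""
        net = make_network(n_x=3, n_z=4, seed=9)
        act = forward_trial(net, (0.35, 0.65))
        g = infomax_innovation(act, net.z_sigma)
        x_flat = act.x.ravel()
        h = 1e-6
        for ij in range(net.C.shape[0]):
            for k in range(net.C.shape[1]):
                Cp, Cm = net.C.copy(), net.C.copy()
                Cp[ij, k] += h
                Cm[ij, k] -= h
                fd = (
                    _log_steepness(Cp, x_flat, net.z_mu, net.z_sigma)
                    - _log_steepness(Cm, x_flat, net.z_mu, net.z_sigma)
                ) / (2 * h)
                assert fd == pytest.approx(g[ij, k], rel=1e-5, abs=1e-9)

    def test_anti_hebbian_sign(self, small_net):
        act = forward_trial(small_net, (0.8, 0.2))
        g = infomax_innovation(act, small_net.z_sigma)
        for k in range(small_net.n_z):
            expected_sign = -1.0 if act.z[k] > 0.5 else 1.0
            assert np.all(np.sign(g[:, k]) == expected_sign)


class TestPlasticityStep:
    def test_recursion_value(self):
        C = np.zeros((1, 1))
        state = PlasticityState(delta_C_prev=np.array([[0.1]]))
        dC, C_new, _ = plasticity_step(
            C, state, np.array([[-0.25]]), PlasticityParams(0.5, 0.2)
        )
        assert dC[0, 0] == pytest.approx(0.015)
        assert C_new[0, 0] == pytest.approx(0.015)

    def test_memoryless_at_beta_one(self):
        state = PlasticityState(delta_C_prev=np.array([[5.0]]))
        dC, _, _ = plasticity_step(
            np.zeros((1, 1)), state, np.array([[0.3]]), PlasticityParams(0.5, 1.0)
        )
        assert dC[0, 0] == pytest.approx(0.15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlasticityParams(-0.1, 0.5)
        with pytest.raises(ValueError):
            PlasticityParams(0.1, 1.5)


class TestAdaptSequence:
    def test_static_alpha_zero_bit_exact(self, default_net):
        design = make_factorial_design(RangeCondition(), seed=3)
        res = adapt_sequence(default_net, PlasticityParams(0.0, 0.5), design)
        assert np.array_equal(res.params_final.C, default_net.C)
        assert np.all(res.dC_norms == 0.0)

    def test_static_beta_zero_bit_exact(self, default_net):
        design = make_factorial_design(RangeCondition(), seed=3)
        res = adapt_sequence(default_net, PlasticityParams(0.3, 0.0), design)
        assert np.array_equal(res.params_final.C, default_net.C)

    def test_update_magnitude_settles(self):
        """Stationary inputs: |dC| over the last 32 trials below the first 32."""
        design = make_factorial_design(RangeCondition(), seed=0)
        firsts, lasts = [], []
        for s in range(100):
            net = make_network(seed=s)
            res = adapt_sequence(net, PlasticityParams(0.1, 0.1),
                                 make_factorial_design(RangeCondition(), seed=s))
            firsts.append(res.dC_norms[:32].mean())
            lasts.append(res.dC_norms[-32:].mean())
        assert np.mean(lasts) < np.mean(firsts)

    def test_responsive_range_focusing(self):
        """Inputs end up within the responsive band mu_z +/- 2 sigma_z."""
        from evsynth.simulation import responsive_fraction

        inc = 0
        for s in range(50):
            net = make_network(seed=200 + s)
            design = make_factorial_design(RangeCondition(), seed=s)
            res = adapt_sequence(net, PlasticityParams(0.1, 0.1), design)
            from evsynth.core import forward_batch

            _, vin_pre, _, _ = forward_batch(net, res.gains, res.losses)
            _, vin_post, _, _ = forward_batch(res.params_final, res.gains, res.losses)
            pre = responsive_fraction(vin_pre, net.z_mu, net.z_sigma)
            post = responsive_fraction(vin_post, net.z_mu, net.z_sigma)
            inc += int(post > pre)
        assert inc >= 48

    def test_engine_matches_reference(self, default_net):
        """JIT fast path agrees with the step-by-step numpy implementation
        (up to accumulation order in dot products)."""
        from evsynth.core import trials_to_arrays

        design = make_factorial_design(RangeCondition(), seed=13)
        pp = PlasticityParams(0.15, 0.2)
        ref = adapt_sequence(default_net, pp, design)
        g, l, _, _ = trials_to_arrays(design)
        out = run_sequence(default_net, pp, g, l)
        assert np.allclose(out["Z"], ref.Z, rtol=1e-9, atol=1e-11)
        assert np.allclose(out["C"], ref.params_final.C, rtol=1e-9, atol=1e-10)
        assert np.allclose(out["V"], ref.V, rtol=1e-8, atol=1e-10)


class TestInformationLoss:
    def test_identity_entropy_zero(self):
        rng = np.random.default_rng(0)
        d = 4
        # whiten samples so the sample covariance is exactly the identity
        X = rng.normal(size=(500, d))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X, rowvar=False))).T
        est = information_loss(X, np.eye(d), np.zeros(d), np.ones(d))
        assert est.entropy_term == pytest.approx(0.0, abs=1e-8)

    def test_gaussian_entropy_matches_knn_oracle(self):
        """Gaussian log-det entropy within 5% of a Kozachenko-Leonenko
        nearest-neighbor estimate in the linear regime."""
        from scipy.spatial import cKDTree
        from scipy.special import digamma, gammaln

        rng = np.random.default_rng(4)
        n, d_in, d_out = 10000, 6, 4
        X = rng.normal(0, 0.3, (n, d_in)) + 0.5
        C = rng.normal(0, 0.4, (d_in, d_out))
        est = information_loss(X, C, np.zeros(d_out), np.ones(d_out))
        h_gauss = est.entropy_term + 0.5 * d_out * (1 + np.log(2 * np.pi))
        V = X @ C
        k = 4
        dist, _ = cKDTree(V).query(V, k + 1)
        h_knn = (
            digamma(n) - digamma(k)
            + 0.5 * d_out * np.log(np.pi) - gammaln(d_out / 2 + 1)
            + d_out * np.mean(np.log(dist[:, k]))
        )
        assert h_gauss == pytest.approx(h_knn, rel=0.06)

    def test_steepness_term_increases_under_adaptation(self):
        """The rule ascends the mean log-steepness of activation functions
        (its exact objective once the non-local entropy gradient is
        dropped); checked over 100 seeded runs."""
        inc = 0
        for s in range(100):
            net = make_network(n_x=4, n_z=2, seed=s)
            design = make_factorial_design(RangeCondition(), seed=s)
            res = adapt_sequence(net, PlasticityParams(0.1, 0.1), design,
                                 record_C=True)
            e0 = information_loss(res.X, res.C_traj[0], net.z_mu, net.z_sigma)
            e1 = information_loss(res.X, res.C_traj[-1], net.z_mu, net.z_sigma)
            inc += int(e1.steepness_term > e0.steepness_term)
        assert inc == 100

    def test_too_few_samples_rejected(self, small_net):
        with pytest.raises(ValueError):
            information_loss(np.zeros((1, 8)), small_net.C,
                             small_net.z_mu, small_net.z_sigma)


class TestAttributeAdaptation:
    def test_centered_threshold_stationary(self):
        mu = np.array([[0.3]])
        sigma = np.array([[0.1]])
        new_mu, _ = attribute_adaptation_step(mu, sigma, [0.3], rate=0.01)
        assert new_mu[0, 0] == pytest.approx(0.3)

    def test_threshold_converges_to_constant_input(self):
        mu = np.array([[0.1], [0.9]])
        sigma = np.array([[0.2], [0.2]])
        u_star = np.array([0.6, 0.4])
        for _ in range(2000):
            mu, sigma = attribute_adaptation_step(mu, sigma, u_star, rate=0.002)
        assert mu[0, 0] == pytest.approx(0.6, abs=0.05)
        assert mu[1, 0] == pytest.approx(0.4, abs=0.05)

    def test_sigma_floored(self):
        mu = np.array([[0.5]])
        sigma = np.array([[1e-3]])
        _, new_sigma = attribute_adaptation_step(mu, sigma, [0.5], rate=5.0,
                                                 min_sigma=1e-3)
        assert new_sigma[0, 0] >= 1e-3

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            attribute_adaptation_step(np.array([[0.5]]), np.array([[0.1]]),
                                      [0.5], rate=0.0)
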