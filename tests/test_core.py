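"""Math-core oracles: closed forms, hand-computed toys, MC and FD checks."""

import numpy as np
import pytest

from pvrnnlab.core import (
    AdaptiveVariables,
    Architecture,
    Clamp,
    LayerSpec,
    MetaPriorConfig,
    PVRNNParams,
    backward,
    forward,
    free_energy,
    generate,
    init_params,
    kl_gaussians,
    mtrnn_step,
    output,
    posterior_params,
    prior_params,
    reparameterize,
)


class TestPriorPosteriorMaps:
    def test_zero_weights_give_unit_gaussian(self):
        w = np.zeros((2, 3))
        b = np.zeros(2)
        mu, sig = prior_params(np.ones(3), w, b, w, b)
        np.testing.assert_array_equal(mu, 0.0)
        np.testing.assert_array_equal(sig, 1.0)

    def test_scalar_prior_evaluation(self):
        # W_mu = 1, d = 0.5, b = 0  ->  mu = tanh(0.5)
        mu, sig = prior_params(
            np.array([0.5]), np.array([[1.0]]), np.zeros(1), np.array([[0.0]]), np.zeros(1)
        )
        assert mu[0] == pytest.approx(np.tanh(0.5), abs=1e-12)

    def test_prior_mean_bounded_by_tanh(self, rng):
        w = rng.standard_normal((4, 6)) * 0.5
        mu, sig = prior_params(rng.uniform(-1, 1, 6), w, np.zeros(4), w, np.zeros(4))
        assert np.all(np.abs(mu) < 1.0)
        assert np.all(sig > 0)

    def test_posterior_scalar_evaluation(self):
        mu, sig = posterior_params(np.array([0.3]), np.array([-1.0]))
        assert mu[0] == pytest.approx(np.tanh(0.3), abs=1e-12)
        assert sig[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_posterior_saturates(self):
        mu, _ = posterior_params(np.array([50.0]), np.array([0.0]))
        assert mu[0] == pytest.approx(1.0, abs=1e-12)


class TestReparameterize:
    def test_zero_eps_returns_mean(self):
        z = reparameterize(np.array([0.4]), np.array([2.0]), np.zeros(1))
        assert z[0] == 0.4

    def test_monte_carlo_mean(self, rng):
        mu, sig, n = 0.7, 1.3, 100_000
        z = reparameterize(mu, sig, rng.standard_normal(n))
        assert abs(z.mean() - mu) < 4 * sig / np.sqrt(n)


class TestMtrnnStep:
    def test_tau_one_removes_leak(self):
        arch = Architecture((LayerSpec(2, 1, 1.0),))
        p = init_params(arch, np.random.default_rng(0))
        h_prev = np.array([[5.0, -5.0]])
        d_prev = np.array([[0.3, 0.1]])
        z = np.array([[0.2]])
        h, d = mtrnn_step(h_prev, d_prev, z, p, arch)
        expected = d_prev @ p.w_dd.T + z @ p.w_zd.T + p.b_d
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_leak_only_dynamics(self, tiny_arch):
        p = init_params(tiny_arch, np.random.default_rng(0))
        zeros = PVRNNParams(**{k: np.zeros_like(v) for k, v in p.as_dict().items()})
        h0 = np.full((1, tiny_arch.n_d), 2.0)
        h, _ = mtrnn_step(h0, np.zeros_like(h0), np.zeros((1, tiny_arch.n_z)), zeros, tiny_arch)
        np.testing.assert_allclose(h[0], (1.0 - 1.0 / tiny_arch.tau_d) * 2.0, atol=1e-14)

    def test_two_layer_scalar_hand_computation(self):
        # 1 unit per layer, hand-set scalar weights
        arch = Architecture((LayerSpec(1, 1, 2.0), LayerSpec(1, 1, 4.0)))
        p = init_params(arch, np.random.default_rng(0))
        p.w_dd[:] = np.array([[0.5, -0.3], [0.2, 0.7]]) * arch.mask_dd
        p.w_zd[:] = np.array([[1.5, 0.0], [0.0, -2.0]]) * arch.mask_zd
        p.b_d[:] = [0.1, -0.2]
        h_prev = np.array([[0.4, -0.6]])
        d_prev = np.tanh(h_prev)
        z = np.array([[0.3, 0.9]])
        h, d = mtrnn_step(h_prev, d_prev, z, p, arch)
        in1 = 0.5 * d_prev[0, 0] - 0.3 * d_prev[0, 1] + 1.5 * 0.3 + 0.1
        in2 = 0.2 * d_prev[0, 0] + 0.7 * d_prev[0, 1] - 2.0 * 0.9 - 0.2
        assert h[0, 0] == pytest.approx(0.5 * 0.4 + 0.5 * in1, abs=1e-14)
        assert h[0, 1] == pytest.approx(0.75 * (-0.6) + 0.25 * in2, abs=1e-14)
        np.testing.assert_allclose(d, np.tanh(h), atol=1e-14)

    def test_connectivity_restricted_to_neighbors(self):
        arch = Architecture((LayerSpec(2, 1, 2.0), LayerSpec(2, 1, 4.0), LayerSpec(2, 1, 8.0)))
        # layer 1 (rows 0:2) must not see layer 3 (cols 4:6) and vice versa
        assert np.all(arch.mask_dd[0:2, 4:6] == 0)
        assert np.all(arch.mask_dd[4:6, 0:2] == 0)
        assert np.all(arch.mask_dd[2:4, :] == 1)


class TestOutput:
    def test_zero_weights_constant_output(self, tiny_arch):
        p = init_params(tiny_arch, np.random.default_rng(0))
        p.w_out[:] = 0.0
        p.b_out[:] = [0.3, -0.7]
        x = output(np.ones((1, tiny_arch.n_d)), p)
        np.testing.assert_allclose(x[0], np.tanh([0.3, -0.7]), atol=1e-14)

    def test_output_strictly_inside_unit_box(self, tiny_arch, rng):
        p = init_params(tiny_arch, rng)
        x = output(rng.uniform(-1, 1, (20, tiny_arch.n_d)), p)
        assert np.all(np.abs(x) < 1.0)


class TestKL:
    def test_identical_distributions_zero(self):
        mu = np.array([0.3, -0.2])
        sig = np.array([0.5, 2.0])
        assert kl_gaussians(mu, sig, mu, sig) == pytest.approx(0.0, abs=1e-14)

    def test_unit_shift_closed_form(self):
        assert kl_gaussians(1.0, 1.0, 0.0, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_gaussians(0.0, 0.0, 0.0, 1.0)

    def test_monte_carlo_oracle(self, rng):
        """Closed form vs MC estimate of E_q[log q - log p], 2-D Gaussians."""
        mu_q, sig_q = np.array([0.4, -0.8]), np.array([0.7, 1.5])
        mu_p, sig_p = np.array([-0.1, 0.3]), np.array([1.2, 0.6])
        n = 1_000_000
        z = mu_q + sig_q * rng.standard_normal((n, 2))
        log_q = -0.5 * ((z - mu_q) / sig_q) ** 2 - np.log(sig_q)
        log_p = -0.5 * ((z - mu_p) / sig_p) ** 2 - np.log(sig_p)
        samples = (log_q - log_p).sum(axis=1)
        mc, se = samples.mean(), samples.std() / np.sqrt(n)
        assert kl_gaussians(mu_q, sig_q, mu_p, sig_p) == pytest.approx(mc, abs=3 * se)

    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(200):
            mu = rng.standard_normal((2, 3))
            sig = np.exp(rng.standard_normal((2, 3)))
            assert kl_gaussians(mu[0], sig[0], mu[1], sig[1]) >= 0.0


class TestFreeEnergy:
    def _toy(self):
        """1-layer, 1 d-unit, 1 z-unit, 2 steps, hand-set everything."""
        arch = Architecture((LayerSpec(1, 1, 2.0),), n_out=1)
        p = init_params(arch, np.random.default_rng(0))
        p.w_dd[:] = 0.5
        p.w_zd[:] = 1.0
        p.b_d[:] = 0.0
        p.w_pmu[:] = 0.8
        p.w_psig[:] = -0.5
        p.b_pmu[:] = 0.1
        p.b_psig[:] = 0.05
        p.w_out[:] = 1.2
        p.b_out[:] = -0.1
        a = AdaptiveVariables(
            a_mu=np.array([[[0.3], [-0.4]]]), a_sig=np.array([[[-0.2], [0.1]]])
        )
        x = np.array([[0.5], [-0.3]])
        return arch, p, a, x

    def test_two_step_toy_matches_hand_sum(self):
        arch, p, a, x = self._toy()
        trace = forward(p, arch, 2, mode="posterior", a=a)
        # hand computation, z = mu_q (eps = 0)
        d = h = 0.0
        loss_hand = 0.0
        for t in range(2):
            mu_p = np.tanh(0.8 * d + 0.1)
            sig_p = np.exp(-0.5 * d + 0.05)
            mu_q = np.tanh(a.a_mu[0, t, 0])
            sig_q = np.exp(a.a_sig[0, t, 0])
            h = 0.5 * h + 0.5 * (0.5 * d + 1.0 * mu_q)
            d = np.tanh(h)
            xh = np.tanh(1.2 * d - 0.1)
            loss_hand += 0.5 * (x[t, 0] - xh) ** 2
            loss_hand += (
                np.log(sig_p / sig_q)
                + (sig_q**2 + (mu_q - mu_p) ** 2) / (2 * sig_p**2)
                - 0.5
            )
        loss, recon, kl = free_energy(x, trace, (1.0,), arch)
        assert loss == pytest.approx(loss_hand, abs=1e-12)

    def test_zero_meta_prior_leaves_reconstruction_only(self):
        arch, p, a, x = self._toy()
        trace = forward(p, arch, 2, mode="posterior", a=a)
        loss, recon, _ = free_energy(x, trace, (0.0,), arch)
        assert loss == pytest.approx(recon, abs=1e-14)

    def test_posterior_equal_prior_zeroes_kl(self, tiny_arch, rng):
        # constant prior (zero prior-map weights) reproduced exactly by a
        p = init_params(tiny_arch, rng)
        p.w_pmu[:] = 0.0
        p.w_psig[:] = 0.0
        p.b_pmu[:] = rng.standard_normal(tiny_arch.n_z) * 0.5
        p.b_psig[:] = rng.standard_normal(tiny_arch.n_z) * 0.5
        T = 4
        a = AdaptiveVariables(
            a_mu=np.tile(np.arctanh(np.tanh(p.b_pmu)), (1, T, 1)),
            a_sig=np.tile(p.b_psig, (1, T, 1)),
        )
        trace = forward(p, tiny_arch, T, mode="posterior", a=a)
        _, _, kl = free_energy(trace.x_hat, trace, (1.0, 1.0), tiny_arch)
        np.testing.assert_allclose(kl, 0.0, atol=1e-12)


class TestGradients:
    def test_bptt_matches_finite_differences(self, tiny_arch, rng):
        """Analytic free-energy gradients vs central differences, 5-step toy."""
        arch = tiny_arch
        p = init_params(arch, rng)
        T, B = 5, 2
        a = AdaptiveVariables(
            rng.standard_normal((B, T, arch.n_z)) * 0.3,
            rng.standard_normal((B, T, arch.n_z)) * 0.3,
        )
        eps = rng.standard_normal((B, T, arch.n_z))
        x = rng.uniform(-0.8, 0.8, (B, T, arch.n_out))
        w = (0.7, 1.3)

        def loss_fn():
            tr = forward(p, arch, T, mode="posterior", a=a, eps=eps)
            return free_energy(x, tr, w, arch)[0]

        trace = forward(p, arch, T, mode="posterior", a=a, eps=eps)
        g, ag = backward(p, arch, trace, x, w)
        h = 1e-6
        masks = p.mask_dict(arch)
        checked = 0
        for k, arr in p.as_dict().items():
            m = masks[k]
            support = np.argwhere(np.ones(arr.shape, bool) if m is None else m > 0)
            sel = support[rng.choice(len(support), size=min(6, len(support)), replace=False)]
            for idx in map(tuple, sel):
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss_fn()
                arr[idx] = orig - h
                lm = loss_fn()
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                if abs(fd) > 1e-7 or abs(g[k][idx]) > 1e-7:
                    assert abs(fd - g[k][idx]) / max(abs(fd), abs(g[k][idx])) < 1e-4
                    checked += 1
        assert checked > 10
        for arr, garr in ((a.a_mu, ag.a_mu), (a.a_sig, ag.a_sig)):
            flat = np.argwhere(np.ones(arr.shape, bool))
            for idx in map(tuple, flat[rng.choice(len(flat), size=8, replace=False)]):
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss_fn()
                arr[idx] = orig - h
                lm = loss_fn()
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - garr[idx]) / max(1e-8, abs(fd), abs(garr[idx])) < 1e-4


class TestGenerate:
    def test_requested_length(self, tiny_arch, tiny_params, rng):
        trace = generate(tiny_params, tiny_arch, 1024, rng=rng)
        assert trace.x_hat.shape == (1, 1024, 2)

    def test_mean_clamp_pins_sampled_unit(self, tiny_arch, tiny_params, rng):
        clamp = Clamp(unit=2, channel="mean", value=0.7)
        trace = generate(tiny_params, tiny_arch, 50, clamp=clamp, rng=rng)
        np.testing.assert_array_equal(trace.z[0, :, 2], 0.7)

    def test_variance_clamp_pins_prior_sigma(self, tiny_arch, tiny_params, rng):
        clamp = Clamp(unit=0, channel="variance", value=-0.5)
        trace = generate(tiny_params, tiny_arch, 50, clamp=clamp, rng=rng)
        np.testing.assert_allclose(trace.sig_p[0, :, 0], np.exp(-0.5), atol=1e-12)

    def test_prior_mean_mode_is_deterministic(self, tiny_arch, tiny_params):
        t1 = generate(tiny_params, tiny_arch, 100, mode="prior_mean")
        t2 = generate(tiny_params, tiny_arch, 100, mode="prior_mean")
        np.testing.assert_array_equal(t1.x_hat, t2.x_hat)

    def test_out_of_range_clamp_rejected(self, tiny_arch, tiny_params, rng):
        with pytest.raises(IndexError):
            generate(tiny_params, tiny_arch, 10, clamp=Clamp(99, "mean", 0.0), rng=rng)

    def test_rollout_respects_range_invariants(self, tiny_arch, tiny_params, rng):
        trace = generate(tiny_params, tiny_arch, 200, rng=rng)
        assert np.all(trace.sig_p > 0)
        assert np.all(np.abs(trace.d) < 1.0)
        assert np.all(np.abs(trace.mu_p) < 1.0)


class TestDeterminism:
    def test_forward_reproducible_under_fixed_streams(self, tiny_arch, rng):
        p = init_params(tiny_arch, np.random.default_rng(5))
        a = AdaptiveVariables(
            rng.standard_normal((1, 20, tiny_arch.n_z)),
            rng.standard_normal((1, 20, tiny_arch.n_z)),
        )
        eps = rng.standard_normal((1, 20, tiny_arch.n_z))
        t1 = forward(p, tiny_arch, 20, mode="posterior", a=a, eps=eps)
        t2 = forward(p, tiny_arch, 20, mode="posterior", a=a, eps=eps)
        np.testing.assert_array_equal(t1.x_hat, t2.x_hat)
        np.testing.assert_array_equal(t1.h, t2.h)


class TestMetaPriorConfig:
    @pytest.mark.parametrize(
        "name,lower", [("weak", 0.1), ("normal", 1.0), ("strong", 10.0)]
    )
    def test_presets(self, name, lower):
        mp = MetaPriorConfig.preset(name)
        assert mp.w == (lower, 1.0, 1.0)
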