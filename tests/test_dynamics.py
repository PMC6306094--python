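import copy
import dataclasses

import numpy as np
import pytest

from olfnet import DynamicsConfig, MothState, generate_moth, simulate
from olfnet.dynamics import check_convergence, drift, sigmoid, step_em
from olfnet.stimuli import build_learning_schedule, build_schedule


def phase_slice(res, sched, name):
    t0, t1 = sched.phase_bounds[name]
    return (res.time >= t0) & (res.time < t1)


@pytest.fixture(scope="module")
def small_run(small_setup):
    moth, cfg, maps, sched = small_setup
    res = simulate(moth, sched, cfg, seed=4,
                   record=("RN", "LN", "PN", "QN", "KC", "EN"),
                   record_stride=2)
    return moth, cfg, maps, sched, res


class TestDrift:
    def test_zero_weights_zero_input_decays_to_sigmoid_origin(self, small_moth):
        """With no drive the fixed point is s(0) = 0 for every population."""
        moth = copy.deepcopy(small_moth)
        for name in ("M_LG", "M_LR", "M_LL", "M_LP", "M_RQ", "M_LQ",
                     "M_PK", "M_QK", "M_KE"):
            getattr(moth, name)[:] = 0.0
        moth.M_RP[:] = 0.0
        moth.M_RL[:] = 0.0
        moth.rn_spont[:] = 0.0
        cfg = DynamicsConfig.from_template(moth.template, lh_inhibition=0.0)
        t = moth.template
        x = MothState(np.full(t.n_glomeruli, 3.0), np.full(t.n_glomeruli, 3.0),
                      np.full(t.n_glomeruli, 3.0), np.full(t.n_qn, 3.0),
                      np.full(t.n_kc, 3.0), np.full(t.n_en, 3.0))
        d = drift(x, moth, np.zeros(t.n_glomeruli), 0.0, cfg)
        for pop in ("uR", "uL", "P", "Q", "K", "E"):
            np.testing.assert_allclose(getattr(d, pop),
                                       -getattr(x, pop) / cfg.tau)

    def test_pn_drift_independent_of_octopamine_when_channel_zero(
            self, small_moth):
        """M_OP = 0: PN dynamics identical with and without octopamine."""
        assert np.all(small_moth.M_OP == 0.0)
        cfg = DynamicsConfig.from_template(small_moth.template)
        t = small_moth.template
        rng = np.random.default_rng(0)
        x = MothState(rng.uniform(0, 10, t.n_glomeruli),
                      rng.uniform(0, 10, t.n_glomeruli),
                      rng.uniform(0, 10, t.n_glomeruli),
                      rng.uniform(0, 10, t.n_qn),
                      rng.uniform(0, 10, t.n_kc),
                      rng.uniform(0, 10, t.n_en))
        drive = rng.uniform(0, 5, t.n_glomeruli)
        d0 = drift(x, small_moth, drive, 0.0, cfg)
        d1 = drift(x, small_moth, drive, 1.0, cfg)
        np.testing.assert_allclose(d0.P, d1.P)
        # RNs do have an octopamine channel
        assert not np.allclose(d0.uR, d1.uR)

    def test_dimension_mismatch_raises(self, small_moth):
        cfg = DynamicsConfig.from_template(small_moth.template)
        bad = MothState(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(2),
                        np.zeros(5), np.zeros(1))
        with pytest.raises(ValueError):
            drift(bad, small_moth, np.zeros(3), 0.0, cfg)


class TestStepEM:
    def test_zero_noise_zero_drift_is_identity(self):
        x = MothState(*[np.full(3, 5.0) for _ in range(6)])
        z = MothState(*[np.zeros(3) for _ in range(6)])
        out = step_em(x, z, dt=0.01, eps=0.0, rng=None)
        for pop in ("uR", "uL", "P", "Q", "K", "E"):
            np.testing.assert_array_equal(getattr(out, pop),
                                          getattr(x, pop))

    def test_zero_noise_reduces_to_forward_euler(self):
        rng = np.random.default_rng(1)
        x = MothState(*[rng.uniform(1, 5, 4) for _ in range(6)])
        f = MothState(*[rng.uniform(-1, 1, 4) for _ in range(6)])
        out = step_em(x, f, dt=0.02, eps=0.0, rng=None)
        for pop in ("uR", "uL", "P", "Q", "K", "E"):
            np.testing.assert_allclose(
                getattr(out, pop),
                np.maximum(getattr(x, pop) + 0.02 * getattr(f, pop), 0.0))

    def test_increment_variance_matches_eps_sq_dt(self):
        """Var(x1 - x0) ~ eps^2 * dt for pure-noise steps."""
        eps, dt = 2.0, 0.01
        rng = np.random.default_rng(7)
        x = MothState(*[np.full(50, 100.0) for _ in range(6)])
        zero = MothState(*[np.zeros(50) for _ in range(6)])
        incs = []
        for _ in range(400):
            out = step_em(x, zero, dt=dt, eps=eps, rng=rng)
            incs.append(out.uR - x.uR)
        var = np.var(np.concatenate(incs))
        assert var == pytest.approx(eps ** 2 * dt, rel=0.05)
        # KC/EN coordinates receive no noise
        out = step_em(x, zero, dt=dt, eps=eps, rng=rng)
        np.testing.assert_array_equal(out.K, x.K)
        np.testing.assert_array_equal(out.E, x.E)

    def test_euler_global_error_is_first_order(self):
        # exponential decay dx/dt = -x integrated to t=1
        errs = []
        for dt in (0.02, 0.01, 0.005):
            x = 1.0
            for _ in range(int(1.0 / dt)):
                x += dt * -x
            errs.append(abs(x - np.exp(-1.0)))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.1)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.1)


class TestSimulate:
    def test_fused_loop_matches_drift_step_composition(self, small_setup):
        moth, cfg, maps, _ = small_setup
        sched = build_learning_schedule(2, 0, 1, dt=cfg.dt, odor_maps=maps,
                                        baseline_stims=2, post_stims=2,
                                        quiet=1.0)
        n = 60
        res = simulate(moth, sched, cfg, seed=9, plastic=False,
                       record=("RN", "LN", "PN", "QN", "KC", "EN"))
        drive = sched.glomerular_drive()
        rng = np.random.default_rng(9)
        state = MothState.zeros(moth)
        for i in range(n):
            d = drift(state, moth, drive[i], sched.octopamine[i], cfg)
            state = step_em(state, d, cfg.dt, cfg.noise, rng)
        for pop, attr in zip(("RN", "LN", "PN", "QN", "KC", "EN"),
                             ("uR", "uL", "P", "Q", "K", "E")):
            np.testing.assert_allclose(res.rates[pop][n - 1],
                                       getattr(state, attr).astype(np.float32),
                                       rtol=1e-5, atol=1e-5)

    def test_rates_nonnegative_and_finite(self, small_run):
        *_, res = small_run
        for pop, arr in res.rates.items():
            assert np.isfinite(arr).all(), pop
            assert (arr >= 0).all(), pop

    def test_deterministic_given_seed(self, small_setup):
        moth, cfg, maps, sched = small_setup
        a = simulate(moth, sched, cfg, seed=11, record=("PN",))
        b = simulate(moth, sched, cfg, seed=11, record=("PN",))
        np.testing.assert_array_equal(a.rates["PN"], b.rates["PN"])
        np.testing.assert_array_equal(a.weights_final["M_KE"],
                                      b.weights_final["M_KE"])

    def test_kc_silent_absent_odor(self, small_run):
        """Baseline KC response absent any odor is essentially zero."""
        *_, sched, res = small_run
        rest = phase_slice(res, sched, "settle")
        assert (res.rates["KC"][rest] < 1.0).mean() > 0.995

    def test_kc_unresponsive_to_octopamine_without_odor(self, small_run):
        """Octopamine alone shifts the AL but leaves KCs silent."""
        *_, sched, res = small_run
        octo = phase_slice(res, sched, "control_octopamine")
        rest = phase_slice(res, sched, "settle")
        assert (res.rates["KC"][octo] < 1.0).mean() > 0.97
        # ... while AL activity visibly shifts
        assert (res.rates["RN"][octo].mean()
                > 1.1 * res.rates["RN"][rest].mean())

    def test_al_returns_to_baseline_after_octopamine(self, small_run):
        *_, sched, res = small_run
        before = phase_slice(res, sched, "settle")
        after = phase_slice(res, sched, "rest")
        m0 = res.rates["PN"][before].mean()
        m1 = res.rates["PN"][after].mean()
        assert m1 / m0 == pytest.approx(1.0, abs=0.2)

    def test_kc_en_deterministic_given_al_trajectory(self, small_setup):
        """KC/EN receive no direct noise: replaying the integration with
        the same AL noise stream reproduces them exactly."""
        moth, cfg, maps, sched = small_setup
        a = simulate(moth, sched, cfg, seed=21, record=("KC", "EN"))
        b = simulate(moth, sched, cfg, seed=21, record=("KC", "EN"))
        np.testing.assert_array_equal(a.rates["KC"], b.rates["KC"])
        np.testing.assert_array_equal(a.rates["EN"], b.rates["EN"])

    def test_fixed_point_reached_under_constant_input(self, small_moth):
        """With constant input and no noise the network settles to the
        drift's algebraic fixed point (a few tau per cascade stage)."""
        cfg = DynamicsConfig.from_template(small_moth.template, noise=0.0)
        sched = build_schedule([{"kind": "quiet", "duration": 5.0}],
                               dt=cfg.dt, n_odors=1)
        res = simulate(small_moth, sched, cfg, record=("RN", "LN", "PN"))
        final = MothState(
            res.rates["RN"][-1].astype(float),
            res.rates["LN"][-1].astype(float),
            res.rates["PN"][-1].astype(float),
            np.zeros(small_moth.template.n_qn),
            np.zeros(small_moth.template.n_kc),
            np.zeros(small_moth.template.n_en))
        d = drift(final, small_moth, np.zeros(small_moth.template.n_glomeruli),
                  0.0, cfg)
        assert np.abs(d.uR).max() * cfg.tau < 0.05
        assert np.abs(d.P).max() * cfg.tau < 0.05

    def test_dt_mismatch_raises(self, small_setup):
        moth, cfg, maps, sched = small_setup
        bad = dataclasses.replace(cfg, dt=0.02)
        with pytest.raises(ValueError):
            simulate(moth, sched, bad)


class TestConvergence:
    def test_em_matches_rk4_at_10ms(self, small_setup):
        """Noise-free Euler at dt = 10 ms tracks the adaptive RK
        reference within 1% of the peak rate."""
        moth, cfg, maps, _ = small_setup
        sched = build_learning_schedule(2, 0, 1, dt=0.01, odor_maps=maps,
                                        baseline_stims=1, post_stims=1,
                                        quiet=2.0, stims_per_session=2,
                                        control_octo_duration=4.0)
        err, peak = check_convergence(moth, sched, cfg)
        assert err < 0.01 * peak

    def test_sigmoid_shape(self):
        x = np.linspace(-10, 1000, 500)
        y = sigmoid(x, slope=1.0, fmax=180.0)
        assert (y[x <= 0] == 0).all()
        assert (np.diff(y) >= 0).all()
        assert y.max() <= 180.0
        assert sigmoid(np.array([1e-3]), 1.0, 180.0)[0] == pytest.approx(
            1e-3, rel=1e-4)
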