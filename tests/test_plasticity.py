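import dataclasses

import numpy as np
import pytest

from olfnet import (DynamicsConfig, PlasticState, apply_plasticity,
                    generate_moth, hebbian_update, simulate)
from olfnet.dynamics import MothState
from olfnet.stimuli import build_learning_schedule, odor_maps_for


class TestHebbianUpdate:
    def test_silent_presynaptic_side_blocks_growth(self):
        """'Fire together, wire together' is an AND gate."""
        W = np.full((3, 2), 0.5)
        out = hebbian_update(W, f_pre=np.zeros(2), f_post=np.ones(3) * 9.0,
                             gamma=1.0, dt=1.0)
        np.testing.assert_array_equal(out, W)

    def test_single_pair_increment(self):
        W = np.zeros((1, 1))
        out = hebbian_update(W, f_pre=[3.0], f_post=[2.0], gamma=1.0, dt=1.0)
        assert out[0, 0] == pytest.approx(6.0)

    def test_matches_elementwise_brute_force(self):
        """Masked update equals the entry-by-entry rule on a toy matrix."""
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 1, (3, 2))
        mask = np.array([[True, False], [True, True], [False, True]])
        W = W * mask
        pre, post = rng.uniform(0, 4, 2), rng.uniform(0, 4, 3)
        gamma, dt = 0.7, 0.01
        expected = W.copy()
        for a in range(3):
            for b in range(2):
                if mask[a, b]:
                    expected[a, b] += dt * gamma * post[a] * pre[b]
        out = hebbian_update(W, pre, post, gamma, dt, mask=mask)
        np.testing.assert_allclose(out, expected)
        assert (out[~mask] == 0).all()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            hebbian_update(np.zeros((1, 1)), [-1.0], [1.0], 1.0, 1.0)


class TestApplyPlasticity:
    def make_state(self, moth):
        t = moth.template
        rng = np.random.default_rng(0)
        return MothState(rng.uniform(0, 5, t.n_glomeruli),
                         rng.uniform(0, 5, t.n_glomeruli),
                         rng.uniform(0, 5, t.n_glomeruli),
                         rng.uniform(0, 5, t.n_qn),
                         rng.uniform(0, 5, t.n_kc),
                         rng.uniform(0, 5, t.n_en))

    def test_closed_gate_is_identity(self, small_moth):
        ps = PlasticState.from_moth(small_moth)
        before = {k: getattr(ps, k).copy() for k in ("M_PK", "M_QK", "M_KE")}
        apply_plasticity(ps, self.make_state(small_moth), o=0, dt=0.01)
        for k, v in before.items():
            np.testing.assert_array_equal(getattr(ps, k), v)

    def test_open_gate_grows_all_three_layers(self, small_moth):
        ps = PlasticState.from_moth(small_moth)
        before = {k: getattr(ps, k).copy() for k in ("M_PK", "M_QK", "M_KE")}
        apply_plasticity(ps, self.make_state(small_moth), o=1, dt=0.01)
        for k in ("M_PK", "M_QK", "M_KE"):
            assert (getattr(ps, k) >= before[k]).all()
            assert (getattr(ps, k) > before[k]).any()
        # structural zeros stay zero
        assert (ps.M_PK[~ps.pk_mask] == 0).all()

    def test_invalid_gate_rejected(self, small_moth):
        with pytest.raises(ValueError):
            apply_plasticity(PlasticState.from_moth(small_moth),
                             self.make_state(small_moth), o=2, dt=0.01)


class TestPlasticityInSimulation:
    def test_weights_constant_without_training(self, small_setup):
        """No-gate schedules leave plastic weights bit-exactly unchanged."""
        moth, cfg, maps, _ = small_setup
        sched = build_learning_schedule(2, 0, 0, dt=cfg.dt, odor_maps=maps,
                                        baseline_stims=2, post_stims=2)
        res = simulate(moth, sched, cfg, seed=5)
        for k in ("M_PK", "M_QK", "M_KE"):
            np.testing.assert_array_equal(res.weights_final[k],
                                          res.weights_initial[k])

    def test_gate_soundness_octopamine_alone_never_trains(self, small_setup):
        """Weight trajectories depend on octopamine only through o(t):
        control octopamine (gate closed) produces zero growth."""
        moth, cfg, maps, sched = small_setup
        res = simulate(moth, sched, cfg, seed=5, plastic=False)
        for k in ("M_PK", "M_QK", "M_KE"):
            np.testing.assert_array_equal(res.weights_final[k],
                                          res.weights_initial[k])

    def test_weights_nondecreasing_during_training(self, small_setup):
        moth, cfg, maps, sched = small_setup
        res = simulate(moth, sched, cfg, seed=5)
        for k in ("M_PK", "M_QK", "M_KE"):
            assert (res.weights_final[k] >= res.weights_initial[k]).all()
        assert (res.weights_final["M_KE"] > res.weights_initial["M_KE"]).any()

    def test_al_matrices_untouched_by_training(self, small_setup):
        moth, cfg, maps, sched = small_setup
        before = {k: getattr(moth, k).copy()
                  for k in ("M_LR", "M_LL", "M_LP", "M_RP", "M_RL", "M_OR")}
        simulate(moth, sched, cfg, seed=5)
        for k, v in before.items():
            np.testing.assert_array_equal(getattr(moth, k), v)

    def test_silent_kcs_gain_no_output_weight(self, small_setup):
        """A KC that never fires during training keeps its naive KC->EN
        weight exactly."""
        moth, cfg, maps, sched = small_setup
        res = simulate(moth, sched, cfg, seed=5)
        train_resp = res.responses("KC", 0, "train")
        silent = train_resp.max(axis=0) == 0.0
        assert silent.any()
        dKE = res.weights_final["M_KE"] - res.weights_initial["M_KE"]
        assert np.abs(dKE[:, silent]).max() == 0.0

    def test_trained_odor_kcs_gain_more_output_weight(self, small_setup):
        moth, cfg, maps, sched = small_setup
        res = simulate(moth, sched, cfg, seed=5)
        resp = res.responses("KC", 0, "baseline").mean(axis=0)
        dKE = (res.weights_final["M_KE"] - res.weights_initial["M_KE"])[0]
        responsive = resp >= 1.0
        assert dKE[responsive].mean() > 5 * max(dKE[~responsive].mean(), 1e-12)

    def test_optional_decay_shrinks_inactive_weights(self, small_moth):
        ps = PlasticState.from_moth(small_moth)
        ps.decay = 0.5
        t = small_moth.template
        quiet = MothState(np.zeros(t.n_glomeruli), np.zeros(t.n_glomeruli),
                          np.zeros(t.n_glomeruli), np.zeros(t.n_qn),
                          np.zeros(t.n_kc), np.zeros(t.n_en))
        before = ps.M_KE.copy()
        apply_plasticity(ps, quiet, o=1, dt=0.1)
        assert (ps.M_KE < before).all()
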