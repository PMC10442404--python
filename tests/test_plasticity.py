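"""The predictive learning rule: errors, influence traces, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prespike import (
    InputTrace,
    NeuronParams,
    PlasticityParams,
    SequenceSpec,
    SynapseState,
    batch_train,
    epoch_gradient,
    epoch_loss,
    filter_raster,
    generate_sequence_epoch,
    global_signal,
    online_step,
    prediction_error,
    run_epoch_trained,
    run_epoch_voltage,
    update_influence,
)


def _subthreshold_instance(seed=5, n_channels=2, T=10.0):
    """A noisy spike-free instance (high threshold keeps the neuron silent)."""
    nparams = NeuronParams(v_th=50.0)
    spec = SequenceSpec(n_seq=n_channels, inter_spike_delay=2.0, jitter_range=0.0,
                        background_rate=40.0, n_distractors=0, onset=1.0, T=T)
    trace = filter_raster(generate_sequence_epoch(spec, seed), nparams.h)
    return trace, nparams


class TestStepQuantities:
    def test_prediction_error_arithmetic(self):
        eps = prediction_error(np.array([1.0, 0.0]), 0.5, np.array([0.4, 0.2]))
        assert np.allclose(eps, [0.8, -0.1])

    def test_zero_voltage_passes_input_through(self, rng):
        x = rng.random(4)
        assert np.allclose(prediction_error(x, 0.0, rng.random(4)), x)

    def test_perfect_prediction_zero_error(self):
        w = np.array([0.3, 0.7])
        assert np.allclose(prediction_error(0.5 * w, 0.5, w), 0.0)

    def test_global_signal_dot_product(self):
        assert global_signal(np.array([0.8, -0.1]), np.array([0.4, 0.2])) == \
            pytest.approx(0.30)

    def test_global_signal_orthogonal(self):
        assert global_signal(np.array([1.0, -1.0]), np.array([0.5, 0.5])) == \
            pytest.approx(0.0)

    def test_influence_geometric_fixed_point(self, nparams):
        c = 0.7
        p = np.zeros(1)
        for _ in range(20_000):
            p = update_influence(p, np.array([c]), nparams)
        assert p[0] == pytest.approx(c / (1 - nparams.alpha), rel=1e-6)


class TestInfluenceIsVoltageGradient:
    def test_p_matches_finite_difference_dv_dw(self):
        trace, nparams = _subthreshold_instance()
        w = np.array([0.25, 0.4])
        res = run_epoch_trained(trace, SynapseState(w), nparams,
                                PlasticityParams(eta=1.0), train=False)
        # final-step influence vs. centered finite differences of v_T
        h = 1e-6
        fd = np.empty(2)
        for i in range(2):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            vp, _ = run_epoch_voltage(trace, wp, nparams)
            vm, _ = run_epoch_voltage(trace, wm, nparams)
            fd[i] = (vp[-1] - vm[-1]) / (2 * h)
        assert np.allclose(res.syn.p, fd, rtol=1e-4)


class TestOnlineStep:
    def test_zero_error_is_fixed_point(self):
        syn = SynapseState(np.array([0.2, 0.3]), np.array([1.0, 2.0]))
        out = online_step(syn, np.zeros(2), 0.7, 0.0,
                          PlasticityParams(eta=0.1, mode="online"))
        assert np.allclose(out.w, syn.w)

    def test_heterosynaptic_decay_with_silent_input(self):
        # x = 0 and v > 0: the first term reduces each weight by eta*v^2*w
        w = np.array([0.4, 0.1])
        v = 0.8
        eps = prediction_error(np.zeros(2), v, w)
        g = global_signal(eps, w)
        out = online_step(SynapseState(w), eps, v, g,
                          PlasticityParams(eta=0.01, mode="online"))
        first_term_only = w + 0.01 * eps * v
        assert np.allclose(first_term_only, w - 0.01 * v**2 * w)
        assert np.all(out.w < w)  # both terms depress here

    def test_scaled_rule_zero_weight_stays_zero(self, rng):
        w = np.array([0.0, 0.5])
        pp = PlasticityParams(eta=0.1, mode="online_scaled")
        for _ in range(50):
            eps = rng.normal(size=2)
            out = online_step(SynapseState(w, rng.random(2)), eps,
                              rng.random(), rng.normal(), pp)
            w = out.w
        assert w[0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_oja_identity(self, seed):
        """First update term == x*v - v^2*w (time-shifted Oja rule)."""
        r = np.random.default_rng(seed)
        x, w = r.random(5), r.random(5)
        v = r.random()
        eps = prediction_error(x, v, w)
        assert np.allclose(eps * v, x * v - v**2 * w, atol=1e-12)

    def test_scaled_rule_preserves_nonnegativity(self, rng):
        pp = PlasticityParams(eta=1e-3, mode="online_scaled")
        nparams = NeuronParams()
        trace = InputTrace(rng.random((400, 4)), nparams.h, 2.0)
        syn = SynapseState(rng.random(4) * 0.05)
        for _ in range(5):
            syn = run_epoch_trained(trace, syn, nparams, pp).syn
            assert np.all(syn.w >= 0)


class TestEpochTraining:
    def test_frozen_training_equals_plain_voltage_run(self, two_input_trace, nparams):
        w = np.array([0.03, 0.03])
        res = run_epoch_trained(two_input_trace, SynapseState(w), nparams,
                                PlasticityParams(eta=1e-3), train=False)
        v, s = run_epoch_voltage(two_input_trace, w, nparams)
        assert np.array_equal(res.v, v)
        assert np.array_equal(res.s.astype(int), s)
        assert np.allclose(res.syn.w, w)
        assert res.loss > 0  # loss recorded even with plasticity off

    def test_divergence_guard_raises(self, two_input_trace, nparams):
        with pytest.raises(FloatingPointError):
            run_epoch_trained(two_input_trace, SynapseState(np.array([1.0, 1.0])),
                              nparams, PlasticityParams(eta=5.0, mode="online"))

    def test_single_channel_online_matches_batch_minimizer(self):
        """Online training at small eta converges to the loss minimum that
        batch gradient descent (and a brute-force scan) find on the same
        repeated epoch."""
        trace, nparams = _subthreshold_instance(seed=3, n_channels=1, T=20.0)
        pp_online = PlasticityParams(eta=2e-5, mode="online")
        syn = SynapseState(np.array([0.1]))
        for _ in range(4000):
            syn = run_epoch_trained(trace, syn, nparams, pp_online).syn
        traj, _ = batch_train(trace, np.array([0.1]), nparams,
                              PlasticityParams(eta=2e-5, mode="batch"), 4000)
        ws = np.linspace(0.02, 0.2, 181)
        brute = ws[np.argmin([epoch_loss(trace, np.array([w]), nparams)
                              for w in ws])]
        assert traj[-1, 0] == pytest.approx(brute, abs=0.002)
        assert syn.w[0] == pytest.approx(traj[-1, 0], rel=0.05)


class TestEpochGradient:
    def test_zero_input_zero_gradient(self, nparams):
        trace = InputTrace(np.zeros((100, 2)), nparams.h, 2.0)
        assert not epoch_gradient(trace, np.array([0.3, 0.1]), nparams).any()

    def test_gradient_matches_finite_differences(self):
        trace, nparams = _subthreshold_instance(seed=9, n_channels=2, T=10.0)
        w = np.array([0.3, 0.2])
        g = epoch_gradient(trace, w, nparams)
        h = 1e-6
        for i in range(2):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd = (epoch_loss(trace, wp, nparams) - epoch_loss(trace, wm, nparams)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5)

    def test_timescale_separation_online_approaches_batch(self):
        """K online epochs at eta/K approach one batch step's direction."""
        trace, nparams = _subthreshold_instance(seed=13, n_channels=2, T=10.0)
        w0 = np.array([0.3, 0.2])
        g = epoch_gradient(trace, w0, nparams)
        batch_dir = -g / np.linalg.norm(g)
        K, eta = 50, 1e-6
        syn = SynapseState(w0.copy())
        pp = PlasticityParams(eta=eta / K, mode="online")
        for _ in range(K):
            syn = run_epoch_trained(trace, syn, nparams, pp).syn
        step = syn.w - w0
        cos = step @ batch_dir / np.linalg.norm(step)
        assert cos > 0.99

    def test_max_weight_change_per_window_vanishes_linearly_in_eta(self):
        trace, nparams = _subthreshold_instance(seed=21, n_channels=2, T=10.0)
        drifts = []
        for eta in (1e-7, 1e-8):
            res = run_epoch_trained(trace, SynapseState(np.array([0.3, 0.2])),
                                    nparams, PlasticityParams(eta=eta, mode="online"))
            drifts.append(np.abs(res.syn.w - [0.3, 0.2]).max())
        assert drifts[1] == pytest.approx(drifts[0] / 10, rel=0.05)


class TestBatchTraining:
    def test_zero_epochs_flat_trajectory(self, two_input_trace, nparams):
        traj, rec = batch_train(two_input_trace, np.array([0.01, 0.01]), nparams,
                                PlasticityParams(eta=1e-4, mode="batch"), 0)
        assert traj.shape == (1, 2)
        assert rec.loss.size == 0

    def test_plain_gd_and_adam_reach_similar_loss(self):
        trace, nparams = _subthreshold_instance(seed=3, n_channels=1, T=20.0)
        w0 = np.array([0.1])
        _, rec_gd = batch_train(trace, w0, nparams,
                                PlasticityParams(eta=2e-5, mode="batch"), 4000)
        _, rec_adam = batch_train(
            trace, w0, nparams,
            PlasticityParams(eta=1e-3, mode="batch", batch_optimizer="adam"), 4000)
        assert rec_adam.loss[-1] == pytest.approx(rec_gd.loss[-1], rel=0.01)

    def test_loss_normalization_is_epoch_zero(self, two_input_trace, nparams):
        _, rec = batch_train(two_input_trace, np.array([0.02, 0.02]), nparams,
                             PlasticityParams(eta=1e-5, mode="batch"), 5)
        assert rec.loss_norm[0] == pytest.approx(1.0)
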