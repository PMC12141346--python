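"""WTA plasticity machinery: traces, local updates, scaling, eligibility."""

import dataclasses

import numpy as np
import pytest

from rlsm.wta import (
    RSTDPParams,
    WTAConfig,
    apply_synaptic_scaling,
    build_wta,
    eligibility_step,
    load_weights,
    local_weight_update,
    presyn_trace_step,
    run_wta,
    save_weights,
)


@pytest.fixture
def params():
    return RSTDPParams()


def drive_raster(n_steps=200, n_pre=30, rate=0.2, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((n_steps, n_pre)) < rate


class TestBuild:
    def test_afferent_columns_sum_to_alpha(self, params, rng):
        wta = build_wta(WTAConfig(), 135, rng, params)
        assert np.allclose(wta.state.w.sum(axis=0), params.alpha, rtol=1e-12)

    def test_same_seed_same_weights(self, params):
        a = build_wta(WTAConfig(), 50, np.random.default_rng(3), params)
        b = build_wta(WTAConfig(), 50, np.random.default_rng(3), params)
        assert np.array_equal(a.state.w, b.state.w)

    def test_single_winner_degenerate_case(self, params, rng):
        wta = build_wta(WTAConfig(n_excitatory=1, n_inhibitory=1), 20, rng, params)
        raster = drive_raster(n_pre=20, rate=0.5)
        exc, _ = run_wta(wta, raster, params, dt=1.0)
        assert exc.shape == (200, 1)

    def test_zero_size_layers_rejected(self, params, rng):
        with pytest.raises(ValueError):
            build_wta(WTAConfig(), 0, rng, params)
        with pytest.raises(ValueError):
            WTAConfig(n_excitatory=0)


class TestTraces:
    def test_presyn_trace_decays_to_one_over_e(self):
        x = np.array([1.0])
        for _ in range(300):
            x = presyn_trace_step(x, np.zeros(1), tau_pre=300.0, dt=1.0)
        assert x[0] == pytest.approx(np.exp(-1.0), rel=1e-10)

    def test_spike_is_unit_increment(self):
        x = presyn_trace_step(np.zeros(2), np.array([1.0, 0.0]), 300.0, 1.0)
        assert x[0] == 1.0 and x[1] == 0.0

    def test_rapid_spikes_superpose(self):
        x = np.zeros(1)
        for _ in range(5):
            x = presyn_trace_step(x, np.ones(1), tau_pre=1e9, dt=1e-6)
        assert x[0] == pytest.approx(5.0, rel=1e-9)

    def test_eligibility_decays_to_one_over_e(self):
        e = np.array([0.5])
        for _ in range(500):
            e = eligibility_step(e, 0.0, tau_trace=500.0, dt=1.0)
        assert e[0] == pytest.approx(0.5 * np.exp(-1.0), rel=1e-10)

    def test_eligibility_zero_stays_zero(self):
        e = eligibility_step(np.zeros(3), 0.0, 500.0, 1.0)
        assert np.all(e == 0.0)

    def test_eligibility_superposition(self):
        # response to one update read dt_later: delta * exp(-dt_later/tau)
        e = eligibility_step(np.zeros(1), 0.02, 500.0, 1.0)
        for _ in range(100):
            e = eligibility_step(e, 0.0, 500.0, 1.0)
        assert e[0] == pytest.approx(0.02 * np.exp(-100.0 / 500.0), rel=1e-9)

    def test_trace_response_is_linear_in_the_train(self, rng):
        tau, dt = 300.0, 1.0
        train_a = (rng.random(100) < 0.3).astype(float)
        train_b = (rng.random(100) < 0.3).astype(float)

        def respond(train):
            x = np.zeros(1)
            for s in train:
                x = presyn_trace_step(x, np.array([s]), tau, dt)
            return x[0]

        assert respond(train_a + train_b) == pytest.approx(
            respond(train_a) + respond(train_b), rel=1e-9
        )


class TestLocalUpdate:
    def test_pointwise_value(self, params):
        dw = local_weight_update(np.array([25.0]), np.array([0.5]), params)
        assert dw[0] == pytest.approx(2.5e-4, rel=1e-12)

    def test_zero_at_target(self, params):
        dw = local_weight_update(np.array([20.0]), np.array([0.7]), params)
        assert dw[0] == 0.0

    @pytest.mark.parametrize("x_pre", [0.0, 5.0, 19.0, 21.0, 40.0])
    def test_sign_follows_trace_minus_target(self, params, x_pre):
        dw = local_weight_update(np.array([x_pre]), np.array([0.5]), params)
        assert np.sign(dw[0]) == np.sign(x_pre - params.x_tar)

    def test_rejects_out_of_bound_weights(self, params):
        with pytest.raises(ValueError):
            local_weight_update(np.array([25.0]), np.array([1.5]), params)

    def test_conventional_soft_bound_form(self):
        p = RSTDPParams(weight_dependence="conventional")
        dw = local_weight_update(np.array([25.0]), np.array([0.4]), p)
        assert dw[0] == pytest.approx(1e-4 * 5.0 * 0.6, rel=1e-12)


class TestScaling:
    def test_column_arithmetic(self):
        w = apply_synaptic_scaling(np.array([[1.0], [2.0], [3.0]]), alpha=15.0)
        assert np.allclose(w[:, 0], [2.5, 5.0, 7.5])

    def test_idempotent_on_scaled_columns(self):
        w = np.array([[5.0, 1.0], [10.0, 14.0]])
        assert np.allclose(apply_synaptic_scaling(w, 15.0), w)

    def test_single_synapse_column_blows_past_wmax_then_clamps(self):
        # normalization alone maps [0.2] -> [15]; the engine clamps the
        # result back to w_max afterwards, documenting the interplay.
        w = apply_synaptic_scaling(np.array([[0.2]]), 15.0)
        assert w[0, 0] == pytest.approx(15.0)
        assert np.clip(w, 0.0, 1.0)[0, 0] == 1.0

    def test_dead_column_is_a_hard_failure(self):
        with pytest.raises(ValueError):
            apply_synaptic_scaling(np.array([[0.0], [0.0]]), 15.0)


class TestRunWTA:
    def test_silent_input_changes_nothing(self, params, rng):
        wta = build_wta(WTAConfig(n_excitatory=4, n_inhibitory=2), 10, rng, params)
        w0 = wta.state.w.copy()
        exc, e = run_wta(wta, np.zeros((100, 10), dtype=bool), params, 1.0)
        assert not exc.any()
        assert np.all(e == 0.0)
        assert np.array_equal(wta.state.w, w0)

    def test_lateral_inhibition_sparsifies(self, params):
        raster = drive_raster(n_steps=300, n_pre=30, rate=0.5, seed=1)
        counts = {}
        for inh_w in (0.0, -3.0):
            cfg = WTAConfig(n_excitatory=8, n_inhibitory=4, inhibition_weight=inh_w)
            wta = build_wta(cfg, 30, np.random.default_rng(0), params)
            exc, _ = run_wta(wta, raster, params, 1.0, plastic=False)
            counts[inh_w] = exc.sum()
        assert counts[0.0] >= counts[-3.0]
        assert counts[-3.0] > 0

    def test_training_is_seed_deterministic(self, params):
        raster = drive_raster(n_steps=300, n_pre=30, rate=0.4, seed=2)
        finals = []
        for _ in range(2):
            wta = build_wta(WTAConfig(n_excitatory=5, n_inhibitory=2), 30,
                            np.random.default_rng(9), params)
            run_wta(wta, raster, params, 1.0, plastic=True)
            finals.append(wta.state.w.copy())
        assert np.array_equal(finals[0], finals[1])

    def test_weights_stay_clamped_and_scaled(self, params):
        raster = drive_raster(n_steps=400, n_pre=40, rate=0.5, seed=3)
        wta = build_wta(WTAConfig(n_excitatory=5, n_inhibitory=2), 40,
                        np.random.default_rng(4), params)
        sums = []
        run_wta(wta, raster, params, 1.0, plastic=True,
                on_weight_update=lambda w: sums.append(w.sum(axis=0).copy()))
        assert len(sums) > 0
        w = wta.state.w
        assert np.all(w >= 0.0) and np.all(w <= params.w_max)

    def test_mismatched_raster_rejected(self, params, rng):
        wta = build_wta(WTAConfig(), 30, rng, params)
        with pytest.raises(ValueError):
            run_wta(wta, np.zeros((10, 7), dtype=bool), params, 1.0)


def test_weight_checkpoint_round_trip(tmp_path, params, rng):
    wta = build_wta(WTAConfig(n_excitatory=3, n_inhibitory=1), 7, rng, params)
    path = tmp_path / "w.tsv"
    save_weights(wta.state, path)
    assert np.allclose(load_weights(path), wta.state.w)


def test_param_validation():
    with pytest.raises(ValueError):
        RSTDPParams(gamma=1.0)  # gamma must be << eta
    with pytest.raises(ValueError):
        RSTDPParams(tau_pre=-1.0)
    with pytest.raises(ValueError):
        RSTDPParams(weight_dependence="other")
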