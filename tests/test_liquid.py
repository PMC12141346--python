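"""Reservoir construction statistics and simulation sanity."""

import dataclasses

import numpy as np
import pytest

from rlsm.data import SpikeSample
from rlsm.liquid import (
    LiquidConfig,
    LiquidTopology,
    attach_inputs,
    build_liquid,
    connection_probability,
    run_liquid,
)


@pytest.fixture
def config():
    return LiquidConfig()


def test_connection_probability_values():
    assert connection_probability(0.0, 0.3, 2.0) == pytest.approx(0.3)
    assert connection_probability(2.0, 0.3, 2.0) == pytest.approx(0.3 * np.exp(-1.0))
    d = np.linspace(0, 10, 50)
    p = connection_probability(d, 0.4, 2.0)
    assert np.all(np.diff(p) < 0) and p[0] == pytest.approx(0.4)
    with pytest.raises(ValueError):
        connection_probability(-1.0, 0.3, 2.0)
    with pytest.raises(ValueError):
        connection_probability(1.0, 0.3, -2.0)


def test_excitatory_inhibitory_split_exact(config):
    topo = build_liquid(config)
    assert topo.is_excitatory.sum() == 108
    assert (~topo.is_excitatory).sum() == 27


def test_dale_sign_consistency_and_no_self_edges(config):
    topo = build_liquid(config)
    assert np.all(np.diag(topo.weight_matrix) == 0.0)
    for i in range(topo.n_neurons):
        out = topo.weight_matrix[i][topo.weight_matrix[i] != 0]
        if topo.is_excitatory[i]:
            assert np.all(out > 0)
        else:
            assert np.all(out < 0)


def test_build_is_seed_reproducible(config):
    a = build_liquid(config)
    b = build_liquid(config)
    assert np.array_equal(a.weight_matrix, b.weight_matrix)
    assert np.array_equal(a.input_matrix, b.input_matrix)
    c = build_liquid(dataclasses.replace(config, seed=1))
    assert not np.array_equal(a.weight_matrix, c.weight_matrix)


def test_vanishing_lambda_gives_empty_edge_set(config):
    topo = build_liquid(dataclasses.replace(config, lambda_=1e-9))
    assert np.count_nonzero(topo.weight_matrix) == 0


def test_saturated_probabilities_give_complete_digraph(config):
    cfg = dataclasses.replace(
        config, c_ee=1.0, c_ei=1.0, c_ii=1.0, c_ie=1.0, lambda_=1e9
    )
    topo = build_liquid(cfg)
    assert np.count_nonzero(topo.weight_matrix) == 135 * 134


def test_attach_inputs_counts_fanout_events(config):
    topo = build_liquid(config)
    chan = int(np.flatnonzero(topo.input_matrix.sum(axis=1) > 0)[0])
    fanout = np.count_nonzero(topo.input_matrix[chan])
    sample = SpikeSample(
        times=np.array([0.05]),
        channels=np.array([chan]),
        label=0,
        duration=0.1,
        n_channels=70,
    )
    sched = attach_inputs(topo, sample, dt=1.0)
    assert sched.shape == (100, 135)
    assert np.count_nonzero(sched) == fanout
    assert sched.sum() == pytest.approx(fanout * config.input_weight)
    empty = SpikeSample(np.array([]), np.array([]), 0, 0.1, 70)
    assert attach_inputs(topo, empty, dt=1.0).sum() == 0.0


def test_attach_inputs_rejects_channel_mismatch(config):
    topo = build_liquid(config)
    sample = SpikeSample(np.array([0.01]), np.array([3]), 0, 0.1, 30)
    with pytest.raises(ValueError):
        attach_inputs(topo, sample, dt=1.0)


def test_silent_input_means_silent_reservoir(config):
    topo = build_liquid(config)
    raster = run_liquid(topo, config, np.zeros((50, 135)), 50.0, 1.0)
    assert not raster.any()


def test_two_neuron_chain_matches_hand_simulation():
    """A driven neuron excites its target: step-by-step scalar oracle."""
    lifp = dataclasses.replace(LiquidConfig().lif, t_ref=0.0)
    cfg = dataclasses.replace(
        LiquidConfig(
            n_neurons=2, grid_shape=(2, 1, 1), n_input_channels=1, lif=lifp
        )
    )
    topo = LiquidTopology(
        positions=np.array([[0, 0, 0], [1, 0, 0]]),
        is_excitatory=np.array([True, True]),
        weight_matrix=np.array([[0.0, 0.3], [0.0, 0.0]]),
        input_matrix=np.array([[4.0, 0.0]]),
    )
    sched = np.zeros((30, 2))
    sched[0, 0] = 4.0  # one input event at t=0 onto neuron 0
    raster = run_liquid(topo, cfg, sched, 30.0, 1.0)

    # scalar oracle mirroring the engine's update order
    de = np.exp(-1.0 / 5.0)
    v0 = v1 = 0.0
    c_in0 = c_rec1 = 0.0
    spikes0, spikes1 = [], []
    prev0 = False
    for t in range(30):
        c_in0 = c_in0 * de + (4.0 if t == 0 else 0.0)
        c_rec1 = c_rec1 * de + (0.3 if prev0 else 0.0)
        v0 = v0 + (1.0 / 20.0) * (-v0 + 30.0 * c_in0)
        v1 = v1 + (1.0 / 20.0) * (-v1 + 30.0 * c_rec1)
        s0 = v0 >= 15.0
        s1 = v1 >= 15.0
        if s0:
            v0 = 0.0
        if s1:
            v1 = 0.0
        spikes0.append(s0)
        spikes1.append(s1)
        prev0 = s0
    assert np.array_equal(raster[:, 0], np.array(spikes0))
    assert np.array_equal(raster[:, 1], np.array(spikes1))
    assert raster[:, 0].any()  # the driven neuron fired


def test_different_samples_separate(config):
    topo = build_liquid(config)
    rng = np.random.default_rng(0)
    rates = []
    rasters = []
    for seed in (1, 2):
        r = np.random.default_rng(seed)
        times = np.sort(r.uniform(0, 0.1, size=200))
        chans = r.integers(0, 70, size=200)
        sample = SpikeSample(times, chans, 0, 0.1, 70)
        sched = attach_inputs(topo, sample, dt=1.0)
        rasters.append(run_liquid(topo, config, sched, 100.0, 1.0))
    assert rasters[0].any() and rasters[1].any()
    assert not np.array_equal(rasters[0], rasters[1])


def test_edge_list_round_trip(tmp_path, config):
    topo = build_liquid(config)
    path = tmp_path / "edges.tsv"
    topo.save_edge_list(path)
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    assert len(table) == np.count_nonzero(topo.weight_matrix)
    row = table.iloc[0]
    assert topo.weight_matrix[int(row["pre"]), int(row["post"])] == pytest.approx(
        row["weight"]
    )


def test_config_validation():
    with pytest.raises(ValueError):
        LiquidConfig(n_neurons=10, grid_shape=(3, 3, 3))
    with pytest.raises(ValueError):
        LiquidConfig(c_ee=1.5)
    with pytest.raises(ValueError):
        LiquidConfig(lambda_=0.0)
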