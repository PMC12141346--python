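"""Construction and simulation of a 3-D recurrent spiking reservoir.

The reservoir ("liquid") is a column of LIF neurons placed on an integer
grid — 135 neurons on a 15x3x3 column by default — with an 80/20
excitatory/inhibitory split.  A directed synapse from neuron ``i`` to
``j`` exists with the distance-dependent probability

    P(d_ij) = C_xy * exp(-(d_ij / lambda)^2)

where ``d_ij`` is the Euclidean distance between the grid positions,
``lambda`` scales the reach of connectivity, and the base probability
``C_xy`` depends on the excitatory/inhibitory type of the presynaptic
(``x``) and postsynaptic (``y``) neuron.  Weight signs follow the
presynaptic type (Dale-consistent); magnitudes are drawn uniformly from a
configurable range.  Input channels project to excitatory neurons only,
each channel reaching a given neuron with probability
``input_fanout_prob`` at fixed weight ``input_weight``.

Simulation is event-free and clocked: spikes emitted at step ``t`` reach
their targets' synaptic currents at step ``t + 1`` (one ``dt`` of axonal
delay), while external input spikes inject current in their own step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import LIFParams, LIFState, lif_step
from .synapses import ReleaseState, SynapseModelParams

__all__ = [
    "LiquidConfig",
    "LiquidTopology",
    "connection_probability",
    "build_liquid",
    "attach_inputs",
    "run_liquid",
]


@dataclass(frozen=True)
class LiquidConfig:
    """Full parameterization of one reservoir.

    ``c_xy`` is the base connection probability for a presynaptic neuron of
    type ``x`` onto a postsynaptic neuron of type ``y`` (E = excitatory,
    I = inhibitory).  Defaults follow the canonical 135-neuron column:
    C_EE|C_EI|C_II|C_IE = 0.3|0.2|0.1|0.4, lambda = 2.
    """

    n_neurons: int = 135
    grid_shape: tuple[int, int, int] = (15, 3, 3)
    frac_excitatory: float = 0.8
    c_ee: float = 0.3
    c_ei: float = 0.2
    c_ii: float = 0.1
    c_ie: float = 0.4
    lambda_: float = 2.0
    lif: LIFParams = field(default_factory=LIFParams)
    synapse: SynapseModelParams = field(default_factory=SynapseModelParams)
    tau_syn_inhibitory: float = 10.0
    w_low: float = 0.05
    w_high: float = 0.15
    n_input_channels: int = 70
    input_fanout_prob: float = 0.3
    input_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(np.prod(self.grid_shape)) != self.n_neurons:
            raise ValueError(
                f"grid_shape {self.grid_shape} does not hold {self.n_neurons} neurons"
            )
        for name in ("c_ee", "c_ei", "c_ii", "c_ie", "input_fanout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if not 0.0 <= self.frac_excitatory <= 1.0:
            raise ValueError("frac_excitatory must lie in [0, 1]")


@dataclass
class LiquidTopology:
    """A realized reservoir: placements, types, and weighted wiring.

    ``weight_matrix[i, j]`` is the weight of the synapse ``i -> j`` (0 when
    absent); ``input_matrix[c, j]`` the weight from input channel ``c``.
    """

    positions: np.ndarray  # (n, 3) int
    is_excitatory: np.ndarray  # (n,) bool
    weight_matrix: np.ndarray  # (n, n) float, pre x post
    input_matrix: np.ndarray  # (n_channels, n) float

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.input_matrix.shape[0]

    @property
    def recurrent_edges(self) -> list[tuple[int, int, float]]:
        pre, post = np.nonzero(self.weight_matrix)
        return [(int(i), int(j), float(self.weight_matrix[i, j])) for i, j in zip(pre, post)]

    @property
    def input_edges(self) -> list[tuple[int, int, float]]:
        ch, post = np.nonzero(self.input_matrix)
        return [(int(c), int(j), float(self.input_matrix[c, j])) for c, j in zip(ch, post)]

    def save_edge_list(self, path) -> None:
        """Write the recurrent wiring as a ``pre<TAB>post<TAB>weight`` table."""
        with open(path, "w") as fh:
            fh.write("pre\tpost\tweight\n")
            for i, j, w in self.recurrent_edges:
                fh.write(f"{i}\t{j}\t{w:.17g}\n")


def connection_probability(d: float | np.ndarray, c_xx: float, lambda_: float) -> float | np.ndarray:
    """Distance-dependent connection probability C * exp(-(d/lambda)^2)."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if not 0.0 <= c_xx <= 1.0:
        raise ValueError("base probability must lie in [0, 1]")
    out = c_xx * np.exp(-((d / lambda_) ** 2))
    return float(out) if out.ndim == 0 else out


def build_liquid(config: LiquidConfig, rng: np.random.Generator | None = None) -> LiquidTopology:
    """Realize a reservoir from its configuration.

    Neurons fill the grid in C order; excitatory/inhibitory labels are a
    random assignment with exactly ``floor(frac_excitatory * n)`` excitatory
    neurons.  Every ordered pair is wired independently by
    :func:`connection_probability`; self-loops are excluded.  The build is
    bit-reproducible from ``(config, rng seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    grid = np.indices(config.grid_shape).reshape(3, -1).T  # (n, 3)
    n_exc = int(np.floor(config.frac_excitatory * n))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[rng.permutation(n)[:n_exc]] = True

    diff = grid[:, None, :] - grid[None, :, :]
    dist = np.sqrt((diff.astype(np.float64) ** 2).sum(axis=2))

    base = np.empty((n, n), dtype=np.float64)
    base[np.ix_(is_exc, is_exc)] = config.c_ee
    base[np.ix_(is_exc, ~is_exc)] = config.c_ei
    base[np.ix_(~is_exc, ~is_exc)] = config.c_ii
    base[np.ix_(~is_exc, is_exc)] = config.c_ie

    prob = base * np.exp(-((dist / config.lambda_) ** 2))
    np.fill_diagonal(prob, 0.0)
    connected = rng.random((n, n)) < prob

    magnitude = rng.uniform(config.w_low, config.w_high, size=(n, n))
    sign = np.where(is_exc, 1.0, -1.0)[:, None]
    weights = np.where(connected, magnitude * sign, 0.0)

    fan = rng.random((config.n_input_channels, n)) < config.input_fanout_prob
    fan &= is_exc[None, :]  # afferents target excitatory neurons only
    input_matrix = np.where(fan, config.input_weight, 0.0)

    return LiquidTopology(
        positions=grid,
        is_excitatory=is_exc,
        weight_matrix=weights,
        input_matrix=input_matrix,
    )


def attach_inputs(topology: LiquidTopology, sample, dt: float) -> np.ndarray:
    """Turn one spike sample into a per-step current-injection schedule.

    Each input spike adds ``input_weight`` worth of PSC drive to every
    reservoir neuron wired to its channel, in the time bin containing the
    spike.  Returns an ``(n_steps, n_neurons)`` array of injection amounts.
    """
    if sample.n_channels != topology.n_channels:
        raise ValueError(
            f"sample has {sample.n_channels} channels, topology expects {topology.n_channels}"
        )
    times_ms = np.asarray(sample.times, dtype=np.float64) * 1000.0
    channels = np.asarray(sample.channels, dtype=np.intp)
    if channels.size and (channels.min() < 0 or channels.max() >= topology.n_channels):
        raise ValueError("spike channel index out of range")
    n_steps = int(round(sample.duration * 1000.0 / dt))
    bins = np.minimum((times_ms / dt).astype(np.intp), n_steps - 1)
    counts = np.zeros((n_steps, topology.n_channels), dtype=np.float64)
    np.add.at(counts, (bins, channels), 1.0)
    return counts @ topology.input_matrix


def run_liquid(
    topology: LiquidTopology,
    config: LiquidConfig,
    input_schedule: np.ndarray,
    duration: float,
    dt: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the reservoir; return a boolean spike raster (n_steps, n).

    With the default deterministic synapse model the run is a pure function
    of the topology and schedule.  With the stochastic release model a
    seeded ``rng`` is required and per-synapse facilitation/resource states
    evolve during the run.
    """
    n_steps = int(round(duration / dt))
    schedule = np.asarray(input_schedule, dtype=np.float64)
    if schedule.shape != (n_steps, topology.n_neurons):
        raise ValueError(
            f"input schedule shape {schedule.shape} != ({n_steps}, {topology.n_neurons})"
        )
    syn = config.synapse
    if syn.stochastic and rng is None:
        raise ValueError("stochastic synapse model needs a seeded rng")

    is_exc = topology.is_excitatory
    w_exc = topology.weight_matrix * is_exc[:, None]
    w_inh = topology.weight_matrix * (~is_exc)[:, None]
    decay_e = np.exp(-dt / syn.tau_syn)
    decay_i = np.exp(-dt / config.tau_syn_inhibitory)

    n = topology.n_neurons
    state = LIFState.resting(n, config.lif)
    c_input = np.zeros(n)
    c_exc = np.zeros(n)
    c_inh = np.zeros(n)
    prev_spikes = np.zeros(n, dtype=bool)
    release = ReleaseState.fresh((n, n)) if syn.stochastic else None
    raster = np.zeros((n_steps, n), dtype=bool)

    for t in range(n_steps):
        c_input = c_input * decay_e + schedule[t]
        if release is not None:
            release.facilitation *= np.exp(-dt / syn.tau_facil)
            release.resources = 1.0 - (1.0 - release.resources) * np.exp(
                -dt / syn.resource_recovery_tau
            )
            if prev_spikes.any():
                rows = np.flatnonzero(prev_spikes)
                p = np.clip(
                    syn.release_prob_base + release.facilitation[rows], 0.0, 1.0
                )
                released = rng.random(p.shape) < p
                amount = np.where(released, release.resources[rows], 0.0)
                release.resources[rows] = np.where(
                    released, 0.0, release.resources[rows]
                )
                release.facilitation[rows] += syn.facilitation_increment
                add_e = (amount * w_exc[rows]).sum(axis=0)
                add_i = (amount * w_inh[rows]).sum(axis=0)
            else:
                add_e = add_i = 0.0
        else:
            if prev_spikes.any():
                add_e = prev_spikes @ w_exc
                add_i = prev_spikes @ w_inh
            else:
                add_e = add_i = 0.0
        c_exc = c_exc * decay_e + add_e
        c_inh = c_inh * decay_i + add_i
        state, spikes = lif_step(state, config.lif, c_input + c_exc + c_inh, dt)
        raster[t] = spikes
        prev_spikes = spikes
    return raster


def raster_spike_times(raster: np.ndarray, dt: float) -> list[np.ndarray]:
    """Convert a boolean raster to per-neuron spike-time arrays (ms)."""
    return [
        (np.flatnonzero(raster[:, j]) + 1) * dt for j in range(raster.shape[1])
    ]
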