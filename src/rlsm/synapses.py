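"""Synaptic current models for the recurrent reservoirs.

Two interchangeable models transduce presynaptic spikes into postsynaptic
current:

* a deterministic exponential postsynaptic-current (PSC) kernel — every
  spike adds its synaptic weight to a current that decays with ``tau_syn``;
  this is the default and the model all closed-form tests assume;
* a stochastic facilitation/depression model in which each spike releases
  transmitter as a Bernoulli trial whose probability facilitates with
  activity, and whose released amount is limited by a depletable resource
  pool that recovers exponentially.

The stochastic model captures the qualitative role of probabilistic
release and neurotransmitter dynamics in enriching reservoir state while
keeping the deterministic path available for exact verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseModelParams",
    "ReleaseState",
    "synapse_current_step",
    "stochastic_release",
    "decay_release_state",
]


@dataclass(frozen=True)
class SynapseModelParams:
    """Parameters shared by both synapse models.

    tau_syn : PSC decay constant, ms (default 5 for excitatory synapses;
        reservoirs use 10 ms for inhibitory ones).
    release_prob_base : baseline transmitter release probability in [0, 1];
        only meaningful when ``stochastic`` is set.
    facilitation_increment : additive bump of the release probability per
        presynaptic spike; decays with ``tau_facil``.
    resource_recovery_tau : time constant, ms, of the resource pool's
        recovery towards 1 after depletion.
    stochastic : selects the probabilistic-release model.
    """

    tau_syn: float = 5.0
    release_prob_base: float = 1.0
    facilitation_increment: float = 0.1
    tau_facil: float = 100.0
    resource_recovery_tau: float = 200.0
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError(f"tau_syn must be positive, got {self.tau_syn}")
        if not 0.0 <= self.release_prob_base <= 1.0:
            raise ValueError("release_prob_base must lie in [0, 1]")
        if self.tau_facil <= 0 or self.resource_recovery_tau <= 0:
            raise ValueError("facilitation/recovery time constants must be positive")


@dataclass
class ReleaseState:
    """Per-synapse facilitation (added release probability) and resources."""

    facilitation: np.ndarray
    resources: np.ndarray

    @classmethod
    def fresh(cls, shape) -> "ReleaseState":
        return cls(
            facilitation=np.zeros(shape, dtype=np.float64),
            resources=np.ones(shape, dtype=np.float64),
        )


def synapse_current_step(
    current: np.ndarray,
    spikes: np.ndarray,
    weights: np.ndarray,
    params: SynapseModelParams,
    dt: float,
    post: np.ndarray | None = None,
    n_post: int | None = None,
    release_amount: np.ndarray | float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the exponential-PSC model over a bank of synapses.

    ``current[s]`` is the PSC of synapse ``s``; it decays by
    ``exp(-dt/tau_syn)`` and each presynaptic spike adds
    ``weight * release_amount``.  Inhibitory synapses carry negative
    weights and therefore contribute negative current.

    Returns ``(updated PSC, summed current per postsynaptic neuron)``.
    With ``post`` omitted all synapses are assumed to converge on a single
    neuron, otherwise ``post[s]`` names the target and ``n_post`` sizes the
    output vector.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    weights = np.asarray(weights, dtype=np.float64)
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    spikes = np.asarray(spikes, dtype=bool)
    new_current = np.asarray(current, dtype=np.float64) * np.exp(-dt / params.tau_syn)
    new_current = new_current + np.where(spikes, weights * release_amount, 0.0)
    if post is None:
        summed = np.array([new_current.sum()])
    else:
        if n_post is None:
            raise ValueError("n_post is required when post indices are given")
        summed = np.bincount(np.asarray(post), weights=new_current, minlength=n_post)
    return new_current, summed


def stochastic_release(
    params: SynapseModelParams,
    facilitation: np.ndarray,
    resources: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve a presynaptic spike on each synapse of the bank.

    Release happens as a Bernoulli trial with probability
    ``clip(release_prob_base + facilitation, 0, 1)``; on release the whole
    resource pool is emitted (so the expected released amount per spike is
    ``p * resources``) and the pool empties.  Facilitation then increments
    by ``facilitation_increment``.  Probabilities and resources are clamped
    to [0, 1]; degenerate parameters therefore cannot escape those bounds.

    Returns ``(released amount, new facilitation, new resources)``.
    """
    facilitation = np.asarray(facilitation, dtype=np.float64)
    resources = np.clip(np.asarray(resources, dtype=np.float64), 0.0, 1.0)
    p = np.clip(params.release_prob_base + facilitation, 0.0, 1.0)
    if params.stochastic:
        released_mask = rng.random(size=p.shape) < p
    else:
        released_mask = p > 0.0
    amount = np.where(released_mask, resources, 0.0)
    new_resources = np.where(released_mask, 0.0, resources)
    new_facil = facilitation + params.facilitation_increment
    return amount, new_facil, new_resources


def decay_release_state(
    params: SynapseModelParams, state: ReleaseState, dt: float
) -> ReleaseState:
    """Relax facilitation towards 0 and resources towards 1 over ``dt`` ms."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    facil = state.facilitation * np.exp(-dt / params.tau_facil)
    res = 1.0 - (1.0 - state.resources) * np.exp(-dt / params.resource_recovery_tau)
    return ReleaseState(facilitation=facil, resources=np.clip(res, 0.0, 1.0))
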