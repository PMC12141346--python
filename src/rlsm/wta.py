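"""Winner-takes-all layer with reward-modulated STDP on its afferents.

The layer holds ``n_excitatory`` winner neurons, each receiving an
all-to-all plastic projection from the first reservoir, and
``n_inhibitory`` interneurons implementing lateral inhibition: every
winner excites every interneuron, and every interneuron inhibits every
winner, so strongly driven winners silence the rest and the layer's
output stays sparse.

Plasticity on the reservoir->winner synapses combines four pieces:

* a presynaptic trace ``x_pre`` per reservoir neuron, incremented by one
  at each presynaptic spike and decaying with ``tau_pre``;
* a local update triggered whenever a winner ``j`` fires:
  ``dw_local = eta * (x_pre - x_tar) * (w_max * w)**mu``, potentiating
  synapses whose recent presynaptic drive exceeds the target ``x_tar``
  and depressing the rest;
* multiplicative synaptic scaling that renormalizes each winner's summed
  afferent weight to ``alpha`` after every update, preventing runaway
  potentiation;
* an eligibility trace ``e_trace`` per synapse that accumulates the local
  updates and decays with ``tau_trace``, so that a global reward arriving
  at the end of a sample can credit the synapses that were recently
  active (see :mod:`rlsm.feedback`).

Step order inside :func:`run_wta` (mirrored exactly by the scalar oracle
used in the tests): (1) decay ``e_trace``; (2) decay ``x_pre`` and add this
step's presynaptic spikes; (3) update synaptic currents — presynaptic
spikes of this step drive the winners through ``w``, while winner/
interneuron spikes of the *previous* step carry the lateral loop (one
``dt`` delay); (4) integrate all LIF neurons; (5) for each winner that
fired: compute ``dw_local`` from the current ``x_pre``, add it to
``e_trace``, and — when plastic — add it to ``w``, clamp to
``[0, w_max]``, and rescale that winner's afferent column to ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .neurons import LIFParams, LIFState, lif_step

__all__ = [
    "WTAConfig",
    "RSTDPParams",
    "RSTDPState",
    "WTANetwork",
    "build_wta",
    "presyn_trace_step",
    "local_weight_update",
    "apply_synaptic_scaling",
    "eligibility_step",
    "run_wta",
]


@dataclass(frozen=True)
class WTAConfig:
    """Sizes and fixed wiring of the winner-takes-all layer.

    ``inhibition_weight`` (negative) is the interneuron->winner weight and
    ``exc_to_inh_weight`` the winner->interneuron weight, both all-to-all.
    ``n_inhibitory = 0`` disables lateral inhibition (useful for micro
    networks).  The outgoing projection to the second reservoir is owned
    by that reservoir's input wiring; ``wta_to_liquid2_prob`` and
    ``wta_to_liquid2_weight`` parameterize it.
    """

    n_excitatory: int = 20
    n_inhibitory: int = 5
    lif: LIFParams = field(default_factory=LIFParams)
    inhibition_weight: float = -3.0
    exc_to_inh_weight: float = 1.5
    tau_syn: float = 5.0
    tau_syn_inhibitory: float = 10.0
    wta_to_liquid2_prob: float = 0.3
    wta_to_liquid2_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.n_excitatory < 1:
            raise ValueError("need at least one winner neuron")
        if self.n_inhibitory < 0:
            raise ValueError("n_inhibitory must be non-negative")
        if self.inhibition_weight > 0:
            raise ValueError("inhibition_weight must be non-positive")


@dataclass(frozen=True)
class RSTDPParams:
    """Constants of the reward-modulated STDP rule.

    Defaults: tau_pre = 300 ms, eta = 1e-4, w_max = 1, x_tar = 20,
    alpha = 15, tau_trace = 500 ms.  ``gamma`` (the strict-feedback decay
    factor, required << eta) defaults to eta / 10.  ``k`` scales the
    eligibility trace into the weight range on reward; ``None`` selects
    the adaptive choice ``w_max / max(1, max|e_trace|)`` per sample.
    ``weight_dependence`` chooses between the literal ``(w_max * w)**mu``
    update factor and the conventional soft-bound ``(w_max - w)**mu``.
    """

    tau_pre: float = 300.0
    eta: float = 1e-4
    w_max: float = 1.0
    x_tar: float = 20.0
    mu: float = 1.0
    alpha: float = 15.0
    tau_trace: float = 500.0
    gamma: float = 1e-5
    k: float | None = None
    weight_dependence: str = "literal"
    strict_decay_eligible_only: bool = False

    def __post_init__(self) -> None:
        if min(self.tau_pre, self.tau_trace) <= 0:
            raise ValueError("trace time constants must be positive")
        if self.eta <= 0 or self.w_max <= 0 or self.alpha <= 0:
            raise ValueError("eta, w_max and alpha must be positive")
        if not self.gamma < self.eta:
            raise ValueError("gamma must be well below eta")
        if self.weight_dependence not in ("literal", "conventional"):
            raise ValueError("weight_dependence must be 'literal' or 'conventional'")


@dataclass
class RSTDPState:
    """Plastic weights plus the two traces that drive their updates."""

    w: np.ndarray  # (n_pre, n_winners)
    x_pre: np.ndarray  # (n_pre,)
    e_trace: np.ndarray  # (n_pre, n_winners)

    def reset_traces(self) -> None:
        self.x_pre[:] = 0.0
        self.e_trace[:] = 0.0

    def copy(self) -> "RSTDPState":
        return RSTDPState(self.w.copy(), self.x_pre.copy(), self.e_trace.copy())


@dataclass
class WTANetwork:
    config: WTAConfig
    n_liquid: int
    state: RSTDPState
    w_exc_to_inh: np.ndarray  # (n_exc, n_inh)
    w_inh_to_exc: np.ndarray  # (n_inh, n_exc)


def build_wta(
    config: WTAConfig,
    n_liquid: int,
    rng: np.random.Generator,
    params: RSTDPParams | None = None,
) -> WTANetwork:
    """Initialize the layer: random afferent weights scaled to ``alpha``.

    Initial weights are Uniform(0, w_max) per synapse and then normalized
    so each winner's afferent column sums to ``alpha``; the lateral loop
    is wired all-to-all at the configured fixed weights.
    """
    if n_liquid < 1:
        raise ValueError("reservoir size must be positive")
    if params is None:
        params = RSTDPParams()
    w = rng.uniform(0.0, params.w_max, size=(n_liquid, config.n_excitatory))
    w = apply_synaptic_scaling(w, params.alpha)
    np.clip(w, 0.0, params.w_max, out=w)
    state = RSTDPState(
        w=w,
        x_pre=np.zeros(n_liquid),
        e_trace=np.zeros((n_liquid, config.n_excitatory)),
    )
    return WTANetwork(
        config=config,
        n_liquid=n_liquid,
        state=state,
        w_exc_to_inh=np.full(
            (config.n_excitatory, config.n_inhibitory), config.exc_to_inh_weight
        ),
        w_inh_to_exc=np.full(
            (config.n_inhibitory, config.n_excitatory), config.inhibition_weight
        ),
    )


def presyn_trace_step(
    x_pre: np.ndarray, spikes: np.ndarray, tau_pre: float, dt: float
) -> np.ndarray:
    """Decay the presynaptic trace and add one unit per arriving spike."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return x_pre * np.exp(-dt / tau_pre) + np.asarray(spikes, dtype=np.float64)


def local_weight_update(
    x_pre: np.ndarray, w: np.ndarray, params: RSTDPParams
) -> np.ndarray:
    """Local update on a winner's afferents when that winner fires.

    ``dw = eta * (x_pre - x_tar) * f(w)`` with ``f(w) = (w_max * w)**mu``
    (literal form) or ``(w_max - w)**mu`` (conventional soft bound).
    """
    w = np.asarray(w, dtype=np.float64)
    if np.any(w < 0) or np.any(w > params.w_max):
        raise ValueError("weights outside [0, w_max]")
    if params.weight_dependence == "literal":
        factor = (params.w_max * w) ** params.mu
    else:
        factor = (params.w_max - w) ** params.mu
    dw = params.eta * (np.asarray(x_pre, dtype=np.float64) - params.x_tar) * factor
    if not np.all(np.isfinite(dw)):
        raise FloatingPointError("non-finite local weight update")
    return dw


def apply_synaptic_scaling(w: np.ndarray, alpha: float) -> np.ndarray:
    """Normalize each winner's summed afferent weight to ``alpha``.

    Columns index winners; proportions within a column are preserved.  An
    all-zero column means a winner with no drive left — a dead neuron —
    and is a hard error.
    """
    w = np.asarray(w, dtype=np.float64)
    sums = w.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("cannot scale a column with non-positive weight sum (dead neuron)")
    return w * (alpha / sums)


def eligibility_step(
    e_trace: np.ndarray, delta_w_local: np.ndarray | float, tau_trace: float, dt: float
) -> np.ndarray:
    """Decay the eligibility trace and fold in this step's local updates."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return e_trace * np.exp(-dt / tau_trace) + delta_w_local


def run_wta(
    wta: WTANetwork,
    liquid_raster: np.ndarray,
    params: RSTDPParams,
    dt: float,
    plastic: bool = True,
    accumulate_eligibility: bool = True,
    reset_traces: bool = True,
    on_weight_update: Callable[[np.ndarray], None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drive the layer with a reservoir raster for one sample.

    Parameters
    ----------
    liquid_raster
        Boolean ``(n_steps, n_liquid)`` spike raster from the first
        reservoir.
    plastic
        Fold local updates into ``w`` online (with clamping and per-event
        scaling).  Disable during the feedback phase — where the reward
        path owns the weights — and during test evaluation.
    accumulate_eligibility
        Maintain ``e_trace``; disable for pure evaluation runs.
    reset_traces
        Zero ``x_pre`` and ``e_trace`` at the start of the sample
        (per-sample bookkeeping; pass ``False`` to carry traces over).
    on_weight_update
        Optional hook called with the weight matrix after every plastic
        update event (used to instrument scaling conservation).

    Returns
    -------
    (winner raster ``(n_steps, n_excitatory)``, end-of-sample eligibility
    snapshot ``(n_liquid, n_excitatory)``).
    """
    cfg = wta.config
    st = wta.state
    if liquid_raster.ndim != 2 or liquid_raster.shape[1] != wta.n_liquid:
        raise ValueError("liquid raster does not match the reservoir size")
    if reset_traces:
        st.reset_traces()
    n_steps = liquid_raster.shape[0]
    n_exc, n_inh = cfg.n_excitatory, cfg.n_inhibitory

    decay_pre = np.exp(-dt / params.tau_pre)
    decay_trace = np.exp(-dt / params.tau_trace)
    decay_e = np.exp(-dt / cfg.tau_syn)
    decay_i = np.exp(-dt / cfg.tau_syn_inhibitory)

    exc_state = LIFState.resting(n_exc, cfg.lif)
    inh_state = LIFState.resting(n_inh, cfg.lif)
    c_ff = np.zeros(n_exc)  # feed-forward drive through plastic w
    c_ie = np.zeros(n_exc)  # interneuron -> winner (negative)
    c_ei = np.zeros(n_inh)  # winner -> interneuron
    prev_exc = np.zeros(n_exc, dtype=bool)
    prev_inh = np.zeros(n_inh, dtype=bool)
    exc_raster = np.zeros((n_steps, n_exc), dtype=bool)

    for t in range(n_steps):
        pre_spikes = liquid_raster[t]
        if accumulate_eligibility:
            st.e_trace *= decay_trace
        st.x_pre = st.x_pre * decay_pre + pre_spikes
        c_ff = c_ff * decay_e + (pre_spikes @ st.w if pre_spikes.any() else 0.0)
        c_ie = c_ie * decay_i + (prev_inh @ wta.w_inh_to_exc if prev_inh.any() else 0.0)
        c_ei = c_ei * decay_e + (prev_exc @ wta.w_exc_to_inh if prev_exc.any() else 0.0)

        exc_state, exc_spikes = lif_step(exc_state, cfg.lif, c_ff + c_ie, dt)
        if n_inh:
            inh_state, inh_spikes = lif_step(inh_state, cfg.lif, c_ei, dt)
        else:
            inh_spikes = prev_inh

        if exc_spikes.any() and (plastic or accumulate_eligibility):
            fired = np.flatnonzero(exc_spikes)
            dw = local_weight_update(st.x_pre[:, None], st.w[:, fired], params)
            if accumulate_eligibility:
                st.e_trace[:, fired] += dw
            if plastic:
                cols = st.w[:, fired] + dw
                np.clip(cols, 0.0, params.w_max, out=cols)
                cols = apply_synaptic_scaling(cols, params.alpha)
                np.clip(cols, 0.0, params.w_max, out=cols)
                st.w[:, fired] = cols
                if on_weight_update is not None:
                    on_weight_update(st.w)

        exc_raster[t] = exc_spikes
        prev_exc, prev_inh = exc_spikes, inh_spikes

    return exc_raster, st.e_trace.copy()


def save_weights(state: RSTDPState, path) -> None:
    """Checkpoint the plastic weight matrix as a plain TSV (pre x winner)."""
    np.savetxt(path, state.w, delimiter="\t", fmt="%.17g")


def load_weights(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
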