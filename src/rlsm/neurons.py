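"""Leaky integrate-and-fire (LIF) neuron dynamics.

The membrane potential of each neuron follows

    tau_m * dV/dt = -(V - V_rest) + R_m * I(t)

integrated with forward Euler at a fixed step ``dt``.  When ``V`` crosses
the threshold ``V_th`` at the end of a step the neuron emits a spike, the
potential is hard-reset to ``V_rest`` and the neuron becomes refractory for
``t_ref`` milliseconds, during which it holds ``V_rest`` and ignores input.

All times are in milliseconds and potentials in millivolts.  The membrane
resistance is treated as a dimensionless gain on the synaptic current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LIFParams", "LIFState", "lif_step", "simulate_neurons"]


@dataclass(frozen=True)
class LIFParams:
    """Parameters of the leaky integrate-and-fire neuron.

    Defaults are the reservoir configuration used throughout the package:
    ``tau_m`` = 20 ms, ``R_m`` = 30, ``V_th`` = 15 mV, ``V_rest`` = 0 mV.
    ``t_ref`` = 2 ms is a conventional refractory period; set it to 0 to
    recover the memoryless threshold unit used in closed-form tests.
    """

    tau_m: float = 20.0
    r_m: float = 30.0
    v_th: float = 15.0
    v_rest: float = 0.0
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass
class LIFState:
    """Mutable per-neuron state: membrane potential and refractory timer."""

    v: np.ndarray
    refractory_remaining: np.ndarray

    @classmethod
    def resting(cls, n_neurons: int, params: LIFParams) -> "LIFState":
        """All neurons at rest with no refractory time pending."""
        return cls(
            v=np.full(n_neurons, params.v_rest, dtype=np.float64),
            refractory_remaining=np.zeros(n_neurons, dtype=np.float64),
        )

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]


def lif_step(
    state: LIFState,
    params: LIFParams,
    i_input: np.ndarray,
    dt: float,
) -> tuple[LIFState, np.ndarray]:
    """Advance all neurons by one Euler step; return (new state, spike mask).

    Non-refractory neurons integrate the membrane equation; any neuron
    ending the step at or above threshold spikes, resets to ``V_rest`` and
    starts its refractory clock.  Refractory neurons clamp to ``V_rest``
    and run down their timer.

    Raises
    ------
    FloatingPointError
        If the potential or input current is non-finite (numerical blow-up).
    ValueError
        If ``dt`` is not positive.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    i_input = np.asarray(i_input, dtype=np.float64)
    if not np.all(np.isfinite(i_input)) or not np.all(np.isfinite(state.v)):
        raise FloatingPointError("non-finite membrane potential or input current")

    refractory = state.refractory_remaining > 0.0
    v = state.v + (dt / params.tau_m) * (
        -(state.v - params.v_rest) + params.r_m * i_input
    )
    v = np.where(refractory, params.v_rest, v)
    timer = np.where(refractory, np.maximum(state.refractory_remaining - dt, 0.0), 0.0)

    spikes = (v >= params.v_th) & ~refractory
    v = np.where(spikes, params.v_rest, v)
    timer = np.where(spikes, params.t_ref, timer)

    return LIFState(v=v, refractory_remaining=timer), spikes


def simulate_neurons(
    params: LIFParams,
    input_current_series: np.ndarray,
    dt: float,
    duration: float,
) -> list[np.ndarray]:
    """Iterate :func:`lif_step` over a dense current series.

    Parameters
    ----------
    input_current_series
        Array of shape ``(n_steps, n_neurons)`` giving the input current of
        every neuron at every step; ``n_steps`` must equal ``duration / dt``.
    dt, duration
        Step size and total simulated time, both in ms.

    Returns
    -------
    list of arrays, one per neuron, holding spike times in ms (spikes are
    stamped at the end of the step in which threshold was crossed).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    series = np.asarray(input_current_series, dtype=np.float64)
    if series.ndim == 1:
        series = series[:, None]  # single neuron
    n_steps = int(round(duration / dt))
    if series.shape[0] != n_steps:
        raise ValueError(
            f"series has {series.shape[0]} steps but duration/dt = {n_steps}"
        )
    n = series.shape[1]
    state = LIFState.resting(n, params)
    spike_times: list[list[float]] = [[] for _ in range(n)]
    for step in range(n_steps):
        state, spikes = lif_step(state, params, series[step], dt)
        t = (step + 1) * dt
        for idx in np.flatnonzero(spikes):
            spike_times[idx].append(t)
    return [np.asarray(s, dtype=np.float64) for s in spike_times]
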