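"""Reward system: turning prediction outcomes into global weight updates.

Once per sample the readout's predicted label is compared with the true
one and the plastic reservoir->winner weights receive the global part of
the three-factor rule, ``dw_feedback = r * e_trace``:

* ``none`` — no reward path at all (the unsupervised baseline);
* ``forgiving`` — positive reinforcement only: on a correct prediction
  every synapse gains ``k * e_trace`` (``k`` matches the eligibility
  trace to the weight range); on a wrong one nothing happens;
* ``strict`` — same reinforcement when correct, but a wrong prediction
  additionally shrinks every plastic weight multiplicatively,
  ``dw = -gamma * w`` with ``gamma << eta``, letting the layer forget
  wiring that backed a misclassification.

After a reinforcement the synaptic-scaling normalization is re-applied so
each winner's afferent sum returns to ``alpha``.  The strict decay is
deliberately not followed by rescaling: it is itself a uniform
multiplicative shrink per column, which rescaling would cancel exactly;
the next reinforcement restores the column sums instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .wta import RSTDPParams, RSTDPState, apply_synaptic_scaling

__all__ = ["FeedbackMode", "Reward", "FeedbackOutcome", "compute_reward", "apply_feedback"]


class FeedbackMode(str, Enum):
    NONE = "none"
    FORGIVING = "forgiving"
    STRICT = "strict"


@dataclass(frozen=True)
class Reward:
    """Reward descriptor: the binary reward and whether to apply decay."""

    predicted: int
    actual: int
    r: float
    decay: bool


@dataclass
class FeedbackOutcome:
    """Record of one sample's reward step: signal and realized change."""

    predicted: int
    actual: int
    reward: float
    delta_w: np.ndarray


def compute_reward(predicted: int, actual: int, mode: FeedbackMode) -> Reward:
    """Binary reward from the label comparison.

    A match yields ``r = 1`` (learning enabled) in any mode.  A mismatch
    yields ``r = 0``; under strict feedback it additionally raises the
    decay directive.
    """
    mode = FeedbackMode(mode)
    if predicted < 0 or actual < 0:
        raise ValueError("labels must be non-negative class indices")
    correct = predicted == actual
    r = 1.0 if (correct and mode is not FeedbackMode.NONE) else 0.0
    decay = (not correct) and mode is FeedbackMode.STRICT
    return Reward(predicted=predicted, actual=actual, r=r, decay=decay)


def _k_scale(e_trace: np.ndarray, params: RSTDPParams) -> float:
    """Adaptive scale matching the eligibility trace to the weight range.

    The homeostatic mean weight is ``alpha / n_pre`` (synaptic scaling
    pins each winner's afferent sum to ``alpha`` over ``n_pre``
    synapses); ``k`` is chosen so the sample's peak ``|e_trace|`` maps to
    exactly that scale, making one reward a weight change of typical
    weight size regardless of how much eligibility the sample generated.
    """
    if params.k is not None:
        return params.k
    peak = float(np.abs(e_trace).max()) if e_trace.size else 0.0
    w_ref = params.alpha / e_trace.shape[0]
    return w_ref / max(1e-9, peak)


def apply_feedback(
    state: RSTDPState, reward: Reward, params: RSTDPParams
) -> FeedbackOutcome:
    """Apply the global reward update to the plastic weights in place.

    ``reward.r == 1`` adds ``k * e_trace`` to every synapse, clamps to
    ``[0, w_max]`` and rescales each winner's afferent sum to ``alpha``.
    A strict-mode decay directive shrinks every weight by ``gamma * w``.
    Otherwise the state is untouched.  Returns the outcome with the
    realized per-synapse change.
    """
    if not np.all(np.isfinite(state.e_trace)):
        raise FloatingPointError("non-finite eligibility trace")
    if reward.r > 0:
        w_before = state.w.copy()
        k = _k_scale(state.e_trace, params)
        state.w += k * state.e_trace
        np.clip(state.w, 0.0, params.w_max, out=state.w)
        state.w = apply_synaptic_scaling(state.w, params.alpha)
        np.clip(state.w, 0.0, params.w_max, out=state.w)
        delta = state.w - w_before
    elif reward.decay:
        delta = -params.gamma * state.w
        if params.strict_decay_eligible_only:
            delta = np.where(state.e_trace != 0.0, delta, 0.0)
        state.w = state.w + delta
    else:
        delta = np.zeros_like(state.w)
    return FeedbackOutcome(
        predicted=reward.predicted,
        actual=reward.actual,
        reward=reward.r,
        delta_w=delta,
    )
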