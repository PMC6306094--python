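"""Octopamine-gated Hebbian plasticity.

The three plastic layers are the excitatory and inhibitory inputs to
the Kenyon cells (PN->KC, QN->KC) and the Kenyon-cell output onto the
readout neuron (KC->EN).  Growth follows the "fire together, wire
together" rule

    dW_ab = gamma * f_a * f_b * dt,

applied each timestep while the training gate o(t) = 1 (octopamine
delivered during training).  Structural zeros of the PN->KC
connectivity stay zero: training changes strengths, not wiring.  There
is no weight decay by default and no weight ceiling; runaway KC
excitation is braked by Hebbian growth of the inhibitory QN->KC layer.
Antennal-lobe matrices and the octopamine channels are never plastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlasticState", "hebbian_update", "apply_plasticity",
           "hebbian_step"]


@dataclass
class PlasticState:
    """Current plastic matrices plus their growth rates."""

    M_PK: np.ndarray
    M_QK: np.ndarray
    M_KE: np.ndarray
    pk_mask: np.ndarray           # structural PN->KC connectivity (bool)
    gamma_pk: float
    gamma_qk: float
    gamma_ke: float
    decay: float = 0.0            # optional exponential decay while gated on

    @classmethod
    def from_moth(cls, moth) -> "PlasticState":
        t = moth.template
        return cls(M_PK=moth.M_PK.copy(), M_QK=moth.M_QK.copy(),
                   M_KE=moth.M_KE.copy(), pk_mask=moth.pk_mask,
                   gamma_pk=t.gamma_pk, gamma_qk=t.gamma_qk,
                   gamma_ke=t.gamma_ke)


def hebbian_update(W: np.ndarray, f_pre: np.ndarray, f_post: np.ndarray,
                   gamma: float, dt: float,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """One Hebbian increment: W + dt*gamma*outer(f_post, f_pre), masked.

    ``mask`` (boolean, same shape as W) marks the structural
    connectivity; entries outside it never grow.  Firing rates must be
    nonnegative, so the update can only increase weights.
    """
    if gamma < 0:
        raise ValueError("growth rate gamma must be >= 0")
    f_pre = np.asarray(f_pre, dtype=float)
    f_post = np.asarray(f_post, dtype=float)
    if (f_pre < 0).any() or (f_post < 0).any():
        raise ValueError("firing rates must be nonnegative")
    dW = (gamma * dt) * np.outer(f_post, f_pre)
    if mask is not None:
        dW = dW * mask
    return W + dW


def apply_plasticity(state: PlasticState, moth_state, o: int,
                     dt: float) -> PlasticState:
    """Advance the plastic weights by one timestep under gate ``o``.

    With ``o == 0`` this is the identity (weights are bit-exactly
    unchanged).  With ``o == 1`` the Hebbian rule is applied to the
    (PN, KC), (QN, KC) and (KC, EN) pairs with their respective growth
    rates.  Mutates and returns ``state``.
    """
    if o not in (0, 1):
        raise ValueError("gate o must be 0 or 1")
    if o == 0:
        return state
    if state.decay > 0.0:
        f = 1.0 - state.decay * dt
        state.M_PK *= f
        state.M_QK *= f
        state.M_KE *= f
    state.M_PK += hebbian_update(0.0, moth_state.P, moth_state.K,
                                 state.gamma_pk, dt, mask=state.pk_mask)
    state.M_QK += hebbian_update(0.0, moth_state.Q, moth_state.K,
                                 state.gamma_qk, dt)
    state.M_KE += hebbian_update(0.0, moth_state.K, moth_state.E,
                                 state.gamma_ke, dt)
    return state


def hebbian_step(weights: dict, pk_mask: np.ndarray, state, gammas: dict,
                 dt: float) -> None:
    """In-place gated update of a ``{"M_PK", "M_QK", "M_KE"}`` dict.

    Fast path used inside the integration loop; semantics identical to
    :func:`apply_plasticity` with the gate open and no decay.
    """
    K = state.K
    weights["M_PK"] += (gammas["M_PK"] * dt) * (K[:, None] * state.P) * pk_mask
    weights["M_QK"] += (gammas["M_QK"] * dt) * (K[:, None] * state.Q)
    weights["M_KE"] += (gammas["M_KE"] * dt) * (state.E[:, None] * K)
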