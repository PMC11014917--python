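"""Attachment error correction: force-dependent detachment of erroneous
kMT-KT bonds.

Amphitelic pairs are stabilised by inter-KT tension and never detach.  Any
other attached MT detaches stochastically:

* plain force dependence (syntelic, monotelic, and the singly-attached
  sister of a merotelic pair): rate ``R_detach * exp(F/F0)``;
* an MT on a dual-pole (merotelic) KT additionally carries the occupancy
  ratio ``n_i/n_j`` and the angle factor ``exp(beta_sign * beta)``, where
  ``beta`` is the angle between the KT->tip vector and the KT->sister axis.
  With the default ``beta_sign = -1`` an erroneous kMT pointing toward the
  sister's pole (small ``beta``) detaches fastest, so kMTs aligned with
  bi-orientation survive.

``F`` is the magnitude of the attachment-spring force on that MT and
``F0`` the normalising force scale (default: the stall force).
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .state import SpindleState

__all__ = [
    "syntelic_detach_rate",
    "merotelic_detach_rate",
    "detach_probability",
    "apply_error_correction",
]


def syntelic_detach_rate(F_i_kt: float, R_detach: float, F0: float) -> float:
    """Force-dependent detachment rate ``R_detach * exp(F/F0)`` (1/s)."""
    if np.any(np.asarray(F_i_kt) < 0):
        raise ValueError("spring load must be non-negative")
    return K.syntelic_detach_rate(F_i_kt, R_detach, F0)


def merotelic_detach_rate(F_i_kt: float, n_i: int, n_j: int, beta: float,
                          R_detach: float, F0: float,
                          beta_sign: float = -1.0) -> float:
    """Detachment rate of one MT on a merotelic (dual-pole) kinetochore.

    ``n_i``: MTs on this KT from the considered MT's own pole; ``n_j``:
    from the opposite pole (must be >= 1, otherwise the KT is not
    merotelic); ``beta``: attachment-bond angle with the inter-KT axis,
    in [0, pi].
    """
    if np.any(np.asarray(F_i_kt) < 0):
        raise ValueError("spring load must be non-negative")
    if n_i < 1 or n_j < 1:
        raise ValueError("merotelic rate requires n_i >= 1 and n_j >= 1")
    if not 0.0 <= beta <= np.pi:
        raise ValueError("beta must lie in [0, pi]")
    return K.merotelic_detach_rate(F_i_kt, n_i, n_j, beta, R_detach, F0,
                                   beta_sign)


def detach_probability(rate: float, dt: float) -> float:
    """Per-step detachment probability ``1 - exp(-rate*dt)``."""
    return K.event_probability(rate, dt)


def apply_error_correction(state: SpindleState) -> int:
    """Sample and apply one step of detachments in place.

    Rates are evaluated on a frozen snapshot of the occupancy table (per-MT
    independent Bernoulli trials), detachments applied afterwards, and the
    classifications recomputed.  Returns the number of MTs detached.
    """
    p = state.params
    n = int(K.apply_error_correction(
        state.ctr, state.axis, state.sep, state.mt_pole, state.mt_len,
        state.mt_att, state.counts, state.classes, p.d_cent, p.K_kmt_kt,
        p.l_kmt_kt, p.f_push, p.R_detach, p.F0, p.beta_sign, p.dt))
    if n:
        state.reclassify()
    return n
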