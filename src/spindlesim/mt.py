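"""Microtubule dynamic instability, load-corrected switching, and
search-and-capture.

Free MTs grow at ``v_g``, shrink at ``v_s`` and switch stochastically with
the constant rescue/catastrophe frequencies ``f_r``/``f_c`` (per-step
probability ``1 - exp(-rate*dt)``); a fully shrunk free MT is re-nucleated
in a fresh random direction.  An attached (loaded) MT instead rescues with
the per-step probability ``1 - exp(-F/f_s)`` set by its current tensile
spring load, and catastrophes at the length-dependent rate ``R_cat * l``.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .state import SpindleState

__all__ = [
    "loaded_rescue_probability",
    "loaded_catastrophe_rate",
    "free_switch_probability",
    "step_mt_lengths_and_switching",
    "search_and_capture",
]


def loaded_rescue_probability(F_depol: float, f_s: float) -> float:
    """Per-step rescue probability ``1 - exp(-F/f_s)`` of a loaded
    depolymerizing MT (dimensionless, bounded in [0, 1))."""
    if np.any(np.asarray(F_depol) < 0):
        raise ValueError("depolymerization load must be non-negative")
    return K.loaded_rescue_probability(F_depol, f_s)


def loaded_catastrophe_rate(l_mt: float, R_cat: float) -> float:
    """Length-dependent catastrophe rate ``R_cat * l_mt`` (1/s) of a
    loaded MT."""
    if np.any(np.asarray(l_mt) < 0):
        raise ValueError("MT length must be non-negative")
    return K.loaded_catastrophe_rate(l_mt, R_cat)


def free_switch_probability(rate: float, dt: float) -> float:
    """Per-step switching probability ``1 - exp(-rate*dt)`` from an
    exponential waiting time."""
    return K.event_probability(rate, dt)


def step_mt_lengths_and_switching(state: SpindleState) -> None:
    """Advance all MT lengths and growth states by one time step in place.

    Attached MTs are re-aimed at their KT each step; tips are clipped at
    the cell boundary; an attached MT shrunk to zero length stays attached
    (its large spring stretch makes rescue almost certain next step).
    """
    p = state.params
    K.step_mts(state.ctr, state.axis, state.sep, state.mt_pole, state.mt_dir,
               state.mt_len, state.mt_grow, state.mt_att,
               p.r_cell, p.d_cent, p.v_g, p.v_s, p.f_r, p.f_c, p.f_s,
               p.R_cat, p.R_cat_free, p.K_kmt_kt, p.l_kmt_kt, p.dt)


def search_and_capture(state: SpindleState) -> int:
    """Attach free MTs that pass within ``r_kt`` of an eligible KT.

    A KT is eligible while its pair is not amphitelic (bi-oriented pairs
    accept no new attachments) and its occupancy is below ``n_max``; capture
    succeeds with probability ``p_capture``, at most one new attachment per
    MT per step.  Updates bookkeeping and classifications in place; returns
    the number of new attachments.
    """
    p = state.params
    return int(K.search_and_capture(
        state.ctr, state.axis, state.sep, state.mt_pole, state.mt_dir,
        state.mt_len, state.mt_grow, state.mt_att, state.counts,
        state.classes, p.d_cent, p.r_kt, p.p_capture, p.n_max, p.l_kmt_kt))
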