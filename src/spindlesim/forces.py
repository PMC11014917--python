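"""Force field: polar ejection, kMT-KT springs, cohesion, steric and
boundary repulsion, and their assembly into net forces.

The scalar operations mirror the model's closed forms:

* polar ejection  ``F = A_pe * exp(-x/L)`` away from each pole,
* kMT-KT spring   ``F = K_kmt_kt * (x - l_kmt_kt)`` (Hookean, restoring),
* sister cohesion ``F = K_cohesion * (|x1-x2| - l_cohesion)``,
* steric          ``F = A_ch_ch / d^2`` pairwise between arm centres,
* boundary        ``F = A_boundary * exp(-x/L)`` inward.

Vector assembly over a full state runs in the numba kernel; the wrappers
here validate inputs and exist as the reference entry points for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .state import SpindleState

__all__ = [
    "ForceAccumulator",
    "polar_ejection_force",
    "kmt_kt_spring_force",
    "cohesion_force",
    "interchromosome_repulsion",
    "boundary_repulsion",
    "assemble_forces",
    "STERIC_FLOOR",
]

STERIC_FLOOR = K.STERIC_FLOOR


@dataclass
class ForceAccumulator:
    """Net forces for one configuration.

    ``body (n_ch, 3)``: force on each chromosome body (ejection + steric +
    boundary + both KTs' spring forces).  ``kt (2*n_ch, 3)``: per-KT force
    (kMT springs + cohesion share).  ``kmt (2*n_ch, 3)``: the kMT-spring
    part alone.  ``mt_load (n_mt,)``: signed spring force of each attached
    MT (its magnitude is the load entering the detachment and rescue rules).
    """

    body: np.ndarray
    kt: np.ndarray
    kmt: np.ndarray
    mt_load: np.ndarray


def polar_ejection_force(x: float, A_pe: float, L: float) -> float:
    """Ejection-force magnitude at distance ``x`` from a pole (pN)."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("distance from pole must be non-negative")
    return K.polar_ejection_force(x, A_pe, L)


def kmt_kt_spring_force(tip, kt, K_kmt_kt: float, l_kmt_kt: float):
    """Force vector on a KT from the spring linking it to an MT tip.

    Pulls the KT toward the tip when stretched beyond the rest length,
    pushes when compressed.  Returns ``(force_vector_on_kt, signed_load)``;
    the equal-and-opposite load magnitude is what the detachment and rescue
    rules consume.
    """
    tip = np.asarray(tip, dtype=float)
    kt = np.asarray(kt, dtype=float)
    off = tip - kt
    x = float(np.linalg.norm(off))
    if x < 1e-12:
        raise ValueError("MT tip coincides with the KT position")
    f = K.spring_force(x, K_kmt_kt, l_kmt_kt)
    return f * off / x, f


def cohesion_force(x1, x2, K_cohesion: float, l_cohesion: float):
    """Restoring cohesion forces ``(f_on_1, f_on_2)`` between sister KTs."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    off = x2 - x1
    d = float(np.linalg.norm(off))
    if d < 1e-12:
        raise ValueError("sister KTs coincide")
    f = K.spring_force(d, K_cohesion, l_cohesion)
    f1 = f * off / d
    return f1, -f1


def interchromosome_repulsion(centers, A_ch_ch: float) -> np.ndarray:
    """Pairwise inverse-square repulsion between arm centres.

    Returns the ``(n, 3)`` net force on each chromosome; mutual distances
    are floored at ``STERIC_FLOOR`` um.
    """
    c = np.asarray(centers, dtype=float)
    diff = c[:, None, :] - c[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, np.inf)
    d = np.maximum(d, STERIC_FLOOR)
    mag = A_ch_ch / d ** 2
    return np.einsum("ij,ijk->ik", mag / d, diff)


def boundary_repulsion(x: float, A_boundary: float, L: float) -> float:
    """Inward boundary-force magnitude at distance ``x`` from the wall."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("distance to boundary must be non-negative; "
                         "chromosome outside the cell")
    return K.boundary_force(x, A_boundary, L)


def assemble_forces(state: SpindleState) -> ForceAccumulator:
    """Evaluate every force term of the model for ``state``.

    Side-effect free with respect to positions.
    """
    p = state.params
    n_ch, n_mt = state.n_ch, state.n_mt
    body = np.empty((n_ch, 3))
    kt = np.empty((2 * n_ch, 3))
    kmt = np.empty((2 * n_ch, 3))
    load = np.empty(n_mt)
    K.assemble_forces(state.ctr, state.axis, state.sep, state.mt_pole,
                      state.mt_len, state.mt_att,
                      p.r_cell, p.d_cent, p.A_pe, p.L, p.K_kmt_kt,
                      p.l_kmt_kt, p.f_push, p.K_cohesion, p.l_cohesion,
                      p.A_ch_ch, p.A_boundary, body, kt, kmt, load)
    return ForceAccumulator(body=body, kt=kt, kmt=kmt, mt_load=load)
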