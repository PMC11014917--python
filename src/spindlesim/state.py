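"""Spindle state: centrosomes, chromosome pairs, microtubules, bookkeeping.

The state is stored as flat NumPy arrays (see :mod:`spindlesim._kernels` for
the layout); chromosome pairs are rigid bodies described by a centre, a unit
sister axis and a sister separation, so the two kinetochores of pair ``i``
sit at ``ctr[i] +/- 0.5*sep[i]*axis[i]`` (flat KT index ``2*i + slot``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import ModelParameters


class AttachmentClass(enum.IntEnum):
    """Five-way attachment census category of a chromosome pair."""

    unattached = K.UNATTACHED
    monotelic = K.MONOTELIC
    syntelic = K.SYNTELIC
    amphitelic = K.AMPHITELIC
    merotelic = K.MEROTELIC


#: fixed reporting order of the census classes
CLASS_ORDER = ("amphitelic", "syntelic", "merotelic", "monotelic", "unattached")


class StateCorruptionError(RuntimeError):
    """Raised when attachment bookkeeping is internally inconsistent."""


class InitializationError(RuntimeError):
    """Raised when rejection sampling of initial positions exhausts retries."""


@dataclass
class SpindleState:
    """Instantaneous mechanical state of the spindle.

    Centrosomes are static at ``(-d_cent, 0, 0)`` and ``(+d_cent, 0, 0)``
    (poles 0 and 1).  ``counts[k, p]`` caches the number of MTs from pole
    ``p`` attached to flat KT ``k``; ``classes[i]`` caches the pair's
    :class:`AttachmentClass`.
    """

    params: ModelParameters
    time: float
    seed: int
    ctr: np.ndarray        # (n_ch, 3) pair centres / arm centres
    axis: np.ndarray       # (n_ch, 3) unit sister axes
    sep: np.ndarray        # (n_ch,)   sister separations
    mt_pole: np.ndarray    # (n_mt,)   int8 nucleating pole
    mt_dir: np.ndarray     # (n_mt, 3) unit directions
    mt_len: np.ndarray     # (n_mt,)   lengths
    mt_grow: np.ndarray    # (n_mt,)   bool growth state
    mt_att: np.ndarray     # (n_mt,)   int32 flat KT index or -1
    counts: np.ndarray = field(default=None)  # (2*n_ch, 2)
    classes: np.ndarray = field(default=None)  # (n_ch,) int8

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((2 * self.params.n_ch, 2), dtype=np.int32)
            self.classes = np.zeros(self.params.n_ch, dtype=np.int8)
            self.reclassify()

    @property
    def n_ch(self) -> int:
        return self.ctr.shape[0]

    @property
    def n_mt(self) -> int:
        return self.mt_pole.shape[0]

    @property
    def centrosomes(self) -> np.ndarray:
        d = self.params.d_cent
        return np.array([[-d, 0.0, 0.0], [d, 0.0, 0.0]])

    def kt_positions(self) -> np.ndarray:
        """Kinetochore positions, shape ``(2*n_ch, 3)``."""
        out = np.empty((2 * self.n_ch, 3))
        K.kt_positions(self.ctr, self.axis, self.sep, out)
        return out

    def mt_tips(self) -> np.ndarray:
        """MT plus-end positions, shape ``(n_mt, 3)``."""
        return (self.centrosomes[self.mt_pole]
                + self.mt_len[:, None] * self.mt_dir)

    def reclassify(self) -> np.ndarray:
        """Recompute the occupancy table and per-pair classifications."""
        K.kt_pole_counts(self.mt_att, self.mt_pole, self.n_ch, self.counts)
        K.classify_all(self.counts, self.classes)
        return self.classes

    def check_consistency(self) -> None:
        """Verify bidirectional attachment bookkeeping and geometry bounds."""
        counts = np.zeros_like(self.counts)
        K.kt_pole_counts(self.mt_att, self.mt_pole, self.n_ch, counts)
        if not np.array_equal(counts, self.counts):
            raise StateCorruptionError("occupancy table out of sync with MTs")
        if (self.mt_att >= 2 * self.n_ch).any():
            raise StateCorruptionError("attachment target out of range")
        classes = np.zeros_like(self.classes)
        K.classify_all(self.counts, classes)
        if not np.array_equal(classes, self.classes):
            raise StateCorruptionError("cached classifications stale")
        if (np.linalg.norm(self.kt_positions(), axis=1)
                > self.params.r_cell + 1e-9).any():
            raise StateCorruptionError("kinetochore outside the cell")
        if (self.sep <= 0).any():
            raise StateCorruptionError("non-positive sister separation")

    def census_counts(self) -> dict:
        """Number of pairs in each attachment class, in reporting order."""
        vals = np.bincount(self.classes, minlength=5)
        return {name: int(vals[AttachmentClass[name]]) for name in CLASS_ORDER}

    # -- snapshot export ----------------------------------------------------

    def pairs_frame(self) -> pd.DataFrame:
        """One row per chromosome pair: class and both KT positions."""
        kt = self.kt_positions()
        return pd.DataFrame({
            "time": self.time,
            "pair_id": np.arange(self.n_ch),
            "attachment_class": [AttachmentClass(c).name for c in self.classes],
            "kt1_x": kt[0::2, 0], "kt1_y": kt[0::2, 1], "kt1_z": kt[0::2, 2],
            "kt2_x": kt[1::2, 0], "kt2_y": kt[1::2, 1], "kt2_z": kt[1::2, 2],
        })

    def mts_frame(self) -> pd.DataFrame:
        """One row per microtubule: pole, length, state, attachment."""
        return pd.DataFrame({
            "time": self.time,
            "mt_id": np.arange(self.n_mt),
            "pole": self.mt_pole.astype(int),
            "length": self.mt_len,
            "state": np.where(self.mt_grow, "growing", "shrinking"),
            "attached_pair": np.where(self.mt_att >= 0, self.mt_att // 2, -1),
        })


def classify_attachment(sister1_poles, sister2_poles) -> AttachmentClass:
    """Classify one pair from the multisets of poles attached to each sister.

    Merotely (either sister holding MTs from both poles) takes precedence,
    then syntelic, amphitelic, monotelic, unattached.  Pure function.
    """
    a0 = sum(1 for p in sister1_poles if p == 0)
    b0 = sum(1 for p in sister1_poles if p == 1)
    a1 = sum(1 for p in sister2_poles if p == 0)
    b1 = sum(1 for p in sister2_poles if p == 1)
    if min(a0, b0, a1, b1) < 0:
        raise ValueError("pole counts must be non-negative")
    counts = np.array([[a0, b0], [a1, b1]], dtype=np.int32)
    out = np.zeros(1, dtype=np.int8)
    K.classify_all(counts, out)
    return AttachmentClass(out[0])


def initialize_state(p: ModelParameters, seed: int) -> SpindleState:
    """Build the t=0 state: pairs uniform in the cell sphere (rejecting
    positions within ``r_kt`` of a centrosome), random sister orientations
    at the cohesion rest length, all MTs at zero length growing outward in
    random directions, no attachments.

    Seeds the engine RNG; two states from the same seed are identical.
    """
    K.seed_rng(seed)
    n_ch, n_mt = p.n_ch, 2 * p.n_mt_per_pole
    ctr = np.empty((n_ch, 3))
    axis = np.empty((n_ch, 3))
    sep = np.empty(n_ch)
    status = K.init_pairs(n_ch, p.r_cell, p.d_cent, p.r_kt, p.l_cohesion,
                          ctr, axis, sep)
    if status != 0:
        raise InitializationError("placement rejection-sampling retry cap hit")
    mt_pole = np.empty(n_mt, dtype=np.int8)
    mt_dir = np.empty((n_mt, 3))
    mt_len = np.empty(n_mt)
    mt_grow = np.empty(n_mt, dtype=np.bool_)
    mt_att = np.empty(n_mt, dtype=np.int32)
    K.init_mts(p.n_mt_per_pole, mt_pole, mt_dir, mt_len, mt_grow, mt_att)
    return SpindleState(params=p, time=0.0, seed=seed, ctr=ctr, axis=axis,
                        sep=sep, mt_pole=mt_pole, mt_dir=mt_dir,
                        mt_len=mt_len, mt_grow=mt_grow, mt_att=mt_att)
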