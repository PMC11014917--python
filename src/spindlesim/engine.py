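"""Replicate engine: the fixed-order step loop and seeded ensembles.

One step advances the state by ``dt`` through the ordered sub-steps

1. assemble forces,
2. overdamped motion of chromosome bodies, sister separations and axes,
3. MT length dynamics and (load-corrected) rescue/catastrophe switching,
4. search-and-capture,
5. force-dependent error correction,
6. reclassification.

The order is fixed because the stochastic outcome depends on it.  Each
replicate runs on its own deterministically derived RNG stream, so
ensembles are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .correction import apply_error_correction
from .forces import assemble_forces
from .mt import search_and_capture, step_mt_lengths_and_switching
from .params import ModelParameters, fingerprint
from .state import SpindleState, initialize_state

__all__ = ["ReplicateResult", "step", "run_replicate", "run_ensemble",
           "replicate_seed"]


@dataclass
class Snapshot:
    """Light per-time record of a running replicate."""

    time: float
    classes: np.ndarray          # (n_ch,) int8
    ctr: np.ndarray              # (n_ch, 3) pair centres


@dataclass
class ReplicateResult:
    """Final observables of one simulated cell.

    ``classes`` is the per-pair five-way classification at ``t_end``;
    ``kt_counts`` the attached-MT count of every kinetochore (flat index
    ``2*pair + slot``); ``census`` the per-class pair counts.
    """

    seed: int
    fingerprint: str
    classes: np.ndarray
    ctr: np.ndarray              # (n_ch, 3) final pair centres
    kt_positions: np.ndarray     # (2*n_ch, 3)
    kt_counts: np.ndarray        # (2*n_ch,)
    census: dict
    snapshots: list = field(default_factory=list)

    @property
    def n_ch(self) -> int:
        return self.classes.shape[0]

    def census_percent(self) -> dict:
        """Census as percentages of chromosome pairs, in reporting order."""
        return {k: 100.0 * v / self.n_ch for k, v in self.census.items()}


def step(state: SpindleState) -> SpindleState:
    """Advance ``state`` in place by one time step; returns it."""
    p = state.params
    fa = assemble_forces(state)
    K.move_chromosomes(state.ctr, state.axis, state.sep, state.mt_pole,
                       state.mt_att, fa.body, fa.kt, fa.kmt,
                       p.r_cell, p.gamma_ch, p.dt)
    step_mt_lengths_and_switching(state)
    search_and_capture(state)
    apply_error_correction(state)
    state.reclassify()
    state.time += p.dt
    return state


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic 31-bit engine seed for replicate ``index``."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicate(p: ModelParameters, seed: int,
                  snapshot_every: float | None = None,
                  check_every: int = 400) -> ReplicateResult:
    """Simulate one cell from t=0 to ``t_end`` and collect observables.

    ``snapshot_every`` (s) records light snapshots; ``check_every`` steps
    triggers a bookkeeping-consistency audit (0 disables).
    """
    state = initialize_state(p, seed)
    n_steps = int(round(p.t_end / p.dt))
    snaps: list[Snapshot] = []

    def record():
        snaps.append(Snapshot(state.time, state.classes.copy(),
                              state.ctr.copy()))

    next_snap = 0.0
    for n in range(n_steps):
        if snapshot_every is not None and state.time >= next_snap - 1e-9:
            record()
            next_snap += snapshot_every
        step(state)
        if check_every and (n + 1) % check_every == 0:
            state.check_consistency()
    state.check_consistency()
    if snapshot_every is not None:
        record()
    return ReplicateResult(
        seed=seed,
        fingerprint=fingerprint(p),
        classes=state.classes.copy(),
        ctr=state.ctr.copy(),
        kt_positions=state.kt_positions(),
        kt_counts=state.counts.sum(axis=1).astype(np.int64),
        census=state.census_counts(),
        snapshots=snaps,
    )


def run_ensemble(p: ModelParameters, n_replicates: int, base_seed: int,
                 snapshot_every: float | None = None,
                 progress: bool = False):
    """Run ``n_replicates`` independent seeded replicates.

    Returns ``(results, census)`` where ``census`` is the per-class mean
    percentage and its standard error over replicates (a DataFrame in the
    fixed class order).  Replicate ``i`` uses the stream derived from
    ``(base_seed, i)``, so results do not depend on execution order.
    """
    from .summaries import attachment_census

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    iterator = range(n_replicates)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="replicates")
    results = [run_replicate(p, replicate_seed(base_seed, i),
                             snapshot_every=snapshot_every)
               for i in iterator]
    return results, attachment_census(results)
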