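"""Ensemble observables: attachment census, axial chromosome distributions,
kMT occupancy of bi-oriented kinetochores, and spring-strength sweeps.

All summaries are pure functions of :class:`~spindlesim.engine.ReplicateResult`
lists; re-running them on stored results reproduces them bit-for-bit.
Percentages use chromosome pairs as the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import ReplicateResult
from .state import CLASS_ORDER, AttachmentClass

__all__ = [
    "attachment_census",
    "axial_distribution",
    "amphitelic_spread",
    "kmt_occupancy",
    "force_sweep_summary",
]


def _census_matrix(results: list[ReplicateResult]) -> np.ndarray:
    """Per-replicate census percentages, shape (n_rep, 5) in class order."""
    if not results:
        raise ValueError("empty ensemble")
    rows = np.empty((len(results), len(CLASS_ORDER)))
    for r, res in enumerate(results):
        pct = res.census_percent()
        rows[r] = [pct[name] for name in CLASS_ORDER]
    return rows


def _sem(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standard error of the mean; 0 for a single observation."""
    n = values.shape[axis]
    if n < 2:
        return np.zeros_like(np.mean(values, axis=axis))
    return np.std(values, axis=axis, ddof=1) / np.sqrt(n)


def attachment_census(results: list[ReplicateResult],
                      merge_mono_unattached: bool = False) -> pd.DataFrame:
    """Mean census percentage and SEM over replicates.

    Rows follow the fixed class order (amphitelic, syntelic, merotelic,
    monotelic, unattached); ``merge_mono_unattached`` collapses the last
    two rows into ``monotelic_or_unattached`` for reporting.
    """
    rows = _census_matrix(results)
    df = pd.DataFrame({"mean": rows.mean(axis=0), "sem": _sem(rows)},
                      index=list(CLASS_ORDER))
    df.index.name = "attachment_class"
    if merge_mono_unattached:
        merged = rows[:, 3] + rows[:, 4]
        df = df.iloc[:3].copy()
        df.loc["monotelic_or_unattached"] = [merged.mean(), _sem(merged)]
    return df


def axial_distribution(results: list[ReplicateResult],
                       bin_width: float = 1.0,
                       x_range: tuple[float, float] | None = None
                       ) -> pd.DataFrame:
    """Histogram of pair-centre x-coordinates, stratified by class.

    Bins of ``bin_width`` um covering ``x_range`` (default: the data range
    symmetrised about 0); counts are pooled over all replicates, one column
    per attachment class plus ``total``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    xs = np.concatenate([r.ctr[:, 0] for r in results])
    cls = np.concatenate([r.classes for r in results])
    if x_range is None:
        lim = max(1.0, np.ceil(np.abs(xs).max() / bin_width) * bin_width)
        x_range = (-lim, lim)
    edges = np.arange(x_range[0], x_range[1] + 0.5 * bin_width, bin_width)
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for name in CLASS_ORDER:
        sel = cls == int(AttachmentClass[name])
        out[name], _ = np.histogram(xs[sel], bins=edges)
    df = pd.DataFrame(out)
    df["total"] = df[list(CLASS_ORDER)].sum(axis=1)
    return df


def amphitelic_spread(results: list[ReplicateResult]) -> float:
    """Standard deviation of amphitelic pair-centre x-positions, pooled
    over replicates (the axial 'spread' of the bi-oriented distribution).

    NaN if the ensemble contains no amphitelic pair.
    """
    xs = np.concatenate([r.ctr[:, 0] for r in results])
    cls = np.concatenate([r.classes for r in results])
    sel = cls == int(AttachmentClass.amphitelic)
    if not sel.any():
        return float("nan")
    return float(np.std(xs[sel]))


def kmt_occupancy(results: list[ReplicateResult]) -> pd.Series:
    """Mean attached-MT count per amphitelic kinetochore.

    Per-replicate means are averaged across replicates that contain at
    least one amphitelic pair; returns a Series with ``mean``, ``sem`` and
    ``n_replicates``.  All values NaN if no replicate has amphitelic pairs.
    """
    per_rep = []
    for r in results:
        amp_pairs = np.flatnonzero(r.classes == int(AttachmentClass.amphitelic))
        if amp_pairs.size == 0:
            continue
        kt_idx = np.concatenate([2 * amp_pairs, 2 * amp_pairs + 1])
        per_rep.append(r.kt_counts[kt_idx].mean())
    if not per_rep:
        return pd.Series({"mean": np.nan, "sem": np.nan, "n_replicates": 0})
    arr = np.asarray(per_rep)
    return pd.Series({"mean": arr.mean(), "sem": float(_sem(arr)),
                      "n_replicates": len(arr)})


def force_sweep_summary(sweep: dict[float, list[ReplicateResult]]
                        ) -> pd.DataFrame:
    """Census table of a kMT-KT spring-strength sweep.

    ``sweep`` maps each ``K_kmt_kt`` value to its ensemble; the result has
    one row per value (ascending) with ``<class>_mean`` / ``<class>_sem``
    columns in percent.
    """
    if len(sweep) < 2:
        raise ValueError("a sweep needs at least two K_kmt_kt values")
    rows = []
    for k in sorted(sweep):
        rows_mat = _census_matrix(sweep[k])
        entry = {"K_kmt_kt": k}
        means = rows_mat.mean(axis=0)
        sems = _sem(rows_mat)
        for i, name in enumerate(CLASS_ORDER):
            entry[f"{name}_mean"] = means[i]
            entry[f"{name}_sem"] = sems[i]
        rows.append(entry)
    return pd.DataFrame(rows)
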