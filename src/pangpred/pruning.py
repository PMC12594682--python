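"""Linkage-disequilibrium pruning of marker columns.

LD between two marker columns is measured as the squared Pearson correlation
of their numeric values (dosages for additive markers, raw 0/2 or 0/1/2
columns for PAV/OHE markers).  Two pruning modes are provided:

* :func:`prune_windowed` — greedy left-to-right scan with a sliding window
  counted in retained marker positions, used for the genome-wide baseline
  set where physical order matters;
* :func:`prune_joint` — all-pairs greedy pruning within marker groups
  (vertices), with a preceding column-MAF filter and no window, used for the
  small per-vertex marker sets where every pair should be checked.

Zero-variance columns make r^2 undefined; both pruners drop them up front
with a warning, recording them in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .encoding import MarkerMatrix

__all__ = ["DropRecord", "PruneReport", "pairwise_r2", "prune_windowed", "prune_joint"]


@dataclass(frozen=True)
class DropRecord:
    """Why a marker column was removed.

    ``cause_marker_id`` names the retained column whose r^2 with this one
    exceeded the threshold; it is ``None`` when the column was removed for a
    non-LD reason (zero variance, MAF filter), in which case ``r2`` is NaN
    and ``reason`` says which.
    """

    marker_id: str
    cause_marker_id: Optional[str]
    r2: float
    reason: str = "ld"


@dataclass
class PruneReport:
    """Outcome of one pruning pass: an ordered retained set plus drop audit."""

    retained: list[str]
    dropped: list[DropRecord] = field(default_factory=list)

    @property
    def dropped_ids(self) -> list[str]:
        return [d.marker_id for d in self.dropped]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"marker_id": mid, "status": "retained", "cause": None, "r2": np.nan,
                 "reason": None} for mid in self.retained]
        rows += [
            {"marker_id": d.marker_id, "status": "dropped", "cause": d.cause_marker_id,
             "r2": d.r2, "reason": d.reason}
            for d in self.dropped
        ]
        return pd.DataFrame(rows)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two marker columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("r2 undefined for zero-variance column")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _normalize_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns so that dot products are Pearson r.

    Returns (normalized matrix, boolean mask of zero-variance columns); the
    zero-variance columns are left as zeros in the normalized matrix.
    """
    x = values - values.mean(axis=0, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=0))
    zero_var = norms == 0.0
    safe = np.where(zero_var, 1.0, norms)
    return x / safe, zero_var


def _column_maf(values: np.ndarray) -> np.ndarray:
    """Column-level MAF proxy: min(mean/2, 1 - mean/2) of a [0, 2] column."""
    f = values.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def _check_positional_order(matrix: MarkerMatrix) -> None:
    """Error if columns with known coordinates are not (chromosome, position)-sorted."""
    coords = [
        (c.chromosome, c.position)
        for c in matrix.meta
        if c.chromosome is not None and c.position is not None
    ]
    if len(coords) < 2:
        return
    seen_done: set[str] = set()
    prev_chrom: Optional[str] = None
    prev_pos = -1
    for chrom, pos in coords:
        if chrom != prev_chrom:
            if chrom in seen_done:
                raise ValueError(f"columns are not position-sorted: chromosome {chrom} interleaved")
            if prev_chrom is not None:
                seen_done.add(prev_chrom)
            prev_chrom, prev_pos = chrom, pos
        elif pos < prev_pos:
            raise ValueError(
                f"columns are not position-sorted: {chrom}:{pos} after {chrom}:{prev_pos}"
            )
        else:
            prev_pos = pos


def prune_windowed(
    matrix: MarkerMatrix, window: int = 50, r2_max: float = 0.8
) -> PruneReport:
    """Sliding-window greedy LD pruning for position-ordered marker sets.

    The scan runs left to right.  Each candidate is compared with the most
    recent ``window - 1`` retained markers (candidate + trailing retained =
    one window of ``window`` marker positions).  If any pair exceeds
    ``r2_max``, the lower-MAF member of the pair is dropped (on a tie the
    later one), so a common candidate can evict a rarer retained marker.
    Afterwards no retained pair within a window has r^2 > ``r2_max``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    _check_positional_order(matrix)
    ids = matrix.marker_ids
    xn, zero_var = _normalize_columns(matrix.values)
    mafs = _column_maf(matrix.values)

    dropped: list[DropRecord] = []
    for j in np.flatnonzero(zero_var):
        dropped.append(DropRecord(ids[j], None, np.nan, reason="zero_variance"))
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance column(s) dropped before windowed pruning",
            stacklevel=2,
        )

    retained: list[int] = []
    for j in range(matrix.n_markers):
        if zero_var[j]:
            continue
        win = retained[-(window - 1):] if window > 1 else []
        if win:
            r2 = (xn[:, win].T @ xn[:, j]) ** 2
        else:
            r2 = np.empty(0)
        keep_candidate = True
        evict: list[tuple[int, float]] = []
        for i, r2_ij in zip(win, r2):
            if r2_ij > r2_max:
                if mafs[j] > mafs[i]:
                    evict.append((i, float(r2_ij)))
                else:  # tie goes against the later (candidate) column
                    dropped.append(DropRecord(ids[j], ids[i], float(r2_ij)))
                    keep_candidate = False
                    break
        if keep_candidate:
            for i, r2_ij in evict:
                retained.remove(i)
                dropped.append(DropRecord(ids[i], ids[j], r2_ij))
            retained.append(j)

    # Evictions shorten distances in the retained sequence, which can bring a
    # never-compared pair inside the window; sweep until the window-local
    # guarantee holds for the final retained set.
    while True:
        ret = np.asarray(retained)
        hit = None  # first violating pair (ai, bi) in retained-index order
        for d in range(1, min(window, len(ret))):
            r2_d = (xn[:, ret[d:]] * xn[:, ret[:-d]]).sum(axis=0) ** 2
            viol = np.flatnonzero(r2_d > r2_max)
            if viol.size:
                cand = (int(viol[0]), int(viol[0]) + d)
                if hit is None or cand[1] < hit[1] or (cand[1] == hit[1] and cand[0] > hit[0]):
                    hit = cand
        if hit is None:
            break
        a, b = retained[hit[0]], retained[hit[1]]
        r2_ab = float((xn[:, a] @ xn[:, b]) ** 2)
        victim, keeper = (b, a) if mafs[b] <= mafs[a] else (a, b)
        retained.remove(victim)
        dropped.append(DropRecord(ids[victim], ids[keeper], r2_ab))
    return PruneReport([ids[j] for j in retained], dropped)


def prune_joint(
    matrix: MarkerMatrix,
    groups: Mapping[str, str],
    r2_max: float = 0.6,
    maf_min: float = 0.05,
) -> PruneReport:
    """Joint (windowless) LD pruning within marker groups (vertices).

    Per group: columns whose column-MAF (``min(mean/2, 1 - mean/2)``) is
    <= ``maf_min`` are removed first; the survivors are scanned greedily in
    input order and a column is dropped iff its r^2 with any already-retained
    column of the same group exceeds ``r2_max``.  Columns in different groups
    are never compared.
    """
    ids = matrix.marker_ids
    missing_group = [mid for mid in ids if mid not in groups]
    if missing_group:
        raise ValueError(f"marker(s) without group assignment: {missing_group[:5]}")

    xn, zero_var = _normalize_columns(matrix.values)
    mafs = _column_maf(matrix.values)

    dropped: list[DropRecord] = []
    retained: list[int] = []
    retained_by_group: dict[str, list[int]] = {}

    n_zero = 0
    for j, mid in enumerate(ids):
        if mafs[j] <= maf_min:
            dropped.append(DropRecord(mid, None, np.nan, reason="maf"))
            continue
        if zero_var[j]:
            n_zero += 1
            dropped.append(DropRecord(mid, None, np.nan, reason="zero_variance"))
            continue
        grp = groups[mid]
        prior = retained_by_group.get(grp, [])
        cause = None
        if prior:
            r2 = (xn[:, prior].T @ xn[:, j]) ** 2
            hit = np.flatnonzero(r2 > r2_max)
            if hit.size:
                cause = (prior[hit[0]], float(r2[hit[0]]))
        if cause is not None:
            dropped.append(DropRecord(mid, ids[cause[0]], cause[1]))
        else:
            retained.append(j)
            retained_by_group.setdefault(grp, []).append(j)
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance column(s) dropped before joint pruning", stacklevel=2
        )
    return PruneReport([ids[j] for j in retained], dropped)
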