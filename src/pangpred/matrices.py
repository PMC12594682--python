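"""Assembly of the four analysis marker matrices.

* **BASELINE** — backbone-reference SNPs under the standard pipeline: strict
  filters (CR > 0.8, MAF > 0.05, het < 0.05), additive encoding, mean
  imputation, sliding-window LD pruning (window 50, r^2 0.8).
* **PanG-CORE** — BASELINE plus high-CR (>= 0.8) vertex SNPs, additively
  encoded and imputed like the baseline.
* **PanG-PAV** — BASELINE plus low-CR (< 0.8) vertex SNPs encoded as
  presence-absence.
* **PanG-OHE** — BASELINE plus the same low-CR SNPs in the modified 3-column
  one-hot encoding.

Vertex-derived columns are filtered to MAF > 0.05 and LD-pruned jointly
within each vertex (r^2 threshold 0.6, no window) before being appended, so
redundant allele columns — e.g. the near-mirror-image absence and reference
columns of a rare-alt OHE triple — collapse to a single marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    MarkerMatrix,
    additive_meta,
    encode_additive,
    encode_ohe3,
    encode_pav,
    partition_by_cr,
)
from .genotypes import GenotypeCalls, VertexRecord
from .pruning import prune_joint, prune_windowed
from .qc import filter_snps, mean_impute, snp_stats
from .vertices import assign_snps_to_vertices

__all__ = [
    "VertexSnpPool",
    "build_baseline",
    "build_vertex_pool",
    "build_pang_matrix",
    "matrix_summary",
    "PANG_MODES",
]

PANG_MODES = ("CORE", "PAV", "OHE")


@dataclass
class VertexSnpPool:
    """Vertex-assigned SNP calls that passed the intermediate filter.

    ``cr`` is the call rate over the full accession panel (subpopulation
    call rates are reporting-only statistics computed elsewhere).
    """

    calls: GenotypeCalls
    vertex_by_snp: dict[str, str]
    rank_by_reference: dict[str, int]
    cr: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.calls.snp_ids if s not in self.vertex_by_snp]
        if missing:
            raise ValueError(f"pool SNP(s) without vertex assignment: {missing[:5]}")

    @property
    def n_snps(self) -> int:
        return self.calls.n_snps

    def reference_of(self, snp_id: str) -> str:
        return {s.snp_id: s.source_reference for s in self.calls.snps}[snp_id]


def build_baseline(
    calls_backbone: GenotypeCalls,
    cr_min: float = 0.8,
    maf_min: float = 0.05,
    het_max: float = 0.05,
    window: int = 50,
    r2_max: float = 0.8,
) -> MarkerMatrix:
    """Standard single-reference SNP matrix: filter, encode, impute, prune.

    Columns are position-ordered; all are additive with no vertex of origin.
    Imputation of a column depends only on that column, so imputing before
    the windowed pruning leaves the final matrix identical to pruning first.
    """
    calls = calls_backbone.sorted_by_position()
    stats = snp_stats(calls)
    kept = filter_snps(stats, cr_min=cr_min, maf_min=maf_min, het_max=het_max)
    calls = calls.subset_snps(kept)
    dosages = mean_impute(encode_additive(calls)) if kept else np.empty(
        (calls.n_accessions, 0)
    )
    matrix = MarkerMatrix(calls.accession_ids, additive_meta(calls), dosages)
    report = prune_windowed(matrix, window=window, r2_max=r2_max)
    return matrix.subset_markers(report.retained)


def build_vertex_pool(
    calls_by_reference: Mapping[str, GenotypeCalls],
    vertices: Sequence[VertexRecord],
    maf_min: float = 0.05,
    cr_min: float = 0.05,
    het_max: float = 0.05,
) -> VertexSnpPool:
    """Pool vertex-assigned SNPs across non-backbone references.

    Each reference's call set is filtered independently with the permissive
    intermediate thresholds (MAF > 0.05, CR > 0.05, het < 0.05 — the loose
    CR floor keeps SNPs inside rare dispensable sequences), then SNPs are
    assigned to the supplied (pre-selected) vertices; unassigned SNPs are
    discarded.  Pool call rates are recomputed over the full panel.
    """
    refs = list(calls_by_reference)
    if not refs:
        raise ValueError("no call sets given")
    panel = calls_by_reference[refs[0]].accession_ids
    for ref in refs[1:]:
        if calls_by_reference[ref].accession_ids != panel:
            raise ValueError(f"accession panel of {ref!r} differs from {refs[0]!r}")

    rank_by_reference = {v.source_reference: v.rank for v in vertices}
    pieces: list[GenotypeCalls] = []
    assignment: dict[str, str] = {}
    for ref in refs:
        calls = calls_by_reference[ref]
        stats = snp_stats(calls)
        kept = filter_snps(stats, cr_min=cr_min, maf_min=maf_min, het_max=het_max)
        sub = calls.subset_snps(kept)
        ref_vertices = [v for v in vertices if v.source_reference == ref]
        assigned = assign_snps_to_vertices(sub.snps, ref_vertices)
        if assigned:
            pieces.append(sub.subset_snps(list(assigned)))
            assignment.update(assigned)

    if pieces:
        pooled = GenotypeCalls(
            panel,
            [s for p in pieces for s in p.snps],
            np.hstack([p.calls for p in pieces]),
        )
    else:
        pooled = GenotypeCalls(panel, [], np.empty((len(panel), 0), dtype=np.int8))
    cr = snp_stats(pooled)["call_rate"]
    return VertexSnpPool(pooled, assignment, rank_by_reference, cr)


_ALLELE_ROLE_ORDER = {"OHE_ABSENCE": 0, "OHE_REF": 1, "OHE_ALT": 2}


def _sorted_marker_order(matrix: MarkerMatrix, rank_by_reference: Mapping[str, int]) -> list[str]:
    """Deterministic appended-column order: reference rank, vertex, position, allele role."""
    def key(c):
        return (
            rank_by_reference.get(c.source_reference, 10**9),
            c.source_reference,
            c.vertex_id or "",
            c.position or 0,
            c.source_snp_id,
            _ALLELE_ROLE_ORDER.get(c.encoding, 0),
        )

    return [c.marker_id for c in sorted(matrix.meta, key=key)]


def build_pang_matrix(
    baseline: MarkerMatrix,
    pool: VertexSnpPool,
    mode: str,
    cr_threshold: float = 0.8,
    r2_max: float = 0.6,
    maf_min: float = 0.05,
) -> MarkerMatrix:
    """Append encoded vertex SNPs to the baseline matrix.

    ``mode`` selects the SNPs and encoding: "CORE" takes high-CR
    (>= ``cr_threshold``) pool SNPs additively encoded and imputed; "PAV"
    and "OHE" take the low-CR SNPs in presence-absence or modified one-hot
    encoding.  Appended columns are MAF-filtered and LD-pruned jointly
    within each vertex, then concatenated after the unchanged baseline
    columns.
    """
    if mode not in PANG_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {PANG_MODES}")
    if baseline.accession_ids != pool.calls.accession_ids:
        raise ValueError("baseline and pool accession panels differ")

    stats = snp_stats(pool.calls)
    high, low = partition_by_cr(stats, threshold=cr_threshold)
    chosen = high if mode == "CORE" else low
    if not chosen:
        warnings.warn(f"no pool SNPs selected for mode {mode}; returning baseline", stacklevel=2)
        return baseline
    sub = pool.calls.subset_snps(chosen)

    if mode == "CORE":
        dosages = mean_impute(encode_additive(sub))
        appended = MarkerMatrix(
            sub.accession_ids, additive_meta(sub, pool.vertex_by_snp), dosages
        )
    elif mode == "PAV":
        appended = encode_pav(sub, pool.vertex_by_snp)
    else:
        appended = encode_ohe3(sub, pool.vertex_by_snp)

    appended = appended.subset_markers(
        _sorted_marker_order(appended, pool.rank_by_reference)
    )
    groups = {c.marker_id: c.vertex_id for c in appended.meta}
    report = prune_joint(appended, groups, r2_max=r2_max, maf_min=maf_min)
    appended = appended.subset_markers(report.retained)
    return baseline.hstack(appended)


def matrix_summary(matrix: MarkerMatrix) -> pd.DataFrame:
    """Marker counts per (source reference, encoding); baseline as one row.

    Vertex-free (baseline-origin) columns are collapsed into a single
    "BASELINE" row regardless of encoding; appended vertex columns are
    grouped by their vertex's source reference and encoding.
    """
    if matrix.n_markers == 0:
        return pd.DataFrame(columns=["source_reference", "encoding", "n_markers"])
    rows = []
    for c in matrix.meta:
        if c.is_baseline:
            rows.append(("BASELINE", "BASELINE"))
        else:
            rows.append((c.source_reference, c.encoding))
    df = pd.DataFrame(rows, columns=["source_reference", "encoding"])
    out = (
        df.value_counts(["source_reference", "encoding"], sort=False)
        .rename("n_markers")
        .reset_index()
    )
    return out.sort_values(
        ["source_reference", "encoding"], key=lambda s: s.where(s != "BASELINE", "")
    ).reset_index(drop=True)
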