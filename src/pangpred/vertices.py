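"""Selection of large non-backbone vertices and SNP-to-vertex assignment."""

from __future__ import annotations

from typing import Iterable, Sequence

from .genotypes import SnpRecord, VertexRecord

__all__ = ["select_vertices", "assign_snps_to_vertices"]


def select_vertices(
    vertices: Iterable[VertexRecord],
    min_size_bp: int = 5000,
    backbone: str = "NB",
) -> list[VertexRecord]:
    """Keep vertices strictly larger than ``min_size_bp`` whose source is not
    the backbone reference; input order is preserved.

    Restricting to large vertices (> 5,000 bp by default) targets structural
    variants big enough to contain genes and unlikely to be in tight linkage
    with flanking core SNPs; excluding the backbone guarantees the selected
    vertices represent sequence absent from the backbone reference.
    """
    if min_size_bp < 0:
        raise ValueError("min_size_bp must be >= 0")
    return [
        v
        for v in vertices
        if v.size_bp > min_size_bp and v.source_reference != backbone
    ]


def assign_snps_to_vertices(
    snps: Sequence[SnpRecord], vertices: Sequence[VertexRecord]
) -> dict[str, str]:
    """Map each SNP id to the vertex containing it, if any.

    A SNP (1-based position p, called against reference R) lies in a vertex
    [start, end) on reference R iff chromosomes match and start < p <= end.
    A SNP covered by several overlapping vertices is attributed to the
    lowest-rank (earliest-added reference), then left-most (smallest start),
    then lexicographically-first vertex — mirroring the attribution of shared
    vertices to the first reference that introduced them.
    """
    by_key: dict[tuple[str, str], list[VertexRecord]] = {}
    for v in vertices:
        by_key.setdefault((v.source_reference, v.chromosome), []).append(v)
    for vs in by_key.values():
        vs.sort(key=lambda v: (v.rank, v.start, v.vertex_id))

    assignment: dict[str, str] = {}
    for s in snps:
        candidates = by_key.get((s.source_reference, s.chromosome), ())
        for v in candidates:
            if v.start < s.position <= v.end:
                assignment[s.snp_id] = v.vertex_id
                break
    return assignment
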