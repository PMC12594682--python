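"""Core containers for genotype calls and pan-genome vertices.

Genotype calls are held as a dense ``int8`` matrix of accessions x SNPs over
the four-state alphabet {missing, hom-ref, het, hom-alt}.  Rice gene bank
accessions are near-fully inbred, so heterozygotes are rare but must still be
representable; phasing is never retained.  Structural-variant vertices arrive
as genomic intervals on one of the non-backbone reference sequences of the
pan-genome graph, not as a graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Call",
    "SnpRecord",
    "GenotypeCalls",
    "VertexRecord",
    "NUCLEOTIDES",
]

NUCLEOTIDES = frozenset("ACGT")


class Call(IntEnum):
    """Diploid genotype call states.

    Integer values are chosen so that non-missing states equal the additive
    (alt-allele dosage) encoding.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


_VALID_CALL_VALUES = frozenset(int(c) for c in Call)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP called against one linear reference sequence.

    ``position`` is 1-based, following VCF convention.
    """

    snp_id: str
    source_reference: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"SNP {self.snp_id}: alleles must be single nucleotides A/C/G/T, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt allele are identical")


@dataclass
class GenotypeCalls:
    """Accessions x SNPs genotype call matrix.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, one per matrix row.
    snps
        One :class:`SnpRecord` per matrix column.
    calls
        ``int8`` matrix over the :class:`Call` alphabet.
    """

    accession_ids: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.snps = list(self.snps)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.accession_ids), len(self.snps)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{n} accessions x {m} SNPs"
            )
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids are not unique")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("SNP ids are not unique")
        present = set(np.unique(self.calls).tolist()) if self.calls.size else set()
        if not present <= _VALID_CALL_VALUES:
            raise ValueError(
                f"call matrix contains invalid states {present - _VALID_CALL_VALUES}"
            )

    # -- basic views ----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def accession_indexer(self, accession_ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given accession ids (error on unknown id)."""
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in accession_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from None

    def subset_accessions(self, accession_ids: Sequence[str]) -> "GenotypeCalls":
        idx = self.accession_indexer(accession_ids)
        return GenotypeCalls(
            [self.accession_ids[i] for i in idx], self.snps, self.calls[idx, :]
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeCalls":
        lookup = {s.snp_id: j for j, s in enumerate(self.snps)}
        try:
            idx = [lookup[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None
        return GenotypeCalls(
            self.accession_ids, [self.snps[j] for j in idx], self.calls[:, idx]
        )

    def sorted_by_position(self) -> "GenotypeCalls":
        """Columns reordered by (chromosome, position, snp_id); stable."""
        order = sorted(
            range(self.n_snps),
            key=lambda j: (self.snps[j].chromosome, self.snps[j].position, self.snps[j].snp_id),
        )
        return GenotypeCalls(
            self.accession_ids, [self.snps[j] for j in order], self.calls[:, order]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeCalls):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class VertexRecord:
    """A structural-variant vertex of the pan-genome graph.

    Coordinates follow BED convention (0-based, half-open).  ``rank`` is the
    order in which the vertex's source reference was added to the graph;
    vertices shared between references are attributed to the earliest one, so
    rank carries the tie-breaking order for overlapping assignments.
    """

    vertex_id: str
    source_reference: str
    chromosome: str
    start: int
    end: int
    rank: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"vertex {self.vertex_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.rank < 1:
            raise ValueError(f"vertex {self.vertex_id}: rank must be >= 1")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def contains_position(self, chromosome: str, position: int) -> bool:
        """True if a 1-based SNP position lies inside this vertex.

        A 1-based position p is inside [start, end) iff start < p <= end.
        """
        return self.chromosome == chromosome and self.start < position <= self.end
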