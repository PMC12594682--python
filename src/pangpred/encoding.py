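"""Numeric marker encodings of genotype calls.

Four encodings are provided:

* **additive** — alt-allele dosage 0/1/2 with missing calls left missing
  (NaN), to be mean-imputed downstream;
* **PAV** — presence-absence: any non-missing call (heterozygotes included)
  codes 0, a missing call codes 2;
* **modified one-hot (OHE3)** — three columns per SNP counting copies of the
  three possible alleles (absence, reference nucleotide, alternative
  nucleotide): hom-ref (0 2 0), hom-alt (0 0 2), het (0 1 1), missing
  (2 0 0).  The absence column is by construction identical to the PAV
  encoding of the same SNP;
* **classical one-hot (OHE4)** — four indicator columns per genotype state.
  Provided for comparison only; with near-zero heterozygosity the dedicated
  heterozygote column is almost always a rare-state indicator and is never
  fed to prediction here.

Every encoded column carries provenance metadata (:class:`MarkerMeta`)
naming the source SNP, the encoding, the allele the column counts, and —
for vertex-derived markers — the vertex and its source reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genotypes import Call, GenotypeCalls

__all__ = [
    "MarkerMeta",
    "MarkerMatrix",
    "encode_additive",
    "encode_pav",
    "encode_ohe3",
    "encode_ohe4",
    "partition_by_cr",
    "ENCODINGS",
]

ENCODINGS = (
    "ADDITIVE",
    "PAV",
    "OHE_ABSENCE",
    "OHE_REF",
    "OHE_ALT",
    "OHE4_MISSING",
    "OHE4_HOM_REF",
    "OHE4_HET",
    "OHE4_HOM_ALT",
)

_META_FIELDS = (
    "marker_id",
    "source_snp_id",
    "encoding",
    "allele_role",
    "vertex_id",
    "source_reference",
    "chromosome",
    "position",
)


@dataclass(frozen=True)
class MarkerMeta:
    """Provenance of one numeric marker column."""

    marker_id: str
    source_snp_id: str
    encoding: str
    allele_role: str
    source_reference: str
    vertex_id: Optional[str] = None
    chromosome: Optional[str] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")

    @property
    def is_baseline(self) -> bool:
        """True for markers without a vertex (backbone/BASELINE origin)."""
        return self.vertex_id is None


class MarkerMatrix:
    """Fully numeric accessions x markers matrix with per-column provenance.

    No missing values are allowed; all values lie in [0, 2].  This is the
    object genomic prediction consumes (the Z matrix of the mixed model).
    """

    def __init__(
        self,
        accession_ids: list[str],
        meta: list[MarkerMeta],
        values: np.ndarray,
    ) -> None:
        self.accession_ids = list(accession_ids)
        self.meta = list(meta)
        self.values = np.asarray(values, dtype=float)
        n, m = len(self.accession_ids), len(self.meta)
        if self.values.shape != (n, m):
            raise ValueError(
                f"value matrix shape {self.values.shape} != {n} accessions x {m} markers"
            )
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids are not unique")
        ids = [c.marker_id for c in self.meta]
        if len(set(ids)) != m:
            raise ValueError("marker ids are not unique")
        if self.values.size:
            if np.isnan(self.values).any():
                raise ValueError("marker matrix must not contain missing values")
            if self.values.min() < 0.0 or self.values.max() > 2.0:
                raise ValueError("marker values must lie in [0, 2]")

    # -- views ----------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.meta)

    @property
    def marker_ids(self) -> list[str]:
        return [c.marker_id for c in self.meta]

    def meta_frame(self) -> pd.DataFrame:
        """Provenance metadata as a DataFrame (one row per column)."""
        return pd.DataFrame([{f: getattr(c, f) for f in _META_FIELDS} for c in self.meta])

    def subset_markers(self, marker_ids: list[str]) -> "MarkerMatrix":
        lookup = {c.marker_id: j for j, c in enumerate(self.meta)}
        idx = [lookup[mid] for mid in marker_ids]
        return MarkerMatrix(
            self.accession_ids, [self.meta[j] for j in idx], self.values[:, idx]
        )

    def subset_accessions(self, accession_ids: list[str]) -> "MarkerMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [lookup[a] for a in accession_ids]
        return MarkerMatrix(
            [self.accession_ids[i] for i in idx], self.meta, self.values[idx, :]
        )

    def hstack(self, other: "MarkerMatrix") -> "MarkerMatrix":
        """Append another matrix's columns (same accession panel, same order)."""
        if self.accession_ids != other.accession_ids:
            raise ValueError("accession panels differ")
        return MarkerMatrix(
            self.accession_ids,
            self.meta + other.meta,
            np.hstack([self.values, other.values]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.meta == other.meta
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"<MarkerMatrix {self.n_accessions} accessions x {self.n_markers} markers>"


def _vertex_of(snp_id: str, vertex_by_snp: Optional[Mapping[str, str]]) -> Optional[str]:
    return None if vertex_by_snp is None else vertex_by_snp.get(snp_id)


def encode_additive(calls: GenotypeCalls) -> np.ndarray:
    """Alt-allele dosage matrix: hom-ref 0, het 1, hom-alt 2, missing NaN."""
    x = calls.calls.astype(float)
    x[calls.calls == Call.MISSING] = np.nan
    return x


def additive_meta(
    calls: GenotypeCalls, vertex_by_snp: Optional[Mapping[str, str]] = None
) -> list[MarkerMeta]:
    """MarkerMeta for the additive encoding (one column per SNP)."""
    return [
        MarkerMeta(
            marker_id=s.snp_id,
            source_snp_id=s.snp_id,
            encoding="ADDITIVE",
            allele_role=f"alt:{s.alt_allele}",
            source_reference=s.source_reference,
            vertex_id=_vertex_of(s.snp_id, vertex_by_snp),
            chromosome=s.chromosome,
            position=s.position,
        )
        for s in calls.snps
    ]


def encode_pav(
    calls: GenotypeCalls, vertex_by_snp: Optional[Mapping[str, str]] = None
) -> MarkerMatrix:
    """Presence-absence encoding: present (any call) -> 0, missing -> 2."""
    values = np.where(calls.calls == Call.MISSING, 2.0, 0.0)
    meta = [
        MarkerMeta(
            marker_id=f"{s.snp_id}:PAV",
            source_snp_id=s.snp_id,
            encoding="PAV",
            allele_role="absence",
            source_reference=s.source_reference,
            vertex_id=_vertex_of(s.snp_id, vertex_by_snp),
            chromosome=s.chromosome,
            position=s.position,
        )
        for s in calls.snps
    ]
    return MarkerMatrix(calls.accession_ids, meta, values)


def encode_ohe3(
    calls: GenotypeCalls, vertex_by_snp: Optional[Mapping[str, str]] = None
) -> MarkerMatrix:
    """Modified one-hot encoding: allele counts of (absence, ref, alt).

    Per accession and SNP the triple is one of (2,0,0) missing, (0,2,0)
    hom-ref, (0,1,1) het, (0,0,2) hom-alt; rows of a triple always sum to 2
    (diploid allele-count conservation), and the absence column equals the
    PAV encoding.  Columns are interleaved per SNP in the fixed order
    (absence, reference, alternative).
    """
    g = calls.calls
    n, m = g.shape
    absence = np.where(g == Call.MISSING, 2.0, 0.0)
    ref = np.where(g == Call.HOM_REF, 2.0, np.where(g == Call.HET, 1.0, 0.0))
    alt = np.where(g == Call.HOM_ALT, 2.0, np.where(g == Call.HET, 1.0, 0.0))
    values = np.empty((n, 3 * m), dtype=float)
    values[:, 0::3] = absence
    values[:, 1::3] = ref
    values[:, 2::3] = alt
    meta: list[MarkerMeta] = []
    for s in calls.snps:
        common = dict(
            source_snp_id=s.snp_id,
            source_reference=s.source_reference,
            vertex_id=_vertex_of(s.snp_id, vertex_by_snp),
            chromosome=s.chromosome,
            position=s.position,
        )
        meta.append(
            MarkerMeta(f"{s.snp_id}:ABS", encoding="OHE_ABSENCE", allele_role="absence", **common)
        )
        meta.append(
            MarkerMeta(
                f"{s.snp_id}:REF", encoding="OHE_REF", allele_role=f"ref:{s.ref_allele}", **common
            )
        )
        meta.append(
            MarkerMeta(
                f"{s.snp_id}:ALT", encoding="OHE_ALT", allele_role=f"alt:{s.alt_allele}", **common
            )
        )
    return MarkerMatrix(calls.accession_ids, meta, values)


def encode_ohe4(
    calls: GenotypeCalls, vertex_by_snp: Optional[Mapping[str, str]] = None
) -> MarkerMatrix:
    """Classical one-hot: indicator columns for (missing, hom-ref, het, hom-alt)."""
    g = calls.calls
    n, m = g.shape
    values = np.empty((n, 4 * m), dtype=float)
    states = (Call.MISSING, Call.HOM_REF, Call.HET, Call.HOM_ALT)
    for k, state in enumerate(states):
        values[:, k::4] = (g == state).astype(float)
    labels = ("MISSING", "HOM_REF", "HET", "HOM_ALT")
    meta: list[MarkerMeta] = []
    for s in calls.snps:
        for label in labels:
            meta.append(
                MarkerMeta(
                    marker_id=f"{s.snp_id}:OHE4_{label}",
                    source_snp_id=s.snp_id,
                    encoding=f"OHE4_{label}",
                    allele_role=f"state:{label}",
                    source_reference=s.source_reference,
                    vertex_id=_vertex_of(s.snp_id, vertex_by_snp),
                    chromosome=s.chromosome,
                    position=s.position,
                )
            )
    return MarkerMatrix(calls.accession_ids, meta, values)


def partition_by_cr(stats: pd.DataFrame, threshold: float = 0.8) -> tuple[list[str], list[str]]:
    """Split SNP ids into (high-CR, low-CR) at a call-rate threshold.

    A call rate exactly at the threshold goes to the high-CR (core) side; the
    partition is exhaustive and disjoint.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    cr = stats["call_rate"].to_numpy()
    high = [sid for sid, c in zip(stats.index, cr) if c >= threshold]
    low = [sid for sid, c in zip(stats.index, cr) if c < threshold]
    return high, low
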