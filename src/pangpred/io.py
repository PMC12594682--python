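"""File formats: VCF genotype calls, BED-like vertex tables, phenotype and
subpopulation TSVs, and the self-describing marker-matrix TSV.

The marker matrix is stored as a single TSV with two blocks separated by a
blank line: a metadata block (one row per marker column, carrying the full
provenance needed to classify every column as baseline- or vertex-origin)
and a numeric block (one row per accession).  Values are written with
Python's shortest round-tripping float representation, so a write/read cycle
is bit-exact.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .encoding import MarkerMatrix, MarkerMeta, _META_FIELDS
from .genotypes import Call, GenotypeCalls, SnpRecord, VertexRecord

__all__ = [
    "read_genotype_vcf",
    "write_genotype_vcf",
    "read_vertices",
    "write_vertices",
    "read_phenotypes",
    "write_phenotypes",
    "read_subpops",
    "write_subpops",
    "read_marker_matrix",
    "write_marker_matrix",
    "write_additive_export",
]

MARKER_MATRIX_MAGIC = "##pangpred-marker-matrix\tv1"


# ---------------------------------------------------------------------------
# VCF genotype calls
# ---------------------------------------------------------------------------

def read_genotype_vcf(
    path: str,
    source_reference: str,
    skip_multiallelic: bool = False,
) -> GenotypeCalls:
    """Read diploid biallelic SNP calls from a VCF into a call matrix.

    GT fields map as: missing -> MISSING, 0/0 -> HOM_REF, 0/1 (either order,
    phased or not) -> HET, 1/1 -> HOM_ALT.  Records that are not biallelic
    SNPs (multi-allelic, or with non-single-nucleotide alleles) are skipped
    with a warning when ``skip_multiallelic`` is set and rejected otherwise.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    source_reference
        Name of the linear reference the calls were made against; recorded
        on every :class:`SnpRecord`.
    """
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"cannot open VCF {path!r}: {exc}") from exc
    accession_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
    gt_map = np.array([Call.HOM_REF, Call.HET, Call.HOM_ALT, Call.MISSING], dtype=np.int8)
    for rec in vcf:
        alts = rec.ALT
        is_biallelic_snp = (
            len(alts) == 1 and len(rec.REF) == 1 and len(alts[0]) == 1
            and rec.REF in "ACGT" and alts[0] in "ACGT"
        )
        if not is_biallelic_snp:
            if skip_multiallelic:
                n_skipped += 1
                continue
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} is not a biallelic SNP "
                f"(REF={rec.REF}, ALT={','.join(alts) or '.'}); "
                "pass skip_multiallelic=True to drop such records"
            )
        if rec.ploidy != 2:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} is not diploid (ploidy={rec.ploidy})")
        gt = np.asarray(rec.gt_types)
        columns.append(gt_map[gt])
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                source_reference=source_reference,
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[0],
            )
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP record(s) in {path}", stacklevel=2)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(accession_ids), 0), dtype=np.int8)
    )
    gc = GenotypeCalls(accession_ids, snps, calls)
    gc.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gc


_GT_STRINGS = {
    int(Call.MISSING): "./.",
    int(Call.HOM_REF): "0/0",
    int(Call.HET): "0/1",
    int(Call.HOM_ALT): "1/1",
}


def write_genotype_vcf(calls: GenotypeCalls, path: str) -> None:
    """Write calls as a minimal VCFv4.2 file (GT-only, unphased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: list[str] = []
        for s in calls.snps:
            if s.chromosome not in seen:
                seen.append(s.chromosome)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.accession_ids)
            + "\n"
        )
        for j, s in enumerate(calls.snps):
            gts = "\t".join(_GT_STRINGS[int(v)] for v in calls.calls[:, j])
            fh.write(
                f"{s.chromosome}\t{s.position}\t{s.snp_id}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Vertex tables (BED-like)
# ---------------------------------------------------------------------------

def read_vertices(path: str, reference_ranks: Mapping[str, int]) -> list[VertexRecord]:
    """Read a BED-like vertex table: chrom, start, end, vertex_id, source_reference.

    Coordinates are BED-convention 0-based half-open.  ``reference_ranks``
    maps each source reference name to its graph build rank; an unknown
    reference is an error.
    """
    records: list[VertexRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            chrom, start_s, end_s, vertex_id, ref = parts[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            if ref not in reference_ranks:
                raise ValueError(f"{path}:{lineno}: unknown reference {ref!r}")
            records.append(
                VertexRecord(
                    vertex_id=vertex_id,
                    source_reference=ref,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    rank=reference_ranks[ref],
                )
            )
    return records


def write_vertices(vertices: list[VertexRecord], path: str) -> None:
    with open(path, "w") as fh:
        for v in vertices:
            fh.write(f"{v.chromosome}\t{v.start}\t{v.end}\t{v.vertex_id}\t{v.source_reference}\n")


# ---------------------------------------------------------------------------
# Phenotype / subpopulation tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype TSV (accession_id + one column per trait) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate accession ids")
    return df


def write_phenotypes(phenos: pd.DataFrame, path: str) -> None:
    phenos.to_csv(path, sep="\t", index_label="accession_id")


def read_subpops(path: str) -> pd.Series:
    """Subpopulation TSV (accession_id, subpopulation) -> Series."""
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    if "subpopulation" not in df.columns:
        raise ValueError(f"{path}: missing 'subpopulation' column")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate accession ids")
    return df["subpopulation"]


def write_subpops(subpops: pd.Series, path: str) -> None:
    subpops.rename("subpopulation").to_csv(path, sep="\t", index_label="accession_id")


# ---------------------------------------------------------------------------
# Marker matrix TSV
# ---------------------------------------------------------------------------

def _fmt(value: object) -> str:
    return "." if value is None else str(value)


def write_marker_matrix(matrix: MarkerMatrix, path: str) -> None:
    """Serialize a marker matrix with its provenance metadata block."""
    with open(path, "w") as fh:
        fh.write(MARKER_MATRIX_MAGIC + "\n")
        fh.write("\t".join(_META_FIELDS) + "\n")
        for c in matrix.meta:
            fh.write("\t".join(_fmt(getattr(c, f)) for f in _META_FIELDS) + "\n")
        fh.write("\n")
        header_cells = ["accession_id"] + matrix.marker_ids
        fh.write("\t".join(header_cells) + "\n")
        for i, acc in enumerate(matrix.accession_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i, :])
            fh.write(f"{acc}\t{row}\n" if matrix.n_markers else f"{acc}\n")


def read_marker_matrix(path: str) -> MarkerMatrix:
    """Read a marker matrix written by :func:`write_marker_matrix`."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if not lines or lines[0] != MARKER_MATRIX_MAGIC:
        raise ValueError(f"{path}: not a pangpred marker-matrix file")
    try:
        sep = lines.index("")
    except ValueError:
        raise ValueError(f"{path}: missing blank separator line") from None
    header = lines[1].split("\t")
    if tuple(header) != _META_FIELDS:
        raise ValueError(f"{path}: unexpected metadata header {header}")
    meta: list[MarkerMeta] = []
    for line in lines[2:sep]:
        vals = line.split("\t")
        if len(vals) != len(_META_FIELDS):
            raise ValueError(f"{path}: malformed metadata row {line!r}")
        kw = dict(zip(_META_FIELDS, vals))
        kw["vertex_id"] = None if kw["vertex_id"] == "." else kw["vertex_id"]
        kw["chromosome"] = None if kw["chromosome"] == "." else kw["chromosome"]
        kw["position"] = None if kw["position"] == "." else int(kw["position"])
        meta.append(MarkerMeta(**kw))  # type: ignore[arg-type]

    body = [ln for ln in lines[sep + 1 :] if ln != ""]
    if not body:
        raise ValueError(f"{path}: missing value block")
    value_header = body[0].split("\t")
    if value_header[1:] != [c.marker_id for c in meta]:
        raise ValueError(f"{path}: metadata rows do not match value columns")
    accession_ids: list[str] = []
    rows: list[list[float]] = []
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != len(meta) + 1:
            raise ValueError(f"{path}: value row has {len(parts) - 1} columns, expected {len(meta)}")
        accession_ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(meta)))
    values = values.reshape(len(accession_ids), len(meta))
    return MarkerMatrix(accession_ids, meta, values)


def write_additive_export(matrix: MarkerMatrix, path: str) -> None:
    """Optional raw-text export: one row per accession, whitespace dosages.

    A transposed plain "1 row per sample" dosage table for interoperability
    with external genomic-prediction tooling; metadata is not preserved, use
    :func:`write_marker_matrix` for the canonical serialization.
    """
    with open(path, "w") as fh:
        fh.write("accession_id " + " ".join(matrix.marker_ids) + "\n")
        for i, acc in enumerate(matrix.accession_ids):
            fh.write(acc + " " + " ".join(repr(float(v)) for v in matrix.values[i, :]) + "\n")
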