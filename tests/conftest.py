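"""Shared fixtures: compact builders for call matrices and marker matrices."""

import numpy as np
import pytest

from pangpred.encoding import MarkerMatrix, MarkerMeta
from pangpred.genotypes import GenotypeCalls, SnpRecord

# shorthand for call states in fixture matrices
M, R, H, A = -1, 0, 1, 2


@pytest.fixture
def make_calls():
    """Factory: build GenotypeCalls from a plain state matrix.

    Rows are accessions, columns SNPs; states use the -1/0/1/2 alphabet.
    """

    def _make(states, reference="NB", chromosome="chr1", positions=None, ids=None):
        states = np.asarray(states, dtype=np.int8)
        n, m = states.shape
        if positions is None:
            positions = [(j + 1) * 10 for j in range(m)]
        if ids is None:
            ids = [f"s{j}" for j in range(m)]
        snps = [
            SnpRecord(ids[j], reference, chromosome, positions[j], "A", "G")
            for j in range(m)
        ]
        return GenotypeCalls([f"acc{i}" for i in range(n)], snps, states)

    return _make


@pytest.fixture
def make_marker_matrix():
    """Factory: wrap a plain value matrix as additive markers with positions."""

    def _make(values, prefix="m", reference="NB", chromosome="chr1", positions=None):
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        if positions is None:
            positions = [(j + 1) * 10 for j in range(m)]
        meta = [
            MarkerMeta(
                marker_id=f"{prefix}{j}",
                source_snp_id=f"{prefix}{j}",
                encoding="ADDITIVE",
                allele_role="alt:G",
                source_reference=reference,
                chromosome=chromosome,
                position=positions[j],
            )
            for j in range(m)
        ]
        return MarkerMatrix([f"acc{i}" for i in range(n)], meta, values)

    return _make
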