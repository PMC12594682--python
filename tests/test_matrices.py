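"""Assembly of BASELINE and pan-genomic marker matrices."""

import warnings

import numpy as np
import pytest

from pangpred.genotypes import GenotypeCalls, SnpRecord, VertexRecord
from pangpred.matrices import (
    build_baseline,
    build_pang_matrix,
    build_vertex_pool,
    matrix_summary,
)

from conftest import A, M, R


def calls_from(states, reference="NB", positions=None, ids=None, accessions=None):
    states = np.asarray(states, dtype=np.int8)
    n, m = states.shape
    positions = positions or [(j + 1) * 10 for j in range(m)]
    ids = ids or [f"{reference}_s{j}" for j in range(m)]
    accessions = accessions or [f"acc{i}" for i in range(n)]
    snps = [SnpRecord(ids[j], reference, "chr1", positions[j], "A", "G") for j in range(m)]
    return GenotypeCalls(accessions, snps, states)


def test_baseline_keeps_clean_orthogonal_snps():
    rng = np.random.default_rng(0)
    states = rng.choice([R, A], size=(40, 10), p=[0.6, 0.4]).astype(np.int8)
    mm = build_baseline(calls_from(states))
    assert mm.n_markers == 10
    assert all(c.encoding == "ADDITIVE" and c.vertex_id is None for c in mm.meta)
    assert not np.isnan(mm.values).any()


def test_baseline_drops_low_cr_snp():
    rng = np.random.default_rng(1)
    states = rng.choice([R, A], size=(20, 3)).astype(np.int8)
    states[:10, 1] = M  # CR 0.5 < 0.8
    mm = build_baseline(calls_from(states))
    assert [c.source_snp_id for c in mm.meta] == ["NB_s0", "NB_s2"]


def test_baseline_prunes_duplicated_column():
    rng = np.random.default_rng(2)
    col = rng.choice([R, A], size=20).astype(np.int8)
    other = rng.choice([R, A], size=(20, 1)).astype(np.int8)
    states = np.column_stack([col, col, other])
    mm = build_baseline(calls_from(states))
    assert sum(c.source_snp_id in ("NB_s0", "NB_s1") for c in mm.meta) == 1


def make_vertex(vid="v1", ref="REF_x", start=0, end=6000, rank=1):
    return VertexRecord(vid, ref, "chr1", start, end, rank)


def test_pool_keeps_low_cr_vertex_snps():
    rng = np.random.default_rng(3)
    n = 40
    states = rng.choice([R, A], size=(n, 2)).astype(np.int8)
    states[: int(n * 0.7), 0] = M  # CR 0.3, inside vertex: retained
    calls = calls_from(states, reference="REF_x", positions=[100, 9000])
    pool = build_vertex_pool({"REF_x": calls}, [make_vertex(end=6000)])
    assert pool.calls.snp_ids == ["REF_x_s0"]  # s1 outside the vertex
    assert pool.cr.iloc[0] == pytest.approx(0.3)
    assert pool.vertex_by_snp["REF_x_s0"] == "v1"


def test_pool_filters_rare_alleles_and_checks_panels():
    n = 40
    states = np.full((n, 1), R, dtype=np.int8)
    states[0, 0] = A  # maf ~0.0125 <= 0.05
    calls = calls_from(states, reference="REF_x", positions=[100])
    pool = build_vertex_pool({"REF_x": calls}, [make_vertex()])
    assert pool.n_snps == 0
    other = calls_from(states, reference="REF_y", positions=[100],
                       accessions=[f"z{i}" for i in range(n)])
    with pytest.raises(ValueError, match="panel"):
        build_vertex_pool({"REF_x": calls, "REF_y": other}, [make_vertex()])


def _signal_setup(seed=5, n=60):
    rng = np.random.default_rng(seed)
    base_states = rng.choice([R, A], size=(n, 8)).astype(np.int8)
    baseline = build_baseline(calls_from(base_states))
    present = rng.random(n) < 0.5
    vx_states = rng.choice([R, A], size=(n, 2)).astype(np.int8)
    vx_states[~present, :] = M
    vx_calls = calls_from(vx_states, reference="REF_x", positions=[100, 200])
    pool = build_vertex_pool({"REF_x": vx_calls}, [make_vertex()])
    return baseline, pool


def test_pang_modes_append_after_baseline_prefix():
    baseline, pool = _signal_setup()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        core = build_pang_matrix(baseline, pool, "CORE")
        pav = build_pang_matrix(baseline, pool, "PAV")
        ohe = build_pang_matrix(baseline, pool, "OHE")
    # low-CR pool: CORE appends nothing, PAV collapses the two correlated
    # presence columns to one, OHE keeps at most 3 per SNP
    assert core.marker_ids == baseline.marker_ids
    assert pav.marker_ids[: baseline.n_markers] == baseline.marker_ids
    assert ohe.marker_ids[: baseline.n_markers] == baseline.marker_ids
    np.testing.assert_array_equal(
        pav.values[:, : baseline.n_markers], baseline.values
    )
    appended = pav.meta[baseline.n_markers :]
    assert len(appended) == 1 and appended[0].encoding == "PAV"
    assert appended[0].vertex_id == "v1"
    for mm in (core, pav, ohe):
        assert not np.isnan(mm.values).any()
        assert (mm.values.std(axis=0) > 0).all()


def test_pang_ohe_absence_equals_pav_for_intact_groups():
    baseline, pool = _signal_setup(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pav = build_pang_matrix(baseline, pool, "PAV")
        ohe = build_pang_matrix(baseline, pool, "OHE")
    pav_cols = {c.source_snp_id: j for j, c in enumerate(pav.meta) if c.encoding == "PAV"}
    for j, c in enumerate(ohe.meta):
        if c.encoding == "OHE_ABSENCE" and c.source_snp_id in pav_cols:
            np.testing.assert_array_equal(
                ohe.values[:, j], pav.values[:, pav_cols[c.source_snp_id]]
            )


def test_pang_unknown_mode_and_empty_selection(make_calls):
    baseline, pool = _signal_setup(seed=13)
    with pytest.raises(ValueError, match="mode"):
        build_pang_matrix(baseline, pool, "BANANA")
    with pytest.warns(UserWarning, match="returning baseline"):
        out = build_pang_matrix(baseline, pool, "CORE")  # all pool SNPs are low-CR
    assert out == baseline


def test_matrix_summary_counts():
    baseline, pool = _signal_setup(seed=17)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pav = build_pang_matrix(baseline, pool, "PAV")
    out = matrix_summary(pav)
    assert out.iloc[0]["source_reference"] == "BASELINE"
    assert out.iloc[0]["n_markers"] == baseline.n_markers
    ref_rows = out[out["source_reference"] == "REF_x"]
    assert ref_rows["n_markers"].sum() == pav.n_markers - baseline.n_markers
    assert matrix_summary(baseline).shape[0] == 1
    from pangpred.encoding import MarkerMatrix

    empty = MarkerMatrix(["a"], [], np.empty((1, 0)))
    assert matrix_summary(empty).empty
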