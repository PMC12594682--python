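"""Fold plans, predictive ability, cross-validation and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from pangpred.evaluation import (
    backbone_presence_summary,
    cr_by_subpop_summary,
    cross_validate,
    delta_gpa,
    delta_summary,
    gpa,
    make_folds,
)
from pangpred.matrices import VertexSnpPool

from conftest import A, M, R


def test_make_folds_balanced_and_deterministic():
    plan = make_folds([f"a{i}" for i in range(10)], k=5, replications=3, seed=1)
    for r in range(3):
        sizes = np.bincount(plan.assignments[r])[1:]
        assert sizes.tolist() == [2] * 5
    plan11 = make_folds([f"a{i}" for i in range(11)], k=5, replications=1, seed=1)
    assert sorted(np.bincount(plan11.assignments[0])[1:].tolist()) == [2, 2, 2, 2, 3]
    again = make_folds([f"a{i}" for i in range(10)], k=5, replications=3, seed=1)
    assert np.array_equal(plan.assignments, again.assignments)
    assert plan.fingerprint() == again.fingerprint()
    with pytest.raises(ValueError):
        make_folds(["a", "b"], k=5)


def test_each_accession_tested_once_per_replication():
    plan = make_folds([f"a{i}" for i in range(23)], k=5, replications=4, seed=9)
    for r in range(4):
        assert set(plan.assignments[r]) == {1, 2, 3, 4, 5}


def test_gpa_reference_values():
    y = np.array([1.0, 2.0, 3.0, 5.0])
    assert gpa(y, y) == pytest.approx(1.0)
    assert gpa(y, -y) == pytest.approx(-1.0)
    with pytest.warns(UserWarning, match="zero variance"):
        assert np.isnan(gpa(y, np.full(4, 2.0)))
    with pytest.raises(ValueError):
        gpa(y[:2], y[:2])


def test_gpa_invariant_to_positive_affine_predictions():
    rng = np.random.default_rng(0)
    y, p = rng.normal(size=50), rng.normal(size=50)
    assert gpa(y, 3.0 * p + 7.0) == pytest.approx(gpa(y, p), abs=1e-12)


def _phenos(mm, y):
    return pd.DataFrame(
        {"t": y}, index=pd.Index(mm.accession_ids, name="accession_id")
    )


def test_cv_high_heritability_recovers_signal(make_marker_matrix):
    rng = np.random.default_rng(10)
    Z = rng.integers(0, 3, (150, 60)).astype(float)
    mm = make_marker_matrix(Z)
    y = Z @ rng.normal(0, 1.0, 60)  # h2 = 1
    plan = make_folds(mm.accession_ids, k=5, replications=2, seed=3)
    res = cross_validate(mm, _phenos(mm, y), "t", plan)
    assert res.summaries().loc["ALL", "mean_gpa"] > 0.9


def test_cv_null_phenotype_near_zero(make_marker_matrix):
    rng = np.random.default_rng(20)
    Z = rng.integers(0, 3, (150, 40)).astype(float)
    mm = make_marker_matrix(Z)
    y = rng.normal(size=150)
    plan = make_folds(mm.accession_ids, k=5, replications=3, seed=4)
    res = cross_validate(mm, _phenos(mm, y), "t", plan)
    assert abs(res.summaries().loc["ALL", "mean_gpa"]) < 0.15


def test_cv_shared_plan_and_delta(make_marker_matrix):
    rng = np.random.default_rng(30)
    Z = rng.integers(0, 3, (60, 20)).astype(float)
    mm1 = make_marker_matrix(Z, prefix="x")
    mm2 = make_marker_matrix(np.clip(Z + 0.0, 0, 2), prefix="y")
    y = Z @ rng.normal(0, 0.5, 20) + rng.normal(size=60)
    phen = _phenos(mm1, y)
    plan = make_folds(mm1.accession_ids, k=3, replications=2, seed=5)
    r1 = cross_validate(mm1, phen, "t", plan, matrix_label="one")
    r2 = cross_validate(mm2, phen, "t", plan, matrix_label="two")
    assert r1.plan_fingerprint == r2.plan_fingerprint
    d_self = delta_gpa(r1, r1)
    assert (d_self["delta"] == 0.0).all()
    d = delta_gpa(r2, r1)
    summ = delta_summary(d)
    # identical matrices (same values) under one plan give identical GPA
    np.testing.assert_allclose(d["delta"], 0.0, atol=1e-12)
    assert summ.loc["ALL", "mean_delta"] == pytest.approx(0.0, abs=1e-12)
    other_plan = make_folds(mm1.accession_ids, k=3, replications=2, seed=6)
    r3 = cross_validate(mm1, phen, "t", other_plan)
    with pytest.raises(ValueError, match="fold plans"):
        delta_gpa(r3, r1)


def test_cv_subpopulation_groups(make_marker_matrix):
    rng = np.random.default_rng(40)
    Z = rng.integers(0, 3, (60, 15)).astype(float)
    mm = make_marker_matrix(Z)
    y = Z @ rng.normal(0, 1.0, 15)
    phen = _phenos(mm, y)
    subpops = pd.Series(
        ["p1"] * 30 + ["p2"] * 28 + ["tiny"] * 2, index=mm.accession_ids
    )
    plan = make_folds(mm.accession_ids, k=3, replications=2, seed=7)
    with pytest.warns(UserWarning, match="fewer than 3"):
        res = cross_validate(
            mm, phen, "t", plan, subpops=subpops, groups=["ALL", "p1", "p2", "tiny"]
        )
    tab = res.table
    assert set(tab["group"]) == {"ALL", "p1", "p2", "tiny"}
    assert tab.loc[tab["group"] == "tiny", "gpa"].isna().all()
    assert tab.loc[tab["group"] != "tiny", "gpa"].notna().all()


def _pool_from_states(make_calls, states, reference="REF_x"):
    calls = make_calls(states, reference=reference, positions=None)
    vertex_by_snp = {sid: "v1" for sid in calls.snp_ids}
    cr = pd.Series(
        (calls.calls != -1).mean(axis=0), index=calls.snp_ids
    )
    return VertexSnpPool(calls, vertex_by_snp, {reference: 1}, cr)


def test_cr_by_subpop_summary_constructed_pattern(make_calls):
    # 4 accessions in subpop A fully called, 4 in B fully missing
    states = np.array([[R, A]] * 4 + [[M, M]] * 4, dtype=np.int8)
    pool = _pool_from_states(make_calls, states)
    subpops = pd.Series(
        ["A"] * 4 + ["B"] * 4, index=pool.calls.accession_ids
    )
    out = cr_by_subpop_summary(pool, subpops)
    a = out[(out["subpopulation"] == "A")].iloc[0]
    b = out[(out["subpopulation"] == "B")].iloc[0]
    assert a["mean_cr"] == 1.0 and b["mean_cr"] == 0.0


def test_cr_by_subpop_single_snp_partial(make_calls):
    states = np.array([[R], [R], [A], [R], [M]], dtype=np.int8)
    pool = _pool_from_states(make_calls, states)
    subpops = pd.Series(["A"] * 5, index=pool.calls.accession_ids)
    out = cr_by_subpop_summary(pool, subpops)
    assert out.iloc[0]["mean_cr"] == pytest.approx(0.8)


def test_backbone_presence_summary_cells(make_calls):
    # snp0: missing in backbone (acc0), CR 0.25 -> (absent, low)
    # snp1: called in backbone, CR 1.0    -> (present, high)
    states = np.array(
        [[M, R], [M, A], [R, R], [M, R]], dtype=np.int8
    )
    pool = _pool_from_states(make_calls, states)
    out = backbone_presence_summary(pool, "acc0", cr_threshold=0.8)
    assert out.loc["absent_in_backbone", "cr_low"] == 1
    assert out.loc["present_in_backbone", "cr_high"] == 1
    assert out.to_numpy().sum() == 2
    with pytest.raises(KeyError):
        backbone_presence_summary(pool, "ghost")


def test_backbone_presence_empty_pool(make_calls):
    states = np.empty((3, 0), dtype=np.int8)
    calls = make_calls(states, reference="REF_x")
    pool = VertexSnpPool(calls, {}, {"REF_x": 1}, pd.Series(dtype=float))
    out = backbone_presence_summary(pool, "acc0")
    assert out.to_numpy().sum() == 0
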