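"""LD computation and the two pruning modes."""

import numpy as np
import pytest

from pangpred.pruning import pairwise_r2, prune_joint, prune_windowed


def brute_force_window_check(matrix, retained, window, r2_max):
    """Exhaustive post-check: no retained pair within a window exceeds r2_max."""
    idx = {mid: j for j, mid in enumerate(matrix.marker_ids)}
    cols = [matrix.values[:, idx[mid]] for mid in retained]
    for b in range(len(cols)):
        for a in range(max(0, b - window + 1), b):
            assert pairwise_r2(cols[a], cols[b]) <= r2_max + 1e-12


def test_pairwise_r2_reference_cases():
    x = np.array([0.0, 1.0, 2.0, 2.0])
    assert pairwise_r2(x, x) == pytest.approx(1.0)
    assert pairwise_r2(x, 2.0 - x) == pytest.approx(1.0)
    assert pairwise_r2(
        np.array([0.0, 0.0, 2.0, 2.0]), np.array([0.0, 2.0, 0.0, 2.0])
    ) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        pairwise_r2(np.ones(4), x)


def test_windowed_identical_columns_collapse(make_marker_matrix):
    col = np.array([0.0, 1.0, 2.0, 0.0, 2.0])
    m = make_marker_matrix(np.column_stack([col, col, col]))
    report = prune_windowed(m, window=50, r2_max=0.8)
    assert len(report.retained) == 1
    assert {d.cause_marker_id for d in report.dropped} == {report.retained[0]}


def test_windowed_orthogonal_columns_survive(make_marker_matrix):
    rng = np.random.default_rng(0)
    x = np.linalg.qr(rng.normal(size=(30, 10)))[0]  # orthogonal columns
    x = (x - x.min()) / (x.max() - x.min()) * 2.0
    m = make_marker_matrix(x)
    report = prune_windowed(m, window=5, r2_max=0.8)
    assert report.retained == m.marker_ids


def test_windowed_guarantee_is_window_local(make_marker_matrix):
    """Two identical columns separated by more than the window both survive."""
    rng = np.random.default_rng(1)
    dup = rng.integers(0, 3, 40).astype(float)
    fillers = rng.integers(0, 3, (40, 6)).astype(float)
    values = np.column_stack([dup, fillers, dup])
    m = make_marker_matrix(values)
    report = prune_windowed(m, window=3, r2_max=0.8)
    assert "m0" in report.retained and "m7" in report.retained


def test_windowed_drops_lower_maf_member(make_marker_matrix):
    common = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0])  # MAF 0.5
    rare = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 0.0])  # correlated, MAF 1/3
    m = make_marker_matrix(np.column_stack([rare, common]))
    report = prune_windowed(m, window=10, r2_max=0.5)
    # the later but more common column evicts the earlier rare one
    assert report.retained == ["m1"]
    assert report.dropped[0].marker_id == "m0"


def test_windowed_postcondition_random_instance(make_marker_matrix):
    rng = np.random.default_rng(42)
    base = rng.integers(0, 3, (60, 30)).astype(float)
    # plant correlated neighbours
    for j in range(0, 30, 5):
        base[:, j + 1] = np.clip(base[:, j] + (rng.random(60) < 0.1), 0, 2)
    m = make_marker_matrix(base)
    report = prune_windowed(m, window=8, r2_max=0.5)
    brute_force_window_check(m, report.retained, 8, 0.5)
    assert set(report.retained) | {d.marker_id for d in report.dropped} == set(m.marker_ids)
    assert set(report.retained).isdisjoint(report.dropped_ids)


def test_windowed_rejects_unsorted(make_marker_matrix):
    m = make_marker_matrix(np.zeros((4, 3)) + [[0.0, 1.0, 2.0]] , positions=[30, 10, 20])
    with pytest.raises(ValueError, match="position-sorted"):
        prune_windowed(m)


def test_windowed_drops_zero_variance_with_warning(make_marker_matrix):
    values = np.column_stack([np.ones(5), np.arange(5) % 3])
    m = make_marker_matrix(values)
    with pytest.warns(UserWarning, match="zero-variance"):
        report = prune_windowed(m)
    assert report.retained == ["m1"]
    assert report.dropped[0].reason == "zero_variance"


# --- joint (within-vertex) pruning -----------------------------------------


def test_joint_ohe_rare_alt_collapses_to_one_column(make_calls, make_marker_matrix):
    """A rare alternative allele leaves one informative column per SNP:
    the ALT column fails MAF and the absence/REF columns are near-mirror
    images, so joint pruning keeps a single marker."""
    from conftest import A, M, R
    from pangpred.encoding import encode_ohe3

    rng = np.random.default_rng(3)
    n = 200
    states = np.where(rng.random(n) < 0.5, M, R).astype(np.int8)
    states[rng.choice(n, size=4, replace=False)] = A  # alt freq ~0.02
    calls = make_calls(states.reshape(-1, 1))
    ohe = encode_ohe3(calls)
    groups = {mid: "v1" for mid in ohe.marker_ids}
    report = prune_joint(ohe, groups, r2_max=0.6, maf_min=0.05)
    assert len(report.retained) == 1
    reasons = {d.marker_id: d.reason for d in report.dropped}
    assert reasons["s0:ALT"] == "maf"
    assert reasons[[m for m in ("s0:ABS", "s0:REF") if m != report.retained[0]][0]] == "ld"


def test_joint_independent_columns_survive(make_marker_matrix):
    rng = np.random.default_rng(7)
    values = (rng.random((100, 6)) < 0.5) * 2.0
    m = make_marker_matrix(values)
    groups = {mid: "v1" for mid in m.marker_ids}
    report = prune_joint(m, groups, r2_max=0.6, maf_min=0.05)
    assert report.retained == m.marker_ids


def test_joint_pruning_is_within_group_only(make_marker_matrix):
    col = (np.arange(20) % 2) * 2.0
    m = make_marker_matrix(np.column_stack([col, col, col, col]))
    groups = {"m0": "g1", "m1": "g1", "m2": "g2", "m3": "g2"}
    report = prune_joint(m, groups, r2_max=0.6, maf_min=0.0)
    assert report.retained == ["m0", "m2"]  # one per group, cross-group untouched


def test_joint_requires_group_for_every_marker(make_marker_matrix):
    m = make_marker_matrix(((np.arange(10) % 2) * 2.0).reshape(-1, 1))
    with pytest.raises(ValueError, match="without group"):
        prune_joint(m, {}, r2_max=0.6)


def test_joint_monotone_in_threshold(make_marker_matrix):
    rng = np.random.default_rng(11)
    base = rng.integers(0, 3, (80, 12)).astype(float)
    base[:, 6:] = np.clip(base[:, :6] + (rng.random((80, 6)) < 0.2), 0, 2)
    m = make_marker_matrix(base)
    groups = {mid: "v" for mid in m.marker_ids}
    loose = set(prune_joint(m, groups, r2_max=0.9, maf_min=0.0).retained)
    tight = set(prune_joint(m, groups, r2_max=0.3, maf_min=0.0).retained)
    assert tight <= loose


def test_joint_invariant_to_column_scaling(make_marker_matrix):
    rng = np.random.default_rng(13)
    values = rng.integers(0, 3, (50, 8)).astype(float)
    m1 = make_marker_matrix(values)
    m2 = make_marker_matrix(values * 0.5)
    groups = {mid: "v" for mid in m1.marker_ids}
    r1 = prune_joint(m1, groups, r2_max=0.6, maf_min=0.0)
    r2 = prune_joint(m2, groups, r2_max=0.6, maf_min=0.0)
    assert r1.retained == r2.retained


def test_joint_postcondition_exhaustive(make_marker_matrix):
    rng = np.random.default_rng(17)
    values = rng.integers(0, 3, (60, 40)).astype(float)
    values[:, 20:] = np.clip(values[:, :20] + (rng.random((60, 20)) < 0.15), 0, 2)
    m = make_marker_matrix(values)
    groups = {mid: f"v{j % 4}" for j, mid in enumerate(m.marker_ids)}
    report = prune_joint(m, groups, r2_max=0.6, maf_min=0.0)
    idx = {mid: j for j, mid in enumerate(m.marker_ids)}
    kept_by_group = {}
    for mid in report.retained:
        kept_by_group.setdefault(groups[mid], []).append(mid)
    for members in kept_by_group.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                r2 = pairwise_r2(
                    m.values[:, idx[members[a]]], m.values[:, idx[members[b]]]
                )
                assert r2 <= 0.6 + 1e-12
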