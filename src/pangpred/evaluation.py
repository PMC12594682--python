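"""Repeated cross-validation, predictive ability, and descriptive summaries.

Model accuracy is assessed by replicated k-fold cross-validation (default 10
replications of 5-fold).  Genomic predictive ability (GPA) is the Pearson
correlation between observed phenotypes and predicted breeding values,
pooled over the k test folds of a replication; the identical fold plan is
reused across all marker matrices being compared, so differences in GPA
reflect the matrices and not the partitions.  Delta-GPA is reported per
replication against a named baseline matrix.

Also here: the reporting operations over vertex SNP pools — call-rate
summaries per source reference within subpopulations, and the 2x2
classification of pool SNPs by backbone-sample presence vs call rate.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .encoding import MarkerMatrix
from .genotypes import Call
from .matrices import VertexSnpPool
from .rrblup import RidgeBLUP

__all__ = [
    "FoldPlan",
    "CvResult",
    "make_folds",
    "gpa",
    "cross_validate",
    "delta_gpa",
    "delta_summary",
    "cr_by_subpop_summary",
    "backbone_presence_summary",
]


@dataclass
class FoldPlan:
    """Shared fold partitions for repeated k-fold cross-validation.

    ``assignments`` is a (replications x n_accessions) integer array of fold
    labels in 1..k, columns aligned with ``accession_ids``.  Within each
    replication the folds partition the accessions with sizes differing by
    at most one.
    """

    seed: int
    k: int
    replications: int
    accession_ids: list[str]
    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.shape != (self.replications, len(self.accession_ids)):
            raise ValueError("assignments shape does not match replications x accessions")
        for r in range(self.replications):
            labels = self.assignments[r]
            if set(np.unique(labels)) != set(range(1, self.k + 1)):
                raise ValueError(f"replication {r}: folds do not cover 1..k")
            sizes = np.bincount(labels)[1:]
            if sizes.max() - sizes.min() > 1:
                raise ValueError(f"replication {r}: fold sizes differ by more than 1")

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(str(self.seed).encode())
        h.update("\x00".join(self.accession_ids).encode())
        h.update(self.assignments.tobytes())
        return h.hexdigest()[:16]


def make_folds(
    accessions: Sequence[str], k: int = 5, replications: int = 10, seed: int = 0
) -> FoldPlan:
    """Uniform random fold partitions, deterministic given the seed."""
    accessions = list(accessions)
    n = len(accessions)
    if n < k:
        raise ValueError(f"need at least k={k} accessions, got {n}")
    rng = np.random.default_rng(seed)
    assignments = np.empty((replications, n), dtype=int)
    base = np.arange(n) % k + 1  # balanced labels: sizes differ by <= 1
    for r in range(replications):
        assignments[r] = base[rng.permutation(n)]
    return FoldPlan(seed, k, replications, accessions, assignments)


def gpa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Genomic predictive ability: Pearson r of observed vs predicted.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    if y_true.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(y_true) == 0.0 or np.ptp(y_pred) == 0.0:
        warnings.warn("GPA undefined: zero variance in observed or predicted values",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


@dataclass
class CvResult:
    """Tidy per-(replication, group) GPA table for one matrix and trait."""

    trait: str
    matrix_label: str
    plan_fingerprint: str
    table: pd.DataFrame  # columns: replication, trait, matrix, group, gpa

    def summaries(self) -> pd.DataFrame:
        """Mean and SD of GPA over replications, per evaluation group."""
        g = self.table.groupby("group", sort=False)["gpa"]
        return pd.DataFrame({"mean_gpa": g.mean(), "sd_gpa": g.std(ddof=1)})


def cross_validate(
    matrix: MarkerMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    plan: FoldPlan,
    subpops: Optional[pd.Series] = None,
    groups: Union[str, Sequence[str]] = "ALL",
    matrix_label: Optional[str] = None,
) -> CvResult:
    """Replicated k-fold cross-validation of rrBLUP on one marker matrix.

    For every replication, each fold is predicted by a model trained on the
    other k-1 folds; predictions are pooled over the k folds and one GPA per
    evaluation group is computed from the pooled test set.  ``groups`` is
    "ALL" (every test accession) and/or subpopulation labels, which restrict
    the test set to the accessions of that subpopulation; a group with a
    degenerate test pool gets an undefined (NaN) GPA for that replication.

    Accessions with a missing phenotype must be excluded before building the
    fold plan; any plan accession lacking the trait or a matrix row is an
    error.
    """
    roster = plan.accession_ids
    Z_all = matrix.subset_accessions(roster).values
    y_all = phenotypes.loc[roster, trait].to_numpy(dtype=float)
    if np.isnan(y_all).any():
        raise ValueError(f"trait {trait!r} missing for some plan accessions")
    group_list = ["ALL"] if groups == "ALL" else list(groups)
    if subpops is None and group_list != ["ALL"]:
        raise ValueError("subpopulation groups requested but no assignment given")
    label = matrix_label if matrix_label is not None else "matrix"

    group_masks = {}
    for g in group_list:
        if g == "ALL":
            group_masks[g] = np.ones(len(roster), dtype=bool)
        else:
            group_masks[g] = subpops.reindex(roster).to_numpy() == g

    rows = []
    for r in range(plan.replications):
        labels = plan.assignments[r]
        y_pred = np.full(len(roster), np.nan)
        for f in range(1, plan.k + 1):
            test = labels == f
            res = RidgeBLUP(y_all[~test], Z_all[~test]).fit()
            y_pred[test] = res.predict(Z_all[test])
        for g in group_list:
            mask = group_masks[g]
            if mask.sum() < 3:
                warnings.warn(f"group {g!r}: fewer than 3 test accessions", stacklevel=2)
                value = float("nan")
            else:
                value = gpa(y_all[mask], y_pred[mask])
            rows.append(
                {"replication": r + 1, "trait": trait, "matrix": label,
                 "group": g, "gpa": value}
            )
    return CvResult(trait, label, plan.fingerprint(), pd.DataFrame(rows))


def delta_gpa(result: CvResult, baseline: CvResult) -> pd.DataFrame:
    """Per-replication delta GPA = GPA(result) - GPA(baseline), with summaries.

    Both results must come from the same fold plan and trait; groups are
    matched on (replication, group).  Returns the per-replication table with
    a ``delta`` column; use :func:`delta_summary` for mean and SD per group.
    """
    if result.plan_fingerprint != baseline.plan_fingerprint:
        raise ValueError("results come from different fold plans")
    if result.trait != baseline.trait:
        raise ValueError("results are for different traits")
    merged = result.table.merge(
        baseline.table[["replication", "group", "gpa"]],
        on=["replication", "group"],
        suffixes=("", "_baseline"),
        validate="one_to_one",
    )
    merged["delta"] = merged["gpa"] - merged["gpa_baseline"]
    return merged


def delta_summary(delta_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of delta GPA over replications, per evaluation group."""
    g = delta_table.groupby("group", sort=False)["delta"]
    return pd.DataFrame({"mean_delta": g.mean(), "sd_delta": g.std(ddof=1)})


def cr_by_subpop_summary(
    pool: VertexSnpPool, subpops: pd.Series
) -> pd.DataFrame:
    """Mean call rate with quartiles per (source reference, subpopulation).

    Call rates are recomputed within each subpopulation's accessions; SNPs
    are grouped by the source reference of their vertex.  Mirrors the
    pattern where SNPs from a reference have a markedly higher call rate in
    accessions of that reference's own subpopulation.
    """
    calls = pool.calls
    refs = np.array([s.source_reference for s in calls.snps])
    rows = []
    for label in pd.unique(subpops):
        members = subpops.index[subpops == label]
        members = [a for a in members if a in set(calls.accession_ids)]
        if not members:
            warnings.warn(f"subpopulation {label!r} has no accessions in the panel",
                          stacklevel=2)
            continue
        idx = calls.accession_indexer(members)
        sub = calls.calls[idx, :]
        cr = (sub != Call.MISSING).mean(axis=0)
        for ref in pd.unique(refs):
            sel = cr[refs == ref]
            rows.append(
                {
                    "source_reference": ref,
                    "subpopulation": label,
                    "mean_cr": float(sel.mean()),
                    "q25_cr": float(np.percentile(sel, 25)),
                    "q75_cr": float(np.percentile(sel, 75)),
                    "n_snps": int(sel.size),
                }
            )
    return pd.DataFrame(rows)


def backbone_presence_summary(
    pool: VertexSnpPool, backbone_accession: str, cr_threshold: float = 0.8
) -> pd.DataFrame:
    """2x2 counts of pool SNPs: called in the backbone sample x high CR.

    Vertex SNPs are absent from the backbone reference by construction, so
    any call in the backbone sample itself flags a likely misalignment; the
    cross-tabulation against CR > ``cr_threshold`` quantifies how strongly
    backbone presence and high call rate co-occur.
    """
    calls = pool.calls
    if backbone_accession not in calls.accession_ids:
        raise KeyError(f"unknown accession {backbone_accession!r}")
    i = calls.accession_ids.index(backbone_accession)
    present = calls.calls[i, :] != Call.MISSING
    high = pool.cr.to_numpy() > cr_threshold
    out = pd.DataFrame(
        {
            "cr_high": [int((present & high).sum()), int((~present & high).sum())],
            "cr_low": [int((present & ~high).sum()), int((~present & ~high).sum())],
        },
        index=pd.Index(["present_in_backbone", "absent_in_backbone"], name="backbone"),
    )
    return out
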