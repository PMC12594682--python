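"""Per-SNP quality statistics, threshold filtering and mean imputation.

Call rate (CR) is the frequency of non-missing calls for a SNP over a chosen
accession subset; MAF and heterozygosity are computed over the non-missing
calls only.  SNPs with no non-missing call in the subset get undefined (NaN)
MAF and heterozygosity but a defined CR of 0.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genotypes import Call, GenotypeCalls

__all__ = ["snp_stats", "filter_snps", "mean_impute"]


def snp_stats(calls: GenotypeCalls, subset: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Per-SNP call rate, minor allele frequency and heterozygosity.

    Parameters
    ----------
    calls
        The genotype call matrix.
    subset
        Accession ids to restrict to; ``None`` means all accessions.

    Returns
    -------
    DataFrame indexed by ``snp_id`` with columns ``call_rate``, ``maf``,
    ``het_rate`` and ``n_nonmissing``, in the input SNP order.
    """
    if subset is None:
        mat = calls.calls
        n = calls.n_accessions
    else:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("accession subset is empty")
        idx = calls.accession_indexer(subset)
        mat = calls.calls[idx, :]
        n = len(subset)

    n_het = (mat == Call.HET).sum(axis=0)
    n_hom_alt = (mat == Call.HOM_ALT).sum(axis=0)
    n_missing = (mat == Call.MISSING).sum(axis=0)
    n_nonmissing = n - n_missing

    call_rate = n_nonmissing / n
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = (2.0 * n_hom_alt + n_het) / (2.0 * n_nonmissing)
        het_rate = n_het / n_nonmissing
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    undefined = n_nonmissing == 0
    maf[undefined] = np.nan
    het_rate = np.where(undefined, np.nan, het_rate)

    return pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "het_rate": het_rate,
            "n_nonmissing": n_nonmissing,
        },
        index=pd.Index(calls.snp_ids, name="snp_id"),
    )


def filter_snps(
    stats: pd.DataFrame,
    cr_min: Optional[float] = None,
    maf_min: Optional[float] = None,
    het_max: Optional[float] = None,
) -> list[str]:
    """SNP ids surviving strict threshold filters, in input order.

    A SNP survives iff CR > ``cr_min`` AND maf > ``maf_min`` AND
    het_rate < ``het_max``; each comparison is strict, and a threshold of
    ``None`` is skipped.  Undefined (NaN) maf/het fail any threshold on them.
    """
    for name, value in (("cr_min", cr_min), ("maf_min", maf_min), ("het_max", het_max)):
        if value is not None and not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    keep = np.ones(len(stats), dtype=bool)
    if cr_min is not None:
        keep &= stats["call_rate"].to_numpy() > cr_min
    if maf_min is not None:
        keep &= stats["maf"].to_numpy() > maf_min
    if het_max is not None:
        keep &= stats["het_rate"].to_numpy() < het_max
    return [sid for sid, k in zip(stats.index, keep) if k]


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace NaN entries by their column mean over non-missing entries.

    Raises on any all-missing column; callers are expected to have filtered
    those out (e.g. by a CR threshold) first.
    """
    x = np.array(dosages, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D dosage matrix")
    missing = np.isnan(x)
    if not missing.any():
        return x
    n_obs = (~missing).sum(axis=0)
    bad = np.flatnonzero(n_obs == 0)
    if bad.size:
        raise ValueError(f"column(s) {bad.tolist()} have no non-missing entries")
    col_mean = np.nansum(x, axis=0) / n_obs
    rows, cols = np.nonzero(missing)
    x[rows, cols] = col_mean[cols]
    return x
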