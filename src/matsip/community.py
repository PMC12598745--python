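"""Metaproteome community profiling by normalized spectral abundance factors.

The relative abundance of a protein in a sample is its NSAF: the
spectral-count density ``#PSMs / #AAs`` normalized to sum to one over
the sample. Summing NSAF over the proteins attributed to a
metagenome-assembled genome (MAG) gives the MAG's proteome abundance;
proteins identified identically in more than one MAG are removed before
normalization so that abundances reflect only attributable signal.

Quality control mirrors standard metaproteomic practice: peptide- and
protein-level FDR above 5% and proteins without protein-unique peptides
are discarded before any quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidValueError, SchemaError

__all__ = [
    "filter_records",
    "nsaf",
    "mag_abundance",
    "abundance_matrix",
    "abundance_threshold_mask",
    "abundance_correlation",
]

RECORD_COLUMNS = [
    "sample_id", "protein_id", "mag_id", "psms", "aa_len",
    "has_unique_peptide", "peptide_fdr", "protein_fdr", "multi_mag",
]

FDR_THRESHOLD = 0.05


def _check_records(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(f"protein table missing columns {sorted(missing)}")
    if (records["aa_len"] <= 0).any():
        raise InvalidValueError("aa_len must be positive")
    for col in ("peptide_fdr", "protein_fdr"):
        if ((records[col] < 0) | (records[col] > 1)).any():
            raise InvalidValueError(f"{col} must lie in [0, 1]")


def filter_records(records: pd.DataFrame,
                   fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Discard records failing FDR or uniqueness quality control.

    Removes records with peptide or protein FDR above ``fdr_threshold``
    and proteins without protein-unique peptides. Per-reason removal
    counts are attached as ``result.attrs['removals']``.
    """
    _check_records(records)
    bad_pep = records["peptide_fdr"] > fdr_threshold
    bad_prot = records["protein_fdr"] > fdr_threshold
    no_unique = ~records["has_unique_peptide"].astype(bool)
    keep = ~(bad_pep | bad_prot | no_unique)
    out = records[keep].copy()
    out.attrs["removals"] = {
        "peptide_fdr": int(bad_pep.sum()),
        "protein_fdr": int(bad_prot.sum()),
        "no_unique_peptide": int(no_unique.sum()),
        "total": int((~keep).sum()),
    }
    return out


def nsaf(records: pd.DataFrame) -> pd.Series:
    """NSAF per protein for one sample's (filtered) records.

    ``NSAF_i = (psms_i / aa_len_i) / Σ_j (psms_j / aa_len_j)``; sums to 1.
    """
    if records["sample_id"].nunique() > 1:
        raise SchemaError("nsaf expects records from a single sample")
    saf = records["psms"].to_numpy(dtype=float) / records["aa_len"].to_numpy(dtype=float)
    total = saf.sum()
    if total <= 0:
        raise InsufficientDataError("no spectral counts in sample")
    return pd.Series(saf / total, index=records["protein_id"].to_numpy(), name="nsaf")


def mag_abundance(records: pd.DataFrame) -> pd.Series:
    """Per-MAG proteome abundance for one sample: the sum of NSAF over
    proteins attributed to each MAG.

    Proteins found identically in multiple MAGs (``multi_mag``) are
    excluded *before* NSAF normalization, so the returned column sums to 1
    over MAGs plus the 'unbinned' bucket.
    """
    usable = records[~records["multi_mag"].astype(bool)]
    if len(usable) == 0:
        raise InsufficientDataError("no single-MAG proteins in sample")
    values = nsaf(usable)
    return values.groupby(usable["mag_id"].to_numpy()).sum().rename("abundance")


def abundance_matrix(records: pd.DataFrame,
                     prefiltered: bool = False) -> pd.DataFrame:
    """MAG × sample relative-abundance matrix from a multi-sample protein
    table. Columns are samples and each sums to 1; absent MAG/sample
    combinations are 0."""
    if not prefiltered:
        records = filter_records(records)
    cols = {
        sample: mag_abundance(group)
        for sample, group in records.groupby("sample_id")
    }
    return pd.DataFrame(cols).fillna(0.0).sort_index()


def abundance_threshold_mask(matrix: pd.DataFrame,
                             min_abundance: float = 0.001) -> list[str]:
    """MAGs whose abundance reaches ``min_abundance`` in every sample
    (the display threshold for community profiles)."""
    keep = (matrix >= min_abundance).all(axis=1)
    return list(matrix.index[keep])


def abundance_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of MAG abundance profiles across samples.

    Restricted to MAGs present (abundance > 0) in all samples; requires at
    least 3 samples. A MAG with zero variance across samples yields NaN
    (undefined), never 0.
    """
    if matrix.shape[1] < 3:
        raise InsufficientDataError("correlation needs at least 3 samples")
    present = matrix.index[(matrix > 0).all(axis=1)]
    sub = matrix.loc[present]
    # rows are variables (MAGs), observations are samples
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.to_numpy())
    zero_var = sub.std(axis=1, ddof=0).to_numpy() == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, np.where(zero_var, np.nan, 1.0))
    return pd.DataFrame(corr, index=present, columns=present)
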