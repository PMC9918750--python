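"""Immune activity scores: SIA, Immunoscore-like metric, RNA surrogates.

The Signature of Immune Activation (SIA) balances cytotoxic against
pro-tumoural myeloid infiltration:

    SIA = d(CD8+) / (d(CD8+) + d(CD68+CD163+))

with d(.) an area-normalised cell density.  SIA lies in [0, 1]; when
both densities are zero the score is undefined and the patient is
excluded downstream (logged).

The Immunoscore-like metric (IS) averages, per patient, the cohort
percentile ranks of CD3+ and CD8+ cell densities in tumour centre and
invasive margin (four channels; three when one region is missing for a
marker; two channels — CD3 and CD8 only — for cohorts sampled from bulk
tumour).  The mean percentile is categorised Low (0-25], Intermediate
(25-70] and High (70-100].

RNA surrogates replace densities by transcripts: CD8A/C1QA (or B/C)
ratios for bulk profiles, and marker-positive cell counts for single
cell data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("siascore")

__all__ = [
    "compute_sia",
    "compute_is",
    "rna_sia",
    "rna_is_like",
    "sc_qc_filter",
    "sc_sia",
]


def compute_sia(cd8_density, m2_density):
    """SIA = cd8 / (cd8 + m2); NaN where both densities are zero.

    Accepts scalars or aligned vectors of non-negative densities.
    """
    cd8 = np.asarray(cd8_density, dtype=float)
    m2 = np.asarray(m2_density, dtype=float)
    if (cd8 < 0).any() or (m2 < 0).any():
        raise ValueError("densities must be non-negative")
    total = cd8 + m2
    with np.errstate(invalid="ignore", divide="ignore"):
        sia = np.where(total > 0, cd8 / np.where(total > 0, total, 1.0), np.nan)
    n_undef = int(np.isnan(sia).sum())
    if n_undef:
        logger.info("SIA undefined (0/0) for %d patient(s); excluded", n_undef)
    if np.isscalar(cd8_density) and np.isscalar(m2_density):
        return float(sia)
    return sia


def _percentile_rank(values: pd.Series) -> pd.Series:
    """Cohort percentile of each non-missing value (ties averaged; the
    cohort maximum maps to exactly 100)."""
    v = values.dropna()
    pct = pd.Series(100.0 * rankdata(v, method="average") / len(v), index=v.index)
    return pct.reindex(values.index)


def compute_is(channels: pd.DataFrame, bounds=(25.0, 70.0)) -> pd.DataFrame:
    """Immunoscore-like mean percentile and category per patient.

    ``channels`` is a patients x density-channels table (e.g. columns
    ``cd3_centre``, ``cd8_centre``, ``cd3_margin``, ``cd8_margin``, or
    just ``cd3``/``cd8`` for bulk cohorts); missing entries (NaN) mark
    incomplete cases and are simply left out of the per-patient mean.
    Each channel is percentile-ranked within the cohort first.

    Returns a frame with ``IS`` (mean percentile, NaN when no channel is
    available) and ``IS_category`` (Low <= 25 < Intermediate <= 70 <
    High).
    """
    if len(channels) < 3:
        raise ValueError("need a cohort of at least 3 patients")
    pct = channels.apply(_percentile_rank, axis=0)
    is_score = pct.mean(axis=1, skipna=True)
    n_missing = int(is_score.isna().sum())
    if n_missing:
        logger.info("IS undefined for %d patient(s) with no channels; excluded",
                    n_missing)
    lo, hi = bounds
    category = pd.Series(
        np.select(
            [is_score <= lo, is_score <= hi],
            ["Low", "Intermediate"],
            default="High",
        ),
        index=is_score.index,
    ).where(is_score.notna())
    return pd.DataFrame({"IS": is_score, "IS_category": category})


def rna_sia(matrix, denominator: str = "C1QA",
            pre_therapy_only: bool = True) -> pd.Series:
    """Bulk-RNA SIA surrogate: CD8A / C1QA (or C1QB/C1QC) per patient.

    When the matrix annotations carry a ``timepoint`` column, only
    pre-therapy samples (labels starting with "pre", case-insensitive)
    enter the score.  A patient with several retained samples receives
    the mean of their per-sample ratios.  A zero denominator with
    positive CD8A yields +inf (ranked above every finite score); 0/0 is
    undefined (NaN) and excluded.
    """
    if denominator.upper() not in ("C1QA", "C1QB", "C1QC"):
        raise ValueError("denominator must be one of C1QA, C1QB, C1QC")
    mat = matrix.to_linear()
    for gene in ("CD8A", denominator):
        if not mat.has_gene(gene):
            raise KeyError(f"gene {gene!r} required for the RNA SIA surrogate "
                           "is absent from the matrix")
    num = mat.gene("CD8A").astype(float)
    den = mat.gene(denominator).astype(float)
    keep = pd.Series(True, index=num.index)
    if pre_therapy_only and "timepoint" in mat.obs.columns:
        keep = mat.obs["timepoint"].astype(str).str.lower().str.startswith("pre")
        logger.info("pre-therapy filter retained %d/%d samples",
                    int(keep.sum()), len(keep))
    num, den = num[keep], den[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score[(den == 0) & (num > 0)] = np.inf
    score[(den == 0) & (num == 0)] = np.nan

    if "patient" in mat.obs.columns:
        patient = mat.obs.loc[score.index, "patient"]
        grouped = score.groupby(patient).mean()
        multi = patient.value_counts()
        for pid in multi[multi > 1].index:
            logger.info("patient %s has %d samples; SIA averaged",
                        pid, multi[pid])
        return grouped
    return score


def rna_is_like(matrix) -> pd.Series:
    """IS-like bulk surrogate: mean of CD8A and CD3E expression."""
    mat = matrix.to_linear()
    for gene in ("CD8A", "CD3E"):
        if not mat.has_gene(gene):
            raise KeyError(f"gene {gene!r} required for the IS-like surrogate "
                           "is absent from the matrix")
    return 0.5 * (mat.gene("CD8A").astype(float) + mat.gene("CD3E").astype(float))


def sc_qc_filter(matrix, min_genes: int = 250, mito_ceiling: float = 0.05,
                 mito_prefix: str = "MT-"):
    """Single-cell QC: drop low-complexity and high-mitochondrial cells.

    Keeps cells with at least ``min_genes`` detected (nonzero) genes and
    a mitochondrial count fraction of at most ``mito_ceiling``.  The
    ceiling is a fraction (0.05 = 5%); pass ``0.0005`` to reproduce a
    literal 0.05% reading.  Mitochondrial genes are identified by symbol
    prefix.  Returns ``(filtered_matrix, report_dict)``.
    """
    from .io import ExpressionMatrix

    counts = matrix.values
    detected = (counts > 0).sum(axis=0)
    mito_mask = counts.index.str.upper().str.startswith(mito_prefix.upper())
    total = counts.sum(axis=0)
    if mito_mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = counts.loc[mito_mask].sum(axis=0) / total.replace(0, np.nan)
        mito_frac = mito_frac.fillna(0.0)
        pass_mito = mito_frac <= mito_ceiling
    else:
        logger.warning("no genes with prefix %r found; mitochondrial filter "
                       "skipped", mito_prefix)
        pass_mito = pd.Series(True, index=counts.columns)
    pass_genes = detected >= min_genes
    keep = pass_genes & pass_mito
    report = {
        "n_input": int(counts.shape[1]),
        "n_removed_min_genes": int((~pass_genes).sum()),
        "n_removed_mito": int((pass_genes & ~pass_mito).sum()),
        "n_kept": int(keep.sum()),
        "min_genes": min_genes,
        "mito_ceiling": mito_ceiling,
    }
    filtered = ExpressionMatrix(
        counts.loc[:, keep], matrix.obs.loc[keep], matrix.scale
    )
    return filtered, report


M2_GENE_PAIRS = {
    "CD68&CD163": ("CD68", "CD163"),
    "CD68&C1QA": ("CD68", "C1QA"),
    "CD68&C1QB": ("CD68", "C1QB"),
    "CD68&C1QC": ("CD68", "C1QC"),
}


def sc_sia(matrix, m2_definition: str = "CD68&CD163",
           group_by: str = "patient", positivity_threshold: float = 0.0) -> pd.Series:
    """Single-cell SIA from marker-positive cell counts.

    Per patient (or lesion): n_cd8 = cells with CD8A expression above
    the positivity threshold (default: any nonzero count); n_m2 = cells
    positive for both genes of the chosen M2 definition; SIA =
    n_cd8 / (n_cd8 + n_m2), NaN when both counts are zero.
    """
    try:
        gene_a, gene_b = M2_GENE_PAIRS[m2_definition]
    except KeyError:
        raise ValueError(
            f"unknown M2 definition {m2_definition!r}; "
            f"choose from {sorted(M2_GENE_PAIRS)}"
        ) from None
    for gene in ("CD8A", gene_a, gene_b):
        if not matrix.has_gene(gene):
            raise KeyError(f"gene {gene!r} required for single-cell SIA "
                           "is absent from the matrix")
    if group_by not in matrix.obs.columns:
        raise KeyError(f"grouping column {group_by!r} missing from cell labels")
    cd8_pos = matrix.gene("CD8A") > positivity_threshold
    m2_pos = (matrix.gene(gene_a) > positivity_threshold) & \
             (matrix.gene(gene_b) > positivity_threshold)
    groups = matrix.obs[group_by]
    n_cd8 = cd8_pos.groupby(groups).sum()
    n_m2 = m2_pos.groupby(groups).sum()
    return compute_sia_from_counts(n_cd8, n_m2)


def compute_sia_from_counts(n_cd8: pd.Series, n_m2: pd.Series) -> pd.Series:
    total = n_cd8 + n_m2
    with np.errstate(invalid="ignore", divide="ignore"):
        sia = n_cd8 / total.replace(0, np.nan)
    return sia.rename("SIA")
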