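"""Normalization to the pipeline's working space and the DEG universe.

The working space is log2(TPM + 1).  FPKM input is first renormalized per
sample to TPM (columns sum to 1e6), log-transformed, and genes with a
missing-value fraction above the threshold are removed.  Differential
expression is a pluggable two-group stage whose output (the DEG universe)
feeds ceRNA identification; effect sizes are mean log2TPM differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import TPM_TOTAL, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Transcript biotypes counted as long non-coding when length > 200 nt.
LNCRNA_BIOTYPES = frozenset(
    {
        "processed_transcript",
        "lincRNA",
        "3prime_overlapping_ncrna",
        "antisense",
        "non_coding",
        "sense_intronic",
        "sense_overlapping",
    }
)


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalize each sample column so abundances sum to 1e6.

    TPM_g = FPKM_g / sum_over_genes(FPKM) * 1e6, per sample.  Raises
    ``ValueError`` naming the sample if a column has no positive signal.
    """
    if matrix.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {matrix.unit}")
    colsums = matrix.values.sum(axis=0, skipna=True)
    dead = colsums[colsums <= 0]
    if len(dead):
        raise ValueError(f"all-zero expression column(s): {', '.join(map(str, dead.index))}")
    tpm = matrix.values.div(colsums, axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "TPM", matrix.gene_meta, matrix.sample_meta)


def log_and_filter(matrix: ExpressionMatrix, missing_frac: float = 0.30) -> ExpressionMatrix:
    """log2(x+1)-transform TPM and drop genes with too many missing values.

    A value is *missing* when it is NA; zeros are observed measurements.
    Genes whose missing fraction is strictly greater than ``missing_frac``
    are removed (a gene missing in exactly that fraction is retained).
    Remaining NAs are left in place for downstream pairwise handling.
    """
    if matrix.unit != "TPM":
        raise ValueError(f"expected TPM input, got {matrix.unit}")
    if not 0.0 <= missing_frac <= 1.0:
        raise ValueError(f"missing_frac must be in [0, 1], got {missing_frac}")
    na_frac = matrix.values.isna().mean(axis=1)
    keep = na_frac <= missing_frac
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("log_and_filter: removed %d genes with >%0.0f%% missing values",
                    n_removed, 100 * missing_frac)
    vals = np.log2(matrix.values.loc[keep] + 1.0)
    gmeta = None if matrix.gene_meta is None else matrix.gene_meta.loc[keep[keep].index]
    return ExpressionMatrix(vals, "log2TPM", gmeta, matrix.sample_meta)


def classify_lncrna(gene_meta: pd.DataFrame) -> pd.Series:
    """Assign each gene a class in {"lncRNA", "mRNA", "excluded"}.

    lncRNA iff the biotype is one of the seven non-coding classes in
    :data:`LNCRNA_BIOTYPES` *and* transcript length is strictly greater
    than 200 nt; mRNA iff biotype is protein_coding; anything else is
    excluded (unknown biotypes trigger a warning, not an error).
    """
    biotype = gene_meta["biotype"]
    length = gene_meta["length"]
    known = set(LNCRNA_BIOTYPES) | {"protein_coding"}
    unknown = sorted(set(biotype.dropna().unique()) - known)
    if unknown:
        warnings.warn(f"unknown biotype(s) excluded: {unknown}", stacklevel=2)
    cls = pd.Series("excluded", index=gene_meta.index, name="rna_class")
    cls[biotype.isin(LNCRNA_BIOTYPES) & (length > 200)] = "lncRNA"
    cls[biotype == "protein_coding"] = "mRNA"
    return cls


@dataclass
class DEResult:
    """Per-gene two-group differential-expression table.

    ``table`` columns: log2fc, p, fdr, direction (up / down / ns).
    """

    table: pd.DataFrame
    group_a: list
    group_b: list
    method: str
    lfc_cut: float
    fdr_cut: float

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]


def differential_expression(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.01,
    method: str = "mannwhitney",
) -> DEResult:
    """Two-group DE on log2TPM with Benjamini–Hochberg correction.

    log2FC = mean(group A) - mean(group B) in log2TPM space.  The default
    test is a two-sided Mann–Whitney U; ``method="ttest"`` substitutes
    Welch's t.  Direction is "up"/"down" only when both |log2FC| > lfc_cut
    and FDR < fdr_cut hold, else "ns".
    """
    if matrix.unit != "log2TPM":
        raise ValueError(f"expected log2TPM input, got {matrix.unit}")
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples")

    a = matrix.values[group_a].to_numpy(float)
    b = matrix.values[group_b].to_numpy(float)
    log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", nan_policy="omit")
        p = np.asarray(res.pvalue, float)
    elif method == "ttest":
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, float)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    direction = np.where(
        (np.abs(log2fc) > lfc_cut) & (fdr < fdr_cut),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "direction": direction},
        index=matrix.genes,
    )
    return DEResult(table, group_a, group_b, method, lfc_cut, fdr_cut)
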