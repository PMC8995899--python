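"""Expression-matrix container with an explicit unit space.

Bulk RNA-seq abundance passes through three unit spaces in this pipeline:
FPKM (as deposited), TPM (per-sample renormalized, columns sum to 1e6) and
log2TPM (log2(x+1) of TPM).  Keeping the unit on the container lets every
stage assert the space it needs instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("FPKM", "TPM", "log2TPM")

TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus gene/sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    unit
        One of ``"FPKM"``, ``"TPM"``, ``"log2TPM"``.
    gene_meta
        Optional per-gene table (index = gene id); the preprocessing stage
        expects ``biotype`` and ``length`` columns when classifying lncRNAs.
    sample_meta
        Optional per-sample table (index = sample id), e.g. ``group``
        (tumor / adjacent) and ``cin_stratum`` labels.
    """

    values: pd.DataFrame
    unit: str
    gene_meta: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if self.unit in ("FPKM", "TPM"):
            vals = self.values.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"negative values are not allowed in {self.unit} space")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        meta = None if self.sample_meta is None else self.sample_meta.loc[sample_ids]
        return ExpressionMatrix(self.values.loc[:, sample_ids], self.unit, self.gene_meta, meta)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gmeta = None if self.gene_meta is None else self.gene_meta.loc[gene_ids]
        return ExpressionMatrix(self.values.loc[gene_ids], self.unit, gmeta, self.sample_meta)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        unit: str,
        gene_meta: pd.DataFrame | None = None,
        sample_meta: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values, unit, gene_meta, sample_meta)
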