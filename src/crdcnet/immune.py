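"""Closed-form immune quantities: cytolytic activity, mutation burden, purity.

All three are pure per-sample functions.  Heavier immune deconvolution
(ESTIMATE, TIMER, TIDE, IPS, SubMap) is deliberately out of scope; the
purity transform consumes an externally computed ESTIMATE score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def cyt(gzma_tpm, prf1_tpm):
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM.

    Zero expression of either gene yields 0 (limit convention); negative
    input is an error.
    """
    g = np.asarray(gzma_tpm, float)
    p = np.asarray(prf1_tpm, float)
    if np.any(g < 0) or np.any(p < 0):
        raise ValueError("TPM values must be non-negative")
    out = np.sqrt(g * p)
    return float(out) if out.ndim == 0 else out


def tmb(nonsyn_count, total_cds):
    """Tumor mutation burden: non-synonymous CDS mutations / total CDS * 1e6."""
    n = np.asarray(nonsyn_count, float)
    d = np.asarray(total_cds, float)
    if np.any(d <= 0):
        raise ValueError("total_cds must be positive")
    out = n / d * 1e6
    return float(out) if out.ndim == 0 else out

# coefficients of the published ESTIMATE-score-to-purity cosine transform
_PURITY_A = 0.6049872018
_PURITY_B = 0.0001467884


def tumor_purity(estimate_score):
    """Tumor purity: cos(0.6049872018 + 0.0001467884 * ESTIMATE score)."""
    s = np.asarray(estimate_score, float)
    out = np.cos(_PURITY_A + _PURITY_B * s)
    return float(out) if out.ndim == 0 else out


def immune_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply all three metrics to a per-sample table.

    Expects columns gzma, prf1, nonsyn, total_cds, estimate_score; returns
    a table with cyt, tmb, purity indexed like the input.
    """
    return pd.DataFrame(
        {
            "cyt": cyt(table["gzma"], table["prf1"]),
            "tmb": tmb(table["nonsyn"], table["total_cds"]),
            "purity": tumor_purity(table["estimate_score"]),
        },
        index=table.index,
    )
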