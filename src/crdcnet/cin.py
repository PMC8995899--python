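"""Chromosomal-instability scoring and StepMiner dichotomization.

The CIN score of a sample is the plain sum of the TPM values of a CIN
signature gene set (CIN70 in real data); higher means more chromosomal
instability.  Any numeric score vector is dichotomized by the StepMiner
criterion: sort ascending, fit a one-step function at every interior
split, and take the split maximizing the signal-to-noise ratio

    SNR(t) = sum_i (fit_i - mu)^2 / sum_i (fit_i - x_i)^2,

where fit_i = mu1 for i <= t and mu2 for i > t (group means) and mu is
the grand mean.  The sorted value at position t is the threshold; samples
with score <= threshold are labeled Low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


@dataclass
class ScoreVector:
    scores: pd.Series
    score_name: str
    gene_set_used: list[str]


def cin_score(matrix: ExpressionMatrix, signature, score_name: str = "CIN") -> ScoreVector:
    """Per-sample sum of TPM over the signature genes present in the matrix."""
    if matrix.unit != "TPM":
        raise ValueError(f"CIN score is defined on TPM values, got {matrix.unit}")
    signature = list(signature)
    present = [g for g in signature if g in matrix.genes]
    missing = sorted(set(signature) - set(present))
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    if missing:
        logger.warning("cin_score: %d/%d signature genes absent from matrix",
                       len(missing), len(signature))
    scores = matrix.values.loc[present].sum(axis=0)
    scores.name = score_name
    return ScoreVector(scores, score_name, present)


@dataclass
class StepMinerSplit:
    threshold: float
    split_index: int  # t, 1-based count of samples in the Low group
    snr: float  # np.inf for a perfect step fit
    labels: pd.Series  # per-sample {"High", "Low"}


def _stepminer_snr(sorted_values: np.ndarray) -> np.ndarray:
    """SNR at every interior split t = 1..n-1 of an ascending vector."""
    x = sorted_values
    n = x.size
    t = np.arange(1, n)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    mu = total / n
    mu1 = csum[:-1] / t
    mu2 = (total - csum[:-1]) / (n - t)
    # numerator: between-step variation around the grand mean
    num = t * (mu1 - mu) ** 2 + (n - t) * (mu2 - mu) ** 2
    # denominator: residual sum of squares of the step fit
    den = (csq[:-1] - t * mu1**2) + (total_sq - csq[:-1] - (n - t) * mu2**2)
    den = np.maximum(den, 0.0)  # guard tiny negative round-off
    with np.errstate(divide="ignore"):
        snr = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return snr


def stepminer_split(values, index=None) -> StepMinerSplit:
    """Dichotomize a score vector at the SNR-maximizing sorted split.

    Both groups must be non-empty (t in [1, n-1]).  A perfect step fit has
    zero residual and is scored +inf; ties — including ties among perfect
    fits — resolve to the smallest t, making the result deterministic.
    Samples with score exactly equal to the threshold are labeled Low.
    """
    if isinstance(values, pd.Series):
        index = values.index
        arr = values.to_numpy(float)
    else:
        arr = np.asarray(values, float)
        if index is None:
            index = pd.RangeIndex(arr.size)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values to split")
    if np.ptp(arr) == 0:
        raise ValueError("all values are equal; no split exists")
    order = np.argsort(arr, kind="stable")
    x = arr[order]
    snr = _stepminer_snr(x)
    t = int(np.argmax(snr)) + 1  # argmax returns first max -> smallest t
    threshold = float(x[t - 1])
    labels = pd.Series(np.where(arr <= threshold, "Low", "High"), index=index, name="label")
    return StepMinerSplit(threshold, t, float(snr[t - 1]), labels)
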