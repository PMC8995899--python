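"""Survival plumbing and the CRDC risk model.

Univariate and multivariate Cox proportional-hazards fits (internal Newton
solver, Efron ties), Kaplan–Meier / log-rank comparison (lifelines), ROC
AUC, and the risk score: for a gene signature, each gene's univariate Cox
log hazard ratio becomes its coefficient and the per-sample score is

    risk(s) = sum_i expression_i(s) * log(HR_i),

computed on log2TPM by default.  Model training follows the
disease-specific-survival endpoint restricted to samples without
postoperative treatment, so treatment does not confound the coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

from ._cox import CoxConvergenceError, CoxData, CoxFit
from .cin import ScoreVector
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ("time", "event")


def check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (index = sample, columns time/event/...)."""
    for col in SURVIVAL_COLUMNS:
        if col not in survival.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
    if (survival["time"] <= 0).any():
        bad = survival.index[survival["time"] <= 0][:5].tolist()
        raise ValueError(f"non-positive survival times, e.g. {bad}")
    return survival


def training_subset(survival: pd.DataFrame) -> pd.DataFrame:
    """Samples without postoperative treatment (coefficient-training subset)."""
    if "treatment" in survival.columns:
        return survival.loc[~survival["treatment"].astype(bool)]
    return survival


def fit_univariate_cox(values: pd.Series, survival: pd.DataFrame) -> CoxFit:
    """Univariate Cox PH of survival on a single per-sample covariate."""
    survival = check_survival(survival)
    common = survival.index.intersection(values.index)
    sub = survival.loc[common]
    if int(sub["event"].sum()) < 10:
        logger.warning("fit_univariate_cox: only %d events", int(sub["event"].sum()))
    x = values.loc[common].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError("constant expression vector")
    return CoxData(sub["time"], sub["event"]).fit(x)


def multivariate_cox(covariates: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Joint Cox PH fit; returns a per-covariate table (HR, CI, p).

    Raises ``ValueError`` naming a collinear pair if the design is rank
    deficient.
    """
    survival = check_survival(survival)
    common = survival.index.intersection(covariates.index)
    sub = survival.loc[common]
    X = covariates.loc[common].to_numpy(float)
    n_cov = X.shape[1]
    if sub["event"].sum() < 10 * n_cov:
        logger.warning("multivariate_cox: %d events for %d covariates",
                       int(sub["event"].sum()), n_cov)
    if np.linalg.matrix_rank(np.corrcoef(X, rowvar=False).reshape(n_cov, n_cov)) < n_cov:
        corr = np.corrcoef(X, rowvar=False)
        i, j = np.unravel_index(
            np.argmax(np.abs(np.triu(corr, 1))), corr.shape
        )
        raise ValueError(
            f"collinear covariates: {covariates.columns[i]!r} and {covariates.columns[j]!r}"
        )
    fit = CoxData(sub["time"], sub["event"]).fit(X)
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "beta": fit.beta,
            "hr": fit.hr,
            "se": fit.se,
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": fit.p,
        },
        index=covariates.columns,
    )


def module_cox_p(
    expression: pd.DataFrame, survival: pd.DataFrame, statistic: str = "lr"
) -> float:
    """Significance of a multivariate Cox fit over a gene set's expression.

    ``statistic="lr"`` (default) is the likelihood-ratio test of the full
    model against the null; ``"wald"`` takes the smallest per-gene Wald p.
    """
    survival = check_survival(survival)
    common = survival.index.intersection(expression.index)
    data = CoxData(survival.loc[common, "time"], survival.loc[common, "event"])
    fit = data.fit(expression.loc[common].to_numpy(float))
    if statistic == "lr":
        return fit.lr_p
    if statistic == "wald":
        return float(fit.p.min())
    raise ValueError(f"unknown statistic {statistic!r}")


def km_logrank(labels: pd.Series, survival: pd.DataFrame):
    """Two-group log-rank test plus per-group Kaplan–Meier curves.

    Returns ``(chi2, p, curves)`` where ``curves`` maps group label to its
    KM survival-function DataFrame.
    """
    survival = check_survival(survival)
    common = survival.index.intersection(labels.index)
    labels = labels.loc[common]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    sub = survival.loc[common]
    masks = {g: labels == g for g in groups}
    for g, m in masks.items():
        if sub.loc[m, "event"].sum() == 0:
            logger.warning("km_logrank: group %r has no events", g)
    g1, g2 = groups
    res = logrank_test(
        sub.loc[masks[g1], "time"], sub.loc[masks[g2], "time"],
        event_observed_A=sub.loc[masks[g1], "event"],
        event_observed_B=sub.loc[masks[g2], "event"],
    )
    curves = {}
    for g, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub.loc[m, "time"], sub.loc[m, "event"], label=str(g))
        curves[g] = kmf.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


def roc_auc(scores: pd.Series, labels: pd.Series) -> float:
    """ROC AUC of a score against binary labels (Mann–Whitney; ties = 1/2)."""
    common = labels.index.intersection(scores.index)
    y = np.asarray(labels.loc[common])
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(y, scores.loc[common].to_numpy(float)))


@dataclass
class RiskModel:
    """A gene signature with per-gene log(HR) coefficients.

    ``table`` rows are the signature genes; columns: beta (natural-log HR),
    hr, p, ci_low, ci_high.
    """

    table: pd.DataFrame
    endpoint: str = "DSS"
    subset_rule: str = "treatment == False"
    dropped: list = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def coefficients(self) -> pd.Series:
        return self.table["beta"]


def fit_risk_model(
    matrix: ExpressionMatrix, genes, survival: pd.DataFrame, endpoint: str = "DSS"
) -> RiskModel:
    """Fit one univariate Cox model per signature gene on the training subset.

    Genes whose fit fails to converge are dropped with a warning rather
    than imputed.
    """
    if matrix.unit != "log2TPM":
        raise ValueError(f"risk model is trained on log2TPM, got {matrix.unit}")
    train = training_subset(check_survival(survival))
    rows, dropped = {}, []
    for g in genes:
        if g not in matrix.genes:
            raise KeyError(f"model gene {g!r} absent from expression matrix")
        try:
            fit = fit_univariate_cox(matrix.values.loc[g, train.index], train)
        except (CoxConvergenceError, ValueError) as exc:
            logger.warning("risk model: dropping gene %s (%s)", g, exc)
            dropped.append(g)
            continue
        ci = fit.conf_int()[0]
        rows[g] = {
            "beta": fit.beta[0], "hr": fit.hr[0], "p": fit.p[0],
            "ci_low": float(np.exp(ci[0])), "ci_high": float(np.exp(ci[1])),
        }
    if not rows:
        raise ValueError("no signature gene produced a converged Cox fit")
    return RiskModel(pd.DataFrame.from_dict(rows, orient="index"),
                     endpoint=endpoint, dropped=dropped)


def crdc_score(matrix: ExpressionMatrix, model: RiskModel,
               score_name: str = "CRDC") -> ScoreVector:
    """Per-sample risk score: sum_i expression_i * log(HR_i)."""
    missing = [g for g in model.genes if g not in matrix.genes]
    if missing:
        raise KeyError(f"model gene(s) absent from matrix: {missing}")
    expr = matrix.values.loc[model.genes]
    scores = expr.T @ model.coefficients
    scores.name = score_name
    return ScoreVector(scores, score_name, model.genes)
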