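"""Vectorized Cox proportional-hazards solver (Efron tie handling).

Newton–Raphson maximization of the Cox partial likelihood.  The survival
layout (sort order, tie groups, Efron correction terms) is precomputed once
per dataset in :class:`CoxData`, so repeated fits against the same survival
— the permutation module filter performs thousands of them — cost only the
per-iteration linear algebra, a few tens of microseconds at cohort sizes of
a few hundred.

Validated in the test suite against lifelines (tied and untied data) and
against a brute-force partial-likelihood grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CoxConvergenceError(RuntimeError):
    """Raised when Newton iteration fails to converge (e.g. separation)."""


@dataclass
class CoxFit:
    beta: np.ndarray          # log hazard ratios, one per covariate
    se: np.ndarray            # Wald standard errors
    cov: np.ndarray           # covariance of beta
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        """Two-sided Wald p-value per covariate."""
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def lr_stat(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lr_p(self) -> float:
        """Likelihood-ratio p-value of the full model against the null."""
        return float(stats.chi2.sf(max(self.lr_stat, 0.0), df=len(self.beta)))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(lower, upper) CI for each log hazard ratio."""
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.beta - zq * self.se, self.beta + zq * self.se])


class CoxData:
    """Survival times/events with the Efron bookkeeping precomputed.

    Samples are sorted by ascending time; tied times share one risk set.
    Each event contributes one Efron term with fraction l/d for l = 0..d-1
    within its tie group of d events.
    """

    def __init__(self, time, event):
        time = np.asarray(time, float)
        event = np.asarray(event, bool)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D and the same length")
        if np.any(time <= 0):
            raise ValueError("survival times must be positive")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        t_sorted = time[self.order]
        self.event_sorted = event[self.order]
        self.n_events = int(event.sum())
        if self.n_events == 0:
            raise ValueError("no events; partial likelihood is undefined")

        # first index of each tie block, per sample
        new_block = np.r_[True, t_sorted[1:] != t_sorted[:-1]]
        block_id = np.cumsum(new_block) - 1
        block_first = np.flatnonzero(new_block)
        self.risk_start = block_first[block_id]  # per-sample risk-set start

        ev_idx = np.flatnonzero(self.event_sorted)
        ev_block = block_id[ev_idx]
        # d_j: events per tie block, gathered back onto each event
        d_per_block = np.bincount(ev_block, minlength=block_id[-1] + 1)
        d = d_per_block[ev_block]
        # Efron fraction l/d within each block, in block order
        l = np.arange(ev_idx.size) - np.searchsorted(ev_idx, block_first[ev_block])
        self.ev_idx = ev_idx
        self.ev_group = ev_block                      # tie-block id per event term
        self.ev_frac = l / d                          # l/d per event term
        self.ev_risk_start = self.risk_start[ev_idx]  # risk-set start per event term
        self.n_blocks = int(block_id[-1] + 1)

    def fit(self, X, max_iter: int = 60, tol: float = 1e-9) -> CoxFit:
        """Fit beta for covariate matrix X (n x p), original sample order."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("covariate rows must match the number of samples")
        p = X.shape[1]
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant covariate column(s): "
                             f"{np.flatnonzero(sd == 0).tolist()}")
        # center+scale for conditioning; Cox is invariant to centering
        Xs = (X[self.order] - X[self.order].mean(axis=0)) / sd

        beta = np.zeros(p)
        ll = self._loglik_grad_hess(Xs, beta)
        ll_null = ll[0]
        converged = False
        for _ in range(max_iter):
            loglik, grad, info = ll
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise CoxConvergenceError("singular information matrix") from exc
            # step-halving line search
            new_beta = beta + step
            new_ll = self._loglik_grad_hess(Xs, new_beta)
            halves = 0
            while new_ll[0] < loglik - 1e-12 and halves < 20:
                step *= 0.5
                new_beta = beta + step
                new_ll = self._loglik_grad_hess(Xs, new_beta)
                halves += 1
            beta, ll = new_beta, new_ll
            if np.max(np.abs(ll[1])) < tol * max(1.0, abs(ll[0])) or np.max(np.abs(step)) < 1e-10:
                converged = True
                break
        loglik, grad, info = ll
        try:
            cov_s = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix at optimum") from exc
        # undo scaling
        beta_out = beta / sd
        cov = cov_s / np.outer(sd, sd)
        se = np.sqrt(np.diag(cov))
        if not converged or not np.all(np.isfinite(beta_out)):
            raise CoxConvergenceError("Newton iteration did not converge")
        return CoxFit(beta_out, se, cov, float(loglik), float(ll_null),
                      self.n, self.n_events, converged)

    def _loglik_grad_hess(self, Xs: np.ndarray, beta: np.ndarray):
        n, p = Xs.shape
        eta = Xs @ beta
        eta -= eta.max()  # overflow guard; cancels in the ratios
        w = np.exp(eta)
        wx = w[:, None] * Xs
        wxx = wx[:, :, None] * Xs[:, None, :]
        # suffix cumulative sums: risk-set aggregates for each start index
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        ei, eg, ef, ers = self.ev_idx, self.ev_group, self.ev_frac, self.ev_risk_start
        # tie-block event aggregates (for the Efron correction)
        D0 = np.bincount(eg, weights=w[ei], minlength=self.n_blocks)
        D1 = np.zeros((self.n_blocks, p))
        D2 = np.zeros((self.n_blocks, p, p))
        np.add.at(D1, eg, wx[ei])
        np.add.at(D2, eg, wxx[ei])

        R0 = S0[ers] - ef * D0[eg]
        R1 = S1[ers] - ef[:, None] * D1[eg]
        R2 = S2[ers] - ef[:, None, None] * D2[eg]

        loglik = float(eta[ei].sum() - np.log(R0).sum())
        mean1 = R1 / R0[:, None]
        grad = Xs[ei].sum(axis=0) - mean1.sum(axis=0)
        info = (R2 / R0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mean1, mean1)
        return loglik, grad, info


def cox_fit(X, time, event, **kwargs) -> CoxFit:
    """One-shot Cox fit; see :class:`CoxData` for repeated fits."""
    return CoxData(time, event).fit(X, **kwargs)
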