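"""Cluster-robust regression models used by the reduced-form stages.

Two model families cover every association in the analysis:

* :class:`ClusterLogit` — maximum-likelihood logistic regression whose
  standard errors come from a cluster sandwich, so that the 22-study
  consortium structure (within-study correlation) does not understate
  uncertainty.
* :class:`LeftTruncatedCox` — Cox proportional-hazards regression on the
  age scale with delayed entry (subjects enter the risk set at their
  diagnosis age), Breslow tie handling, and the same cluster sandwich.

The sandwich is V = A^{-1} (sum_g s_g s_g') A^{-1}, with A the observed
information, s_g the score summed over cluster g, scaled by the
small-sample factor G/(G-1) * (N-1)/(N-k) (the convention of the major
survey-statistics packages; switchable off).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .types import EffectEstimate, MrscoreError, Z95


class ConvergenceError(MrscoreError):
    pass


class SeparationError(MrscoreError):
    pass


def _cluster_sums(scores: np.ndarray, groups: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Sum score rows within clusters; no groups means one cluster per row."""
    if groups is None:
        return scores, scores.shape[0]
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    out = np.zeros((g, scores.shape[1]))
    np.add.at(out, codes, scores)
    return out, g


def _correction(n: int, k: int, g: int, small_sample: bool) -> float:
    if not small_sample:
        return 1.0
    if g <= 1 or n <= k:
        return 1.0
    return (g / (g - 1)) * ((n - 1) / (n - k))


class _ResultsMixin:
    """Shared result-table machinery (params/bse/p/CI/summary).

    Clustered fits use a Student-t reference with G-1 degrees of freedom
    (``crit_dof``); unclustered fits use the normal reference. The t
    reference keeps Wald tests calibrated when the number of clusters is
    small, where the sandwich variance is itself noisy.
    """

    crit_dof: int | None = None

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        if self.crit_dof is not None:
            from scipy.stats import t as t_dist

            return 2.0 * t_dist.sf(np.abs(self.zvalues), self.crit_dof)
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def _crit(self) -> float:
        if self.crit_dof is not None:
            from scipy.stats import t as t_dist

            return float(t_dist.ppf(0.975, self.crit_dof))
        return Z95

    def conf_int(self) -> np.ndarray:
        lo = self.params - self._crit * self.bse
        hi = self.params + self._crit * self.bse
        return np.column_stack([lo, hi])

    def effect_estimate(self, name: str, label: str = "") -> EffectEstimate:
        """Exponentiated effect (OR/HR) for one named coefficient."""
        j = self.exog_names.index(name)
        return EffectEstimate.from_log(
            self.params[j],
            self.bse[j],
            n=self.nobs,
            n_events=getattr(self, "n_events", None),
            label=label or name,
            dof=self.crit_dof,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"{type(self).__name__}: n={self.nobs}"
            + (f", events={self.n_events}" if getattr(self, "n_events", None) is not None else "")
            + (f", clusters={self.ngroups}" if self.ngroups else ""),
            f"{'':<14}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<14}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.zvalues[i]:>8.2f}{self.pvalues[i]:>10.3g}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
            )
        return "\n".join(lines)


class ClusterLogitResults(_ResultsMixin):
    def __init__(self, params, bse, cov, exog_names, nobs, ngroups, llf):
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.cov_params = cov
        self.exog_names = list(exog_names)
        self.nobs = int(nobs)
        self.ngroups = ngroups
        self.llf = llf
        self.crit_dof = (ngroups - 1) if ngroups is not None and ngroups > 1 else None


class ClusterLogit:
    """Logistic regression with cluster-robust (sandwich) standard errors.

    Parameters
    ----------
    endog : binary outcome (0/1)
    exog : covariate matrix, without intercept (one is added by default)
    groups : cluster labels (e.g. study id); ``None`` treats every
        observation as its own cluster (heteroskedasticity-robust SEs)
    """

    def __init__(
        self,
        endog,
        exog,
        groups=None,
        exog_names: Sequence[str] | None = None,
        add_intercept: bool = True,
    ):
        y = np.asarray(endog, dtype=float).reshape(-1)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not set(np.unique(y)).issubset({0.0, 1.0}):
            raise MrscoreError("outcome must be binary 0/1")
        names = list(exog_names) if exog_names else [f"x{i+1}" for i in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["const"] + names
        if len(names) != X.shape[1]:
            raise MrscoreError("exog_names length mismatch")
        self.endog, self.exog, self.exog_names = y, X, names
        self.groups = None if groups is None else np.asarray(groups)

    def fit(
        self, maxiter: int = 50, tol: float = 1e-8, small_sample: bool = True
    ) -> ClusterLogitResults:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        y, X = self.endog, self.exog
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                mle = sm.Logit(y, X).fit(
                    method="newton", maxiter=maxiter, tol=tol, disp=0, warn_convergence=False
                )
        except PerfectSeparationError as exc:
            raise SeparationError(
                f"perfect separation fitting outcome on {self.exog_names[1:]}"
            ) from exc
        except Exception as exc:  # singular hessian etc. under diverging params
            raise SeparationError(
                f"logistic fit failed (separation or collinearity) on {self.exog_names[1:]}: {exc}"
            ) from exc
        if not mle.mle_retvals.get("converged", False):
            raise ConvergenceError(f"no convergence in {maxiter} Newton iterations")
        b = np.asarray(mle.params)
        if np.max(np.abs(b)) > 30:
            raise SeparationError(
                f"diverging coefficients (|b|>30) fitting outcome on {self.exog_names[1:]}"
            )
        p = expit(X @ b)
        W = p * (1 - p)
        A = X.T @ (X * W[:, None])
        scores = X * (y - p)[:, None]
        s_g, g = _cluster_sums(scores, self.groups)
        B = s_g.T @ s_g
        Ainv = np.linalg.inv(A)
        c = _correction(len(y), X.shape[1], g, small_sample)
        V = c * (Ainv @ B @ Ainv)
        return ClusterLogitResults(
            b, np.sqrt(np.diag(V)), V, self.exog_names, len(y),
            g if self.groups is not None else None, float(mle.llf),
        )


class ClusterOLSResults(_ResultsMixin):
    def __init__(self, params, bse, cov, exog_names, nobs, ngroups):
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.cov_params = cov
        self.exog_names = list(exog_names)
        self.nobs = int(nobs)
        self.ngroups = ngroups
        self.crit_dof = (ngroups - 1) if ngroups is not None and ngroups > 1 else None


class ClusterOLS:
    """Linear regression with the same cluster sandwich as ClusterLogit."""

    def __init__(self, endog, exog, groups=None, exog_names=None, add_intercept=True):
        y = np.asarray(endog, dtype=float).reshape(-1)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(exog_names) if exog_names else [f"x{i+1}" for i in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["const"] + names
        self.endog, self.exog, self.exog_names = y, X, names
        self.groups = None if groups is None else np.asarray(groups)

    def fit(self, small_sample: bool = True) -> ClusterOLSResults:
        y, X = self.endog, self.exog
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ b
        A = X.T @ X
        scores = X * resid[:, None]
        s_g, g = _cluster_sums(scores, self.groups)
        Ainv = np.linalg.inv(A)
        c = _correction(len(y), X.shape[1], g, small_sample)
        V = c * (Ainv @ (s_g.T @ s_g) @ Ainv)
        return ClusterOLSResults(
            b, np.sqrt(np.diag(V)), V, self.exog_names, len(y),
            g if self.groups is not None else None,
        )


class CoxResults(_ResultsMixin):
    def __init__(
        self, params, bse, cov, exog_names, nobs, n_events, ngroups, llf,
        schoenfeld, event_times, information, n_excluded=0,
    ):
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.cov_params = cov
        self.exog_names = list(exog_names)
        self.nobs = int(nobs)
        self.n_events = int(n_events)
        self.ngroups = ngroups
        self.llf = llf
        self.crit_dof = (ngroups - 1) if ngroups is not None and ngroups > 1 else None
        self.schoenfeld = schoenfeld        # (d, p) residuals, one row per event
        self.event_times = event_times      # (d,) exit times of the events
        self.information = information      # observed information at the MLE
        self.n_excluded = n_excluded        # subjects dropped for missing ages


class LeftTruncatedCox:
    """Cox PH regression with delayed entry, Breslow ties, cluster sandwich.

    The time axis is age: a subject is at risk at age t when
    ``entry < t <= exit``, so nobody contributes before their diagnosis
    age (left truncation) and events are compared only with subjects old
    enough to have been under observation.
    """

    def __init__(self, entry, exit, event, exog, groups=None, exog_names=None):
        entry = np.asarray(entry, dtype=float)
        exit_ = np.asarray(exit, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.isnan(entry).any() or np.isnan(exit_).any():
            raise MrscoreError("entry/exit contain missing values; filter first")
        if np.any(exit_ <= entry):
            raise MrscoreError("every subject needs entry < exit")
        if event.sum() < 1:
            raise MrscoreError("no events")
        self.entry, self.exit, self.event, self.exog = entry, exit_, event, X
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i+1}" for i in range(X.shape[1])
        ]
        self.groups = None if groups is None else np.asarray(groups)

    # -- Breslow partial likelihood via a descending sweep over event times
    def _sweep(self, beta: np.ndarray):
        X, entry, exit_, event = self.exog, self.entry, self.exit, self.event
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; Breslow terms are ratio-invariant
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = np.einsum("i,ij,ik->ijk", w, X, X)

        times = np.unique(self.exit[event == 1])[::-1]  # descending
        exit_order = np.argsort(exit_)[::-1]
        entry_order = np.argsort(entry)[::-1]
        add_ptr = rem_ptr = 0
        S0 = 0.0
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        loglik = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        # per-event-time records for residuals (ascending order at the end)
        rec_d, rec_S0, rec_xbar = [], [], []
        for t in times:
            while add_ptr < n and exit_[exit_order[add_ptr]] >= t:
                i = exit_order[add_ptr]
                S0 += w[i]; S1 += wX[i]; S2 += wXX[i]
                add_ptr += 1
            while rem_ptr < n and entry[entry_order[rem_ptr]] >= t:
                i = entry_order[rem_ptr]
                S0 -= w[i]; S1 -= wX[i]; S2 -= wXX[i]
                rem_ptr += 1
            if S0 <= 0:
                raise MrscoreError("empty risk set at an event time")
            d_idx = np.where((exit_ == t) & (event == 1))[0]
            d_k = len(d_idx)
            xbar = S1 / S0
            loglik += eta[d_idx].sum() - d_k * np.log(S0)
            grad += X[d_idx].sum(axis=0) - d_k * xbar
            hess -= d_k * (S2 / S0 - np.outer(xbar, xbar))
            rec_d.append(d_k); rec_S0.append(S0); rec_xbar.append(xbar.copy())
        # ascending order for downstream prefix sums
        asc = slice(None, None, -1)
        return (
            loglik, grad, hess,
            times[asc],
            np.array(rec_d)[asc],
            np.array(rec_S0)[asc],
            np.array(rec_xbar)[asc],
        )

    def fit(
        self, maxiter: int = 50, tol: float = 1e-8, small_sample: bool = True
    ) -> CoxResults:
        X = self.exog
        n, p = X.shape
        beta = np.zeros(p)
        loglik, grad, hess, *_ = self._sweep(beta)
        for _ in range(maxiter):
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as exc:
                raise SeparationError("singular information matrix in Cox fit") from exc
            # step-halving to keep the partial likelihood increasing
            for _ in range(30):
                cand = beta + step
                ll_new, g_new, h_new, *_ = self._sweep(cand)
                if ll_new >= loglik - 1e-12:
                    break
                step = step / 2.0
            beta, loglik, grad, hess = cand, ll_new, g_new, h_new
            if np.max(np.abs(beta)) > 50:
                raise SeparationError("diverging hazard coefficients (separation-like)")
        else:
            raise ConvergenceError(f"Cox fit did not converge in {maxiter} iterations")

        loglik, grad, hess, times, d_k, S0_k, xbar_k = self._sweep(beta)
        info = -hess
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix at the Cox MLE") from exc

        # score residuals: U_i = delta_i (x_i - xbar(T_i))
        #   - w_i * sum_{t_k in (entry_i, exit_i]} (d_k / S0_k) (x_i - xbar_k)
        eta = X @ beta
        eta = eta - eta.max()
        w = np.exp(eta)
        C0 = np.concatenate([[0.0], np.cumsum(d_k / S0_k)])
        C1 = np.vstack([np.zeros(p), np.cumsum((d_k / S0_k)[:, None] * xbar_k, axis=0)])
        hi = np.searchsorted(times, self.exit, side="right")
        lo = np.searchsorted(times, self.entry, side="right")
        c0 = C0[hi] - C0[lo]
        c1 = C1[hi] - C1[lo]
        U = -w[:, None] * (X * c0[:, None] - c1)
        ev = self.event == 1
        pos = np.searchsorted(times, self.exit[ev])
        U[ev] += X[ev] - xbar_k[pos]

        s_g, g = _cluster_sums(U, self.groups)
        c = _correction(n, p, g, small_sample)
        V = c * (info_inv @ (s_g.T @ s_g) @ info_inv)

        # Schoenfeld residuals (one per event, in event-time order)
        order = np.argsort(self.exit[ev], kind="stable")
        ev_idx = np.where(ev)[0][order]
        sch = X[ev_idx] - xbar_k[np.searchsorted(times, self.exit[ev_idx])]
        return CoxResults(
            beta, np.sqrt(np.diag(V)), V, self.exog_names, n, int(ev.sum()),
            g if self.groups is not None else None, float(loglik),
            sch, self.exit[ev_idx], info,
        )


def ph_check(results: CoxResults, transform: str = "rank") -> dict:
    """Grambsch–Therneau test of the proportional-hazards assumption.

    Associates the Schoenfeld residuals with (a transform of) event time;
    under proportional hazards the association is null. Returns per-covariate
    chi-square p-values and a global p.
    """
    r = results.schoenfeld
    d, p = r.shape
    if d < 2:
        raise MrscoreError("need at least 2 events for the PH check")
    if transform == "rank":
        g = np.argsort(np.argsort(results.event_times)).astype(float)
    elif transform == "time":
        g = results.event_times.astype(float)
    else:
        raise MrscoreError(f"unknown transform {transform!r}")
    q = g - g.mean()
    M = q @ r                       # (p,)
    vbar = results.information / d  # average per-event information
    denom = float(np.sum(q**2))
    try:
        stat_global = float(M @ np.linalg.solve(vbar * denom, M))
    except np.linalg.LinAlgError as exc:
        raise MrscoreError("singular information in PH check") from exc
    out = {
        "global_stat": stat_global,
        "global_p": float(chi2.sf(stat_global, p)),
        "covariates": {},
    }
    for j, name in enumerate(results.exog_names):
        stat = float(M[j] ** 2 / (vbar[j, j] * denom))
        out["covariates"][name] = {"stat": stat, "p": float(chi2.sf(stat, 1))}
    return out
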