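"""Proportional-hazards models for lifespan and healthspan.

Two hazard models are used throughout:

* **Mortality risk** — the standard Cox proportional-hazards model on the
  follow-up time scale, with age at assessment among the covariates.  The
  partial likelihood is maximised by Newton–Raphson with Efron's tie
  correction.

* **Morbidity risk** — a fully parametric Gompertz-baseline
  proportional-hazards model on the age scale, for disease-free survival
  (healthspan), where delayed-entry machinery is deliberately not used: the
  hazard is ``h(t) = h0 * exp(Gamma * t + x @ beta)`` and the likelihood is

      l = sum_i [ d_i (ln h0 + Gamma t_i + x_i b)
                  - (h0 / Gamma) e^{x_i b} (e^{Gamma t_i} - 1) ]

  maximised over ``(ln h0, ln Gamma, beta)`` so the positivity constraints
  are built into the parameterisation.

Both follow the statsmodels convention: a model object built from data whose
``fit()`` returns a results object carrying estimates, standard errors from
the observed information matrix, Wald confidence intervals and p-values, and
a ``summary()`` table.  Kaplan–Meier curves, the two-group log-rank test and
the Kolmogorov–Smirnov age-balance check round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "GompertzPH",
    "GompertzPHResults",
    "KMCurve",
    "LogRankResult",
    "fit_cox",
    "fit_gompertz_ph",
    "km_estimate",
    "logrank_test",
    "ks_age_balance",
    "fit_sex_stratified",
    "summary_table",
]

_GRAD_TOL = 1e-8
_MAX_ITER = 100


def _check_design(X: np.ndarray, names: list[str], augment_constant: bool) -> None:
    """Reject rank-deficient designs instead of returning arbitrary betas."""
    if X.shape[1] == 0:
        return
    M = np.column_stack([np.ones(X.shape[0]), X]) if augment_constant else X
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(
            f"design matrix with columns {names} is rank deficient "
            "(collinear or constant covariates)"
        )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------


class CoxPH:
    """Cox proportional-hazards model on right-censored data.

    Parameters
    ----------
    durations : observed times (event or censoring), strictly positive.
    events : event indicator (1 = event, 0 = censored).
    exog : covariate matrix, shape (n, p).
    names : covariate names (optional).
    """

    def __init__(self, durations, events, exog, names=None):
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=int)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.exog = X
        n, p = X.shape
        if self.durations.shape != (n,) or self.events.shape != (n,):
            raise ValueError("durations, events and exog have inconsistent shapes")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be strictly positive")
        if not set(np.unique(self.events)) <= {0, 1}:
            raise ValueError("events must be 0/1")
        if self.events.sum() == 0:
            raise ValueError("no events; the partial likelihood is flat")
        self.names = list(names) if names is not None else [f"x{i}" for i in range(p)]
        _check_design(X, self.names, augment_constant=True)
        # events-only covariate variation check: a covariate constant among
        # everyone cannot be estimated (caught by rank check above when a
        # constant column is present).
        order = np.argsort(self.durations, kind="stable")
        self._t = self.durations[order]
        self._d = self.events[order]
        self._X = X[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str, event_col: str,
                       covariate_cols: list[str]) -> "CoxPH":
        return cls(
            df[duration_col].to_numpy(),
            df[event_col].to_numpy(),
            df[list(covariate_cols)].to_numpy(dtype=float),
            names=list(covariate_cols),
        )

    # -- Efron partial likelihood ------------------------------------------

    def _loglik_grad_hess(self, beta: np.ndarray):
        t, d, X = self._t, self._d, self._X
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # stabilise exp; partial likelihood is invariant
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = np.einsum("i,ij,ik->ijk", w, X, X)
        # reverse cumulative sums: risk set at sorted index i is {j >= i}
        rw = np.cumsum(w[::-1])[::-1]
        rwx = np.cumsum(wx[::-1], axis=0)[::-1]
        rwxx = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and t[j] == t[i]:
                j += 1
            ev = np.arange(i, j)[d[i:j] == 1]
            k = ev.size
            if k:
                s_x = X[ev].sum(axis=0)
                S_D = w[ev].sum()
                S_Dx = wx[ev].sum(axis=0)
                S_Dxx = wxx[ev].sum(axis=0)
                ll += eta[ev].sum() + eta.max() * 0  # eta already shifted; ok
                for l in range(k):
                    f = l / k
                    phi = rw[i] - f * S_D
                    zx = rwx[i] - f * S_Dx
                    zxx = rwxx[i] - f * S_Dxx
                    ll -= np.log(phi)
                    grad -= zx / phi
                    hess -= zxx / phi - np.outer(zx, zx) / phi**2
                grad += s_x
            i = j
        return ll, grad, hess

    def loglik(self, beta) -> float:
        return self._loglik_grad_hess(np.asarray(beta, dtype=float))[0]

    def fit(self) -> "CoxPHResults":
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = self._loglik_grad_hess(beta)
        converged = False
        niter = 0
        for niter in range(1, _MAX_ITER + 1):
            if np.max(np.abs(grad)) < _GRAD_TOL:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix; possible separation")
                break
            # step-halving to guarantee ascent (tolerance scaled to the
            # log-likelihood magnitude so float noise cannot stall it)
            ascent_tol = 1e-10 * (1.0 + abs(ll))
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new, grad_new, hess_new = self._loglik_grad_hess(cand)
                if ll_new > ll - ascent_tol:
                    break
                alpha /= 2.0
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if np.max(np.abs(alpha * step)) < 1e-12:
                break
            if np.max(np.abs(beta)) > 50:
                warnings.warn(
                    "coefficients diverging: monotone partial likelihood "
                    "(perfect separation); estimates are not reliable"
                )
                break
        else:
            niter = _MAX_ITER
        if not converged and np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
        # under a monotone partial likelihood the gradient vanishes as the
        # coefficient runs away; flag implausibly large standardised effects
        scale = self._X.std(axis=0)
        if np.any(np.abs(beta) * np.where(scale > 0, scale, 1.0) > 10):
            warnings.warn(
                "extreme coefficient: monotone partial likelihood "
                "(perfect separation) suspected; estimates are not reliable"
            )
        try:
            cov = np.linalg.inv(-hess) if p else np.zeros((0, 0))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return CoxPHResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            llf=ll,
            niter=niter,
            converged=converged,
        )


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, observed-information SEs, Wald tests."""

    model: CoxPH
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    niter: int
    converged: bool

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    @property
    def nobs(self) -> int:
        return self.model.durations.size

    @property
    def nevents(self) -> int:
        return int(self.model.events.sum())

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "p": self.pvalues,
                "N": self.nobs,
                "events": self.nevents,
            }
        )


# ---------------------------------------------------------------------------
# Gompertz-baseline proportional hazards, full maximum likelihood
# ---------------------------------------------------------------------------


class GompertzPH:
    """Gompertz-baseline PH model on the age scale (no delayed entry).

    ``ages`` are ages at event or censoring; ``events`` flags observed
    events.  Covariates enter the log-hazard linearly.  Optimisation is over
    ``theta = (ln h0, ln Gamma, beta)``.
    """

    _LOG_GAMMA_FLOOR = np.log(1e-8)

    def __init__(self, ages, events, exog=None, names=None):
        self.ages = np.asarray(ages, dtype=float)
        self.events = np.asarray(events, dtype=int)
        n = self.ages.size
        if exog is None:
            exog = np.empty((n, 0))
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.exog = X
        if self.ages.shape != (n,) or self.events.shape != (n,) or X.shape[0] != n:
            raise ValueError("ages, events and exog have inconsistent shapes")
        if np.any(self.ages <= 0):
            raise ValueError("ages must be strictly positive")
        if self.events.sum() == 0:
            raise ValueError("all observations censored; h0 is not identifiable")
        p = X.shape[1]
        self.names = list(names) if names is not None else [f"x{i}" for i in range(p)]
        _check_design(X, self.names, augment_constant=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str, event_col: str,
                       covariate_cols: list[str] = ()) -> "GompertzPH":
        cols = list(covariate_cols)
        return cls(
            df[age_col].to_numpy(),
            df[event_col].to_numpy(),
            df[cols].to_numpy(dtype=float) if cols else None,
            names=cols,
        )

    def _unpack(self, theta):
        a, g = theta[0], theta[1]
        beta = np.asarray(theta[2:], dtype=float)
        return a, g, beta

    def loglik(self, theta) -> float:
        a, g, beta = self._unpack(np.asarray(theta, dtype=float))
        h0, gam = np.exp(a), np.exp(g)
        t, d, X = self.ages, self.events, self.exog
        eta = X @ beta if beta.size else np.zeros_like(t)
        cumh = (h0 / gam) * np.exp(eta) * np.expm1(gam * t)
        return float(np.sum(d * (a + gam * t + eta) - cumh))

    def score(self, theta) -> np.ndarray:
        a, g, beta = self._unpack(np.asarray(theta, dtype=float))
        h0, gam = np.exp(a), np.exp(g)
        t, d, X = self.ages, self.events, self.exog
        eta = X @ beta if beta.size else np.zeros_like(t)
        egt = np.exp(gam * t)
        cumh = (h0 / gam) * np.exp(eta) * (egt - 1.0)
        resid = d - cumh
        da = resid.sum()
        dg = np.sum(d * gam * t + cumh - h0 * np.exp(eta) * t * egt)
        grad = [da, dg]
        if beta.size:
            grad.extend(X.T @ resid)
        return np.asarray(grad)

    def _num_hess(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = theta.size
        H = np.zeros((k, k))
        for j in range(k):
            h = 1e-6 * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            H[:, j] = (self.score(tp) - self.score(tm)) / (2 * h)
        return (H + H.T) / 2.0

    def _start(self) -> np.ndarray:
        t, d = self.ages, self.events
        gam0 = 0.05
        h0 = d.sum() / np.sum(np.expm1(gam0 * t) / gam0)
        return np.concatenate([[np.log(h0), np.log(gam0)], np.zeros(self.exog.shape[1])])

    def fit(self) -> "GompertzPHResults":
        theta = self._start()
        # global polish first: bounded quasi-Newton is robust far from the
        # optimum (and when the true Gamma is at the exponential edge)
        bounds = [(-60.0, 10.0), (self._LOG_GAMMA_FLOOR, np.log(2.0))] + [
            (None, None)
        ] * self.exog.shape[1]
        res = optimize.minimize(
            lambda th: -self.loglik(th),
            theta,
            jac=lambda th: -self.score(th),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = res.x
        ll = self.loglik(theta)
        converged = False
        niter = 0
        for niter in range(1, _MAX_ITER + 1):
            grad = self.score(theta)
            if np.max(np.abs(grad)) < _GRAD_TOL:
                converged = True
                break
            H = self._num_hess(theta)
            try:
                step = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError:
                break
            ascent_tol = 1e-10 * (1.0 + abs(ll))
            alpha = 1.0
            improved = False
            for _ in range(30):
                cand = theta + alpha * step
                if cand[1] < self._LOG_GAMMA_FLOOR:
                    cand[1] = self._LOG_GAMMA_FLOOR
                ll_new = self.loglik(cand)
                if ll_new >= ll - ascent_tol:
                    improved = True
                    break
                alpha /= 2.0
            if not improved:
                break
            theta, ll = cand, ll_new
        grad = self.score(theta)
        if np.max(np.abs(grad)) < max(_GRAD_TOL, 1e-6 * (1 + abs(ll))):
            converged = True
        if not converged:
            warnings.warn("Gompertz-PH fit did not reach the gradient tolerance")
        H = self._num_hess(theta)
        try:
            cov_t = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_t = np.full((theta.size, theta.size), np.nan)
        names = ["log_h0", "log_gamma", *self.names]
        return GompertzPHResults(
            model=self,
            params_transformed=pd.Series(theta, index=names),
            cov_transformed=pd.DataFrame(cov_t, index=names, columns=names),
            llf=ll,
            niter=niter,
            converged=converged,
        )


@dataclass
class GompertzPHResults:
    """Fitted Gompertz-PH model.

    Estimates are carried on the unconstrained scale ``(ln h0, ln Gamma,
    beta)``; ``h0``/``gamma`` and their intervals are obtained by
    exponentiating, which keeps the Wald intervals inside the positive
    half-line.
    """

    model: GompertzPH
    params_transformed: pd.Series
    cov_transformed: pd.DataFrame
    llf: float
    niter: int
    converged: bool

    @property
    def h0(self) -> float:
        return float(np.exp(self.params_transformed["log_h0"]))

    @property
    def gamma(self) -> float:
        return float(np.exp(self.params_transformed["log_gamma"]))

    @property
    def params(self) -> pd.Series:
        """Covariate log-hazard coefficients."""
        return self.params_transformed.iloc[2:]

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_transformed))
        return pd.Series(se[2:], index=self.params.index)

    def gamma_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        g = self.params_transformed["log_gamma"]
        se = np.sqrt(self.cov_transformed.loc["log_gamma", "log_gamma"])
        return float(np.exp(g - z * se)), float(np.exp(g + z * se))

    def h0_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        a = self.params_transformed["log_h0"]
        se = np.sqrt(self.cov_transformed.loc["log_h0", "log_h0"])
        return float(np.exp(a - z * se)), float(np.exp(a + z * se))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    @property
    def nobs(self) -> int:
        return self.model.ages.size

    @property
    def nevents(self) -> int:
        return int(self.model.events.sum())

    def summary(self) -> pd.DataFrame:
        rows = {
            "h0": {
                "coef": self.h0,
                "ci_lower": self.h0_conf_int()[0],
                "ci_upper": self.h0_conf_int()[1],
                "p": np.nan,
            },
            "gamma": {
                "coef": self.gamma,
                "ci_lower": self.gamma_conf_int()[0],
                "ci_upper": self.gamma_conf_int()[1],
                "p": np.nan,
            },
        }
        ci = self.conf_int()
        for name in self.params.index:
            rows[name] = {
                "coef": self.params[name],
                "ci_lower": ci.loc[name, "lower"],
                "ci_upper": ci.loc[name, "upper"],
                "p": self.pvalues[name],
            }
        out = pd.DataFrame(rows).T
        out["N"] = self.nobs
        out["events"] = self.nevents
        return out


# ---------------------------------------------------------------------------
# Convenience fitters
# ---------------------------------------------------------------------------


def fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
            covariate_cols: list[str]) -> CoxPHResults:
    """Fit the follow-up-scale Cox mortality model from a phenotype table."""
    return CoxPH.from_dataframe(df, duration_col, event_col, covariate_cols).fit()


def fit_gompertz_ph(df: pd.DataFrame, age_col: str, event_col: str,
                    covariate_cols: list[str] = ()) -> GompertzPHResults:
    """Fit the age-scale Gompertz-PH morbidity model from a phenotype table."""
    return GompertzPH.from_dataframe(df, age_col, event_col, covariate_cols).fit()


def fit_sex_stratified(
    df: pd.DataFrame,
    model: str,
    time_col: str,
    event_col: str,
    covariate_cols: list[str],
    sex_col: str = "sex",
):
    """Fit the chosen model separately for each sex, sex dropped as covariate.

    Returns a dict label -> results.  A stratum with zero events raises, as
    for the underlying models.
    """
    cols = [c for c in covariate_cols if c != sex_col]
    out = {}
    for label, sub in df.groupby(sex_col, sort=True):
        if model == "cox":
            out[label] = fit_cox(sub, time_col, event_col, cols)
        elif model == "gompertz":
            out[label] = fit_gompertz_ph(sub, time_col, event_col, cols)
        else:
            raise ValueError("model must be 'cox' or 'gompertz'")
    return out


def summary_table(results_by_label: dict, coef_name: str) -> pd.DataFrame:
    """Stack one coefficient across fits into a per-stratum summary table.

    Output columns mirror the per-phenotype/sex reporting layout:
    coef, ci lower/upper, p-value, N, events.
    """
    rows = []
    for label, res in results_by_label.items():
        ci = res.conf_int()
        rows.append(
            {
                "stratum": label,
                "coef": res.params[coef_name],
                "ci_lower": ci.loc[coef_name, "lower"],
                "ci_upper": ci.loc[coef_name, "upper"],
                "p": res.pvalues[coef_name],
                "N": res.nobs,
                "events": res.nevents,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, age balance
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def mean_lifetime(self) -> float:
        """Area under the curve up to the last event time (discrete identity:
        with no censoring this equals the sample mean)."""
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        return float(np.sum(np.diff(t) * s[:-1]) + self.times[-1] * 0)


def _km_single(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    uniq = np.unique(t[d == 1])
    surv, at_risk, nev = [], [], []
    s = 1.0
    for u in uniq:
        n_risk = int(np.sum(t >= u))
        n_ev = int(np.sum((t == u) & (d == 1)))
        s *= 1.0 - n_ev / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        nev.append(n_ev)
    return KMCurve(
        times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(nev),
    )


def km_estimate(times, events, groups=None):
    """Kaplan-Meier curves, one per group (single curve when groups is None)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        return _km_single(times, events)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        out[g] = _km_single(times[mask], events[mask])
    return out


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray = field(default=None, repr=False)
    expected: np.ndarray = field(default=None, repr=False)


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance.

    At each distinct event time the observed events in group 1 are compared
    with their conditional expectation given the margins; the chi-square
    statistic on 1 df is ``(sum O - sum E)^2 / sum V``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels.size}")
    g1 = groups == labels[0]
    if events.sum() == 0:
        raise ValueError("no events in either group")
    uniq = np.unique(times[events == 1])
    O = E = V = 0.0
    obs, exp = [], []
    for u in uniq:
        at_risk = times >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & g1).sum())
        e1 = d * n1 / n
        O += d1
        E += e1
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs.append(d1)
        exp.append(e1)
    stat = 0.0 if V == 0 else (O - E) ** 2 / V
    return LogRankResult(
        statistic=float(stat),
        df=1,
        pvalue=float(stats.chi2.sf(stat, 1)) if V > 0 else 1.0,
        observed=np.asarray(obs),
        expected=np.asarray(exp),
    )


def ks_age_balance(ages_by_group: dict) -> pd.DataFrame:
    """Pairwise two-sample Kolmogorov-Smirnov tests of age distributions.

    Used to verify burden groups are age-balanced before comparing their
    survival.  Returns one row per pair with D and p; the minimum p across
    pairs is the headline balance figure.
    """
    labels = list(ages_by_group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if len(ages_by_group[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            x, y = np.asarray(ages_by_group[a]), np.asarray(ages_by_group[b])
            if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
                d, p = 0.0, 1.0
            else:
                d, p = stats.ks_2samp(x, y)
            rows.append({"group_a": a, "group_b": b, "D": float(d), "p": float(p)})
    return pd.DataFrame(rows)
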