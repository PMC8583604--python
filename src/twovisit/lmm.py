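"""Random-intercept linear mixed model for two repeated measures.

The model for subject i with n_i observations (here n_i <= 2, but the
code handles any cluster size) is

    y_i = X_i beta + u_i 1 + e_i,   u_i ~ N(0, sigma_b^2),  e_i ~ N(0, sigma_e^2 I),

so Cov(y_i) = sigma_e^2 (I + lambda J) with variance ratio
lambda = sigma_b^2 / sigma_e^2 and J the all-ones matrix.  Estimation
profiles the (restricted) Gaussian log-likelihood over log(lambda):
given lambda, the GLS estimate of beta and the scale sigma_e^2 are
closed-form, using the rank-one Woodbury identities

    (I + lambda J)^{-1} = I - lambda/(1 + n_i lambda) J,
    |I + lambda J| = 1 + n_i lambda.

Sufficient statistics (per-cluster sums of X and y) are precomputed once
so each objective evaluation costs O(p^2) regardless of sample size.
Wald inference uses the standard-normal reference, the conventional
default for mixed models without small-sample df corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["RandomInterceptLMM", "ModelSpec", "LmmFit", "fit_random_intercept_lmm", "wald_p"]

_LOG2PI = np.log(2.0 * np.pi)


class EstimationError(ValueError):
    """Raised when a model cannot be estimated from the given data."""


class _Profile:
    """Profiled objective over the variance ratio, from sufficient statistics."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        _, start, counts = np.unique(groups, return_index=True, return_counts=True)
        self.n, self.p = X.shape
        self.n_clusters = counts.size
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        # per-cluster sums, grouped by cluster size
        edges = np.append(start, self.n)
        s = np.add.reduceat(X, start, axis=0)          # (m, p) cluster sums of rows of X
        t = np.add.reduceat(y, start)                  # (m,)  cluster sums of y
        self.sizes = np.unique(counts)
        self.SS, self.St, self.T2, self.m_of = {}, {}, {}, {}
        for u in self.sizes:
            mask = counts == u
            su, tu = s[mask], t[mask]
            self.SS[u] = su.T @ su
            self.St[u] = su.T @ tu
            self.T2[u] = float(tu @ tu)
            self.m_of[u] = int(mask.sum())
        del edges

    def gls(self, lam: float):
        """Return (A, b, rss, logdet) at variance ratio lam (unit residual scale)."""
        A = self.xtx.copy()
        b = self.xty.copy()
        q = self.yty
        logdet = 0.0
        for u in self.sizes:
            c = lam / (1.0 + u * lam)
            A -= c * self.SS[u]
            b -= c * self.St[u]
            q -= c * self.T2[u]
            logdet += self.m_of[u] * np.log1p(u * lam)
        beta = np.linalg.solve(A, b)
        rss = max(q - b @ beta, 0.0)
        return A, beta, rss, logdet

    def neg2loglik(self, lam: float, reml: bool) -> float:
        A, _, rss, logdet = self.gls(lam)
        n, p = self.n, self.p
        dof = n - p if reml else n
        if rss <= 0.0:
            return -np.inf  # degenerate perfect fit
        sigma2 = rss / dof
        val = dof * (_LOG2PI + np.log(sigma2) + 1.0) + logdet
        if reml:
            val += np.linalg.slogdet(A)[1]
        return val


class RandomInterceptLMM(BaseEstimator):
    """Gaussian linear mixed model with a subject-level random intercept.

    A scikit-learn style estimator: ``fit(X, y, groups=...)`` where
    ``groups`` labels the subject each row belongs to.  The design
    matrix ``X`` holds the fixed-effect covariates; an intercept column
    is prepended unless ``fit_intercept=False``.

    Parameters
    ----------
    method : {"reml", "ml"}
        Restricted or full maximum likelihood for the variance
        components.  Fixed effects are GLS either way.
    fit_intercept : bool
        Prepend a constant column to ``X``.
    ratio_bounds : pair of float
        Search interval for the variance ratio sigma_b^2/sigma_e^2; the
        profile is optimised over its logarithm.  The lower bound acts
        as the sigma_b^2 = 0 boundary.
    tol : float
        Absolute tolerance on log(ratio) for the scalar optimiser.

    Attributes
    ----------
    params_ : ndarray of shape (p,)
        Fixed-effect estimates (intercept first when fitted).
    bse_, zvalues_, pvalues_ : ndarray
        Wald standard errors, z statistics and two-sided normal p-values.
    sigma_b2_, sigma_e2_ : float
        Random-intercept and residual variances.
    loglik_ : float
        Maximised (restricted) log-likelihood.
    converged_, boundary_ : bool
        Optimiser status; ``boundary_`` marks sigma_b2 at (or below)
        the lower search bound.
    """

    def __init__(
        self,
        method: str = "reml",
        fit_intercept: bool = True,
        ratio_bounds: tuple[float, float] = (1e-8, 1e8),
        tol: float = 1e-10,
    ):
        self.method = method
        self.fit_intercept = fit_intercept
        self.ratio_bounds = ratio_bounds
        self.tol = tol

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (subject labels, one per row) is required")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (X.shape[0] == y.size == groups.size):
            raise ValueError("X, y and groups must have matching first dimensions")
        if np.isnan(X).any() or np.isnan(y).any():
            raise EstimationError("NaNs in the design or outcome; drop missing rows before fitting")
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        n, p = X.shape
        if n <= p:
            raise EstimationError(f"need more observations ({n}) than fixed effects ({p})")

        prof = _Profile(X, y, groups)
        reml = self.method == "reml"
        lo, hi = np.log(self.ratio_bounds[0]), np.log(self.ratio_bounds[1])
        obj = lambda t: prof.neg2loglik(np.exp(t), reml)
        res = optimize.minimize_scalar(
            obj, bounds=(lo, hi), method="bounded", options={"xatol": self.tol}
        )
        # guard against a local dip: compare with both boundaries
        candidates = [(res.fun, res.x), (obj(lo), lo), (obj(hi), hi)]
        fbest, tbest = min(candidates, key=lambda c: c[0])
        lam = float(np.exp(tbest))

        A, beta, rss, _ = prof.gls(lam)
        dof = n - p if reml else n
        boundary = tbest <= lo + 1e-9
        degenerate = rss <= max(1e-12 * prof.yty, 1e-300)
        if degenerate:
            warnings.warn("zero residual variation: boundary fit, inference degenerate")
            sigma_e2 = rss / dof if rss > 0 else 0.0
        else:
            sigma_e2 = rss / dof
        cov = sigma_e2 * np.linalg.inv(A)

        self.n_features_in_ = p - int(self.fit_intercept)
        self.params_ = beta
        self.cov_params_ = cov
        with np.errstate(divide="ignore", invalid="ignore"):
            self.bse_ = np.sqrt(np.abs(np.diag(cov)))
            z = beta / self.bse_
        z[np.isnan(z)] = 0.0  # 0/0: no evidence either way
        self.zvalues_ = z
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self.sigma_e2_ = sigma_e2
        self.sigma_b2_ = 0.0 if boundary else lam * sigma_e2
        self.loglik_ = -0.5 * fbest if np.isfinite(fbest) else np.inf
        self.converged_ = bool(res.success) and not degenerate
        self.boundary_ = bool(boundary or degenerate)
        self.n_obs_ = n
        self.n_subjects_ = prof.n_clusters
        if self.fit_intercept:
            self.intercept_ = beta[0]
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        return self

    def predict(self, X):
        """Population-level (fixed-effects only) prediction."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    @property
    def icc_(self) -> float:
        tot = self.sigma_b2_ + self.sigma_e2_
        return self.sigma_b2_ / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# study-pipeline surface: named terms over a cohort table

TERMS = ("intercept", "time", "group", "group:time")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the fit and how time is coded.

    ``fixed_terms`` is drawn from ``("intercept", "time", "group",
    "group:time")``; the intercept is always included and the
    interaction requires both main effects.  ``time_coding`` is
    ``"days"`` (days from baseline, the study analysis) or ``"visit"``
    (0/1 indicator, the power-study scale).
    """

    outcome: str
    fixed_terms: tuple[str, ...] = ("intercept", "time")
    time_coding: str = "days"
    estimation: str = "reml"

    def validate(self) -> None:
        unknown = set(self.fixed_terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        if "intercept" not in self.fixed_terms:
            raise ValueError("the intercept is always part of the model")
        if "group:time" in self.fixed_terms and not {"group", "time"} <= set(self.fixed_terms):
            raise ValueError("group:time requires both group and time main effects")
        if self.time_coding not in ("days", "visit"):
            raise ValueError("time_coding must be 'days' or 'visit'")


@dataclass
class LmmFit:
    """Result of a named-term random-intercept fit."""

    terms: tuple[str, ...]
    estimates: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    z_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    sigma_b2: float = 0.0
    sigma_e2: float = 0.0
    loglik: float = np.nan
    n_subjects: int = 0
    n_observations: int = 0
    converged: bool = False
    boundary: bool = False


def design_matrix(data, spec: ModelSpec, group_b_label: str = "PDTA_CAD"):
    """Build (X, y, groups) for the named terms, dropping missing-outcome rows."""
    from . import study

    spec.validate()
    keep = data[spec.outcome].notna().to_numpy()
    sub = data.loc[keep]
    y = sub[spec.outcome].to_numpy(dtype=float)
    if spec.time_coding == "days":
        time = sub["days_from_baseline"].to_numpy(dtype=float)
    elif "time" in sub.columns:
        time = sub["time"].to_numpy(dtype=float)
    else:
        time = (sub["visit"] == study.VISIT_FOLLOWUP).to_numpy(dtype=float)
    if "cad" in sub.columns:
        grp = sub["cad"].to_numpy(dtype=float)
    else:
        grp = (sub["group"] == group_b_label).to_numpy(dtype=float)
    cols = {"time": time, "group": grp, "group:time": grp * time}
    terms = [t for t in TERMS if t in spec.fixed_terms]
    X = np.column_stack([cols[t] for t in terms if t != "intercept"]) if len(terms) > 1 else np.empty((y.size, 0))
    return X, y, sub["subject_id"].to_numpy(), tuple(terms)


def fit_random_intercept_lmm(data, spec: ModelSpec) -> LmmFit:
    """Fit the random-intercept model for one outcome of a cohort table.

    Subjects observed at a single visit contribute that observation;
    rows with a missing outcome are dropped (no listwise deletion of
    the subject).
    """
    X, y, groups, terms = design_matrix(data, spec)
    if y.size == 0:
        raise EstimationError(f"outcome {spec.outcome!r} has no non-missing values")
    est = RandomInterceptLMM(method=spec.estimation).fit(X, y, groups=groups)
    fit = LmmFit(
        terms=terms,
        estimates=dict(zip(terms, est.params_)),
        standard_errors=dict(zip(terms, est.bse_)),
        z_stats=dict(zip(terms, est.zvalues_)),
        p_values=dict(zip(terms, est.pvalues_)),
        sigma_b2=est.sigma_b2_,
        sigma_e2=est.sigma_e2_,
        loglik=est.loglik_,
        n_subjects=est.n_subjects_,
        n_observations=est.n_obs_,
        converged=est.converged_,
        boundary=est.boundary_,
    )
    return fit


def wald_p(fit: LmmFit, term: str) -> float:
    """Two-sided Wald p-value for one named term, p = 2(1 - Phi(|EE/SE|))."""
    if term not in fit.terms:
        raise KeyError(f"term {term!r} not in fit (has {fit.terms})")
    se = fit.standard_errors[term]
    if se == 0:
        warnings.warn(f"degenerate fit: SE of {term!r} is zero")
        return 0.0 if fit.estimates[term] != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(fit.estimates[term] / se)))
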