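"""Family random-intercept linear mixed model: REML fit, conditional
residuals and joint Wald tests.

Model
-----
For individual i in family f(i),

    y_i = x_i' beta + gamma_f(i) + eps_i,
    gamma_f ~ N(0, sigma2_family),  eps_i ~ N(0, sigma2_resid),

so the marginal covariance is block diagonal with exchangeable blocks
V_f = sigma2_resid * I + sigma2_family * 11'.  Everything here exploits
that structure: for a family of size s,

    V_f^{-1}   = (1/sigma2_resid) * (I - c * 11'),  c = theta / (1 + s*theta)
    log|V_f|   = (s-1) log sigma2_resid + log(sigma2_resid * (1 + s*theta))

with theta = sigma2_family / sigma2_resid, which makes the restricted
log-likelihood an O(n p^2) computation regardless of family sizes.

Estimation profiles the restricted likelihood over theta >= 0 (log-spaced
grid then bounded derivative-free refinement); sigma2_resid has a closed
form at each theta and fixed effects come from generalized least squares at
the optimum.  The family random effects are predicted by their BLUPs
(shrunken family residual means), which is what the GRAMMAR screening stage
consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitError

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

ALLELE_CONTRAST = "allele_contrast"
COPY_TOTAL = "copy_total"


# ---------------------------------------------------------------------------
# blockwise restricted log-likelihood
# ---------------------------------------------------------------------------

def _group_layout(families) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factorize family labels and return (codes, order, sizes) such that
    ``order`` sorts rows into contiguous family blocks."""
    codes, _ = pd.factorize(np.asarray(families))
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes)
    return codes, order, sizes


def _block_sums(M: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Per-family column sums of a row-blocked matrix/vector."""
    return np.add.reduceat(M, starts, axis=0)


@dataclass
class _Workspace:
    """Sufficient statistics for profiled REML given a (X, y, family) layout.

    Rows must be grouped so that each family occupies a contiguous block.
    """

    xtx: np.ndarray       # (p, p)
    xty: np.ndarray       # (p,)
    yty: float
    s_x: np.ndarray       # (F, p) family sums of X rows
    s_y: np.ndarray       # (F,)   family sums of y
    sizes: np.ndarray     # (F,)
    n: int
    p: int

    @classmethod
    def build(cls, X: np.ndarray, y: np.ndarray, sizes: np.ndarray) -> "_Workspace":
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        return cls(
            xtx=X.T @ X,
            xty=X.T @ y,
            yty=float(y @ y),
            s_x=_block_sums(X, starts),
            s_y=_block_sums(y, starts),
            sizes=sizes.astype(float),
            n=X.shape[0],
            p=X.shape[1],
        )

    def _core(self, theta: float):
        """A = X'W^{-1}X, u = X'W^{-1}y, q = y'W^{-1}y for W = I + theta*ZZ'."""
        if theta == 0.0:
            return self.xtx, self.xty, self.yty, 0.0
        c = theta / (1.0 + self.sizes * theta)
        A = self.xtx - (self.s_x.T * c) @ self.s_x
        u = self.xty - self.s_x.T @ (c * self.s_y)
        q = self.yty - float(c @ (self.s_y**2))
        logdet_w = float(np.sum(np.log1p(self.sizes * theta)))
        return A, u, q, logdet_w

    def profile_loglik(self, theta: float) -> float:
        """Restricted log-likelihood profiled over beta and sigma2_resid."""
        A, u, q, logdet_w = self._core(theta)
        try:
            cho = linalg.cho_factor(A, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        beta = linalg.cho_solve(cho, u, check_finite=False)
        rss = q - float(u @ beta)
        df = self.n - self.p
        if rss <= 0 or df <= 0:
            return -np.inf
        sigma2 = rss / df
        return -0.5 * (df * (_LOG2PI + np.log(sigma2) + 1.0) + logdet_w + logdet_a)

    def solve_at(self, theta: float):
        """GLS solution and pieces at a given theta (profiled sigma2)."""
        A, u, q, logdet_w = self._core(theta)
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        beta = linalg.cho_solve(cho, u, check_finite=False)
        rss = max(q - float(u @ beta), 0.0)
        sigma2_resid = rss / (self.n - self.p)
        a_inv = linalg.cho_solve(cho, np.eye(self.p), check_finite=False)
        return beta, a_inv, sigma2_resid, logdet_w


def reml_loglik(y, X, families, sigma2_family: float, sigma2_resid: float) -> float:
    """Blockwise restricted log-likelihood at given variance components.

    Equals the dense-matrix evaluation
    -0.5 * [(n-p) log 2pi + log|V| + log|X'V^-1 X| + r'V^-1 r]
    with V = sigma2_family * ZZ' + sigma2_resid * I and r the GLS residual.
    """
    if sigma2_resid <= 0:
        raise FitError("sigma2_resid must be > 0")
    if sigma2_family < 0:
        raise FitError("sigma2_family must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, order, sizes = _group_layout(families)
    ws = _Workspace.build(X[order], y[order], sizes)
    theta = sigma2_family / sigma2_resid
    A, u, q, logdet_w = ws._core(theta)
    cho = linalg.cho_factor(A, lower=True, check_finite=False)
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    beta = linalg.cho_solve(cho, u, check_finite=False)
    rss = q - float(u @ beta)
    n, p = ws.n, ws.p
    # log|V| = n log s2e + log|W|; log|X'V^-1X| = log|A| - p log s2e
    return -0.5 * (
        (n - p) * _LOG2PI
        + (n - p) * np.log(sigma2_resid)
        + logdet_w
        + logdet_a
        + rss / sigma2_resid
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class FamilyLMM(BaseEstimator, RegressorMixin):
    """REML-fitted linear mixed model with a family random intercept.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an intercept column to the design.
    grid_size : int, default 31
        Number of log-spaced points for the variance-ratio profile grid.
    grid_bounds : tuple, default (1e-4, 1e3)
        Range of the variance ratio theta = sigma2_family / sigma2_resid
        scanned before local refinement (theta = 0 is always included).
    tol : float, default 1e-8
        Absolute tolerance on theta for the bounded refinement.

    Attributes (after ``fit``)
    --------------------------
    fixed_names_, beta_, cov_beta_ : fixed-effect labels, estimates, covariance
    sigma2_family_, sigma2_resid_ : variance components (family may be 0)
    family_effects_ : pd.Series of BLUP-predicted family intercepts
    reml_loglik_, converged_, n_used_ : fit diagnostics
    """

    def __init__(self, fit_intercept: bool = True, grid_size: int = 31,
                 grid_bounds: tuple = (1e-4, 1e3), tol: float = 1e-8):
        self.fit_intercept = fit_intercept
        self.grid_size = grid_size
        self.grid_bounds = grid_bounds
        self.tol = tol

    # -- internals ----------------------------------------------------------
    def _design(self, X, feature_names):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        feature_names = list(feature_names)
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            feature_names = ["intercept"] + feature_names
        return X, feature_names

    @staticmethod
    def _check_rank(X, names):
        if X.shape[0] <= X.shape[1] + 1:
            raise FitError(
                f"n={X.shape[0]} too small for p={X.shape[1]} fixed effects"
            )
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[-1] < 1e-8 * sv[0]:
            # identify aliased columns by rank-revealing QR on the
            # correlation structure
            _, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
            raise FitError(f"rank-deficient design; aliased columns: {bad or names}")

    def fit(self, X, y, groups=None, feature_names=None):
        y = np.asarray(y, dtype=float).ravel()
        X, names = self._design(X, feature_names)
        if X.shape[0] != y.shape[0]:
            raise FitError("X and y have different lengths")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise FitError("non-finite values in design or response")
        if groups is None:
            groups = np.arange(len(y))  # all singletons
        groups = np.asarray(groups)
        if groups.shape[0] != y.shape[0]:
            raise FitError("groups and y have different lengths")
        self._check_rank(X, names)

        codes, order, sizes = _group_layout(groups)
        _, fam_labels = pd.factorize(groups)
        ws = _Workspace.build(X[order], y[order], sizes)

        lo, hi = self.grid_bounds
        grid = np.concatenate(([0.0], np.geomspace(lo, hi, self.grid_size)))
        vals = np.array([ws.profile_loglik(t) for t in grid])
        i = int(np.argmax(vals))
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, len(grid) - 1)]
        if hi_b <= lo_b:
            hi_b = lo_b + 1.0
        res = optimize.minimize_scalar(
            lambda t: -ws.profile_loglik(t),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": self.tol},
        )
        candidates = [(vals[i], grid[i]), (vals[0], 0.0)]
        if np.isfinite(res.fun):
            candidates.append((-res.fun, float(res.x)))
        loglik, theta = max(candidates, key=lambda c: c[0])
        # prefer the boundary when the profile is flat to numerical noise
        # (e.g. all-singleton families identify only the variance total)
        ll0 = ws.profile_loglik(0.0)
        if theta > 0 and ll0 >= loglik - 1e-9:
            theta, loglik = 0.0, ll0

        beta, a_inv, sigma2_resid, _ = ws.solve_at(theta)
        self.converged_ = bool(np.isfinite(loglik))
        self.fixed_names_ = names
        self.beta_ = beta
        self.cov_beta_ = sigma2_resid * a_inv
        self.sigma2_resid_ = float(sigma2_resid)
        self.sigma2_family_ = float(theta * sigma2_resid)
        self.reml_loglik_ = float(loglik)
        self.n_used_ = int(ws.n)
        self.theta_ = float(theta)

        # BLUPs: gamma_f = theta * T_f / (1 + s_f * theta), T_f = family
        # sum of marginal residuals
        resid = y - X @ beta
        t_f = np.bincount(codes, weights=resid)
        with np.errstate(invalid="ignore"):
            blup = theta * t_f / (1.0 + sizes * theta)
        self.family_effects_ = pd.Series(blup, index=fam_labels)
        self._groups_ = groups
        self._resid_conditional_ = resid - blup[codes]
        return self

    def predict(self, X, groups=None):
        X, _ = self._design(X, None if not hasattr(self, "fixed_names_") else
                            self.fixed_names_[1:] if self.fit_intercept else self.fixed_names_)
        yhat = X @ self.beta_
        if groups is not None:
            eff = self.family_effects_.reindex(np.asarray(groups)).fillna(0.0).to_numpy()
            yhat = yhat + eff
        return yhat

    @property
    def conditional_residuals_(self) -> np.ndarray:
        """Y* = y - fixed part - family BLUP for the training data."""
        return self._resid_conditional_


def fit_lmm_reml(y, X, families, feature_names=None, fit_intercept=False,
                 tol: float = 1e-8) -> FamilyLMM:
    """Functional wrapper: REML-fit the family random-intercept model.

    ``X`` is used as given (no intercept added by default, matching designs
    that already carry a constant column).
    """
    model = FamilyLMM(fit_intercept=fit_intercept, tol=tol)
    return model.fit(X, y, groups=families, feature_names=feature_names)


def conditional_residuals(fit: FamilyLMM, y, X_null, families) -> np.ndarray:
    """GRAMMAR conditional residuals Y* = y - X beta_hat - gamma_hat.

    Uses the fitted fixed effects and family BLUPs; families absent from the
    fit contribute no BLUP (prediction 0).
    """
    if not fit.converged_:
        raise FitError("null-model fit did not converge")
    X = np.asarray(X_null, dtype=float)
    if fit.fit_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise FitError("fit/y length mismatch")
    resid = y - X @ fit.beta_
    eff = fit.family_effects_.reindex(np.asarray(families)).fillna(0.0).to_numpy()
    return resid - eff


@dataclass
class JointTestResult:
    """Outcome of the joint Wald test of the genotype terms.

    ``df`` counts the retained terms (0-2); with df = 0 the p-value is 1 and
    ``dropped_reason`` says why every term was dropped.
    """

    statistic: float
    df: int
    p_value: float
    tested_terms: tuple[str, ...]
    dropped_reason: str | None = None


def wald_joint_test(fit: FamilyLMM, term_labels=(ALLELE_CONTRAST, COPY_TOTAL)) -> JointTestResult:
    """Joint Wald chi-square test of the listed fixed-effect terms.

    statistic = beta' C^{-1} beta over the retained terms, C their joint
    covariance submatrix; p from chi-square with df = number retained.
    """
    if not fit.converged_:
        raise FitError("cannot test an unconverged fit")
    idx = [j for j, name in enumerate(fit.fixed_names_) if name in set(term_labels)]
    retained = tuple(fit.fixed_names_[j] for j in idx)
    if not idx:
        return JointTestResult(0.0, 0, 1.0, (), dropped_reason="invariant")
    beta = fit.beta_[idx]
    C = fit.cov_beta_[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(C, beta))
    except np.linalg.LinAlgError:
        # singular covariance after retention: drop to a single term
        j = int(np.argmax(np.abs(beta) / np.sqrt(np.diag(C))))
        stat = float(beta[j] ** 2 / C[j, j])
        return JointTestResult(
            stat, 1, float(stats.chi2.sf(stat, 1)), (retained[j],),
            dropped_reason="collinear",
        )
    stat = max(stat, 0.0)
    df = len(idx)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return JointTestResult(stat, df, max(min(p, 1.0), 0.0), retained)
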