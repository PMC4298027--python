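"""Phylogenetic regression: PGLS and phylogenetic RMA with ML Pagel's lambda.

The estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so they
compose with sklearn tooling; the module-level functions ``pgls_fit``,
``prma_fit``, ``fit_lambda_ml``, ``relative_size`` and ``correlation_battery``
are thin wrappers over them.

Model: y = a + b x + e with e ~ N(0, sigma^2 V_lambda), where V_lambda is the
phylogenetic covariance with off-diagonals multiplied by Pagel's lambda.
lambda is estimated by profiling the (restricted, by default) log-likelihood
over [0, 1]. "Relative size" of a brain structure is its residual from a
phylogenetic reduced-major-axis fit on log rest-of-brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .trees import PhyloTree

__all__ = [
    "ScalingFit",
    "PGLSRegression",
    "PhyloRMARegression",
    "fit_lambda_ml",
    "pgls_fit",
    "prma_fit",
    "relative_size",
    "correlation_battery",
    "rob_scaling",
]


@dataclass(frozen=True)
class ScalingFit:
    """Summary of one bivariate phylogenetic regression."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    p_slope: float
    lambda_hat: float
    n: int
    method: str
    label: str = ""
    residuals: pd.Series = field(default=None, repr=False, compare=False)

    def row(self) -> dict:
        return {
            "label": self.label,
            "method": self.method,
            "slope": self.slope,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "intercept": self.intercept,
            "intercept_ci_low": self.intercept_ci[0],
            "intercept_ci_high": self.intercept_ci[1],
            "r2": self.r_squared,
            "p": self.p_slope,
            "lambda": self.lambda_hat,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# GLS internals
# ---------------------------------------------------------------------------


def _gls_solve(X: np.ndarray, y: np.ndarray, V: np.ndarray, lam_for_msg: float):
    """GLS estimates and the pieces every likelihood needs.

    Returns (beta, cov_unscaled, rss, logdet_V, logdet_XtViX, Vi).
    """
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular phylogenetic covariance at lambda={lam_for_msg:g}"
        ) from exc
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    # solve the whitened least-squares problem by QR (cho[0] holds L with
    # V = L L'); this keeps lambda = 0 numerically identical to plain OLS
    Xw = linalg.solve_triangular(cho[0], X, lower=True)
    yw = linalg.solve_triangular(cho[0], y, lower=True)
    XtViX = Xw.T @ Xw
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"singular design under lambda={lam_for_msg:g} covariance"
        )
    cov_unscaled = np.linalg.inv(XtViX)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design under lambda={lam_for_msg:g} covariance"
        )
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    return beta, cov_unscaled, rss, logdet_V, logdet_XtViX, cho


def _cov_builder(tree: PhyloTree, taxa):
    """Closure building the lambda-transformed covariance for a fixed taxon
    order without re-walking the tree per likelihood evaluation."""
    V1 = tree.vcv(1.0).loc[taxa, taxa].to_numpy()
    diag = np.diag(np.diag(V1))
    off = V1 - diag
    return lambda lam: lam * off + diag


def _profile_loglik(lam: float, X, y, make_V, reml: bool) -> float:
    V = make_V(lam)
    n, p = X.shape
    _, _, rss, logdet_V, logdet_XtViX, _ = _gls_solve(X, y, V, lam)
    if reml:
        df = n - p
        sigma2 = rss / df
        return -0.5 * (
            df * (np.log(2 * np.pi * sigma2) + 1) + logdet_V + logdet_XtViX
        )
    sigma2 = rss / n
    return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1) + logdet_V)


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def _optimize_lambda(X, y, tree, taxa, reml: bool, tol: float = 1e-6) -> float:
    """Constrained ML of lambda by coarse grid + local refinement.

    The profile can touch either boundary; a 21-point scan brackets the
    optimum before Brent refinement, and both endpoints compete with the
    interior solution.
    """
    make_V = _cov_builder(tree, taxa)
    f = lambda lam: -_profile_loglik(lam, X, y, make_V, reml)
    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([f(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    best_lam, best_val = grid[k], vals[k]
    if hi > lo:
        res = optimize.minimize_scalar(
            f, bounds=(lo, hi), method="bounded", options={"xatol": tol}
        )
        if res.fun < best_val:
            best_lam, best_val = float(res.x), float(res.fun)
    for endpoint in (0.0, 1.0):
        v = f(endpoint)
        if v <= best_val + 1e-12:
            if v < best_val - 1e-12 or abs(endpoint - best_lam) < 10 * tol:
                best_lam, best_val = endpoint, v
    return float(np.clip(best_lam, 0.0, 1.0))


def _align(x, y, tree: PhyloTree, taxa):
    """Coerce inputs to arrays ordered by an explicit taxon list."""
    if taxa is None:
        if isinstance(x, pd.Series):
            taxa = list(x.index)
        elif isinstance(y, pd.Series):
            taxa = list(y.index)
        else:
            taxa = tree.tips
    taxa = list(taxa)
    missing = set(taxa) - set(tree.tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxa")
    xv = (x.loc[taxa] if isinstance(x, pd.Series) else pd.Series(x, index=taxa)).to_numpy(float)
    yv = (y.loc[taxa] if isinstance(y, pd.Series) else pd.Series(y, index=taxa)).to_numpy(float)
    if len(xv) != len(yv) or len(xv) != len(taxa):
        raise ValueError("x, y and taxa lengths differ")
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("missing values in x or y")
    return xv, yv, taxa


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class PGLSRegression(BaseEstimator, RegressorMixin):
    """Bivariate phylogenetic generalized least squares with Pagel's lambda.

    Parameters
    ----------
    tree : PhyloTree
        Dated phylogeny whose tips cover the sample.
    taxa : sequence of str, optional
        Row order of ``X``/``y``. Defaults to the index of a pandas input or,
        failing that, the tree's tip order.
    lam : float in [0, 1] or "ml"
        Pagel's lambda; ``"ml"`` (default) profiles the likelihood over [0, 1].
    reml : bool
        Use the restricted likelihood for the lambda profile (default True).

    Fitted attributes: ``coef_`` (slope, shape (1,)), ``intercept_``,
    ``lambda_``, ``r_squared_``, ``p_slope_``, ``slope_ci_``,
    ``intercept_ci_``, ``resid_`` (pd.Series by taxon), ``n_``.

    Slope inference uses a two-sided t test with n - 2 df; R^2 is
    1 - GLS RSS / GLS TSS about the GLS mean of y.
    """

    method_name = "pgls"

    def __init__(self, tree=None, taxa=None, lam="ml", reml=True):
        self.tree = tree
        self.taxa = taxa
        self.lam = lam
        self.reml = reml

    # -- shared preparation -------------------------------------------------

    def _prepare(self, X, y):
        if self.tree is None:
            raise ValueError("tree is required")
        X = X.iloc[:, 0] if isinstance(X, pd.DataFrame) else X
        if isinstance(X, np.ndarray) and X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("exactly one predictor is supported")
            X = X[:, 0]
        x, yv, taxa = _align(X, y, self.tree, self.taxa)
        n = len(taxa)
        if n < 4:
            raise ValueError(f"need at least 4 species, got {n}")
        if np.ptp(x) == 0:
            raise ValueError("predictor has zero variance")
        if self.lam == "ml":
            lam_hat = _optimize_lambda(_design(x), yv, self.tree, taxa, self.reml)
        else:
            lam_hat = float(self.lam)
            if not 0.0 <= lam_hat <= 1.0:
                raise ValueError(f"lambda must lie in [0, 1], got {lam_hat}")
        V = _cov_builder(self.tree, taxa)(lam_hat)
        return x, yv, taxa, lam_hat, V

    def _gls_moments(self, x, y, V, lam):
        """GLS means, (co)variances and correlation about the GLS mean."""
        one = np.ones_like(x)
        _, _, _, _, _, cho = _gls_solve(_design(x), y, V, lam)
        Vi1 = linalg.cho_solve(cho, one)
        w = float(one @ Vi1)
        xbar = float(x @ Vi1) / w
        ybar = float(y @ Vi1) / w
        dx, dy = x - xbar, y - ybar
        Sxx = float(dx @ linalg.cho_solve(cho, dx))
        Syy = float(dy @ linalg.cho_solve(cho, dy))
        Sxy = float(dx @ linalg.cho_solve(cho, dy))
        r = Sxy / np.sqrt(Sxx * Syy) if Sxx > 0 and Syy > 0 else 0.0
        return xbar, ybar, Sxx, Syy, Sxy, r, cho, w

    def fit(self, X, y):
        x, yv, taxa, lam_hat, V = self._prepare(X, y)
        n = len(taxa)
        Xd = _design(x)
        beta, cov_unscaled, rss, _, _, cho = _gls_solve(Xd, yv, V, lam_hat)
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 * np.diag(cov_unscaled))
        tcrit = stats.t.ppf(0.975, df)
        tstat = beta[1] / se[1]
        # GLS total sum of squares about the GLS mean of y
        one = np.ones(n)
        Vi1 = linalg.cho_solve(cho, one)
        ybar = float(yv @ Vi1) / float(one @ Vi1)
        dy = yv - ybar
        tss = float(dy @ linalg.cho_solve(cho, dy))

        self.intercept_ = float(beta[0])
        self.coef_ = np.array([beta[1]])
        self.lambda_ = lam_hat
        self.n_ = n
        self.taxa_ = taxa
        self.sigma2_ = sigma2
        self.slope_se_ = float(se[1])
        self.slope_ci_ = (float(beta[1] - tcrit * se[1]), float(beta[1] + tcrit * se[1]))
        self.intercept_ci_ = (
            float(beta[0] - tcrit * se[0]),
            float(beta[0] + tcrit * se[0]),
        )
        self.p_slope_ = float(2 * stats.t.sf(abs(tstat), df))
        self.r_squared_ = float(1.0 - rss / tss) if tss > 0 else 0.0
        self.resid_ = pd.Series(yv - Xd @ beta, index=taxa, name="residual")
        return self

    def predict(self, X):
        X = X.iloc[:, 0] if isinstance(X, pd.DataFrame) else X
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.coef_[0] * x

    def summary(self, label: str = "") -> ScalingFit:
        return ScalingFit(
            slope=float(self.coef_[0]),
            intercept=self.intercept_,
            slope_ci=self.slope_ci_,
            intercept_ci=self.intercept_ci_,
            r_squared=self.r_squared_,
            p_slope=self.p_slope_,
            lambda_hat=self.lambda_,
            n=self.n_,
            method=self.method_name,
            label=label,
            residuals=self.resid_,
        )


class PhyloRMARegression(PGLSRegression):
    """Phylogenetic reduced major-axis (standardized major-axis) regression.

    The slope is sign(r_gls) * sqrt(GLS var(y) / GLS var(x)) — symmetric in x
    and y — with the line passing through the GLS means; it equals the PGLS
    slope divided by |r_gls|. Residuals from this line define the "relative
    size" of a structure when x is log rest-of-brain. Slope confidence limits
    follow the standard major-axis construction (Jolicoeur) applied to the
    GLS correlation; the p-value is the t test of r_gls = 0 on n - 2 df.
    """

    method_name = "prma"

    def fit(self, X, y):
        x, yv, taxa, lam_hat, V = self._prepare(X, y)
        n = len(taxa)
        df = n - 2
        xbar, ybar, Sxx, Syy, Sxy, r, cho, w = self._gls_moments(x, yv, V, lam_hat)
        if abs(r) < 1e-12:
            raise ValueError("GLS correlation is zero: RMA slope undefined")
        slope = float(np.sign(r) * np.sqrt(Syy / Sxx))
        intercept = float(ybar - slope * xbar)

        tcrit = stats.t.ppf(0.975, df)
        B = tcrit**2 * (1 - r**2) / df
        lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
        slope_ci = (min(lo, hi), max(lo, hi))

        resid = yv - (intercept + slope * x)
        rss = float(resid @ linalg.cho_solve(cho, resid))
        sigma2 = rss / df
        var_slope = slope**2 * (1 - r**2) / df
        var_intercept = sigma2 / w + xbar**2 * var_slope
        half = tcrit * np.sqrt(var_intercept)

        tstat = r * np.sqrt(df / max(1 - r**2, 1e-300))

        self.intercept_ = intercept
        self.coef_ = np.array([slope])
        self.lambda_ = lam_hat
        self.n_ = n
        self.taxa_ = taxa
        self.sigma2_ = sigma2
        self.gls_corr_ = float(r)
        self.slope_ci_ = (float(slope_ci[0]), float(slope_ci[1]))
        self.intercept_ci_ = (float(intercept - half), float(intercept + half))
        self.p_slope_ = float(2 * stats.t.sf(abs(tstat), df))
        self.r_squared_ = float(r**2)
        self.resid_ = pd.Series(resid, index=taxa, name="residual")
        return self


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_lambda_ml(x, y, tree: PhyloTree, taxa=None, reml: bool = True) -> float:
    """Constrained ML estimate of Pagel's lambda for the regression of y on x."""
    xv, yv, taxa = _align(x, y, tree, taxa)
    if len(taxa) < 4:
        raise ValueError(f"need at least 4 species, got {len(taxa)}")
    return _optimize_lambda(_design(xv), yv, tree, taxa, reml)


def pgls_fit(x, y, tree: PhyloTree, lam="ml", taxa=None, label: str = "",
             reml: bool = True) -> ScalingFit:
    est = PGLSRegression(tree=tree, taxa=taxa, lam=lam, reml=reml).fit(x, y)
    return est.summary(label)


def prma_fit(x, y, tree: PhyloTree, lam="ml", taxa=None, label: str = "",
             reml: bool = True) -> ScalingFit:
    est = PhyloRMARegression(tree=tree, taxa=taxa, lam=lam, reml=reml).fit(x, y)
    return est.summary(label)


def relative_size(structure, rob, tree: PhyloTree, lam="ml", taxa=None) -> pd.Series:
    """Relative size: residuals of log structure volume from its pRMA fit on
    log rest-of-brain (ML lambda by default). One value per species; the
    GLS-weighted mean of the residuals is zero."""
    fit = prma_fit(rob, structure, tree, lam=lam, taxa=taxa)
    return fit.residuals


_BATTERY = [
    ("pch~fm", "pch", "fm"),
    ("pch~pf", "pch", "pf"),
    ("pch_r~fm_l", "pch_r", "fm_l"),
    ("pch_l~fm_r", "pch_l", "fm_r"),
    ("pch_r~pf_l", "pch_r", "pf_l"),
    ("pch_l~pf_r", "pch_l", "pf_r"),
]


def correlation_battery(table: pd.DataFrame, tree: PhyloTree, lam="ml") -> list[ScalingFit]:
    """The six PGLS regressions among relative sizes: bilateral PCH on FM and
    PF, plus the four contralateral hemisphere pairings.

    ``table`` is a species-mean trait table (see ``data.species_means``);
    relative sizes are pRMA residuals on log rest-of-brain, computed per
    trait with its own ML lambda.
    """
    taxa = list(table.index)
    rel = {
        t: relative_size(table[f"log_{t}"], table["log_rob"], tree, lam=lam, taxa=taxa)
        for t in ("pch", "fm", "pf", "pch_l", "pch_r", "fm_l", "fm_r", "pf_l", "pf_r")
    }
    return [
        pgls_fit(rel[xk], rel[yk], tree, lam=lam, taxa=taxa, label=lab)
        for lab, yk, xk in _BATTERY
    ]


def rob_scaling(table: pd.DataFrame, tree: PhyloTree, lam="ml",
                traits: Sequence[str] = ("pch_l", "pch_r", "fm_l", "fm_r", "pf_l", "pf_r"),
                ) -> dict[str, ScalingFit]:
    """PGLS scaling of each hemisphere-specific log volume on log rest-of-brain
    (the laterality table's ingredients)."""
    taxa = list(table.index)
    return {
        t: pgls_fit(table["log_rob"], table[f"log_{t}"], tree, lam=lam, taxa=taxa,
                    label=f"{t}~rob")
        for t in traits
    }
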