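"""Site-effect removal with parametric empirical-Bayes ComBat.

Multisite MRI pools scans from different scanners and sequences; the
resulting additive/multiplicative "batch" effects on connectivity edges can
rival the case-control effect. ComBat models each edge g in site i as

    y_ijg = alpha_g + x_ij' beta_g + gamma_ig + delta_ig * eps_ijg

and shrinks the per-site location (gamma) and scale (delta) estimates toward
site-level priors (normal for gamma, inverse-gamma for delta, hyperparameters
by method of moments) before removing them, while covariate effects —
critically the diagnosis contrast — are fitted and restored.

The module also provides the before/after audit: a per-edge one-way ANOVA
across sites with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .synth import SubjectRecord


class DesignError(ValueError):
    """The covariate/batch design matrix is unusable."""


class AnalysisError(ValueError):
    """The requested analysis is not defined for these inputs."""


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


@dataclass
class SiteEffectReport:
    """Per-edge cross-site ANOVA results with BH-FDR flags."""

    f_stats: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    q: float
    group: str = "all"

    @property
    def n_edges(self) -> int:
        return self.p_values.size

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_edges

    def to_frame(self, edge_names: list[str] | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge": edge_names
                if edge_names is not None
                else np.arange(self.n_edges),
                "F": self.f_stats,
                "p": self.p_values,
                "significant": self.significant,
            }
        )

    def summary(self) -> dict:
        return {
            "group": self.group,
            "q": self.q,
            "n_edges": self.n_edges,
            "n_significant": self.n_significant,
            "percent_significant": self.percent_significant,
        }


def site_effect_scan(
    edges: np.ndarray,
    site_ids: list[str] | np.ndarray,
    q: float = 0.05,
    group: str = "all",
) -> SiteEffectReport:
    """Per-edge one-way ANOVA of edge values across sites, BH-FDR at ``q``.

    ``edges`` is (n_subjects, n_edges); callers subset rows to the group of
    interest (patients / controls) beforehand. With two sites the F-test is
    equivalent to a two-sample t-test.
    """
    edges = np.asarray(edges, dtype=float)
    site_ids = np.asarray(site_ids)
    if edges.shape[0] != site_ids.size:
        raise ValueError("edge rows and site_ids length differ")
    uniq = np.unique(site_ids)
    if uniq.size < 2:
        raise AnalysisError("site-effect scan needs >= 2 sites in the subset")
    groups = [edges[site_ids == s] for s in uniq]
    if any(g.shape[0] < 2 for g in groups):
        raise AnalysisError("every site in the subset needs >= 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*groups, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    return SiteEffectReport(
        f_stats=np.asarray(f), p_values=p, significant=bh_fdr(p, q), q=q, group=group
    )


@dataclass
class CombatModel:
    """Fitted ComBat parameters (one column per edge)."""

    site_levels: list[str]
    n_per_site: np.ndarray
    grand_alpha: np.ndarray  # (n_edges,)
    beta_cov: np.ndarray  # (n_cov, n_edges)
    pooled_var: np.ndarray  # (n_edges,)
    gamma_hat: np.ndarray  # (n_sites, n_edges) raw site locations
    delta_sq_hat: np.ndarray  # (n_sites, n_edges) raw site variances
    gamma_star: np.ndarray  # EB-shrunk locations
    delta_sq_star: np.ndarray  # EB-shrunk variances (> 0)
    prior_gamma_bar: np.ndarray = field(default=None)  # (n_sites,)
    prior_tau_sq: np.ndarray = field(default=None)
    prior_lambda: np.ndarray = field(default=None)
    prior_theta: np.ndarray = field(default=None)
    n_iter: np.ndarray = field(default=None)


def _validate_design(cov: np.ndarray | None, n: int) -> np.ndarray:
    if cov is None:
        return np.empty((n, 0))
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise DesignError(f"covariates have {cov.shape[0]} rows, expected {n}")
    return cov


def _eb_site_fit(
    z_site: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, float, float, float, int]:
    """Iterative conditional EB update of one site's gamma*, delta^2*."""
    n = z_site.shape[0]
    g_hat = z_site.mean(axis=0)
    d_hat = z_site.var(axis=0, ddof=1)
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1)
    v = d_hat.mean()
    s2 = d_hat.var(ddof=1)
    # Inverse-gamma hyperparameters by method of moments
    lam = (v * v + 2.0 * s2) / s2 if s2 > 0 else 2.0
    theta = (v**3 + v * s2) / s2 if s2 > 0 else v
    g_star = g_hat.copy()
    d_star = d_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)
        ss = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star)) / (np.max(np.abs(g_star)) + 1e-12),
            np.max(np.abs(d_new - d_star)) / (np.max(np.abs(d_star)) + 1e-12),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star, g_bar, t2, lam, theta, it


class CombatHarmonizer(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes ComBat as a scikit-learn transformer.

    ``fit`` learns per-edge grand model, per-site location/scale and their
    EB-shrunk versions from a subjects x edges matrix; ``fit_transform``
    returns the harmonized training data; ``transform`` applies the fitted
    model to new subjects from the same sites (fold-wise mode).

    Parameters
    ----------
    eb : bool
        Empirical-Bayes shrinkage of site parameters (default). With
        ``eb=False`` the raw per-site location/scale estimates are removed
        instead, which equalizes per-site edge means exactly but borrows no
        strength across edges.
    tol, max_iter : convergence of the iterative conditional EB updates.
    """

    def __init__(self, eb: bool = True, tol: float = 1e-6, max_iter: int = 100):
        self.eb = eb
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, sites, covariates=None):
        self.fit_transform(X, y, sites=sites, covariates=covariates)
        return self

    def fit_transform(self, X, y=None, *, sites, covariates=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D subjects x edges matrix")
        n, n_edges = X.shape
        sites = np.asarray(sites)
        if sites.size != n:
            raise ValueError("sites length does not match number of subjects")
        cov = _validate_design(covariates, n)
        levels = sorted(np.unique(sites).tolist())
        if len(levels) < 2:
            warnings.warn(
                "single site: harmonization is a no-op", UserWarning, stacklevel=2
            )
            self.model_ = None
            self.site_levels_ = levels
            return X.copy()
        counts = np.array([(sites == s).sum() for s in levels])
        if np.any(counts < 2):
            raise DesignError("every site needs >= 2 subjects")

        batch = np.zeros((n, len(levels)))
        for i, s in enumerate(levels):
            batch[sites == s, i] = 1.0
        design = np.hstack([batch, cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DesignError(
                "batch + covariate design is rank deficient "
                "(constant or collinear covariate?)"
            )

        beta = np.linalg.lstsq(design, X, rcond=None)[0]
        beta_batch = beta[: len(levels)]
        beta_cov = beta[len(levels):]
        alpha = (counts / n) @ beta_batch
        resid = X - design @ beta
        # residual variance with the design's degrees of freedom, so that
        # per-site ddof=1 variances standardize to exactly 1 after adjustment
        pooled_var = (resid**2).sum(axis=0) / max(n - design.shape[1], 1)
        pooled_var = np.maximum(pooled_var, 1e-12)
        sigma = np.sqrt(pooled_var)

        cov_effect = cov @ beta_cov if cov.shape[1] else 0.0
        Z = (X - alpha - cov_effect) / sigma

        n_sites = len(levels)
        gamma_hat = np.empty((n_sites, n_edges))
        delta_sq_hat = np.empty((n_sites, n_edges))
        gamma_star = np.empty((n_sites, n_edges))
        delta_sq_star = np.empty((n_sites, n_edges))
        g_bar = np.empty(n_sites)
        tau_sq = np.empty(n_sites)
        lam = np.empty(n_sites)
        theta = np.empty(n_sites)
        iters = np.empty(n_sites, dtype=int)
        for i, s in enumerate(levels):
            z_site = Z[sites == s]
            gamma_hat[i] = z_site.mean(axis=0)
            delta_sq_hat[i] = np.maximum(z_site.var(axis=0, ddof=1), 1e-12)
            if self.eb:
                (
                    gamma_star[i],
                    delta_sq_star[i],
                    g_bar[i],
                    tau_sq[i],
                    lam[i],
                    theta[i],
                    iters[i],
                ) = _eb_site_fit(z_site, self.tol, self.max_iter)
            else:
                gamma_star[i] = gamma_hat[i]
                delta_sq_star[i] = delta_sq_hat[i]
                g_bar[i] = tau_sq[i] = lam[i] = theta[i] = np.nan
                iters[i] = 0

        self.model_ = CombatModel(
            site_levels=levels,
            n_per_site=counts,
            grand_alpha=alpha,
            beta_cov=beta_cov,
            pooled_var=pooled_var,
            gamma_hat=gamma_hat,
            delta_sq_hat=delta_sq_hat,
            gamma_star=gamma_star,
            delta_sq_star=delta_sq_star,
            prior_gamma_bar=g_bar,
            prior_tau_sq=tau_sq,
            prior_lambda=lam,
            prior_theta=theta,
            n_iter=iters,
        )
        self.site_levels_ = levels
        return self._adjust(Z, sites, cov_effect, sigma)

    def transform(self, X, *, sites, covariates=None):
        if not hasattr(self, "model_"):
            raise RuntimeError("CombatHarmonizer is not fitted")
        X = np.asarray(X, dtype=float)
        if self.model_ is None:  # single-site fit was a no-op
            return X.copy()
        sites = np.asarray(sites)
        unseen = set(np.unique(sites)) - set(self.site_levels_)
        if unseen:
            raise DesignError(f"sites not seen during fit: {sorted(unseen)}")
        cov = _validate_design(covariates, X.shape[0])
        m = self.model_
        if cov.shape[1] != m.beta_cov.shape[0]:
            raise DesignError(
                f"expected {m.beta_cov.shape[0]} covariate columns, got {cov.shape[1]}"
            )
        sigma = np.sqrt(m.pooled_var)
        cov_effect = cov @ m.beta_cov if cov.shape[1] else 0.0
        Z = (X - m.grand_alpha - cov_effect) / sigma
        return self._adjust(Z, sites, cov_effect, sigma)

    def _adjust(self, Z, sites, cov_effect, sigma):
        m = self.model_
        out = np.empty_like(Z)
        for i, s in enumerate(m.site_levels):
            mask = sites == s
            if not np.any(mask):
                continue
            out[mask] = (Z[mask] - m.gamma_star[i]) / np.sqrt(m.delta_sq_star[i])
        out = out * sigma + m.grand_alpha + cov_effect
        return out


def combat_fit_transform(
    edges: np.ndarray,
    site_ids,
    covariates: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, CombatModel | None]:
    """Functional wrapper: harmonize ``edges`` and return the fitted model."""
    h = CombatHarmonizer(tol=tol, max_iter=max_iter)
    adjusted = h.fit_transform(edges, sites=site_ids, covariates=covariates)
    return adjusted, h.model_


def design_from_records(records: list[SubjectRecord]) -> np.ndarray:
    """Covariate design (diagnosis, age, sex) with constant columns dropped.

    Diagnosis enters as a preserved covariate so harmonization does not
    scrub the case-control contrast.
    """
    cols = {
        "diagnosis": np.array(
            [1.0 if r.diagnosis == "patient" else 0.0 for r in records]
        ),
        "age": np.array([r.age for r in records]),
        "sex": np.array([1.0 if r.sex == "M" else 0.0 for r in records]),
    }
    keep = [v for v in cols.values() if np.ptp(v) > 0]
    return np.column_stack(keep) if keep else np.empty((len(records), 0))
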