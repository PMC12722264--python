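"""Generation-proxy selection mapping (GPSM).

Birth year (the generation proxy) is regressed on each SNP in the mixed
model ``y = mu + x_i b_i + g + e`` with ``g ~ N(0, G sigma_g^2)`` and
``e ~ N(0, I sigma_e^2)``, where G is the VanRaden genomic relationship
matrix.  Markers whose alleles changed frequency over time show an
association between dosage and birth year; the polygenic term absorbs
the drift-like, relationship-structured component so that significant
markers indicate directional selection rather than pedigree structure.

Variance components are estimated once by REML under the null model
(no SNP) using the eigendecomposition of G, then held fixed for the
per-marker generalized-least-squares scan — the standard mixed-model
association strategy.  Significance uses a Bonferroni threshold of
``alpha / n_markers`` and the scan keeps the candidate marker inside G
(non-LOCO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from bovpop.genotype_io import MISSING, GenotypeDataset
from bovpop.popgen_stats import GRM

__all__ = [
    "VarianceComponents",
    "GPSMResult",
    "reml_null",
    "mlma_scan",
    "bonferroni_threshold",
    "qq_data",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    pve: float
    log_likelihood: float
    n_iterations: int
    boundary: bool = False  # ratio pinned at a boundary of the search range


@dataclass
class GPSMResult:
    table: pd.DataFrame  # marker, chromosome, position, effect, se, stat, p
    threshold: float
    vc: VarianceComponents

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _reml_loglik(
    log_lambda: float, lam_g: np.ndarray, y_rot: np.ndarray, one_rot: np.ndarray
) -> tuple[float, float, float]:
    """Restricted log-likelihood at variance ratio sigma_g^2/sigma_e^2.

    Returns (ll, sigma2_e_hat, mu_hat) with sigma_e profiled out; the
    fixed-effect design is the intercept only.
    """
    ratio = np.exp(log_lambda)
    w = ratio * lam_g + 1.0  # V = sigma_e^2 * diag(w) in the rotated basis
    xwx = np.sum(one_rot**2 / w)
    mu = np.sum(one_rot * y_rot / w) / xwx
    r = y_rot - one_rot * mu
    n = len(y_rot)
    rss = np.sum(r**2 / w)
    s2e = rss / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi * s2e)
        + np.sum(np.log(w))
        + np.log(xwx)
        + (n - 1)
    )
    return ll, s2e, mu


def reml_null(
    y: np.ndarray,
    grm: GRM,
    log_lambda_bounds: tuple[float, float] = (-12.0, 12.0),
) -> VarianceComponents:
    """REML variance components for ``y = mu + g + e`` via eigen-rotation.

    One-dimensional profile likelihood over the log variance ratio,
    maximized by bounded scalar optimization on the eigen-rotated data.
    A ratio at either bound is reported with ``boundary=True`` (the
    corresponding component is effectively pinned near zero).
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 30:
        raise ValueError("REML needs at least 30 individuals")
    if np.ptp(y) == 0.0:
        raise ValueError("generation proxy is constant: zero total variance")
    lam, U = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0.0, None)
    yc = y - y.mean()
    y_rot = U.T @ yc
    one_rot = U.T @ np.ones(n)

    neg = lambda t: -_reml_loglik(t, lam, y_rot, one_rot)[0]
    res = optimize.minimize_scalar(
        neg, bounds=log_lambda_bounds, method="bounded",
        options={"xatol": 1e-8, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res}")
    ll, s2e, _ = _reml_loglik(res.x, lam, y_rot, one_rot)
    ratio = float(np.exp(res.x))
    boundary = bool(
        res.x <= log_lambda_bounds[0] + 1e-6 or res.x >= log_lambda_bounds[1] - 1e-6
    )
    s2g = ratio * s2e
    if boundary and res.x <= log_lambda_bounds[0] + 1e-6:
        s2g = 0.0
    return VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
        pve=float(s2g / (s2g + s2e)),
        log_likelihood=float(ll),
        n_iterations=int(res.nfev),
        boundary=boundary,
    )


def mlma_scan(
    ds: GenotypeDataset,
    y: np.ndarray,
    vc: VarianceComponents,
    grm: GRM,
    alpha: float = 0.05,
) -> GPSMResult:
    """Per-marker GLS association of the generation proxy with dosage.

    The covariance structure ``V = sigma_g^2 G + sigma_e^2 I`` is held
    fixed at the null REML estimates; each marker is tested by the Wald
    statistic ``b / se(b)`` against a t reference with n-2 degrees of
    freedom, where ``se`` uses the per-marker GLS residual scale (the
    variance ratio, not the absolute level, is taken from the null fit).
    With sigma_g^2 = 0 this is exactly simple linear regression.  Missing
    dosages are mean-imputed; monomorphic markers are skipped.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    lam, U = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0.0, None)
    w = vc.sigma2_g * lam + vc.sigma2_e
    a = 1.0 / w

    y_rot = U.T @ y
    one_rot = U.T @ np.ones(n)

    p = ds.allele_freqs()
    Z = ds.calls.astype(np.float64)
    miss = ds.calls == MISSING
    if miss.any():
        Z[miss] = np.broadcast_to(2.0 * p, Z.shape)[miss]
    X_rot = U.T @ Z

    s11 = np.sum(a * one_rot**2)
    s1y = np.sum(a * one_rot * y_rot)
    syy = np.sum(a * y_rot**2)
    s1x = X_rot.T @ (a * one_rot)
    sxx = (X_rot**2).T @ a
    sxy = X_rot.T @ (a * y_rot)

    det = s11 * sxx - s1x**2
    poly = (p > 0.0) & (p < 1.0) & (det > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (s11 * sxy - s1x * s1y) / det
        mu = (sxx * s1y - s1x * sxy) / det
        rss = syy - mu * s1y - beta * sxy
        scale = np.maximum(rss, 0.0) / (n - 2)
        var_beta = (s11 / det) * scale
        tstat = beta / np.sqrt(var_beta)
    pvals = np.where(poly, 2.0 * stats.t.sf(np.abs(tstat), df=n - 2), np.nan)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    thr = bonferroni_threshold(int(poly.sum()), alpha)
    table = pd.DataFrame(
        {
            "marker_id": ds.markers["marker_id"],
            "chromosome": ds.markers["chromosome"],
            "position_bp": ds.markers["position_bp"],
            "allele_a1": ds.markers["allele_a1"],
            "freq_a1": p,
            "effect": np.where(poly, beta, np.nan),
            "se": np.where(poly, np.sqrt(var_beta), np.nan),
            "stat": np.where(poly, tstat, np.nan),
            "p_value": np.where(poly, pvals, np.nan),
            "tested": poly,
        }
    )
    table["significant"] = table["p_value"] < thr
    return GPSMResult(table=table, threshold=thr, vc=vc)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / n_markers``."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return alpha / n_markers


def qq_data(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected and observed -log10 p quantiles plus genomic inflation.

    Expected quantiles are ``-log10((i - 0.5) / M)``; the inflation
    factor is the median association chi-square over its null median
    0.4549.  Zero p-values are clamped to the smallest positive float.
    """
    p = np.asarray(p_values, dtype=np.float64)
    p = p[np.isfinite(p)]
    if (p <= 0).any():
        p = np.clip(p, np.finfo(float).tiny, None)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    chi2 = stats.chi2.isf(p, df=1)
    inflation = float(np.median(chi2) / 0.4549364231195724)
    return expected, observed, inflation
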