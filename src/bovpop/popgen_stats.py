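"""Genomic relationships, PCA, diversity, and differentiation statistics.

Implements the VanRaden genomic relationship matrix
``G = (M - 2P)(M - 2P)' / (2 sum p_i (1 - p_i))`` with in-sample allele
frequencies and mean imputation of missing calls, principal components
from a relationship matrix, observed/expected heterozygosity, the
proportion of polymorphic markers, the allele-sharing statistic
``(IBS2 + 0.5 IBS1) / m`` between individuals, and the Weir-Cockerham
(1984) two-population per-marker fixation index theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "GRM",
    "PCAResult",
    "grm_vanraden",
    "grm_per_snp_standardized",
    "pca_from_grm",
    "heterozygosity",
    "polymorphic_proportion",
    "pairwise_shared_distance",
    "fst_weir_cockerham",
    "diversity_summary",
]


@dataclass
class GRM:
    """Genomic relationship matrix with the frequencies that built it."""

    values: np.ndarray
    allele_freqs: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x k, eigenvector * sqrt(eigenvalue)
    explained_fraction: np.ndarray  # per component, of total variance (trace)


def _imputed_dosage(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Float dosage matrix with missing calls set to 2p, plus the p vector."""
    p = ds.allele_freqs()
    if np.isnan(p).any():
        raise ValueError("dataset contains all-missing markers")
    Z = ds.calls.astype(np.float64)
    miss = ds.calls == MISSING
    if miss.any():
        Z[miss] = np.broadcast_to(2.0 * p, Z.shape)[miss]
    return Z, p


def grm_vanraden(ds: GenotypeDataset) -> GRM:
    """VanRaden G: centered dosage cross-product over ``2 sum p(1-p)``."""
    Z, p = _imputed_dosage(ds)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    Zc = Z - 2.0 * p
    G = (Zc @ Zc.T) / denom
    return GRM(values=(G + G.T) / 2.0, allele_freqs=p, n_markers=ds.n_markers)


def grm_per_snp_standardized(ds: GenotypeDataset) -> GRM:
    """Relationship matrix from per-SNP standardized dosages.

    Each marker's centered dosage is divided by its binomial standard
    deviation ``sqrt(2 p (1 - p))`` before the cross-product, which is
    then averaged over polymorphic markers (each SNP contributes equal
    variance — the covariance of each SNP divided by its variance).
    """
    Z, p = _imputed_dosage(ds)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers monomorphic")
    Zc = (Z[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    G = (Zc @ Zc.T) / poly.sum()
    return GRM(values=(G + G.T) / 2.0, allele_freqs=p, n_markers=ds.n_markers)


def pca_from_grm(grm: GRM, k: int) -> PCAResult:
    """Top-k principal components of a relationship matrix.

    Scores are eigenvectors scaled by the square root of their (non-negative)
    eigenvalues; explained fractions are eigenvalues over the trace.
    """
    vals, vecs = np.linalg.eigh(grm.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if k > len(vals):
        raise ValueError(f"k={k} exceeds matrix rank bound {len(vals)}")
    lam = np.clip(vals[:k], 0.0, None)
    trace = max(np.clip(vals, 0.0, None).sum(), np.finfo(float).tiny)
    return PCAResult(
        scores=vecs[:, :k] * np.sqrt(lam),
        explained_fraction=lam / trace,
    )


def heterozygosity(ds: GenotypeDataset) -> tuple[pd.DataFrame, pd.Series]:
    """Observed heterozygosity per individual and expected per population.

    HO is the heterozygote count over non-missing calls per individual
    (NaN for all-missing individuals, excluded from means downstream).
    HE per population is the mean over markers of ``2 p (1 - p)`` with p
    estimated within that population.
    """
    obs = ds.calls != MISSING
    n_obs = obs.sum(axis=1)
    het = (ds.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_obs > 0, het / n_obs, np.nan)
    ho_df = pd.DataFrame(
        {
            "sample_id": ds.samples["sample_id"],
            "population": ds.samples.get("population", "ALL"),
            "ho": ho,
        }
    )
    he = {}
    for pop, idx in ds.samples.groupby("population", observed=True).indices.items():
        sub = ds.take_samples(np.sort(idx))
        p = sub.allele_freqs()
        he[pop] = float(np.nanmean(2.0 * p * (1.0 - p)))
    return ho_df, pd.Series(he, name="he")


def polymorphic_proportion(ds: GenotypeDataset, maf_threshold: float = 0.05) -> float:
    """Fraction of markers with minor-allele frequency above the threshold."""
    p = ds.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        return float(np.mean(maf > maf_threshold))


def pairwise_shared_distance(ds: GenotypeDataset) -> tuple[pd.DataFrame, dict]:
    """Allele-sharing proportion and its complement for every sample pair.

    For each pair the shared proportion is ``s = (IBS2 + 0.5 IBS1) / m``
    over mutually non-missing loci, equal to ``1 - mean(|g_i - g_j|) / 2``.
    Both ``s`` and the distance ``1 - s`` are reported per pair, with the
    population summary (mean and SD over pairs) for each.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two individuals")
    A = [(ds.calls == k).astype(np.float64) for k in (0, 1, 2)]
    O = (ds.calls != MISSING).astype(np.float64)
    m_pair = O @ O.T
    absdiff = (
        A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
        + 2.0 * (A[0] @ A[2].T + A[2] @ A[0].T)
    )
    iu = np.triu_indices(ds.n_samples, k=1)
    m = m_pair[iu]
    ok = m > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        shared = 1.0 - absdiff[iu] / (2.0 * m)
    ids = ds.samples["sample_id"].to_numpy()
    table = pd.DataFrame(
        {
            "sample_i": ids[iu[0]],
            "sample_j": ids[iu[1]],
            "n_loci": m.astype(int),
            "shared": np.where(ok, shared, np.nan),
            "distance": np.where(ok, 1.0 - shared, np.nan),
        }
    )
    n_valid = int(ok.sum())
    sd = (
        float(np.nanstd(table["shared"], ddof=1)) if n_valid > 1 else float("nan")
    )
    summary = {
        "shared_mean": float(np.nanmean(table["shared"])),
        "shared_sd": sd,
        "distance_mean": float(np.nanmean(table["distance"])),
        "distance_sd": sd,
        "n_pairs_excluded": int((~ok).sum()),
    }
    return table, summary


def _pop_counts(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker sample size, allele-1 frequency, observed het proportion."""
    obs = ds.calls != MISSING
    n = obs.sum(axis=0).astype(np.float64)
    dose = np.where(obs, ds.calls, 0).sum(axis=0, dtype=np.int64)
    het = (ds.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def fst_weir_cockerham(
    ds_a: GenotypeDataset, ds_b: GenotypeDataset
) -> tuple[pd.DataFrame, dict]:
    """Weir-Cockerham (1984) two-population theta per marker, plus summary.

    Datasets must share an identical, harmonized marker map.  Markers
    monomorphic in the pooled sample have undefined theta and are excluded
    (their count is reported); negative per-marker estimates are retained
    in the mean, which avoids the upward bias of truncation.

    The summary carries two genome-wide numbers: ``mean_theta`` (the mean
    +/- SD of per-marker ratios, the usual table format) and
    ``theta_multilocus`` (sum of a over sum of a+b+c, the Weir-Cockerham
    combined estimator).  With only two populations the per-marker mean
    is noticeably Jensen-biased toward zero, so parameter recovery should
    be judged on the multilocus estimator.
    """
    if not ds_a.markers["marker_id"].equals(ds_b.markers["marker_id"]):
        raise ValueError("datasets must share a harmonized marker map")
    n1, p1, h1 = _pop_counts(ds_a)
    n2, p2, h2 = _pop_counts(ds_b)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    defined = np.isfinite(theta)
    with np.errstate(invalid="ignore"):
        multilocus = float(
            np.nansum(np.where(defined, a, np.nan))
            / np.nansum(np.where(defined, denom, np.nan))
        )
    table = pd.DataFrame(
        {
            "marker_id": ds_a.markers["marker_id"],
            "chromosome": ds_a.markers["chromosome"],
            "position_bp": ds_a.markers["position_bp"],
            "theta": theta,
        }
    )
    summary = {
        "mean_theta": float(np.nanmean(theta)) if defined.any() else np.nan,
        "sd_theta": float(np.nanstd(theta[defined], ddof=1)) if defined.sum() > 1 else np.nan,
        "theta_multilocus": multilocus if defined.any() else np.nan,
        "n_markers_used": int(defined.sum()),
        "n_markers_excluded": int((~defined).sum()),
    }
    return table, summary


def diversity_summary(ds: GenotypeDataset, maf_threshold: float = 0.05) -> pd.DataFrame:
    """Per-population diversity table: HO, HE, polymorphic share, distance.

    Mirrors the usual array-study summary: observed heterozygosity
    (mean +/- SD over individuals), expected heterozygosity (mean +/- SD
    over markers), the proportion of polymorphic markers, and the mean
    +/- SD pairwise allele-sharing distance within the population.
    """
    rows = []
    for pop, idx in ds.samples.groupby("population", observed=True).indices.items():
        sub = ds.take_samples(np.sort(idx))
        ho_df, _ = heterozygosity(sub)
        p = sub.allele_freqs()
        he_per_marker = 2.0 * p * (1.0 - p)
        _, dist = pairwise_shared_distance(sub)
        rows.append(
            {
                "population": pop,
                "n_samples": sub.n_samples,
                "ho_mean": float(np.nanmean(ho_df["ho"])),
                "ho_sd": float(np.nanstd(ho_df["ho"], ddof=1)),
                "he_mean": float(np.nanmean(he_per_marker)),
                "he_sd": float(np.nanstd(he_per_marker, ddof=1)),
                "polymorphic_proportion": polymorphic_proportion(sub, maf_threshold),
                "distance_mean": dist["distance_mean"],
                "distance_sd": dist["distance_sd"],
                "shared_mean": dist["shared_mean"],
            }
        )
    return pd.DataFrame(rows)
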