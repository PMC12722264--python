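"""Two-locus linkage disequilibrium: r-squared, EM haplotypes, decay, pruning.

``r2`` is the squared sample correlation between 0/1/2 genotype dosages
(the composite measure used for array data); the gametic ``D`` and
``D'`` come from EM haplotype-frequency estimation over unphased
genotypes, with double heterozygotes split by the current phase odds.
The genome scan enumerates intra-chromosomal pairs within a distance
window and the decay table averages r2 in 10-kb bins up to 100 kb and
100-kb bins up to 1 Mb.  Two marker-thinning procedures are provided:
pairwise-r2 pruning and variance-inflation-factor (VIF) pruning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "genotype_r2",
    "em_haplotype_freqs",
    "ld_scan",
    "decay_bin_edges",
    "assign_decay_bin",
    "bin_ld_decay",
    "prune_r2",
    "prune_vif",
]

EM_TOL = 1e-10
EM_MAX_ITER = 1000


def genotype_r2(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, complete-case.

    Returns NaN when fewer than two mutually non-missing pairs remain or
    either marker has zero variance on the joint sample.
    """
    x = np.asarray(calls_i)
    y = np.asarray(calls_j)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xf = x[ok].astype(np.float64)
    yf = y[ok].astype(np.float64)
    if xf.std() == 0.0 or yf.std() == 0.0:
        return float("nan")
    r = np.corrcoef(xf, yf)[0, 1]
    return float(r * r)


def _em_batch(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized two-locus EM over a (P, 3, 3) genotype-count array.

    ``counts[p, i, j]`` is the number of individuals with dosage i at the
    first and j at the second locus of pair p.  Returns haplotype
    frequencies (AB, Ab, aB, ab), D, D', and convergence flags, where
    allele A/B is allele-1 at each locus.
    """
    c = counts.astype(np.float64)
    n_ind = c.sum(axis=(1, 2))
    two_n = np.maximum(2.0 * n_ind, 1e-300)

    # unambiguous haplotype contributions (dosages index: 0,1,2 copies)
    base_ab = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]  # AB
    base_aB = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]  # Ab
    base_bA = 2 * c[:, 0, 2] + c[:, 0, 1] + c[:, 1, 2]  # aB
    base_nn = 2 * c[:, 0, 0] + c[:, 0, 1] + c[:, 1, 0]  # ab
    dh = c[:, 1, 1]  # double heterozygotes: AB/ab or Ab/aB

    fAB = (base_ab + 0.5 * dh) / two_n
    fAb = (base_aB + 0.5 * dh) / two_n
    faB = (base_bA + 0.5 * dh) / two_n
    fab = (base_nn + 0.5 * dh) / two_n

    converged = np.zeros(len(c), dtype=bool)
    for _ in range(EM_MAX_ITER):
        num = fAB * fab
        den = num + fAb * faB
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        nAB = (base_ab + w * dh) / two_n
        nAb = (base_aB + (1.0 - w) * dh) / two_n
        naB = (base_bA + (1.0 - w) * dh) / two_n
        nab = (base_nn + w * dh) / two_n
        delta = np.max(
            np.stack(
                [np.abs(nAB - fAB), np.abs(nAb - fAb), np.abs(naB - faB), np.abs(nab - fab)]
            ),
            axis=0,
        )
        fAB, fAb, faB, fab = nAB, nAb, naB, nab
        converged |= delta < EM_TOL
        if converged.all():
            break

    fA = fAB + fAb
    fB = fAB + faB
    D = fAB - fA * fB
    with np.errstate(invalid="ignore", divide="ignore"):
        dmax = np.where(
            D >= 0,
            np.minimum(fA * (1.0 - fB), (1.0 - fA) * fB),
            np.minimum(fA * fB, (1.0 - fA) * (1.0 - fB)),
        )
        dprime = np.where(dmax > 0, D / dmax, 0.0)
    return {
        "fAB": fAB,
        "fAb": fAb,
        "faB": faB,
        "fab": fab,
        "fA": fA,
        "fB": fB,
        "D": D,
        "Dprime": dprime,
        "converged": converged,
    }


def em_haplotype_freqs(
    calls_i: np.ndarray, calls_j: np.ndarray
) -> dict[str, float | bool]:
    """EM two-locus haplotype frequencies for one marker pair.

    Returns ``fAB, fAb, faB, fab, D, Dprime, converged`` with A/B the
    allele-1 of each marker; complete-case over mutually observed calls.
    """
    x = np.asarray(calls_i)
    y = np.asarray(calls_j)
    ok = (x != MISSING) & (y != MISSING)
    counts = np.zeros((1, 3, 3))
    for i in range(3):
        for j in range(3):
            counts[0, i, j] = np.sum((x == i) & (y == j) & ok)
    out = _em_batch(counts)
    return {k: (bool(v[0]) if k == "converged" else float(v[0])) for k, v in out.items()}


def ld_scan(
    ds: GenotypeDataset,
    max_distance_bp: int = 1_000_000,
    with_d: bool = True,
) -> pd.DataFrame:
    """All intra-chromosomal marker pairs within the distance window.

    Returns a pair table with distance, genotypic r2, and (optionally)
    EM-based D/D' and complete-case allele-1 frequencies; no r2 floor is
    applied.  Pairs where either marker has zero variance on the joint
    sample are excluded; their count is stored in ``result.attrs``.
    """
    ds = ds.sorted_by_position()
    chrom = ds.markers["chromosome"].to_numpy()
    pos = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    mids = ds.markers["marker_id"].to_numpy()

    obs = (ds.calls != MISSING)
    Xf = ds.calls.astype(np.float64) * obs  # missing as 0, masked by obs

    frames: list[pd.DataFrame] = []
    n_undefined = 0
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        m_c = len(sel)
        if m_c < 2:
            continue
        p_c = pos[sel]
        for offset in range(1, m_c):
            d = p_c[offset:] - p_c[:-offset]
            within = d <= max_distance_bp
            if not within.any():
                break
            ii = sel[np.flatnonzero(within)]
            jj = sel[np.flatnonzero(within) + offset]

            o1, o2 = obs[:, ii], obs[:, jj]
            both = o1 & o2
            x = Xf[:, ii] * both
            y = Xf[:, jj] * both
            n = both.sum(axis=0).astype(np.float64)
            s1, s2 = x.sum(axis=0), y.sum(axis=0)
            s11 = (x * x).sum(axis=0)
            s22 = (y * y).sum(axis=0)
            s12 = (x * y).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                varx = n * s11 - s1 * s1
                vary = n * s22 - s2 * s2
                cov = n * s12 - s1 * s2
                r2 = np.where((varx > 0) & (vary > 0), cov**2 / (varx * vary), np.nan)
            defined = np.isfinite(r2) & (n >= 2)
            n_undefined += int((~defined).sum())
            if not defined.any():
                continue
            keep = np.flatnonzero(defined)
            frame = pd.DataFrame(
                {
                    "marker_i": mids[ii[keep]],
                    "marker_j": mids[jj[keep]],
                    "chromosome": str(c),
                    "distance_bp": d[np.flatnonzero(within)][keep],
                    "r2": r2[keep],
                }
            )
            if with_d:
                counts = np.zeros((len(keep), 3, 3))
                xo = ds.calls[:, ii[keep]]
                yo = ds.calls[:, jj[keep]]
                bo = both[:, keep]
                for gi in range(3):
                    for gj in range(3):
                        counts[:, gi, gj] = ((xo == gi) & (yo == gj) & bo).sum(axis=0)
                em = _em_batch(counts)
                frame["D"] = em["D"]
                frame["Dprime"] = em["Dprime"]
                frame["freq_a1_i"] = em["fA"]
                frame["freq_a1_j"] = em["fB"]
            frames.append(frame)

    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(
            ["chromosome", "marker_i", "marker_j"], kind="stable"
        ).reset_index(drop=True)
    else:
        cols = ["marker_i", "marker_j", "chromosome", "distance_bp", "r2"]
        if with_d:
            cols += ["D", "Dprime", "freq_a1_i", "freq_a1_j"]
        out = pd.DataFrame(columns=cols)
    out.attrs["n_undefined"] = n_undefined
    return out


def decay_bin_edges() -> np.ndarray:
    """Edges of the decay bins: 10-kb steps to 100 kb, then 100-kb to 1 Mb."""
    return np.concatenate(
        [np.arange(10_000, 100_000, 10_000), np.arange(100_000, 1_000_001, 100_000)]
    )


def assign_decay_bin(distance_bp: np.ndarray) -> np.ndarray:
    """Bin index for each distance; -1 outside [10 kb, 1 Mb].

    Bins are half-open low-inclusive, with the final bin closed at 1 Mb.
    """
    d = np.asarray(distance_bp, dtype=np.int64)
    edges = decay_bin_edges()
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[(d < edges[0]) | (d > 1_000_000)] = -1
    idx[d == 1_000_000] = len(edges) - 2
    return idx


def bin_ld_decay(pairs: pd.DataFrame, min_pairs: int = 50) -> pd.DataFrame:
    """Mean r2 per distance bin; bins under ``min_pairs`` flagged unreliable."""
    edges = decay_bin_edges()
    idx = assign_decay_bin(pairs["distance_bp"].to_numpy()) if len(pairs) else np.array([], int)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        r2 = pairs.loc[mask, "r2"] if mask.any() else pd.Series(dtype=float)
        rows.append(
            {
                "bin_low_bp": int(edges[b]),
                "bin_high_bp": int(edges[b + 1]),
                "mean_r2": float(r2.mean()) if len(r2) else np.nan,
                "n_pairs": int(mask.sum()),
                "reliable": bool(mask.sum() >= min_pairs),
            }
        )
    return pd.DataFrame(rows)


def _window_starts(m: int, window: int, step: int) -> list[int]:
    if m <= window:
        return [0]
    starts = list(range(0, m - window + 1, step))
    if starts[-1] != m - window:
        starts.append(m - window)
    return starts


def _imputed_centered(ds: GenotypeDataset) -> np.ndarray:
    p = np.nan_to_num(ds.allele_freqs(), nan=0.0)
    Z = ds.calls.astype(np.float64)
    miss = ds.calls == MISSING
    if miss.any():
        Z[miss] = np.broadcast_to(2.0 * p, Z.shape)[miss]
    return Z - Z.mean(axis=0)


def prune_r2(
    ds: GenotypeDataset,
    r2_max: float = 0.8,
    window_snps: int = 50,
    step_snps: int = 5,
) -> list[str]:
    """Greedy windowed pairwise-r2 pruning; returns kept marker ids.

    Within each sliding window, for every pair with r2 above the ceiling
    the marker later in map order is removed (deterministic tie-break);
    missing calls are mean-imputed for the correlation.
    """
    ds = ds.sorted_by_position()
    Z = _imputed_centered(ds)
    chrom = ds.markers["chromosome"].to_numpy()
    kept = np.ones(ds.n_markers, dtype=bool)
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        for start in _window_starts(len(sel), window_snps, step_snps):
            idx = sel[start : start + window_snps]
            active = idx[kept[idx]]
            if len(active) < 2:
                continue
            B = Z[:, active]
            sd = B.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                R = (B.T @ B) / len(B)
                R = R / np.outer(sd, sd)
            r2 = np.nan_to_num(R**2, nan=0.0)
            alive = np.ones(len(active), dtype=bool)
            for a in range(len(active)):
                if not alive[a]:
                    continue
                for b in range(a + 1, len(active)):
                    if alive[b] and r2[a, b] > r2_max:
                        alive[b] = False
            kept[active[~alive]] = False
    return ds.markers["marker_id"].to_numpy()[kept].tolist()


def prune_vif(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_max: float = 2.0,
) -> list[str]:
    """Variance-inflation-factor pruning; returns kept marker ids.

    Within each window the marker with the highest VIF (diagonal of the
    inverse correlation matrix, lightly ridge-regularized so exact
    collinearity reads as effectively infinite) is removed until all
    VIFs are at most ``vif_max``.
    """
    ds = ds.sorted_by_position()
    Z = _imputed_centered(ds)
    chrom = ds.markers["chromosome"].to_numpy()
    kept = np.ones(ds.n_markers, dtype=bool)
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        for start in _window_starts(len(sel), window_snps, step_snps):
            idx = sel[start : start + window_snps]
            while True:
                active = idx[kept[idx]]
                if len(active) < 2:
                    break
                B = Z[:, active]
                sd = B.std(axis=0)
                if (sd == 0).any():  # constant marker: drop, cannot inflate
                    kept[active[sd == 0]] = False
                    continue
                R = (B.T @ B) / len(B) / np.outer(sd, sd)
                vif = np.diag(
                    np.linalg.inv(R + 1e-10 * np.eye(len(active)))
                )
                worst = int(np.argmax(vif))
                if vif[worst] <= vif_max:
                    break
                kept[active[worst]] = False
    return ds.markers["marker_id"].to_numpy()[kept].tolist()
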