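"""Runs of homozygosity: sliding-window detection, classes, islands.

Detection follows the sliding-window consensus used for SNP-array data:
50-SNP windows slide across each chromosome; a window is "homozygous" if
it contains at most one heterozygous and at most one missing call; a
marker is ROH-eligible if at least 5% of the windows covering it are
homozygous.  Maximal runs of consecutive eligible markers — split at
inter-marker gaps above 1 Mb — are reported as ROH when they span at
least 30 SNPs and 500 kb at a density of at least one SNP per 50 kb.
Called segments are grouped into the five conventional length classes
and markers inside an ROH in at least half the population mark islands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "ROHParams",
    "window_homozygosity_calls",
    "call_roh",
    "classify_roh",
    "roh_summary",
    "chromosome_coverage",
    "roh_islands",
    "LENGTH_CLASSES",
]

#: (upper bound in Mb, label); bounds are low-exclusive / high-inclusive.
LENGTH_CLASSES = [
    (2.0, "<2 Mb"),
    (4.0, "2-4 Mb"),
    (8.0, "4-8 Mb"),
    (16.0, "8-16 Mb"),
    (np.inf, ">16 Mb"),
]


@dataclass(frozen=True)
class ROHParams:
    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 1
    window_threshold: float = 0.05
    min_snps: int = 30
    min_length_kb: float = 500.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if min(
            self.window_snps,
            self.min_snps,
            self.min_length_kb,
            self.max_density_kb_per_snp,
            self.max_gap_kb,
        ) <= 0:
            raise ValueError("ROH parameters must be positive")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must lie in (0, 1]")


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of length-w windows over the last axis."""
    cs = np.cumsum(x, axis=-1, dtype=np.int64)
    cs = np.concatenate([np.zeros((*x.shape[:-1], 1), dtype=np.int64), cs], axis=-1)
    return cs[..., w:] - cs[..., :-w]


def _eligibility_matrix(
    calls: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Per-individual, per-marker ROH eligibility for one chromosome block.

    ``calls`` has shape (n_individuals, m_markers) for one chromosome.
    Windows truncate to the chromosome if it is shorter than the nominal
    window, so short chromosomes are still scanned.
    """
    n, m = calls.shape
    w = min(params.window_snps, m)
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    het_w = _window_sums(het, w)  # (n, m - w + 1) window het counts
    mis_w = _window_sums(mis, w)
    hom_window = (het_w <= params.window_het_max) & (mis_w <= params.window_missing_max)
    # marker j is covered by window starts in [max(0, j-w+1), min(j, m-w)]
    hw = hom_window.astype(np.int64)
    cum = np.concatenate([np.zeros((n, 1), dtype=np.int64), np.cumsum(hw, axis=1)], axis=1)
    starts_lo = np.maximum(0, np.arange(m) - w + 1)
    starts_hi = np.minimum(np.arange(m), m - w)
    n_windows = starts_hi - starts_lo + 1
    hom_count = cum[:, starts_hi + 1] - cum[:, starts_lo]
    frac = hom_count / n_windows
    return frac >= params.window_threshold - 1e-12


def window_homozygosity_calls(
    calls: np.ndarray, markers: pd.DataFrame, params: ROHParams = ROHParams()
) -> np.ndarray:
    """Fraction of overlapping homozygous windows per marker, one individual.

    ``calls`` is a single individual's dosage vector aligned with
    ``markers`` (sorted by chromosome and position).
    """
    calls = np.asarray(calls)
    chrom = markers["chromosome"].to_numpy()
    out = np.zeros(len(calls))
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        block = calls[sel][None, :]
        n, m = block.shape
        w = min(params.window_snps, m)
        het = (block == 1).astype(np.int64)
        mis = (block == MISSING).astype(np.int64)
        hom_window = (
            (_window_sums(het, w) <= params.window_het_max)
            & (_window_sums(mis, w) <= params.window_missing_max)
        ).astype(np.int64)
        cum = np.concatenate([np.zeros((1, 1), dtype=np.int64), np.cumsum(hom_window, axis=1)], axis=1)
        starts_lo = np.maximum(0, np.arange(m) - w + 1)
        starts_hi = np.minimum(np.arange(m), m - w)
        out[sel] = (cum[0, starts_hi + 1] - cum[0, starts_lo]) / (starts_hi - starts_lo + 1)
    return out


def call_roh(ds: GenotypeDataset, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Call ROH segments for every individual in the dataset.

    Returns one row per segment: sample_id, chromosome, start/end bp
    (first/last member marker positions, 1-based inclusive), n_snps,
    length_kb, and length_class.
    """
    ds = ds.sorted_by_position()
    chrom = ds.markers["chromosome"].to_numpy()
    pos = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    ids = ds.samples["sample_id"].to_numpy()
    pops = ds.samples.get("population", pd.Series(["ALL"] * ds.n_samples)).to_numpy()

    rows: list[dict] = []
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        p_c = pos[sel]
        gap_break = np.zeros(len(sel), dtype=bool)
        if len(sel) > 1:
            gap_break[1:] = np.diff(p_c) > params.max_gap_kb * 1000.0
        elig = _eligibility_matrix(ds.calls[:, sel], params)
        for i in range(ds.n_samples):
            e = elig[i]
            # run starts where eligibility begins or a gap splits the run
            run_start = np.flatnonzero(np.concatenate([[e[0]], (e[1:] & (~e[:-1] | gap_break[1:]))]))
            run_end_mask = np.concatenate([(e[:-1] & (~e[1:] | gap_break[1:])), [e[-1]]])
            run_end = np.flatnonzero(run_end_mask)
            for s, t in zip(run_start, run_end):
                n_snps = t - s + 1
                length_kb = (p_c[t] - p_c[s]) / 1000.0
                if n_snps < params.min_snps:
                    continue
                if length_kb < params.min_length_kb:
                    continue
                if length_kb / n_snps > params.max_density_kb_per_snp:
                    continue
                rows.append(
                    {
                        "sample_id": ids[i],
                        "population": pops[i],
                        "chromosome": str(c),
                        "start_bp": int(p_c[s]),
                        "end_bp": int(p_c[t]),
                        "n_snps": int(n_snps),
                        "length_kb": float(length_kb),
                    }
                )
    seg = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "population",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "length_kb",
        ],
    )
    return classify_roh(seg)


def classify_roh(segments: pd.DataFrame) -> pd.DataFrame:
    """Assign the five length classes; bounds low-exclusive, high-inclusive."""
    seg = segments.copy()
    labels = []
    for kb in seg.get("length_kb", pd.Series(dtype=float)):
        mb = kb / 1000.0
        for upper, label in LENGTH_CLASSES:
            if mb <= upper:
                labels.append(label)
                break
    seg["length_class"] = pd.Series(labels, index=seg.index, dtype=object)
    return seg


def roh_summary(segments: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Population-level ROH metrics including zero-count individuals."""
    rows = []
    for pop, grp in samples.groupby("population", observed=True):
        ids = grp["sample_id"]
        seg = segments[segments["sample_id"].isin(ids)]
        counts = seg.groupby("sample_id").size().reindex(ids, fill_value=0)
        rows.append(
            {
                "population": pop,
                "n_individuals": len(ids),
                "min_per_individual": int(counts.min()) if len(counts) else 0,
                "max_per_individual": int(counts.max()) if len(counts) else 0,
                "mean_per_individual": float(counts.mean()) if len(counts) else 0.0,
                "sd_per_individual": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                "total": int(len(seg)),
                "mean_length_kb": float(seg["length_kb"].mean()) if len(seg) else 0.0,
                "sd_length_kb": float(seg["length_kb"].std(ddof=1)) if len(seg) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    order = np.argsort(starts)
    total = 0
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return int(total)


def chromosome_coverage(
    segments: pd.DataFrame,
    markers: pd.DataFrame,
    n_individuals: int,
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean per-individual fraction of each chromosome covered by ROH.

    Chromosome length defaults to the last marker position (a proxy);
    real assembly lengths can be supplied.  Coverage is the average over
    all individuals of each one's ROH interval-union length.
    """
    chroms = list(dict.fromkeys(markers["chromosome"].astype(str)))
    lengths = chromosome_lengths or {
        c: int(markers.loc[markers["chromosome"].astype(str) == c, "position_bp"].max())
        for c in chroms
    }
    rows = []
    for c in chroms:
        seg_c = segments[segments["chromosome"].astype(str) == c]
        covered = 0
        for _, grp in seg_c.groupby("sample_id"):
            covered += _union_length(
                grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()
            )
        rows.append(
            {
                "chromosome": c,
                "length_bp": lengths[c],
                "percent_covered": 100.0 * covered / (n_individuals * lengths[c])
                if n_individuals
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def roh_islands(
    segments: pd.DataFrame,
    ds: GenotypeDataset,
    freq_threshold: float = 0.5,
) -> pd.DataFrame:
    """Population hotspots: runs of markers inside an ROH in >= threshold.

    The in-ROH frequency of a marker is the fraction of individuals whose
    segment set covers its position; maximal runs of consecutive markers
    at or above the threshold become islands with bp bounds, member
    markers, and peak frequency.
    """
    ds = ds.sorted_by_position()
    chrom = ds.markers["chromosome"].to_numpy()
    pos = ds.markers["position_bp"].to_numpy(dtype=np.int64)
    mids = ds.markers["marker_id"].to_numpy()
    n = ds.n_samples

    freq = np.zeros(ds.n_markers)
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        cover = np.zeros(len(sel))
        seg_c = segments[segments["chromosome"].astype(str) == str(c)]
        for _, row in seg_c.iterrows():
            inside = (pos[sel] >= row["start_bp"]) & (pos[sel] <= row["end_bp"])
            cover[inside] += 1.0
        freq[sel] = cover / n if n else 0.0

    rows = []
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        hot = freq[sel] >= freq_threshold
        if not hot.any():
            continue
        start = np.flatnonzero(np.concatenate([[hot[0]], hot[1:] & ~hot[:-1]]))
        end = np.flatnonzero(np.concatenate([hot[:-1] & ~hot[1:], [hot[-1]]]))
        for s, t in zip(start, end):
            rows.append(
                {
                    "chromosome": str(c),
                    "start_bp": int(pos[sel][s]),
                    "end_bp": int(pos[sel][t]),
                    "n_markers": int(t - s + 1),
                    "marker_ids": ",".join(mids[sel][s : t + 1]),
                    "peak_frequency": float(freq[sel][s : t + 1].max()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "n_markers",
            "marker_ids",
            "peak_frequency",
        ],
    )
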