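"""Tiered genotype quality control with attrition accounting.

Two profiles mirror how SNP-array studies tailor QC to the analysis:

* ``roh`` — call-rate filters only (sample call rate, then marker call
  rate), keeping rare homozygous stretches intact for ROH detection;
* ``full`` — call-rate filters plus autosome restriction, minor-allele
  frequency >= 0.05, and a Hardy-Weinberg exact-test p-value >= 1e-6,
  applied sequentially in that order.

The report lists markers/samples removed by each criterion in application
order so that initial - sum(removed) = final along both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_call_rate",
    "filter_autosomes",
    "marker_maf",
    "hwe_exact_test",
    "run_qc",
    "DEFAULT_AUTOSOMES",
]

#: Cattle autosome labels (BTA1-29).
DEFAULT_AUTOSOMES = frozenset(str(c) for c in range(1, 30))


@dataclass(frozen=True)
class QCThresholds:
    animal_call_rate: float = 0.95
    marker_call_rate: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6


@dataclass
class QCReport:
    """Per-criterion attrition counts for one population/profile."""

    profile: str
    initial_samples: int
    initial_markers: int
    removed: dict[str, int] = field(default_factory=dict)
    final_samples: int = 0
    final_markers: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": name, "removed": count}
            for name, count in self.removed.items()
        ]
        rows.append({"criterion": "final_samples", "removed": self.final_samples})
        rows.append({"criterion": "final_markers", "removed": self.final_markers})
        return pd.DataFrame(rows)


def filter_call_rate(
    ds: GenotypeDataset, animal_min: float = 0.95, marker_min: float = 0.95
) -> tuple[GenotypeDataset, int, int]:
    """Drop low-call-rate samples first, then low-call-rate markers.

    Returns ``(filtered, n_samples_removed, n_markers_removed)``.  Marker
    call rates are recomputed on the surviving samples, matching the
    sequential attrition accounting of array-QC reports.
    """
    if not (0.0 <= animal_min <= 1.0 and 0.0 <= marker_min <= 1.0):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    keep_s = ds.sample_call_rate() >= animal_min
    ds2 = ds.take_samples(np.flatnonzero(keep_s)) if not keep_s.all() else ds
    keep_m = ds2.marker_call_rate() >= marker_min
    ds3 = ds2.take_markers(np.flatnonzero(keep_m)) if not keep_m.all() else ds2
    return ds3, int((~keep_s).sum()), int((~keep_m).sum())


def filter_autosomes(
    ds: GenotypeDataset, autosome_labels: frozenset[str] | set[str] = DEFAULT_AUTOSOMES
) -> tuple[GenotypeDataset, int]:
    """Keep only markers on the listed autosome labels."""
    keep = ds.markers["chromosome"].astype(str).isin(autosome_labels).to_numpy()
    if keep.all():
        return ds, 0
    return ds.take_markers(np.flatnonzero(keep)), int((~keep).sum())


def marker_maf(ds: GenotypeDataset) -> np.ndarray:
    """Minor-allele frequency per marker over non-missing calls.

    Markers with no observed calls get NaN (an undefined-MAF signal).
    """
    p = ds.allele_freqs()
    return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))


@lru_cache(maxsize=100_000)
def _hwe_het_probs(n_het_obs: int, n_hom1: int, n_hom2: int) -> tuple[float, ...]:
    """Conditional probabilities of every possible heterozygote count.

    Given the total genotype count and the minor-allele count, enumerate
    P(n_het | allele counts) by the standard recurrence of the exact
    conditional test (Wigginton et al. style, plain p).
    """
    n = n_het_obs + n_hom1 + n_hom2
    n_a = 2 * min(n_hom1, n_hom2) + n_het_obs  # minor allele count
    het_min = n_a % 2
    probs = {}
    # start from the maximum heterozygote count and recurse downward:
    # P(h-2)/P(h) = h(h-1) / (4 (hom1+1)(hom2+1)) with hom counts at h
    h_max = min(n_a, 2 * n - n_a)
    probs[h_max] = 1.0
    h = h_max
    while h - 2 >= het_min:
        hom_minor = (n_a - h) // 2
        hom_major = n - h - hom_minor
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_minor + 1) * (hom_major + 1))
        h -= 2
    total = sum(probs.values())
    out = np.zeros(h_max + 1)
    for h, v in probs.items():
        out[h] = v / total
    return tuple(out)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts.

    Sums the conditional probabilities (given allele counts) of all
    heterozygote counts no more probable than the observed one.
    """
    if min(n_hom1, n_het, n_hom2) < 0 or n_hom1 + n_het + n_hom2 < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    probs = np.asarray(_hwe_het_probs(n_het, n_hom1, n_hom2))
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


def _hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    hom1 = (ds.calls == 2).sum(axis=0)
    het = (ds.calls == 1).sum(axis=0)
    hom2 = (ds.calls == 0).sum(axis=0)
    out = np.ones(ds.n_markers)
    for j in range(ds.n_markers):
        if hom1[j] + het[j] + hom2[j] >= 1:
            out[j] = hwe_exact_test(int(hom1[j]), int(het[j]), int(hom2[j]))
    return out


def run_qc(
    ds: GenotypeDataset,
    profile: str = "full",
    thresholds: QCThresholds = QCThresholds(),
    autosome_labels: frozenset[str] | set[str] = DEFAULT_AUTOSOMES,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the tiered QC profile sequentially and account for attrition.

    ``roh`` applies only the two call-rate filters; ``full`` continues
    with autosome restriction, MAF >= ``maf_min`` (remove MAF < threshold)
    and exact-HWE p >= ``hwe_p_min``.  HWE is computed within the dataset
    given, which is expected to be a single population.
    """
    if profile not in ("roh", "full"):
        raise ValueError(f"unknown QC profile: {profile!r}")
    report = QCReport(
        profile=profile,
        initial_samples=ds.n_samples,
        initial_markers=ds.n_markers,
    )

    ds, n_s, n_m = filter_call_rate(
        ds, thresholds.animal_call_rate, thresholds.marker_call_rate
    )
    report.removed["animal_call_rate"] = n_s
    report.removed["marker_call_rate"] = n_m
    _check_nonempty(ds, "call rate")

    if profile == "full":
        ds, n_auto = filter_autosomes(ds, autosome_labels)
        report.removed["non_autosomal"] = n_auto
        _check_nonempty(ds, "autosome filter")

        maf = marker_maf(ds)
        keep = ~(np.isnan(maf) | (maf < thresholds.maf_min))
        report.removed["maf"] = int((~keep).sum())
        ds = ds.take_markers(np.flatnonzero(keep))
        _check_nonempty(ds, "MAF filter")

        hwe_p = _hwe_pvalues(ds)
        keep = hwe_p >= thresholds.hwe_p_min
        report.removed["hwe"] = int((~keep).sum())
        ds = ds.take_markers(np.flatnonzero(keep))
        _check_nonempty(ds, "HWE filter")

    report.final_samples = ds.n_samples
    report.final_markers = ds.n_markers
    return ds, report


def _check_nonempty(ds: GenotypeDataset, stage: str) -> None:
    if ds.n_samples == 0 or ds.n_markers == 0:
        raise ValueError(f"dataset empty after {stage} stage")


def qc_report_table(reports: dict[str, QCReport]) -> pd.DataFrame:
    """Combine per-population reports into a criteria x populations table."""
    cols = {}
    for popname, rep in reports.items():
        col = dict(rep.removed)
        col["final_samples"] = rep.final_samples
        col["final_markers"] = rep.final_markers
        cols[popname] = col
    return pd.DataFrame(cols).fillna(0).astype(int)
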