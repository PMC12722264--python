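"""Synthetic multi-population SNP-array genotypes with known ground truth.

The generator emulates the structure of breed-association panels: several
populations descended from a shared founder gene pool, linkage
disequilibrium that decays with physical distance, Balding-Nichols
frequency divergence between populations on a controllable F_ST scale,
planted autozygous segments, and birth years with optional per-marker
allele-frequency trends plus a polygenic (GRM-correlated) component.

Model
-----
* A founder pool of ``founder_pool_size`` haplotypes per genome carries
  allele frequencies drawn uniformly on ``[maf_floor, 1 - maf_floor]``.
* Sample haplotypes are mosaics of founder haplotypes: the copied founder
  switches between adjacent markers with probability
  ``1 - exp(-recombination_rate * mosaic_generations * d_Mb)``, i.e.
  crossovers accumulated over ``mosaic_generations`` meioses.  The finite
  pool is the sole source of LD, so LD strength scales with
  ``1/founder_pool_size`` and decays with the switch rate.
* Population divergence follows the Balding-Nichols model: the population
  frequency of each marker is a Beta draw with mean equal to the realized
  founder-pool frequency and variance ``F * p * (1 - p)``, where
  ``F = divergence_fst``; mosaic alleles are then flipped at the minimal
  rate that moves the marginal frequency to the drawn value, preserving
  as much of the shared haplotype structure as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "FounderPool",
    "make_founder_pool",
    "draw_population",
    "plant_autozygosity",
    "assign_birth_years_with_trend",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genotype generator.

    Attributes
    ----------
    n_populations, n_per_population, n_markers
        Shape of the study: populations, diploid individuals per
        population, markers spread over the chromosomes proportionally to
        length (evenly spaced, array-like).
    chromosome_lengths_bp
        Physical chromosome lengths; defaults to five 50-Mb autosomes,
        giving SNP-array-like marker spacing at the default marker count.
    founder_pool_size
        Haplotypes in the shared founder pool; smaller pools mean stronger
        LD and stronger shared gametic phase between populations.
    recombination_rate
        Expected crossovers per Mb per meiosis (cattle-like 0.01 = 1 cM/Mb).
    mosaic_generations
        Meioses separating sampled haplotypes from the founder pool; the
        product with ``recombination_rate`` sets the LD decay scale.
    divergence_fst
        Balding-Nichols F for every population (pairwise F_ST target).
    maf_floor
        Minimum founder minor-allele frequency.
    roh_plan
        List of ``(individual_fraction, segment_length_bp)`` autozygous
        segments to plant (one genomic interval per entry, copied into the
        given fraction of individuals).
    trend_plan
        List of ``(marker_index, frequency_change_per_year)`` selected
        markers whose genotypes are re-drawn against birth year.
    birth_year_range
        Inclusive (first, last) birth years.
    polygenic_pve
        Target proportion of birth-year variance explained by the genomic
        relationship matrix.
    seed
        Mandatory RNG seed; all output is bit-reproducible given the seed.
    """

    seed: int
    n_populations: int = 2
    n_per_population: int = 200
    n_markers: int = 5_000
    chromosome_lengths_bp: tuple[int, ...] = (50_000_000,) * 5
    founder_pool_size: int = 50
    recombination_rate: float = 0.01
    mosaic_generations: int = 30
    divergence_fst: float = 0.0
    maf_floor: float = 0.05
    roh_plan: tuple[tuple[float, int], ...] = ()
    trend_plan: tuple[tuple[int, float], ...] = ()
    birth_year_range: tuple[int, int] = (1961, 2024)
    polygenic_pve: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must lie in [0, 1)")
        if not 0.0 < self.maf_floor <= 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5]")
        if self.founder_pool_size < 2:
            raise ValueError("founder pool needs at least 2 haplotypes")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (start, end) with start <= end")


@dataclass
class SimTruth:
    """Ground truth recorded while generating a dataset."""

    planted_roh: list[tuple[str, str, int, int]] = field(default_factory=list)
    selected_markers: list[tuple[str, float]] = field(default_factory=list)
    realized_founder_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "planted_roh": [list(t) for t in self.planted_roh],
            "selected_markers": [list(t) for t in self.selected_markers],
            "realized_founder_freqs": {
                k: np.asarray(v).tolist() for k, v in self.realized_founder_freqs.items()
            },
            "warnings": list(self.warnings),
        }


@dataclass
class FounderPool:
    """Founder haplotypes and the marker map they live on."""

    haplotypes: np.ndarray  # (pool_size, n_markers) of {0, 1}
    markers: pd.DataFrame
    config: SimConfig

    @property
    def freqs(self) -> np.ndarray:
        """Realized allele-1 frequency of each marker in the pool."""
        return self.haplotypes.mean(axis=0)


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform random marker positions allocated to chromosomes by length.

    Random placement reproduces the irregular inter-marker spacing of
    real arrays, so every LD-decay distance bin receives pairs.
    """
    lengths = np.asarray(config.chromosome_lengths_bp, dtype=np.int64)
    weights = lengths / lengths.sum()
    counts = np.floor(weights * config.n_markers).astype(int)
    # distribute the remainder to the longest chromosomes first
    for i in np.argsort(-lengths)[: config.n_markers - counts.sum()]:
        counts[i] += 1
    rows = []
    pairs = np.array([["A", "G"], ["A", "C"], ["T", "C"], ["T", "G"]])
    pick = rng.integers(0, len(pairs), size=config.n_markers)
    k = 0
    for c, (length, m_c) in enumerate(zip(lengths, counts), start=1):
        pos = np.sort((rng.random(m_c) * (length - 1)).astype(np.int64) + 1)
        while len(np.unique(pos)) < m_c:  # resolve rare collisions
            pos = np.unique(pos)
            extra = (rng.random(m_c - len(pos)) * (length - 1)).astype(np.int64) + 1
            pos = np.sort(np.concatenate([pos, extra]))
        for j in range(m_c):
            a1, a2 = pairs[pick[k]]
            rows.append(
                {
                    "marker_id": f"snp{c}_{j + 1}",
                    "chromosome": str(c),
                    "position_bp": int(pos[j]),
                    "allele_a1": a1,
                    "allele_a2": a2,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def make_founder_pool(config: SimConfig) -> FounderPool:
    """Draw the shared founder haplotype pool for a simulation."""
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    markers = _marker_map(config, rng)
    target = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=config.n_markers)
    haplotypes = (
        rng.random((config.founder_pool_size, config.n_markers)) < target
    ).astype(np.uint8)
    return FounderPool(haplotypes=haplotypes, markers=markers, config=config)


def _switch_probs(pool: FounderPool) -> np.ndarray:
    """Per-interval founder-switch probability (1.0 across chromosome breaks)."""
    cfg = pool.config
    pos = pool.markers["position_bp"].to_numpy(dtype=np.float64)
    chrom = pool.markers["chromosome"].to_numpy()
    d_mb = np.diff(pos) / 1e6
    lam = cfg.recombination_rate * cfg.mosaic_generations
    probs = 1.0 - np.exp(-lam * np.maximum(d_mb, 0.0))
    probs[chrom[1:] != chrom[:-1]] = 1.0
    return probs


def _mosaic_haplotypes(
    pool: FounderPool, n_haplotypes: int, rng: np.random.Generator
) -> np.ndarray:
    """Build mosaic haplotypes by copying founder segments with crossovers."""
    m = pool.markers.shape[0]
    switch = rng.random((n_haplotypes, m - 1)) < _switch_probs(pool) if m > 1 else np.zeros((n_haplotypes, 0), bool)
    seg_id = np.zeros((n_haplotypes, m), dtype=np.int64)
    if m > 1:
        seg_id[:, 1:] = np.cumsum(switch, axis=1)
    founders = rng.integers(0, pool.config.founder_pool_size, size=(n_haplotypes, m))
    chosen = np.take_along_axis(founders, seg_id, axis=1)
    return pool.haplotypes[chosen, np.arange(m)[None, :]]


def draw_population(
    pool: FounderPool, config: SimConfig, population_index: int
) -> GenotypeDataset:
    """Sample one diverged population of diploid genotypes from the pool.

    Divergence is Balding-Nichols: per-marker population frequencies are
    Beta draws with mean at the realized pool frequency and variance
    ``F p (1-p)``; mosaic haplotype alleles are flipped 0->1 or 1->0 at the
    minimal marginal rate that reaches the drawn frequency.
    """
    root = np.random.SeedSequence([config.seed, 1 + population_index])
    rng = np.random.default_rng(root)
    n = config.n_per_population
    m = pool.markers.shape[0]
    p = pool.freqs.astype(np.float64)
    F = config.divergence_fst

    if F > 0.0:
        poly = (p > 0.0) & (p < 1.0)
        q = p.copy()
        ab_scale = (1.0 - F) / F
        q[poly] = rng.beta(p[poly] * ab_scale, (1.0 - p[poly]) * ab_scale)
        q = np.clip(q, 0.01, 0.99)
        q[~poly] = p[~poly]
    else:
        q = p

    haps = _mosaic_haplotypes(pool, 2 * n, rng)

    if F > 0.0:
        # minimal-rate flips: raise 0s where q > p, lower 1s where q < p
        with np.errstate(divide="ignore", invalid="ignore"):
            up = np.where(p < 1.0, np.clip((q - p) / (1.0 - p), 0.0, 1.0), 0.0)
            down = np.where(p > 0.0, np.clip((p - q) / p, 0.0, 1.0), 0.0)
        u = rng.random(haps.shape)
        haps = np.where((haps == 0) & (u < up[None, :]), 1, haps)
        haps = np.where((haps == 1) & (u < down[None, :]), 0, haps)

    calls = (haps[0::2] + haps[1::2]).astype(np.uint8)

    if config.missing_rate > 0.0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    label = f"POP{population_index + 1}"
    samples = pd.DataFrame(
        {
            "sample_id": [f"{label}_{i + 1:04d}" for i in range(n)],
            "population": label,
            "birth_year": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    return GenotypeDataset(samples, pool.markers.copy(), calls)


def plant_autozygosity(
    ds: GenotypeDataset,
    roh_plan: tuple[tuple[float, int], ...],
    seed: int,
) -> tuple[GenotypeDataset, SimTruth]:
    """Force autozygosity over planned intervals by collapsing heterozygotes.

    Each plan entry ``(fraction, length_bp)`` picks one random genomic
    interval and a random ``round(fraction * n)`` subset of individuals; in
    those individuals every heterozygous call inside the interval is
    replaced by a random homozygote (one haplotype copied over the other).
    Exact interval bounds per carrier are recorded in the returned truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    truth = SimTruth()
    calls = ds.calls.copy()
    pos = ds.markers["position_bp"].to_numpy()
    chrom = ds.markers["chromosome"].to_numpy()
    chrom_ids = list(dict.fromkeys(chrom))
    chrom_max = {c: pos[chrom == c].max() for c in chrom_ids}

    for fraction, length in roh_plan:
        length = int(length)
        fitting = [c for c in chrom_ids if chrom_max[c] > length]
        if not fitting:
            raise ValueError(
                f"planned segment of {length} bp exceeds every chromosome"
            )
        c = fitting[rng.integers(len(fitting))]
        start = int(rng.integers(1, chrom_max[c] - length + 1))
        end = start + length - 1
        inside = (chrom == c) & (pos >= start) & (pos <= end)
        n_carriers = max(1, round(fraction * ds.n_samples))
        carriers = rng.choice(ds.n_samples, size=n_carriers, replace=False)
        for i in carriers:
            row = calls[i, inside]
            het = row == 1
            row[het] = 2 * rng.integers(0, 2, size=int(het.sum())).astype(np.uint8)
            calls[i, inside] = row
            truth.planted_roh.append(
                (str(ds.samples["sample_id"].iloc[i]), str(c), start, end)
            )
    out = GenotypeDataset(ds.samples.copy(), ds.markers.copy(), calls)
    return out, truth


def assign_birth_years_with_trend(
    ds: GenotypeDataset,
    trend_plan: tuple[tuple[int, float], ...],
    birth_year_range: tuple[int, int],
    polygenic_pve: float,
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Assign birth years and re-draw trend-marker genotypes against year.

    Years are uniform over the range.  When ``polygenic_pve > 0`` the year
    ranks follow a latent score ``sqrt(p') * g + sqrt(1-p') * e`` with
    ``g`` drawn from the realized genomic relationship structure.  The
    Gaussian-to-uniform rank transform attenuates the linear variance
    share by the factor 3/pi (Stein's lemma on cov(Phi(z), g)), so the
    latent share is set to ``p' = pve * pi / 3`` to meet the REML target
    in expectation.  Each trend marker ``(index, slope)`` is re-drawn per
    individual from ``Binomial(2, p0 + slope * (year - start))`` with
    ``p0`` centred so the trajectory straddles the marker's frequency.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    truth = truth if truth is not None else SimTruth()
    n = ds.n_samples
    start, end = birth_year_range
    span = end - start

    if polygenic_pve > 0.0:
        from bovpop.popgen_stats import grm_vanraden

        G = grm_vanraden(ds).values
        L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
        g = L @ rng.standard_normal(n)
        g = (g - g.mean()) / g.std()
        e = rng.standard_normal(n)
        # compensate the 3/pi attenuation of the rank-uniform transform
        share = min(polygenic_pve * np.pi / 3.0, 0.999)
        latent = np.sqrt(share) * g + np.sqrt(1.0 - share) * e
        order = np.argsort(latent, kind="stable")
        years = np.empty(n, dtype=np.int64)
        # uniform grid over the range, assigned in latent order
        grid = start + np.floor((np.arange(n) + 0.5) * (span + 1) / n).astype(np.int64)
        years[order] = np.minimum(grid, end)
    else:
        years = rng.integers(start, end + 1, size=n)

    calls = ds.calls.copy()
    freqs = ds.allele_freqs()
    for idx, slope in trend_plan:
        if not 0 <= idx < ds.n_markers:
            raise ValueError(f"trend marker index {idx} outside the map")
        p_mid = freqs[idx] if np.isfinite(freqs[idx]) else 0.5
        p0 = p_mid - slope * span / 2.0
        p_end = p0 + slope * span
        if not (0.0 < p0 < 1.0 and 0.0 < p_end < 1.0):
            truth.warnings.append(
                f"trend at marker {idx}: trajectory [{p0:.3f}, {p_end:.3f}] "
                "leaves (0,1) and is clipped"
            )
        p_year = np.clip(p0 + slope * (years - start), 0.01, 0.99)
        calls[:, idx] = rng.binomial(2, p_year).astype(np.uint8)
        truth.selected_markers.append(
            (str(ds.markers["marker_id"].iloc[idx]), float(slope))
        )

    samples = ds.samples.copy()
    samples["birth_year"] = pd.array(years, dtype="Int64")
    return GenotypeDataset(samples, ds.markers.copy(), calls), truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """End-to-end simulation: pool, populations, planted ROH, birth years.

    Returns a single combined dataset (populations labelled ``POP1`` ...)
    and the ground truth.  Fully deterministic given ``config.seed``.
    """
    pool = make_founder_pool(config)
    parts = [
        draw_population(pool, config, k) for k in range(config.n_populations)
    ]
    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    calls = np.vstack([p.calls for p in parts])
    ds = GenotypeDataset(samples, pool.markers.copy(), calls)

    truth = SimTruth(realized_founder_freqs={"pool": pool.freqs})
    if config.roh_plan:
        ds, roh_truth = plant_autozygosity(ds, config.roh_plan, config.seed)
        truth.planted_roh = roh_truth.planted_roh
    ds, truth = assign_birth_years_with_trend(
        ds,
        config.trend_plan,
        config.birth_year_range,
        config.polygenic_pve,
        config.seed,
        truth=truth,
    )
    return ds, truth
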