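# Methods

This note documents the statistical models and procedures implemented
in `bovpop`, the assumptions behind them, the synthetic-data generator
used to validate them, and the numerical and design choices made where
the underlying methodology left the choice open.

## Data model

Genotypes are diploid biallelic dosage calls (0/1/2 copies of allele
A1) with a dedicated missing code, stored SNP-major in PLINK 1
bed/bim/fam.  Population labels and birth years travel in a sidecar
TSV keyed by `sample_id`, because fam files have no field for either.
When several populations are combined, marker sets are intersected and
oriented to the first dataset's A1/A2: swapped-allele markers are
flipped 0↔2; markers whose allele pairs cannot be reconciled are
dropped, as are strand-ambiguous A/T and C/G markers — for those the
sign of gametic-phase statistics is meaningless if the genotyping
strand cannot be resolved, and a phase analysis with indeterminate
signs is worse than a smaller marker panel.

## Quality control

Two sequential profiles, with attrition counted per criterion so that
`initial − Σ removed = final` along both axes:

* **roh** — samples with call rate < 0.95 removed first, then markers
  with call rate < 0.95 on the survivors.  Nothing else: MAF and
  Hardy–Weinberg filters would preferentially delete exactly the
  low-heterozygosity markers that ROH detection needs.
* **full** — the call-rate filters, then non-autosomal markers
  (default labels 1–29, the cattle autosomes), then MAF (keep ≥ 0.05),
  then the Hardy–Weinberg exact test (keep p ≥ 1e-6).

The HWE test is the exact conditional test (plain p, no mid-p): given
the allele counts, the probability of each heterozygote count follows
a one-parameter distribution computed by the standard downward
recurrence, and the p-value sums all outcomes no more probable than
the observed one.  It is validated against a full multinomial
enumeration oracle for every genotype configuration with n ≤ 10.  HWE
is applied within population — pooled samples would fail HWE merely
because of the Wahlund effect.

## Relationships, diversity, differentiation

**GRM.** G = (M − 2P)(M − 2P)′ / 2Σpᵢ(1 − pᵢ) with allele frequencies
estimated from the analyzed sample and missing calls mean-imputed to
2pᵢ before centering (the convention of the formula's source; it
leaves imputed entries with zero centered contribution).  For an
outbred Hardy–Weinberg sample the expected diagonal is 1, which is one
of the verification quantities.  PCA takes the top-k eigenpairs of a
relationship matrix; scores are eigenvectors scaled by √eigenvalue and
explained fractions are eigenvalues over the trace.  Two scalings are
offered: VanRaden (each SNP weighted by its variance) and per-SNP
standardized (each SNP's covariance divided by its own variance); the
pipeline's PCA defaults to the per-SNP standardized form.

**Diversity.** HO per individual is the heterozygote share of its
non-missing calls; HE per population is the mean over markers of
2p(1−p).  The allele-sharing proportion between two individuals is
s = (IBS₂ + 0.5·IBS₁)/m over mutually non-missing loci, equal to
1 − mean(|gᵢ − gⱼ|)/2; both s and the distance 1 − s are reported
per pair and in the population summary, because the two conventions
coexist in the literature and the tabulated values (~0.68–0.70 for
within-breed cattle panels) do not disambiguate which was printed.

**F_ST.** The Weir–Cockerham (1984) two-population estimator from
genotype counts, with the observed heterozygosity correction, per
marker.  Markers monomorphic in the pooled sample are excluded (count
reported); negative per-marker values are retained — truncating them
at zero biases the mean upward.  Two genome-wide summaries are
reported: the per-marker mean ± SD (the usual table format) and the
multilocus ratio-of-sums Σa / Σ(a+b+c).  **These are not
interchangeable**: with only two populations the per-marker θ is a
ratio with a 1-d.f. noisy numerator, and averaging ratios is biased
toward zero (≈ 0.118 when the true divergence is 0.15, verified
against an independent enumeration-free Balding–Nichols simulation).
Parameter recovery must therefore be judged on the multilocus
estimator, which is unbiased for the divergence parameter; the
per-marker mean is still reported because that is the quantity most
published tables show.

## Phylogeny

Populations are summarized by mean genotype vectors (per marker, mean
of non-missing dosages; markers unobserved in any population are
dropped everywhere).  The distance between populations is
mean|Δmean|/2 — a normalized mean allele-sharing mismatch bounded in
[0, 1].  This concrete form was an open choice (mean-genotype "IBS"
distance is not uniquely defined); it was chosen over Euclidean
distance because it is linear in per-marker differences and maximal
(1.0) exactly at fixation for opposite alleles.  Trees come from
canonical Saitou–Nei Neighbor-Joining with deterministic smallest-index
tie-breaking; negative branch lengths are clamped to zero with the
deficit moved to the sibling edge so path lengths are preserved.  NJ
is exact on additive inputs: on 100 random 8-taxon tree metrics the
implementation reproduces every leaf-to-leaf path length to < 1e-9
(and therefore the topology).  scikit-bio's independent NJ is used as
a cross-check in the test suite; trees serialize via scikit-bio
TreeNode to standard Newick.  Output trees are unrooted.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over mutually
non-missing individuals (the composite genotypic measure appropriate
for unphased array data).  Gametic D = f(AB) − f(A)f(B) and
D′ = D/D_max come from two-locus haplotype frequencies estimated by EM
over unphased genotypes: double heterozygotes are split between the
coupling and repulsion phases by the current odds
f(AB)f(ab) / (f(AB)f(ab) + f(Ab)f(aB)), iterated to |Δf| < 1e-10
(cap 1000 iterations; convergence is flagged per pair).  EM output is
checked for marginal consistency (haplotype frequencies reproduce the
allele frequencies to 1e-8).

The genome scan enumerates all intra-chromosomal pairs within 1 Mb
(no r² floor) using an offset-vectorized pass, so the scan is a few
matrix operations per inter-marker offset rather than a pair loop.
Decay bins are half-open low-inclusive — [10,20) … [90,100) kb, then
[100,200) … [900,1000] kb with the final bin closed — and a bin with
fewer than 50 pairs is flagged unreliable rather than dropped.  Pairs
under 10 kb stay in the raw table but outside the decay table.

Two thinning procedures: pairwise-r² pruning (windows of 50 SNPs,
step 5; within a window the later marker of any pair with r² above
the ceiling is removed — deterministic map-order tie-break) and VIF
pruning (same windows; iteratively remove the marker with the largest
diagonal of the inverse correlation matrix until all VIF ≤ 2; a tiny
ridge, 1e-10, makes exact collinearity read as effectively infinite
VIF so duplicates are removed first).  The guarantee both procedures
provide — and the property the tests re-check from raw genotypes — is
defined over the procedure's own window placements on the original
map; windows drawn over the surviving subsequence span wider genomic
ranges and are outside the guarantee.  Missing calls are mean-imputed
for pruning correlations only.

## Consistency of gametic phase

For each marker pair and population, the signed LD value is
√r² · sign(D), with sign(0) = 0 and D taken from the EM fit within
that population (LD is computed per population, then correlated
across).  The CGP curve is the Pearson correlation of these signed
values across the pair of populations, per distance bin, over marker
pairs with defined LD in both (complete case, counts logged).  A
whole-population allele relabeling leaves the curve unchanged
(flipping both loci of a pair preserves the sign); relabeling a single
locus in one population negates exactly that locus's pairs — both
properties are asserted in tests, and they are the reason
strand-ambiguous markers are dropped during harmonization.

## Runs of homozygosity

Detection follows the sliding-window consensus for array data with
all parameters at their conventional values: 50-SNP windows, a window
is "homozygous" if it has ≤ 1 heterozygous and ≤ 1 missing call, a
marker is eligible if ≥ 5% of the windows covering it are homozygous,
and maximal runs of consecutive eligible markers — split at
inter-marker gaps > 1 Mb — are reported if they have ≥ 30 SNPs,
≥ 500 kb, and ≤ 50 kb per SNP.  Segment coordinates are first/last
member marker positions.  Classes: (0,2], (2,4], (4,8], (8,16],
(16,∞) Mb — the class labels do not state boundary membership, so the
half-open convention here is a documented choice (16.0 Mb → "8-16 Mb").

Numerical details: windows truncate at chromosome ends (markers near
the termini are judged by the windows that fit; a chromosome shorter
than 50 SNPs is scanned with a single full-chromosome window), and
segment content is controlled only through the window rule — there is
no extra per-segment heterozygote cap.

Two intrinsic resolution limits of this window rule are worth stating
plainly, because they bound what any user should expect:

* a fully homozygous run of fewer than ~49 consecutive SNPs cannot
  produce a single qualifying window when the flanking background has
  realistic heterozygosity (~0.35 per marker), so ROH between the
  30-SNP reporting floor and the window span are systematically
  undetectable — in practice the shortest detectable ROH is set by
  the window length times the marker spacing, not by the 500-kb rule;
* segment ends are fuzzy by a few markers: a single het (or a
  homozygous-by-chance marker) adjacent to a true ROH is still
  window-eligible, so called boundaries wander outward past the true
  segment by an amount no detector could remove, since such flanking
  markers are statistically indistinguishable from ROH membership.

Both effects are quantified honestly by the verification script
(sensitivity is reported separately for all qualifying planted
segments and for window-supported ones; boundary precision is
reported as the fraction of recovered segments within one marker of
truth).

Islands: a marker's in-ROH frequency is the fraction of individuals
whose segment set covers its position (computed per marker, not per
window); maximal runs of markers at frequency ≥ 0.5 are islands with
bp bounds and peak frequency.  Chromosome coverage is the mean over
individuals of each one's ROH interval-union length divided by the
chromosome length (last marker position as proxy unless real lengths
are supplied).

## Generation-proxy selection mapping

The model is y = μ + xᵢbᵢ + g + e per marker, with y the birth years,
g ~ N(0, Gσ²_g) the polygenic term on the VanRaden GRM and
e ~ N(0, Iσ²_e).  Variance components are estimated once under the
null (no SNP) by REML: after eigendecomposition G = UΛU′, the
restricted likelihood is a one-dimensional function of the variance
ratio, maximized by bounded scalar search over log-ratio ∈ [−12, 12]
(a fit at either bound is flagged; the corresponding component is
effectively zero).  The eigen-path likelihood agrees with a direct
matrix-inversion oracle to < 1e-6.  PVE = σ²_g/(σ²_g+σ²_e).

The scan holds the variance *ratio* fixed at the null estimates and
tests each marker by GLS in the rotated basis, re-estimating the
absolute residual scale per marker from the GLS residuals (the
standard computational strategy for mixed-model association; per-SNP
REML would cost M times more for no inferential gain here).  The Wald
statistic is referred to t with n−2 degrees of freedom, which makes
the σ²_g = 0 limit exactly equal to ordinary simple regression and is
slightly conservative in the far tail relative to χ²(1).  The
candidate marker remains in G (non-LOCO), matching the plain
mixed-model-association mode this analysis conventionally uses; for
birth year as the response the proximal-contamination loss is
negligible because no single marker carries appreciable year variance
under the null.  Missing dosages are mean-imputed; monomorphic
markers are skipped with a reason.  Significance: α/M with α = 0.05
and M the number of markers tested after QC.  Q-Q data pairs sorted
observed −log₁₀p with −log₁₀((i−0.5)/M); the inflation factor is the
median association χ² over 0.4549.

Birth year is used as-is (continuous, unscaled); only internal mean
centering is applied.  No further fixed covariates are fitted — the
model contains exactly the mean, the SNP, and the polygenic term.

## Annotation and enrichment

Candidate markers (Bonferroni-significant scan hits, ROH-island
members) are expanded to ±100-kb windows, clipped at position 1 and
merged when they overlap.  Features come from local GFF3 or TSV
interval tables only — gene and QTL counts depend on the annotation
database version, so no live lookups are performed and the background
is always the supplied table (restricted to the analyzed chromosomes
by default).  A feature hits a window on ≥ 1 bp overlap (1-based
inclusive coordinates).  Enrichment per category is the upper-tail
hypergeometric probability P[X ≥ k] of observing k category members
among the n hits drawn from a background of N with K members —
over-representation only; depletion is not tested — adjusted across
categories by Benjamini–Hochberg.  Both tails of machinery are
validated against exhaustive enumeration (all draws for N ≤ 12; a
step-up oracle for the FDR adjustment).

## Synthetic data generator

The generator produces multi-population genotype panels whose
structure is known exactly, so that every stage above can be tested
as a recovery problem.

* **LD and shared phase** come from a finite founder pool: each
  sample haplotype is a mosaic of `founder_pool_size` founder
  haplotypes, switching founders between adjacent markers with
  probability 1 − exp(−c·g·d), where c is the recombination rate
  (default 0.01 crossovers/Mb/meiosis, cattle-like), g the number of
  meioses separating samples from the pool (default 30), and d the
  distance.  The pool is the sole source of LD: its size sets the LD
  level (≈ 1/(h−1) between tightly linked markers) and two
  populations drawn from one pool share gametic phase.  An explicit
  correlation matrix would not give this shared-phase property.
* **Divergence** is Balding–Nichols: each population's per-marker
  frequency is a Beta draw with mean at the realized pool frequency
  and variance F·p(1−p), clipped to [0.01, 0.99] to avoid fixation
  artifacts; mosaic alleles are then flipped at the minimal marginal
  rate that reaches the drawn frequency, preserving as much haplotype
  structure as possible.  With two populations the expected
  multilocus Weir–Cockerham θ equals F.
* **Marker maps** place markers uniformly at random within
  chromosomes (default five 50-Mb autosomes), reproducing the
  irregular spacing of real arrays so every decay bin receives pairs.
* **Autozygosity** is planted by choosing a genomic interval and a
  subset of individuals and collapsing every heterozygote inside to a
  random homozygote (one haplotype copied over the other); exact
  interval bounds per carrier are recorded as truth.
* **Birth years** are uniform over 1961–2024, assigned by rank of a
  latent score √p′·ĝ + √(1−p′)·ε with ĝ drawn from the realized GRM's
  Cholesky factor.  The Gaussian-to-uniform rank transform attenuates
  the linear variance share by 3/π (Stein's lemma:
  cov(Φ(z), g) = E[φ(z)]·cov(z, g)), so the latent share is set to
  p′ = pve·π/3 and the REML PVE target is met in expectation; a small
  (~0.02) downward REML-side bias remains at n = 500.  Trend markers
  are re-drawn per individual from Binomial(2, p₀ + slope·(year −
  start)) with p₀ centred on the marker's current frequency —
  deliberately independent of neighboring LD, which makes detection
  power analytically predictable but means simulated selection
  signals have no LD shadow, unlike real sweeps.
* Everything is bit-reproducible given the seed (numpy SeedSequence
  streams per stage).

What the generator does **not** emulate: pedigree structure and
family relatedness beyond the founder pool, genotyping error, sex
chromosomes, selection acting through a phenotype, LD between a trend
locus and its neighbors, and realistic site-frequency spectra (founder
frequencies are uniform).  Passing recovery tests on this generator
therefore shows the estimators are correct for their generative
assumptions, not that real data meet those assumptions.

### Study conditions used in verification

Chosen at design time to match each analysis's needs:

* F_ST and PCA recovery: 2 × 200 individuals, 5,000 markers, default
  pool (50), F ∈ {0, 0.05, 0.15}.
* Gametic-phase runs: pool of 5 — a deliberately small founder base
  emulating closely related breed populations with small effective
  size and strong shared LD, the regime where phase consistency is
  informative.
* GPSM/REML runs: pool of 400, 500 individuals × 2,000 markers —
  effectively unlinked markers, so type-I error and power have their
  nominal interpretation; 20 replicates per quantity.
* ROH recovery: 50 individuals × 10,000 markers (≈ 25-kb spacing,
  denser than a 50K bovine array) with 20 planted segments,
  log-uniform 0.6–20 Mb.

These sizes keep the full verification under two minutes on one CPU
while leaving each quantity's sampling error well inside its
tolerance.

## Known limitations

* ROH shorter than the window span are undetectable and ROH
  boundaries are fuzzy by a few markers (see above) — properties of
  the window rule itself, faithfully reproduced here.
* The per-marker mean F_ST is biased toward zero for two populations;
  use the multilocus estimator for parameter-level statements.
* EM haplotype frequencies assume Hardy–Weinberg within population
  for phase resolution of double heterozygotes.
* The mixed-model scan is non-LOCO; for traits (unlike birth year)
  with large single-locus effects, LOCO would be preferable and is
  exposed as an option through the variance-component interface.
* The CLI pipeline computes within-population LD on the harmonized
  shared marker set; whether a study's decay curves should instead
  use all within-population QC-passing markers is exposed through the
  library interface (run `ld_scan` on any dataset).
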