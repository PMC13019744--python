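# Methods

This note documents the statistical procedures implemented in
`rohscan`, the choices made where the standard workflow leaves details
open, and what the synthetic-data validation does and does not
demonstrate.

## Genotype model and quality control

Genotypes are stored as four states per (individual, marker): homozygous
for allele A, heterozygous, homozygous for allele B, missing. All
downstream statistics depend only on this partition, never on allele
identity; for PED text input (which declares no A1/A2) "allele A" is the
first allele observed at a marker.

QC applies five filters in a fixed order: (1) non-autosomal and
unplaced markers (chromosome label outside the configured autosome set,
default "1".."29", or position 0) are dropped; (2) individuals with
genotype missingness > 10%; (3) markers with call rate < 90%; (4)
markers with minor allele frequency < 0.05; (5) markers with exact
Hardy–Weinberg p < 1e-6. Individuals are filtered before the
frequency-based marker filters because MAF and HWE depend on the
retained individual set; the order is fixed so reports are reproducible.
All removal inequalities are strict.

The HWE test is the exact conditional (Levene–Haldane) test: given the
marker's allele counts, every compatible heterozygote count h has
probability ∝ n!·2^h / (n_AA! h! n_BB!), and the two-sided p-value sums
the probabilities of all configurations no more likely than the observed
one. At a p-floor of 1e-6 the chi-square approximation is unreliable,
which is why the exact test is used; it is validated against an
independent rational-arithmetic enumeration. A monomorphic marker admits
one configuration, so p = 1.

## ROH detection

Detection follows the windowed scanning procedure of the standard
array toolchain, with these parameters (defaults in brackets):

| parameter | default | meaning |
|---|---|---|
| window_snps | 50 | sliding window length, markers |
| max_het_per_window | 1 | heterozygous calls tolerated per window |
| max_missing_per_window | 1 | missing calls tolerated per window |
| window_hit_threshold | 0.05 | min fraction of homozygous windows per SNP |
| max_gap_bp | 1,000,000 | split runs at larger inter-marker gaps |
| min_density_bp_per_snp | 100,000 | mean density bound (1 SNP / 100 kb) |
| min_length_bp | 1,000,000 | minimum run length |
| fp_alpha | 0.05 | false-positive rate for the minimum-SNP count |

Each SNP's score divides by the number of windows that actually overlap
it (fewer near chromosome ends; zero when a chromosome is shorter than
the window, in which case no run can be called there). The per-SNP
threshold is strict (score > 0.05). Runs are trimmed so both ends are
homozygous non-missing calls; length is end − start + 1 on 1-based
inclusive coordinates.

The minimum SNPs per run defaults to the false-positive-controlled
count l = ceil(ln(α/(n_s·n_i)) / ln(1−het)), recomputed from each
panel's dimensions and mean heterozygosity (the realized value is logged
and written to the run manifest, since it cannot be recovered from the
outputs); `min_snps_override` pins an explicit integer for exact
replication of an external run. The heterozygous/missing allowance is
applied per window; an optional strict per-segment cap
(`segment_het_cap` / `segment_missing_cap`, off by default) is available
for pipelines that interpret the allowance per run.

The detector is verified, over hundreds of randomized small panels,
against a brute-force oracle that enumerates every marker interval and
keeps maximal intervals satisfying all constraints.

Windowed scoring has a known edge behaviour: run boundaries erode or
extend by a few marker spacings around a true autozygous tract (the
windows crossing the boundary mix tract and background markers, and
background markers homozygous by chance can be absorbed). Measured at
zero genotyping error, boundary deviations average ~3 inter-marker
spacings; tract recovery is therefore validated in base-pair terms
(every well-supported planted tract is hit and its bases ≥ 80%
recovered; cohort-mean F_ROH within a few percent of the planted
fraction) rather than as marker-exact boundaries.

## Summaries

Segments are classified into 1–5, 5–10, 10–20 and > 20 Mb with
half-open boundaries [lo, hi) — a 5.00 Mb run belongs to 5–10 Mb. Class
summaries report count, count share, mean ± sample SD, total length and
length share. Per-chromosome coverage is, by default, the
population-average fraction of the chromosome inside ROH,
100·ΣL/(n_individuals·chromosome length); a cohort-total variant
(denominator = chromosome length) is available via a flag since both
conventions appear in the literature.

## Inbreeding coefficients

F_ROH = Σ L_ROH / L_auto, where L_auto is the marker-covered autosomal
span (per chromosome, last − first marker position + 1, summed).
Class-specific F_ROH restricts the numerator to one length class; the
overall F_ROH is computed as the sum of the four class components, so
the additivity identity holds to the last bit.

F_HOM is the method-of-moments excess-homozygosity estimator: per
individual, (O_hom − E_hom)/(m − E_hom) over its non-missing markers,
with E_hom = Σ_i [1 − 2p̂_i(1−p̂_i)·N_i/(N_i−1)], p̂_i the sample allele
frequency and N_i the non-missing allele count at marker i. The
finite-sample factor N/(N−1) is the default (it makes the estimator
unbiased under the Hardy–Weinberg null, verified by simulation to within
±0.01 at 200 individuals × 20k markers) and can be disabled. A plain
"proportion of homozygous genotypes" cannot be negative; the excess form
is used precisely because cohorts with heterozygote excess (balancing
selection, substructure) show negative F_HOM. Individuals' own genotypes
are not excluded from the frequency estimates (only material at very
small n). Monomorphic markers cancel from numerator and denominator.

Pearson correlations among the six measures (F_HOM, F_ROH and the four
class components) are computed from the product-moment formula with a
two-sided t-test on n−2 df, cross-checked against an independent
statistics library. All 15 pairs are reported without multiple-testing
correction; a class absent from the whole cohort yields an undefined
(NaN) correlation in the fitted results.

## ROH islands

Per-marker incidence counts the individuals with a run spanning the
marker. The island threshold is the k-th largest incidence with
k = ceil(top_fraction · n_markers) (default top 1%): "top 1%" is a count
statement, so ties at the cutoff are all included (candidates are
markers with incidence ≥ threshold). Islands are maximal runs of
consecutive candidate markers on a chromosome with at least 2 members
(singletons discarded); bounds are the first/last member positions. No
intra-island gap constraint is imposed beyond marker adjacency, so
physical gaps inside sparse islands are visible in the output for audit.
If every marker has identical incidence (e.g. no ROH at all) the rule
cannot discriminate; a warning is emitted and the fitted model reports
no islands. Genes are attached on ≥ 1 bp overlap of closed intervals;
GFF3 input is filtered to `gene` features (identifier from Name, then
ID).

## Synthetic panels

The generator emulates a medium-density array study of a livestock
cohort. Defaults (chosen once as the study-scale conditions the package
is exercised under):

* 380 individuals; 29 synthetic autosomes with linearly decreasing
  lengths totalling ~2.47 Gb (the scale of a caprine genome; synthetic
  lengths, not real assembly coordinates);
* marker positions by exponential spacing, mean 40 kb (~60k markers);
  per-marker MAF uniform on [0.05, 0.5];
* background genotypes drawn from Hardy–Weinberg proportions
  (verified: per-marker chi-square goodness-of-fit pass rate ≥ 94% at
  α = 0.05, and mean heterozygosity matches the closed form
  E[2pq] = 0.365 for the MAF distribution above);
* planted identical-by-descent tracts: per-individual target
  autozygosity drawn from a gamma distribution with mean 0.0290 and
  SD 0.0289 clipped to [0.0009, 0.1991] (matching the reported cohort
  distribution of F_ROH in the population this emulates), tract lengths
  drawn from the four length classes with weights
  (0.502, 0.292, 0.153, 0.054); inside a tract one founder allele per
  marker is drawn by population frequency, so tracts are homozygous for
  either allele, as real autozygosity is;
* genotyping errors flip a call to one of the other two states
  uniformly (rate 0.002 — typical array discordance) and calls are
  masked missing at rate 0.01.

What the simulation does **not** model: linkage disequilibrium outside
planted tracts (the 1 Mb minimum-length rule is the caller's guard
against LD-induced short homozygous stretches, and that rule is testable
without modelling LD), allele-frequency spectra skewed below MAF 0.05,
batch effects, and relatedness structure. Passing the recovery tests
therefore shows the detector and estimators are correct for the stated
model, not that any particular real cohort is free of LD artefacts.

## Numerical and interface choices

* Positions are 1-based inclusive everywhere except `islands.bed`
  (0-based half-open, for interoperability).
* Marker sort is (chromosome block, position, marker id); the id
  tie-break makes sorting deterministic for tied positions.
* The whole pipeline is deterministic: identical inputs and parameters
  give byte-identical tables, and the run manifest records parameters,
  input checksums and row counts.
* TSV output prints 4 decimals (2 for Mb and percentage columns).
* Degenerate inputs fail loudly: all-missing panels, monomorphic-only
  panels for F_HOM, constant vectors for a single correlation,
  chromosome-label mismatches between islands and gene files.

## Problem sizes used in validation

The test suite runs on panels from a few markers (hand-checkable
examples and format round-trips) through 200-marker randomized panels
(200 oracle-equivalence replicates) to 100–200 individuals × 20k markers
(recovery and null-bias checks); the acceptance script runs the full
380 × ~60k default. These sizes keep the complete validation suite in
the minutes range on one CPU while exercising every code path at the
scale the defaults describe.
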