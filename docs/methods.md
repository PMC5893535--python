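# Methods

## Peak universe and counting

All coordinates are 0-based half-open (BED convention); 1-based inputs
(the GWAS SNP table) are converted at the reader boundary. Chromosome
names match by exact string comparison.

Per-sample peak calls are pooled, then merged whenever the gap between
proximal ends is strictly less than 10 bp (ties at exactly 10 bp stay
separate); merging is transitive, so chains collapse into single
intervals. Peaks overlapping a blacklist interval by at least one base are
removed whole, not trimmed. Fragments are counted over the merged,
non-overlapping universe under an any-overlap rule: a fragment adds 1 to
every peak it overlaps by ≥ 1 bp, so a fragment spanning two peaks counts
once in each. This is the simplest well-defined assignment; published
counting tools differ in how they resolve multi-peak overlaps, and no
concordance with a specific tool is claimed.

## Normalization, filtering, MDS

Raw counts C_R become normalized signal per sample library size S_L (the
count of qualified fragments, supplied in the metadata):

    C_N = log2(C_R / S_L × 100,000,000 + 1)

An alternative library-size definition (e.g. properly paired fragments)
is supported by passing a different library-size vector; there is no
second code path. Peaks are retained when their mean C_N across the
analysis samples is ≥ 6.5 by default; the threshold may also be given as
`quantile:q` (the constant 6.5 sits near the 75% quantile in cohorts of
this depth, which is how the default was chosen).

Sample embedding uses classical (Torgerson) multidimensional scaling:
double-center the squared Euclidean distance matrix of C_N profiles,
eigendecompose, scale eigenvectors by the root eigenvalues (clipped at
zero). The result is deterministic up to axis sign. Classical scaling was
chosen over SMACOF-style iterative MDS because the input distances are
exactly Euclidean, where classical scaling is exact and has no
initialization or convergence parameters.

## Pairwise differential test

Counts are scaled to the geometric-mean library size. A single common NB
dispersion φ is estimated by the method of moments, pooling (s² − m)
against m² across peaks and within-group replicates, floored at 1e-8.
The per-peak p-value is the classic conditional exact NB test: group sums
S_A, S_B (rounded) are NB with sizes n_A/φ, n_B/φ under the null of a
common mean, the split of the total t = S_A + S_B follows a
beta-binomial(t, n_A/φ, n_B/φ), and the two-sided p-value sums the
probabilities of all splits no more likely than the observed one. For
very deep peaks (t > 200,000) a normal approximation with the exact
beta-binomial variance replaces enumeration. log2 fold change is computed
on scaled group means with a 0.5 pseudo-count. Significance follows
|log2FC| > 0.8 and BH FDR < 0.05 by default. This is the same model
family as the standard count-based differential packages with common
dispersion; tagwise empirical-Bayes shrinkage and TMM normalization are
deliberately out of scope, and exact concordance with any one package is
not claimed. BH adjustment itself is delegated to statsmodels and
cross-checked in the tests against a hand-rolled step-up oracle.

The three-group comparison (normal/early/late) is a one-way ANOVA F-test
on C_N per peak with BH FDR (< 0.01 default), reported with the sign of
each adjacent group-mean contrast. A count-model likelihood-ratio omnibus
would be the heavier alternative; on log-scale signal with these sample
sizes the F-test is a reasonable approximation and is documented as such.

## Global shift and paired eyes

The global-shift summary counts peaks with negative log2FC as reduced and
positive as increased; exact zeros are ties, kept in the denominator of
`frac_reduced` but not the numerator (the tie convention is a package
choice). The MA-trend curve is the mean log2FC per mean-signal bin
(50 bins by default). For a donor with eyes at different disease stages,
the per-peak shift is simply C_N(left) − C_N(right), since C_N is already
library-size normalized; same-stage pairs serve as the symmetric control
and should split near 50/50.

## Stage regression and DARs

Per peak, ordinary least squares of C_N on

    [1, stage (0/1/2), region (−1/+1), gender (−1/+1), age (years), interval (hours)]

requires ≥ 7 samples and a full-rank design (rank deficiency is reported
with the offending columns). The stage coefficient α₁ is tested two-sided
by t-test, BH-adjusted across peaks; the paired structure of some donors
is ignored (independent-sample OLS), a known simplification. DARs are
peaks with stage FDR < 0.01 and α₁ < 0, sorted ascending by α₁, truncated
to the top 5000 (defaults). Ties break by smaller FDR, then genomic
coordinate, for determinism. A two-sided test followed by a sign filter
was preferred over a one-sided test because the claim being ranked is a
significantly negative coefficient, not a one-sided hypothesis fixed in
advance for every peak; one-sided testing would halve the p-values and
change FDR values.

## Footprints

Each fragment contributes two Tn5 insertion positions: start + 4 and
end − 5 (the half-open end shifted back into the fragment), the standard
correction for the 9-bp Tn5 dimer offset; the shifts are configurable and
(0, 0) gives the naive fragment boundary coordinates.

Insertion profiles aggregate per-base counts in a 200-bp window centered
on each motif midpoint, positionally flipped for minus-strand sites. Each
site's window counts are divided by the total insertions in its flanking
normalization window — interpreted as 150 bp immediately outside each
window edge (300 bp total); the geometry is configurable because "a
flanking 300 bp window" is ambiguous between total and per-side — then
averaged across sites. Sites with zero flank insertions are excluded from
the normalized average; if none remain the profile is flagged as having
null normalization and only raw counts are returned.

The footprint occupancy score uses the motif span as the central region
and the two adjacent 3×motif-length intervals as flanks: N_C is the
central count, N_L and N_R are the flank counts divided by 3 (kept as
real numbers; the +1 pseudo-counts apply after division), and

    FOS = min(−log2((N_C+1)/(N_L+1)), −log2((N_C+1)/(N_R+1))).

Uniform insertion density gives FOS = 0; deeper central protection gives
larger positive scores; central enrichment goes negative.

Footprint-in-DAR enrichment classifies each footprinted site as in-DAR or
in-non-DAR by any-overlap (sites in neither are ignored; a site in both is
an error, as the sets must be disjoint) and computes the upper-tail
hypergeometric p-value for k of K classified sites falling in the n DARs
out of N = n + |non-DARs| regions, BH-adjusted across motifs. Stratified
(gene-proximal vs distal) enrichment runs the same test on stratified
region sets. Footprint *detection* is an input, not a responsibility of
this package.

## Annotation and SNP overlap

Nearest-gene assignment minimizes the distance from the peak midpoint to
the gene body (0 on overlap; ties to the lexicographically first
gene_id) — a deliberate simplification of annotation-tool behavior, not a
bit-for-bit reproduction. Categories follow a fixed precedence evaluated
against the assigned gene: promoter-proximal (peak within 2 kb of the TSS
or overlapping the 5′UTR), then 3′UTR (overlapping the 3′UTR or within
2 kb of the TES), then exonic, intronic, intergenic. Gene-proximal peaks
are those within 2 kb of the gene body; gene ranking assigns each gene the
minimum α₁ over its proximal peaks and sorts ascending, yielding a ranked
list for external gene-set enrichment.

SNP overlap takes the minimum GWAS P over SNPs inside each (optionally
±extended) region, defaulting to P = 1 for regions with no SNP, and
reports the proportion of regions below a threshold. Non-peak controls
are same-width intervals immediately downstream of each peak (side
configurable); flanks that would overlap any peak are skipped rather than
truncated, keeping the control width distribution identical to the peaks'.

## Synthetic cohorts

The generator emulates the statistical structure of the study cohorts,
not their sequence content. Expected counts are

    μ = S_L / 10⁸ × 2^(α₀ + α₁·stage + α₂·region + α₃·gender + α₄·age + α₅·interval)

with NB noise at a single dispersion (default 0.05; a lognormal-Poisson
alternative with matched variance exists for robustness checks — the NB
default intentionally matches the differential test's model family, so
type-I results should be read as within-model calibration). Defaults:
25 samples in the 11/5/9 normal/early/late retina design with alternating
region and gender codes, ages uniform on 79–94 years, procurement
intervals 4–13 h, library sizes 20–50 million; per-peak baseline
α₀ ~ N(7.5, 0.8) (putting mean C_N near the 6.5 filter threshold);
confounder coefficients 0.1 (region), 0.05 (gender), −0.005/year (age),
−0.02/hour (interval). A fraction (default 0.9) of peaks receive a stage
effect α₁ ~ N(−0.4, 0.25); the rest have α₁ = 0. The spread 0.25 is the
closed-form calibration making the expected fraction of reduced peaks
equal the planted affected fraction (0.9·Φ(0.4/σ) + 0.05 = 0.90 ⇒
σ ≈ 0.25); it also lets the planted coefficient density cross zero, as
the real stage-coefficient distributions do.

Paired-eye metadata shares gender, age, interval and region between the
two eyes of a donor, differing only in stage and library size — omitting
this sharing biases the symmetric-pair control away from 50/50.

Fragment simulation places Poisson numbers of fragments with midpoints
uniform in each peak plus uniform background, lengths drawn from a
sub-nucleosomal (60–120 bp, 70%) / mono-nucleosomal (180–250 bp) mixture.
Footprint simulation draws Poisson insertions at a flank rate per bp and
rate × (1 − occupancy) in the central motif span, with the closed-form
expected FOS −log2((rate_c·L + 1)/(rate_f·L + 1)) returned alongside.

What the synthetic data does *not* emulate: sequence composition and
mappability, GC or accessibility-dependent biases, correlated peaks
(LD-like block structure), batch effects, cell-type mixture shifts
between disease stages, and real footprint shapes (flat depletion rather
than the V-shaped profiles of real TF footprints). Passing
parameter-recovery and calibration tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
everything real tissue data can do.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 500–2000 peaks and 24–25
samples, and null panels of 1000 peaks — sizes at which NB exact
enumeration, per-peak OLS and the simulators all complete in seconds
while leaving the statistical checks well-powered. Deterministic seeds
are fixed in the tests; the acceptance script derives every stream from
its `--seed` argument. Degenerate inputs are handled explicitly:
zero-variance peaks yield t = 0 (p = 1) rather than NaN; all-zero peaks
give p = 1 in the exact test; empty flank windows flag null normalization
instead of dividing by zero; the BH adjustment validates its input range.

## Known limitations

- The NB exact test uses one common dispersion; strongly peak-dependent
  overdispersion would miscalibrate extremes.
- The three-group omnibus test is Gaussian on log-scale signal, not a
  count model.
- OLS treats samples as independent although some donors contribute both
  eyes; a mixed model would be the next step.
- Nearest-gene annotation is midpoint-based and ignores transcript-level
  isoform structure beyond one TSS/TES per gene model.
- The paper-scale analyses (~10⁵ peaks, tens of millions of fragments per
  sample) are supported by the same code paths but are exercised here at
  reduced scale.
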