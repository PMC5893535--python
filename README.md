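# atacshift

Differential chromatin accessibility analysis for bulk ATAC-seq cohorts,
built around the kind of study that profiles postmortem retina and retinal
pigment epithelium (RPE) across stages of age-related macular degeneration
(AMD): many samples, strong confounders (donor age, death-to-procurement
interval, macula vs periphery, gender), and a genome-wide *decrease* in
accessibility with disease progression rather than a handful of isolated
hits.

The package takes fragment intervals (BED), peak sets and sample metadata
and produces, as tested library functions and a thin CLI:

- a consensus peak universe (proximal-end merging at < 10 bp, blacklist
  exclusion) and a peak × sample fragment-count matrix;
- library-size normalized signal `C_N = log2(C_R / S_L × 10⁸ + 1)` with the
  mean-signal ≥ 6.5 peak filter and classical (Torgerson) MDS of samples;
- pairwise differential accessibility via a negative-binomial exact test
  (common method-of-moments dispersion, significance at |log2FC| > 0.8 and
  BH FDR < 0.05), a three-group omnibus test, and global-shift summaries
  (fraction of reduced peaks, MA-trend curve) including paired-eye
  comparisons;
- a per-peak linear model
  `C_N = α₀ + α₁·stage + α₂·region + α₃·gender + α₄·age + α₅·interval + ε`
  with stage coded 0/1/2, from which differentially accessible regions
  (DARs) are the top peaks with significantly negative α₁ (FDR < 0.01,
  ranked by coefficient);
- Tn5 insertion profiles around motif occurrences and the footprint
  occupancy score
  `FOS = min(−log2((N_C+1)/(N_L+1)), −log2((N_C+1)/(N_R+1)))`, plus
  hypergeometric enrichment of footprinted sites in DARs;
- peak → nearest-gene annotation (promoter-proximal / 3′UTR / exonic /
  intronic / intergenic), min-coefficient gene ranking, and GWAS SNP
  overlap (min-P per region, P = 1 default, ±5 kb extension, same-width
  flanking non-peak controls);
- a synthetic-cohort generator with planted stage effects, confounder
  coefficients, library sizes and footprint depths, so every stage of the
  pipeline is testable against known ground truth without any downloads.

## Worked example

```python
import numpy as np
from atacshift import (CohortConfig, differential_test, fit_stage_model,
                       global_shift, normalize_counts, select_dars, simulate_cohort)

cfg = CohortConfig(n_peaks=2000, seed=1)          # retina-style 25-sample cohort
counts, truth = simulate_cohort(cfg)
norm = normalize_counts(counts)

normal = [s.sample_id for s in counts.samples if s.stage_code == 0]
disease = [s.sample_id for s in counts.samples if s.stage_code > 0]
res = differential_test(counts, normal, disease)
shift = global_shift(res)
print(f"{shift.n_reduced}/{shift.n_peaks} peaks reduced ({100*shift.frac_reduced:.1f}%)")

fits = fit_stage_model(norm)
print(f"mean stage coefficient: {fits.alpha[:, 1].mean():.3f} "
      f"(planted: {truth.alpha1.mean():.3f})")
dars, non_dars = select_dars(fits, fdr_cut=0.01, top_n=500)
print(f"{len(dars.peaks)} DARs selected; strongest coefficient {dars.coefficients[0]:.2f}")
```

prints

```
1790/2000 peaks reduced (89.5%)
mean stage coefficient: -0.370 (planted: -0.362)
500 DARs selected; strongest coefficient -1.71
```

Ninety percent of the simulated peaks carry a negative stage effect, and
the NB test recovers that global shift (89.5% of peaks reduced in disease);
the covariate-adjusted regression recovers the planted coefficients nearly
unbiasedly, and DAR selection returns the requested top-ranked subset.

The same analyses run from the shell: `atacshift count | normalize | diff |
mds | dar | footprint fos | footprint enrich | annotate | snp-overlap |
simulate | run`, with `atacshift run --config pipeline.yaml` executing the
whole chain and writing a manifest for reproducibility.

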