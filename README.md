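# perchpop

Population-genomic analysis of demographic change and parallel adaptation
in structured fish populations — built around the study design of two
isolated, recently expanded lake populations (think Green Bay and
Muskegon Lake yellow perch) compared against a large, stable main-basin
metapopulation sampled at several sites.

The package provides, as a library and a CLI:

- a **forward Wright–Fisher simulator** (recombination via the Haldane
  map, reversible two-allele mutation, viability selection, piecewise
  demography with splits and migration) plus ground-truth sidecars, and a
  calibrated three-population preset mirroring the study system;
- **dataset construction** from VCF: study-wide vs within-group MAF
  filtering, missing-data handling, Hardy–Weinberg exact-test reporting;
- **diversity statistics**: folded MAF spectra, Tajima's D in physical
  bins, sliding-window observed heterozygosity, and missing-data-aware
  nucleotide diversity with invariant sites in the denominator;
- **differentiation**: per-site and weighted Weir–Cockerham F_ST,
  pairwise matrices, cross-population SNP-sharing;
- a **consensus outlier-window scan**: windows holding at least one SNP
  with theta ≥ 0.6 in at least 80 % of pairwise comparisons, merged into
  maximal intervals and annotatable with BED/GFF3 features;
- **LD-based contemporary Ne** (Burrows-composite r² with Waples
  sample-size correction and chromosome-block jackknife intervals) and a
  simplified recombination-bin **Ne(t) trajectory** via the Sved relation
  E[r²] ≈ 1/(1 + 4 Ne c), dating each bin to t ≈ 1/(2c) generations.

The science, estimator formulas, numerical choices and their limitations
are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate the three-population preset at desk scale and run every stage
(filtering, diversity, F_ST, outlier scan, Ne):

```bash
perchpop all -o demo --seed 7 --scale 0.012
```

which prints, among other things, the per-population summary

```json
"gb":  {"n_snps": 1560, "median_maf": 0.08, "mean_tajimas_d": -0.192, "mean_hobs": 0.211},
"mus": {"n_snps": 1556, "median_maf": 0.08, "mean_tajimas_d": -0.206, "mean_hobs": 0.210},
"m1":  {"n_snps": 1184, "median_maf": 0.12, "mean_tajimas_d": +0.342, "mean_hobs": 0.246}
```

and writes `demo/report.json` with the full run.  Reading it:

- the two focal populations (`gb`, `mus`) carry ~1.3× more within-group
  SNPs than each main-basin subsample, at a lower median minor-allele
  frequency (0.08 vs 0.12–0.14) and with negative genome-wide Tajima's D —
  the joint signature of expansion-driven excess rare variation — while
  the main basin's positive D (~ +0.35) marks a mild decline;
- the F_ST matrix in the same report shows the three-population
  structure: `gb~m1` = 0.063 versus `m1~m2` = 0.0008 (subsamples of one
  panmictic deme are statistically indistinguishable);
- the consensus scan retains exactly one merged outlier window,
  `chr1:2250000-3000000` supported by all 10 focal-vs-main comparisons —
  it contains the planted selected site (chr1:2500834 in
  `demo/truth.yaml`), and no spurious window appears.

The same stages are available individually (`perchpop simulate`,
`filter`, `stats`, `fst`, `scan`, `ne`, `report`), rerunnable from the
cached outputs of earlier stages, and everything is importable from
Python (`perchpop.simulate_wright_fisher`, `perchpop.tajimas_d`,
`perchpop.wc_fst_pair`, `perchpop.ne_point_ld`, ...).

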