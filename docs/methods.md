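# Methods

`perchpop` implements the population-genomic workflow used to study
demographic change and parallel adaptation in lake-dwelling fish
populations: two divergent, recently expanded populations (the "focal"
demes, modelled on Green Bay and Muskegon Lake yellow perch) compared with
a large, stable main-basin metapopulation sampled at five sites.  This
note documents the models, the estimators, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Forward Wright–Fisher engine

Diploid individuals evolve in discrete, non-overlapping generations.  Each
offspring is the random union of two gametes; each gamete starts from a
random parental haplotype, and crossovers fall as a Poisson process along
the physical map (expected count per inter-site gap = rho × distance in
bp), with the parental haplotype redrawn independently at every chromosome
boundary.  The parity of the crossover count decides switching, which
realizes the Haldane map function exactly.  Sites mutate reversibly
between the two alleles at rate `mu` per site per generation (an
infinite-sites model is not assumed; at `theta = 4 N mu` per site above
~0.1 multi-hit effects are visible in the site-frequency spectrum).
Viability selection acts before parent sampling with genotype fitnesses
1 : 1+hs : 1+s, multiplicative across selected sites and restricted to the
designated demes.  Migration, when configured, swaps a binomial number of
individuals symmetrically between deme pairs after reproduction.

Deme sizes follow piecewise-constant schedules in generations before
present; a child deme is founded at its split time by reproduction from
its parent.  Everything is reproducible from a single integer seed.
Intended scale: up to ~1000 diploids, ~2×10⁵ sites and a few thousand
generations on one CPU.

**Stationary warm start.** `init="stationary"` makes each site segregating
with probability `min(1, theta · a1(2N))` and draws its derived-allele
frequency from the `theta/f` density truncated to `(1/2N, 1 − 1/2N)`,
assigning alleles at linkage equilibrium.  Two consequences are worth
knowing.  First, linkage disequilibrium starts at zero and relaxes to its
drift equilibrium on a timescale of roughly `1/(2c + 1/2N)` generations,
so scenarios that interrogate LD keep a few hundred generations of
burn-in.  Second, the density omits the near-fixation class that reverse
mutation maintains at stationarity; because alleles near fixation fold to
rare minor-allele frequencies, a freshly warm-started deme shows a mildly
*positive* Tajima's D (about +0.4 at the preset's scale) that decays over
~2N generations.  The preset uses this deliberately as the main basin's
slight-decline signature, which matches the study system's positive
main-basin D.  Analyses that need a strictly neutral equilibrium (the
coalescent cross-checks in the test suite) instead burn in ≥ 10 × 2N
generations from a monomorphic start.

**Selected sites.** A selected allele is injected as standing variation at
frequency `f0` in every deme alive at generation `t0` (defaulting to the
start).  Injection resets that one column at linkage equilibrium — the
surrounding haplotype structure is rebuilt by the subsequent generations —
so `t0` should predate sampling by at least tens of generations.

## The three-population preset

`make_perch_scenario(scale)` encodes the study system's statistical
structure:

- one large stable deme (`main`), subsampled five times at the present
  (populations `m1`–`m5`);
- two focal demes that split from it, expand ~5× at the split, and expand
  again (4× and 6×) in the recent past;
- one shared selected site (s up to 1, h = 0.5, f0 = 0.08) under selection
  in both focal demes from the split onward;
- 3000 evenly spaced sites on four 5-Mb chromosomes; 25 diploids sampled
  per population.

`scale` applies the standard population-genetic rescaling — sizes and
times shrink by `scale` while `mu`, `rho` and `s` grow by `1/scale` — so
the diffusion-scale observables (F_ST, Tajima's D, the folded spectrum)
are preserved while runtime falls quadratically.  At the recommended desk
settings (`scale` 0.012–0.02, seconds per replicate) the preset yields:
focal demes with ~1.3× more within-group SNPs, median MAF ~0.08 against
~0.13 in the main subsamples, genome-wide mean Tajima's D ≈ −0.2 against
≈ +0.45, weighted F_ST ≈ 0.05–0.07 between focal and main demes and
|F_ST| < 0.005 among the five main subsamples, and a planted selected site
at F_ST ≈ 0.8–1.0.

Two aspects are deliberate simplifications rather than literal history.
The focal demes carry no contemporary bottleneck: minima at or below the
sampled-lineage scale (25 diploids = 50 lineages) collapse the sampled
genealogy within a handful of generations and invert every diversity
signal the preset must carry, so the "rebound from a small minimum"
narrative is represented only by the recent growth steps.  And the
generator's discrete non-overlapping generations ignore the overlapping
generations and mixed-age sampling of real perch, which are known to bias
LD-based Ne downward in real data; nothing in the package corrects for
age structure.

## Dataset construction

`build_dataset` produces either one *study-wide* dataset (minor allele
frequency computed across all samples jointly) or one *within-group*
dataset per population (within-population MAF and polymorphism), the
latter being the substrate for all demographic statistics.  MAF uses
called alleles only; sites with more than 50 % missing calls in a group
are dropped from that group (configurable).  Multiallelic records are
skipped at VCF input, invariant records optionally retained for
nucleotide diversity.  Internally every interval is 0-based half-open;
VCF positions are 1-based only at the I/O boundary.  Hardy–Weinberg exact
p-values (Levene/Wigginton enumeration via a multiplicative recurrence)
are reported per population, never filtered on by default.

## Diversity statistics

- **MAF spectra**: per-site folded frequencies with a fixed-width
  histogram (0.015 bins) and the median over polymorphic sites.
- **Tajima's D**: per physical bin (default 5 Mb, scaled down in
  simulations).  S counts polymorphic sites; mean pairwise diversity comes
  from allele counts, `2j(n−j)/(n(n−1))` per site, which absorbs per-site
  sample-size variation from missing calls; the a1…e2 constants use
  `n_chrom` = 2 × diploids with any call in the bin.  Bins with S = 0 (or
  below `min_snps_per_bin`) report NaN, never zero; the genome-wide mean
  averages defined bins.
- **Observed heterozygosity**: per SNP the fraction of called diploids
  that are heterozygous, averaged over SNPs in sliding windows (default
  5 Mb window, 2.5 Mb step).
- **Nucleotide diversity**: missing-data-aware ratio of sums,
  `pi = sum_site j(n−j) / sum_site n(n−1)/2`, with invariant sites
  contributing comparisons but no differences — the convention that keeps
  pi unbiased under missingness.  A read-depth mask is out of scope at the
  genotype level.

## Differentiation and the consensus outlier scan

Per-site Weir–Cockerham (1984) variance components a, b, c give
`theta = a/(a+b+c)`; sites monomorphic across a pair are excluded, and
negative per-site estimates are retained (the multi-site "weighted"
estimate is the ratio of sums `Σa / Σ(a+b+c)`, which can itself be
slightly negative for panmictic subsamples).  The consensus scan slides
windows over the genome (defaults follow the heterozygosity grid, scaled
in simulation); a window is *high* for a comparison if it contains at
least one SNP with theta ≥ 0.6, and windows high in at least
`ceil(0.8 × n_comparisons)` comparisons are retained, then merged into
maximal intervals.  Both the merged count and the raw grid count are
reported, since either convention is defensible for "number of outlier
windows".  Retained windows can be annotated with BED/GFF3 feature
intervals under half-open overlap semantics; annotation stops at feature
identifiers.

## LD-based effective population size

Locus pairs (between-chromosome only, by default, to avoid physical
linkage) give squared Pearson correlations of genotype dosages over
pairwise-complete individuals.  Pooling uses the mean r², rescaled by
`(S/(S−1))²` to the Burrows-composite small-sample convention — the
convention whose no-LD expectation the Waples corrections describe
(`E_sample = 1/S + 3.19/S²` for harmonic-mean S ≥ 30, the three-term form
below) — and the drift component `r²_drift = r²_mean − E_sample` inverts
to Ne through the Waples (2006) quadratic.  A non-positive drift signal
reports Ne = ∞ explicitly.

Confidence intervals default to a delete-one-chromosome block jackknife
on the mean r² with a t quantile on (blocks − 1) degrees of freedom.
This choice matters: pairs sharing a locus are correlated, and — more
importantly — all pairs share the realized genealogy, so the parametric
chi-square interval on n′ = n_pairs (provided as an option, and standard
in the field) is strongly anti-conservative, and even a per-locus
jackknife (also provided) reaches only ~55 % coverage where the
chromosome-block jackknife reaches its nominal level in the package's
recovery experiments.

**Ne(t) trajectory.** Within-chromosome pairs are binned by recombination
fraction (Haldane map applied to physical distance with a per-chromosome
rate); each bin's corrected mean r² is inverted through the Sved-type
expectation `E[r²_drift] ≈ 1/(alpha + 4 Ne c)` with `alpha = 1`, and the
implied Ne is dated to `t ≈ 1/(2c)` generations before present.  This is
an intentionally simplified analogue of recombination-segment demographic
methods, good for qualitative shape (recent growth shows larger Ne in
recent bins) and order-of-magnitude level; the default bins start at
c = 0.02 because below that the inversion overestimates Ne by more than a
factor of two at desk sample sizes.  Even within the default range a
~1.5–1.8× upward bias remains at a true constant Ne of 100, inside the
factor-two envelope the recovery experiments check.

## Verification strategy, and what it shows

Every estimator is checked against an independent oracle: Weir–Cockerham
components against step-by-step formula evaluation on enumerated small
instances; Tajima's D and pi against exhaustive pairwise-difference
enumeration on ≤ 8-haplotype fixtures (haplotypes encoded as homozygous
diploids, oracles enumerating the duplicated chromosome pool the genotype
data actually contain); HWE p-values against exact-arithmetic
enumeration; dosage r² against the direct-count Burrows composite; and
the forward engine against coalescent simulation (msprime) under the same
reversible binary mutation model.  Parameter recovery (Ne within 25 % with
honest interval coverage, expansion/contraction signatures of D and the
spectrum, trajectory shape, planted-locus recovery with ~zero spurious
windows and an empty permutation null) runs on replicated desk-scale
scenarios with truth sidecars; replicate counts (8–20 per experiment) and
scenario sizes (≤ 8000 sites, ≤ 1000 diploids, ≤ 1500 generations) were
chosen so the whole suite runs in a few minutes on one CPU.

Passing these tests shows the statistics are implemented correctly and
recover truth under the generator's assumptions.  It does not show that
real whole-genome data would behave as well: the generator has no
sequencing error, no depth-dependent missingness, even site spacing,
uniform recombination, free of age structure and gene flow, and its
diversity levels sit orders of magnitude above real per-bp theta because
desk-scale site counts stand in for whole chromosomes.

## Known limitations

- Discrete generations; no overlapping generations or age structure
  (biases LD-Ne on real mixed-age samples).
- Two-allele reversible mutation; no sequence context, no multi-allelic
  sites.
- The Ne(t) trajectory is qualitative; it is not a substitute for
  purpose-built demographic-history software.
- The parametric LD-Ne interval is anti-conservative by construction and
  kept only for comparability.
- Depth-based genotype masking ("covered by at least three reads") is not
  modelled; pi operates on called genotypes.
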