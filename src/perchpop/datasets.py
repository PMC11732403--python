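"""Construction of analysis-ready SNP datasets and Hardy-Weinberg checks.

Two filtering modes mirror common practice for structure versus demographic
analyses: a single *study-wide* dataset keeps sites by minor allele
frequency computed across all samples jointly, while *within-group*
datasets keep, for each population separately, the sites that are
polymorphic and common enough inside that population.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import MISSING, DatasetSpec, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)


def _site_mask(gm: GenotypeMatrix, idx, spec: DatasetSpec) -> np.ndarray:
    d = gm.dosage if idx is None else gm.dosage[idx, :]
    n_samples = d.shape[0]
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
    n_alleles = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = n_called >= (1.0 - spec.max_missing_frac) * n_samples
    keep &= n_alleles > 0
    if spec.polymorphic_only:
        keep &= (alt > 0) & (alt < n_alleles)
    keep &= maf >= spec.maf_min
    if spec.biallelic_only:
        keep &= np.asarray(gm.alt, dtype=object) != "."
    return keep


def build_dataset(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    spec: DatasetSpec,
):
    """Filter a genotype matrix into the analysis dataset(s) defined by
    ``spec``.

    Returns the filtered :class:`GenotypeMatrix` for ``study_wide`` mode, or
    a ``{population: GenotypeMatrix}`` dict for ``within_group`` mode (each
    matrix restricted to that population's samples and its qualifying
    sites).  Site order is preserved.
    """
    if spec.mode == "study_wide":
        keep = _site_mask(gm, None, spec)
        return gm.take_sites(keep)
    out = {}
    for pop in pops.populations:
        idx = pops.indices(gm, pop)
        keep = _site_mask(gm, idx, spec)
        sub = gm.take_sites(keep).take_samples([gm.samples[i] for i in idx])
        out[pop] = sub
        log.info("within-group dataset %s: %d sites", pop, int(keep.sum()))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _het_probabilities(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count conditional on the
    minor-allele count ``n_a`` among ``2n`` alleles (Levene/Wigginton
    construction), computed by the stable multiplicative recurrence.

    Returns (possible het counts, their probabilities)."""
    n_b = 2 * n - n_a
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # unnormalized log-probabilities via recurrence
    # P(h+2)/P(h) = (na-h)(nb-h) / ((h+2)(h+1))  [counts of each genotype]
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 1.0
    for i in range(1, len(hets)):
        h = hets[i - 1]
        ratio = ((n_a - h) * (n_b - h)) / ((h + 2.0) * (h + 1.0))
        probs[i] = probs[i - 1] * ratio
        if probs[i] > 1e250:  # rescale to avoid overflow
            probs[: i + 1] /= probs[i]
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic site.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of all configurations no
    more probable than the observed one.  Monomorphic input returns 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0
    hets, probs = _het_probabilities(n_minor, n)
    p_obs = probs[np.searchsorted(hets, n_het)]
    # tolerance guards against ties lost to floating rounding
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_report(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Per-population fraction of polymorphic sites out of Hardy-Weinberg
    equilibrium at level ``alpha`` (reported, not filtered)."""
    out = {}
    for pop in pops.populations:
        idx = pops.indices(gm, pop)
        d = gm.dosage[idx, :]
        n_rr = (d == 0).sum(axis=0)
        n_ra = (d == 1).sum(axis=0)
        n_aa = (d == 2).sum(axis=0)
        poly = gm.is_polymorphic(idx)
        pvals = np.array(
            [
                hwe_exact_test(int(n_rr[j]), int(n_ra[j]), int(n_aa[j]))
                for j in np.flatnonzero(poly)
            ]
        )
        out[pop] = {
            "n_sites": int(poly.sum()),
            "frac_out_of_hwe": float((pvals < alpha).mean()) if len(pvals) else 0.0,
        }
    return out
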