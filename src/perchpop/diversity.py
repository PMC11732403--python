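"""Site-frequency and windowed diversity statistics.

Implements the demographic-signal toolbox: minor-allele-frequency spectra,
Tajima's D in physical bins, observed heterozygosity in sliding windows,
and missing-data-aware nucleotide diversity that keeps invariant sites in
the denominator.  All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, WindowStat, iter_windows


# ---------------------------------------------------------------------------
# minor allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class MafSummary:
    """Per-site minor allele frequencies for one population with the
    fixed-width histogram used for density curves (default bin 0.015)."""

    maf: np.ndarray
    median: float
    bin_width: float
    bin_edges: np.ndarray
    histogram: np.ndarray
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.histogram,
            }
        )


def maf_summary(
    gm: GenotypeMatrix,
    pops: PopulationMap | None = None,
    population: str | None = None,
    bin_width: float = 0.015,
    polymorphic_only: bool = True,
) -> MafSummary:
    """Minor allele frequencies over called alleles for one population.

    Sites with zero called alleles are excluded (counted in
    ``n_excluded``); the median is taken over polymorphic sites.
    """
    idx = pops.indices(gm, population) if population is not None else None
    alt, n = gm.allele_counts(idx)
    usable = n > 0
    if polymorphic_only:
        usable &= (alt > 0) & (alt < n)
    p = alt[usable] / n[usable]
    maf = np.minimum(p, 1.0 - p)
    n_bins = int(np.ceil(0.5 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], 0.5 + 1e-12)
    hist, _ = np.histogram(maf, bins=edges)
    return MafSummary(
        maf=maf,
        median=float(np.median(maf)) if maf.size else float("nan"),
        bin_width=bin_width,
        bin_edges=edges,
        histogram=hist,
        n_excluded=int((~usable).sum()),
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaComponents:
    """All intermediates of Tajima's 1989 statistic for one bin."""

    n_chrom: int
    S: int
    pi_hat: float
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    e1: float = 0.0
    e2: float = 0.0
    D: float = float("nan")


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for sample size ``n``
    chromosomes."""
    if n < 2:
        raise ValueError("need at least two chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d_from_counts(alt: np.ndarray, n: np.ndarray, n_chrom: int) -> TajimaComponents:
    """Tajima's D from per-site alt-allele counts ``alt`` among ``n`` called
    alleles, using ``n_chrom`` for the constants.

    ``pi_hat`` is the mean number of pairwise differences accumulated from
    allele counts: for a biallelic site with j alt alleles among n called,
    2 j (n - j) / (n (n - 1)).
    """
    poly = (alt > 0) & (alt < n)
    S = int(poly.sum())
    a, m = alt[poly].astype(float), n[poly].astype(float)
    pi_hat = float(np.sum(2.0 * a * (m - a) / (m * (m - 1))))
    comp = TajimaComponents(n_chrom=n_chrom, S=S, pi_hat=pi_hat)
    if n_chrom < 3 or S == 0:
        return comp
    k = tajima_constants(n_chrom)
    for key, val in k.items():
        setattr(comp, key, val)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    comp.D = float((pi_hat - S / k["a1"]) / np.sqrt(var))
    return comp


@dataclass
class TajimaResult:
    bins: list[tuple[WindowStat, TajimaComponents]]
    mean_D: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, c in self.bins:
            rows.append(
                {
                    "chrom": w.chrom, "start": w.start, "end": w.end,
                    "D": c.D, "S": c.S, "pi_hat": c.pi_hat,
                    "n_chrom": c.n_chrom,
                }
            )
        return pd.DataFrame(rows)


def tajimas_d(
    gm: GenotypeMatrix,
    pops: PopulationMap | None = None,
    population: str | None = None,
    bin_size: int = 5_000_000,
    min_snps_per_bin: int = 1,
) -> TajimaResult:
    """Tajima's D in non-overlapping physical bins per chromosome.

    ``n_chrom`` per bin is twice the number of diploids with at least one
    called genotype in the bin; bins with ``S`` below ``min_snps_per_bin``
    report a missing (NaN) D.  Returns all bins and the genome-wide mean of
    the defined bin values.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    idx = pops.indices(gm, population) if population is not None else None
    d = gm.dosage if idx is None else gm.dosage[idx, :]
    out: list[tuple[WindowStat, TajimaComponents]] = []
    for chrom in gm.chroms:
        on = gm.chrom == chrom
        length = (
            gm.contig_lengths.get(chrom) if gm.contig_lengths else None
        ) or int(gm.pos[on].max())
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            # sites with 1-based pos in (start, end]
            sel = on & (gm.pos > start) & (gm.pos <= end)
            sub = d[:, sel]
            called_any = (sub != MISSING).any(axis=1)
            n_chrom = 2 * int(called_any.sum())
            called = sub != MISSING
            alt = np.where(called, sub, 0).sum(axis=0, dtype=np.int64)
            n = 2 * called.sum(axis=0, dtype=np.int64)
            comp = tajima_d_from_counts(alt, n, max(n_chrom, 0))
            if comp.S < min_snps_per_bin:
                comp.D = float("nan")
            out.append(
                (
                    WindowStat(chrom, start, end, comp.D, comp.S),
                    comp,
                )
            )
    ds = np.array([c.D for _, c in out])
    mean = float(np.nanmean(ds)) if np.isfinite(ds).any() else float("nan")
    return TajimaResult(bins=out, mean_D=mean)


# ---------------------------------------------------------------------------
# windowed observed heterozygosity
# ---------------------------------------------------------------------------

def windowed_heterozygosity(
    gm: GenotypeMatrix,
    pops: PopulationMap | None = None,
    population: str | None = None,
    window: int = 5_000_000,
    step: int = 2_500_000,
) -> list[WindowStat]:
    """Mean per-SNP observed heterozygosity in sliding windows.

    Per SNP, H_obs is the fraction of called diploids that are
    heterozygous; window value is the mean over SNPs in the window (NaN for
    windows without SNPs).
    """
    idx = pops.indices(gm, population) if population is not None else None
    d = gm.dosage if idx is None else gm.dosage[idx, :]
    called = (d != MISSING).sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hobs = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    poly = gm.is_polymorphic(idx)
    out = []
    for chrom in gm.chroms:
        on = gm.chrom == chrom
        length = (
            gm.contig_lengths.get(chrom) if gm.contig_lengths else None
        ) or int(gm.pos[on].max())
        for start, end in iter_windows(length, window, step):
            sel = on & (gm.pos > start) & (gm.pos <= end) & poly & (called > 0)
            vals = hobs[sel]
            out.append(
                WindowStat(
                    chrom, start, end,
                    float(np.mean(vals)) if vals.size else float("nan"),
                    int(sel.sum()),
                )
            )
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity with invariant sites (missing-data-aware)
# ---------------------------------------------------------------------------

def nucleotide_diversity_pixy(
    gm: GenotypeMatrix,
    pops: PopulationMap | None = None,
    population: str | None = None,
    window: int = 5_000_000,
    step: int | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity with the missing-data-aware
    denominator: pi = sum(site differences) / sum(site comparisons), where
    a site with j alt alleles among n called contributes j(n-j)
    differences and n(n-1)/2 comparisons; uncalled sites contribute to
    neither sum.  Requires invariant sites to have been retained upstream
    for an unbiased denominator.
    """
    idx = pops.indices(gm, population) if population is not None else None
    alt, n = gm.allele_counts(idx)
    alt = alt.astype(float)
    n = n.astype(float)
    diffs = alt * (n - alt)
    comps = n * (n - 1) / 2.0
    step = step or window
    out = []
    for chrom in gm.chroms:
        on = gm.chrom == chrom
        length = (
            gm.contig_lengths.get(chrom) if gm.contig_lengths else None
        ) or int(gm.pos[on].max())
        for start, end in iter_windows(length, window, step):
            sel = on & (gm.pos > start) & (gm.pos <= end)
            tot_comp = comps[sel].sum()
            tot_diff = diffs[sel].sum()
            value = float(tot_diff / tot_comp) if tot_comp > 0 else float("nan")
            out.append(
                WindowStat(
                    chrom, start, end, value,
                    int((sel & (alt > 0) & (alt < n)).sum()),
                    extra={
                        "n_diffs": float(tot_diff),
                        "n_comparisons": float(tot_comp),
                    },
                )
            )
    return out


# ---------------------------------------------------------------------------
# cross-population summary table
# ---------------------------------------------------------------------------

@dataclass
class PopulationSummaries:
    per_group: pd.DataFrame
    fold_excess_min: float
    fold_excess_max: float
    median_maf_ratio: float


def population_summaries(
    datasets: dict[str, GenotypeMatrix],
    focal: list[str],
    reference: list[str],
    bin_size: int = 5_000_000,
) -> PopulationSummaries:
    """Summary table across within-group datasets.

    Per group: SNP count, median MAF and genome-wide mean Tajima's D.
    Across groups: the min/max fold-excess of focal over reference SNP
    counts, and the ratio of the mean focal median MAF to the midpoint of
    the reference median-MAF range.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two groups")
    rows = {}
    for name, ds in datasets.items():
        ms = maf_summary(ds)
        td = tajimas_d(ds, bin_size=bin_size)
        rows[name] = {
            "n_snps": int(ds.is_polymorphic().sum()),
            "median_maf": ms.median,
            "mean_tajimas_d": td.mean_D,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "population"
    folds = [
        rows[f]["n_snps"] / rows[r]["n_snps"] for f in focal for r in reference
    ]
    ref_medians = [rows[r]["median_maf"] for r in reference]
    focal_medians = [rows[f]["median_maf"] for f in focal]
    midpoint = (min(ref_medians) + max(ref_medians)) / 2.0
    return PopulationSummaries(
        per_group=df,
        fold_excess_min=float(min(folds)),
        fold_excess_max=float(max(folds)),
        median_maf_ratio=float(np.mean(focal_medians) / midpoint),
    )


def summaries_from_counts(
    focal_counts: list[int],
    reference_counts: list[int],
    focal_medians: list[float] | None = None,
    reference_medians: list[float] | None = None,
) -> dict[str, float]:
    """The same cross-group ratios computed directly from reported SNP
    counts and median MAFs (no genotype data required)."""
    folds = [f / r for f in focal_counts for r in reference_counts]
    out = {
        "fold_excess_min": float(min(folds)),
        "fold_excess_max": float(max(folds)),
    }
    if focal_medians and reference_medians:
        midpoint = (min(reference_medians) + max(reference_medians)) / 2.0
        out["median_maf_ratio"] = float(np.mean(focal_medians) / midpoint)
    return out
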