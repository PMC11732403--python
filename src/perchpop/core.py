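"""Core in-memory containers shared by every stage of the pipeline.

Coordinates are VCF-style 1-based at I/O boundaries only; every internal
interval (windows, bins, features) is 0-based half-open ``[start, end)``.
Genotypes are stored as alt-allele dosage per diploid sample: 0, 1, 2, or
-1 for a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages for samples x sites.

    Parameters
    ----------
    chrom, pos : per-site chromosome label and 1-based position (pos strictly
        increasing within each chromosome).
    ref, alt : per-site allele strings; ``alt == "."`` marks an invariant
        (monomorphic reference) site retained for nucleotide diversity.
    dosage : int8 array of shape (n_samples, n_sites); -1 encodes a missing
        call.
    samples : ordered sample identifiers.
    contig_lengths : optional chromosome lengths (bp) used for windowing and
        VCF contig headers.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        if len(self.samples) == 0:
            raise ValueError("at least one sample required")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for c in self.chroms:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # -- subsetting ----------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            contig_lengths=self.contig_lengths,
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([lookup[n] for n in names], dtype=np.intp)
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx, :],
            samples=list(names),
            contig_lengths=self.contig_lengths,
        )

    # -- per-site allele bookkeeping ------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Return (alt allele count, called allele count) per site."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx, :]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
        n_called = 2 * called.sum(axis=0, dtype=np.int64)
        return alt, n_called

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        alt, n = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    def is_polymorphic(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        alt, n = self.allele_counts(sample_idx)
        return (alt > 0) & (alt < n)

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )

    def equal(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class PopulationMap:
    """Assignment of every sample to exactly one population."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("population map is empty")

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample", "population"],
            dtype=str, comment="#",
        )
        dup = df["sample"][df["sample"].duplicated()]
        if len(dup):
            raise ValueError(f"samples assigned more than once: {sorted(set(dup))}")
        return cls(dict(zip(df["sample"], df["population"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_for(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    def indices(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        """Row indices in ``gm`` of the samples belonging to ``population``."""
        members = set(self.samples_for(population))
        idx = np.array(
            [i for i, s in enumerate(gm.samples) if s in members], dtype=np.intp
        )
        if idx.size == 0:
            raise KeyError(f"population {population!r} absent from genotype matrix")
        return idx


@dataclass
class DatasetSpec:
    """How to turn raw calls into an analysis-ready SNP dataset.

    ``study_wide`` filters on minor allele frequency computed across all
    samples jointly; ``within_group`` filters each population on its own
    within-population MAF and polymorphism, yielding one dataset per
    population.
    """

    mode: str = "within_group"
    maf_min: float = 0.02
    biallelic_only: bool = True
    polymorphic_only: bool = True
    max_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("study_wide", "within_group"):
            raise ValueError(f"unknown dataset mode {self.mode!r}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")


@dataclass
class WindowStat:
    """A statistic attached to a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    value: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must be < end")


def window_stats_frame(stats: Iterable[WindowStat]) -> pd.DataFrame:
    rows = []
    for w in stats:
        row = {"chrom": w.chrom, "start": w.start, "end": w.end,
               "value": w.value, "n_snps": w.n_snps}
        row.update(w.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def iter_windows(length: int, window: int, step: int):
    """Sliding 0-based half-open windows covering [0, length)."""
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window size")
    start = 0
    while start < length:
        yield start, min(start + window, length)
        if start + window >= length:
            break
        start += step
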