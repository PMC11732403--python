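"""Weir-Cockerham F_ST at site, pair and matrix level, plus SNP-sharing.

The estimator follows Weir & Cockerham (1984) for a biallelic locus:
variance components a (among populations), b (among individuals within
populations) and c (within individuals), with theta = a / (a + b + c).
Multi-site combination uses the weighted "ratio of sums"
sum(a) / sum(a + b + c); negative per-site estimates are retained, not
truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class WCComponents:
    """Per-site Weir-Cockerham intermediates for r populations."""

    r: int
    n_i: np.ndarray      # called diploids per pop (per site: shape r x sites)
    p_i: np.ndarray      # alt-allele frequency per pop
    h_i: np.ndarray      # observed het fraction per pop
    n_bar: np.ndarray
    n_c: np.ndarray
    p_bar: np.ndarray
    s2: np.ndarray
    h_bar: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray    # NaN where undefined (monomorphic across pops)


def wc_components(
    counts: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> WCComponents:
    """Weir-Cockerham variance components from per-population per-site
    summaries.

    ``counts`` holds, per population, arrays ``(n_called_diploids,
    alt_freq, het_fraction)``.  Sites where fewer than two populations have
    called diploids, or that are monomorphic across populations, yield
    ``theta = NaN``.
    """
    r = len(counts)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.stack([np.asarray(c[0], dtype=float) for c in counts])
    p_i = np.stack([np.asarray(c[1], dtype=float) for c in counts])
    h_i = np.stack([np.asarray(c[2], dtype=float) for c in counts])
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        inner = (
            p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0
        )
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        den = a + b + c
        theta = np.where(den != 0.0, a / den, np.nan)
    # sites monomorphic across all pops are undefined, components zeroed
    mono = (p_bar <= 0.0) | (p_bar >= 1.0)
    bad = mono | (n_i <= 0).any(axis=0) | (n_bar <= 1.0)
    theta = np.where(bad, np.nan, theta)
    for arr in (a, b, c):
        arr[mono] = 0.0
    return WCComponents(
        r=r, n_i=n_i, p_i=p_i, h_i=h_i, n_bar=n_bar, n_c=n_c,
        p_bar=p_bar, s2=s2, h_bar=h_bar, a=a, b=b, c=c, theta=theta,
    )


def _pop_counts(gm: GenotypeMatrix, idx: np.ndarray):
    d = gm.dosage[idx, :]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), 0.0)
        h = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), 0.0)
    return n, p, h


@dataclass
class FstTable:
    """Per-site Weir-Cockerham estimates for one pairwise comparison."""

    pop_a: str
    pop_b: str
    chrom: np.ndarray
    pos: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    weighted_theta: float
    mean_theta: float

    @property
    def label(self) -> str:
        return f"{self.pop_a}~{self.pop_b}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom, "pos": self.pos,
                "a": self.a, "b": self.b, "c": self.c, "theta": self.theta,
            }
        )


def wc_fst_pair(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> FstTable:
    """Per-site and weighted Weir-Cockerham theta for one population pair.

    Sites monomorphic across the pair are excluded from the table and from
    both sums (weighted theta = sum(a) / sum(a+b+c)); ``mean_theta`` is the
    unweighted average of per-site estimates.
    """
    ia, ib = pops.indices(gm, pop_a), pops.indices(gm, pop_b)
    comp = wc_components([_pop_counts(gm, ia), _pop_counts(gm, ib)])
    keep = ~np.isnan(comp.theta)
    den = comp.a[keep] + comp.b[keep] + comp.c[keep]
    num = comp.a[keep]
    weighted = float(num.sum() / den.sum()) if den.sum() != 0 else float("nan")
    return FstTable(
        pop_a=pop_a,
        pop_b=pop_b,
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        a=comp.a[keep],
        b=comp.b[keep],
        c=comp.c[keep],
        theta=comp.theta[keep],
        weighted_theta=weighted,
        mean_theta=float(np.mean(comp.theta[keep])) if keep.any() else float("nan"),
    )


def mean_pairwise_fst(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of weighted mean theta for every population pair
    (NaN diagonal; NaN entries where a pair has no usable site)."""
    names = populations or pops.populations
    if len(names) < 2:
        raise ValueError("need at least two populations")
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, pa in enumerate(names):
        for pb in names[i + 1:]:
            w = wc_fst_pair(gm, pops, pa, pb).weighted_theta
            mat.loc[pa, pb] = w
            mat.loc[pb, pa] = w
    return mat


@dataclass
class SharedSnps:
    n_shared: int
    n_a: int
    fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def shared_snp_fraction(
    dataset_a: GenotypeMatrix,
    dataset_b: GenotypeMatrix,
) -> SharedSnps:
    """Fraction of dataset A's polymorphic sites that are also polymorphic
    in dataset B (both on the same coordinate system)."""
    keys_a = _poly_keys(dataset_a)
    if not keys_a:
        raise ValueError("dataset A has no polymorphic sites")
    keys_b = _poly_keys(dataset_b)
    shared = len(keys_a & keys_b)
    return SharedSnps(
        n_shared=shared, n_a=len(keys_a), fraction=shared / len(keys_a)
    )


def shared_fraction_from_counts(n_shared: int, n_a: int) -> SharedSnps:
    """SNP-sharing summary from reported counts alone."""
    if n_a <= 0:
        raise ValueError("denominator count must be positive")
    return SharedSnps(n_shared=n_shared, n_a=n_a, fraction=n_shared / n_a)


def _poly_keys(gm: GenotypeMatrix) -> set:
    poly = gm.is_polymorphic()
    return {
        (c, int(p)) for c, p in zip(gm.chrom[poly], gm.pos[poly])
    }
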