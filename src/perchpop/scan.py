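"""Consensus high-F_ST outlier-window scan across pairwise comparisons.

A window is "high" for a comparison when it contains at least one SNP with
per-site theta at or above the threshold; windows high in at least
ceil(min_share_fraction x n_comparisons) comparisons are retained, and
overlapping retained windows are merged into maximal intervals.  Retained
windows can be annotated with user-supplied BED/GFF3 feature intervals
(half-open overlap semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .core import iter_windows
from .fst import FstTable


@dataclass
class ScanSpec:
    """Parameters of the consensus outlier-window scan."""

    fst_high_threshold: float = 0.6
    min_share_fraction: float = 0.8
    window_size: int = 5_000_000
    window_step: int = 2_500_000

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_high_threshold <= 1.0:
            raise ValueError("fst_high_threshold must lie in (0, 1]")
        if not 0.0 < self.min_share_fraction <= 1.0:
            raise ValueError("min_share_fraction must lie in (0, 1]")
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")


@dataclass
class OutlierWindow:
    """A retained (possibly merged) outlier interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    supporting_comparisons: list[str]
    n_snps_total: int
    n_high_fst_snps: int
    high_fst_positions: list[int] = field(default_factory=list)
    features: list[str] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.supporting_comparisons)


@dataclass
class ScanResult:
    windows: list[OutlierWindow]          # merged maximal intervals
    n_grid_windows_retained: int          # count before merging
    spec: ScanSpec
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_support": w.n_support,
                "n_snps_total": w.n_snps_total,
                "n_high_fst_snps": w.n_high_fst_snps,
                "features": ",".join(w.features) if w.features else "intergenic",
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)


def _chrom_lengths(tables: list[FstTable], contig_lengths) -> dict[str, int]:
    lengths: dict[str, int] = dict(contig_lengths or {})
    for t in tables:
        for c in np.unique(t.chrom):
            m = int(t.pos[t.chrom == c].max())
            lengths[c] = max(lengths.get(c, 0), m)
    return lengths


def consensus_outlier_windows(
    fst_tables: list[FstTable],
    spec: ScanSpec | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> ScanResult:
    """Run the consensus scan over per-comparison F_ST tables.

    All tables must share one coordinate system; the retention quota is
    ceil(min_share_fraction x number of comparisons).
    """
    spec = spec or ScanSpec()
    if len(fst_tables) < 2:
        raise ValueError("need at least two pairwise comparisons")
    labels = [t.label for t in fst_tables]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate comparison labels")
    lengths = _chrom_lengths(fst_tables, contig_lengths)
    quota = ceil(spec.min_share_fraction * len(fst_tables))

    # per chromosome, evaluate each grid window against every comparison
    retained: list[tuple[str, int, int, list[str]]] = []
    for chrom in sorted(lengths):
        for start, end in iter_windows(lengths[chrom], spec.window_size,
                                       spec.window_step):
            support = []
            for t in fst_tables:
                on = (t.chrom == chrom) & (t.pos > start) & (t.pos <= end)
                if np.any(t.theta[on] >= spec.fst_high_threshold):
                    support.append(t.label)
            if len(support) >= quota:
                retained.append((chrom, start, end, support))

    n_grid = len(retained)
    merged = _merge(retained)

    windows = []
    for chrom, start, end, support in merged:
        positions: set[int] = set()
        total: set[int] = set()
        for t in fst_tables:
            on = (t.chrom == chrom) & (t.pos > start) & (t.pos <= end)
            total.update(int(p) for p in t.pos[on])
            hi = on & (t.theta >= spec.fst_high_threshold)
            positions.update(int(p) for p in t.pos[hi])
        windows.append(
            OutlierWindow(
                chrom=chrom, start=start, end=end,
                supporting_comparisons=sorted(support),
                n_snps_total=len(total),
                n_high_fst_snps=len(positions),
                high_fst_positions=sorted(positions),
            )
        )
    return ScanResult(
        windows=windows,
        n_grid_windows_retained=n_grid,
        spec=spec,
        n_comparisons=len(fst_tables),
    )


def _merge(retained):
    """Merge overlapping/adjacent retained grid windows into maximal
    intervals, pooling their supporting comparisons."""
    out = []
    for chrom, start, end, support in sorted(
        retained, key=lambda r: (r[0], r[1])
    ):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end),
                       sorted(set(prev[3]) | set(support)))
        else:
            out.append((chrom, start, end, list(support)))
    return out


# ---------------------------------------------------------------------------
# feature-interval annotation
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    chrom: str
    start: int   # 0-based half-open
    end: int
    name: str


def read_features(path) -> list[Feature]:
    """Read feature intervals from BED (0-based half-open) or GFF3
    (1-based closed, converted).  Malformed lines raise with their line
    number."""
    text = open(path).read().splitlines()
    is_gff = str(path).endswith((".gff", ".gff3")) or any(
        ln.startswith("##gff-version") for ln in text[:5]
    )
    feats = []
    for i, line in enumerate(text, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if is_gff:
                if len(parts) < 9:
                    raise ValueError("GFF3 line has fewer than 9 fields")
                chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                s, e = int(start) - 1, int(end)
                name = _gff_name(parts[8]) or ftype
            else:
                if len(parts) < 3:
                    raise ValueError("BED line has fewer than 3 fields")
                chrom, s, e = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{s}-{e}"
            if s >= e:
                raise ValueError(f"empty or inverted interval [{s}, {e})")
        except ValueError as err:
            raise ValueError(f"{path}: malformed feature line {i}: {err}") from None
        feats.append(Feature(chrom, s, e, name))
    return feats


def _gff_name(attrs: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
    )
    return fields.get("ID") or fields.get("Name")


def annotate_windows(
    windows: list[OutlierWindow],
    features: list[Feature] | str,
) -> list[OutlierWindow]:
    """Attach the identifiers of all features overlapping each window
    (half-open semantics); windows without any overlap get an empty feature
    list and render as "intergenic"."""
    if isinstance(features, (str, bytes)) or hasattr(features, "__fspath__"):
        features = read_features(features)
    by_chrom: dict[str, list[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for w in windows:
        hits = [
            f.name
            for f in by_chrom.get(w.chrom, [])
            if f.start < w.end and w.start < f.end
        ]
        w.features = hits
    return windows


def write_bed(result: ScanResult, path) -> None:
    """Retained windows as BED with support and high-SNP counts."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_support\tn_high_fst_snps\tfeatures\n")
        for w in result.windows:
            feats = ",".join(w.features) if w.features else "intergenic"
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_support}\t"
                f"{w.n_high_fst_snps}\t{feats}\n"
            )
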