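"""End-to-end pipeline: simulate -> filter -> stats -> fst -> scan -> ne.

Stages communicate through files in the output directory so any stage can
be rerun from cached upstream outputs; every output carries provenance
(package version, seed, configuration hash).  Reports avoid timestamps so
identical configuration and seed reproduce byte-identical bodies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import DatasetSpec, GenotypeMatrix, PopulationMap, window_stats_frame
from .datasets import build_dataset, hwe_report
from .diversity import (
    maf_summary,
    nucleotide_diversity_pixy,
    population_summaries,
    tajimas_d,
    windowed_heterozygosity,
)
from .fst import mean_pairwise_fst, shared_snp_fraction, wc_fst_pair
from .ne import (
    ld_pairwise_r2,
    ne_point_ld,
    ne_trajectory_linkage_bins,
    trajectory_frame,
)
from .scan import ScanSpec, annotate_windows, consensus_outlier_windows, write_bed
from .sim import SimConfig, make_perch_scenario, population_map_for, simulate_wright_fisher
from .vcfio import read_vcf, write_vcf


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``vcf`` (+ ``population_map``) or the simulation preset
    (``simulate=True``) must be provided.
    """

    outdir: str = "perchpop_run"
    seed: int = 0
    # input data
    vcf: str | None = None
    population_map: str | None = None
    features: str | None = None
    # or simulation
    simulate: bool = True
    scale: float = 0.02
    sim_config: str | None = None      # explicit scenario YAML overrides preset
    # analysis parameters
    maf_min: float = 0.02
    focal: list[str] = field(default_factory=lambda: ["gb", "mus"])
    reference: list[str] = field(default_factory=lambda: ["m1", "m2", "m3", "m4", "m5"])
    bin_size: int = 500_000
    window: int = 500_000
    step: int = 250_000
    fst_high_threshold: float = 0.6
    min_share_fraction: float = 0.8
    ne_maf_screen: float = 0.02
    ne_max_pairs: int = 50_000
    recomb_rate: float = 1e-7

    def validate(self) -> None:
        if not self.simulate and self.sim_config is None:
            if self.vcf is None:
                raise ValueError("run config: either 'vcf' or simulation required")
            if self.population_map is None:
                raise ValueError("run config: missing field 'population_map'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # a location, not an analysis parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> dict:
    return {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }


def _write_tsv(df, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        p = _provenance(cfg)
        fh.write(f"#perchpop={p['version']} seed={p['seed']} config={p['config_hash']}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> tuple[Path, Path]:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.sim_config:
        sim = SimConfig.from_yaml(cfg.sim_config)
        sim.seed = cfg.seed
    else:
        sim = make_perch_scenario(cfg.scale, seed=cfg.seed)
    gm, truth = simulate_wright_fisher(sim)
    vcf_path = out / "simulated.vcf"
    write_vcf(gm, vcf_path, source=f"perchpop-{__version__}-seed{cfg.seed}")
    truth.to_yaml(out / "truth.yaml")
    pm = population_map_for(sim)
    pm.to_tsv(out / "popmap.tsv")
    return vcf_path, out / "popmap.tsv"


def _load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    if cfg.simulate or cfg.sim_config:
        vcf = Path(cfg.outdir) / "simulated.vcf"
        pmp = Path(cfg.outdir) / "popmap.tsv"
        if not vcf.exists():
            vcf, pmp = stage_simulate(cfg)
    else:
        vcf, pmp = Path(cfg.vcf), Path(cfg.population_map)
    pm = PopulationMap.from_tsv(pmp)
    gm = read_vcf(vcf, pm)
    return gm, pm


def stage_filter(cfg: RunConfig, gm, pm):
    spec = DatasetSpec(mode="within_group", maf_min=cfg.maf_min)
    within = build_dataset(gm, pm, spec)
    study = build_dataset(
        gm, pm, DatasetSpec(mode="study_wide", maf_min=cfg.maf_min)
    )
    return within, study


def stage_stats(cfg: RunConfig, gm, pm, within) -> dict:
    out = Path(cfg.outdir)
    stats: dict = {"populations": {}}
    for pop, ds in within.items():
        ms = maf_summary(ds)
        td = tajimas_d(ds, bin_size=cfg.bin_size)
        hob = windowed_heterozygosity(ds, window=cfg.window, step=cfg.step)
        stats["populations"][pop] = {
            "n_snps": int(ds.is_polymorphic().sum()),
            "median_maf": ms.median,
            "mean_tajimas_d": td.mean_D,
            "mean_hobs": float(np.nanmean([w.value for w in hob])),
        }
        _write_tsv(td.to_frame(), out / f"tajima_{pop}.tsv", cfg)
        _write_tsv(window_stats_frame(hob), out / f"hobs_{pop}.tsv", cfg)
        _write_tsv(ms.to_frame(), out / f"maf_hist_{pop}.tsv", cfg)
    # pi uses the unfiltered matrix (invariant sites retained)
    for pop in pm.populations:
        pw = nucleotide_diversity_pixy(gm, pm, pop, window=cfg.window)
        stats["populations"][pop]["pi"] = float(
            np.nanmean([w.value for w in pw])
        )
        _write_tsv(window_stats_frame(pw), out / f"pi_{pop}.tsv", cfg)
    stats["hwe"] = hwe_report(gm, pm)
    focal = [p for p in cfg.focal if p in within]
    ref = [p for p in cfg.reference if p in within]
    if focal and ref:
        summ = population_summaries(
            within, focal=focal, reference=ref, bin_size=cfg.bin_size
        )
        stats["fold_excess_min"] = summ.fold_excess_min
        stats["fold_excess_max"] = summ.fold_excess_max
        stats["median_maf_ratio"] = summ.median_maf_ratio
        shared = {}
        for f in focal:
            for r in ref:
                sh = shared_snp_fraction(within[f], within[r])
                shared[f"{f}~{r}"] = {
                    "n_shared": sh.n_shared,
                    "n_focal": sh.n_a,
                    "percent": sh.percent,
                }
        stats["shared_snps"] = shared
    return stats


def stage_fst(cfg: RunConfig, gm, pm) -> dict:
    out = Path(cfg.outdir)
    mat = mean_pairwise_fst(gm, pm)
    _write_tsv(mat.reset_index(), out / "fst_matrix.tsv", cfg)
    tables = []
    for f in cfg.focal:
        for r in cfg.reference:
            if f in pm.populations and r in pm.populations:
                t = wc_fst_pair(gm, pm, f, r)
                tables.append(t)
                _write_tsv(t.to_frame(), out / f"fst_{f}_{r}.tsv", cfg)
    return {"matrix": mat, "tables": tables}


def stage_scan(cfg: RunConfig, gm, tables) -> dict:
    if len(tables) < 2:
        raise PipelineError("scan", "needs at least two pairwise comparisons")
    spec = ScanSpec(
        fst_high_threshold=cfg.fst_high_threshold,
        min_share_fraction=cfg.min_share_fraction,
        window_size=cfg.window,
        window_step=cfg.step,
    )
    res = consensus_outlier_windows(
        tables, spec, contig_lengths=gm.contig_lengths
    )
    if cfg.features:
        annotate_windows(res.windows, cfg.features)
    write_bed(res, Path(cfg.outdir) / "outlier_windows.bed")
    return {
        "n_windows": len(res.windows),
        "n_grid_windows": res.n_grid_windows_retained,
        "windows": [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_support": w.n_support,
                "n_high_fst_snps": w.n_high_fst_snps,
                "features": w.features,
            }
            for w in res.windows
        ],
    }


def stage_ne(cfg: RunConfig, within) -> dict:
    out = Path(cfg.outdir)
    res = {}
    rows = []
    for pop, ds in within.items():
        try:
            ld = ld_pairwise_r2(
                ds,
                maf_screen=cfg.ne_maf_screen,
                max_pairs=cfg.ne_max_pairs,
                seed=cfg.seed,
            )
            est = ne_point_ld(ld)
            res[pop] = {
                "ne": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_pairs": est.n_pairs,
                "n_snps": est.n_snps,
            }
            rows.append({"population": pop, **res[pop]})
        except ValueError as e:
            res[pop] = {"error": str(e)}
        try:
            tb = ne_trajectory_linkage_bins(
                ds,
                recomb_rate=cfg.recomb_rate,
                maf_screen=cfg.ne_maf_screen,
                seed=cfg.seed,
            )
            _write_tsv(trajectory_frame(tb), out / f"ne_trajectory_{pop}.tsv", cfg)
        except ValueError:
            pass
    if rows:
        import pandas as pd

        _write_tsv(pd.DataFrame(rows), out / "ne_estimates.tsv", cfg)
    return res


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in dependency order and write ``report.json``.

    Any stage failure aborts with the stage name and offending input.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(cfg), "config": cfg.to_dict()}

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - annotate stage context
            raise PipelineError(stage, str(e)) from e

    if cfg.simulate or cfg.sim_config:
        run("simulate", stage_simulate, cfg)
    gm, pm = run("load", _load_inputs, cfg)
    within, study = run("filter", stage_filter, cfg, gm, pm)
    report["study_wide_snps"] = int(study.is_polymorphic().sum())
    report["stats"] = run("stats", stage_stats, cfg, gm, pm, within)
    fst = run("fst", stage_fst, cfg, gm, pm)
    report["fst_matrix"] = {
        a: {b: (None if np.isnan(v) else round(float(v), 6))
            for b, v in row.items()}
        for a, row in fst["matrix"].to_dict("index").items()
    }
    report["scan"] = run("scan", stage_scan, cfg, gm, fst["tables"])
    report["ne"] = run("ne", stage_ne, cfg, within)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True,
                  default=float)
    return report
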