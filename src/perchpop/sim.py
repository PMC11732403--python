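"""Forward Wright-Fisher simulation with recombination, selection and demography.

The engine evolves diploid individuals in discrete, non-overlapping
generations.  Each offspring is formed by random union of gametes; gametes
recombine with crossovers falling as a Poisson process along the physical
map (Haldane map function, uniform rate per chromosome), sites mutate
reversibly between the two alleles at rate ``mu`` per site per generation,
and viability selection acts multiplicatively across designated selected
sites in designated demes before parents are drawn.  Deme sizes follow
piecewise-constant schedules in generations before present; demes may split
from a parent deme at a configured time.

Scale guidance: the engine is intended for desk-scale scenarios
(N <= ~1000 diploids, L <= ~2e5 sites, a few thousand generations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class DemeSchedule:
    """Piecewise-constant diploid size history for one deme.

    ``n_t`` lists (generation-before-present, diploid size) breakpoints with
    strictly decreasing times; the size attached to a breakpoint applies from
    that generation forward in time (towards the present) until the next
    breakpoint.  A deme with ``split_from`` set comes into existence at
    ``split_time`` by sampling founders from its parent deme.
    """

    deme_id: str
    n_t: list[tuple[int, int]]
    split_from: str | None = None
    split_time: int | None = None

    def __post_init__(self) -> None:
        if not self.n_t:
            raise ValueError(f"deme {self.deme_id}: empty size schedule")
        times = [t for t, _ in self.n_t]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"deme {self.deme_id}: breakpoints must be strictly decreasing"
            )
        if any(t < 0 for t in times):
            raise ValueError(f"deme {self.deme_id}: negative breakpoint time")
        if any(n < 2 for _, n in self.n_t):
            raise ValueError(f"deme {self.deme_id}: sizes must be >= 2")
        if (self.split_from is None) != (self.split_time is None):
            raise ValueError(
                f"deme {self.deme_id}: split_from and split_time go together"
            )
        if self.split_time is not None and self.split_time < times[0]:
            raise ValueError(
                f"deme {self.deme_id}: split_time must be >= every breakpoint"
            )

    @property
    def origin_time(self) -> int:
        """Oldest generation at which the deme exists."""
        return self.split_time if self.split_time is not None else self.n_t[0][0]

    def size_at(self, g: int) -> int:
        """Diploid size at generation ``g`` before present.

        The size set at breakpoint t holds for all generations g <= t until
        the next (more recent) breakpoint; generations older than the first
        breakpoint use the oldest size."""
        size = self.n_t[0][1]
        for t, n in self.n_t:
            if t >= g:
                size = n
            else:
                break
        return size


@dataclass
class SelectedSite:
    """A site under viability selection (fitnesses 1 : 1+hs : 1+s) in a set
    of demes.  The selected allele is injected as standing variation at
    frequency ``f0`` in every deme alive at generation ``t0`` (``None`` means
    the start of the simulation)."""

    site: int
    demes: frozenset[str]
    s: float
    h: float = 0.5
    f0: float = 0.1
    t0: int | None = None

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must lie in [0, 1]")
        object.__setattr__(self, "demes", frozenset(self.demes))


@dataclass
class SampleSpec:
    """Draw ``n`` diploids from ``deme`` at the present and label them as
    belonging to population ``label`` in the output."""

    label: str
    deme: str
    n: int


@dataclass
class SimConfig:
    demes: list[DemeSchedule]
    L: int
    chrom_lengths: list[int]
    mu: float
    rho: float | list[float]
    samples: list[SampleSpec]
    selected_sites: list[SelectedSite] = field(default_factory=list)
    migration: list[tuple[str, str, float]] = field(default_factory=list)
    init: str | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must lie in [0, 1)")
        rhos = self.rho if isinstance(self.rho, list) else [self.rho]
        if any(r < 0 for r in rhos):
            raise ValueError("rho must be >= 0")
        if isinstance(self.rho, list) and len(self.rho) != len(self.chrom_lengths):
            raise ValueError("per-chromosome rho list length mismatch")
        if self.L < 1 or not self.chrom_lengths:
            raise ValueError("need at least one site and one chromosome")
        ids = [d.deme_id for d in self.demes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate deme ids")
        for d in self.demes:
            if d.split_from is not None and d.split_from not in ids:
                raise ValueError(f"unknown parent deme {d.split_from!r}")
        for ss in self.selected_sites:
            if not 0 <= ss.site < self.L:
                raise ValueError("selected site index out of range")
            unknown = ss.demes - set(ids)
            if unknown:
                raise ValueError(f"selected site names unknown demes {unknown}")
        for a, b, m in self.migration:
            if not 0.0 <= m < 1.0:
                raise ValueError("migration rate must lie in [0, 1)")
            if a not in ids or b not in ids:
                raise ValueError("migration names unknown deme")
        per_deme: dict[str, int] = {}
        for sp in self.samples:
            if sp.deme not in ids:
                raise ValueError(f"sample from unknown deme {sp.deme!r}")
            per_deme[sp.deme] = per_deme.get(sp.deme, 0) + sp.n
        for d in self.demes:
            want = per_deme.get(d.deme_id, 0)
            if want > d.size_at(0):
                raise ValueError(
                    f"deme {d.deme_id}: requested {want} sampled diploids but "
                    f"final size is {d.size_at(0)}"
                )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for ss in d["selected_sites"]:
            ss["demes"] = sorted(ss["demes"])
        d["migration"] = [list(m) for m in d["migration"]]
        d["demes"] = [
            {**dd, "n_t": [list(x) for x in dd["n_t"]]} for dd in d["demes"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        demes = [
            DemeSchedule(
                deme_id=x["deme_id"],
                n_t=[tuple(t) for t in x["n_t"]],
                split_from=x.get("split_from"),
                split_time=x.get("split_time"),
            )
            for x in d["demes"]
        ]
        sel = [
            SelectedSite(
                site=x["site"], demes=frozenset(x["demes"]), s=x["s"],
                h=x.get("h", 0.5), f0=x.get("f0", 0.1), t0=x.get("t0"),
            )
            for x in d.get("selected_sites", [])
        ]
        samples = [SampleSpec(**x) for x in d["samples"]]
        return cls(
            demes=demes,
            L=d["L"],
            chrom_lengths=list(d["chrom_lengths"]),
            mu=d["mu"],
            rho=d["rho"],
            samples=samples,
            selected_sites=sel,
            migration=[tuple(m) for m in d.get("migration", [])],
            init=d.get("init", 0.0),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulationTruth:
    """Ground truth written alongside every simulated dataset: a faithful
    echo of the configuration, the realized per-deme Ne(t) schedule, the
    selected-site coordinates and the seed."""

    config: SimConfig
    ne_schedule: dict[str, list[tuple[int, int]]]
    selected_positions: list[tuple[str, int, int]]  # (chrom, 1-based pos, site idx)
    seed: int

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "ne_schedule": {k: [list(x) for x in v] for k, v in self.ne_schedule.items()},
            "selected_positions": [list(x) for x in self.selected_positions],
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            config=SimConfig.from_dict(d["config"]),
            ne_schedule={k: [tuple(x) for x in v] for k, v in d["ne_schedule"].items()},
            selected_positions=[tuple(x) for x in d["selected_positions"]],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# genome layout helpers
# ---------------------------------------------------------------------------

def site_layout(L: int, chrom_lengths: list[int]):
    """Distribute ``L`` evenly spaced sites across chromosomes in proportion
    to physical length.  Returns (chrom labels, 1-based positions,
    per-chromosome slice bounds)."""
    total = float(sum(chrom_lengths))
    counts = [max(1, int(round(L * cl / total))) for cl in chrom_lengths]
    # fix rounding so counts sum to L
    while sum(counts) > L:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < L:
        counts[int(np.argmin(counts))] += 1
    chroms, poss, bounds = [], [], []
    off = 0
    for ci, (cl, n) in enumerate(zip(chrom_lengths, counts)):
        name = f"chr{ci + 1}"
        pos = (np.floor((np.arange(n) + 0.5) * cl / n) + 1).astype(np.int64)
        chroms.extend([name] * n)
        poss.append(pos)
        bounds.append((off, off + n))
        off += n
    return np.array(chroms, dtype=object), np.concatenate(poss), bounds


def _recomb_arrays(pos, bounds, rho, chrom_lengths):
    """Crossover bookkeeping per inter-site gap.

    Returns ``(lam, boundary_cols)``: ``lam[i]`` is the expected number of
    crossovers (map distance in Morgans, rho x physical distance) between
    sites i and i+1 within a chromosome and 0 across chromosome boundaries;
    ``boundary_cols`` are the template columns (site indices) where a fresh
    chromosome starts and the parental haplotype is redrawn at random (free
    recombination).  Crossover counts are Poisson and parity of the count
    decides switching, which realizes the Haldane map function exactly."""
    L = len(pos)
    lam = np.zeros(L - 1) if L > 1 else np.zeros(0)
    boundary = []
    rhos = rho if isinstance(rho, list) else [rho] * len(chrom_lengths)
    for ci, (s, e) in enumerate(bounds):
        if e - s > 1:
            d = np.diff(pos[s:e]).astype(float)
            lam[s:e - 1] = rhos[ci] * d
        if e < L:
            boundary.append(e)
    return lam, np.array(boundary, dtype=np.intp)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class _Deme:
    __slots__ = ("schedule", "haps", "fit_sites", "fit_tables")

    def __init__(self, schedule: DemeSchedule):
        self.schedule = schedule
        self.haps: np.ndarray | None = None  # (2N, L) int8
        self.fit_sites: np.ndarray | None = None
        self.fit_tables: np.ndarray | None = None


def _reproduce(rng, haps, n_children, recomb, weights):
    """One generation of random union of gametes with recombination.

    Each gamete starts from a random parental haplotype; crossovers fall as
    a Poisson process along the map (``recomb = (lam, boundary_cols)``), and
    the parental haplotype is redrawn at every chromosome boundary."""
    lam, boundary = recomb
    n_parents = haps.shape[0] // 2
    L = haps.shape[1]
    n_gam = 2 * n_children
    parent = rng.choice(n_parents, size=n_gam, p=weights)
    start = rng.integers(0, 2, size=n_gam, dtype=np.int64)
    tmpl = np.zeros((n_gam, L), dtype=np.uint8)
    if L > 1:
        if boundary.size:
            tmpl[:, boundary] = rng.integers(
                0, 2, size=(n_gam, boundary.size), dtype=np.uint8
            )
        lam_tot = float(lam.sum())
        if lam_tot > 0:
            k = rng.poisson(lam_tot, size=n_gam)
            tot = int(k.sum())
            if tot:
                rows = np.repeat(np.arange(n_gam), k)
                gaps = rng.choice(lam.size, size=tot, p=lam / lam_tot)
                # parity of Poisson crossover counts decides switching
                np.bitwise_xor.at(tmpl, (rows, gaps + 1), np.uint8(1))
        np.bitwise_xor.accumulate(tmpl, axis=1, out=tmpl)
    base = haps[2 * parent + start]
    alt = haps[2 * parent + (start ^ 1)]
    # child = base where template 0, alt where 1, in pure uint8 arithmetic
    np.bitwise_xor(base, alt, out=alt)
    np.bitwise_and(alt.view(np.uint8), tmpl, out=tmpl)
    np.bitwise_xor(base.view(np.uint8), tmpl, out=tmpl)
    return tmpl.view(np.int8)


def simulate_wright_fisher(config: SimConfig):
    """Run the forward simulation and return ``(GenotypeMatrix,
    SimulationTruth)`` for the configured present-day samples.

    Fully reproducible from ``config.seed``; monomorphic outcomes (e.g. no
    mutation) are valid outputs, not errors.
    """
    rng = np.random.default_rng(config.seed)
    chrom, pos, bounds = site_layout(config.L, config.chrom_lengths)
    recomb = _recomb_arrays(pos, bounds, config.rho, config.chrom_lengths)
    L = config.L

    demes = {d.deme_id: _Deme(d) for d in config.demes}
    order = [d.deme_id for d in config.demes]
    for d in config.demes:
        sel = [ss for ss in config.selected_sites if d.deme_id in ss.demes]
        if sel:
            dd = demes[d.deme_id]
            dd.fit_sites = np.array([ss.site for ss in sel], dtype=np.intp)
            dd.fit_tables = np.array(
                [[1.0, 1.0 + ss.h * ss.s, 1.0 + ss.s] for ss in sel]
            )

    t_start = max(d.origin_time for d in config.demes)
    roots = [d for d in config.demes if d.split_from is None]

    def _init_haps(n_dip: int) -> np.ndarray:
        h = np.zeros((2 * n_dip, L), dtype=np.int8)
        if config.init == "stationary":
            # warm start at the neutral mutation-drift equilibrium: each site
            # is segregating with probability ~ theta * a1(2N-1) and, when
            # segregating, carries a derived-allele frequency drawn from the
            # 1/f stationary density; alleles assigned at linkage equilibrium
            theta = 4.0 * n_dip * config.mu
            a1 = np.sum(1.0 / np.arange(1, 2 * n_dip))
            p_seg = min(1.0, theta * a1)
            seg = rng.random(L) < p_seg
            fmin = 1.0 / (2 * n_dip)
            u = rng.random(L)
            f = fmin * ((1.0 - fmin) / fmin) ** u
            f = np.where(seg, f, 0.0)
            h[:] = (rng.random((2 * n_dip, L)) < f[None, :]).astype(np.int8)
        else:
            f0 = float(config.init)
            if not 0.0 <= f0 <= 1.0:
                raise ValueError("init frequency must lie in [0, 1]")
            if f0 > 0:
                h[:] = (rng.random((2 * n_dip, L)) < f0).astype(np.int8)
        return h

    for d in roots:
        demes[d.deme_id].haps = _init_haps(d.size_at(t_start))

    def _inject_selected(g: int) -> None:
        for ss in config.selected_sites:
            t0 = ss.t0 if ss.t0 is not None else t_start
            if t0 == g:
                for did in order:
                    dd = demes[did]
                    if dd.haps is not None:
                        n = dd.haps.shape[0]
                        dd.haps[:, ss.site] = (
                            rng.random(n) < ss.f0
                        ).astype(np.int8)

    def _fitness(dd: _Deme) -> np.ndarray | None:
        if dd.fit_sites is None:
            return None
        g = dd.haps[0::2][:, dd.fit_sites].astype(np.intp) + \
            dd.haps[1::2][:, dd.fit_sites].astype(np.intp)
        w = np.ones(g.shape[0])
        for k in range(g.shape[1]):
            w *= dd.fit_tables[k][g[:, k]]
        tot = w.sum()
        if tot <= 0:
            return None
        return w / tot

    def _mutate(haps: np.ndarray) -> None:
        n_entries = haps.size
        n_mut = rng.binomial(n_entries, config.mu)
        if n_mut:
            idx = rng.integers(0, n_entries, size=n_mut)
            flat = haps.reshape(-1)
            np.bitwise_xor.at(flat, idx, np.int8(1))

    _inject_selected(t_start)
    for g in range(t_start, 0, -1):
        # found demes whose split time has arrived (they exist at g already)
        for d in config.demes:
            if d.split_time == g and demes[d.deme_id].haps is None:
                parent = demes[d.split_from]
                if parent.haps is None:
                    raise ValueError(
                        f"deme {d.deme_id} splits from {d.split_from} before "
                        "the parent exists"
                    )
                demes[d.deme_id].haps = _reproduce(
                    rng, parent.haps, d.size_at(g), recomb,
                    _fitness(parent),
                )
                _inject_selected(g)  # allow t0 == split_time to hit the child
        # reproduce g -> g-1
        for did in order:
            dd = demes[did]
            if dd.haps is None:
                continue
            n_next = dd.schedule.size_at(g - 1)
            dd.haps = _reproduce(rng, dd.haps, n_next, recomb, _fitness(dd))
            _mutate(dd.haps)
        # symmetric migration between configured pairs
        for a, b, m in config.migration:
            da, db = demes[a], demes[b]
            if da.haps is None or db.haps is None or m <= 0:
                continue
            na, nb = da.haps.shape[0] // 2, db.haps.shape[0] // 2
            n_mig = rng.binomial(min(na, nb), m)
            if n_mig:
                ia = rng.choice(na, size=n_mig, replace=False)
                ib = rng.choice(nb, size=n_mig, replace=False)
                ra = np.concatenate([2 * ia, 2 * ia + 1])
                rb = np.concatenate([2 * ib, 2 * ib + 1])
                tmp = da.haps[ra].copy()
                da.haps[ra] = db.haps[rb]
                db.haps[rb] = tmp
        if g - 1 > 0:
            _inject_selected(g - 1)

    # present-day sampling
    sample_rows, sample_ids, assignments = [], [], {}
    cursor: dict[str, np.ndarray] = {}
    offset: dict[str, int] = {}
    for sp in config.samples:
        dd = demes[sp.deme]
        n_dip = dd.haps.shape[0] // 2
        if sp.deme not in cursor:
            cursor[sp.deme] = rng.permutation(n_dip)
            offset[sp.deme] = 0
        take = cursor[sp.deme][offset[sp.deme]: offset[sp.deme] + sp.n]
        offset[sp.deme] += sp.n
        for j, ind in enumerate(take):
            sid = f"{sp.label}_{j:03d}"
            sample_ids.append(sid)
            assignments[sid] = sp.label
            sample_rows.append(
                dd.haps[2 * ind].astype(np.int16) + dd.haps[2 * ind + 1]
            )
    dosage = np.asarray(sample_rows, dtype=np.int8)

    contigs = {f"chr{i + 1}": int(cl) for i, cl in enumerate(config.chrom_lengths)}
    gm = GenotypeMatrix(
        chrom=chrom,
        pos=pos,
        ref=np.full(L, "A", dtype=object),
        alt=np.full(L, "T", dtype=object),
        dosage=dosage,
        samples=sample_ids,
        contig_lengths=contigs,
    )
    truth = SimulationTruth(
        config=config,
        ne_schedule={
            d.deme_id: [(int(t), int(n)) for t, n in d.n_t] for d in config.demes
        },
        selected_positions=[
            (str(chrom[ss.site]), int(pos[ss.site]), int(ss.site))
            for ss in config.selected_sites
        ],
        seed=config.seed,
    )
    return gm, truth


def population_map_for(config: SimConfig) -> PopulationMap:
    """The sample->population mapping implied by a simulation config."""
    d = {}
    for sp in config.samples:
        for j in range(sp.n):
            d[f"{sp.label}_{j:03d}"] = sp.label
    return PopulationMap(d)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

# Baseline (scale=1) parameterization of the three-population lake system:
# one large, stable-then-mildly-contracting main-basin deme subsampled five
# times, and two divergent demes that split from it, each carrying an old
# expansion (source of excess rare variants and negative Tajima's D), a
# recent minimum, and a 10x / 47x contemporary rebound, plus one shared
# selected site.  Times are generations before present; sizes are diploids.
_PERCH_BASE = {
    "chrom_lengths": [5_000_000] * 4,
    "L": 3000,
    "mu": 1.2e-6,
    "rho": 2.0e-9,
    # stable main basin; two focal demes split off and expand ~5x at the
    # split (historic expansion: frozen sample lineages accumulate excess
    # rare variants and negative Tajima's D), then grow again in the recent
    # past (4x and 6x, echoing the contemporary-rebound pattern)
    "main": [(5500, 20_000)],
    "split_time": 4500,
    "green_bay": [(4500, 110_000), (150, 450_000)],
    "muskegon": [(4500, 110_000), (100, 675_000)],
    "s_sel": 0.02,
    "sel_f0": 0.08,
    "n_per_site": 25,
}


def _scale_times(pairs, scale):
    out = []
    prev = None
    for t, n in pairs:
        ts = max(0, int(round(t * scale)))
        ns = max(2, int(round(n * scale)))
        if prev is not None and ts >= prev:
            ts = prev - 1
            if ts < 0:
                continue
        out.append((ts, ns))
        prev = ts
    return out


def make_perch_scenario(scale: float = 1.0, seed: int = 0) -> SimConfig:
    """Preset mirroring the three-population lake study system.

    ``scale`` rescales the scenario towards desk size using the standard
    population-genetic rescaling: deme sizes and event times shrink by
    ``scale`` while mutation, recombination and selection intensities grow
    by ``1/scale``, preserving the diffusion-scale structure (F_ST, Tajima's
    D, site-frequency shape) of the baseline.  ``scale=0.02`` is the
    recommended desk setting (main deme of 400 diploids, ~160 generations
    simulated).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    b = _PERCH_BASE
    split = max(1, int(round(b["split_time"] * scale)))

    main_nt = _scale_times(b["main"], scale)
    gb_nt = _scale_times(b["green_bay"], scale)
    mus_nt = _scale_times(b["muskegon"], scale)
    # split must be at least as old as every child breakpoint
    split = max(split, gb_nt[0][0], mus_nt[0][0])
    demes = [
        DemeSchedule("main", main_nt),
        DemeSchedule("green_bay", gb_nt, split_from="main", split_time=split),
        DemeSchedule("muskegon", mus_nt, split_from="main", split_time=split),
    ]
    L = b["L"]
    sel = SelectedSite(
        site=L // 8,  # middle of chromosome 1
        demes=frozenset({"green_bay", "muskegon"}),
        s=min(b["s_sel"] / scale, 1.0),
        h=0.5,
        f0=b["sel_f0"],
        t0=split,
    )
    n = b["n_per_site"]
    samples = [SampleSpec("gb", "green_bay", n), SampleSpec("mus", "muskegon", n)]
    samples += [SampleSpec(f"m{i + 1}", "main", n) for i in range(5)]
    return SimConfig(
        demes=demes,
        L=L,
        chrom_lengths=list(b["chrom_lengths"]),
        mu=min(b["mu"] / scale, 0.1),
        rho=b["rho"] / scale,
        samples=samples,
        selected_sites=[sel],
        init="stationary",
        seed=seed,
    )


def constant_ne_scenario(
    N: int = 100,
    n_sample: int = 50,
    L: int = 8000,
    n_chrom: int = 10,
    chrom_len: int = 1_000_000,
    mu: float = 1.5e-4,
    rho: float = 2e-6,
    generations: int = 400,
    seed: int = 0,
) -> SimConfig:
    """Single deme of constant size, warm-started at mutation-drift
    equilibrium: the reference scenario for LD-based Ne parameter recovery
    (point estimate from between-chromosome pairs, flat Ne(c) trajectory
    from within-chromosome pairs)."""
    return SimConfig(
        demes=[DemeSchedule("pop", [(generations, N)])],
        L=L,
        chrom_lengths=[chrom_len] * n_chrom,
        mu=mu,
        rho=rho,
        samples=[SampleSpec("pop", "pop", n_sample)],
        init="stationary",
        seed=seed,
    )


def expansion_scenario(
    N_anc: int = 100,
    growth_factor: int = 10,
    t_expand: int = 30,
    split_time: int = 200,
    n_sample: int = 25,
    L: int = 3000,
    n_chrom: int = 10,
    chrom_len: int = 1_000_000,
    mu: float = 2e-4,
    rho: float = 2e-6,
    generations: int = 500,
    seed: int = 0,
) -> SimConfig:
    """Two demes split from a common ancestor; one stays constant, the other
    expands ``growth_factor``-fold at ``t_expand`` generations before
    present.  The expanded deme is expected to show more segregating sites,
    a lower median MAF and negative Tajima's D relative to the stable deme."""
    return SimConfig(
        demes=[
            DemeSchedule("stable", [(generations, N_anc)]),
            DemeSchedule(
                "expanded",
                [(split_time, N_anc), (t_expand, N_anc * growth_factor)],
                split_from="stable",
                split_time=split_time,
            ),
        ],
        L=L,
        chrom_lengths=[chrom_len] * n_chrom,
        mu=mu,
        rho=rho,
        samples=[
            SampleSpec("stable", "stable", n_sample),
            SampleSpec("expanded", "expanded", n_sample),
        ],
        init="stationary",
        seed=seed,
    )


def contraction_scenario(
    N_anc: int = 600,
    N_now: int = 100,
    t_contract: int = 60,
    n_sample: int = 25,
    L: int = 2000,
    n_chrom: int = 8,
    chrom_len: int = 1_000_000,
    mu: float = 5e-5,
    rho: float = 2e-6,
    generations: int = 200,
    seed: int = 0,
) -> SimConfig:
    """Single deme contracting ``N_anc -> N_now`` at ``t_contract``
    generations before present; expected to yield positive Tajima's D."""
    return SimConfig(
        demes=[DemeSchedule("pop", [(generations, N_anc), (t_contract, N_now)])],
        L=L,
        chrom_lengths=[chrom_len] * n_chrom,
        mu=mu,
        rho=rho,
        samples=[SampleSpec("pop", "pop", n_sample)],
        init="stationary",
        seed=seed,
    )


def recent_growth_scenario(
    N_anc: int = 100,
    N_now: int = 1000,
    t_grow: int = 20,
    n_sample: int = 50,
    L: int = 3000,
    n_chrom: int = 10,
    chrom_len: int = 1_000_000,
    mu: float = 2e-4,
    rho: float = 2e-6,
    generations: int = 400,
    seed: int = 0,
) -> SimConfig:
    """Single deme growing ``N_anc -> N_now`` at ``t_grow`` generations
    before present: the reference scenario for the recombination-bin Ne(t)
    trajectory (larger Ne at small t than at large t)."""
    return SimConfig(
        demes=[DemeSchedule("pop", [(generations, N_anc), (t_grow, N_now)])],
        L=L,
        chrom_lengths=[chrom_len] * n_chrom,
        mu=mu,
        rho=rho,
        samples=[SampleSpec("pop", "pop", n_sample)],
        init="stationary",
        seed=seed,
    )
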