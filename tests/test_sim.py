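"""Wright-Fisher engine: determinism, degenerate inputs, neutral
equilibrium against an independent coalescent oracle, and the qualitative
response to demography and selection."""

import numpy as np
import pytest

from perchpop.diversity import tajimas_d
from perchpop.fst import wc_fst_pair
from perchpop.sim import (
    DemeSchedule,
    SampleSpec,
    SelectedSite,
    SimConfig,
    expansion_scenario,
    make_perch_scenario,
    population_map_for,
    simulate_wright_fisher,
)


def small_config(**kw):
    base = dict(
        demes=[DemeSchedule("p", [(60, 50)])],
        L=200,
        chrom_lengths=[100_000, 100_000],
        mu=1e-3,
        rho=1e-6,
        samples=[SampleSpec("p", "p", 10)],
        init="stationary",
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestEngineBasics:
    def test_seed_determinism(self):
        gm1, _ = simulate_wright_fisher(small_config())
        gm2, _ = simulate_wright_fisher(small_config())
        gm3, _ = simulate_wright_fisher(small_config(seed=2))
        assert gm1.equal(gm2)
        assert not gm1.equal(gm3)

    def test_no_mutation_from_fixed_start_is_monomorphic(self):
        gm, _ = simulate_wright_fisher(small_config(mu=0.0, init=1.0))
        assert np.all(gm.dosage == 2)
        assert gm.is_polymorphic().sum() == 0

    def test_dosages_within_bounds(self):
        gm, _ = simulate_wright_fisher(small_config())
        assert gm.dosage.min() >= 0 and gm.dosage.max() <= 2

    def test_sample_larger_than_deme_rejected(self):
        with pytest.raises(ValueError, match="final size"):
            small_config(samples=[SampleSpec("p", "p", 60)])

    def test_truth_echoes_config(self, tmp_path):
        cfg = small_config(
            selected_sites=[SelectedSite(site=5, demes={"p"}, s=0.1)]
        )
        gm, truth = simulate_wright_fisher(cfg)
        assert truth.seed == cfg.seed
        assert truth.selected_positions[0][2] == 5
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        from perchpop.sim import SimulationTruth

        again = SimulationTruth.from_yaml(path)
        assert again.config.to_dict() == cfg.to_dict()
        assert again.ne_schedule == truth.ne_schedule

    def test_migration_mixes_demes(self):
        demes = [
            DemeSchedule("a", [(80, 60)]),
            DemeSchedule("b", [(60, 60)], split_from="a", split_time=60),
        ]
        samples = [SampleSpec("a", "a", 15), SampleSpec("b", "b", 15)]
        common = dict(
            demes=demes, L=400, chrom_lengths=[200_000], mu=2e-3, rho=1e-6,
            samples=samples, init="stationary",
        )
        fst_iso, fst_mig = [], []
        for seed in range(3):
            gm, _ = simulate_wright_fisher(SimConfig(**common, seed=seed))
            pm = population_map_for(SimConfig(**common, seed=seed))
            fst_iso.append(wc_fst_pair(gm, pm, "a", "b").weighted_theta)
            gm, _ = simulate_wright_fisher(
                SimConfig(**common, migration=[("a", "b", 0.1)], seed=seed)
            )
            fst_mig.append(wc_fst_pair(gm, pm, "a", "b").weighted_theta)
        assert np.mean(fst_mig) < np.mean(fst_iso)


NEUTRAL = dict(N=100, L=3000, MU=1e-4, GENS=1500, N_SAMPLE=15, REPS=8)


@pytest.fixture(scope="module")
def neutral_reps():
    out = []
    for seed in range(NEUTRAL["REPS"]):
        cfg = SimConfig(
            demes=[DemeSchedule("p", [(NEUTRAL["GENS"], NEUTRAL["N"])])],
            L=NEUTRAL["L"],
            chrom_lengths=[300_000] * 4,
            mu=NEUTRAL["MU"],
            rho=1e-6,
            samples=[SampleSpec("p", "p", NEUTRAL["N_SAMPLE"])],
            init=0.0,
            seed=seed,
        )
        gm, _ = simulate_wright_fisher(cfg)
        out.append(gm)
    return out


class TestNeutralEquilibrium:
    """Long neutral runs from a monomorphic start should match coalescent
    expectations: Tajima's D within Monte-Carlo error of an independent
    coalescent simulation of the same scenario (same reversible two-allele
    mutation model), and the folded site-frequency spectrum close to
    1/i + 1/(2n - i).

    The sample is a modest fraction of the deme (15 of 100 diploids) so
    that the coalescent approximation itself is accurate."""

    def test_mean_tajimas_d_matches_coalescent_oracle(self, neutral_reps):
        import msprime

        wf_d = []
        for gm in neutral_reps:
            res = tajimas_d(gm, bin_size=300_000)
            wf_d.append(res.mean_D)
        # independent coalescent oracle: same theta, sample size and
        # reversible binary mutation model
        ms_d = []
        for seed in range(1, 31):
            ts = msprime.sim_ancestry(
                samples=NEUTRAL["N_SAMPLE"],
                population_size=NEUTRAL["N"],
                sequence_length=NEUTRAL["L"],
                recombination_rate=4e-4,
                random_seed=seed,
            )
            mts = msprime.sim_mutations(
                ts, rate=NEUTRAL["MU"], random_seed=seed,
                model=msprime.BinaryMutationModel(),
            )
            ms_d.append(mts.Tajimas_D())
        diff = abs(np.mean(wf_d) - np.mean(ms_d))
        assert diff < 0.2, f"WF mean D {np.mean(wf_d):.3f} vs coalescent {np.mean(ms_d):.3f}"

    def test_folded_sfs_matches_neutral_expectation(self, neutral_reps):
        n = 2 * NEUTRAL["N_SAMPLE"]
        counts = np.zeros(n // 2)
        for gm in neutral_reps:
            alt, ntot = gm.allele_counts()
            poly = (alt > 0) & (alt < ntot)
            folded = np.minimum(alt[poly], ntot[poly] - alt[poly])
            for f in folded:
                counts[f - 1] += 1
        i = np.arange(1, n // 2 + 1)
        expect = 1.0 / i + 1.0 / (n - i)
        expect[-1] /= 2.0  # i = n/2 folds onto itself
        expect /= expect.sum()
        obs = counts / counts.sum()
        tv = 0.5 * np.abs(obs - expect).sum()
        assert tv < 0.06, f"total-variation distance {tv:.3f}"


class TestDemographicResponse:
    def test_expansion_direction(self):
        """An expanded deme carries more segregating sites and a lower
        median MAF than its stable sister in most replicates."""
        wins = 0
        reps = 5
        for seed in range(reps):
            cfg = expansion_scenario(L=1500, n_chrom=6, seed=seed)
            gm, _ = simulate_wright_fisher(cfg)
            pm = population_map_for(cfg)
            res = {}
            for pop in ("stable", "expanded"):
                idx = pm.indices(gm, pop)
                poly = gm.is_polymorphic(idx)
                res[pop] = (
                    int(poly.sum()),
                    float(np.median(gm.maf(idx)[poly])),
                )
            if res["expanded"][0] > res["stable"][0] and \
               res["expanded"][1] < res["stable"][1]:
                wins += 1
        assert wins >= 4

    def test_selected_site_is_extreme_fst_outlier(self):
        """A planted selected site should exceed the genome-wide 99th
        percentile of per-site F_ST in most replicates."""
        hits = 0
        reps = 5
        for seed in range(reps):
            demes = [
                DemeSchedule("a", [(120, 200)]),
                DemeSchedule("b", [(60, 200)], split_from="a", split_time=60),
            ]
            cfg = SimConfig(
                demes=demes,
                L=1000,
                chrom_lengths=[500_000, 500_000],
                mu=5e-4,
                rho=1e-6,
                samples=[SampleSpec("a", "a", 25), SampleSpec("b", "b", 25)],
                selected_sites=[
                    SelectedSite(site=250, demes={"b"}, s=0.5, f0=0.1, t0=60)
                ],
                init="stationary",
                seed=seed,
            )
            gm, truth = simulate_wright_fisher(cfg)
            pm = population_map_for(cfg)
            tab = wc_fst_pair(gm, pm, "a", "b")
            sel_pos = truth.selected_positions[0][1]
            on = tab.pos == sel_pos
            if not on.any():
                continue
            q99 = np.quantile(tab.theta, 0.99)
            if tab.theta[on][0] >= q99:
                hits += 1
        assert hits >= 3


class TestPerchPreset:
    def test_scale_one_validates(self):
        cfg = make_perch_scenario(1.0)
        assert len(cfg.demes) == 3
        assert len(cfg.samples) == 7

    def test_scaling_shrinks_sizes_linearly(self):
        full = make_perch_scenario(1.0)
        tenth = make_perch_scenario(0.1)
        for d1, d01 in zip(full.demes, tenth.demes):
            for (t1, n1), (t01, n01) in zip(d1.n_t, d01.n_t):
                assert n01 == max(2, round(n1 * 0.1))
                assert t01 <= t1
        # rates rescale inversely so diffusion-scale structure is preserved
        assert tenth.mu == pytest.approx(full.mu * 10)

    def test_infeasible_scale_rejected(self):
        with pytest.raises(ValueError):
            make_perch_scenario(0.0)
        with pytest.raises(ValueError):
            make_perch_scenario(1.5)

    def test_preset_population_structure(self, preset_sim):
        gm, truth, pm = preset_sim
        assert set(pm.populations) == {"gb", "mus", "m1", "m2", "m3", "m4", "m5"}
        assert gm.n_samples == 175
        # the planted selected site is near-fixed in both focal demes only
        site = truth.selected_positions[0][2]
        for pop in ("gb", "mus"):
            assert gm.alt_freq(pm.indices(gm, pop))[site] > 0.8
        assert gm.alt_freq(pm.indices(gm, "m1"))[site] < 0.5
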