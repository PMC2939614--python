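import math

import numpy as np
import pytest

from fwdgwas.evolve import (
    AdmixtureConfig,
    DemographicModel,
    EvolutionConfig,
    FitnessTriple,
    MigrationModel,
    SelectionModel,
    admixture_generation,
    evolve,
    genotype_fitness,
    interval_recomb_probs,
    migrate,
    mutate_haplotype,
    random_mating_generation,
    recombine_gamete,
    scale_config,
    size_schedule,
)
from fwdgwas.popmodel import (
    HaplotypePanel,
    Locus,
    Population,
    SubPopulation,
    initialize_population,
)

from conftest import single_locus_population


class TestSizeSchedule:
    def test_linear_first_step(self):
        s = size_schedule(DemographicModel(993, 100000, 500, "linear"))
        assert s[0] == 993 and s[1] == 1191 and s[-1] == 100000

    def test_endpoints_exact(self):
        for sched in ("linear", "exponential"):
            s = size_schedule(DemographicModel(993, 100000, 500, sched))
            assert s[0] == 993 and s[-1] == 100000

    def test_constant(self):
        s = size_schedule(DemographicModel(50, 50, 10, "constant"))
        assert s == [50] * 11

    def test_t0_mismatch_errors(self):
        with pytest.raises(ValueError):
            size_schedule(DemographicModel(10, 20, 0, "linear"))


class TestScaleConfig:
    def _cfg(self, lam, sel=None, NT=50000, T=500):
        return EvolutionConfig(
            DemographicModel(1000, NT, T, "linear"),
            mu=1e-8,
            selection=sel,
            lam=lam,
        )

    def test_lambda_one_identity(self):
        cfg = self._cfg(1.0)
        assert scale_config(cfg) is cfg

    def test_sizes_and_generations_divided(self):
        out = scale_config(self._cfg(2.0))
        sizes = size_schedule(out.demographic)
        assert sizes[-1] == 25000 and len(sizes) - 1 == 250
        out5 = scale_config(self._cfg(5.0, NT=50000))
        assert size_schedule(out5.demographic)[-1] == 10000

    def test_fitness_deviation_scaled(self):
        sel = SelectionModel(((0, FitnessTriple(1, 0.996, 0.992)),))
        out = scale_config(self._cfg(2.0, sel=sel))
        f = dict(out.selection.loci)[0]
        assert f.w12 == pytest.approx(0.992)
        assert f.w22 == pytest.approx(0.984)

    def test_mutation_magnified_and_lam_reset(self):
        out = scale_config(self._cfg(5.0))
        assert out.mu == pytest.approx(5e-8)
        assert out.lam == 1.0 and out.recomb_scale == 5.0


class TestRecombination:
    def test_haldane_values(self):
        loci = [
            Locus("a", "1", 100, 0.0, 0),
            Locus("b", "1", 200, 0.0, 1),  # 0 cM
            Locus("c", "1", 300, 10.0, 2),  # 10 cM
            Locus("d", "2", 100, 0.0, 3),  # new chromosome
        ]
        r = interval_recomb_probs(loci)
        assert r[0] == 0.0
        assert r[1] == pytest.approx(0.5 * (1 - math.exp(-0.2)))
        assert r[2] == 0.5

    def test_scaling_caps_at_half(self):
        loci = [Locus("a", "1", 100, 0.0, 0), Locus("b", "1", 200, 30.0, 1)]
        r = interval_recomb_probs(loci, scale=5.0)
        assert r[0] == 0.5

    def test_no_recombination_passes_parental_haplotype(self, rng):
        haps = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.uint8)
        loci = [Locus(f"m{i}", "1", 100 * (i + 1), 0.0, i) for i in range(3)]
        pop = initialize_population(HaplotypePanel(loci, haps))
        ind = pop.individual(0, 0)
        seen = set()
        for _ in range(50):
            g = recombine_gamete(ind, np.zeros(2), rng)
            assert g.sum() in (0, 3)  # intact haplotype
            seen.add(int(g.sum()))
        assert seen == {0, 3}

    def test_homozygous_parent_gamete_fixed(self, rng):
        haps = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        loci = [Locus("a", "1", 100, 0.0, 0), Locus("b", "1", 200, 50.0, 1)]
        pop = initialize_population(HaplotypePanel(loci, haps))
        g = recombine_gamete(pop.individual(0, 0), np.array([0.3]), rng)
        np.testing.assert_array_equal(g, [1, 0])

    def test_recombinant_fraction_binomial(self, rng):
        """Double het in coupling, r=0.2: recombinant fraction over 1e5 meioses."""
        from fwdgwas.evolve import _gametes_for

        haps = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        n = 100_000
        g = _gametes_for(haps, np.zeros(n, dtype=np.int64), np.array([0.2]), rng)
        recomb = (g[:, 0] != g[:, 1]).mean()
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(recomb - 0.2) < 3 * se


class TestMutation:
    def test_mu_zero_identity(self, rng):
        hap = np.array([0, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(mutate_haplotype(hap, 0.0, rng), hap)

    def test_mu_one_flips_all(self, rng):
        hap = np.array([0, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(mutate_haplotype(hap, 1.0, rng), [1, 0, 1])

    def test_flip_count_binomial(self, rng):
        hap = np.zeros(10_000, dtype=np.uint8)
        counts = [mutate_haplotype(hap, 0.01, rng).sum() for _ in range(50)]
        se = math.sqrt(10_000 * 0.01 * 0.99 / 50)
        assert abs(np.mean(counts) - 100) < 3 * se


class TestFitness:
    def test_no_selection_is_one(self, tiny_panel):
        pop = initialize_population(tiny_panel)
        assert genotype_fitness(pop.individual(0, 0), None) == 1.0

    def test_het_fitness(self):
        haps = np.array([[1], [0]], dtype=np.uint8)
        pop = initialize_population(HaplotypePanel([Locus("a", "1", 1)], haps))
        sel = SelectionModel(((0, FitnessTriple(1, 0.996, 0.994)),))
        assert genotype_fitness(pop.individual(0, 0), sel) == pytest.approx(0.996)

    def test_multiplicative_product(self):
        haps = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        loci = [Locus("a", "1", 1), Locus("b", "1", 2, index=1)]
        pop = initialize_population(HaplotypePanel(loci, haps))
        sel = SelectionModel(
            (
                (0, FitnessTriple(1, 0.996, 0.994)),
                (1, FitnessTriple(1, 1.001, 1.005)),
            )
        )
        assert genotype_fitness(pop.individual(0, 0), sel) == pytest.approx(
            0.996 * 1.005
        )


class TestRandomMating:
    def test_child_ancestry_is_parental_mean(self, rng):
        pop = single_locus_population(10, 0.5, rng)
        sp = pop.subpops[0]
        sp.ancestry[sp.sex == 0] = 0.0
        sp.ancestry[sp.sex == 1] = 1.0
        child = random_mating_generation(pop, [20], None, np.zeros(0), 0.0, rng)
        np.testing.assert_allclose(child.subpops[0].ancestry, 0.5)

    def test_neutral_parent_choice_uniform(self, rng):
        """Chi-square goodness of fit of parental usage over 1e4 draws, N=10."""
        from scipy.stats import chisquare

        pop = single_locus_population(10, 0.5, rng)
        sp = pop.subpops[0]
        sp.sex[:] = np.arange(10) % 2
        counts = np.zeros(10)
        child = random_mating_generation(pop, [10_000], None, np.zeros(0), 0.0, rng)
        # recover usage through ancestry tags unique per individual
        for probe in range(10):
            sp.ancestry[:] = 0.0
            sp.ancestry[probe] = 1.0
            child = random_mating_generation(
                pop, [10_000], None, np.zeros(0), 0.0, rng
            )
            counts[probe] = child.subpops[0].ancestry.sum() * 2
        # each individual is probed within its sex stratum of 5: expect 2/5 * 1e4
        stat, p = chisquare(counts)
        assert p > 0.001

    def test_hwe_after_one_generation(self, rng):
        from scipy.stats import chisquare

        p0 = 0.3
        pop = single_locus_population(10_000, p0, rng)
        child = random_mating_generation(pop, [10_000], None, np.zeros(0), 0.0, rng)
        g = child.subpops[0].genotype(0)
        obs = np.bincount(g, minlength=3)
        p = child.subpops[0].haps[:, 0].mean()
        exp = 10_000 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        stat, pval = chisquare(obs, exp)
        assert pval > 0.001

    def test_generation_incremented(self, rng):
        pop = single_locus_population(5, 0.5, rng)
        child = random_mating_generation(pop, [5], None, np.zeros(0), 0.0, rng)
        assert child.generation == pop.generation + 1


class TestMigration:
    def _two_demes(self, n, rng):
        pop = single_locus_population(2 * n, 0.5, rng)
        sp = pop.subpops[0]
        from fwdgwas.evolve import _take

        a = _take(sp, np.arange(n))
        b = _take(sp, np.arange(n, 2 * n))
        a.ancestry[:] = 0.0
        b.ancestry[:] = 1.0
        return Population([a, b], pop.loci, 0)

    def test_m_zero_identity(self, rng):
        pop = self._two_demes(50, rng)
        out = migrate(pop, MigrationModel("stepping_stone", m=0.0), rng)
        assert out.sizes == pop.sizes
        np.testing.assert_array_equal(
            out.subpops[0].haps, pop.subpops[0].haps
        )

    def test_half_exchange_expected_composition(self, rng):
        pop = self._two_demes(1000, rng)
        out = migrate(pop, MigrationModel("stepping_stone", m=0.5), rng)
        assert out.sizes == [1000, 1000]
        # each deme holds half of each origin (ancestry marks origin)
        assert out.subpops[0].ancestry.mean() == pytest.approx(0.5, abs=1e-9)
        assert out.subpops[1].ancestry.mean() == pytest.approx(0.5, abs=1e-9)

    def test_gene_flow_count(self, rng):
        pop = self._two_demes(10_000, rng)
        out = migrate(
            pop, MigrationModel("gene_flow", p=0.05, source=1, sink=0), rng
        )
        # 500 replacement migrants, ancestry 1, land in the sink
        assert out.sizes == [10_000, 10_000]
        assert out.subpops[0].ancestry.sum() == pytest.approx(500)

    def test_reciprocity_preserves_total(self, rng):
        pop = self._two_demes(101, rng)
        out = migrate(pop, MigrationModel("stepping_stone", m=0.1), rng)
        assert sum(out.sizes) == 202


class TestAdmixture:
    def _mixed_pop(self, n, frac_hi, rng):
        pop = single_locus_population(n, 0.5, rng)
        sp = pop.subpops[0]
        k = int(n * frac_hi)
        sp.ancestry[:] = 0.0
        sp.ancestry[rng.choice(n, size=k, replace=False)] = 1.0
        return pop

    def test_all_zero_ancestry_children_zero(self, rng):
        pop = single_locus_population(100, 0.5, rng)
        out = admixture_generation(
            pop, AdmixtureConfig(0.8), 100, np.zeros(0), 0.0, rng
        )
        assert (out.subpops[0].ancestry == 0).all()

    def test_assort_zero_matches_random_mating_mean(self, rng):
        pop = self._mixed_pop(2000, 0.4, rng)
        out = admixture_generation(
            pop, AdmixtureConfig(0.0), 2000, np.zeros(0), 0.0, rng
        )
        se = np.sqrt(0.4 * 0.6 / 2000)
        assert abs(out.subpops[0].ancestry.mean() - 0.4) < 4 * se

    def test_mean_ancestry_conserved(self, rng):
        pop = self._mixed_pop(2000, 0.3, rng)
        means = []
        for _ in range(30):
            out = admixture_generation(
                pop, AdmixtureConfig(0.8), 2000, np.zeros(0), 0.0, rng
            )
            means.append(out.subpops[0].ancestry.mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.3) < 4 * max(se, 1e-4)

    def test_assortment_slows_mixing(self, rng):
        """With strong assortment most children stay near ancestry 0 or 1."""
        pop = self._mixed_pop(2000, 0.5, rng)
        out = admixture_generation(
            pop, AdmixtureConfig(1.0), 2000, np.zeros(0), 0.0, rng
        )
        anc = out.subpops[0].ancestry
        assert ((anc == 0.0) | (anc == 1.0)).all()


class TestEvolve:
    def _cfg(self, **kw):
        d = dict(
            demographic=DemographicModel(50, 50, 0, "constant"),
            mu=0.0,
            seed=1,
        )
        d.update(kw)
        return EvolutionConfig(**d)

    def test_t0_unchanged(self, rng):
        pop = single_locus_population(50, 0.4, rng)
        out, _ = evolve(pop, self._cfg())
        np.testing.assert_array_equal(out.subpops[0].haps, pop.subpops[0].haps)

    def test_same_seed_identical(self, rng):
        pop = single_locus_population(30, 0.4, rng, n_loci=5)
        cfg = self._cfg(
            demographic=DemographicModel(30, 120, 15, "linear"), mu=1e-4, seed=9
        )
        a, _ = evolve(pop.copy(), cfg)
        b, _ = evolve(pop.copy(), cfg)
        np.testing.assert_array_equal(a.subpops[0].haps, b.subpops[0].haps)
        np.testing.assert_array_equal(a.subpops[0].sex, b.subpops[0].sex)

    def test_summary_log_has_watched_frequencies(self, rng):
        pop = single_locus_population(40, 0.25, rng)
        cfg = self._cfg(
            demographic=DemographicModel(40, 80, 10, "linear"),
            watched_loci=(0,),
            summary_every=5,
        )
        out, log = evolve(pop, cfg)
        gens = [r["generation"] for r in log.records]
        assert gens == [0, 5, 10]
        assert all("freq_0" in r for r in log.records)

    def test_scaled_run_requires_lam_one(self, rng):
        pop = single_locus_population(10, 0.5, rng)
        cfg = self._cfg(lam=2.0, demographic=DemographicModel(10, 20, 10))
        with pytest.raises(ValueError, match="scale_config"):
            evolve(pop, cfg)
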