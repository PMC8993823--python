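import msprime
import numpy as np
import pytest

from steppedemo.demography import (
    DemographyParams,
    ScenarioId,
    default_priors,
    draw_parameters,
)
from steppedemo.simulate import (
    MISSING,
    SampleConfig,
    SnpYieldError,
    build_reference_table,
    inject_missingness,
    simulate_genotypes,
    to_msprime_demography,
)

from oracles import hudson_fst


def panmictic_params(n=1e4, t_split=10.0):
    """Equal sizes, no migration, near-zero split: effectively one deme."""
    return DemographyParams(
        scenario=ScenarioId.NO_EXPANSION,
        t_split_years=t_split,
        t_exp_years=t_split * 0.66,
        t_contr_years=t_split * 0.33,
        n_anc=n,
        n_ez_pre=n,
        n_z_pre=n,
        n_ez_lgp=n,
        n_z_lgp=n,
        n_ez_post=n,
        n_z_post=n,
        m_ez_to_z_pre=0.0,
        m_z_to_ez_pre=0.0,
        m_ez_to_z_lgp=0.0,
        m_z_to_ez_lgp=0.0,
    )


def config(**kw) -> SampleConfig:
    base = dict(
        n_ind_ez=2,
        n_ind_z=2,
        n_loci=200,
        target_snps=20,
        missing_fraction=0.0,
        mu=2.8e-9,
        gen_time_years=1.0,
    )
    base.update(kw)
    return SampleConfig(**base)


class TestSimulateGenotypes:
    def test_two_rows_per_individual(self):
        gm = simulate_genotypes(panmictic_params(), config(), seed=1)
        assert gm.values.shape == (8, 20)
        assert gm.n_individuals == 4
        assert list(gm.lineages) == ["EZ", "EZ", "Z", "Z"]

    def test_deterministic_given_seed(self):
        a = simulate_genotypes(panmictic_params(), config(), seed=5)
        b = simulate_genotypes(panmictic_params(), config(), seed=5)
        c = simulate_genotypes(panmictic_params(), config(), seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_every_column_segregating_in_conditional_mode(self):
        gm = simulate_genotypes(panmictic_params(), config(target_snps=50), seed=2)
        sums = gm.values.sum(axis=0)
        assert ((sums > 0) & (sums < gm.n_rows)).all()

    def test_neutral_sfs_proportional_to_one_over_i(self):
        """Mutation mode, panmictic constant size: mean unfolded SFS ~ 1/i.

        In the low-theta limit a locus carries at most one mutation, so the
        frequency of the retained site is distributed as E[l_i] / E[l_total]
        = (1/i) / H_{n-1}."""
        n_snps = 3000
        cfg = config(
            n_ind_ez=4, n_ind_z=1, target_snps=n_snps, n_loci=9000,
            snp_mode="mutation", mu=2e-6,
        )
        gm = simulate_genotypes(panmictic_params(), cfg, seed=42)
        counts = gm.values.sum(axis=0)
        n = gm.n_rows
        hist = np.bincount(counts, minlength=n)[1:n]
        weights = 1.0 / np.arange(1, n)
        probs = weights / weights.sum()
        expected = n_snps * probs
        se = np.sqrt(n_snps * probs * (1 - probs))
        assert (np.abs(hist - expected) <= 3 * se + 1).all()

    def test_conditional_mode_sfs_matches_genealogy_oracle(self):
        """Fixed-S mode samples site frequencies as E[l_i / l_total], the
        ms -s distribution; checked against an independent Monte-Carlo oracle
        computed from raw msprime genealogies."""
        n_snps = 3000
        cfg = config(n_ind_ez=4, n_ind_z=1, target_snps=n_snps, snp_mode="conditional")
        gm = simulate_genotypes(panmictic_params(), cfg, seed=42)
        counts = gm.values.sum(axis=0)
        n = gm.n_rows
        hist = np.bincount(counts, minlength=n)[1:n]
        # oracle: average per-tree normalized branch-length spectrum
        probs = np.zeros(n - 1)
        n_trees = 4000
        reps = msprime.sim_ancestry(
            samples=5, ploidy=2, population_size=1e4, num_replicates=n_trees, random_seed=9
        )
        for ts in reps:
            tree = ts.first()
            spectrum = np.zeros(n - 1)
            for u in tree.nodes():
                if tree.parent(u) != -1:
                    k = tree.num_samples(u)
                    if 1 <= k <= n - 1:
                        spectrum[k - 1] += tree.branch_length(u)
            probs += spectrum / spectrum.sum()
        probs /= n_trees
        expected = n_snps * probs
        se = np.sqrt(n_snps * probs * (1 - probs))
        assert (np.abs(hist - expected) <= 3 * se + 2).all()

    def test_mutation_mode_yield_error_is_informative(self):
        cfg = config(snp_mode="mutation", n_loci=5, target_snps=20)
        with pytest.raises(SnpYieldError, match="n_loci"):
            simulate_genotypes(panmictic_params(), cfg, seed=3)

    def test_old_split_has_higher_fst_than_recent_split(self):
        cfg = config(n_ind_ez=4, n_ind_z=4, target_snps=400)
        old = simulate_genotypes(panmictic_params(t_split=4e5), cfg, seed=7)
        young = simulate_genotypes(panmictic_params(t_split=100.0), cfg, seed=7)
        assert hudson_fst(old) > hudson_fst(young) + 0.2


class TestMigrationConversion:
    def test_island_model_equilibrium_fst(self):
        """Symmetric two-island model: Hudson FST ~ 1/(1 + 8Nm)."""
        n, m = 500.0, 2.5e-3
        p = DemographyParams(
            scenario=ScenarioId.NO_EXPANSION,
            t_split_years=2e5,
            t_exp_years=1e5,
            t_contr_years=5e4,
            n_anc=n,
            n_ez_pre=n,
            n_z_pre=n,
            n_ez_lgp=n,
            n_z_lgp=n,
            n_ez_post=n,
            n_z_post=n,
            m_ez_to_z_pre=m,
            m_z_to_ez_pre=m,
            m_ez_to_z_lgp=m,
            m_z_to_ez_lgp=m,
        )
        # migration must stay on in the most recent epoch for equilibrium, so
        # shrink the Holocene epoch to a negligible 1 generation
        p = DemographyParams(**{**p.as_dict(), "t_contr_years": 1.0, "t_exp_years": 2.0})
        cfg = config(n_ind_ez=4, n_ind_z=4, target_snps=4000)
        gm = simulate_genotypes(p, cfg, seed=11)
        expected = 1.0 / (1.0 + 8 * n * m)
        assert hudson_fst(gm) == pytest.approx(expected, rel=0.25)

    def test_forward_migrant_fraction_direction(self):
        """Forward EZ->Z gene flow: a closed small EZ deme keeps low diversity
        and Z (fed by EZ migrants) coalesces through EZ, so both diversities
        track the small deme; a swapped conversion would inflate both to the
        large deme's scale (500x larger)."""
        n_small, n_big = 100.0, 50_000.0
        p = DemographyParams(
            scenario=ScenarioId.PARALLEL_EXPANSION,
            t_split_years=1e6,
            t_exp_years=2.0,
            t_contr_years=1.0,
            n_anc=n_small,
            n_ez_pre=n_small,
            n_z_pre=n_big,
            n_ez_lgp=n_small + 1,
            n_z_lgp=n_big + 1,
            n_ez_post=n_small,
            n_z_post=n_big,
            m_ez_to_z_pre=0.05,
            m_z_to_ez_pre=0.0,
            m_ez_to_z_lgp=0.05,
            m_z_to_ez_lgp=0.0,
        )
        dem = to_msprime_demography(p, gen_time_years=1.0)
        mu = 1e-4
        div_ez, div_z = [], []
        reps = msprime.sim_ancestry(
            samples={"EZ": 4, "Z": 4},
            demography=dem,
            sequence_length=89,
            num_replicates=60,
            random_seed=5,
        )
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=ts.num_edges + 1)
            div_ez.append(mts.diversity(mts.samples(population=0)))
            div_z.append(mts.diversity(mts.samples(population=1)))
        theta_small = 4 * n_small * mu
        assert np.mean(div_ez) == pytest.approx(theta_small, rel=0.5)
        assert np.mean(div_z) < 10 * theta_small  # swapped would be ~500x


class TestInjectMissingness:
    def test_zero_fraction_is_identity(self):
        gm = simulate_genotypes(panmictic_params(), config(), seed=1)
        out = inject_missingness(gm, 0.0, seed=2)
        assert np.array_equal(out.values, gm.values)

    def test_realized_rate_within_binomial_interval(self):
        gm = simulate_genotypes(
            panmictic_params(), config(n_ind_ez=10, n_ind_z=10, target_snps=1000), seed=3
        )
        out = inject_missingness(gm, 0.42, seed=4)
        n = out.n_individuals * out.n_sites
        realized = out.genotype_missing_mask().sum()
        se = np.sqrt(n * 0.42 * 0.58)
        assert abs(realized - 0.42 * n) < 2.58 * se  # 99% interval

    def test_mask_is_deterministic_and_pairwise(self):
        gm = simulate_genotypes(panmictic_params(), config(target_snps=50), seed=5)
        a = inject_missingness(gm, 0.3, seed=6)
        b = inject_missingness(gm, 0.3, seed=6)
        assert np.array_equal(a.values, b.values)
        a.check_invariants()  # pair rule + no all-missing column

    def test_no_all_missing_columns_at_high_rate(self):
        gm = simulate_genotypes(
            panmictic_params(), config(n_ind_ez=2, n_ind_z=1, target_snps=200), seed=7
        )
        out = inject_missingness(gm, 0.85, seed=8)
        out.check_invariants()

    def test_fraction_validation(self):
        gm = simulate_genotypes(panmictic_params(), config(), seed=1)
        with pytest.raises(ValueError):
            inject_missingness(gm, 1.0, seed=0)


class TestReferenceTable:
    def test_balance_and_scenario_constraints(self, small_sim_table):
        table = small_sim_table
        assert len(table) == 24
        assert np.bincount(table.labels).tolist() == [8, 8, 8]
        noexp = table.params[table.params.scenario == int(ScenarioId.NO_EXPANSION)]
        assert (noexp.n_ez_pre == noexp.n_ez_lgp).all()
        assert (noexp.n_z_pre == noexp.n_z_post).all()
        assert not table.params.seed.duplicated().any()

    def test_reproducible_from_master_seed(self):
        cfg = config(target_snps=15)
        a = build_reference_table([ScenarioId.NO_EXPANSION], default_priors(), 3, cfg, seed=1)
        b = build_reference_table([ScenarioId.NO_EXPANSION], default_priors(), 3, cfg, seed=1)
        assert np.array_equal(a.images, b.images)
        assert a.params.equals(b.params)

    def test_save_load_round_trip(self, small_sim_table, tmp_path):
        small_sim_table.save(tmp_path / "table")
        again = type(small_sim_table).load(tmp_path / "table")
        assert np.array_equal(again.images, small_sim_table.images)
        assert np.array_equal(again.labels, small_sim_table.labels)

    def test_pixel_alphabet(self, small_sim_table):
        assert np.isin(small_sim_table.images, (-1, 0, 1)).all()


def test_sample_config_validation():
    with pytest.raises(ValueError):
        config(missing_fraction=1.0)
    with pytest.raises(ValueError):
        config(mu=0.0)
    with pytest.raises(ValueError):
        config(snp_mode="exact")
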