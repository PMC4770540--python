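import numpy as np
import pytest

from autozygmap.core import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval
from autozygmap.synthetic import (
    FOUNDER_ID,
    SimulationConfig,
    gene_drop,
    simulate_array_genotypes,
    simulate_pedigree,
    simulate_study,
    simulate_variant_table,
)


class TestSimulatePedigree:
    def test_cases_reach_founder_through_both_parents(self):
        config = SimulationConfig()
        ped = simulate_pedigree(config)
        cases = ped.cohort("case")
        assert len(cases) == 3
        for case in cases:
            assert ped.reaches_through_both_parents(case, FOUNDER_ID)

    def test_halfsibs_share_sire_but_not_maternal_founder_path(self):
        ped = simulate_pedigree(SimulationConfig())
        sires = {ped[h].sire for h in ped.cohort("halfsib")} | {
            ped[c].sire for c in ped.cohort("case")
        }
        assert sires == {"SIRE"}
        for sib in ped.cohort("halfsib"):
            assert FOUNDER_ID not in ped.ancestors(ped[sib].dam)

    def test_minimal_pedigree_is_valid(self):
        ped = simulate_pedigree(SimulationConfig(n_cases=1, n_unaffected_sibs=0))
        assert len(ped.cohort("case")) == 1
        assert ped.cohort("halfsib") == []

    def test_deterministic(self):
        a = simulate_pedigree(SimulationConfig(seed=5))
        b = simulate_pedigree(SimulationConfig(seed=5))
        assert a.individuals == b.individuals


class TestGeneDrop:
    def test_non_descendant_gets_zero_copies(self):
        ped = simulate_pedigree(SimulationConfig())
        copies = gene_drop(ped, FOUNDER_ID, seed=0)
        assert copies["HSDAM1"] == 0  # unrelated founder dam
        assert copies["FDAM1"] == 0

    def test_cases_forced_to_two_copies_sibs_at_most_one(self):
        ped = simulate_pedigree(SimulationConfig())
        copies = gene_drop(ped, FOUNDER_ID, seed=3)
        for case in ped.cohort("case"):
            assert copies[case] == 2
        for sib in ped.cohort("halfsib"):
            assert copies[sib] <= 1

    def test_unknown_founder_errors(self):
        ped = simulate_pedigree(SimulationConfig())
        with pytest.raises(KeyError):
            gene_drop(ped, "NOBODY", seed=0)

    def test_mendelian_constraint_on_child_copies(self):
        ped = simulate_pedigree(SimulationConfig())
        rng = np.random.default_rng(11)
        for _ in range(200):
            copies = gene_drop(ped, FOUNDER_ID, seed=rng, force=False)
            for ind in ped.individuals:
                if ind.sire is not None:
                    limit = (copies[ind.sire] > 0) + (copies[ind.dam] > 0)
                    assert 0 <= copies[ind.id] <= limit

    def test_transmission_frequency_matches_binomial_oracle(self):
        """Over many unconstrained drops a het parent transmits with p ~ 0.5."""
        ped = simulate_pedigree(SimulationConfig(n_cases=1, n_unaffected_sibs=0))
        rng = np.random.default_rng(17)
        transmitted = observed = 0
        for _ in range(10_000):
            copies = gene_drop(ped, FOUNDER_ID, seed=rng, force=False)
            # FOUNDER always carries one copy; SIRE is its offspring
            observed += 1
            transmitted += copies["SIRE"]
        p_hat = transmitted / observed
        se = np.sqrt(0.25 / observed)
        assert abs(p_hat - 0.5) <= 3 * se


@pytest.fixture(scope="module")
def small():
    config = SimulationConfig(
        n_chromosomes=3,
        chrom_length_bp=2_000_000,
        planted_interval=GenomicInterval("2", 400_001, 1_400_000),
        genotype_missing_rate=0.05,
        seed=9,
    )
    ped = simulate_pedigree(config)
    copies = gene_drop(ped, FOUNDER_ID, seed=np.random.default_rng([9, 2]))
    g, m = simulate_array_genotypes(ped, copies, config)
    return config, ped, copies, g, m


class TestSimulateArrayGenotypes:
    def test_cases_homozygous_across_planted_interval(self, small):
        config, ped, copies, g, m = small
        iv = config.planted_interval
        inside = (
            (m.df["chrom"] == iv.chrom)
            & (m.df["pos"] >= iv.start)
            & (m.df["pos"] <= iv.end)
        ).to_numpy()
        for case in ped.cohort("case"):
            calls = g.vector(case, np.flatnonzero(inside))
            called = calls[calls != MISSING]
            assert np.isin(called, [HOM_REF, HOM_ALT]).all()

    def test_missing_fraction_within_binomial_bound(self, small):
        config, _, _, g, _ = small
        frac = (g.calls == MISSING).mean()
        n = g.calls.size
        se = np.sqrt(config.genotype_missing_rate * (1 - config.genotype_missing_rate) / n)
        assert abs(frac - config.genotype_missing_rate) <= 3 * se

    def test_missing_rate_one_blanks_everything(self):
        config = SimulationConfig(
            n_chromosomes=1,
            chrom_length_bp=1_000_000,
            planted_interval=GenomicInterval("1", 1, 500_000),
            genotype_missing_rate=1.0,
            seed=2,
        )
        ped = simulate_pedigree(config)
        copies = gene_drop(ped, FOUNDER_ID, seed=0)
        g, _ = simulate_array_genotypes(ped, copies, config)
        assert (g.calls == MISSING).all()

    def test_off_chromosome_interval_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_chromosomes=2,
                planted_interval=GenomicInterval("13", 1, 100),
            )


class TestSimulateVariantTable:
    def test_planted_genotype_pattern(self, study):
        table, causal = study.variant_table, study.causal_variant
        idx = table.sites.index[
            (table.sites["pos"] == causal.pos) & (table.sites["ref"] == causal.ref)
        ][0]
        cohorts = table.roster["cohort"].to_numpy()
        breeds = table.roster["breed"].to_numpy()
        genos = table.genotypes[idx]
        assert (genos[cohorts == "case"] == HOM_ALT).all()
        ctrl = genos[cohorts == "control"]
        assert np.isin(ctrl, [HOM_REF, MISSING]).all()
        outside = (cohorts == "panel") & ~np.isin(
            breeds, list(study.config.carrier_breeds)
        )
        assert np.isin(genos[outside], [HOM_REF, MISSING]).all()

    def test_background_variant_rejected_by_recessive_filter(self, study):
        """Background sites segregate in controls, so the filter removes them all."""
        from autozygmap.variants import recessive_compatible

        cases = study.pedigree.cohort("case")
        controls = study.variant_table.roster.loc[
            study.variant_table.roster["cohort"] == "control", "individual"
        ].tolist()
        kept, _ = recessive_compatible(study.variant_table, cases, controls)
        assert kept.n_sites == 1
        assert kept.sites.loc[0, "pos"] == study.causal_variant.pos

    def test_requires_cases_to_carry_two_copies(self, study):
        bad = dict(study.carrier_states)
        bad[study.pedigree.cohort("case")[0]] = 1
        with pytest.raises(ValueError):
            simulate_variant_table(study.config, bad, study.pedigree, study.gene_model)


class TestDeterminism:
    def test_same_seed_bit_identical_outputs(self):
        config = SimulationConfig(
            n_chromosomes=2,
            chrom_length_bp=1_500_000,
            planted_interval=GenomicInterval("1", 200_001, 1_200_000),
            n_background_variants=50,
            seed=42,
        )
        a = simulate_study(config)
        b = simulate_study(config)
        assert a.pedigree.individuals == b.pedigree.individuals
        assert a.carrier_states == b.carrier_states
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        assert a.marker_map.df.equals(b.marker_map.df)
        assert a.variant_table.sites.equals(b.variant_table.sites)
        np.testing.assert_array_equal(a.variant_table.genotypes, b.variant_table.genotypes)
        assert a.causal_variant == b.causal_variant

    def test_different_seeds_differ(self):
        a = simulate_study(SimulationConfig(seed=1))
        b = simulate_study(SimulationConfig(seed=2))
        assert not np.array_equal(a.genotypes.calls, b.genotypes.calls)
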