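"""Synthetic population generator: genotypes, selfing dynamics, trials."""

import numpy as np
import pandas as pd
import pytest

from shuttlegp.markers import maf
from shuttlegp.simulate import (FamilyGenotypeState, InvalidConfigError,
                                SimConfig, TrialPlan, advance_generation_bulk,
                                make_family_states, sample_family_genotypes,
                                simulate_s0_genotypes,
                                simulate_trait_architecture, simulate_trials)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_snps=5, n_chromosomes=12).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(maf_min=0.6).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(n_reps=0).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(target_h2={"FL": 1.2}).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(gxe_share={"FL": 1.5}, target_h2={"FL": 0.5}).validate()


class TestS0Genotypes:
    def test_one_snp_per_chromosome_boundary(self):
        cfg = SimConfig(n_individuals_A=30, n_individuals_B=20, n_checks=5,
                        n_snps=12, n_chromosomes=12, seed=1)
        m = simulate_s0_genotypes(cfg)
        assert m.n_snps == 12
        assert len(set(m.chromosome)) == 12
        assert maf(m).min() >= 0.025

    def test_seeded_determinism(self):
        cfg = SimConfig(n_individuals_A=40, n_individuals_B=30, n_checks=5,
                        n_snps=50, seed=1)
        a = simulate_s0_genotypes(cfg)
        b = simulate_s0_genotypes(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert list(a.position) == list(b.position)

    def test_spectrum_keeps_rare_alleles_and_high_het(self):
        cfg = SimConfig(n_snps=2000, seed=3)
        m = simulate_s0_genotypes(cfg)
        f = maf(m)
        assert f.min() >= cfg.maf_min
        assert (f < 0.05).sum() > 0          # rare alleles not depleted
        het = np.isclose(m.dosage, 1.0).mean(axis=1)
        assert het.mean() >= 0.2             # S0 plants highly heterozygous
        # positions sorted within chromosome (MarkerMatrix enforces), 12 chrs
        assert len(set(m.chromosome)) == 12


class TestBulkAdvance:
    def test_closed_form_examples(self):
        het0 = np.array([1.0, 0.5, 0.0])
        state = FamilyGenotypeState("F1", 0, np.array([1.0, 1.0, 2.0]), het0)
        s4 = advance_generation_bulk(state, 4)
        assert s4.generation_t == 4
        # fully heterozygous locus after four selfing steps: 93.75% homozygous
        assert 1 - s4.expected_heterozygosity[0] == pytest.approx(0.9375)
        s2 = advance_generation_bulk(state, 2)
        assert s2.expected_heterozygosity[1] == pytest.approx(0.125)
        s0 = advance_generation_bulk(state, 0)
        np.testing.assert_array_equal(s0.expected_heterozygosity, het0)
        np.testing.assert_array_equal(s4.expected_dosage, state.expected_dosage)
        with pytest.raises(ValueError):
            advance_generation_bulk(state, -1)

    def test_sampled_heterozygosity_decay(self):
        # realized het of sampled plants tracks (1/2)^t over >= 1000 loci
        rng = np.random.default_rng(0)
        n_loci = 1500
        d0 = np.ones(n_loci)            # all loci heterozygous at S0
        state = FamilyGenotypeState("F", 0, d0, np.ones(n_loci))
        for t in (1, 4):
            st = advance_generation_bulk(state, t)
            plants = sample_family_genotypes(st, 40, rng)
            realized = np.isclose(plants, 1.0).mean()
            assert realized == pytest.approx(0.5 ** t, abs=0.02)

    def test_sampled_dosage_unbiased(self):
        rng = np.random.default_rng(1)
        d0 = np.array([1.0] * 500 + [0.0] * 250 + [2.0] * 250)
        het0 = np.isclose(d0, 1.0).astype(float)
        st = advance_generation_bulk(FamilyGenotypeState("F", 0, d0, het0), 3)
        plants = sample_family_genotypes(st, 200, rng)
        np.testing.assert_allclose(plants.mean(axis=0).mean(), d0.mean(), atol=0.02)

    def test_states_from_markers(self):
        cfg = SimConfig(n_individuals_A=10, n_individuals_B=5, n_checks=2,
                        n_snps=30, seed=2)
        m = simulate_s0_genotypes(cfg)
        states = make_family_states(m, generation_t=4)
        ho_s0 = np.isclose(m.dosage, 1.0).mean()
        ho_s4 = np.mean([s.expected_heterozygosity.mean() for s in states])
        assert ho_s4 == pytest.approx(ho_s0 / 16, rel=1e-12)


@pytest.fixture(scope="module")
def markers():
    cfg = SimConfig(n_individuals_A=384, n_individuals_B=334, n_checks=50,
                    n_snps=400, seed=5)
    return cfg, simulate_s0_genotypes(cfg)


class TestTraitArchitecture:
    def test_no_gxe_gives_perfect_location_correlation(self, markers):
        cfg, m = markers
        cfg = SimConfig(n_individuals_A=384, n_individuals_B=334, n_checks=50,
                        n_snps=400, seed=5,
                        target_h2={"T": 0.6}, gxe_share={"T": 0.0},
                        loc_effects={"T": {"PAL": 0, "SRO": 0}},
                        trait_scale={"T": 1.0})
        eff = simulate_trait_architecture(cfg, m)["T"]
        tot = {loc: eff.g_main + eff.g_loc[loc] for loc in ("PAL", "SRO")}
        assert np.corrcoef(tot["PAL"], tot["SRO"])[0, 1] == pytest.approx(1.0)

    def test_gxe_share_sets_genetic_correlation(self, markers):
        _, m = markers
        cfg = SimConfig(n_individuals_A=384, n_individuals_B=334, n_checks=50,
                        n_snps=400, seed=6,
                        target_h2={"T": 0.6}, gxe_share={"T": 0.6},
                        loc_effects={"T": {"PAL": 0, "SRO": 0}},
                        trait_scale={"T": 1.0})
        eff = simulate_trait_architecture(cfg, m)["T"]
        tot = {loc: eff.g_main + eff.g_loc[loc] for loc in ("PAL", "SRO")}
        r = np.corrcoef(tot["PAL"], tot["SRO"])[0, 1]
        assert r == pytest.approx(1 - 0.6, abs=0.1)

    def test_zero_heritability_gives_pure_noise(self, markers):
        _, m = markers
        cfg = SimConfig(n_individuals_A=384, n_individuals_B=334, n_checks=50,
                        n_snps=400, seed=7,
                        target_h2={"T": 0.0}, gxe_share={"T": 0.0},
                        loc_effects={"T": {"PAL": 0, "SRO": 0}},
                        trait_scale={"T": 1.0})
        eff = simulate_trait_architecture(cfg, m)["T"]
        assert np.all(eff.g_main == 0)
        assert all(np.all(v == 0) for v in eff.g_loc.values())


class TestTrials:
    def test_plot_counts_match_design(self):
        # full-size single trial: (334 families + 50 checks) x 3 reps
        cfg = SimConfig(n_snps=60, seed=8, target_h2={"FL": 0.51},
                        gxe_share={"FL": 0.59},
                        loc_effects={"FL": {"PAL": 87.4, "SRO": 81.7}},
                        trait_scale={"FL": 4.5})
        m = simulate_s0_genotypes(cfg)
        eff = simulate_trait_architecture(cfg, m)
        rec = simulate_trials(cfg, eff, [TrialPlan("B", 4, "SRO", 2020)])
        assert len(rec) == (334 + 50) * 3
        assert rec.block.between(1, 8).all()
        # checks always recorded at generation 2
        assert (rec.loc[rec.is_check, "generation"] == 2).all()
        assert (rec.loc[~rec.is_check, "generation"] == 4).all()
        # blocks filled as evenly as possible: 384 entries over 8 blocks
        per_block = rec.groupby(["rep", "block"]).size()
        assert per_block.max() - per_block.min() == 0

    def test_zero_noise_recovers_genetic_values(self):
        cfg = SimConfig(n_individuals_A=20, n_individuals_B=15, n_checks=4,
                        n_snps=40, seed=9,
                        target_h2={"T": 0.9}, gxe_share={"T": 0.0},
                        loc_effects={"T": {"PAL": 3.0, "SRO": -1.0}},
                        trait_scale={"T": 1.0}, residual_var={"T": 0.0},
                        block_var=0.0, rep_effect_sd=0.0)
        m = simulate_s0_genotypes(cfg)
        eff = simulate_trait_architecture(cfg, m)
        rec = simulate_trials(cfg, eff, [TrialPlan("B", 4, "PAL", 2020)])
        g = eff["T"].g_main + eff["T"].g_loc["PAL"]
        expected = rec.family.map(g) + 3.0
        np.testing.assert_allclose(rec.value, expected, atol=1e-12)

    def test_between_location_phenotypic_correlation_band(self):
        # with the G x E share tuned high, family-mean correlations between
        # the two sites fall in the low band seen for contrasting locations
        cfg = SimConfig(n_snps=300, seed=11, target_h2={"T": 0.45},
                        gxe_share={"T": 0.7},
                        loc_effects={"T": {"PAL": 10.0, "SRO": 5.0}},
                        trait_scale={"T": 1.0})
        m = simulate_s0_genotypes(cfg)
        eff = simulate_trait_architecture(cfg, m)
        rec = simulate_trials(cfg, eff, [TrialPlan("B", 4, "PAL", 2019),
                                         TrialPlan("B", 4, "SRO", 2020)])
        sub = rec[~rec.is_check]
        means = sub.groupby(["family", "location"]).value.mean().unstack()
        r = means.corr().iloc[0, 1]
        assert 0.2 < r < 0.35

    def test_study_determinism(self, small_cfg, small_bundle):
        from shuttlegp.simulate import simulate_study

        again = simulate_study(small_cfg)
        pd.testing.assert_frame_equal(again.records, small_bundle.records)
        np.testing.assert_array_equal(again.markers.dosage,
                                      small_bundle.markers.dosage)
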