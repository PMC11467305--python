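"""Synthetic-data generator tests: Mendelian transmission, penetrance,
determinism, calibration of background allele frequencies, expression
effects, and the single-hit limiting-dilution sampler."""

import math

import numpy as np
import pandas as pd
import pytest

from pedscreen.pedigree import Phenotype
from pedscreen.simulate import (
    ConfigurationError,
    ExprSimConfig,
    PlantedSv,
    SimConfig,
    SvSimConfig,
    build_paper_fixture,
    simulate_expression,
    simulate_limiting_dilution,
    simulate_pedigree,
    simulate_sv_table,
)


class TestSimulatePedigree:
    def test_class_counts_inconsistent_with_n_members_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_members=10, class_counts={Phenotype.MPLC: 5, Phenotype.NODULE: 9, Phenotype.UNAFFECTED: 1})

    def test_penetrance_rows_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(penetrance={True: {Phenotype.MPLC: 0.5}, False: {Phenotype.UNAFFECTED: 1.0}})

    def test_study_design_class_counts(self):
        """A 5/9/1 design yields a 15-member pedigree with those labels."""
        ped, _geno, _annot = simulate_pedigree(SimConfig(seed=7))
        counts = ped.class_counts()
        assert len(ped) == 15
        assert counts[Phenotype.MPLC] == 5
        assert counts[Phenotype.NODULE] == 9
        assert counts[Phenotype.UNAFFECTED] == 1

    def test_degenerate_penetrance_makes_phenotype_equal_carrier_status(self):
        """With 0/1 penetrance, phenotype is a deterministic function of
        carrier status (carriers -> MPLC, non-carriers -> unaffected)."""
        identity = {
            True: {Phenotype.MPLC: 1.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 0.0},
            False: {Phenotype.MPLC: 0.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 1.0},
        }
        # Find the realized carrier split first, then demand exactly that split.
        for seed in range(30):
            cfg = SimConfig(
                n_members=12,
                class_counts={Phenotype.MPLC: 6, Phenotype.NODULE: 0, Phenotype.UNAFFECTED: 6},
                penetrance=identity,
                background_variant_count=0,
                seed=seed,
            )
            try:
                ped, geno, _ = simulate_pedigree(cfg)
            except ConfigurationError:
                continue  # realized carrier count != 6; infeasible under 0/1 penetrance
            key = geno.variant_keys[0]
            carriers = set(geno.carriers(key))
            for m in ped:
                assert (m.phenotype is Phenotype.MPLC) == (m.id in carriers)
            break
        else:
            pytest.fail("no seed produced a 6/6 carrier split")

    def test_transmission_fraction_is_binomial_half(self):
        """Planted-allele transmission to 1000 offspring ~ Binomial(1000, 1/2)."""
        n_off = 1000
        cfg = SimConfig(
            n_members=n_off + 2,
            class_counts={Phenotype.MPLC: n_off + 2, Phenotype.NODULE: 0, Phenotype.UNAFFECTED: 0},
            penetrance={
                True: {Phenotype.MPLC: 1.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 0.0},
                False: {Phenotype.MPLC: 1.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 0.0},
            },
            background_variant_count=0,
            seed=11,
        )
        ped, geno, _ = simulate_pedigree(cfg)
        key = geno.variant_keys[0]
        offspring = [m.id for m in ped if m.father_id is not None]
        assert len(offspring) == n_off
        carriers = sum(1 for c in offspring if geno.table.loc[key, c] >= 1)
        sd = math.sqrt(n_off * 0.25)
        assert abs(carriers - n_off / 2) < 3 * sd

    def test_mendelian_consistency_of_planted_variants(self):
        """Every offspring planted-variant allele traces to a carrier parent."""
        cfg = SimConfig(planted_variant_count=3, background_variant_count=0, seed=3)
        ped, geno, _ = simulate_pedigree(cfg)
        by_id = {m.id: m for m in ped}
        for key in geno.variant_keys:
            for m in ped:
                gt = geno.table.loc[key, m.id]
                if m.father_id is None or pd.isna(gt) or gt == 0:
                    continue
                parent_gts = [geno.table.loc[key, p] for p in (m.father_id, m.mother_id) if p]
                assert any(pd.notna(g) and g >= 1 for g in parent_gts)

    def test_background_af_calibration(self):
        """Empirical alt-allele fraction over many members tracks the
        annotated AF within 3 binomial SDs (Hardy-Weinberg sampling)."""
        n = 600
        cfg = SimConfig(
            n_members=n,
            class_counts={Phenotype.MPLC: n, Phenotype.NODULE: 0, Phenotype.UNAFFECTED: 0},
            penetrance={
                True: {Phenotype.MPLC: 1.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 0.0},
                False: {Phenotype.MPLC: 1.0, Phenotype.NODULE: 0.0, Phenotype.UNAFFECTED: 0.0},
            },
            planted_variant_count=0,
            background_variant_count=25,
            seed=5,
        )
        _ped, geno, annot = simulate_pedigree(cfg)
        for row in annot.itertuples(index=False):
            af = row.af_1kg_eas
            key = f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}"
            alt_count = int(geno.table.loc[key].sum())
            sd = math.sqrt(2 * n * af * (1 - af))
            assert abs(alt_count - 2 * n * af) <= 3 * sd + 1

    def test_same_seed_reproduces_everything(self):
        a = simulate_pedigree(SimConfig(seed=42))
        b = simulate_pedigree(SimConfig(seed=42))
        assert a[0].members == b[0].members
        pd.testing.assert_frame_equal(a[1].table, b[1].table)
        pd.testing.assert_frame_equal(a[2], b[2])


class TestSimulateSv:
    def test_planted_event_hits_exact_group_counts(self):
        ped, _g, _a = simulate_pedigree(SimConfig(seed=1))
        cfg = SvSimConfig(
            n_background_events=0,
            planted_events=[
                PlantedSv(gene="X", group_carriers={Phenotype.MPLC: 5, Phenotype.NODULE: 9, Phenotype.UNAFFECTED: 0})
            ],
            seed=2,
        )
        table = simulate_sv_table(cfg, ped)
        assert len(table) == 1
        for cls, want in ((Phenotype.MPLC, 5), (Phenotype.NODULE, 9), (Phenotype.UNAFFECTED, 0)):
            assert table[ped.members_in_class(cls)].iloc[0].sum() == want

    def test_carrier_count_exceeding_group_size_rejected(self):
        ped, _g, _a = simulate_pedigree(SimConfig(seed=1))
        cfg = SvSimConfig(
            n_background_events=0,
            planted_events=[PlantedSv(gene="X", group_carriers={Phenotype.UNAFFECTED: 2})],
        )
        with pytest.raises(ConfigurationError):
            simulate_sv_table(cfg, ped)

    def test_same_seed_gives_identical_table(self):
        ped, _g, _a = simulate_pedigree(SimConfig(seed=1))
        cfg = SvSimConfig(n_background_events=12, seed=9)
        pd.testing.assert_frame_equal(simulate_sv_table(cfg, ped), simulate_sv_table(cfg, ped))


class TestSimulateExpression:
    def test_noiseless_planted_effect_recovered_exactly(self):
        cfg = ExprSimConfig(
            n_genes=50, planted_de={"G1": {"mutant": 2.0}}, noise_sd=0.0, seed=0
        )
        m = simulate_expression(cfg)
        log2fc = np.log2(m.loc["G1", "mutant"]) - np.log2(m.loc["G1", "wild"])
        assert log2fc == pytest.approx(2.0, abs=1e-12)

    def test_null_de_count_matches_gaussian_tail(self):
        """With no planted effects, |log2fc| between two conditions is
        N(0, sqrt(2)*noise_sd); the DE count at threshold 1 matches the
        analytic tail probability within 3 binomial SDs."""
        n_genes, sd = 4000, 0.5
        m = simulate_expression(ExprSimConfig(n_genes=n_genes, noise_sd=sd, seed=8))
        log2fc = np.log2(m["mutant"]) - np.log2(m["wild"])
        observed = int((np.abs(log2fc) > 1).sum())
        from scipy.stats import norm

        p_tail = 2 * norm.sf(1.0, scale=math.sqrt(2) * sd)
        expected = n_genes * p_tail
        assert abs(observed - expected) <= 3 * math.sqrt(n_genes * p_tail * (1 - p_tail))

    def test_unknown_condition_in_planted_effects_rejected(self):
        with pytest.raises(ConfigurationError):
            ExprSimConfig(n_genes=10, planted_de={"G1": {"nonexistent": 1.0}})

    def test_same_seed_gives_identical_matrix(self):
        cfg = ExprSimConfig(n_genes=100, seed=4)
        pd.testing.assert_frame_equal(simulate_expression(cfg), simulate_expression(cfg))


class TestSimulateLimitingDilution:
    def test_zero_frequency_all_negative(self):
        t = simulate_limiting_dilution(0.0, [1e3, 1e5], n_per_dose=20, seed=0)
        assert (t["n_positive"] == 0).all()

    def test_saturation_all_positive(self):
        t = simulate_limiting_dilution(1.0, [1e6], n_per_dose=50, seed=0)
        assert (t["n_positive"] == t["n_tested"]).all()

    def test_positive_fraction_matches_single_hit_probability(self):
        """f*d = 1 gives P(positive) = 1 - 1/e; check within 3 binomial SDs."""
        n = 10_000
        t = simulate_limiting_dilution(1e-4, [1e4], n_per_dose=n, seed=13)
        p = 1 - math.exp(-1)
        assert abs(int(t["n_positive"].iloc[0]) - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            simulate_limiting_dilution(1e-4, [-5.0], n_per_dose=5)


class TestPaperFixture:
    def test_fixture_is_deterministic(self):
        a = build_paper_fixture()
        b = build_paper_fixture()
        assert a[0].members == b[0].members
        pd.testing.assert_frame_equal(a[1].table, b[1].table)
        pd.testing.assert_frame_equal(a[2], b[2])
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_fixture_shape_and_carrier_pattern(self, paper_fixture):
        ped, geno, annot, sv = paper_fixture
        counts = ped.class_counts()
        assert (counts[Phenotype.MPLC], counts[Phenotype.NODULE], counts[Phenotype.UNAFFECTED]) == (5, 9, 1)
        # three planted candidates, each with 13 carriers (5 MPLC + 8 nodule)
        planted = [k for k in geno.variant_keys if k.startswith("17:4")][:3]
        assert len(planted) == 3
        for key in planted:
            carriers = set(geno.carriers(key))
            assert len(carriers) == 13
            assert set(ped.members_in_class(Phenotype.MPLC)) <= carriers
            assert not carriers & set(ped.members_in_class(Phenotype.UNAFFECTED))
        assert len(geno) >= 203  # 3 planted + >= 200 background

    def test_fixture_mendelian_consistency(self, paper_fixture):
        """Planted-variant carriers in the second generation have a carrier parent."""
        ped, geno, _annot, _sv = paper_fixture
        planted = [k for k in geno.variant_keys if k.startswith("17:4")][:3]
        for key in planted:
            carriers = set(geno.carriers(key))
            for m in ped:
                if m.id in carriers and m.father_id is not None:
                    assert m.father_id in carriers
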