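"""SNV cascade tests: rule semantics, brute-force segregation oracle,
cascade monotonicity/order-invariance, and the exact binomial cohort
statistic (statsmodels as independent oracle, plus coverage calibration)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from pedscreen.pedigree import Member, Pedigree, Phenotype
from pedscreen.snv import (
    CascadeRules,
    DeleteriousnessRule,
    FrequencyRule,
    RuleError,
    SegregationRule,
    carrier_frequency,
    deleteriousness_filter,
    frequency_filter,
    run_snv_cascade,
    segregation_filter,
)
from pedscreen.variants import AnnotatedVariant, GenotypeMatrix


def _variant(i, **kw):
    return AnnotatedVariant(chrom="1", pos=1000 + i, ref="A", alt="G", **kw)


class TestFrequencyRule:
    @pytest.mark.parametrize(
        "afs,expected",
        [
            ({"af_1kg_eas": 0.02}, False),          # above threshold -> removed
            ({"af_1kg_eas": 0.01}, False),          # boundary: strict "<"
            ({"af_1kg_eas": 0.0099}, True),
            ({}, True),                             # novel -> retained
            ({"af_1kg_eas": 0.001, "af_esp": 0.5}, False),  # any present AF too high
        ],
    )
    def test_threshold_semantics(self, afs, expected):
        retained, trail = frequency_filter([_variant(0, **afs)], FrequencyRule())
        assert bool(retained) is expected
        assert trail["passed"].iloc[0] == expected

    def test_novel_removed_when_absent_does_not_pass(self):
        retained, _ = frequency_filter([_variant(0)], FrequencyRule(treat_absent_as_pass=False))
        assert not retained

    def test_unknown_af_field_rejected(self):
        with pytest.raises(RuleError):
            FrequencyRule(databases=["af_gnomad"])

    def test_invalid_threshold_rejected(self):
        with pytest.raises(RuleError):
            FrequencyRule(max_af=0.0)


def _pedigree(n_mplc=5, n_nodule=9, n_unaffected=1):
    members = [Member(id=f"M{i}", phenotype=Phenotype.MPLC) for i in range(n_mplc)]
    members += [Member(id=f"N{i}", phenotype=Phenotype.NODULE) for i in range(n_nodule)]
    members += [Member(id=f"U{i}", phenotype=Phenotype.UNAFFECTED) for i in range(n_unaffected)]
    return Pedigree(members)


def _matrix(ped, rows):
    keys = [f"1:{1000 + i}:A:G" for i in range(len(rows))]
    return GenotypeMatrix.from_calls(keys, ped.member_ids, rows), [
        _variant(i) for i in range(len(rows))
    ]


class TestSegregationRule:
    def test_published_pattern_is_retained(self):
        """Het in 5/5 MPLC, 8/9 nodule, 0/1 unaffected passes the default rule."""
        ped = _pedigree()
        row = [1] * 5 + [1] * 8 + [0] + [0]
        geno, variants = _matrix(ped, [row])
        retained, counts = segregation_filter(variants, geno, ped, SegregationRule())
        assert len(retained) == 1
        assert counts.iloc[0][["carriers_MPLC", "carriers_NODULE", "carriers_UNAFFECTED"]].tolist() == [5, 8, 0]

    def test_carrier_in_unaffected_member_removes_variant(self):
        ped = _pedigree()
        row = [1] * 14 + [1]
        geno, variants = _matrix(ped, [row])
        retained, _ = segregation_filter(variants, geno, ped, SegregationRule())
        assert not retained

    def test_rule_larger_than_group_rejected(self):
        ped = _pedigree(n_mplc=2)
        geno, variants = _matrix(ped, [[0] * len(ped.member_ids)])
        with pytest.raises(RuleError):
            segregation_filter(variants, geno, ped, SegregationRule())

    def _brute_force(self, ped, geno, rule):
        """Exhaustive re-evaluation, member by member."""
        kept = []
        for key in geno.variant_keys:
            counts = {cls: 0 for cls in Phenotype}
            for m in ped:
                v = geno.table.loc[key, m.id]
                if pd.notna(v) and v >= 1:
                    counts[m.phenotype] += 1
            ok = all(counts[c] >= k for c, k in rule.min_carriers.items())
            if counts[Phenotype.UNAFFECTED] > rule.max_carriers_unaffected:
                ok = False
            if ok:
                kept.append(key)
        return kept

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_enumeration_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        ped = _pedigree(n_mplc=int(rng.integers(1, 5)), n_nodule=int(rng.integers(1, 6)),
                        n_unaffected=int(rng.integers(1, 4)))
        n_var = int(rng.integers(1, 25))
        rows = rng.choice([0, 1, 2], size=(n_var, len(ped.member_ids)))
        rows = rows.astype(object)
        rows[rng.random(rows.shape) < 0.1] = pd.NA  # sprinkle missing calls
        geno, variants = _matrix(ped, rows)
        rule = SegregationRule(
            min_carriers={
                Phenotype.MPLC: int(rng.integers(0, ped.class_counts()[Phenotype.MPLC] + 1)),
                Phenotype.NODULE: int(rng.integers(0, ped.class_counts()[Phenotype.NODULE] + 1)),
            },
            max_carriers_unaffected=int(rng.integers(0, 2)),
        )
        retained, _ = segregation_filter(variants, geno, ped, rule)
        assert [v.key for v in retained] == self._brute_force(ped, geno, rule)


class TestDeleteriousnessRule:
    @pytest.mark.parametrize(
        "sift,poly,mode,expected",
        [
            ("deleterious", "benign", "either", True),
            ("deleterious", "benign", "both", False),
            ("tolerated", "probably_damaging", "polyphen_only", True),
            ("tolerated", "benign", "either", False),
            (None, None, "either", False),  # unscored variants are removed
            (None, "possibly_damaging", "either", True),
        ],
    )
    def test_rule_semantics(self, sift, poly, mode, expected):
        v = _variant(0, sift_call=sift, polyphen_call=poly)
        retained = deleteriousness_filter([v], DeleteriousnessRule(require=mode))
        assert bool(retained) is expected


class TestCascade:
    def test_fixture_yields_exactly_three_candidates(self, paper_fixture, fixture_variants):
        ped, geno, _annot, _sv = paper_fixture
        report = run_snv_cascade(fixture_variants, geno, ped)
        assert len(report) == 3
        assert set(report["gene"]) == {"ETV4", "KLHL10", "ASB16"}
        assert (report[["carriers_MPLC", "carriers_NODULE", "carriers_UNAFFECTED"]].values == [5, 8, 0]).all()

    def test_empty_variant_list_gives_empty_report(self, paper_fixture):
        ped, geno, _annot, _sv = paper_fixture
        assert len(run_snv_cascade([], geno, ped)) == 0

    def test_loosening_max_af_gives_superset(self, paper_fixture, fixture_variants):
        ped, geno, _annot, _sv = paper_fixture
        strict = run_snv_cascade(fixture_variants, geno, ped, CascadeRules())
        loose = run_snv_cascade(
            fixture_variants, geno, ped, CascadeRules(frequency=FrequencyRule(max_af=0.05))
        )
        key = lambda df: {tuple(r) for r in df[["chrom", "pos", "ref", "alt"]].values}
        assert key(strict) <= key(loose)

    def test_filters_commute(self, paper_fixture, fixture_variants):
        """The cascade is a pure intersection: any filter order gives the
        same final candidate set."""
        ped, geno, _annot, _sv = paper_fixture
        rules = CascadeRules()
        variants = fixture_variants

        def freq(vs):
            return frequency_filter(vs, rules.frequency)[0]

        def seg(vs):
            return segregation_filter(vs, geno, ped, rules.segregation)[0]

        def dele(vs):
            return deleteriousness_filter(vs, rules.deleteriousness)

        reference = None
        for order in itertools.permutations([freq, seg, dele]):
            out = variants
            for f in order:
                out = f(out)
            keys = sorted(v.key for v in out)
            if reference is None:
                reference = keys
            assert keys == reference

    def test_planted_variant_recovered_iff_pattern_satisfies_rule(self):
        """Over many simulated pedigrees, the planted variant is a candidate
        exactly when its realized carrier-by-phenotype pattern meets the
        segregation rule (replayed on truth data)."""
        from pedscreen.simulate import SimConfig, simulate_pedigree
        from pedscreen.io import variants_from_table
        from pedscreen.snv import carrier_counts_by_class

        rule = SegregationRule()
        n_match = 0
        for seed in range(100):
            ped, geno, annot = simulate_pedigree(SimConfig(background_variant_count=30, seed=seed))
            variants = variants_from_table(annot)
            report = run_snv_cascade(variants, geno, ped)
            planted_key = geno.variant_keys[0]
            in_candidates = any(
                f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" == planted_key for r in report.itertuples()
            )
            counts = carrier_counts_by_class(planted_key, geno, ped)
            should = (
                all(counts[c] >= k for c, k in rule.min_carriers.items())
                and counts[Phenotype.UNAFFECTED] <= rule.max_carriers_unaffected
            )
            assert in_candidates == should
            n_match += should
        assert n_match > 0  # the pattern is realized at least sometimes


class TestCarrierFrequency:
    def test_published_cohort_renders_three_point_seven_percent(self):
        res = carrier_frequency(6, 162)
        assert res.percent == "3.7"
        assert res.frequency == pytest.approx(6 / 162)

    def test_ci_equals_independent_beta_quantile_oracle(self):
        res = carrier_frequency(6, 162)
        lo, hi = proportion_confint(6, 162, alpha=0.05, method="beta")
        assert res.ci95[0] == pytest.approx(lo, abs=1e-12)
        assert res.ci95[1] == pytest.approx(hi, abs=1e-12)
        assert res.ci95[0] < res.frequency < res.ci95[1]

    def test_zero_carriers_boundary(self):
        res = carrier_frequency(0, 100)
        assert res.percent == "0.0"
        assert res.ci95[0] == 0.0

    def test_rounding_is_half_up(self):
        assert carrier_frequency(1, 400).percent == "0.3"  # 0.25 rounds up
        assert carrier_frequency(5, 200).percent == "2.5"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency(0, 0)

    def test_ci_coverage_93_to_97_percent(self):
        """Clopper-Pearson 95% interval covers p=0.037 in 93-97% of 1000
        binomial draws at n=162 (exact method is conservative)."""
        rng = np.random.default_rng(99)
        p, n = 0.037, 162
        draws = rng.binomial(n, p, size=1000)
        covered = 0
        for k in draws:
            lo, hi = carrier_frequency(int(k), n).ci95
            covered += lo <= p <= hi
        assert 930 <= covered <= 970
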