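"""Rule derivation, application and prioritization accounting."""

import warnings

import pytest

from vusrules import (
    ContingencyTable2x2,
    FeatureComparison,
    PredictorProfile,
    Rule,
    RuleSet,
    apply_rules,
    derive_rules,
    evaluate_predictor_rule,
    prioritize,
)
from vusrules.errors import DerivationError
from vusrules.rules import RULE_IDS, tally_hits
from vusrules.stats import DEPLETED, ENRICHED

from .conftest import DELETERIOUS_5, MIXED_4OF5, make_case, make_variant


def _comparison(feature, level, direction, significant=True, tested=True):
    return FeatureComparison(
        feature=feature, level=level, table=ContingencyTable2x2(1, 9, 9, 1),
        odds_ratio=0.5 if direction == DEPLETED else 2.0,
        p_raw=0.001, p_fdr=0.004, direction=direction,
        significant=significant, tested=tested,
    )


@pytest.fixture
def derived_style_scans():
    """Scan results shaped like the motivating IRD cohort's."""
    return {
        "gene": [
            _comparison("gene", "ABCA4", DEPLETED),
            _comparison("gene", "IMPG2", ENRICHED),
            _comparison("gene", "USH2A", DEPLETED, significant=False),
        ],
        "consequence": [
            _comparison("consequence", "frameshift", DEPLETED),
            _comparison("consequence", "stop_gain", DEPLETED),
            _comparison("consequence", "missense", ENRICHED),
        ],
        "analyst": [
            _comparison("analyst", "B1", DEPLETED),
            _comparison("analyst", "B2", DEPLETED),
            _comparison("analyst", "A2", ENRICHED),
        ],
        "predictor_consensus": _comparison("predictor_consensus", "5of5", DEPLETED),
    }


@pytest.fixture
def derived_style_rules(derived_style_scans):
    return derive_rules(derived_style_scans)


class TestDeriveRules:
    def test_payloads_take_depleted_levels_only(self, derived_style_rules):
        rules = derived_style_rules
        assert rules["gene_rule"].payload == {"ABCA4"}
        assert rules["consequence_rule"].payload == {"frameshift", "stop_gain"}
        assert rules["analyst_rule"].payload == {"B1", "B2"}
        assert rules["predictor_rule"].enabled and rules["predictor_rule"].required == 5

    def test_enriched_levels_flagged_but_never_in_payload(self, derived_style_rules):
        flagged = derived_style_rules.config["enriched_levels_flagged"]
        assert "gene:IMPG2" in flagged["gene_rule"]
        assert "IMPG2" not in derived_style_rules["gene_rule"].payload

    def test_provenance_links_back_to_comparisons(self, derived_style_rules):
        assert set(derived_style_rules["consequence_rule"].provenance) == {
            "consequence:frameshift", "consequence:stop_gain",
        }

    def test_no_significant_levels_disables_all(self, derived_style_scans):
        null_scans = {
            fam: (
                [_comparison(fc.feature, fc.level, fc.direction, significant=False)
                 for fc in scans]
                if isinstance(scans, list)
                else _comparison(scans.feature, scans.level, scans.direction,
                                 significant=False)
            )
            for fam, scans in derived_style_scans.items()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rules = derive_rules(null_scans)
        assert rules.enabled_rules == []

    def test_missing_family_named(self, derived_style_scans):
        del derived_style_scans["analyst"]
        with pytest.raises(DerivationError, match="analyst"):
            derive_rules(derived_style_scans)


class TestPredictorRule:
    @pytest.mark.parametrize(
        "calls,required,expected",
        [
            (("deleterious",) * 5, 5, True),
            (("deleterious",) * 4 + ("tolerated",), 5, False),
            # strict consensus: an unavailable call can never complete 5/5
            (("deleterious",) * 4 + ("unavailable",), 5, False),
            (("deleterious",) * 4 + ("unavailable",), 4, True),
            (("tolerated",) * 5, 1, False),
        ],
    )
    def test_strict_consensus(self, calls, required, expected):
        profile = PredictorProfile(calls)
        assert evaluate_predictor_rule(profile, required) is expected


class TestApplyRules:
    def test_multi_rule_hit(self, derived_style_rules):
        variant = make_variant(
            "NM_000350.2:c.100del", "V1", gene_symbol="ABCA4",
            consequence="frameshift", predictor_profile=PredictorProfile(
                ("unavailable",) * 5
            ),
        )
        case = make_case("V1", "vus_case", analyst_ids=("B1",))
        hits = apply_rules(variant, case, derived_style_rules)
        assert hits.hits == {"gene_rule", "consequence_rule", "analyst_rule"}
        assert hits.hit_count == 3

    def test_near_miss_hits_nothing(self, derived_style_rules):
        variant = make_variant("NM_1:c.1A>G", "V1", predictor_profile=MIXED_4OF5)
        case = make_case("V1", "vus_case", analyst_ids=("A2",))
        assert apply_rules(variant, case, derived_style_rules).hit_count == 0

    def test_co_analyzed_any_analyst_qualifies_flagged(self, derived_style_rules):
        variant = make_variant("NM_1:c.1A>G", "V1")
        case = make_case("V1", "vus_case", analyst_ids=("A2", "B2"))
        hits = apply_rules(variant, case, derived_style_rules)
        assert "analyst_rule" in hits.hits
        assert hits.co_analyst_flag

    def test_disabled_rule_never_hits(self, derived_style_rules):
        rules = RuleSet(
            rules={**derived_style_rules.rules,
                   "gene_rule": Rule("gene_rule", payload=frozenset({"ABCA4"}),
                                     enabled=False)},
        )
        variant = make_variant("NM_1:c.1A>G", "V1", gene_symbol="ABCA4")
        case = make_case("V1", "vus_case")
        assert "gene_rule" not in apply_rules(variant, case, rules).hits

    def test_non_vus_warns_but_evaluates(self, derived_style_rules):
        variant = make_variant("NM_1:c.1del", "S1", classification="pathogenic",
                               consequence="frameshift")
        case = make_case("S1", "solved")
        with pytest.warns(UserWarning, match="non-VUS"):
            hits = apply_rules(variant, case, derived_style_rules)
        assert "consequence_rule" in hits.hits

    def test_pure_function(self, derived_style_rules):
        variant = make_variant("NM_1:c.1A>G", "V1", gene_symbol="ABCA4",
                               predictor_profile=DELETERIOUS_5)
        case = make_case("V1", "vus_case", analyst_ids=("B1",))
        first = apply_rules(variant, case, derived_style_rules)
        assert all(
            apply_rules(variant, case, derived_style_rules) == first for _ in range(3)
        )

    @pytest.mark.parametrize("extra_gene", ["USH2A", "PDE6A", "RHO", "CRB1"])
    def test_growing_payload_is_monotone(self, derived_style_rules, extra_gene):
        """Adding a gene to the gene rule never lowers any hit count."""
        variants = [
            (make_variant(f"NM_1:c.{i}A>G", f"V{i}", gene_symbol=g),
             make_case(f"V{i}", "vus_case"))
            for i, g in enumerate(["ABCA4", "USH2A", "PDE6A", "RHO"])
        ]
        base_rule = derived_style_rules["gene_rule"]
        grown = RuleSet(rules={
            **derived_style_rules.rules,
            "gene_rule": Rule("gene_rule",
                              payload=base_rule.payload | {extra_gene},
                              provenance=base_rule.provenance),
        })
        for variant, case in variants:
            before = apply_rules(variant, case, derived_style_rules).hit_count
            after = apply_rules(variant, case, grown).hit_count
            assert after >= before


class TestPrioritize:
    def test_empty_input_zero_report(self, derived_style_rules):
        report = prioritize([], derived_style_rules)
        assert report.n_total == report.n_ge1 == report.n_ge2 == 0
        assert report.prioritized == []

    def _example_pairs(self):
        return [
            (make_variant("NM_000350.2:c.5383T>G", "V1", gene_symbol="ABCA4",
                          predictor_profile=DELETERIOUS_5),
             make_case("V1", "vus_case", analyst_ids=("B1",))),   # 3 rules
            (make_variant("NM_1:c.2del", "V2", consequence="frameshift"),
             make_case("V2", "vus_case")),                         # 1 rule
            (make_variant("NM_1:c.3A>G", "V3", predictor_profile=MIXED_4OF5),
             make_case("V3", "vus_case", analyst_ids=("A2",))),    # 0 rules
        ]

    def test_tallies_and_sorting(self, derived_style_rules):
        report = prioritize(self._example_pairs(), derived_style_rules)
        assert (report.n_total, report.n_ge1, report.n_ge2) == (3, 2, 1)
        assert report.per_rule["predictor_rule"] == 1
        assert report.per_rule["consequence_rule"] == 1
        # sorted by hit_count desc; the 3-hit ABCA4 variant leads
        assert report.prioritized[0][0] == "NM_000350.2:c.5383T>G"
        assert [t[2] for t in report.prioritized] == [3, 1, 0]

    def test_combination_counts_partition_ge1(self, derived_style_rules):
        report = prioritize(self._example_pairs(), derived_style_rules)
        assert sum(report.per_combination.values()) == report.n_ge1

    def test_tally_consistency_on_synthetic_cohort(self, calibrated_cohort):
        """n_ge1 = n_total - zero-hit count; per-rule counts match a
        recomputation from the per-variant hits."""
        from vusrules import split_variant_sets
        from vusrules.rules import vus_with_cases
        from vusrules.scans import (
            predictor_consensus_comparison, scan_case_feature, scan_categorical,
        )

        _, cohort, _ = calibrated_cohort
        ird = cohort.subset_sub_cohort("IRD")
        vus, ref = split_variant_sets(ird)
        rules = derive_rules({
            "gene": scan_categorical(vus, ref, "gene"),
            "consequence": scan_categorical(vus, ref, "consequence"),
            "analyst": scan_case_feature(ird.cases, "analyst"),
            "predictor_consensus": predictor_consensus_comparison(vus, ref),
        })
        report = prioritize(vus_with_cases(ird), rules)
        zero_hits = sum(h.hit_count == 0 for h in report.per_variant)
        assert report.n_ge1 == report.n_total - zero_hits
        for rid in RULE_IDS:
            assert report.per_rule[rid] == sum(
                rid in h.hits for h in report.per_variant
            )
        t = tally_hits(report.per_variant)
        assert (t["n_ge1"], t["n_ge2"]) == (report.n_ge1, report.n_ge2)
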