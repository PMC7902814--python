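"""Feature scans: enrichment directions, exclusions, correlations,
score comparisons and the predictor-consensus test."""

import numpy as np
import pytest

from vusrules import (
    correlate_counts,
    compare_score_distributions,
    predictor_consensus_comparison,
    scan_case_feature,
    scan_categorical,
)
from vusrules.errors import ConfigurationError, DomainError, InsufficientDataError
from vusrules.stats import DEPLETED, ENRICHED

from .conftest import DELETERIOUS_5, MIXED_4OF5, make_case, make_variant
from .oracles import fisher_two_sided_oracle, pearson_r_oracle


def _variants(gene_counts, classification):
    out = []
    for gene, count in gene_counts.items():
        for i in range(count):
            out.append(
                make_variant(f"NM_1:c.{len(out) + 1}A>G", f"{classification}_{gene}_{i}",
                             gene_symbol=gene, classification=classification)
            )
    return out


class TestScanCategorical:
    def test_injected_depletion_and_enrichment_recovered(self):
        """A gene with only reference variants scans as depleted_in_vus, a
        VUS-only gene as enriched, both significant; matches the 2x2 oracle."""
        background = {f"BG{i}": 5 for i in range(10)}
        vus = _variants({**background, "G2": 6}, "vus")
        ref = _variants({**background, "G1": 20}, "pathogenic")
        results = {fc.level: fc for fc in scan_categorical(vus, ref, "gene")}
        g1, g2 = results["G1"], results["G2"]
        assert g1.direction == DEPLETED and g1.significant
        assert g2.direction == ENRICHED and g2.significant
        assert g1.p_raw == pytest.approx(
            fisher_two_sided_oracle(0, 56, 20, 50), rel=1e-12
        )
        assert g2.p_raw == pytest.approx(
            fisher_two_sided_oracle(6, 50, 0, 70), rel=1e-12
        )
        assert all(fc.p_fdr >= fc.p_raw for fc in results.values() if fc.tested)

    def test_min_total_keeps_untested_levels(self):
        vus = _variants({"G1": 1, "G2": 10}, "vus")
        ref = _variants({"G2": 10}, "pathogenic")
        results = {fc.level: fc for fc in scan_categorical(vus, ref, "gene", min_total=3)}
        assert not results["G1"].tested
        assert results["G1"].p_raw is None
        assert results["G2"].tested

    def test_unknown_feature_rejected(self):
        with pytest.raises(ConfigurationError):
            scan_categorical([], [make_variant("NM_1:c.1A>G", "x",
                                               classification="pathogenic")], "zygosity")

    def test_empty_sets_rejected(self):
        with pytest.raises(InsufficientDataError):
            scan_categorical([], [], "gene")

    def test_label_swap_inverts_direction_preserves_p(self):
        vus = _variants({"G1": 3, "G2": 9}, "vus")
        ref = _variants({"G1": 11, "G2": 2}, "pathogenic")
        fwd = {fc.level: fc for fc in scan_categorical(vus, ref, "gene")}
        rev = {fc.level: fc for fc in scan_categorical(ref, vus, "gene")}
        for level in fwd:
            assert fwd[level].p_raw == rev[level].p_raw
            assert fwd[level].direction != rev[level].direction


class TestScanCaseFeature:
    def test_co_analyzed_cases_excluded_from_analyst_scan(self):
        cases = [make_case(f"c{i}", "vus_case" if i % 3 == 0 else "solved",
                           analyst_ids=("A1",)) for i in range(12)]
        cases += [make_case("co1", "vus_case", analyst_ids=("A1", "A2"))]
        results = scan_case_feature(cases, "analyst", outcome="vus_case")
        assert sum(fc.table.total for fc in results[:1]) == 12  # co1 dropped
        assert {fc.level for fc in results} == {"A1"}

    def test_unknown_inheritance_excluded_from_inheritance_scan(self):
        cases = [make_case(f"d{i}", "vus_case", inheritance="dominant") for i in range(4)]
        cases += [make_case(f"r{i}", "solved", inheritance="recessive") for i in range(4)]
        cases += [make_case("u0", "vus_case", inheritance="unknown")]
        results = scan_case_feature(cases, "inheritance", outcome="vus_case")
        assert {fc.level for fc in results} == {"dominant", "recessive"}
        assert sum(fc.table.a + fc.table.b for fc in results) == 8

    def test_identical_outcome_proportions_not_significant(self):
        cases = []
        for analyst in ("A1", "A2"):
            cases += [make_case(f"{analyst}_v{i}", "vus_case",
                                analyst_ids=(analyst,)) for i in range(5)]
            cases += [make_case(f"{analyst}_s{i}", "solved",
                                analyst_ids=(analyst,)) for i in range(15)]
        results = scan_case_feature(cases, "analyst", outcome="vus_case")
        assert all(fc.p_raw == 1.0 for fc in results)
        assert not any(fc.significant for fc in results)

    def test_bad_outcome_rejected(self):
        with pytest.raises(ConfigurationError):
            scan_case_feature([make_case("c1")], "analyst", outcome="reclassified")


class TestCorrelateCounts:
    def test_proportional_counts_give_r_one(self):
        units = [(s, 2 * s, 3 * s) for s in (1, 2, 3, 4)]
        vus_r, ref_r = correlate_counts(units)
        assert vus_r.r == pytest.approx(1.0)
        assert ref_r.r == pytest.approx(1.0)

    def test_matches_product_moment_oracle(self):
        units = [(1, 1, 2), (2, 2, 4), (3, 4, 5), (4, 3, 9)]
        vus_r, ref_r = correlate_counts(units)
        sizes = [u[0] for u in units]
        assert vus_r.r == pytest.approx(
            pearson_r_oracle(sizes, [u[1] for u in units]), rel=1e-12
        )
        assert ref_r.r == pytest.approx(
            pearson_r_oracle(sizes, [u[2] for u in units]), rel=1e-12
        )
        assert vus_r.n == ref_r.n == 4

    def test_zero_variance_undefined(self):
        with pytest.raises(DomainError):
            correlate_counts([(1, 5, 1), (2, 5, 2), (3, 5, 3)])

    def test_too_few_units(self):
        with pytest.raises(InsufficientDataError):
            correlate_counts([(1, 1, 1)])


class TestScoreDistributions:
    def test_identical_lists_maximal_p(self):
        res = compare_score_distributions([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.p == pytest.approx(1.0)

    def test_exact_rank_sum_on_separated_lists(self):
        # all 3 low ranks on one side: 2 * (1 / C(6,3)) = 0.1 two-sided
        res = compare_score_distributions([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, rel=1e-12)
        assert (res.n1, res.n2) == (3, 3)

    def test_missing_values_dropped_then_empty_is_error(self):
        with pytest.raises(InsufficientDataError):
            compare_score_distributions([None, float("nan")], [1.0, 2.0])

    def test_ccr_bins_cover_all_values(self):
        rng = np.random.default_rng(7)
        vus = rng.uniform(0, 100, 60)
        ref = rng.uniform(0, 100, 80)
        results = compare_score_distributions(vus, ref, method="ccr_bin_fisher")
        assert len(results) == 10
        assert sum(fc.table.a for fc in results) == 60
        assert sum(fc.table.c for fc in results) == 80

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            compare_score_distributions([1.0], [2.0], method="t_test")


class TestPredictorConsensus:
    def test_all_deleterious_everywhere_is_null(self):
        vus = [make_variant(f"NM_1:c.{i}A>G", f"v{i}",
                            predictor_profile=DELETERIOUS_5) for i in range(10)]
        ref = [make_variant(f"NM_1:c.{i}C>T", f"r{i}", classification="pathogenic",
                            predictor_profile=DELETERIOUS_5) for i in range(10)]
        fc = predictor_consensus_comparison(vus, ref)
        assert fc.odds_ratio == 1.0
        assert fc.p_raw == 1.0

    def test_restricted_to_missense(self):
        vus = [make_variant("NM_1:c.1A>G", "v0", predictor_profile=DELETERIOUS_5)]
        ref = [
            make_variant("NM_1:c.2del", "r0", classification="pathogenic",
                         consequence="frameshift", predictor_profile=DELETERIOUS_5),
            make_variant("NM_1:c.3C>T", "r1", classification="pathogenic",
                         predictor_profile=MIXED_4OF5),
        ]
        fc = predictor_consensus_comparison(vus, ref)
        assert fc.table.total == 2  # the frameshift variant never enters

    def test_no_missense_anywhere_is_error(self):
        ref = [make_variant("NM_1:c.2del", "r0", classification="pathogenic",
                            consequence="frameshift")]
        with pytest.raises(InsufficientDataError):
            predictor_consensus_comparison([], ref)

    def test_separating_consensus_rates_detected(self):
        """Monte-Carlo power oracle: consensus probability 0.6 vs 0.3 at
        n = 200 per arm is flagged depleted_in_vus in >= 95% of replicates."""
        rng = np.random.default_rng(1234)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            def arm(p, klass, tag):
                profiles = [
                    DELETERIOUS_5 if rng.random() < p else MIXED_4OF5
                    for _ in range(200)
                ]
                return [
                    make_variant(f"NM_1:c.{i}A>G", f"{tag}{i}", classification=klass,
                                 predictor_profile=pr)
                    for i, pr in enumerate(profiles)
                ]
            fc = predictor_consensus_comparison(
                arm(0.3, "vus", "v"), arm(0.6, "pathogenic", "r")
            )
            hits += fc.significant and fc.direction == DEPLETED
        assert hits >= 0.95 * n_rep
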