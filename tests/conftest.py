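"""Shared fixtures: a small hand-built cohort and a calibrated synthetic one."""

import pytest

from vusrules import (
    CaseRecord,
    CohortTable,
    PredictorProfile,
    VariantRecord,
    calibrated_config,
    generate_cohort,
)

DELETERIOUS_5 = PredictorProfile(("deleterious",) * 5)
MIXED_4OF5 = PredictorProfile(
    ("deleterious", "deleterious", "deleterious", "deleterious", "tolerated")
)


def make_case(case_id, status="solved", **kwargs):
    defaults = dict(
        sub_cohort="IRD",
        inheritance="dominant",
        platform="CES",
        panel_id="panel_106g_syndromic",
        panel_gene_count=106,
        analyst_ids=("A1",),
        disease_label="retinitis_pigmentosa",
    )
    defaults.update(kwargs)
    return CaseRecord(case_id=case_id, diagnostic_status=status, **defaults)


def make_variant(variant_id, case_id, **kwargs):
    defaults = dict(
        gene_symbol="USH2A",
        classification="vus",
        consequence="missense",
        genomic_region="exonic",
        zygosity="het",
        predictor_profile=MIXED_4OF5,
        gene_pli=0.0,
        ccr_percentile=40.0,
        gene_coding_length=15606,
    )
    defaults.update(kwargs)
    return VariantRecord(variant_id=variant_id, case_id=case_id, **defaults)


@pytest.fixture
def toy_cohort():
    """2 sub-cohorts, all four statuses, one co-analyzed case."""
    cases = [
        make_case("S1", "solved"),
        make_case("S2", "solved", inheritance="recessive", analyst_ids=("B1",)),
        make_case("P1", "partially_solved", inheritance="recessive"),
        make_case("V1", "vus_case", inheritance="recessive", analyst_ids=("B1",)),
        make_case("V2", "vus_case", analyst_ids=("A2", "B2"), platform="TSO"),
        make_case("U1", "unsolved"),
        make_case("N1", "solved", sub_cohort="non_IRD",
                  disease_label="metabolic_disorder"),
    ]
    variants = [
        make_variant("NM_000350.2:c.100del", "S1", gene_symbol="ABCA4",
                     classification="pathogenic", consequence="frameshift"),
        make_variant("NM_206933.2:c.2276G>T", "S2", classification="pathogenic",
                     predictor_profile=DELETERIOUS_5),
        make_variant("NM_206933.2:c.2299del", "S2", classification="likely_pathogenic",
                     consequence="frameshift"),
        make_variant("NM_000350.2:c.5461-10T>C", "P1", gene_symbol="ABCA4",
                     classification="pathogenic", consequence="splice_region",
                     genomic_region="splicing"),
        make_variant("NM_000350.2:c.5383T>G", "V1", gene_symbol="ABCA4",
                     predictor_profile=DELETERIOUS_5),
        make_variant("NM_016247.3:c.2872A>G", "V1", gene_symbol="IMPG2"),
        make_variant("NM_000440.2:c.304G>A", "V2", gene_symbol="PDE6A"),
        make_variant("NM_001142800.1:c.2512C>T", "N1", gene_symbol="EYS",
                     classification="pathogenic", consequence="stop_gain"),
    ]
    return CohortTable(cases=cases, variants=variants, provenance={"source": "toy"})


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One calibrated synthetic cohort shared across the session."""
    cfg = calibrated_config(n_cases=2000, seed=20)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth
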