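"""Feature scans: VUS vs reference variants, and case-level outcomes.

Each scan builds one-vs-rest 2x2 tables per feature level, tests them
with the exact Fisher test and adjusts within the feature family
(BH-FDR). Directions are read from the VUS (or outcome) perspective:
``enriched_in_vus`` means the level is over-represented among VUS
relative to the pathogenic/likely-pathogenic reference set.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats as sp_stats

from .errors import ConfigurationError, DomainError, InsufficientDataError
from .records import CaseRecord, VariantRecord
from .stats import (
    ContingencyTable2x2,
    CorrelationResult,
    FeatureComparison,
    RankTestResult,
    test_comparisons,
)

VARIANT_FEATURES = {
    "gene": lambda v: v.gene_symbol,
    "consequence": lambda v: v.consequence,
    "genomic_region": lambda v: v.genomic_region,
}

CASE_FEATURES = ("inheritance", "analyst", "platform", "sub_cohort")

#: outcomes accepted by scan_case_feature (the diagnostic-status taxonomy)
CASE_OUTCOMES = ("vus_case", "unsolved", "solved", "partially_solved")


def scan_categorical(
    vus_set: list[VariantRecord],
    reference_set: list[VariantRecord],
    feature: str,
    min_total: int = 3,
    alpha: float = 0.05,
) -> list[FeatureComparison]:
    """One-vs-rest enrichment scan of a variant feature.

    For every observed level with total count >= ``min_total``, tests the
    table [VUS at level, VUS elsewhere; reference at level, reference
    elsewhere]; levels below ``min_total`` are returned untested.
    """
    try:
        getter = VARIANT_FEATURES[feature]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant feature {feature!r}; expected one of "
            f"{sorted(VARIANT_FEATURES)}"
        ) from None
    if not vus_set and not reference_set:
        raise InsufficientDataError("both variant sets are empty")
    vus_counts = Counter(getter(v) for v in vus_set)
    ref_counts = Counter(getter(v) for v in reference_set)
    n_vus, n_ref = len(vus_set), len(reference_set)
    comparisons = []
    for level in sorted(set(vus_counts) | set(ref_counts)):
        a, c = vus_counts[level], ref_counts[level]
        table = ContingencyTable2x2(
            a, n_vus - a, c, n_ref - c,
            row_labels=("vus", "reference"),
            col_labels=(level, "rest"),
        )
        comparisons.append(
            FeatureComparison(
                feature=feature,
                level=level,
                table=table,
                tested=(a + c) >= min_total,
            )
        )
    return test_comparisons(comparisons, alpha=alpha)


def scan_case_feature(
    cases: list[CaseRecord],
    feature: str,
    outcome: str = "vus_case",
    alpha: float = 0.05,
    min_total: int = 3,
) -> list[FeatureComparison]:
    """One-vs-rest scan of a case feature against a diagnostic outcome.

    Exclusions mirror diagnostic practice: co-analyzed cases (two
    analysts) are dropped from the analyst scan, and cases with unknown
    inheritance from the inheritance scan. ``enriched_in_vus`` here means
    the level has proportionally more cases with the outcome.
    """
    if feature not in CASE_FEATURES:
        raise ConfigurationError(
            f"unknown case feature {feature!r}; expected one of {CASE_FEATURES}"
        )
    if outcome not in CASE_OUTCOMES:
        raise ConfigurationError(
            f"unknown outcome {outcome!r}; expected one of {CASE_OUTCOMES}"
        )
    if feature == "analyst":
        pool = [c for c in cases if not c.co_analyzed]
        level_of = lambda c: c.analyst_ids[0]
    elif feature == "inheritance":
        pool = [c for c in cases if c.inheritance != "unknown"]
        level_of = lambda c: c.inheritance
    elif feature == "platform":
        pool, level_of = list(cases), (lambda c: c.platform)
    else:
        pool, level_of = list(cases), (lambda c: c.sub_cohort)
    if not pool:
        raise InsufficientDataError(f"no cases left for feature {feature!r}")
    with_outcome = Counter(level_of(c) for c in pool if c.diagnostic_status == outcome)
    totals = Counter(level_of(c) for c in pool)
    n_with = sum(with_outcome.values())
    n_pool = len(pool)
    comparisons = []
    for level in sorted(totals):
        a = with_outcome[level]
        b = totals[level] - a
        table = ContingencyTable2x2(
            a, b, n_with - a, (n_pool - totals[level]) - (n_with - a),
            row_labels=(level, "other_" + feature),
            col_labels=(outcome, "not_" + outcome),
        )
        comparisons.append(
            FeatureComparison(
                feature=feature,
                level=level,
                table=table,
                tested=totals[level] >= min_total,
            )
        )
    return test_comparisons(comparisons, alpha=alpha)


def correlate_counts(units) -> tuple[CorrelationResult, CorrelationResult]:
    """Pearson correlation of unit size vs per-unit VUS and reference
    variant counts.

    ``units`` is an iterable of (size, vus_count, reference_count); one
    unit per virtual panel for the panel-size analysis, per gene for the
    gene-size analysis. Raises DomainError when either vector has zero
    variance (undefined correlation).
    """
    arr = np.asarray(list(units), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (size, vus, reference) triples")
    size, vus, ref = arr[:, 0], arr[:, 1], arr[:, 2]
    results = []
    for variant_class, counts in (("vus", vus), ("reference", ref)):
        if np.ptp(size) == 0 or np.ptp(counts) == 0:
            raise DomainError(
                f"zero variance in size or {variant_class} counts: "
                "correlation undefined"
            )
        r = float(sp_stats.pearsonr(size, counts).statistic)
        results.append(
            CorrelationResult(feature="size", variant_class=variant_class,
                              r=r, n=arr.shape[0])
        )
    return results[0], results[1]


DEFAULT_CCR_BINS = tuple(float(edge) for edge in range(0, 101, 10))


def compare_score_distributions(
    vus_scores,
    reference_scores,
    method: str = "wilcoxon_rank",
    ccr_bins=DEFAULT_CCR_BINS,
    alpha: float = 0.05,
):
    """Compare a per-variant score between VUS and reference variants.

    ``wilcoxon_rank``: two-sided rank-sum test (used for the gene pLI
    loss-of-function-intolerance comparison). ``ccr_bin_fisher``: bin the
    constrained-coding-region percentiles (default deciles) and run a
    per-bin one-vs-rest Fisher scan with BH-FDR — an exploratory
    operationalization of the "peaks outside essential regions" view.
    Missing values (None/NaN) are dropped first.
    """
    clean = lambda xs: [float(x) for x in xs if x is not None and not np.isnan(x)]
    vus = clean(vus_scores)
    ref = clean(reference_scores)
    if not vus or not ref:
        raise InsufficientDataError("empty score list after missing-value removal")
    if method == "wilcoxon_rank":
        res = sp_stats.mannwhitneyu(vus, ref, alternative="two-sided", method="auto")
        return RankTestResult(
            feature="score", statistic=float(res.statistic), p=float(res.pvalue),
            n1=len(vus), n2=len(ref),
        )
    if method == "ccr_bin_fisher":
        edges = np.asarray(ccr_bins, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("ccr_bins must be >= 2 strictly increasing edges")
        # right-closed last bin so percentile 100 lands in the top decile
        vus_bin = np.clip(np.digitize(vus, edges[1:-1], right=False), 0, edges.size - 2)
        ref_bin = np.clip(np.digitize(ref, edges[1:-1], right=False), 0, edges.size - 2)
        comparisons = []
        for b in range(edges.size - 1):
            a = int(np.sum(vus_bin == b))
            c = int(np.sum(ref_bin == b))
            label = f"[{edges[b]:g},{edges[b + 1]:g}{']' if b == edges.size - 2 else ')'}"
            comparisons.append(
                FeatureComparison(
                    feature="ccr_bin",
                    level=label,
                    table=ContingencyTable2x2(a, len(vus) - a, c, len(ref) - c),
                )
            )
        return test_comparisons(comparisons, alpha=alpha)
    raise ConfigurationError(f"unknown method {method!r}")


def meets_consensus(profile, required: int) -> bool:
    """Strict predictor consensus: >= ``required`` deleterious calls, and
    for the full 5/5 requirement no call may be unavailable."""
    if not 1 <= required <= 5:
        raise DomainError("required consensus count must be in 1..5")
    if required == 5 and profile.n_unavailable > 0:
        return False
    return profile.n_deleterious >= required


def predictor_consensus_comparison(
    vus_set: list[VariantRecord],
    reference_set: list[VariantRecord],
    required: int = 5,
    alpha: float = 0.05,
) -> FeatureComparison:
    """Test whether full in-silico predictor consensus separates reference
    variants from VUS.

    Both sets are restricted to missense variants (the only class on
    which all five predictors are defined); a variant is "in consensus"
    when >= ``required`` of its calls are deleterious under the strict
    rule of :func:`meets_consensus`. The single resulting comparison is
    its own family (p_fdr = p_raw).
    """
    vus_mis = [v for v in vus_set if v.consequence == "missense"]
    ref_mis = [v for v in reference_set if v.consequence == "missense"]
    if not vus_mis and not ref_mis:
        raise InsufficientDataError("no missense variants in either set")
    a = sum(meets_consensus(v.predictor_profile, required) for v in vus_mis)
    c = sum(meets_consensus(v.predictor_profile, required) for v in ref_mis)
    table = ContingencyTable2x2(
        a, len(vus_mis) - a, c, len(ref_mis) - c,
        row_labels=("vus", "reference"),
        col_labels=(f"consensus_{required}of5", "no_consensus"),
    )
    fc = FeatureComparison(
        feature="predictor_consensus", level=f"{required}of5", table=table
    )
    test_comparisons([fc], alpha=alpha)
    return fc


__all__ = [
    "scan_categorical",
    "scan_case_feature",
    "correlate_counts",
    "compare_score_distributions",
    "predictor_consensus_comparison",
    "meets_consensus",
    "DEFAULT_CCR_BINS",
    "CASE_FEATURES",
    "CASE_OUTCOMES",
    "VARIANT_FEATURES",
]
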