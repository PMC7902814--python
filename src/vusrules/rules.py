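"""The four-rule VUS prioritization engine.

The working hypothesis: VUS that resemble the laboratory's own
pathogenic/likely-pathogenic variants are the ones most likely to be
reclassified as causal. Each rule is derived from a significant,
direction-consistent enrichment scan:

* gene_rule — genes significantly depleted of VUS reports (VUS there
  look out of character for the lab; ABCA4 in the motivating cohort),
* consequence_rule — consequences depleted among VUS (frameshift,
  stop-gain: loss-of-function classes rarely left uncertain),
* analyst_rule — analysts who report significantly fewer VUS cases
  (their rare VUS carry more weight),
* predictor_rule — strict in-silico consensus (all five predictors
  deleterious, none unavailable).

Rules are independent; a variant's priority is simply how many it hits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from . import vocab
from .errors import DerivationError, DomainError
from .records import CaseRecord, PredictorProfile, VariantRecord
from .scans import meets_consensus
from .stats import DEPLETED, FeatureComparison

RULE_IDS = ("gene_rule", "consequence_rule", "analyst_rule", "predictor_rule")

#: scan families consumed by derive_rules, keyed by the rule they feed
SCAN_FAMILIES = {
    "gene_rule": "gene",
    "consequence_rule": "consequence",
    "analyst_rule": "analyst",
    "predictor_rule": "predictor_consensus",
}


@dataclass(frozen=True)
class Rule:
    """One derived rule: a payload plus provenance.

    ``payload`` is a frozenset of gene symbols / consequence terms /
    analyst ids; for the predictor rule it is empty and ``required``
    carries the consensus count. ``provenance`` lists the
    feature:level ids of the significant comparisons that justified the
    payload.
    """

    rule_id: str
    payload: frozenset = frozenset()
    required: int = 5
    predictors: tuple[str, ...] = vocab.PREDICTORS
    enabled: bool = True
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if self.rule_id not in RULE_IDS:
            raise DomainError(f"unknown rule_id {self.rule_id!r}")
        if not 1 <= self.required <= 5:
            raise DomainError("required consensus count must be in 1..5")

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "payload": sorted(self.payload),
            "required": self.required,
            "predictors": list(self.predictors),
            "enabled": self.enabled,
            "provenance": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Rule":
        return cls(
            rule_id=payload["rule_id"],
            payload=frozenset(payload.get("payload", ())),
            required=payload.get("required", 5),
            predictors=tuple(payload.get("predictors", vocab.PREDICTORS)),
            enabled=payload.get("enabled", True),
            provenance=tuple(payload.get("provenance", ())),
        )


@dataclass
class RuleSet:
    """The four rules (each possibly disabled) plus the derivation
    configuration snapshot."""

    rules: dict[str, Rule]
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if sorted(self.rules) != sorted(set(self.rules)):
            raise DomainError("rule_ids must be unique")
        for rule_id, rule in self.rules.items():
            if rule.rule_id != rule_id:
                raise DomainError(f"rule keyed {rule_id!r} has rule_id {rule.rule_id!r}")

    def __getitem__(self, rule_id: str) -> Rule:
        return self.rules[rule_id]

    @property
    def enabled_rules(self) -> list[str]:
        return [r for r in RULE_IDS if r in self.rules and self.rules[r].enabled]

    def to_dict(self) -> dict:
        return {
            "rules": {rid: rule.to_dict() for rid, rule in self.rules.items()},
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleSet":
        return cls(
            rules={rid: Rule.from_dict(r) for rid, r in payload["rules"].items()},
            config=payload.get("config", {}),
        )

    @classmethod
    def all_disabled(cls) -> "RuleSet":
        return cls(
            rules={
                rid: Rule(rule_id=rid, enabled=False) for rid in RULE_IDS
            },
            config={"note": "all rules disabled"},
        )


@dataclass(frozen=True)
class RuleHits:
    """Per-variant rule evaluation result."""

    variant_id: str
    case_id: str
    hits: frozenset
    co_analyst_flag: bool = False

    @property
    def hit_count(self) -> int:
        return len(self.hits)


def _depleted_levels(scan: list[FeatureComparison]) -> tuple[list[str], list[str]]:
    """Significant depleted-in-VUS levels and their comparison ids."""
    hits = [fc for fc in scan if fc.tested and fc.significant and fc.direction == DEPLETED]
    return [fc.level for fc in hits], [fc.comparison_id for fc in hits]


def derive_rules(
    scan_results: dict,
    required: int = 5,
    alpha: float = 0.05,
) -> RuleSet:
    """Derive the four-rule set from scan results.

    ``scan_results`` maps family names to results: ``"gene"``,
    ``"consequence"`` (lists from scan_categorical), ``"analyst"`` (list
    from scan_case_feature with outcome vus_case) and
    ``"predictor_consensus"`` (single FeatureComparison or 1-list).
    Payloads take only significantly *depleted* levels — enriched levels
    (an IMPG2-like gene, a liberal analyst) are flagged in the config
    snapshot but never enter a rule. A family with no qualifying level
    yields an empty, disabled rule with a warning.
    """
    missing = [fam for fam in SCAN_FAMILIES.values() if fam not in scan_results]
    if missing:
        raise DerivationError(f"missing scan famil{'ies' if len(missing) > 1 else 'y'}: "
                              + ", ".join(sorted(missing)))
    rules: dict[str, Rule] = {}
    enriched_flags: dict[str, list[str]] = {}
    for rule_id in ("gene_rule", "consequence_rule", "analyst_rule"):
        scan = scan_results[SCAN_FAMILIES[rule_id]]
        levels, prov = _depleted_levels(scan)
        enriched_flags[rule_id] = [
            fc.comparison_id
            for fc in scan
            if fc.tested and fc.significant and fc.direction != DEPLETED
        ]
        enabled = bool(levels)
        if not enabled:
            warnings.warn(
                f"{rule_id}: no significant depleted level; rule disabled",
                stacklevel=2,
            )
        rules[rule_id] = Rule(
            rule_id=rule_id,
            payload=frozenset(levels),
            enabled=enabled,
            provenance=tuple(prov),
        )
    pred = scan_results["predictor_consensus"]
    if isinstance(pred, list):
        if not pred:
            raise DerivationError("empty predictor_consensus scan")
        pred = pred[0]
    pred_enabled = bool(pred.tested and pred.significant and pred.direction == DEPLETED)
    if not pred_enabled:
        warnings.warn(
            "predictor_rule: consensus comparison not significant with the "
            "reference set enriched; rule disabled",
            stacklevel=2,
        )
    rules["predictor_rule"] = Rule(
        rule_id="predictor_rule",
        required=required,
        enabled=pred_enabled,
        provenance=(pred.comparison_id,) if pred_enabled else (),
    )
    return RuleSet(
        rules=rules,
        config={
            "alpha": alpha,
            "required": required,
            "enriched_levels_flagged": enriched_flags,
        },
    )


def evaluate_predictor_rule(profile: PredictorProfile, required: int = 5) -> bool:
    """True iff >= ``required`` deleterious calls and, for the strict 5/5
    consensus, no unavailable call. Pure and deterministic."""
    return meets_consensus(profile, required)


def apply_rules(
    variant: VariantRecord, case: CaseRecord, rules: RuleSet
) -> RuleHits:
    """Evaluate all enabled rules on one variant, independently.

    Co-analyzed cases hit the analyst rule if *any* of their analysts
    qualifies; such hits are flagged. Disabled rules contribute no hit.
    Non-VUS input is allowed (validation sets contain reclassified
    variants) but warned about.
    """
    if variant.classification != "vus":
        warnings.warn(
            f"apply_rules on non-VUS variant {variant.variant_id} "
            f"({variant.classification})",
            stacklevel=2,
        )
    hits = set()
    co_flag = False
    gene_rule = rules.rules.get("gene_rule")
    if gene_rule and gene_rule.enabled and variant.gene_symbol in gene_rule.payload:
        hits.add("gene_rule")
    cons_rule = rules.rules.get("consequence_rule")
    if cons_rule and cons_rule.enabled and variant.consequence in cons_rule.payload:
        hits.add("consequence_rule")
    analyst_rule = rules.rules.get("analyst_rule")
    if analyst_rule and analyst_rule.enabled:
        qualifying = [a for a in case.analyst_ids if a in analyst_rule.payload]
        if qualifying:
            hits.add("analyst_rule")
            co_flag = case.co_analyzed
    pred_rule = rules.rules.get("predictor_rule")
    if pred_rule and pred_rule.enabled and evaluate_predictor_rule(
        variant.predictor_profile, pred_rule.required
    ):
        hits.add("predictor_rule")
    return RuleHits(
        variant_id=variant.variant_id,
        case_id=variant.case_id,
        hits=frozenset(hits),
        co_analyst_flag=co_flag,
    )


@dataclass
class PrioritizationReport:
    """Rule hits over a VUS set, with the tallies of the accounting:
    total, >=1-rule and >=2-rule counts, per-rule counts, and counts per
    exact rule combination; prioritized list sorted by
    (hit_count desc, gene asc, variant_id asc)."""

    per_variant: list[RuleHits]
    n_total: int
    n_ge1: int
    n_ge2: int
    per_rule: dict[str, int]
    per_combination: dict[str, int]
    prioritized: list[tuple[str, str, int]]  # (variant_id, case_id, hit_count)

    @property
    def fraction_ge1(self) -> float:
        return self.n_ge1 / self.n_total if self.n_total else 0.0

    @property
    def fraction_ge2(self) -> float:
        return self.n_ge2 / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_ge1": self.n_ge1,
            "n_ge2": self.n_ge2,
            "fraction_ge1": self.fraction_ge1,
            "fraction_ge2": self.fraction_ge2,
            "per_rule": dict(self.per_rule),
            "per_combination": dict(self.per_combination),
            "prioritized": [list(t) for t in self.prioritized],
            "per_variant": [
                {
                    "variant_id": h.variant_id,
                    "case_id": h.case_id,
                    "hits": sorted(h.hits),
                    "hit_count": h.hit_count,
                    "co_analyst_flag": h.co_analyst_flag,
                }
                for h in self.per_variant
            ],
        }


def combination_key(hits: frozenset) -> str:
    return "+".join(rid for rid in RULE_IDS if rid in hits)


def tally_hits(per_variant: list[RuleHits]) -> dict:
    """Shared accounting for prioritization and validation reports."""
    n_total = len(per_variant)
    n_ge1 = sum(h.hit_count >= 1 for h in per_variant)
    n_ge2 = sum(h.hit_count >= 2 for h in per_variant)
    per_rule = {rid: sum(rid in h.hits for h in per_variant) for rid in RULE_IDS}
    per_combination = dict(
        Counter(combination_key(h.hits) for h in per_variant if h.hit_count >= 1)
    )
    return {
        "n_total": n_total,
        "n_ge1": n_ge1,
        "n_ge2": n_ge2,
        "per_rule": per_rule,
        "per_combination": per_combination,
    }


def prioritize(
    vus_with_cases: list[tuple[VariantRecord, CaseRecord]], rules: RuleSet
) -> PrioritizationReport:
    """Apply the rule set to every VUS and build the report.

    An empty input yields an all-zero report. The prioritized list is a
    stable total order: hit count descending, then gene symbol, then
    variant id."""
    per_variant = [apply_rules(v, c, rules) for v, c in vus_with_cases]
    gene_of = {h.variant_id + "\x00" + h.case_id: v.gene_symbol
               for (v, _), h in zip(vus_with_cases, per_variant)}
    order = sorted(
        per_variant,
        key=lambda h: (
            -h.hit_count,
            gene_of[h.variant_id + "\x00" + h.case_id],
            h.variant_id,
        ),
    )
    tallies = tally_hits(per_variant)
    return PrioritizationReport(
        per_variant=per_variant,
        prioritized=[(h.variant_id, h.case_id, h.hit_count) for h in order],
        **tallies,
    )


def vus_with_cases(cohort) -> list[tuple[VariantRecord, CaseRecord]]:
    """Pair each reported VUS from a vus_case with its CaseRecord."""
    status = {c.case_id: c for c in cohort.cases}
    return [
        (v, status[v.case_id])
        for v in cohort.variants
        if v.classification == "vus"
        and status[v.case_id].diagnostic_status == "vus_case"
    ]
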