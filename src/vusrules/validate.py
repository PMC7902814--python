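"""Benchmarking a rule set on labelled variant sets.

The motivating study validated its rules three ways: VUS later
reclassified by an independent review, VUS found in trans with a
pathogenic variant in recessive cases, and homozygous VUS in solved
cases. All three reduce to the same computation — apply the rules to
variants with a known (assumed-causal or reclassified) label and count
how many hit at least one rule. Benign-reclassified variants are kept
apart as a specificity check, never pooled with positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import DomainError, InsufficientDataError
from .records import CaseRecord, VariantRecord
from .rules import RuleHits, RuleSet, apply_rules, tally_hits

SET_NAMES = ("reclassified_review", "in_trans_recessive", "homozygous_solved", "custom")
LABELS = ("reclassified_pathogenic", "reclassified_benign", "assumed_causal")
DEFAULT_POSITIVE_LABELS = frozenset({"reclassified_pathogenic", "assumed_causal"})


@dataclass(frozen=True)
class LabeledVariant:
    variant: VariantRecord
    case: CaseRecord
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise DomainError(f"unknown label {self.label!r}")


@dataclass
class LabeledVariantSet:
    """A named benchmarking set of (variant, case, label) triples."""

    set_name: str
    records: list[LabeledVariant]

    def __post_init__(self):
        if self.set_name not in SET_NAMES:
            raise DomainError(f"unknown set_name {self.set_name!r}")
        if not self.records:
            raise InsufficientDataError(f"labelled set {self.set_name} is empty")


@dataclass
class ValidationResult:
    """Rule-hit tallies over one labelled set."""

    set_name: str
    n: int
    n_ge1: int
    n_ge2: int
    per_rule: dict[str, int] = field(default_factory=dict)
    per_combination: dict[str, int] = field(default_factory=dict)
    per_variant: list[RuleHits] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.n_ge2 <= self.n_ge1 <= self.n):
            raise DomainError("tallies must satisfy n_ge2 <= n_ge1 <= n")

    @property
    def fraction_ge1(self) -> float:
        return self.n_ge1 / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "n": self.n,
            "n_ge1": self.n_ge1,
            "n_ge2": self.n_ge2,
            "fraction_ge1": self.fraction_ge1,
            "per_rule": dict(self.per_rule),
            "per_combination": dict(self.per_combination),
            "per_variant": [
                {
                    "variant_id": h.variant_id,
                    "case_id": h.case_id,
                    "hits": sorted(h.hits),
                    "hit_count": h.hit_count,
                }
                for h in self.per_variant
            ],
        }


def _tallied_result(set_name: str, hits: list[RuleHits]) -> ValidationResult:
    t = tally_hits(hits)
    return ValidationResult(
        set_name=set_name,
        n=t["n_total"],
        n_ge1=t["n_ge1"],
        n_ge2=t["n_ge2"],
        per_rule=t["per_rule"],
        per_combination=t["per_combination"],
        per_variant=hits,
    )


def evaluate_ruleset(
    rules: RuleSet,
    labeled: LabeledVariantSet,
    positive_labels=DEFAULT_POSITIVE_LABELS,
) -> ValidationResult:
    """Apply the rules to the positive-labelled variants of a set.

    Success is counted as variants hitting >= 1 rule; the >= 2-rule count
    is the stricter secondary tier. Benign-labelled variants are ignored
    here — see :func:`specificity_check`.
    """
    positives = [r for r in labeled.records if r.label in positive_labels]
    if not positives:
        raise InsufficientDataError(
            f"no positive-labelled variants in set {labeled.set_name}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # reclassified variants are knowingly non-VUS
        hits = [apply_rules(r.variant, r.case, rules) for r in positives]
    return _tallied_result(labeled.set_name, hits)


def specificity_check(rules: RuleSet, labeled: LabeledVariantSet) -> ValidationResult:
    """Tallies restricted to benign-reclassified variants; lower is
    better, no threshold is enforced. Empty benign subset -> zero tallies
    with a warning."""
    benign = [r for r in labeled.records if r.label == "reclassified_benign"]
    if not benign:
        warnings.warn(
            f"no benign-labelled variants in set {labeled.set_name}; "
            "specificity check is vacuous",
            stacklevel=2,
        )
        return ValidationResult(set_name=labeled.set_name, n=0, n_ge1=0, n_ge2=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hits = [apply_rules(r.variant, r.case, rules) for r in benign]
    return _tallied_result(labeled.set_name, hits)


def pooled_success(results: list[ValidationResult]) -> float:
    """Count-pooled success fraction (sum of >=1-rule hits over the sum of
    set sizes) — not the mean of per-set fractions."""
    if not results:
        raise InsufficientDataError("no validation results to pool")
    n = sum(r.n for r in results)
    if n == 0:
        raise DomainError("pooled success undefined: total n is zero")
    return sum(r.n_ge1 for r in results) / n
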