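"""Statistical primitives: exact 2x2 tests, FDR, and result containers.

The enrichment machinery of the pipeline is deliberately simple: every
feature comparison reduces to a one-vs-rest 2x2 contingency table tested
with a two-sided Fisher exact test, with Benjamini-Hochberg FDR applied
within each feature family.

The Fisher p-value is computed by exact hypergeometric enumeration with
integer weights, so results carry no floating-point ambiguity in the
inclusion test (which tables count as "at least as extreme"). The odds
ratio is the sample (cross-product) ratio a*d/(b*c), with the 0/0 -> 1
and x/0 -> +inf conventions, matching the enriched/depleted reading of
the scan results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, DomainError

ENRICHED = "enriched_in_vus"
DEPLETED = "depleted_in_vus"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are the two variant classes (VUS on
    top in the scan convention), columns are level / not-level."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("vus", "reference")
    col_labels: tuple[str, str] = ("level", "rest")

    def __post_init__(self):
        for count in (self.a, self.b, self.c, self.d):
            if count < 0 or int(count) != count:
                raise DomainError(f"counts must be non-negative integers, got {count}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def is_degenerate(self) -> bool:
        """True when some margin is empty (the test carries no information)."""
        return (
            min(self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d) == 0
        )

    def swap_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.c, self.d, self.a, self.b,
            row_labels=(self.row_labels[1], self.row_labels[0]),
            col_labels=self.col_labels,
        )


def odds_ratio_2x2(table: ContingencyTable2x2) -> float:
    """Sample odds ratio a*d/(b*c); 0/0 -> 1.0, x/0 -> +inf."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return 1.0 if num == 0 else math.inf
    return num / den


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's. Weights are exact integers (binomial coefficients), so the
    inclusion comparison is exact; the final ratio is rounded once to
    float.

    Returns (p, odds_ratio). Tables with an empty margin return p = 1.0
    (no information); the all-zero table raises DegenerateTableError.
    """
    if table.total == 0:
        raise DegenerateTableError("all-zero 2x2 table")
    if table.is_degenerate:
        return 1.0, odds_ratio_2x2(table)
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, table.a) * math.comb(r2, c1 - table.a)
    num = 0
    den = 0
    for k in range(k_min, k_max + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        den += w
        if w <= w_obs:
            num += w
    return float(Fraction(num, den)), odds_ratio_2x2(table)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    adjusted_(i) = min_{j >= rank(i)} (m/j) * p_(j), capped at 1; output
    aligned to input order, stable under ties; m = 1 is the identity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FeatureComparison:
    """One one-vs-rest enrichment test for a feature level.

    Levels with fewer observations than the scan's ``min_total`` are kept
    with ``tested=False`` (and p fields None) rather than silently
    dropped. ``direction`` compares the odds ratio to 1; an exact tie is
    reported as depleted with ``tie=True``.
    """

    feature: str
    level: str
    table: ContingencyTable2x2
    odds_ratio: float | None = None
    p_raw: float | None = None
    p_fdr: float | None = None
    direction: str | None = None
    significant: bool = False
    tested: bool = True
    degenerate: bool = False
    tie: bool = False

    @property
    def comparison_id(self) -> str:
        return f"{self.feature}:{self.level}"

    def to_dict(self) -> dict:
        # +inf odds ratios serialize as the string "inf" (strict JSON)
        or_json = (
            "inf"
            if self.odds_ratio is not None and math.isinf(self.odds_ratio)
            else self.odds_ratio
        )
        return {
            "feature": self.feature,
            "level": self.level,
            "table": [self.table.a, self.table.b, self.table.c, self.table.d],
            "row_labels": list(self.table.row_labels),
            "odds_ratio": or_json,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "direction": self.direction,
            "significant": self.significant,
            "tested": self.tested,
            "degenerate": self.degenerate,
            "tie": self.tie,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureComparison":
        a, b, c, d = payload["table"]
        payload = {**payload, "odds_ratio": (
            math.inf if payload["odds_ratio"] == "inf" else payload["odds_ratio"]
        )}
        return cls(
            feature=payload["feature"],
            level=payload["level"],
            table=ContingencyTable2x2(
                a, b, c, d, row_labels=tuple(payload.get("row_labels", ("vus", "reference")))
            ),
            odds_ratio=payload["odds_ratio"],
            p_raw=payload["p_raw"],
            p_fdr=payload["p_fdr"],
            direction=payload["direction"],
            significant=payload["significant"],
            tested=payload.get("tested", True),
            degenerate=payload.get("degenerate", False),
            tie=payload.get("tie", False),
        )


def direction_from_or(odds_ratio: float) -> tuple[str, bool]:
    """Map an odds ratio to (direction, tie_flag); OR = 1 -> depleted, tied."""
    if odds_ratio > 1.0:
        return ENRICHED, False
    return DEPLETED, odds_ratio == 1.0


def test_comparisons(
    comparisons: list[FeatureComparison], alpha: float = 0.05
) -> list[FeatureComparison]:
    """Run Fisher on every tested comparison and BH-FDR across them
    (one family), filling p_raw/p_fdr/direction/significant in place."""
    tested = [fc for fc in comparisons if fc.tested]
    for fc in tested:
        if fc.table.total == 0:
            fc.tested = False
            fc.degenerate = True
            continue
        p, or_ = fisher_exact_2x2(fc.table)
        fc.p_raw = p
        fc.odds_ratio = or_
        fc.degenerate = fc.table.is_degenerate
        fc.direction, fc.tie = direction_from_or(or_)
    tested = [fc for fc in comparisons if fc.tested]
    if tested:
        adjusted = bh_fdr([fc.p_raw for fc in tested])
        for fc, p_adj in zip(tested, adjusted):
            fc.p_fdr = float(p_adj)
            fc.significant = fc.p_fdr < alpha
    return comparisons


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of a size measure against variant counts."""

    feature: str
    variant_class: str  # "vus" | "reference"
    r: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided rank-sum comparison of a score between variant classes."""

    feature: str
    statistic: float
    p: float
    n1: int
    n2: int
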