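"""Cohort data model: cases, variants, predictor profiles.

One :class:`CaseRecord` per index case, one :class:`VariantRecord` per
reported variant per case (so a variant shared by two cases appears
twice), bundled into a :class:`CohortTable` with referential-integrity
checks. Variant identity is the transcript-qualified HGVS string
(e.g. ``NM_000350.2:c.5383T>G``), compared byte-wise after whitespace
normalization; no genomic-coordinate model is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import vocab
from .errors import IntegrityError, SchemaError


def normalize_variant_id(raw: str) -> str:
    """Strip all whitespace from an HGVS identifier (``'NM_1: c.5 T > G'``
    and ``'NM_1:c.5T>G'`` are the same variant)."""
    return "".join(raw.split())


@dataclass(frozen=True)
class PredictorProfile:
    """One call per predictor in the fixed order of :data:`vocab.PREDICTORS`.

    ``unavailable`` is distinct from ``tolerated``: the absence of a
    prediction is not a prediction, which matters for strict consensus.
    """

    calls: tuple[str, str, str, str, str]

    def __post_init__(self):
        if len(self.calls) != len(vocab.PREDICTORS):
            raise SchemaError(
                f"predictor profile needs exactly {len(vocab.PREDICTORS)} calls, "
                f"got {len(self.calls)}"
            )
        for name, call in zip(vocab.PREDICTORS, self.calls):
            if call not in vocab.PREDICTOR_CALLS:
                raise SchemaError(f"unknown predictor call {call!r} for {name}")

    @property
    def n_deleterious(self) -> int:
        return sum(c == "deleterious" for c in self.calls)

    @property
    def n_unavailable(self) -> int:
        return sum(c == "unavailable" for c in self.calls)

    @classmethod
    def from_mapping(cls, calls: dict[str, str]) -> "PredictorProfile":
        """Build from a {predictor_name: call} mapping; missing predictors
        become ``unavailable``."""
        return cls(tuple(calls.get(p, "unavailable") for p in vocab.PREDICTORS))

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(vocab.PREDICTORS, self.calls))


ALL_UNAVAILABLE = PredictorProfile(("unavailable",) * 5)


@dataclass(frozen=True)
class CaseRecord:
    """One diagnostic case.

    ``analyst_ids`` holds one analyst, or two for co-analyzed cases;
    co-analyzed cases are excluded from analyst-level scans.
    """

    case_id: str
    sub_cohort: str
    diagnostic_status: str
    inheritance: str
    platform: str
    panel_id: str
    panel_gene_count: int
    analyst_ids: tuple[str, ...]
    disease_label: str = ""

    def __post_init__(self):
        if self.sub_cohort not in vocab.SUB_COHORTS:
            raise SchemaError(f"unknown sub_cohort {self.sub_cohort!r}")
        if self.diagnostic_status not in vocab.DIAGNOSTIC_STATUSES:
            raise SchemaError(f"unknown diagnostic_status {self.diagnostic_status!r}")
        if self.inheritance not in vocab.INHERITANCES:
            raise SchemaError(f"unknown inheritance {self.inheritance!r}")
        if self.platform not in vocab.PLATFORMS:
            raise SchemaError(f"unknown platform {self.platform!r}")
        if self.panel_gene_count < 1:
            raise SchemaError("panel_gene_count must be >= 1")
        if not (1 <= len(self.analyst_ids) <= 2):
            raise SchemaError("a case carries one analyst, or two if co-analyzed")

    @property
    def co_analyzed(self) -> bool:
        return len(self.analyst_ids) > 1


@dataclass(frozen=True)
class VariantRecord:
    """One reported variant in one case, with its annotations.

    Optional gene metrics (``gene_pli`` in [0,1], ``ccr_percentile`` in
    [0,100], ``gene_coding_length`` in bp) are ``None`` when missing —
    never silently zero.
    """

    variant_id: str
    case_id: str
    gene_symbol: str
    classification: str
    consequence: str
    genomic_region: str
    zygosity: str
    predictor_profile: PredictorProfile = ALL_UNAVAILABLE
    gene_pli: float | None = None
    ccr_percentile: float | None = None
    gene_coding_length: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "variant_id", normalize_variant_id(self.variant_id))
        if self.classification not in vocab.CLASSIFICATIONS:
            raise SchemaError(f"unknown classification {self.classification!r}")
        if self.consequence not in vocab.CONSEQUENCES:
            raise SchemaError(f"unknown consequence {self.consequence!r}")
        if self.genomic_region not in vocab.GENOMIC_REGIONS:
            raise SchemaError(f"unknown genomic_region {self.genomic_region!r}")
        if self.zygosity not in vocab.ZYGOSITIES:
            raise SchemaError(f"unknown zygosity {self.zygosity!r}")
        if self.gene_pli is not None and not (0.0 <= self.gene_pli <= 1.0):
            raise SchemaError(f"gene_pli {self.gene_pli} outside [0, 1]")
        if self.ccr_percentile is not None and not (0.0 <= self.ccr_percentile <= 100.0):
            raise SchemaError(f"ccr_percentile {self.ccr_percentile} outside [0, 100]")
        if self.gene_coding_length is not None and self.gene_coding_length < 1:
            raise SchemaError("gene_coding_length must be a positive bp count")

    @property
    def key(self) -> tuple[str, str]:
        return (self.variant_id, self.case_id)


@dataclass
class CohortTable:
    """Validated bundle of cases and their reported variants."""

    cases: list[CaseRecord]
    variants: list[VariantRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Referential integrity and status/variant-count consistency.

        Raises IntegrityError on: dangling case ids, duplicated
        (variant_id, case_id) pairs, a VUS case with no reported VUS, or
        an unsolved case with reported variants.
        """
        case_ids = {c.case_id for c in self.cases}
        if len(case_ids) != len(self.cases):
            raise IntegrityError("duplicate case_id in cases")
        seen: set[tuple[str, str]] = set()
        per_case_vus: dict[str, int] = {}
        per_case_any: dict[str, int] = {}
        for v in self.variants:
            if v.case_id not in case_ids:
                raise IntegrityError(
                    f"variant {v.variant_id} references unknown case {v.case_id}"
                )
            if v.key in seen:
                raise IntegrityError(
                    f"duplicate (variant_id, case_id) pair {v.key}"
                )
            seen.add(v.key)
            per_case_any[v.case_id] = per_case_any.get(v.case_id, 0) + 1
            if v.classification == "vus":
                per_case_vus[v.case_id] = per_case_vus.get(v.case_id, 0) + 1
        for c in self.cases:
            if c.diagnostic_status == "vus_case" and per_case_vus.get(c.case_id, 0) == 0:
                raise IntegrityError(
                    f"vus_case {c.case_id} has no reported VUS"
                )
            if c.diagnostic_status == "unsolved" and per_case_any.get(c.case_id, 0) > 0:
                raise IntegrityError(
                    f"unsolved case {c.case_id} has reported variants"
                )

    def case_by_id(self, case_id: str) -> CaseRecord:
        try:
            return self._case_index[case_id]
        except AttributeError:
            self._case_index = {c.case_id: c for c in self.cases}
            return self._case_index[case_id]

    def subset_sub_cohort(self, sub_cohort: str) -> "CohortTable":
        """Restrict to one sub-cohort (analyses typically run on IRD only)."""
        if sub_cohort not in vocab.SUB_COHORTS:
            raise SchemaError(f"unknown sub_cohort {sub_cohort!r}")
        keep = {c.case_id for c in self.cases if c.sub_cohort == sub_cohort}
        return CohortTable(
            cases=[c for c in self.cases if c.case_id in keep],
            variants=[v for v in self.variants if v.case_id in keep],
            provenance={**self.provenance, "subset": sub_cohort},
        )

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_variants(self) -> int:
        return len(self.variants)
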