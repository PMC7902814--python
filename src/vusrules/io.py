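"""Read, write, and summarize cohort annotation tables.

The canonical input is a pair of flat tab-separated tables: a variants
table (one row per reported variant per case) and a cases table (one row
per case, so that unsolved cases with zero variants are representable).
Missing optional annotations use the ``NA`` token and stay missing —
never silently zero. Rows that fail vocabulary or range checks are
collected and reported together in a single :class:`SchemaError`.
"""

from __future__ import annotations

import math

import pandas as pd

from . import vocab
from .errors import ConfigurationError, IntegrityError, SchemaError
from .records import CaseRecord, CohortTable, PredictorProfile, VariantRecord

SCHEMA_VERSION = "1"
ANALYST_SEP = ";"

VARIANT_COLUMNS = (
    "case_id",
    "gene_symbol",
    "variant_id",
    "classification",
    "consequence",
    "genomic_region",
    "zygosity",
) + vocab.PREDICTORS
OPTIONAL_VARIANT_COLUMNS = ("gene_pli", "ccr_percentile", "gene_coding_length")

CASE_COLUMNS = (
    "case_id",
    "sub_cohort",
    "diagnostic_status",
    "inheritance",
    "platform",
    "panel_id",
    "panel_gene_count",
    "analyst_ids",
)
OPTIONAL_CASE_COLUMNS = ("disease_label",)


def _read_tsv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read table {path}: {exc}") from exc
    return frame


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def _opt_float(token: str):
    if token in ("", vocab.NA_TOKEN):
        return None
    return float(token)


def _opt_int(token: str):
    value = _opt_float(token)
    if value is None:
        return None
    return int(round(value))


def _parse_cases(cdf: pd.DataFrame) -> tuple[list[CaseRecord], list[str]]:
    bad_rows: list[str] = []
    cases: list[CaseRecord] = []
    for i, row in enumerate(cdf.itertuples(index=False), start=1):
        try:
            cases.append(
                CaseRecord(
                    case_id=row.case_id,
                    sub_cohort=row.sub_cohort,
                    diagnostic_status=row.diagnostic_status,
                    inheritance=row.inheritance,
                    platform=row.platform,
                    panel_id=row.panel_id,
                    panel_gene_count=int(row.panel_gene_count),
                    analyst_ids=tuple(
                        a.strip() for a in row.analyst_ids.split(ANALYST_SEP) if a.strip()
                    ),
                    disease_label=getattr(row, "disease_label", ""),
                )
            )
        except (SchemaError, ValueError) as exc:
            bad_rows.append(f"cases row {i}: {exc}")
    return cases, bad_rows


def _parse_variants(
    vdf: pd.DataFrame, consequence_aliases: dict[str, str] | None = None
) -> tuple[list[VariantRecord], list[str]]:
    bad_rows: list[str] = []
    variants: list[VariantRecord] = []
    for i, row in enumerate(vdf.itertuples(index=False), start=1):
        try:
            consequence = vocab.canonical_consequence(row.consequence, consequence_aliases)
        except KeyError:
            bad_rows.append(
                f"variants row {i}: unknown consequence token {row.consequence!r}"
            )
            continue
        calls = []
        for predictor in vocab.PREDICTORS:
            token = getattr(row, predictor).strip()
            calls.append("unavailable" if token in ("", vocab.NA_TOKEN) else token)
        try:
            variants.append(
                VariantRecord(
                    variant_id=row.variant_id,
                    case_id=row.case_id,
                    gene_symbol=row.gene_symbol,
                    classification=row.classification,
                    consequence=consequence,
                    genomic_region=row.genomic_region,
                    zygosity=row.zygosity,
                    predictor_profile=PredictorProfile(tuple(calls)),
                    gene_pli=_opt_float(getattr(row, "gene_pli", vocab.NA_TOKEN)),
                    ccr_percentile=_opt_float(getattr(row, "ccr_percentile", vocab.NA_TOKEN)),
                    gene_coding_length=_opt_int(
                        getattr(row, "gene_coding_length", vocab.NA_TOKEN)
                    ),
                )
            )
        except (SchemaError, ValueError) as exc:
            bad_rows.append(f"variants row {i}: {exc}")
    return variants, bad_rows


def read_cohort(
    variants_path,
    cases_path,
    consequence_aliases: dict[str, str] | None = None,
) -> CohortTable:
    """Parse and validate a variants + cases TSV pair into a CohortTable.

    Parameters
    ----------
    variants_path, cases_path
        Tab-separated UTF-8 files with header rows; see VARIANT_COLUMNS
        and CASE_COLUMNS for required columns.
    consequence_aliases
        Optional replacement for the default consequence-spelling table.

    Raises
    ------
    SchemaError
        Missing required columns, or any row with an unknown vocabulary
        token / out-of-range value (all offending rows listed, 1-based
        data-row numbers).
    IntegrityError
        Duplicate (variant_id, case_id) pairs or dangling case ids.
    """
    vdf = _read_tsv(variants_path)
    cdf = _read_tsv(cases_path)
    _require_columns(vdf, VARIANT_COLUMNS, variants_path)
    _require_columns(cdf, CASE_COLUMNS, cases_path)
    cases, bad_cases = _parse_cases(cdf)
    variants, bad_variants = _parse_variants(vdf, consequence_aliases)
    bad_rows = bad_cases + bad_variants
    if bad_rows:
        raise SchemaError(
            f"{len(bad_rows)} row(s) failed validation:\n" + "\n".join(bad_rows),
            rows=bad_rows,
        )

    return CohortTable(
        cases=cases,
        variants=variants,
        provenance={
            "variants_path": str(variants_path),
            "cases_path": str(cases_path),
            "schema_version": SCHEMA_VERSION,
        },
    )


def _fmt_opt(value) -> str:
    if value is None:
        return vocab.NA_TOKEN
    if isinstance(value, float):
        if math.isnan(value):
            return vocab.NA_TOKEN
        return repr(value)
    return str(value)


def write_cohort(cohort: CohortTable, variants_path, cases_path) -> None:
    """Write a CohortTable back to the canonical TSV pair (round-trips
    with :func:`read_cohort` up to column order and float formatting)."""
    vrows = [
        {
            "case_id": v.case_id,
            "gene_symbol": v.gene_symbol,
            "variant_id": v.variant_id,
            "classification": v.classification,
            "consequence": v.consequence,
            "genomic_region": v.genomic_region,
            "zygosity": v.zygosity,
            **v.predictor_profile.as_mapping(),
            "gene_pli": _fmt_opt(v.gene_pli),
            "ccr_percentile": _fmt_opt(v.ccr_percentile),
            "gene_coding_length": _fmt_opt(v.gene_coding_length),
        }
        for v in cohort.variants
    ]
    crows = [
        {
            "case_id": c.case_id,
            "sub_cohort": c.sub_cohort,
            "diagnostic_status": c.diagnostic_status,
            "inheritance": c.inheritance,
            "platform": c.platform,
            "panel_id": c.panel_id,
            "panel_gene_count": c.panel_gene_count,
            "analyst_ids": ANALYST_SEP.join(c.analyst_ids),
            "disease_label": c.disease_label,
        }
        for c in cohort.cases
    ]
    vcols = list(VARIANT_COLUMNS) + list(OPTIONAL_VARIANT_COLUMNS)
    ccols = list(CASE_COLUMNS) + list(OPTIONAL_CASE_COLUMNS)
    pd.DataFrame(vrows, columns=vcols).to_csv(variants_path, sep="\t", index=False)
    pd.DataFrame(crows, columns=ccols).to_csv(cases_path, sep="\t", index=False)


def summarize_cohort(cohort: CohortTable) -> dict:
    """Counts and fractions of cases per sub_cohort x diagnostic_status and
    variants per classification. An empty cohort yields all-zero counts."""
    n_cases = cohort.n_cases
    case_counts: dict[str, dict[str, int]] = {
        sc: {st: 0 for st in sorted(vocab.DIAGNOSTIC_STATUSES)}
        for sc in sorted(vocab.SUB_COHORTS)
    }
    for c in cohort.cases:
        case_counts[c.sub_cohort][c.diagnostic_status] += 1
    variant_counts = {cl: 0 for cl in sorted(vocab.CLASSIFICATIONS)}
    for v in cohort.variants:
        variant_counts[v.classification] += 1
    return {
        "n_cases": n_cases,
        "n_variants": cohort.n_variants,
        "cases": {
            sc: {
                st: {
                    "count": count,
                    "fraction": (count / n_cases) if n_cases else 0.0,
                }
                for st, count in by_status.items()
            }
            for sc, by_status in case_counts.items()
        },
        "cases_per_sub_cohort": {
            sc: sum(by_status.values()) for sc, by_status in case_counts.items()
        },
        "variants_per_classification": variant_counts,
    }


def split_variant_sets(
    cohort: CohortTable, dedupe_mode: str = "all_occurrences"
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split into the VUS set and the pathogenic/likely-pathogenic
    reference set.

    vus_set: classification ``vus`` reported in ``vus_case`` cases.
    reference_set: ``pathogenic``/``likely_pathogenic`` variants from
    solved or partially solved cases. Benign/likely-benign rows are
    accepted on input but enter neither set.

    ``dedupe_mode='unique_variants'`` collapses duplicates by variant_id
    within each set, keeping the first occurrence in stable input order;
    ``'all_occurrences'`` keeps every report (the mutational-load view).
    """
    if dedupe_mode not in ("all_occurrences", "unique_variants"):
        raise ConfigurationError(f"unknown dedupe_mode {dedupe_mode!r}")
    status = {c.case_id: c.diagnostic_status for c in cohort.cases}
    vus_set = [
        v
        for v in cohort.variants
        if v.classification == "vus" and status[v.case_id] == "vus_case"
    ]
    reference_set = [
        v
        for v in cohort.variants
        if v.classification in vocab.PATHOGENIC_CLASSES
        and status[v.case_id] in ("solved", "partially_solved")
    ]
    if dedupe_mode == "unique_variants":
        def dedupe(records):
            seen, out = set(), []
            for r in records:
                if r.variant_id not in seen:
                    seen.add(r.variant_id)
                    out.append(r)
            return out

        vus_set, reference_set = dedupe(vus_set), dedupe(reference_set)
    return vus_set, reference_set


def read_labeled_set(
    variants_path, cases_path, set_name: str = "custom"
):
    """Read a labelled variant TSV (variant columns + ``label``) plus a
    cases table, for rule benchmarking. The cases table may describe a
    whole cohort; only the cases referenced by the labelled variants are
    kept, and cohort-level status invariants are not enforced (a
    benchmark set is a slice, not a cohort). Returns a LabeledVariantSet."""
    from .validate import LABELS, LabeledVariant, LabeledVariantSet

    vdf = _read_tsv(variants_path)
    cdf = _read_tsv(cases_path)
    _require_columns(vdf, VARIANT_COLUMNS + ("label",), variants_path)
    _require_columns(cdf, CASE_COLUMNS, cases_path)
    labels = list(vdf["label"])
    bad = [
        f"labelled row {i}: unknown label {tok!r}"
        for i, tok in enumerate(labels, start=1)
        if tok not in LABELS
    ]
    variants, bad_variants = _parse_variants(vdf.drop(columns=["label"]))
    cases, bad_cases = _parse_cases(cdf)
    bad += bad_variants + bad_cases
    if bad:
        raise SchemaError("\n".join(bad), rows=bad)
    case_index = {c.case_id: c for c in cases}
    missing = sorted({v.case_id for v in variants} - set(case_index))
    if missing:
        raise IntegrityError(
            f"labelled variants reference unknown case(s): {', '.join(missing)}"
        )
    records = [
        LabeledVariant(variant=v, case=case_index[v.case_id], label=lab)
        for v, lab in zip(variants, labels)
    ]
    return LabeledVariantSet(set_name=set_name, records=records)
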