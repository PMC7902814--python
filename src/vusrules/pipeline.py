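"""End-to-end orchestration: analyze -> derive rules -> prioritize
(-> validate), with reproducible machine-readable artifacts.

Every JSON artifact embeds the configuration snapshot and SHA-256
checksums of its inputs, uses sorted keys and default (shortest
round-trip) float repr, so identical inputs and configuration produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cohort_io
from .errors import ConfigurationError
from .rules import derive_rules, prioritize, vus_with_cases
from .scans import predictor_consensus_comparison, scan_case_feature, scan_categorical
from .stats import FeatureComparison
from .validate import evaluate_ruleset, pooled_success, specificity_check

log = logging.getLogger("vusrules")

VARIANT_SCAN_FEATURES = ("gene", "consequence", "genomic_region")
CASE_SCAN_FEATURES = ("inheritance", "analyst", "platform")


@dataclass
class PipelineConfig:
    """Options for a full pipeline run; snapshot is embedded in every
    artifact for provenance."""

    variants_path: str
    cases_path: str
    out_dir: str
    alpha: float = 0.05
    min_total: int = 3
    dedupe_mode: str = "all_occurrences"
    #: analyses run on this sub-cohort; None keeps the whole table
    sub_cohort: str | None = "IRD"
    required_consensus: int = 5
    #: optional labelled benchmark sets: {set_name: (variants_tsv, cases_tsv)}
    labeled_sets: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_total < 0:
            raise ConfigurationError("min_total must be >= 0")
        if self.dedupe_mode not in ("all_occurrences", "unique_variants"):
            raise ConfigurationError(f"unknown dedupe_mode {self.dedupe_mode!r}")
        if not 1 <= self.required_consensus <= 5:
            raise ConfigurationError("required_consensus must be in 1..5")

    def snapshot(self) -> dict:
        return {
            "variants_path": str(self.variants_path),
            "cases_path": str(self.cases_path),
            "alpha": self.alpha,
            "min_total": self.min_total,
            "dedupe_mode": self.dedupe_mode,
            "sub_cohort": self.sub_cohort,
            "required_consensus": self.required_consensus,
        }


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_json(payload: dict, path) -> None:
    """Stable serialization: sorted keys, newline-terminated."""
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=1, allow_nan=False) + "\n"
    )


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config": config.snapshot(),
        "input_checksums": {
            "variants": sha256_file(config.variants_path),
            "cases": sha256_file(config.cases_path),
        },
    }


def run_scans(cohort, config: PipelineConfig) -> dict:
    """The analyze stage: split the variant sets and run every feature
    scan plus the predictor-consensus comparison. Returns the
    results-artifact payload (scan lists serialized per comparison)."""
    vus_set, reference_set = cohort_io.split_variant_sets(
        cohort, dedupe_mode=config.dedupe_mode
    )
    log.info(
        "scan base: %d VUS, %d reference variants (%s)",
        len(vus_set), len(reference_set), config.dedupe_mode,
    )
    scans: dict[str, list] = {}
    for feature in VARIANT_SCAN_FEATURES:
        scans[feature] = scan_categorical(
            vus_set, reference_set, feature,
            min_total=config.min_total, alpha=config.alpha,
        )
    for feature in CASE_SCAN_FEATURES:
        scans[feature] = scan_case_feature(
            cohort.cases, feature, outcome="vus_case",
            alpha=config.alpha, min_total=config.min_total,
        )
    consensus = predictor_consensus_comparison(
        vus_set, reference_set, required=config.required_consensus,
        alpha=config.alpha,
    )
    for feature, results in scans.items():
        untested = [fc.level for fc in results if not fc.tested]
        if untested:
            log.info("%s: untested levels (below min_total): %s",
                     feature, ", ".join(untested))
    return {
        "summary": cohort_io.summarize_cohort(cohort),
        "n_vus": len(vus_set),
        "n_reference": len(reference_set),
        "scans": {
            feature: [fc.to_dict() for fc in results]
            for feature, results in scans.items()
        },
        "predictor_consensus": consensus.to_dict(),
    }


def scan_results_from_artifact(payload: dict) -> dict:
    """Rebuild the derive_rules input from a results.json payload."""
    out = {
        feature: [FeatureComparison.from_dict(d) for d in results]
        for feature, results in payload["scans"].items()
    }
    out["predictor_consensus"] = FeatureComparison.from_dict(
        payload["predictor_consensus"]
    )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run analyze -> derive-rules -> prioritize (-> validate); returns
    {artifact name: path}. Artifacts: results.json, ruleset.json,
    report.json, report.tsv and, when labelled sets are configured,
    validation.json."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    cohort = cohort_io.read_cohort(config.variants_path, config.cases_path)
    log.info("read cohort: %d cases, %d variants", cohort.n_cases, cohort.n_variants)
    analysis_cohort = (
        cohort.subset_sub_cohort(config.sub_cohort) if config.sub_cohort else cohort
    )
    if config.sub_cohort:
        log.info("restricted to %s: %d cases, %d variants",
                 config.sub_cohort, analysis_cohort.n_cases, analysis_cohort.n_variants)

    results_payload = {**run_scans(analysis_cohort, config), **provenance}
    results_path = out_dir / "results.json"
    dump_json(results_payload, results_path)

    rules = derive_rules(
        scan_results_from_artifact(results_payload),
        required=config.required_consensus,
        alpha=config.alpha,
    )
    log.info("derived rules: %s enabled", ", ".join(rules.enabled_rules) or "none")
    ruleset_path = out_dir / "ruleset.json"
    dump_json({**rules.to_dict(), **provenance}, ruleset_path)

    report = prioritize(vus_with_cases(analysis_cohort), rules)
    log.info("prioritization: %d/%d VUS hit >=1 rule", report.n_ge1, report.n_total)
    report_path = out_dir / "report.json"
    dump_json({**report.to_dict(), **provenance}, report_path)
    tsv_path = out_dir / "report.tsv"
    _write_report_tsv(report, tsv_path)

    artifacts = {
        "results": str(results_path),
        "ruleset": str(ruleset_path),
        "report": str(report_path),
        "report_tsv": str(tsv_path),
    }

    if config.labeled_sets:
        validations = []
        specificity = []
        for set_name, (lv_path, lc_path) in sorted(config.labeled_sets.items()):
            labeled = cohort_io.read_labeled_set(lv_path, lc_path, set_name=set_name)
            result = evaluate_ruleset(rules, labeled)
            validations.append(result)
            if any(r.label == "reclassified_benign" for r in labeled.records):
                specificity.append(specificity_check(rules, labeled))
        validation_path = out_dir / "validation.json"
        dump_json(
            {
                "sets": [r.to_dict() for r in validations],
                "specificity": [r.to_dict() for r in specificity],
                "pooled_success": pooled_success(validations),
                **provenance,
            },
            validation_path,
        )
        artifacts["validation"] = str(validation_path)
    return artifacts


def _write_report_tsv(report, path) -> None:
    hit_by_key = {(h.variant_id, h.case_id): h for h in report.per_variant}
    lines = ["variant_id\tcase_id\thit_count\trules_hit"]
    for variant_id, case_id, hit_count in report.prioritized:
        h = hit_by_key[(variant_id, case_id)]
        lines.append(
            f"{variant_id}\t{case_id}\t{hit_count}\t{','.join(sorted(h.hits))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
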