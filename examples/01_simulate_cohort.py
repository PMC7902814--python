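"""Generate a calibrated synthetic diagnostic cohort and summarize it.

The generator emulates a two-year targeted-panel caseload: ~35% of cases
belong to the inherited-retinal-dystrophy (IRD) sub-cohort, each case is
solved / partially solved / pending a VUS / unsolved, and each reported
variant carries gene, consequence, region, zygosity and five in-silico
predictor calls. Printed below: the case mix and the variant-class mix.
"""

from vusrules import calibrated_config, generate_cohort, summarize_cohort

config = calibrated_config(n_cases=1937, seed=7)
cohort, truth = generate_cohort(config)
summary = summarize_cohort(cohort)

print(f"cases: {summary['n_cases']}  variants: {summary['n_variants']}")
for sub_cohort, by_status in summary["cases"].items():
    n = summary["cases_per_sub_cohort"][sub_cohort]
    print(f"\n{sub_cohort} ({n} cases)")
    for status, cell in by_status.items():
        print(f"  {status:17s} {cell['count']:5d}  ({100 * cell['fraction']:.1f}% of all cases)")

print("\nvariants per ACMG class:")
for classification, count in summary["variants_per_classification"].items():
    print(f"  {classification:17s} {count:5d}")

print(
    "\nplanted structure (ground truth): "
    f"VUS-depleted gene(s) {sorted(truth.depleted_genes)}, "
    f"VUS-enriched {sorted(truth.enriched_genes)}, "
    f"conservative analysts {sorted(truth.conservative_analysts)}"
)
# The depleted/enriched genes and conservative analysts are what the
# rule-derivation pipeline should later recover from the data alone.
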