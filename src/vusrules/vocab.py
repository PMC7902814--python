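"""Controlled vocabularies for the cohort data model.

Every categorical field of a case or variant record is validated against
one of these frozensets at read time; unknown tokens are schema errors,
never silently coerced. The ACMG/AMP five-tier classification, the
diagnostic-status taxonomy (solved / partially solved / VUS case /
unsolved) and the fixed ordered predictor set mirror how targeted-panel
diagnostic cohorts are reported.
"""

from __future__ import annotations

# --- ACMG/AMP variant classification (five tiers) -------------------------
CLASSIFICATIONS = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign"}
)
#: classes forming the reference (causal) comparator set
PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})
BENIGN_CLASSES = frozenset({"benign", "likely_benign"})

CONSEQUENCES = frozenset(
    {
        "missense",
        "frameshift",
        "stop_gain",
        "splice_region",
        "synonymous",
        "inframe_indel",
        "start_loss",
        "stop_loss",
        "other",
    }
)

GENOMIC_REGIONS = frozenset({"exonic", "splicing", "utr5", "utr3", "intronic"})

ZYGOSITIES = frozenset({"het", "hom", "hemi"})

DIAGNOSTIC_STATUSES = frozenset(
    {"solved", "partially_solved", "vus_case", "unsolved"}
)

INHERITANCES = frozenset({"dominant", "recessive", "x_linked", "unknown"})

PLATFORMS = frozenset({"TSO", "CES"})

SUB_COHORTS = frozenset({"IRD", "non_IRD"})

#: fixed ordered in-silico predictor set; order is part of the data model
PREDICTORS = ("sift", "polyphen", "mcap", "mutationassessor", "mutationtaster")

PREDICTOR_CALLS = frozenset({"deleterious", "tolerated", "unavailable"})

#: token used for missing optional annotations in TSV inputs
NA_TOKEN = "NA"

# Editable mapping from common annotation-pipeline spellings (VEP/SnpEff
# style SO terms among them) to the canonical consequence vocabulary.
# Tokens absent from both this table and CONSEQUENCES are errors, not
# "other": silent misclassification would corrupt the consequence rule.
DEFAULT_CONSEQUENCE_ALIASES: dict[str, str] = {
    "missense_variant": "missense",
    "frameshift_variant": "frameshift",
    "stop_gained": "stop_gain",
    "nonsense": "stop_gain",
    "splice_region_variant": "splice_region",
    "splice_donor_variant": "splice_region",
    "splice_acceptor_variant": "splice_region",
    "synonymous_variant": "synonymous",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "start_lost": "start_loss",
    "stop_lost": "stop_loss",
}


def canonical_consequence(token: str, aliases: dict[str, str] | None = None) -> str:
    """Map an input consequence token to the canonical vocabulary.

    Raises KeyError when the token is neither canonical nor aliased.
    """
    token = token.strip()
    if token in CONSEQUENCES:
        return token
    table = DEFAULT_CONSEQUENCE_ALIASES if aliases is None else aliases
    return table[token]
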