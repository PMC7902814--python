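# Methods

## Data model

The unit of observation is a *reported variant in a case*: a variant
shared by two cases contributes two rows. Cases carry a diagnostic
status with four levels — *solved* (one pathogenic variant in dominant,
two in recessive cases), *partially solved* (one pathogenic allele in a
suspected-recessive gene), *VUS case* (unsolved pending one VUS in
dominant or 1–2 in recessive cases) and *unsolved* (nothing reported) —
plus inheritance pattern, sequencing platform (TSO/CES clinical exome),
virtual panel, and the analyst(s) who signed the diagnosis. Variants
carry the ACMG/AMP five-tier classification, a consequence term from a
closed vocabulary (unknown spellings are schema errors, never coerced to
"other"), genomic region, zygosity, five in-silico predictor calls
(SIFT, PolyPhen, M-CAP, MutationAssessor, MutationTaster; each
deleterious / tolerated / *unavailable* — absence of a prediction is not
a prediction), and optional gene metrics (pLI ∈ [0,1], CCR percentile ∈
[0,100], coding length in bp), which stay missing rather than defaulting
to zero.

Variant identity is the transcript-qualified HGVS string compared
byte-wise after whitespace normalization. No genomic-coordinate model is
used; annotations arrive precomputed, so no liftover, strand or
0/1-based conventions arise. Benign/likely-benign rows are accepted on
input but excluded from every analysis.

## Statistical analysis

Every enrichment question reduces to a one-vs-rest 2×2 table per feature
level, tested with a **two-sided Fisher exact test**. The p-value sums
hypergeometric probabilities of all tables (fixed margins) whose
probability does not exceed the observed table's. Weights are exact
binomial-coefficient integers, so the "at least as extreme" inclusion
test involves no floating-point tolerance; the single rounding happens
in the final rational-to-double conversion. The reported odds ratio is
the sample cross-product ratio ad/bc with 0/0 → 1 and x/0 → +∞.
Zero-margin tables return p = 1 with a degenerate flag instead of
erroring inside scans; the all-zero table is an error. Direction is read
from the odds ratio (OR < 1: *depleted in VUS*; exact ties count as
depleted and are flagged).

**FDR control** uses Benjamini–Hochberg step-up
(adjusted₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (m/j)·p₍ⱼ₎, capped at 1; statsmodels'
implementation behind the package surface), applied *within* each
feature family — all genes together, all analysts together, and so on —
not across families. α = 0.05 by default. Tests are two-sided
throughout; enrichment vs depletion is recovered from the odds ratio
rather than by one-sided testing. Levels with fewer than `min_total`
(default 3) observations are reported as untested, never dropped
silently.

Exclusions mirror diagnostic practice: cases co-analyzed by two analysts
are excluded from the analyst scan (but can still *hit* the analyst rule
if either analyst qualifies, flagged in output); cases with unknown
inheritance are excluded from the inheritance scan.

Auxiliary comparisons: Pearson correlation of panel size (genes) or gene
coding size (bp) against per-unit VUS and reference counts, with
zero-variance inputs rejected as undefined; a two-sided rank-sum
(Wilcoxon/Mann–Whitney, exact for small samples) test for pLI; and an
exploratory per-decile one-vs-rest Fisher scan for CCR percentiles —
the CCR question is inherently distributional, and the binned test is
this package's operationalization of it.

The **predictor-consensus comparison** restricts both variant sets to
missense (the only class all five tools cover), counts variants whose
profile reaches ≥ `required` deleterious calls — for the strict default
`required = 5`, any unavailable call disqualifies — and tests the single
resulting 2×2. The table is stored VUS-row-first so that
`depleted_in_vus` uniformly means "VUS have less of it".

## Rule derivation and application

`derive_rules` consumes the gene, consequence and analyst scans plus the
consensus comparison and emits four independent rules whose payloads are
the significantly depleted levels: the gene rule (ABCA4-like genes), the
consequence rule (frameshift/stop-gain in the calibrated setting), the
analyst rule (low-VUS analysts) and the predictor rule (enabled when
consensus is significantly enriched in the reference set). Enriched
levels — an IMPG2-like gene, a liberal analyst — are flagged in the
provenance snapshot but never become payload: enrichment among VUS is a
reporting bias, not causal evidence. A family with no qualifying level
yields a disabled rule with a warning, never an error.

Rules are evaluated independently per variant (no coupling or
short-circuiting); priority is the hit count, and the report orders
variants by (hit count desc, gene, variant id) — a stable total order.
The engine deliberately stops at a priority list with per-rule
provenance; it performs no automatic reclassification, since rule hits
are prioritization evidence, not ACMG criteria.

Validation applies a derived rule set to labelled variants
(reclassified-on-review, in-trans-with-pathogenic, homozygous-in-solved)
and reports n≥1-rule and n≥2-rule tallies; "success" is the ≥1-rule
fraction, pooled across sets by counts (Σ hits / Σ n), with the ≥2-rule
tier as a secondary stringency level. Benign-reclassified variants feed
a separate specificity check and are never pooled with positives.

## The synthetic-data generator

The generator samples at the variant level *conditioned on class* (VUS
vs reference) rather than simulating geneticist decision-making
mechanistically: downstream analyses consume only class-conditional
distributions, and this keeps every expectation closed-form for tests.
Per case it draws sub-cohort, platform, virtual panel, analyst(s),
diagnostic status (the analyst's VUS-reporting propensity multiplies the
VUS-case probability, exchanging mass with the unsolved category) and
inheritance given status; per variant it draws gene (reference weights,
reweighted by the gene's `vus_rate_multiplier` for VUS), consequence,
region, zygosity and a predictor profile. Recessive two-variant cases
share one gene, which is what makes in-trans benchmark sets meaningful.

Determinism is per-entity: every case and variant slot owns an RNG
substream keyed by (master seed, kind, index), so growing `n_cases`
reproduces all earlier cases byte-for-byte.

Calibrated defaults (`calibrated_config`) encode the study
conditions of a 1937-case service cohort with a 34.5% IRD share: IRD
status mix (40% solved, 7.5% partially solved, 17.5% VUS cases), VUS
consequence mix 84% missense vs 46.6% in the reference set, full
predictor-consensus probabilities 0.58 (reference) vs 0.305 (VUS),
region mixes 92%/82% exonic, panels of 5–237 genes, one high-volume gene
with multiplier 0.05 (strong VUS depletion) and one small gene with
multiplier 40 (effectively VUS-only). Analyst propensities are 1.9 for
the liberal analyst and 0.20 for the two conservative ones; the
conservative value was fixed a priori by a two-proportion power
calculation so that, at ~690 IRD cases, each conservative analyst is
detected with ~98% power — a deliberately strong, unambiguous effect,
since a marginal one could not be recovered reliably by any method.
Solved recessive cases carry an in-trans causal VUS with probability
0.15 and a homozygous causal VUS with probability 0.07, providing
planted benchmark sets; `causal_vus_fraction` (default 0) lets a share
of pending VUS carry reference-class features for sensitivity tests,
with `expected_hit_probability` giving the closed-form lower bound
(gene + consequence + predictor rules; the analyst rule only adds hits).

What the generator does *not* emulate: joint feature dependencies
(consequence, region and predictor availability are drawn independently
within class), allele frequencies, pedigrees beyond the inheritance
label, panel-to-gene containment, and any sequence-level realism.
Passing tests therefore demonstrate that the statistical machinery
recovers class-conditional structure of the configured strength — not
that real cohorts contain such structure, nor how the rules perform
under correlated annotations.

## Numerical and design choices

- Exact integer arithmetic in the Fisher test; p-values are therefore
  reproducible bit-for-bit across platforms.
- JSON artifacts use sorted keys and Python's shortest-round-trip float
  repr; +∞ odds ratios serialize as the string `"inf"` (strict JSON).
  Every artifact embeds the option snapshot and SHA-256 input checksums.
- The `dedupe_mode` switch chooses between counting every report of a
  variant (`all_occurrences`, the mutational-load view and the default)
  and collapsing to unique variants (first occurrence kept, stable
  order); both are exposed because cohort accounting can legitimately be
  done either way.
- Analyses default to the disease sub-cohort (`sub_cohort="IRD"`); the
  non-disease sub-cohort serves contrast summaries only.
- Problem sizes in the test suite (cohorts of 600–2000 cases, 50–100
  seeds for recovery/null studies, 500 label permutations for type-I
  control) were chosen as the smallest sizes at which the calibrated
  effects are decisively powered.

## Known limitations

- Rules are intentionally cohort- and laboratory-specific; payloads
  derived from one cohort do not transfer.
- The predictor rule inherits the strict-consensus decision: variants
  with any unavailable predictor (including all non-missense variants,
  since two tools are missense-only) cannot satisfy 5/5. This matches
  treating absence of evidence as non-evidence, and is configurable via
  `required`.
- Under the global null, rule derivation is a four-family
  multiple-testing procedure; with α = 0.05 per family the chance that
  *some* rule is spuriously enabled is bounded near 1 − (1 − α/2)⁴ ≈ 10%
  (less in practice, because Fisher tests on small discrete counts are
  conservative). Single-cohort rule sets should always be inspected via
  their provenance before use.
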