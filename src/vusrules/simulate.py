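"""Synthetic diagnostic-cohort generator with ground truth.

The generator emulates the statistical structure a targeted-panel
diagnostic cohort presents to the downstream analysis: a mix of solved /
partially solved / VUS-pending / unsolved cases across two sub-cohorts,
gene-wise variant draws with configurable VUS depletion or enrichment
(an ABCA4-like well-characterised gene, an IMPG2-like poorly-annotated
one), analyst-specific VUS-reporting propensities, class-conditional
consequence / region / predictor-profile mixes, and a configurable
fraction of "causal-like" VUS that carry reference-set features.

Sampling is class-conditional (VUS vs reference) rather than a
mechanistic model of geneticist decision-making: the downstream scans
consume only class-conditional distributions, and this keeps every
expectation closed-form for testing. Determinism is per-entity: each
case and each variant slot owns a substream keyed by (master seed, kind,
index), so enlarging ``n_cases`` never perturbs earlier cases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .records import CaseRecord, CohortTable, PredictorProfile, VariantRecord
from .validate import LabeledVariant, LabeledVariantSet

_KIND_CASE = 1
_KIND_VARIANT = 2

_STATUS_ORDER = ("solved", "partially_solved", "vus_case", "unsolved")
_INHERITANCE_ORDER = ("dominant", "recessive", "x_linked", "unknown")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneSpec:
    """One gene in the simulated panel universe.

    ``weight`` is the relative draw probability for reference-class
    variants; VUS draws use ``weight * vus_rate_multiplier`` (values < 1
    deplete the gene of VUS, > 1 enrich it).
    """

    symbol: str
    coding_length: int
    pli: float
    weight: float
    vus_rate_multiplier: float = 1.0
    transcript: str = ""

    def __post_init__(self):
        if self.weight <= 0 or self.vus_rate_multiplier <= 0:
            raise ConfigurationError(
                f"gene {self.symbol}: weight and multiplier must be > 0"
            )
        if not 0.0 <= self.pli <= 1.0:
            raise ConfigurationError(f"gene {self.symbol}: pli outside [0, 1]")
        if self.coding_length < 1:
            raise ConfigurationError(f"gene {self.symbol}: bad coding_length")
        if not self.transcript:
            # crc32 keyed, not hash(): stable across processes
            stable = zlib.crc32(self.symbol.encode()) % 900000 + 100000
            object.__setattr__(self, "transcript", f"NM_{stable}.1")


@dataclass(frozen=True)
class AnalystSpec:
    """share: fraction of cases assigned; vus_reporting_propensity
    multiplies the baseline probability that an assigned case ends up a
    VUS case (mass is exchanged with the unsolved category)."""

    analyst_id: str
    share: float
    vus_reporting_propensity: float = 1.0

    def __post_init__(self):
        if self.share <= 0 or self.vus_reporting_propensity <= 0:
            raise ConfigurationError(
                f"analyst {self.analyst_id}: share and propensity must be > 0"
            )


@dataclass(frozen=True)
class PanelSpec:
    panel_id: str
    gene_count: int
    weight: float = 1.0


def _check_probs(name: str, probs: dict, keys=None) -> None:
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ConfigurationError(f"{name} has negative probabilities")
    if keys is not None and set(probs) - set(keys):
        raise ConfigurationError(f"{name} has unknown keys {set(probs) - set(keys)}")


@dataclass
class SimConfig:
    """Full specification of a simulated cohort; see
    :func:`calibrated_config` for the calibrated defaults."""

    n_cases: int
    sub_cohort_fraction_ird: float
    #: per-sub-cohort distribution over the four diagnostic statuses
    diagnostic_status_probs: dict[str, dict[str, float]]
    #: P(inheritance | diagnostic status)
    inheritance_probs: dict[str, dict[str, float]]
    gene_catalog: list[GeneSpec]
    analyst_catalog: list[AnalystSpec]
    panel_catalog: list[PanelSpec]
    platform_probs: dict[str, float]
    #: class-conditional mixes, keyed "reference" / "vus"
    consequence_probs: dict[str, dict[str, float]]
    region_probs: dict[str, dict[str, float]]
    predictor_consensus_prob: dict[str, float]
    nonmissense_deleterious_prob: dict[str, float]
    predictor_unavailable_prob: float = 0.0
    likely_pathogenic_fraction: float = 0.3
    second_vus_prob_recessive: float = 0.15
    #: fraction of VUS drawn with reference-class features (ground-truth causal)
    causal_vus_fraction: float = 0.0
    #: solved recessive cases carrying a causal VUS in trans / in homozygosis
    in_trans_vus_prob: float = 0.15
    homozygous_vus_prob: float = 0.07
    co_analysis_prob: float = 0.034
    pli_missing_prob: float = 0.02
    ccr_missing_prob: float = 0.05
    disease_labels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "IRD": ("retinitis_pigmentosa", "macular_dystrophy", "cone_rod_dystrophy",
                    "usher_syndrome", "leber_congenital_amaurosis"),
            "non_IRD": ("polymalformative_syndrome", "metabolic_disorder",
                        "encephalopathy_id_epilepsy", "other_rare_disease"),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError("n_cases must be >= 0")
        for frac_name in (
            "sub_cohort_fraction_ird", "predictor_unavailable_prob",
            "likely_pathogenic_fraction", "second_vus_prob_recessive",
            "causal_vus_fraction", "co_analysis_prob",
            "in_trans_vus_prob", "homozygous_vus_prob",
            "pli_missing_prob", "ccr_missing_prob",
        ):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{frac_name}={value} outside [0, 1]")
        if self.in_trans_vus_prob + self.homozygous_vus_prob > 1.0:
            raise ConfigurationError("in_trans + homozygous VUS probabilities exceed 1")
        for sc, probs in self.diagnostic_status_probs.items():
            _check_probs(f"diagnostic_status_probs[{sc}]", probs, _STATUS_ORDER)
        for st, probs in self.inheritance_probs.items():
            _check_probs(f"inheritance_probs[{st}]", probs, _INHERITANCE_ORDER)
        _check_probs("platform_probs", self.platform_probs, ("TSO", "CES"))
        for klass in ("reference", "vus"):
            _check_probs(f"consequence_probs[{klass}]", self.consequence_probs[klass])
            _check_probs(f"region_probs[{klass}]", self.region_probs[klass])
            if not 0.0 <= self.predictor_consensus_prob[klass] <= 1.0:
                raise ConfigurationError("predictor_consensus_prob outside [0, 1]")
            if not 0.0 <= self.nonmissense_deleterious_prob[klass] <= 1.0:
                raise ConfigurationError("nonmissense_deleterious_prob outside [0, 1]")
        _check_probs(
            "analyst shares",
            {a.analyst_id: a.share for a in self.analyst_catalog},
        )
        if not self.gene_catalog or not self.panel_catalog:
            raise ConfigurationError("gene_catalog and panel_catalog must be non-empty")

    # -- derived ground-truth payloads (what the pipeline should recover) --

    def depleted_genes(self) -> frozenset:
        return frozenset(
            g.symbol for g in self.gene_catalog if g.vus_rate_multiplier <= 0.5
        )

    def enriched_genes(self) -> frozenset:
        return frozenset(
            g.symbol for g in self.gene_catalog if g.vus_rate_multiplier >= 2.0
        )

    def conservative_analysts(self) -> frozenset:
        return frozenset(
            a.analyst_id for a in self.analyst_catalog
            if a.vus_reporting_propensity <= 0.5
        )

    def liberal_analysts(self) -> frozenset:
        return frozenset(
            a.analyst_id for a in self.analyst_catalog
            if a.vus_reporting_propensity >= 2.0
        )

    def depleted_consequences(self) -> frozenset:
        ref = self.consequence_probs["reference"]
        vus = self.consequence_probs["vus"]
        return frozenset(
            cq for cq, p_ref in ref.items()
            if p_ref >= 0.05 and vus.get(cq, 0.0) <= p_ref / 3.0
        )


@dataclass
class GroundTruth:
    """What the generator injected, for recovery and sensitivity tests."""

    depleted_genes: frozenset
    enriched_genes: frozenset
    conservative_analysts: frozenset
    liberal_analysts: frozenset
    depleted_consequences: frozenset
    #: (variant_id, case_id) of VUS drawn with reference-class features
    causal_like: frozenset
    #: keys of causal VUS in trans with a pathogenic variant (solved recessive)
    in_trans: frozenset
    #: keys of homozygous causal VUS in solved cases
    homozygous: frozenset


def _rng(seed: int, kind: int, *index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, kind) + index))


def _draw(r: np.random.Generator, probs: dict[str, float], order) -> str:
    keys = [k for k in order if k in probs]
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(r.choice(len(keys), p=p / p.sum()))]


def _gene_probs(catalog, use_multiplier: bool) -> np.ndarray:
    w = np.array(
        [g.weight * (g.vus_rate_multiplier if use_multiplier else 1.0) for g in catalog]
    )
    return w / w.sum()


def generate_cohort(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a cohort and its ground truth; deterministic given
    ``config.seed`` (per-entity substreams)."""
    config.validate()
    genes = config.gene_catalog
    gene_p_ref = _gene_probs(genes, use_multiplier=False)
    gene_p_vus = _gene_probs(genes, use_multiplier=True)
    analysts = config.analyst_catalog
    analyst_shares = np.array([a.share for a in analysts], dtype=float)
    analyst_shares /= analyst_shares.sum()
    panel_w = np.array([p.weight for p in config.panel_catalog], dtype=float)
    panel_w /= panel_w.sum()

    cases: list[CaseRecord] = []
    variants: list[VariantRecord] = []
    causal_keys: set = set()
    in_trans_keys: set = set()
    hom_keys: set = set()

    for i in range(config.n_cases):
        r = _rng(config.seed, _KIND_CASE, i)
        sub = "IRD" if r.random() < config.sub_cohort_fraction_ird else "non_IRD"
        platform = _draw(r, config.platform_probs, ("TSO", "CES"))
        panel = config.panel_catalog[int(r.choice(len(panel_w), p=panel_w))]
        a_idx = int(r.choice(len(analysts), p=analyst_shares))
        analyst_ids = [analysts[a_idx].analyst_id]
        if len(analysts) > 1 and r.random() < config.co_analysis_prob:
            others = [j for j in range(len(analysts)) if j != a_idx]
            other_p = analyst_shares[others] / analyst_shares[others].sum()
            analyst_ids.append(analysts[int(np.asarray(others)[r.choice(len(others), p=other_p)])].analyst_id)
        propensity = float(
            np.mean([
                a.vus_reporting_propensity
                for a in analysts if a.analyst_id in analyst_ids
            ])
        )
        base = dict(config.diagnostic_status_probs[sub])
        p_vus_adj = min(base["vus_case"] * propensity,
                        base["vus_case"] + base["unsolved"])
        base["unsolved"] += base["vus_case"] - p_vus_adj
        base["vus_case"] = p_vus_adj
        status = _draw(r, base, _STATUS_ORDER)
        inheritance = _draw(r, config.inheritance_probs[status], _INHERITANCE_ORDER)
        labels = config.disease_labels.get(sub, ("unspecified",))
        disease = labels[int(r.integers(0, len(labels)))]
        case_id = f"case_{i:05d}"
        cases.append(
            CaseRecord(
                case_id=case_id,
                sub_cohort=sub,
                diagnostic_status=status,
                inheritance=inheritance,
                platform=platform,
                panel_id=panel.panel_id,
                panel_gene_count=panel.gene_count,
                analyst_ids=tuple(analyst_ids),
                disease_label=disease,
            )
        )

        # ---- variant plan for this case -------------------------------
        # (classification, dist_class, zygosity_hint, tag) per slot
        plan: list[tuple[str, str, str | None, str | None]] = []
        if status == "solved":
            if inheritance == "recessive":
                u = r.random()
                if u < config.in_trans_vus_prob:
                    plan = [("reference", "reference", "het", None),
                            ("vus", "reference", "het", "in_trans")]
                elif u < config.in_trans_vus_prob + config.homozygous_vus_prob:
                    plan = [("vus", "reference", "hom", "homozygous")]
                else:
                    plan = [("reference", "reference", "het", None),
                            ("reference", "reference", "het", None)]
            else:
                plan = [("reference", "reference", None, None)]
        elif status == "partially_solved":
            plan = [("reference", "reference", "het", None)]
        elif status == "vus_case":
            n_vus = 1
            if inheritance == "recessive" and r.random() < config.second_vus_prob_recessive:
                n_vus = 2
            for _ in range(n_vus):
                causal = r.random() < config.causal_vus_fraction
                plan.append(("vus", "reference" if causal else "vus", None,
                             "causal" if causal else None))

        # recessive multi-variant cases share one gene (in-trans biology)
        shared_gene_idx: int | None = None
        if inheritance == "recessive" and len(plan) == 2:
            p = gene_p_vus if all(cl == "vus" for cl, *_ in plan) else gene_p_ref
            shared_gene_idx = int(r.choice(len(genes), p=p))

        used_ids: set[str] = set()
        for j, (klass, dist_class, zyg_hint, tag) in enumerate(plan):
            rv = _rng(config.seed, _KIND_VARIANT, i, j)
            gene_idx = shared_gene_idx
            if gene_idx is None:
                p = gene_p_vus if dist_class == "vus" else gene_p_ref
                gene_idx = int(rv.choice(len(genes), p=p))
            gene = genes[gene_idx]
            consequence = _draw(
                rv, config.consequence_probs[dist_class],
                sorted(config.consequence_probs[dist_class]),
            )
            region = _draw(
                rv, config.region_probs[dist_class],
                sorted(config.region_probs[dist_class]),
            )
            if zyg_hint is not None:
                zygosity = zyg_hint
            elif inheritance == "x_linked":
                zygosity = "hemi"
            elif inheritance == "recessive" and len(plan) == 1 and klass != "vus":
                zygosity = "hom"
            else:
                zygosity = "het"
            profile = _sample_profile(rv, consequence, dist_class, config)
            if klass == "reference":
                classification = (
                    "likely_pathogenic"
                    if rv.random() < config.likely_pathogenic_fraction
                    else "pathogenic"
                )
            else:
                classification = "vus"
            for _attempt in range(20):
                pos = int(rv.integers(1, gene.coding_length + 1))
                ref_b, alt_b = rv.choice(4, size=2, replace=False)
                vid = f"{gene.transcript}:c.{pos}{_BASES[ref_b]}>{_BASES[alt_b]}"
                if vid not in used_ids:
                    break
            used_ids.add(vid)
            ccr = (
                None if rv.random() < config.ccr_missing_prob
                else round(float(rv.uniform(0.0, 100.0)), 2)
            )
            pli = None if rv.random() < config.pli_missing_prob else gene.pli
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    case_id=case_id,
                    gene_symbol=gene.symbol,
                    classification=classification,
                    consequence=consequence,
                    genomic_region=region,
                    zygosity=zygosity,
                    predictor_profile=profile,
                    gene_pli=pli,
                    ccr_percentile=ccr,
                    gene_coding_length=gene.coding_length,
                )
            )
            key = (variants[-1].variant_id, case_id)
            if tag == "causal":
                causal_keys.add(key)
            elif tag == "in_trans":
                causal_keys.add(key)
                in_trans_keys.add(key)
            elif tag == "homozygous":
                causal_keys.add(key)
                hom_keys.add(key)

    cohort = CohortTable(
        cases=cases,
        variants=variants,
        provenance={"generator": "vusrules.simulate", "seed": config.seed,
                    "n_cases": config.n_cases},
    )
    truth = GroundTruth(
        depleted_genes=config.depleted_genes(),
        enriched_genes=config.enriched_genes(),
        conservative_analysts=config.conservative_analysts(),
        liberal_analysts=config.liberal_analysts(),
        depleted_consequences=config.depleted_consequences(),
        causal_like=frozenset(causal_keys),
        in_trans=frozenset(in_trans_keys),
        homozygous=frozenset(hom_keys),
    )
    return cohort, truth


def _sample_profile(
    rv: np.random.Generator, consequence: str, dist_class: str, config: SimConfig
) -> PredictorProfile:
    """Missense: full 5/5 consensus with the class-conditional probability,
    otherwise 0-4 deleterious calls; non-missense: the two missense-only
    predictors are unavailable, the rest deleterious with a class rate."""
    if consequence == "missense":
        if rv.random() < config.predictor_consensus_prob[dist_class]:
            calls = ["deleterious"] * 5
        else:
            k = int(rv.integers(0, 5))
            order = rv.permutation(5)
            calls = ["tolerated"] * 5
            for slot in order[:k]:
                calls[int(slot)] = "deleterious"
        if config.predictor_unavailable_prob > 0:
            for idx in range(5):
                if rv.random() < config.predictor_unavailable_prob:
                    calls[idx] = "unavailable"
    else:
        p_del = config.nonmissense_deleterious_prob[dist_class]
        calls = []
        for predictor in ("sift", "polyphen", "mcap", "mutationassessor", "mutationtaster"):
            if predictor in ("mcap", "mutationassessor"):  # missense-only tools
                calls.append("unavailable")
            else:
                calls.append("deleterious" if rv.random() < p_del else "tolerated")
    return PredictorProfile(tuple(calls))


def calibrated_config(n_cases: int = 1937, seed: int = 0) -> SimConfig:
    """Calibrated default configuration.

    Marginals mirror a 1937-case rare-disease service cohort with a
    ~34.5% inherited-retinal-dystrophy share: VUS are 84% missense vs
    46.6% in the pathogenic/likely-pathogenic reference set; full
    predictor consensus rates are 0.58 (reference) vs 0.305 (VUS);
    exonic fractions 92% (VUS) vs 82% (reference); one strongly
    VUS-depleted high-volume gene (ABCA4-like, multiplier 0.05), one
    small VUS-only-like gene (IMPG2-like, multiplier 40); five analysts
    with one liberal (A2-like, x1.9) and two strongly conservative
    (B1/B2-like, x0.2) VUS-reporting propensities.
    """
    genes = [
        # symbol, coding_length, pli, weight, multiplier
        ("ABCA4", 6822, 0.00, 0.170, 0.05),
        ("USH2A", 15606, 0.00, 0.130, 1.0),
        ("CRB1", 4221, 0.00, 0.050, 1.0),
        ("RPGR", 3459, 0.86, 0.050, 1.0),
        ("EYS", 9432, 0.00, 0.050, 1.0),
        ("RHO", 1047, 0.67, 0.040, 1.0),
        ("PRPH2", 1041, 0.56, 0.040, 1.0),
        ("CEP290", 7440, 0.00, 0.040, 1.0),
        ("MYO7A", 6648, 0.00, 0.040, 1.0),
        ("PCDH15", 5865, 0.00, 0.040, 1.0),
        ("RP1", 6471, 0.00, 0.035, 1.0),
        ("PDE6B", 2565, 0.01, 0.030, 1.0),
        ("CNGB3", 2430, 0.00, 0.030, 1.0),
        ("BEST1", 1758, 0.05, 0.030, 1.0),
        ("GUCY2D", 3312, 0.01, 0.030, 1.0),
        ("CHM", 1962, 0.92, 0.025, 1.0),
        ("RPE65", 1602, 0.00, 0.025, 1.0),
        ("PRPF31", 1500, 0.97, 0.025, 1.0),
        ("NR2E3", 1233, 0.03, 0.020, 1.0),
        ("CRX", 900, 0.63, 0.020, 1.0),
        ("RDH12", 951, 0.00, 0.020, 1.0),
        ("TULP1", 1626, 0.00, 0.020, 1.0),
        ("CNGA3", 2085, 0.00, 0.020, 1.0),
        ("CACNA1F", 5934, 0.94, 0.017, 1.0),
        ("IMPG2", 3771, 0.00, 0.003, 40.0),
    ]
    panels = [
        ("panel_05g", 5, 0.02), ("panel_12g", 12, 0.03), ("panel_25g", 25, 0.04),
        ("panel_31g", 31, 0.05), ("panel_45g", 45, 0.06), ("panel_60g", 60, 0.06),
        ("panel_76g", 76, 0.07), ("panel_92g", 92, 0.07),
        ("panel_106g_syndromic", 106, 0.20), ("panel_136g_nonsyndromic", 136, 0.25),
        ("panel_180g", 180, 0.05), ("panel_237g_retnet", 237, 0.10),
    ]
    return SimConfig(
        n_cases=n_cases,
        seed=seed,
        sub_cohort_fraction_ird=668 / 1937,
        diagnostic_status_probs={
            "IRD": {"solved": 0.40, "partially_solved": 0.075,
                    "vus_case": 0.175, "unsolved": 0.35},
            "non_IRD": {"solved": 0.22, "partially_solved": 0.04,
                        "vus_case": 0.165, "unsolved": 0.575},
        },
        inheritance_probs={
            "solved": {"dominant": 0.22, "recessive": 0.62,
                       "x_linked": 0.08, "unknown": 0.08},
            "partially_solved": {"recessive": 1.0},
            "vus_case": {"dominant": 0.40, "recessive": 0.50,
                         "x_linked": 0.04, "unknown": 0.06},
            "unsolved": {"dominant": 0.25, "recessive": 0.55,
                         "x_linked": 0.05, "unknown": 0.15},
        },
        gene_catalog=[
            GeneSpec(symbol=s, coding_length=ln, pli=pli, weight=w,
                     vus_rate_multiplier=m)
            for s, ln, pli, w, m in genes
        ],
        analyst_catalog=[
            AnalystSpec("A1", 0.26, 1.0),
            AnalystSpec("A2", 0.26, 1.9),
            AnalystSpec("B1", 0.17, 0.2),
            AnalystSpec("B2", 0.17, 0.2),
            AnalystSpec("C", 0.14, 1.0),
        ],
        panel_catalog=[PanelSpec(pid, n, w) for pid, n, w in panels],
        platform_probs={"TSO": 0.358, "CES": 0.642},
        consequence_probs={
            "reference": {
                "missense": 0.466, "frameshift": 0.200, "stop_gain": 0.130,
                "splice_region": 0.105, "inframe_indel": 0.040,
                "synonymous": 0.004, "start_loss": 0.015, "stop_loss": 0.010,
                "other": 0.030,
            },
            "vus": {
                "missense": 0.840, "frameshift": 0.012, "stop_gain": 0.018,
                "splice_region": 0.050, "inframe_indel": 0.040,
                "synonymous": 0.010, "start_loss": 0.005, "stop_loss": 0.005,
                "other": 0.020,
            },
        },
        region_probs={
            "reference": {"exonic": 0.820, "splicing": 0.168, "utr5": 0.004,
                          "utr3": 0.004, "intronic": 0.004},
            "vus": {"exonic": 0.920, "splicing": 0.079, "utr3": 0.001},
        },
        predictor_consensus_prob={"reference": 0.58, "vus": 0.305},
        nonmissense_deleterious_prob={"reference": 0.85, "vus": 0.55},
    )


def null_config(n_cases: int = 1937, seed: int = 0) -> SimConfig:
    """The calibrated config with every injected signal switched off:
    all gene multipliers and analyst propensities 1, identical
    class-conditional mixes. Used for type-I / null-calibration checks."""
    cfg = calibrated_config(n_cases=n_cases, seed=seed)
    cfg.gene_catalog = [replace(g, vus_rate_multiplier=1.0) for g in cfg.gene_catalog]
    cfg.analyst_catalog = [
        replace(a, vus_reporting_propensity=1.0) for a in cfg.analyst_catalog
    ]
    cfg.consequence_probs = {
        "reference": dict(cfg.consequence_probs["reference"]),
        "vus": dict(cfg.consequence_probs["reference"]),
    }
    cfg.region_probs = {
        "reference": dict(cfg.region_probs["reference"]),
        "vus": dict(cfg.region_probs["reference"]),
    }
    cfg.predictor_consensus_prob = {"reference": 0.58, "vus": 0.58}
    cfg.nonmissense_deleterious_prob = {"reference": 0.85, "vus": 0.85}
    return cfg


def labeled_sets_from_truth(
    cohort: CohortTable, truth: GroundTruth
) -> dict[str, LabeledVariantSet]:
    """Build the benchmark sets the generator planted: causal VUS in trans
    with a pathogenic variant, and homozygous causal VUS in solved cases.
    Sets that happen to be empty for a given seed are omitted."""
    out: dict[str, LabeledVariantSet] = {}
    for name, keys in (
        ("in_trans_recessive", truth.in_trans),
        ("homozygous_solved", truth.homozygous),
    ):
        records = [
            LabeledVariant(variant=v, case=cohort.case_by_id(v.case_id),
                           label="assumed_causal")
            for v in cohort.variants if (v.variant_id, v.case_id) in keys
        ]
        if records:
            out[name] = LabeledVariantSet(set_name=name, records=records)
    return out


def sim_config_to_dict(config: SimConfig) -> dict:
    """Flat structured-text form of a SimConfig (YAML/JSON friendly)."""
    return {
        "n_cases": config.n_cases,
        "seed": config.seed,
        "sub_cohort_fraction_ird": config.sub_cohort_fraction_ird,
        "diagnostic_status_probs": {k: dict(v) for k, v in config.diagnostic_status_probs.items()},
        "inheritance_probs": {k: dict(v) for k, v in config.inheritance_probs.items()},
        "gene_catalog": [
            {"symbol": g.symbol, "coding_length": g.coding_length, "pli": g.pli,
             "weight": g.weight, "vus_rate_multiplier": g.vus_rate_multiplier,
             "transcript": g.transcript}
            for g in config.gene_catalog
        ],
        "analyst_catalog": [
            {"analyst_id": a.analyst_id, "share": a.share,
             "vus_reporting_propensity": a.vus_reporting_propensity}
            for a in config.analyst_catalog
        ],
        "panel_catalog": [
            {"panel_id": p.panel_id, "gene_count": p.gene_count, "weight": p.weight}
            for p in config.panel_catalog
        ],
        "platform_probs": dict(config.platform_probs),
        "consequence_probs": {k: dict(v) for k, v in config.consequence_probs.items()},
        "region_probs": {k: dict(v) for k, v in config.region_probs.items()},
        "predictor_consensus_prob": dict(config.predictor_consensus_prob),
        "nonmissense_deleterious_prob": dict(config.nonmissense_deleterious_prob),
        "predictor_unavailable_prob": config.predictor_unavailable_prob,
        "likely_pathogenic_fraction": config.likely_pathogenic_fraction,
        "second_vus_prob_recessive": config.second_vus_prob_recessive,
        "causal_vus_fraction": config.causal_vus_fraction,
        "in_trans_vus_prob": config.in_trans_vus_prob,
        "homozygous_vus_prob": config.homozygous_vus_prob,
        "co_analysis_prob": config.co_analysis_prob,
        "pli_missing_prob": config.pli_missing_prob,
        "ccr_missing_prob": config.ccr_missing_prob,
        "disease_labels": {k: list(v) for k, v in config.disease_labels.items()},
    }


def sim_config_from_dict(payload: dict) -> SimConfig:
    payload = dict(payload)
    payload["gene_catalog"] = [GeneSpec(**g) for g in payload["gene_catalog"]]
    payload["analyst_catalog"] = [AnalystSpec(**a) for a in payload["analyst_catalog"]]
    payload["panel_catalog"] = [PanelSpec(**p) for p in payload["panel_catalog"]]
    if "disease_labels" in payload:
        payload["disease_labels"] = {
            k: tuple(v) for k, v in payload["disease_labels"].items()
        }
    cfg = SimConfig(**payload)
    cfg.validate()
    return cfg


def expected_hit_probability(config: SimConfig) -> float:
    """Analytic lower bound on the probability that a causal-like VUS hits
    at least one rule, assuming the true payloads are recovered.

    Uses the gene, consequence and predictor rules only (the analyst
    rule depends on case assignment and only adds hits, so the bound is
    conservative). All three features are drawn independently by
    construction.
    """
    gene_p = _gene_probs(config.gene_catalog, use_multiplier=False)
    p_gene = sum(
        p for g, p in zip(config.gene_catalog, gene_p)
        if g.symbol in config.depleted_genes()
    )
    ref_cons = config.consequence_probs["reference"]
    p_cons = sum(ref_cons.get(cq, 0.0) for cq in config.depleted_consequences())
    p_pred = (
        ref_cons.get("missense", 0.0)
        * config.predictor_consensus_prob["reference"]
        * (1.0 - config.predictor_unavailable_prob) ** 5
    )
    return 1.0 - (1.0 - p_gene) * (1.0 - p_cons) * (1.0 - p_pred)
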