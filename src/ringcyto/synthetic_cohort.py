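"""Seeded synthetic cohorts of ring-chromosome karyotypes, variant tables and FISH patterns.

The generator emulates the statistical structure of a hospital ring-chromosome
(RC) cohort in hematological malignancies: mosaic multi-clone ISCN karyotypes
in which every patient carries at least one ring, a configurable
complex-karyotype fraction, ring-origin distribution, marker-chromosome and
double-minute rates, per-chromosome structural involvement, TP53/TET2/NRAS
mutation rates, and TP53-mutation/17p-copy-number-loss co-occurrence. Default
parameter values are the observed frequencies in myeloid RC cohorts (90%
complex, 17.3% of complex patients with multiple rings, 89% of rings of
unknown origin, 63% markers, ~72% of sequenced complex patients TP53-mutant,
54% of those with cytogenetic TP53 copy-number loss).

Alongside the patient records the generator emits a *truth ledger* recording,
per patient, the intended feature values (complexity class, ring inventory,
marker/dmin flags, mutated genes, CNL mechanism). Generation is noiseless, so
a correct pipeline recovers the ledger exactly; :func:`ledger_recovery_report`
performs that comparison.

Two bookkeeping constraints keep the ledger noiseless by construction:
chromosome-17 structural events are injected only by the CNL-mechanism
sampler (random filler events avoid chromosome 17), and TP53 mutations are
assigned only to complex-karyotype patients, mirroring the observation that
non-complex RC patients lack them.

Each patient draws from an independent random stream keyed on
``(seed, patient_index)``, so growing a cohort never reshuffles existing
patients.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cytostats import ComplexityClass, classify_complexity
from .iscn_core import parse_karyotype, serialize_karyotype
from .variant_integration import PatientRecord, VariantCall

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "ledger_recovery_report",
    "DEFAULT_RING_ORIGIN_DISTRIBUTION",
    "DEFAULT_STRUCTURAL_WEIGHTS",
    "DEFAULT_CNL_MECHANISM_DISTRIBUTION",
]


# Ring origins: ~89% of rings in myeloid RC cohorts cannot be assigned to a
# chromosome; the mapped remainder clusters on a handful of chromosomes.
DEFAULT_RING_ORIGIN_DISTRIBUTION: Dict[str, float] = {
    "unknown": 0.889,
    "7": 0.033,
    "6": 0.033,
    "3": 0.022,
    "2": 0.011,
    "18": 0.012,
}

# Relative weights for which chromosome a random structural event hits.
# Chromosome 17 is deliberately absent: 17 events enter only through the
# CNL-mechanism sampler so the truth ledger stays noiseless.
DEFAULT_STRUCTURAL_WEIGHTS: Dict[str, float] = {
    **{str(i): 0.10 for i in list(range(1, 17)) + list(range(18, 23))},
    "X": 0.05,
    "11": 0.57,
    "18": 0.44,
    "7": 0.44,
    "5": 0.40,
    "3": 0.20,
    "8": 0.20,
    "12": 0.20,
    "22": 0.20,
    "2": 0.15,
    "20": 0.15,
    "21": 0.15,
}

# Mechanism mix among TP53-CNL patients: monosomy 17 dominates, then
# add(17p), derivative 17, dicentric 17, 17p-, isochromosome 17q.
DEFAULT_CNL_MECHANISM_DISTRIBUTION: Dict[str, float] = {
    "monosomy17": 0.57,
    "add17p": 0.19,
    "der17": 0.095,
    "dic17": 0.048,
    "del17p": 0.05,
    "i17q": 0.047,
}

# Approximate highest major band per arm, used to draw plausible breakpoints.
_MAX_BAND: Dict[str, Tuple[int, int]] = {
    "1": (36, 44), "2": (25, 37), "3": (26, 29), "4": (16, 35), "5": (15, 35),
    "6": (25, 27), "7": (22, 36), "8": (23, 24), "9": (24, 34), "10": (15, 26),
    "11": (15, 25), "12": (13, 24), "13": (13, 34), "14": (13, 32), "15": (13, 26),
    "16": (13, 24), "17": (13, 25), "18": (11, 23), "19": (13, 13), "20": (13, 13),
    "21": (13, 22), "22": (13, 13), "X": (22, 28), "Y": (11, 12),
}

_MYELOID_DIAGNOSES = (("AML", 0.522), ("MDS", 0.411), ("CMML->AML", 0.033),
                      ("CML->AML", 0.022), ("CML", 0.011))
_LYMPHOID_DIAGNOSES = (("MM", 0.625), ("ALL", 0.25), ("CLL", 0.125))

_TP53_HOTSPOTS = (
    ("g.7577538C>T", "p.R248W"),
    ("g.7577539G>A", "p.R248Q"),
    ("g.7577539G>C", "p.R248G"),
    ("g.7578190T>C", "p.Y220C"),
    ("g.7577120C>T", "p.R273H"),
    ("g.7577120C>A", "p.R273L"),
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GENE_G_BASE = {"TP53": 7_571_000, "TET2": 106_100_000, "NRAS": 115_250_000,
                "DNMT3A": 25_450_000, "IDH1": 209_100_000, "KRAS": 25_360_000,
                "ASXL1": 31_000_000, "SF3B1": 198_250_000, "CEBPA": 33_790_000}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation parameters; defaults follow observed RC-cohort rates."""

    n_patients: int = 90
    seed: int = 0
    complex_fraction: float = 0.90
    exactly_three_given_noncomplex: float = 5 / 9
    multiple_rc_fraction: float = 0.173  # of complex patients
    ring_origin_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RING_ORIGIN_DISTRIBUTION)
    )
    marker_given_complex: float = 0.63
    dmin_given_complex: float = 0.022
    per_chromosome_structural_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_WEIGHTS)
    )
    ngs_fraction: float = 0.644
    tp53_mutation_rate: float = 0.72   # of sequenced complex patients
    tet2_rate: float = 0.138
    nras_rate: float = 0.121
    tet2_given_noncomplex: float = 0.75
    two_tp53_fraction: float = 0.36    # of TP53-mutant patients
    cnl_given_tp53: float = 0.54
    cnl_mechanism_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CNL_MECHANISM_DISTRIBUTION)
    )
    lymphoid_fraction: float = 0.082
    fish_fraction: float = 0.5  # of patients with a 17p add/ambiguity, get FISH

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = {
            "complex_fraction": self.complex_fraction,
            "exactly_three_given_noncomplex": self.exactly_three_given_noncomplex,
            "multiple_rc_fraction": self.multiple_rc_fraction,
            "marker_given_complex": self.marker_given_complex,
            "dmin_given_complex": self.dmin_given_complex,
            "ngs_fraction": self.ngs_fraction,
            "tp53_mutation_rate": self.tp53_mutation_rate,
            "tet2_rate": self.tet2_rate,
            "nras_rate": self.nras_rate,
            "tet2_given_noncomplex": self.tet2_given_noncomplex,
            "two_tp53_fraction": self.two_tp53_fraction,
            "cnl_given_tp53": self.cnl_given_tp53,
            "lymphoid_fraction": self.lymphoid_fraction,
            "fish_fraction": self.fish_fraction,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        total = sum(self.ring_origin_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"ring_origin_distribution must sum to 1, sums to {total}")
        if any(p < 0 for p in self.ring_origin_distribution.values()):
            raise ValueError("ring_origin_distribution probabilities must be >= 0")


def _choice(rng: np.random.Generator, options: Sequence[str], weights: Sequence[float]) -> str:
    w = np.asarray(weights, dtype=float)
    return str(options[rng.choice(len(options), p=w / w.sum())])


def _band(rng: np.random.Generator, chrom: str, arm: str) -> str:
    p_max, q_max = _MAX_BAND[chrom]
    major = int(rng.integers(1, (p_max if arm == "p" else q_max) + 1))
    if rng.random() < 0.35:
        return f"{major}.{int(rng.integers(1, 4))}"
    return str(major)


def _ring_token(rng: np.random.Generator, origin: str) -> str:
    if origin == "unknown":
        return "+r"
    return f"r({origin})(p{_band(rng, origin, 'p')}q{_band(rng, origin, 'q')})"


def _cnl_token(rng: np.random.Generator, mechanism: str) -> str:
    proximal_p = ("11.1", "11.2", "12", "13")  # at or proximal to 17p13.1
    partner = _choice(rng, [c for c in _MAX_BAND if c not in ("17", "Y")],
                      [1.0] * (len(_MAX_BAND) - 2))
    if mechanism == "monosomy17":
        return "-17"
    if mechanism == "add17p":
        return f"add(17)(p{_choice(rng, proximal_p, [1, 1, 1, 1])})"
    if mechanism == "del17p":
        return f"del(17)(p{_choice(rng, proximal_p, [1, 1, 1, 1])})"
    if mechanism == "der17":
        return f"der(17)t({partner};17)(q{_band(rng, partner, 'q')};p11.2)"
    if mechanism == "dic17":
        return f"dic({partner};17)(q{_band(rng, partner, 'q')};p11.2)"
    if mechanism == "i17q":
        return "i(17)(q10)"
    if mechanism == "idic17":
        return "idic(17)(p11.2)"
    raise ValueError(f"unknown CNL mechanism: {mechanism}")


_FILLER_KINDS = ("whole_loss", "whole_gain", "del", "add", "t", "inv", "dup")
_FILLER_WEIGHTS = (0.22, 0.14, 0.22, 0.18, 0.12, 0.06, 0.06)


def _filler_token(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    chroms = [c for c in weights if c != "17"]
    w = [weights[c] for c in chroms]
    c = _choice(rng, chroms, w)
    kind = _choice(rng, _FILLER_KINDS, _FILLER_WEIGHTS)
    arm = "p" if rng.random() < 0.35 else "q"
    if kind == "whole_loss":
        return f"-{c}"
    if kind == "whole_gain":
        return f"+{c}"
    if kind == "del":
        return f"del({c})({arm}{_band(rng, c, arm)})"
    if kind == "add":
        return f"add({c})({arm}{_band(rng, c, arm)})"
    if kind == "inv":
        return f"inv({c})(p{_band(rng, c, 'p')}q{_band(rng, c, 'q')})"
    if kind == "dup":
        from .iscn_core import band_distal_key

        b1, b2 = sorted((_band(rng, c, "q"), _band(rng, c, "q")), key=band_distal_key)
        return f"dup({c})(q{b1}q{b2})"
    # translocation with a distinct non-17 partner
    partner = c
    while partner in (c, "17"):
        partner = _choice(rng, chroms, w)
    return (
        f"t({c};{partner})(q{_band(rng, c, 'q')};q{_band(rng, partner, 'q')})"
    )


def _modal_delta(tokens: Sequence[str]) -> int:
    delta = 0
    for t in tokens:
        if t.startswith("+") or t == "+r" or t == "+mar":
            delta += 1
        elif t.startswith("-"):
            delta -= 1
    return delta


def _make_variant(rng: np.random.Generator, gene: str, used: set) -> VariantCall:
    """A QC-passing candidate somatic variant with a synthetic g. identifier."""
    if gene == "TP53" and rng.random() < 0.45:
        g, p = _TP53_HOTSPOTS[int(rng.integers(len(_TP53_HOTSPOTS)))]
        if g not in used:
            used.add(g)
            return _qc_pass(rng, gene, g, p)
    base = _GENE_G_BASE.get(gene, 50_000_000)
    while True:
        pos = base + int(rng.integers(0, 20_000))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        g = f"g.{pos}{ref}>{alt}"
        if g not in used:
            break
    used.add(g)
    u = rng.random()
    if gene == "TP53":
        res = int(rng.integers(94, 293))  # DNA-binding domain residues
    else:
        res = int(rng.integers(1, 800))
    if u < 0.70:
        a, b = rng.choice(list(_AA), size=2, replace=False)
        p = f"p.{a}{res}{b}"
    elif u < 0.76:
        p = f"p.{rng.choice(list(_AA))}{res}*"
    elif u < 0.82:
        p = f"p.{rng.choice(list(_AA))}{res}fs"
    elif u < 0.86:
        return _qc_pass(rng, gene, g, None, hint="intron inclusion")
    else:
        p = f"p.{rng.choice(list(_AA))}{res}del"
    return _qc_pass(rng, gene, g, p)


def _qc_pass(rng, gene, g, p, hint=None) -> VariantCall:
    return VariantCall(
        gene=gene,
        genomic_change=g,
        protein_change=p,
        vaf=float(np.round(rng.uniform(2, 60), 1)),
        alt_reads_fwd=int(rng.integers(10, 100)),
        alt_reads_rev=int(rng.integers(10, 100)),
        mean_qscore=float(np.round(rng.uniform(25, 40), 1)),
        known_cancer_flag=True,
        damaging_flag=True,
        effect_hint=hint,
    )


def _failing_variant(rng: np.random.Generator, used: set) -> VariantCall:
    """Sequencing-noise variant failing exactly one candidate-somatic criterion."""
    gene = _choice(rng, ["TP53", "TET2", "NRAS", "KRAS", "ASXL1"], [1, 1, 1, 1, 1])
    v = _make_variant(rng, gene, used)
    mode = int(rng.integers(4))
    if mode == 0:
        return VariantCall(**{**asdict(v), "vaf": float(np.round(rng.uniform(0.05, 0.95), 2))})
    if mode == 1:
        return VariantCall(**{**asdict(v), "alt_reads_rev": int(rng.integers(0, 2))})
    if mode == 2:
        return VariantCall(**{**asdict(v), "mean_qscore": float(np.round(rng.uniform(2, 10), 1))})
    return VariantCall(**{**asdict(v), "known_cancer_flag": False})


def _generate_patient(cfg: GeneratorConfig, idx: int) -> Tuple[PatientRecord, dict]:
    rng = np.random.default_rng([cfg.seed, idx])
    pid = f"P{idx + 1:04d}"
    sex = "XX" if rng.random() < 0.5 else "XY"

    lymphoid = rng.random() < cfg.lymphoid_fraction
    dx_pool = _LYMPHOID_DIAGNOSES if lymphoid else _MYELOID_DIAGNOSES
    diagnosis = _choice(rng, [d for d, _ in dx_pool], [w for _, w in dx_pool])

    if lymphoid:
        cls = ComplexityClass.complex
    elif rng.random() < cfg.complex_fraction:
        cls = ComplexityClass.complex
    elif rng.random() < cfg.exactly_three_given_noncomplex:
        cls = ComplexityClass.exactly_three
    else:
        cls = ComplexityClass.simple
    is_complex = cls is ComplexityClass.complex

    # --- rings -----------------------------------------------------------
    origins = list(cfg.ring_origin_distribution)
    oweights = [cfg.ring_origin_distribution[o] for o in origins]
    ring_origins: List[str] = ["unknown" if lymphoid else _choice(rng, origins, oweights)]
    if is_complex and not lymphoid and rng.random() < cfg.multiple_rc_fraction:
        ring_origins.append(_choice(rng, origins, oweights))
    ring_tokens = [_ring_token(rng, o) for o in ring_origins]

    # --- NGS availability and gene mutations -----------------------------
    has_ngs = rng.random() < cfg.ngs_fraction
    genes: List[str] = []
    tp53_mut = False
    if has_ngs:
        if is_complex and rng.random() < cfg.tp53_mutation_rate:
            tp53_mut = True
            genes.append("TP53")
        tet2_p = cfg.tet2_rate if is_complex else cfg.tet2_given_noncomplex
        if rng.random() < tet2_p:
            genes.append("TET2")
        if rng.random() < cfg.nras_rate:
            genes.append("NRAS")
        if not genes and not is_complex:
            genes.append("IDH1")  # non-complex fallback: the shared IDH1 hotspot
        elif rng.random() < 0.12:
            genes.append(_choice(rng, ["DNMT3A", "KRAS", "ASXL1", "SF3B1", "CEBPA"],
                                 [1, 1, 1, 1, 1]))

    # --- TP53 CNL mechanism ----------------------------------------------
    cnl_mech: Optional[str] = None
    if tp53_mut and rng.random() < cfg.cnl_given_tp53:
        mechs = list(cfg.cnl_mechanism_distribution)
        cnl_mech = _choice(rng, mechs, [cfg.cnl_mechanism_distribution[m] for m in mechs])

    # --- assemble the distinct event set ---------------------------------
    tokens: List[str] = list(ring_tokens)
    distinct: Dict[str, None] = {t: None for t in tokens}
    has_marker = is_complex and rng.random() < cfg.marker_given_complex
    if has_marker:
        tokens.append("+mar")
        distinct["+mar"] = None
    has_dmin = is_complex and rng.random() < cfg.dmin_given_complex
    if has_dmin:
        tokens.append("dmin")
        distinct["dmin"] = None
    if cnl_mech is not None:
        t = _cnl_token(rng, cnl_mech)
        tokens.append(t)
        distinct[t] = None

    if is_complex:
        n_target = max(int(rng.integers(4, 13)), len(distinct))
    elif cls is ComplexityClass.exactly_three:
        n_target = 3
    else:
        n_target = 2
    guard = 0
    while len(distinct) < n_target:
        t = _filler_token(rng, cfg.per_chromosome_structural_rates)
        guard += 1
        if guard > 500:
            raise RuntimeError("filler sampling failed to produce distinct events")
        if t in distinct:
            continue
        tokens.append(t)
        distinct[t] = None

    # --- clone structure ---------------------------------------------------
    n_events = len(distinct)
    stem_tokens = tokens
    sub_token: Optional[str] = None
    if is_complex and n_events >= 5 and rng.random() < 0.35:
        sub_token = tokens[-1]
        stem_tokens = tokens[:-1]
    clauses = []
    stem_modal = 46 + _modal_delta(stem_tokens)
    stem_cells = int(rng.integers(3, 21))
    clauses.append(f"{stem_modal},{sex},{','.join(stem_tokens)}[{stem_cells}]")
    if sub_token is not None:
        sub_modal = stem_modal + _modal_delta([sub_token])
        clauses.append(f"{sub_modal},{sex},idem,{sub_token}[{int(rng.integers(2, 10))}]")
    if rng.random() < 0.6:
        clauses.append(f"46,{sex}[{int(rng.integers(2, 16))}]")
    karyotype = parse_karyotype("/".join(clauses))
    text = serialize_karyotype(karyotype, sort=True)
    karyotype = parse_karyotype(text)

    # --- variant table -----------------------------------------------------
    variants: Optional[Tuple[VariantCall, ...]] = None
    kept_ledger: Optional[List[dict]] = None
    if has_ngs:
        used: set = set()
        vlist: List[VariantCall] = []
        for gene in genes:
            n_var = 1
            if gene == "TP53" and rng.random() < cfg.two_tp53_fraction:
                n_var = 2
            elif gene == "TET2" and not is_complex and rng.random() < 0.67:
                n_var = 2
            for _ in range(n_var):
                vlist.append(_make_variant(rng, gene, used))
        kept_ledger = [
            {"gene": v.gene, "genomic_change": v.genomic_change,
             "protein_change": v.protein_change}
            for v in vlist
        ]
        if rng.random() < 0.35:
            vlist.append(_failing_variant(rng, used))
        order = rng.permutation(len(vlist))
        variants = tuple(vlist[i] for i in order)

    # --- FISH --------------------------------------------------------------
    fish: Optional[Tuple[str, ...]] = None
    if cnl_mech is not None and rng.random() < cfg.fish_fraction:
        fish = ("1R1G",) if cnl_mech == "monosomy17" else ("1R2G",)
    elif cnl_mech is None and tp53_mut and rng.random() < 0.1:
        fish = ("2R2G",)

    record = PatientRecord(
        patient_id=pid,
        diagnosis=diagnosis,
        karyotype=karyotype,
        variants=variants,
        fish_patterns=fish,
    )
    ledger = {
        "patient_id": pid,
        "diagnosis": diagnosis,
        "lymphoid": lymphoid,
        "karyotype": text,
        "n_independent_abnormalities": n_events,
        "complexity_class": classify_complexity(n_events).value,
        "n_rings": len(ring_origins),
        "ring_origins": dict(Counter(ring_origins)),
        "has_marker": has_marker,
        "has_dmin": has_dmin,
        "has_ngs": has_ngs,
        "genes": sorted(set(genes)) if has_ngs else None,
        "kept_variants": kept_ledger,
        "n_tp53_distinct": (
            len({v["genomic_change"] for v in kept_ledger if v["gene"] == "TP53"})
            if kept_ledger is not None
            else 0
        ),
        "cnl_status": "loss" if cnl_mech is not None else "no_evidence",
        "cnl_mechanism": cnl_mech if cnl_mech is not None else "none",
        "fish_patterns": list(fish) if fish else None,
    }
    return record, ledger


def generate_cohort(cfg: GeneratorConfig) -> Tuple[List[PatientRecord], List[dict]]:
    """Generate a cohort and its truth ledger; fully reproducible from ``cfg.seed``."""
    records: List[PatientRecord] = []
    ledger: List[dict] = []
    for i in range(cfg.n_patients):
        r, l = _generate_patient(cfg, i)
        records.append(r)
        ledger.append(l)
    return records, ledger


# ---------------------------------------------------------------------------
# Ledger recovery
# ---------------------------------------------------------------------------

_RECOVERED_FEATURES = (
    "n_independent_abnormalities",
    "complexity_class",
    "n_rings",
    "ring_origins",
    "has_marker",
    "has_dmin",
    "cnl_status",
    "cnl_mechanism",
)


def ledger_recovery_report(
    cohort: Sequence[PatientRecord], ledger: Sequence[dict]
) -> dict:
    """Compare pipeline outputs against the generator's truth ledger.

    Generation is noiseless, so every discrete feature (complexity class, ring
    inventory, marker and dmin flags, CNL status and mechanism) must agree
    exactly; each mismatch is reported with the offending karyotype string.
    """
    from .cytostats import compute_features
    from .tp53_cnl import infer_cnl_from_karyotype

    per_feature_total = {f: 0 for f in _RECOVERED_FEATURES}
    per_feature_ok = {f: 0 for f in _RECOVERED_FEATURES}
    mismatches: List[dict] = []
    by_id = {l["patient_id"]: l for l in ledger}
    for p in cohort:
        truth = by_id[p.patient_id]
        feats = compute_features(p.karyotype)
        call = infer_cnl_from_karyotype(p.karyotype)
        got = {
            "n_independent_abnormalities": feats.n_independent_abnormalities,
            "complexity_class": feats.complexity_class.value,
            "n_rings": feats.n_rings,
            "ring_origins": dict(feats.ring_origins),
            "has_marker": feats.has_marker,
            "has_dmin": feats.has_dmin,
            "cnl_status": call.status.value,
            "cnl_mechanism": call.mechanism.value,
        }
        for f in _RECOVERED_FEATURES:
            per_feature_total[f] += 1
            if got[f] == truth[f]:
                per_feature_ok[f] += 1
            else:
                mismatches.append(
                    {
                        "patient_id": p.patient_id,
                        "feature": f,
                        "expected": truth[f],
                        "observed": got[f],
                        "karyotype": truth["karyotype"],
                    }
                )
    agreement = {
        f: (per_feature_ok[f] / per_feature_total[f] if per_feature_total[f] else 1.0)
        for f in _RECOVERED_FEATURES
    }
    return {
        "n_patients": len(cohort),
        "agreement": agreement,
        "all_agree": not mismatches,
        "mismatches": mismatches,
    }
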