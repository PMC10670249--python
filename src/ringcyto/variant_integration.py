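"""Candidate-somatic variant filtering, mutation classification and cohort stratification.

Variants from a targeted cancer-gene panel enter as table rows carrying their
QC fields (variant allele frequency, per-strand alternate read counts, mean
base quality) and two curation flags (known cancer-associated per COSMIC or
ClinVar; damaging per in-silico prediction). A variant is *candidate somatic*
when all criteria hold jointly:

* VAF >= 1%
* >= 2 alternate reads on each strand
* mean alternate-allele base Qscore >= 11
* known cancer-associated AND predicted damaging

Every rejection carries machine-readable reason codes so filter behaviour is
auditable. Genomic coordinates are opaque identifier strings: variants are
deduplicated and matched on the literal ``g.`` string, with no liftover or
re-annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .iscn_core import Karyotype

__all__ = [
    "VariantCall",
    "PatientRecord",
    "MutationType",
    "Tp53Domain",
    "FilterResult",
    "filter_candidate_somatic",
    "filter_with_reasons",
    "classify_mutation_type",
    "tp53_domain_of",
    "TP53_DOMAIN_BOUNDS",
    "stratify_patients",
    "mutation_tally",
    "MutationTally",
    "oncoplot_matrix",
]


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic variant with QC fields and pathogenicity flags."""

    gene: str
    genomic_change: str
    protein_change: Optional[str] = None
    vaf: Optional[float] = None
    alt_reads_fwd: Optional[int] = None
    alt_reads_rev: Optional[int] = None
    mean_qscore: Optional[float] = None
    known_cancer_flag: Optional[bool] = None
    damaging_flag: Optional[bool] = None
    effect_hint: Optional[str] = None  # e.g. "intron inclusion", "splice"

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0 <= self.vaf <= 100):
            raise ValueError(f"VAF must be a percentage in [0, 100], got {self.vaf}")
        for name in ("alt_reads_fwd", "alt_reads_rev"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: diagnosis, karyotype, variant table, optional FISH patterns.

    ``variants=None`` means no NGS data; an empty tuple means sequenced with
    no reported variants. The distinction matters for stratification
    denominators.
    """

    patient_id: str
    diagnosis: str = ""
    karyotype: Optional[Karyotype] = None
    variants: Optional[tuple] = None
    fish_patterns: Optional[tuple] = None

    @property
    def has_ngs(self) -> bool:
        return self.variants is not None


# ---------------------------------------------------------------------------
# Candidate-somatic filter
# ---------------------------------------------------------------------------

MIN_VAF_PERCENT = 1.0
MIN_ALT_READS_PER_STRAND = 2
MIN_MEAN_QSCORE = 11.0


@dataclass(frozen=True)
class FilterResult:
    kept: tuple
    rejected: tuple  # (VariantCall, (reason codes...)) pairs

    def reasons_for(self, v: VariantCall) -> Tuple[str, ...]:
        for var, reasons in self.rejected:
            if var == v:
                return reasons
        return ()


def _rejection_reasons(v: VariantCall) -> List[str]:
    reasons: List[str] = []
    checks = (
        ("vaf", v.vaf, lambda x: x >= MIN_VAF_PERCENT),
        ("strand_fwd", v.alt_reads_fwd, lambda x: x >= MIN_ALT_READS_PER_STRAND),
        ("strand_rev", v.alt_reads_rev, lambda x: x >= MIN_ALT_READS_PER_STRAND),
        ("qscore", v.mean_qscore, lambda x: x >= MIN_MEAN_QSCORE),
        ("not_known_cancer", v.known_cancer_flag, lambda x: bool(x)),
        ("not_damaging", v.damaging_flag, lambda x: bool(x)),
    )
    for code, value, ok in checks:
        if value is None:
            reasons.append(f"missing:{code}")
        elif not ok(value):
            reasons.append(code)
    return reasons


def filter_with_reasons(variants: Iterable[VariantCall]) -> FilterResult:
    """Apply the candidate-somatic criteria, recording why each variant fails.

    The criteria are conjunctive; a variant with any missing QC field is
    rejected with a ``missing:<field>`` reason rather than guessed at.
    """
    kept: List[VariantCall] = []
    rejected: List[Tuple[VariantCall, Tuple[str, ...]]] = []
    for v in variants:
        reasons = _rejection_reasons(v)
        if reasons:
            rejected.append((v, tuple(reasons)))
        else:
            kept.append(v)
    return FilterResult(kept=tuple(kept), rejected=tuple(rejected))


def filter_candidate_somatic(variants: Iterable[VariantCall]) -> List[VariantCall]:
    """Variants passing all candidate-somatic criteria (order preserved)."""
    return list(filter_with_reasons(variants).kept)


# ---------------------------------------------------------------------------
# Mutation-type classification
# ---------------------------------------------------------------------------


class MutationType(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice_or_intron = "splice_or_intron"
    inframe_del = "inframe_del"
    other = "other"


_AA3 = "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val"
_MISSENSE_1 = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_MISSENSE_3 = re.compile(rf"^({_AA3})(\d+)({_AA3})$")
_RESIDUE_RE = re.compile(rf"^(?:[A-Z]|{_AA3})(\d+)")


def classify_mutation_type(v: VariantCall) -> MutationType:
    """Classify a variant from its protein-change string.

    Token rules: ``fs`` → frameshift (even with a downstream ``*``); a terminal
    ``*``/``Ter`` → nonsense; single-residue X→Y substitution → missense;
    ``del`` without ``fs`` → in-frame deletion; an intron/splice effect hint →
    splice_or_intron. Anything unparseable → other.
    """
    hint = (v.effect_hint or "").lower()
    if "intron" in hint or "splic" in hint:
        return MutationType.splice_or_intron
    p = (v.protein_change or "").strip()
    if p.lower().startswith("p."):
        p = p[2:]
    p = p.strip("()")
    if not p:
        return MutationType.other
    low = p.lower()
    if "intron" in low or "splic" in low:
        return MutationType.splice_or_intron
    if "fs" in low:
        return MutationType.frameshift
    if p.endswith("*") or p.endswith("Ter") or low.endswith("x"):
        return MutationType.nonsense
    if "del" in low:
        return MutationType.inframe_del
    if _MISSENSE_1.match(p) or _MISSENSE_3.match(p):
        return MutationType.missense
    return MutationType.other


def protein_residue(v: VariantCall) -> Optional[int]:
    """First affected residue number from the protein-change string, if any."""
    p = (v.protein_change or "").strip()
    if p.lower().startswith("p."):
        p = p[2:]
    m = _RESIDUE_RE.match(p.strip("()"))
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# TP53 protein domains
# ---------------------------------------------------------------------------


class Tp53Domain(str, Enum):
    transactivation = "transactivation"
    proline_rich = "proline_rich"
    dna_binding = "dna_binding"
    nls = "nls"
    tetramerization = "tetramerization"
    regulatory = "regulatory"
    other = "other"


#: Inclusive residue bounds of the canonical 393-aa TP53 domains. The exact
#: boundaries vary by a few residues across the literature; override the table
#: to adopt a different convention.
TP53_DOMAIN_BOUNDS: Dict[Tp53Domain, Tuple[int, int]] = {
    Tp53Domain.transactivation: (1, 61),
    Tp53Domain.proline_rich: (62, 93),
    Tp53Domain.dna_binding: (94, 292),
    Tp53Domain.nls: (293, 322),
    Tp53Domain.tetramerization: (323, 355),
    Tp53Domain.regulatory: (356, 393),
}

TP53_LENGTH = 393


def tp53_domain_of(
    residue: int, bounds: Mapping[Tp53Domain, Tuple[int, int]] = TP53_DOMAIN_BOUNDS
) -> Tp53Domain:
    """Protein domain containing a TP53 residue (1..393)."""
    if not (1 <= residue <= TP53_LENGTH):
        raise ValueError(f"TP53 residue out of range 1..{TP53_LENGTH}: {residue}")
    for domain, (lo, hi) in bounds.items():
        if lo <= residue <= hi:
            return domain
    return Tp53Domain.other


# ---------------------------------------------------------------------------
# Stratification, tallies, oncoplot
# ---------------------------------------------------------------------------


def _kept_variants(p: PatientRecord) -> List[VariantCall]:
    return filter_candidate_somatic(p.variants or ())


def stratify_patients(
    cohort: Sequence[PatientRecord], genes: Sequence[str]
) -> Dict[str, List[PatientRecord]]:
    """Group sequenced patients by mutated gene, plus a no-TP53 group.

    Groups overlap (a patient with NRAS and TP53 variants appears in both);
    each gene group holds each patient at most once. ``"no_TP53"`` collects
    the sequenced patients with zero kept TP53 variants, so with the "TP53"
    group it partitions the NGS-profiled cohort.
    """
    groups: Dict[str, List[PatientRecord]] = {g: [] for g in genes}
    groups.setdefault("TP53", [])
    groups["no_TP53"] = []
    for p in cohort:
        if not p.has_ngs:
            continue
        mutated = {v.gene for v in _kept_variants(p)}
        for g in genes:
            if g in mutated:
                groups[g].append(p)
        if "TP53" in mutated:
            if "TP53" not in genes:
                groups["TP53"].append(p)
        else:
            groups["no_TP53"].append(p)
    return groups


@dataclass(frozen=True)
class MutationTally:
    gene: str
    n_patients_mutated: int
    n_mutations: int
    n_unique: int
    per_type: Mapping[str, int]
    multiplicity_histogram: Mapping[int, int]  # distinct mutations/patient -> patients


def mutation_tally(cohort: Sequence[PatientRecord], gene: str = "TP53") -> MutationTally:
    """Totals for one gene: mutation count, unique count, types, per-patient multiplicity.

    Uniqueness is keyed on the ``g.`` genomic-change string across the cohort;
    within one patient, repeated identical ``g.`` strings count once toward
    both totals and multiplicity.
    """
    total = 0
    unique: set = set()
    per_type: Dict[str, int] = {}
    hist: Dict[int, int] = {}
    n_mutated = 0
    for p in cohort:
        kept = [v for v in _kept_variants(p) if v.gene == gene]
        by_g: Dict[str, VariantCall] = {}
        for v in kept:
            by_g.setdefault(v.genomic_change, v)
        k = len(by_g)
        if k:
            n_mutated += 1
            hist[k] = hist.get(k, 0) + 1
        total += k
        for g_str, v in by_g.items():
            unique.add(g_str)
            mt = classify_mutation_type(v).value
            per_type[mt] = per_type.get(mt, 0) + 1
    return MutationTally(
        gene=gene,
        n_patients_mutated=n_mutated,
        n_mutations=total,
        n_unique=len(unique),
        per_type=per_type,
        multiplicity_histogram=hist,
    )


def oncoplot_matrix(cohort: Sequence[PatientRecord], genes: Sequence[str]) -> pd.DataFrame:
    """Patient × gene matrix of mutation-type labels for oncoplot rendering.

    Cells hold ";"-joined ordered mutation-type labels (multi-hit preserved,
    sorted for determinism), empty string when unmutated. Columns are ordered
    by descending mutated-patient count (gene name breaks ties); rows follow
    the waterfall convention — lexicographic on mutated-status over the
    ordered gene list, mutated first, patient id breaking ties — so the matrix
    is invariant to input patient order.
    """
    sequenced = [p for p in cohort if p.has_ngs]
    cells: Dict[str, Dict[str, str]] = {}
    mutated_counts: Dict[str, int] = {g: 0 for g in genes}
    for p in sequenced:
        row: Dict[str, str] = {}
        kept = _kept_variants(p)
        for g in genes:
            labels = sorted(
                classify_mutation_type(v).value for v in kept if v.gene == g
            )
            row[g] = ";".join(labels)
            if labels:
                mutated_counts[g] += 1
        cells[p.patient_id] = row
    col_order = sorted(genes, key=lambda g: (-mutated_counts[g], g))
    row_order = sorted(
        cells,
        key=lambda pid: tuple(0 if cells[pid][g] else 1 for g in col_order) + (pid,),
    )
    return pd.DataFrame(
        [[cells[pid][g] for g in col_order] for pid in row_order],
        index=pd.Index(row_order, name="patient_id"),
        columns=col_order,
    )
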