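"""Per-patient cytogenetic features and cohort frequency tables.

A karyotype's *independent abnormalities* are the distinct cytogenetic events
listed across its abnormal clones: each ISCN token is one event (a translocation
or a derivative chromosome counts once, however many segments it involves), an
event repeated in several clones — including clones inherited through ``idem``
— counts once, and uncertain ("?") events are counted like certain ones.
Karyotypes with more than three independent abnormalities are *complex*, the
conventional threshold in myeloid-malignancy cytogenetics.

Ring and marker inventories keep within-clone multiplicity (``+r,+r`` is two
rings) while deduplicating the same event re-listed across clones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .iscn_core import (
    Abnormality,
    AbnormalityKind,
    Karyotype,
    STRUCTURAL_KINDS,
)

__all__ = [
    "ComplexityClass",
    "PatientFeatures",
    "CohortStat",
    "CohortSummary",
    "distinct_events",
    "count_independent_abnormalities",
    "classify_complexity",
    "ring_inventory",
    "structural_involvement",
    "arm_level_add_del",
    "compute_features",
    "summarize_cohort",
]


class ComplexityClass(str, Enum):
    complex = "complex"            # > 3 independent abnormalities
    exactly_three = "exactly_three"
    simple = "simple"              # <= 2


RING_KINDS = (AbnormalityKind.ring_derived, AbnormalityKind.ring_unknown)


def distinct_events(k: Karyotype) -> Dict[str, Tuple[int, Abnormality]]:
    """Distinct abnormality events of a karyotype with their multiplicity.

    Keys are canonical base tokens (copy multiplier excluded). The multiplicity
    of an event is its maximum within-clone count — summing over clones would
    double-count a stemline event re-listed in an idem subclone — times its
    ISCN copy multiplier.
    """
    out: Dict[str, Tuple[int, Abnormality]] = {}
    for clone in k.clones:
        clone_counts: Counter = Counter()
        rep: Dict[str, Abnormality] = {}
        for a in clone.abnormalities:
            key = a.base_token
            clone_counts[key] += a.copies
            rep.setdefault(key, a)
        for key, n in clone_counts.items():
            prev = out.get(key)
            if prev is None or n > prev[0]:
                out[key] = (n, rep[key])
    return out


def count_independent_abnormalities(k: Karyotype) -> int:
    """Number of distinct cytogenetic events across the abnormal clones."""
    return len(distinct_events(k))


def classify_complexity(n: int) -> ComplexityClass:
    if n < 0:
        raise ValueError("abnormality count cannot be negative")
    if n > 3:
        return ComplexityClass.complex
    if n == 3:
        return ComplexityClass.exactly_three
    return ComplexityClass.simple


def ring_inventory(k: Karyotype) -> Tuple[int, Counter]:
    """Ring count and origin multiset of a karyotype.

    Chromosome-derived rings contribute their chromosome label, rings of
    unknown origin contribute ``"unknown"``; multiple rings count with
    multiplicity (within-clone repeats and copy multipliers included).
    """
    origins: Counter = Counter()
    for n, a in distinct_events(k).values():
        if a.kind is AbnormalityKind.ring_derived:
            origins[a.chromosomes[0]] += n
        elif a.kind is AbnormalityKind.ring_unknown:
            origins["unknown"] += n
    return sum(origins.values()), origins


def structural_involvement(k: Karyotype) -> frozenset:
    """Chromosomes named in at least one structural (banded) rearrangement.

    Whole-chromosome gains/losses, markers, unknown-origin rings and double
    minutes carry no locatable chromosome and are excluded.
    """
    chroms: set = set()
    for _, a in distinct_events(k).values():
        if a.kind in STRUCTURAL_KINDS:
            chroms.update(a.chromosomes)
    return frozenset(chroms)


def arm_level_add_del(k: Karyotype) -> List[Tuple[str, str, str]]:
    """(chromosome, arm, kind) records for every add/del event.

    The arm is read from the event's first breakpoint; events without a banded
    breakpoint are recorded with arm ``"unknown"``.
    """
    records: List[Tuple[str, str, str]] = []
    for _, a in distinct_events(k).values():
        if a.kind not in (AbnormalityKind.add, AbnormalityKind.del_):
            continue
        kind = "add" if a.kind is AbnormalityKind.add else "del"
        arm = a.breakpoints[0].arm if a.breakpoints else "unknown"
        chrom = a.chromosomes[0] if a.chromosomes else "unknown"
        records.append((chrom, arm, kind))
    return records


@dataclass(frozen=True)
class PatientFeatures:
    """Cytogenetic feature vector of one patient's karyotype."""

    n_independent_abnormalities: int
    complexity_class: ComplexityClass
    n_rings: int
    ring_origins: Counter
    has_marker: bool
    n_markers: int
    has_dmin: bool
    structural_chromosomes: frozenset
    arm_events: tuple
    numerical_losses: frozenset
    numerical_gains: frozenset
    del_arms: frozenset  # (chromosome, arm) pairs with a segmental deletion


def compute_features(k: Karyotype) -> PatientFeatures:
    events = distinct_events(k)
    n = len(events)
    n_rings, origins = ring_inventory(k)
    n_markers = sum(m for m, a in events.values() if a.kind is AbnormalityKind.mar)
    losses = frozenset(
        a.chromosomes[0] for _, a in events.values() if a.kind is AbnormalityKind.whole_loss
    )
    gains = frozenset(
        a.chromosomes[0] for _, a in events.values() if a.kind is AbnormalityKind.whole_gain
    )
    arm_events = tuple(arm_level_add_del(k))
    return PatientFeatures(
        n_independent_abnormalities=n,
        complexity_class=classify_complexity(n),
        n_rings=n_rings,
        ring_origins=origins,
        has_marker=n_markers > 0,
        n_markers=n_markers,
        has_dmin=any(a.kind is AbnormalityKind.dmin for _, a in events.values()),
        structural_chromosomes=structural_involvement(k),
        arm_events=arm_events,
        numerical_losses=losses,
        numerical_gains=gains,
        del_arms=frozenset((c, arm) for c, arm, kind in arm_events if kind == "del"),
    )


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortStat:
    count: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.count <= self.denominator):
            raise ValueError("count must lie in [0, denominator]")

    @property
    def percent(self) -> float:
        return 100.0 * self.count / self.denominator


@dataclass(frozen=True)
class CohortSummary:
    """Frequency tables over a patient cohort, with explicit denominators."""

    n_patients: int
    stats: Mapping[str, CohortStat]
    ring_origin_histogram: Counter
    complexity_distribution: Counter

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "stats": {
                k: {"count": s.count, "denominator": s.denominator, "percent": s.percent}
                for k, s in self.stats.items()
            },
            "ring_origin_histogram": dict(self.ring_origin_histogram),
            "complexity_distribution": dict(self.complexity_distribution),
        }


def _loss_or_arm_del(f: PatientFeatures, chrom: str, arm: str) -> bool:
    return chrom in f.numerical_losses or (chrom, arm) in f.del_arms


def summarize_cohort(
    patients: Sequence[PatientFeatures],
    denominator_rule: Union[str, Mapping[str, str]] = "complex_for_cnv",
) -> CohortSummary:
    """Cohort frequency tables: composite CNVs, markers, rings, complexity.

    ``denominator_rule`` chooses the denominator per statistic: the default
    ``"complex_for_cnv"`` scores CNV-style statistics (-7/7q-, -5/-5q, -17/-17p,
    +mar, chromosome-11/18 structural involvement, multiple rings) over the
    complex-karyotype subset, the convention of complex-karyotype cohort
    reports; ``"all"`` uses the whole cohort everywhere. A mapping from
    statistic name to "all"/"complex" overrides per statistic. Complexity and
    ring-origin tables always use the whole cohort.
    """
    if not patients:
        raise ValueError("cannot summarize an empty cohort")
    n_all = len(patients)
    complex_set = [f for f in patients if f.complexity_class is ComplexityClass.complex]
    n_complex = len(complex_set)

    predicates = {
        "loss7_or_del7q": lambda f: _loss_or_arm_del(f, "7", "q"),
        "loss5_or_del5q": lambda f: _loss_or_arm_del(f, "5", "q"),
        "loss17_or_del17p": lambda f: _loss_or_arm_del(f, "17", "p"),
        "marker": lambda f: f.has_marker,
        "chr11_structural": lambda f: "11" in f.structural_chromosomes,
        "chr18_structural": lambda f: "18" in f.structural_chromosomes,
        "multiple_rc": lambda f: f.n_rings >= 2,
        "dmin": lambda f: f.has_dmin,
        "any_unknown_ring": lambda f: f.ring_origins.get("unknown", 0) > 0,
    }
    cnv_style = {
        "loss7_or_del7q",
        "loss5_or_del5q",
        "loss17_or_del17p",
        "marker",
        "chr11_structural",
        "chr18_structural",
        "multiple_rc",
    }

    def denominator_for(name: str) -> Sequence[PatientFeatures]:
        if isinstance(denominator_rule, str):
            use_complex = denominator_rule == "complex_for_cnv" and name in cnv_style
        else:
            use_complex = denominator_rule.get(name, "all") == "complex"
        if use_complex and n_complex == 0:
            use_complex = False  # degenerate cohort: fall back to all patients
        return complex_set if use_complex else patients

    stats: Dict[str, CohortStat] = {}
    for name, pred in predicates.items():
        denom = denominator_for(name)
        stats[name] = CohortStat(sum(1 for f in denom if pred(f)), len(denom))

    ring_hist: Counter = Counter()
    for f in patients:
        ring_hist.update(f.ring_origins)
    complexity: Counter = Counter(f.complexity_class.value for f in patients)
    for cls in ComplexityClass:
        complexity.setdefault(cls.value, 0)
        stats[f"complexity_{cls.value}"] = CohortStat(complexity[cls.value], n_all)

    return CohortSummary(
        n_patients=n_all,
        stats=stats,
        ring_origin_histogram=ring_hist,
        complexity_distribution=complexity,
    )
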