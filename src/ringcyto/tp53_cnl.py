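"""TP53 copy-number-loss inference from chromosome-17 abnormalities and FISH patterns.

The TP53 locus sits at band 17p13.1. Several karyotype-visible events imply
its loss: monosomy 17; a 17p deletion whose span covers p13.1; an additional
material event ``add(17)(p...)`` with a breakpoint at or proximal to p13.1
(the distal segment, including p13.1, is replaced); isochromosome 17q and
isodicentric 17p (whole p-arm loss); and derivative or dicentric chromosomes
that give away 17p material. Events that leave the locus status open — an
``add(17p)`` breakpoint distal to p13.1 or with an unknown band, or a der(17)
whose expression shows no informative 17p breakpoint — yield an *ambiguous*
call that interphase FISH can refine.

FISH enters as signal-pattern shorthand: counts of TP53 locus signals ("R",
optionally "dim" for diminished intensity) and centromere-17 signals ("G"),
e.g. "1R2G" = one TP53 signal on two chromosomes 17 (locus loss), "1R1G" =
monosomy 17.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .iscn_core import (
    Abnormality,
    AbnormalityKind,
    BandAddress,
    Karyotype,
    TP53_LOCUS,
    band_distal_key,
)

__all__ = [
    "CnlStatus",
    "CnlMechanism",
    "CnlCall",
    "FishPattern",
    "FishCall",
    "Concordance",
    "ReconciledCall",
    "infer_cnl_from_karyotype",
    "parse_fish_pattern",
    "interpret_fish",
    "reconcile",
    "cnl_mechanism_census",
    "MECHANISM_PRECEDENCE",
    "two_hit_count",
]


class CnlStatus(str, Enum):
    loss = "loss"
    ambiguous_diminished = "ambiguous_diminished"
    normal = "normal"
    no_evidence = "no_evidence"


class CnlMechanism(str, Enum):
    monosomy17 = "monosomy17"
    del17p = "del17p"
    add17p = "add17p"
    der17 = "der17"
    dic17 = "dic17"
    i17q = "i17q"
    idic17 = "idic17"
    none = "none"


#: Single-count precedence when one patient shows several loss mechanisms.
MECHANISM_PRECEDENCE: Tuple[CnlMechanism, ...] = (
    CnlMechanism.monosomy17,
    CnlMechanism.add17p,
    CnlMechanism.der17,
    CnlMechanism.dic17,
    CnlMechanism.del17p,
    CnlMechanism.i17q,
    CnlMechanism.idic17,
)


@dataclass(frozen=True)
class CnlCall:
    status: CnlStatus
    mechanism: CnlMechanism = CnlMechanism.none
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if self.status is CnlStatus.loss and self.mechanism is CnlMechanism.none:
            raise ValueError("a loss call must name its mechanism")
        if self.status is CnlStatus.normal and self.evidence:
            raise ValueError("a normal call carries no evidence")


def _proximal_or_at(band: Optional[str], locus: BandAddress) -> Optional[bool]:
    """True if a p-arm band is at or proximal (centromere side) of the locus band.

    None when the band is unknown.
    """
    if band is None:
        return None
    return band_distal_key(band) <= band_distal_key(locus.band)


def _p_breakpoints(a: Abnormality, locus: BandAddress) -> List[BandAddress]:
    return [b for b in a.breakpoints if b.chromosome == locus.chromosome and b.arm == "p"]


def _del_covers_locus(a: Abnormality, locus: BandAddress) -> Optional[bool]:
    """Does a deletion of the locus chromosome remove the locus band?

    Terminal deletion del(17)(pXX): everything distal to the breakpoint is
    lost, so the locus goes iff the breakpoint is at/proximal to it.
    Interstitial deletion del(17)(pXXpYY): lost iff the span brackets the
    locus. Unknown bands → None (undecidable).
    """
    bps = _p_breakpoints(a, locus)
    if not bps:
        return False
    keys = []
    for b in bps:
        if b.band is None:
            return None
        keys.append(band_distal_key(b.band))
    locus_key = band_distal_key(locus.band)
    if len(keys) == 1:
        return keys[0] <= locus_key
    lo, hi = min(keys), max(keys)
    return lo <= locus_key <= hi


def _classify_event(a: Abnormality, locus: BandAddress):
    """(status, mechanism) contribution of one abnormality, or None if silent."""
    chrom = locus.chromosome
    if a.kind is AbnormalityKind.whole_loss and a.chromosomes == (chrom,):
        return CnlStatus.loss, CnlMechanism.monosomy17
    if chrom not in a.chromosomes:
        return None
    if a.kind is AbnormalityKind.del_:
        covers = _del_covers_locus(a, locus)
        if covers is None:
            return CnlStatus.ambiguous_diminished, CnlMechanism.del17p
        return (CnlStatus.loss, CnlMechanism.del17p) if covers else None
    if a.kind is AbnormalityKind.add:
        bps = _p_breakpoints(a, locus)
        if not bps:
            return None  # add(17)(q...) leaves the p arm intact
        prox = _proximal_or_at(bps[0].band, locus)
        if prox:
            return CnlStatus.loss, CnlMechanism.add17p
        if prox is None:
            return CnlStatus.ambiguous_diminished, CnlMechanism.add17p
        return CnlStatus.ambiguous_diminished, CnlMechanism.add17p
    if a.kind is AbnormalityKind.i:
        # i(17)(q10): the p arm is replaced by a q-arm mirror image.
        if any(b.chromosome == chrom and b.arm == "q" for b in a.breakpoints):
            return CnlStatus.loss, CnlMechanism.i17q
        return CnlStatus.ambiguous_diminished, CnlMechanism.i17q
    if a.kind is AbnormalityKind.idic:
        if _p_breakpoints(a, locus):
            return CnlStatus.loss, CnlMechanism.idic17
        return CnlStatus.ambiguous_diminished, CnlMechanism.idic17
    if a.kind in (AbnormalityKind.der, AbnormalityKind.dic):
        mech = CnlMechanism.der17 if a.kind is AbnormalityKind.der else CnlMechanism.dic17
        for b in _p_breakpoints(a, locus):
            prox = _proximal_or_at(b.band, locus)
            if prox:
                return CnlStatus.loss, mech
        # 17 involved but no informative p breakpoint: unknown-origin material
        # may retain p13.1, so the call stays open for FISH.
        return CnlStatus.ambiguous_diminished, mech
    return None  # balanced t, inv, dup, ring etc. do not delete the locus


def infer_cnl_from_karyotype(k: Karyotype, locus: BandAddress = TP53_LOCUS) -> CnlCall:
    """Aggregate TP53 CNL call over all clones of a karyotype.

    Any clone-level loss dominates; otherwise any ambiguous evidence yields an
    ambiguous call; a karyotype with no informative chromosome-17 events is
    ``no_evidence``. The mechanism reported for a loss follows
    :data:`MECHANISM_PRECEDENCE` so each patient is counted once in the census.
    The call is invariant to clone order and to non-17 abnormalities.
    """
    loss_mechs: List[CnlMechanism] = []
    amb_mechs: List[CnlMechanism] = []
    evidence: List[Abnormality] = []
    seen: set = set()
    for clone in k.clones:
        for a in clone.abnormalities:
            key = a.base_token
            if key in seen:
                continue
            seen.add(key)
            res = _classify_event(a, locus)
            if res is None:
                continue
            status, mech = res
            evidence.append(a)
            (loss_mechs if status is CnlStatus.loss else amb_mechs).append(mech)
    if loss_mechs:
        mech = next(m for m in MECHANISM_PRECEDENCE if m in loss_mechs)
        return CnlCall(CnlStatus.loss, mech, tuple(evidence))
    if amb_mechs:
        mech = next(m for m in MECHANISM_PRECEDENCE if m in amb_mechs)
        return CnlCall(CnlStatus.ambiguous_diminished, mech, tuple(evidence))
    return CnlCall(CnlStatus.no_evidence, CnlMechanism.none, ())


# ---------------------------------------------------------------------------
# FISH signal patterns
# ---------------------------------------------------------------------------


class FishCall(str, Enum):
    normal = "normal"
    tp53_loss_disomic17 = "tp53_loss_disomic17"
    monosomy17 = "monosomy17"
    abnormal_diminished = "abnormal_diminished"


@dataclass(frozen=True)
class FishPattern:
    """Parsed FISH signal-pattern shorthand (R = TP53 probe, G = centromere 17)."""

    n_target_normal: int
    n_target_dim: int
    n_centromere: int
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if min(self.n_target_normal, self.n_target_dim, self.n_centromere) < 0:
            raise ValueError("signal counts cannot be negative")


_FISH_TOKEN = re.compile(r"(\d+)([RG])(dim)?", re.IGNORECASE)


def parse_fish_pattern(raw: str) -> FishPattern:
    """Parse shorthand like "2R2G", "1R1G" or "2Rdim1R2G".

    Each token is <count><R|G> with an optional trailing "dim" binding to the
    preceding signal count; R counts TP53 locus signals, G centromere-17
    signals.
    """
    s = re.sub(r"\s+", "", str(raw))
    if not s:
        raise ValueError("empty FISH pattern")
    consumed = 0
    normal = dim = cen = 0
    for m in _FISH_TOKEN.finditer(s):
        if m.start() != consumed:
            break
        consumed = m.end()
        n = int(m.group(1))
        probe = m.group(2).upper()
        is_dim = m.group(3) is not None
        if probe == "G":
            if is_dim:
                raise ValueError(f"'dim' applies to the TP53 probe only: {raw!r}")
            cen += n
        elif is_dim:
            dim += n
        else:
            normal += n
    if consumed != len(s):
        raise ValueError(f"unparseable FISH pattern: {raw!r}")
    return FishPattern(normal, dim, cen, raw=str(raw))


def interpret_fish(p: FishPattern) -> FishCall:
    """Interpret a FISH pattern for TP53 copy number.

    2R2G → normal; 1R2G → TP53 loss on disomic 17; 1R1G → monosomy 17; any
    diminished signal → abnormal_diminished. Zero centromere signals is an
    invalid (unhybridized) pattern. Patterns with extra signals (e.g. 3R2G)
    read as no-loss and map to normal.
    """
    if p.n_centromere == 0:
        raise ValueError(f"invalid FISH pattern with no centromere signal: {p.raw!r}")
    if p.n_target_dim > 0:
        return FishCall.abnormal_diminished
    if p.n_target_normal >= p.n_centromere and p.n_target_normal >= 2:
        return FishCall.normal
    if p.n_centromere == 1:
        return FishCall.monosomy17
    return FishCall.tp53_loss_disomic17


# ---------------------------------------------------------------------------
# Reconciliation of karyotype and FISH evidence
# ---------------------------------------------------------------------------


class Concordance(str, Enum):
    concordant = "concordant"
    fish_refines = "fish_refines"
    discordant = "discordant"


_FISH_IMPLIED_STATUS = {
    FishCall.normal: CnlStatus.normal,
    FishCall.tp53_loss_disomic17: CnlStatus.loss,
    FishCall.monosomy17: CnlStatus.loss,
    FishCall.abnormal_diminished: CnlStatus.ambiguous_diminished,
}

_FISH_IMPLIED_MECHANISM = {
    FishCall.monosomy17: CnlMechanism.monosomy17,
}


@dataclass(frozen=True)
class ReconciledCall:
    concordance: Concordance
    final_status: CnlStatus
    final_mechanism: CnlMechanism
    karyotype_call: CnlCall
    fish_call: FishCall
    note: str = ""


def reconcile(karyotype_call: CnlCall, fish_call: FishCall) -> ReconciledCall:
    """Join a karyotype-derived CNL call with a FISH call.

    FISH refines ambiguous or evidence-free karyotype calls; agreement on
    status is concordant (a mechanism-level mismatch, e.g. add(17p) by
    karyotype but a monosomy-17 FISH pattern, is surfaced in the note, not
    silently resolved); a definite karyotype call contradicted by FISH is
    discordant, and both readings are preserved in the report.
    """
    k_status = karyotype_call.status
    f_status = _FISH_IMPLIED_STATUS[fish_call]
    f_mech = _FISH_IMPLIED_MECHANISM.get(fish_call)
    if k_status in (CnlStatus.ambiguous_diminished, CnlStatus.no_evidence):
        mech = f_mech or (
            karyotype_call.mechanism
            if f_status is not CnlStatus.normal
            else CnlMechanism.none
        )
        return ReconciledCall(
            Concordance.fish_refines, f_status, mech, karyotype_call, fish_call
        )
    if k_status == f_status:
        note = ""
        if (
            f_mech is not None
            and karyotype_call.mechanism not in (f_mech, CnlMechanism.none)
        ):
            note = (
                f"mechanism mismatch: karyotype {karyotype_call.mechanism.value} "
                f"vs FISH {f_mech.value}"
            )
        return ReconciledCall(
            Concordance.concordant,
            k_status,
            karyotype_call.mechanism,
            karyotype_call,
            fish_call,
            note,
        )
    return ReconciledCall(
        Concordance.discordant,
        k_status,
        karyotype_call.mechanism,
        karyotype_call,
        fish_call,
        note=f"karyotype says {k_status.value}, FISH says {f_status.value}",
    )


# ---------------------------------------------------------------------------
# Census and two-hit accounting
# ---------------------------------------------------------------------------


def cnl_mechanism_census(calls: Mapping[str, CnlCall]) -> dict:
    """Per-mechanism patient counts over a set of CNL calls.

    Each patient counts once, under the highest-precedence mechanism of their
    call. Percentages are reported over two denominators: the patients with a
    CNL loss, and all patients in the input (the ambiguous/no-evidence ones
    included), since which subset a census should be read against depends on
    the question.
    """
    counts: Dict[str, int] = {m.value: 0 for m in MECHANISM_PRECEDENCE}
    n_loss = 0
    for call in calls.values():
        if call.status is CnlStatus.loss:
            n_loss += 1
            counts[call.mechanism.value] += 1
    n_all = len(calls)
    return {
        "counts": counts,
        "n_loss": n_loss,
        "n_total": n_all,
        "percent_of_loss": {
            m: (100.0 * c / n_loss if n_loss else 0.0) for m, c in counts.items()
        },
        "percent_of_total": {
            m: (100.0 * c / n_all if n_all else 0.0) for m, c in counts.items()
        },
    }


def two_hit_count(n_distinct_tp53_mutations: int, cnl_call: CnlCall) -> int:
    """TP53 hit count: distinct mutations plus one when copy-number loss is called."""
    if n_distinct_tp53_mutations < 0:
        raise ValueError("mutation count cannot be negative")
    return n_distinct_tp53_mutations + (1 if cnl_call.status is CnlStatus.loss else 0)
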