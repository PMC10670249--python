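"""Parse and serialize ISCN karyotype nomenclature.

The International System for Human Cytogenetic Nomenclature (ISCN) describes a
specimen's chromosome complement as a slash-separated list of clones, each with a
modal chromosome number, a sex-chromosome designation, a comma-separated list of
abnormality tokens, and an optional metaphase cell count in brackets, e.g.::

    46,XX,r(18)(p11.3q23)[2]/46,XX,t(7;17)(q36;q21)[2]/46,XX[15]

This module covers the constructs that occur in hematological-malignancy
karyotypes: whole-chromosome gains and losses, the structural event vocabulary
(add, del, dup, der, dic, i, idic, ins, inv, t), ring chromosomes of known
(``r(18)(...)``) and unknown (``+r``) origin, marker chromosomes (``+mar``),
double minutes (``dmin``), ``idem`` stemline inheritance, uncertainty markers
(``?``, ``~``), and composite/incomplete karyotypes (``cp``, ``inc``).
Microarray (``arr``) and chromosome-breakage syntax are out of scope.

Any token the grammar does not recognise is preserved as an ``other``
abnormality with ``uncertain=True`` rather than dropped, so downstream event
counts never silently lose records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Iterable, Optional, Union

__all__ = [
    "AbnormalityKind",
    "BandAddress",
    "Abnormality",
    "Clone",
    "Karyotype",
    "IscnParseError",
    "parse_karyotype",
    "serialize_karyotype",
    "serialize_abnormality",
    "modal_number",
    "compare_bands",
    "band_distal_key",
    "CHROMOSOME_LABELS",
    "TP53_LOCUS",
]


class IscnParseError(ValueError):
    """Raised when a karyotype string violates the ISCN clone structure."""


CHROMOSOME_LABELS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_SET = frozenset(CHROMOSOME_LABELS)

# Loss signs seen in published karyotypes: ASCII hyphen, Unicode minus, en dash.
_SIGN_CANON = {"−": "-", "–": "-", "×": "x"}


def _canon_text(text: str) -> str:
    """Canonicalize sign characters and strip all internal whitespace.

    Published karyotypes carry line-break artifacts ("t(7;17) (q36;q21)") and mix
    Unicode minus with ASCII hyphen; both are normalised before tokenizing.
    """
    for bad, good in _SIGN_CANON.items():
        text = text.replace(bad, good)
    return re.sub(r"\s+", "", text)


# ---------------------------------------------------------------------------
# Band addresses
# ---------------------------------------------------------------------------

_BAND_RE = re.compile(r"^\d+(\.\d+)?$")


@total_ordering
@dataclass(frozen=True)
class BandAddress:
    """A cytogenetic band, e.g. 17p13.1.

    ``band`` is None when the arm is known but the band is not (ISCN "p?").
    Ordering (and :func:`compare_bands`) follows physical position along the
    chromosome from pter to qter: on the p arm higher band numbers are more
    distal (closer to pter, hence sort first); on the q arm higher numbers are
    more distal from the centromere and sort last.
    """

    chromosome: str
    arm: str
    band: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_SET and self.chromosome != "?":
            raise ValueError(f"unknown chromosome label: {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.band is not None and not _BAND_RE.match(self.band):
            raise ValueError(f"malformed band string: {self.band!r}")

    @property
    def position_rank(self) -> tuple:
        """Sort key for pter→qter order within one chromosome arm."""
        key = band_distal_key(self.band)
        # p bands: distal-to-proximal toward the centromere, so invert.
        return tuple(-d for d in key) if self.arm == "p" else key

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}{self.band if self.band is not None else '?'}"

    def __lt__(self, other: "BandAddress") -> bool:
        if self.chromosome != other.chromosome or self.arm != other.arm:
            raise ValueError("bands on different chromosome arms are not ordered")
        return self.position_rank < other.position_rank


def band_distal_key(band: Optional[str]) -> tuple:
    """Distance-from-centromere key for a band string within one arm.

    Bands are hierarchical: 13 contains 13.1..13.3, with sub-band numbering
    increasing away from the centromere. The key compares the major band
    number, then sub-band digits one at a time; a bare parent band ranks at the
    proximal edge of its sub-bands (13 < 13.1). Unknown bands rank proximal to
    every known band.
    """
    if band is None:
        return (-1, -1, -1, -1)
    major, _, sub = band.partition(".")
    digits = tuple(int(d) for d in sub)
    # pad so that a bare parent band (13) sorts at the proximal edge of its
    # sub-bands (13.1, 13.2, ...) under both arms' orderings
    digits = (digits + (-1, -1, -1))[:3]
    return (int(major),) + digits


def compare_bands(a: BandAddress, b: BandAddress) -> int:
    """Three-way comparison of two bands on the same chromosome arm.

    Returns -1/0/+1 in pter→qter order: on the p arm the more distal band
    (higher number) comes first; on the q arm the more proximal band comes
    first. Raises ValueError for bands on different chromosomes or arms.
    """
    ra, rb = a.position_rank, b.position_rank  # validates arm agreement below
    if a.chromosome != b.chromosome or a.arm != b.arm:
        raise ValueError("bands on different chromosome arms are not ordered")
    return (ra > rb) - (ra < rb)


#: Cytogenetic location of the TP53 locus.
TP53_LOCUS = BandAddress("17", "p", "13.1")


# ---------------------------------------------------------------------------
# Abnormalities
# ---------------------------------------------------------------------------


class AbnormalityKind(str, Enum):
    whole_gain = "whole_gain"
    whole_loss = "whole_loss"
    add = "add"
    del_ = "del"
    dup = "dup"
    der = "der"
    dic = "dic"
    idic = "idic"
    i = "i"
    ins = "ins"
    inv = "inv"
    t = "t"
    ring_derived = "ring_derived"
    ring_unknown = "ring_unknown"
    mar = "mar"
    dmin = "dmin"
    other = "other"


#: Kinds that name at least one chromosome through a banded rearrangement.
STRUCTURAL_KINDS = frozenset(
    {
        AbnormalityKind.add,
        AbnormalityKind.del_,
        AbnormalityKind.dup,
        AbnormalityKind.der,
        AbnormalityKind.dic,
        AbnormalityKind.idic,
        AbnormalityKind.i,
        AbnormalityKind.ins,
        AbnormalityKind.inv,
        AbnormalityKind.t,
        AbnormalityKind.ring_derived,
    }
)

_KIND_TOKEN = {
    AbnormalityKind.add: "add",
    AbnormalityKind.del_: "del",
    AbnormalityKind.dup: "dup",
    AbnormalityKind.der: "der",
    AbnormalityKind.dic: "dic",
    AbnormalityKind.idic: "idic",
    AbnormalityKind.i: "i",
    AbnormalityKind.ins: "ins",
    AbnormalityKind.inv: "inv",
    AbnormalityKind.t: "t",
    AbnormalityKind.ring_derived: "r",
}
_TOKEN_KIND = {v: k for k, v in _KIND_TOKEN.items()}


@dataclass(frozen=True)
class Abnormality:
    """One cytogenetic event.

    ``plus`` records a supernumerary "+" prefix on a structural token (e.g.
    "+der(5)..."); gains, unknown rings and markers are inherently "+".
    ``raw_token`` keeps the normalised source substring and is excluded from
    equality so that re-serialized events compare equal to their source.
    """

    kind: AbnormalityKind
    chromosomes: tuple = ()
    breakpoints: tuple = ()
    copies: int = 1
    uncertain: bool = False
    plus: bool = False
    raw_token: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be a positive integer")

    @property
    def base_token(self) -> str:
        """Canonical token without the copy multiplier; dedup key."""
        return serialize_abnormality(self, with_copies=False)

    def __str__(self) -> str:
        return serialize_abnormality(self)


def serialize_abnormality(a: Abnormality, with_copies: bool = True) -> str:
    kind = a.kind
    q = "?" if a.uncertain else ""
    if kind is AbnormalityKind.whole_gain:
        tok = f"+{q}{a.chromosomes[0]}"
    elif kind is AbnormalityKind.whole_loss:
        tok = f"-{q}{a.chromosomes[0]}"
    elif kind is AbnormalityKind.mar:
        tok = f"+{q}mar"
    elif kind is AbnormalityKind.ring_unknown:
        tok = f"+{q}r"
    elif kind is AbnormalityKind.dmin:
        tok = ("" if a.copies == 1 or not with_copies else f"{a.copies}") + "dmin"
        return tok
    elif kind in (AbnormalityKind.der, AbnormalityKind.other):
        # Nested expressions (der(5)t(5;17)(p11;q11)) and unrecognised tokens
        # do not reconstruct losslessly from the flat field set; the normalised
        # source token is authoritative.
        tok = a.raw_token
    else:
        name = _KIND_TOKEN[kind]
        groups = _band_groups(a)
        tok = ("+" if a.plus else "") + q + name + f"({';'.join(a.chromosomes)})"
        if groups:
            tok += f"({';'.join(groups)})"
    if kind is AbnormalityKind.der and a.plus and not tok.startswith("+"):
        tok = "+" + tok
    if with_copies and a.copies > 1 and kind is not AbnormalityKind.dmin:
        tok += f"x{a.copies}"
    return tok


def _band_groups(a: Abnormality) -> list:
    """Regroup breakpoints per chromosome in source order for serialization."""
    if not a.breakpoints:
        return []
    groups: list = []
    for chrom in a.chromosomes:
        parts = [
            f"{b.arm}{b.band if b.band is not None else '?'}"
            for b in a.breakpoints
            if b.chromosome == chrom
        ]
        if parts:
            groups.append("".join(parts))
    # Breakpoints on chromosomes not listed (should not happen) are dropped.
    return groups


# ---------------------------------------------------------------------------
# Clones and karyotypes
# ---------------------------------------------------------------------------

ModalNumber = Union[int, tuple]


@dataclass(frozen=True)
class Clone:
    """One cytogenetically distinct cell population.

    ``modal_number`` is an int, or an (lo, hi) tuple for interval counts like
    "41~44". After ``idem`` expansion, inherited stemline abnormalities occupy
    the first ``n_inherited`` positions of ``abnormalities``.
    """

    modal_number: ModalNumber
    sex_designation: str = ""
    abnormalities: tuple = ()
    cell_count: Optional[int] = None
    inherits_from: Optional[int] = field(default=None, compare=False)
    n_inherited: int = field(default=0, compare=False)
    composite: bool = False
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.cell_count is not None and self.cell_count < 1:
            raise ValueError("cell_count must be >= 1 when present")

    @property
    def is_normal(self) -> bool:
        return not self.abnormalities and self.modal_number == 46


@dataclass(frozen=True)
class Karyotype:
    clones: tuple
    source_text: str = field(default="", compare=False)
    iscn_version_hint: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("a karyotype has at least one clone")

    @property
    def incomplete(self) -> bool:
        return any(c.composite or c.incomplete for c in self.clones)

    def __str__(self) -> str:
        return serialize_karyotype(self)


def modal_number(c: Clone) -> ModalNumber:
    """The leading ISCN chromosome-count field; interval counts stay as bounds."""
    return c.modal_number


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_MODAL_RE = re.compile(r"^(\d+)(?:~(\d+))?$")
_WHOLE_RE = re.compile(r"^([+-])(\?)?(\d{1,2}|X|Y)$")
_MAR_RE = re.compile(r"^\+?(\?)?mar$")
_RING_UNKNOWN_RE = re.compile(r"^\+(\?)?r$")
_DMIN_RE = re.compile(r"^(\d+)?(?:~(\d+))?dmin$")
_MULT_RE = re.compile(r"^(.+?)x(\d+)$")
_STRUCT_PIECE = re.compile(r"([a-z]+)|\(([^()]*)\)")
_CHROM_LIST_RE = re.compile(r"^\??(\d{1,2}|X|Y|\?)(;(\d{1,2}|X|Y|\?))*$")
_BP_TOKEN = re.compile(r"([pq])(\?|\d+(?:\.\d+)?)?|\?")
_SEX_RE = re.compile(r"^[XY]{1,4}$")


def parse_karyotype(text: str, iscn_version_hint: Optional[str] = None) -> Karyotype:
    """Parse an ISCN karyotype string into a :class:`Karyotype`.

    Clones are separated by "/", abnormality tokens by ",". ``idem`` clones are
    expanded against the first (stemline) clone at parse time. Unrecognised
    tokens become ``other`` abnormalities with ``uncertain=True``.
    """
    if text is None or not str(text).strip():
        raise IscnParseError("empty karyotype string")
    source = str(text)
    canon = _canon_text(source)
    clone_texts = [c for c in canon.split("/") if c]
    if not clone_texts:
        raise IscnParseError(f"no clones found in {source!r}")
    clones: list = []
    for ct in clone_texts:
        clones.append(_parse_clone(ct, clones))
    return Karyotype(tuple(clones), source_text=source, iscn_version_hint=iscn_version_hint)


def _parse_clone(text: str, previous: list) -> Clone:
    cell_count: Optional[int] = None
    composite = incomplete = False
    m = re.search(r"\[([^\[\]]*)\]$", text)
    if m:
        inner = m.group(1)
        text = text[: m.start()]
        if inner == "inc":
            incomplete = True
        else:
            cm = re.match(r"^(cp)?(\d+)$", inner)
            if not cm:
                raise IscnParseError(f"unparseable cell-count field [{inner}]")
            composite = cm.group(1) == "cp"
            cell_count = int(cm.group(2))

    fields = [f for f in text.split(",") if f != ""]
    if not fields:
        raise IscnParseError(f"clone with no ploidy field in {text!r}")
    mm = _MODAL_RE.match(fields[0])
    if not mm:
        raise IscnParseError(f"unparseable ploidy field {fields[0]!r}")
    modal: ModalNumber = (
        int(mm.group(1)) if mm.group(2) is None else (int(mm.group(1)), int(mm.group(2)))
    )
    rest = fields[1:]

    sex = ""
    if rest and _SEX_RE.match(rest[0]):
        sex = rest[0]
        rest = rest[1:]

    inherits_from: Optional[int] = None
    n_inherited = 0
    abns: list = []
    if rest and rest[0] == "idem":
        if not previous:
            raise IscnParseError("'idem' in the first clone has no stemline to inherit")
        inherits_from = 0
        stem = previous[0]
        abns.extend(stem.abnormalities)
        n_inherited = len(abns)
        if not sex:
            sex = stem.sex_designation
        rest = rest[1:]

    for tok in rest:
        if tok == "inc":
            incomplete = True
            continue
        abns.append(_parse_token(tok))

    return Clone(
        modal_number=modal,
        sex_designation=sex,
        abnormalities=tuple(abns),
        cell_count=cell_count,
        inherits_from=inherits_from,
        n_inherited=n_inherited,
        composite=composite,
        incomplete=incomplete,
    )


def _parse_token(tok: str) -> Abnormality:
    copies = 1
    mm = _MULT_RE.match(tok)
    if mm:  # trailing xN copy multiplier; no ISCN kind token contains "x"
        tok, copies = mm.group(1), int(mm.group(2))
    raw = tok  # multiplier lives in `copies`; serialization re-appends it

    m = _WHOLE_RE.match(tok)
    if m:
        kind = AbnormalityKind.whole_gain if m.group(1) == "+" else AbnormalityKind.whole_loss
        return Abnormality(
            kind,
            chromosomes=(m.group(3),),
            copies=copies,
            uncertain=m.group(2) is not None,
            plus=kind is AbnormalityKind.whole_gain,
            raw_token=raw,
        )
    m = _MAR_RE.match(tok)
    if m:
        return Abnormality(
            AbnormalityKind.mar,
            copies=copies,
            uncertain=m.group(1) is not None,
            plus=True,
            raw_token=raw,
        )
    m = _RING_UNKNOWN_RE.match(tok)
    if m:
        return Abnormality(
            AbnormalityKind.ring_unknown,
            copies=copies,
            uncertain=m.group(1) is not None,
            plus=True,
            raw_token=raw,
        )
    m = _DMIN_RE.match(tok)
    if m:
        n = int(m.group(1)) if m.group(1) else 1
        return Abnormality(
            AbnormalityKind.dmin,
            copies=max(n, 1) * copies,
            uncertain=m.group(2) is not None,
            plus=False,
            raw_token=raw,
        )
    a = _parse_structural(tok, copies, raw)
    if a is not None:
        return a
    return Abnormality(AbnormalityKind.other, uncertain=True, copies=copies, raw_token=raw)


def _parse_structural(tok: str, copies: int, raw: str) -> Optional[Abnormality]:
    body = tok
    plus = body.startswith("+")
    if plus:
        body = body[1:]
    uncertain = "?" in body or "~" in body
    body_clean = body.lstrip("?")
    if not re.match(r"^[a-z]+\(", body_clean):
        return None
    # Reject if anything outside names and parenthesized groups remains.
    if _STRUCT_PIECE.sub("", body_clean).strip("?~"):
        return None

    pieces = _STRUCT_PIECE.findall(body_clean)
    names = [p[0] for p in pieces if p[0]]
    if not names or names[0] not in _TOKEN_KIND:
        return None
    kind = _TOKEN_KIND[names[0]]
    # Nested event names (der(5)t(5;17)...) are expected under der only.
    if names[1:] and kind is not AbnormalityKind.der:
        return None

    chromosomes: list = []
    breakpoints: list = []
    pending: list = []
    for name, group in pieces:
        if name:
            pending = []
            continue
        if _CHROM_LIST_RE.match(group):
            pending = []
            for c in group.split(";"):
                c = c.lstrip("?")
                if c == "":
                    c = "?"
                if c == "?":
                    uncertain = True
                pending.append(c)
                if c != "?" and c not in chromosomes:
                    chromosomes.append(c)
        else:
            segs = group.split(";")
            for j, seg in enumerate(segs):
                chrom = pending[j] if j < len(pending) else (pending[-1] if pending else "?")
                for bm in _BP_TOKEN.finditer(seg):
                    if bm.group(1) is None:
                        uncertain = True  # bare "?" segment
                        continue
                    arm = bm.group(1)
                    band = bm.group(2)
                    if band in (None, "?"):
                        uncertain = True
                        band = None
                    if chrom == "?":
                        uncertain = True
                        continue
                    breakpoints.append(BandAddress(chrom, arm, band))

    if kind is AbnormalityKind.ring_derived and len(chromosomes) != 1:
        # Multi-chromosome rings fall outside the single-origin ring model.
        return Abnormality(
            AbnormalityKind.other,
            chromosomes=tuple(chromosomes),
            breakpoints=tuple(breakpoints),
            copies=copies,
            uncertain=True,
            plus=plus,
            raw_token=raw,
        )
    return Abnormality(
        kind,
        chromosomes=tuple(chromosomes),
        breakpoints=tuple(breakpoints),
        copies=copies,
        uncertain=uncertain,
        plus=plus,
        raw_token=raw,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_SEX_KEY = {"X": 23, "Y": 24}


def _abn_sort_key(a: Abnormality) -> tuple:
    if a.chromosomes:
        c = a.chromosomes[0]
        major = _SEX_KEY.get(c, None)
        major = int(c) if major is None else major
    else:
        major = 99  # mar, +r, dmin sort last, as ISCN prints them
    sex_first = 0 if a.chromosomes and a.chromosomes[0] in ("X", "Y") else 1
    return (sex_first, major, a.kind.value, a.base_token)


def serialize_karyotype(k: Karyotype, sort: bool = False) -> str:
    """Serialize a karyotype back to ISCN text.

    Signs are canonical (ASCII hyphen, "x" multiplier) and whitespace-free.
    With ``sort=True`` abnormalities are re-ordered canonically (sex
    chromosomes first, then ascending chromosome number); by default model
    order is preserved so that parse and serialize are mutual inverses.
    Composite/incomplete karyotypes serialize but carry no round-trip
    guarantee.
    """
    parts = []
    for c in k.clones:
        modal = (
            str(c.modal_number)
            if isinstance(c.modal_number, int)
            else f"{c.modal_number[0]}~{c.modal_number[1]}"
        )
        fields = [modal]
        if c.sex_designation:
            fields.append(c.sex_designation)
        abns = list(c.abnormalities)
        if sort:
            abns = sorted(abns, key=_abn_sort_key)
        fields.extend(serialize_abnormality(a) for a in abns)
        if c.incomplete:
            fields.append("inc")
        clause = ",".join(fields)
        if c.cell_count is not None:
            clause += f"[{'cp' if c.composite else ''}{c.cell_count}]"
        parts.append(clause)
    return "/".join(parts)
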