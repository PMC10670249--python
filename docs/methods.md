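# Methods

## ISCN parsing model

A karyotype string is a `/`-separated list of clones; each clone is a
comma-separated field list: modal chromosome number (integer or `41~44`
interval), sex designation, abnormality tokens, and an optional `[n]`
metaphase cell count (`[cp n]` for composite clones, `inc` for incomplete
descriptions). The grammar targets the constructs seen in
hematological-malignancy karyotypes; microarray (`arr`) nomenclature and
chromosome-breakage syntax are out of scope.

Parsing decisions:

- **Sign canonicalization.** Published karyotypes mix ASCII hyphen, Unicode
  minus (U+2212) and en dash as the loss sign, and `×`/`x` as the copy
  multiplier; all are canonicalized before tokenizing, and all internal
  whitespace is stripped (line-break artifacts such as `t(7;17) (q36;q21)`
  are common in printed karyotypes).
- **`idem` expansion.** A clone beginning with `idem` inherits the first
  (stemline) clone's abnormalities at parse time; inherited events occupy the
  leading positions and their count is kept as provenance. Downstream event
  counting needs fully expanded clones.
- **Uncertainty is preserved, never dropped.** `?` and `~` set
  `uncertain=True` on the event; unrecognised tokens are kept as `other`
  events with `uncertain=True`. Cohort counts include uncertain events,
  because published totals include `?`-qualified records.
- **Interval modal numbers** are stored as bounds and never collapsed;
  complexity counting is based on listed events only and ignores the ploidy
  field entirely.
- **Derivative chromosomes.** `der`/nested expressions record every
  chromosome and breakpoint mentioned, but their canonical serialization is
  the normalised source token: the flat field set does not reconstruct
  nesting losslessly, and the normalised token is a stable dedup key.
- **Multi-chromosome ring tokens** (e.g. `r(1;3)`) fall outside the
  single-origin ring model and are classified `other`; they do not occur in
  this package's scope.

**Serialization order.** `serialize_karyotype` preserves model order by
default and re-orders canonically (sex abnormalities first, then ascending
chromosome number) with `sort=True`. Preserving order keeps parse and
serialize mutual inverses on arbitrary input — a serializer that re-sorts
cannot satisfy `parse(serialize(k)) == k` for clones whose source order was
not canonical. The synthetic generator emits canonical order, so the
round-trip identity holds verbatim on every generated cohort; `cp`/`inc`
karyotypes are excluded from the round-trip guarantee.

## Band ordering

Cytogenetic bands are hierarchical (band 13 contains sub-bands 13.1–13.3,
numbered away from the centromere). The comparator maps a band string to a
padded digit tuple — major band number, then sub-band digits, padding with a
sentinel so a bare parent band ranks at the proximal edge of its sub-bands —
and orders addresses along the chromosome from pter to qter: on the p arm
higher band numbers are more distal and sort first, on the q arm they sort
last. This yields a total order per arm; comparing across arms or
chromosomes is a domain error.

## Independent abnormalities and complexity

An *independent abnormality* is one listed ISCN token after `idem`
expansion, deduplicated across clones by canonical serialization: a
translocation or derivative counts once regardless of how many segments it
involves, and an event re-listed in a subclone counts once. Complexity
classes follow the conventional threshold: more than three independent
events is *complex*; exactly three and ≤ 2 are reported separately. This
reproduces the published reading of the non-complex worked examples (one
abnormality "in addition to the ring").

Ring and marker inventories keep multiplicity *within* a clone (`+r,+r` is
two rings; `+mar×2` two markers) while still counting a stemline ring
re-listed in an idem subclone once: the inventory takes, per canonical
token, the maximum within-clone count across clones. Presence flags
(`has_marker`) collapse multiplicity; the counts retain it.

Composite cohort statistics (−7/7q−, −5/−5q, −17/−17p) count a patient when
any clone shows the whole-chromosome loss *or* a segmental deletion on the
named arm. By default CNV-style statistics (and marker, chromosome-11/18
involvement, multiple-RC rates) are reported over the complex-karyotype
subset — the convention of complex-karyotype cohort tables — while
complexity and ring-origin tables use the whole cohort; every statistic
carries its count and denominator explicitly, and the denominator rule is
overridable per statistic.

## Candidate-somatic filter and mutation typing

The filter is the conjunction of VAF ≥ 1%, ≥ 2 alternate reads on each
strand, mean alternate-base Qscore ≥ 11, and both curation flags (known
cancer-associated; predicted damaging). Each rejected variant carries reason
codes (`vaf`, `strand_fwd`, `strand_rev`, `qscore`, `not_known_cancer`,
`not_damaging`, or `missing:<field>` when a QC field is absent). The filter
is idempotent; a kept variant marks its patient mutated regardless of VAF
above the floor (no clonality weighting).

Mutation types are read from the `p.` string by token rules: `fs` →
frameshift (including `fs*N`), terminal `*`/`Ter` → nonsense, single-residue
X→Y substitution (one- or three-letter code) → missense, `del` without `fs`
→ in-frame deletion, an intron/splice effect annotation → splice_or_intron,
anything unparseable → other. Genomic coordinates are opaque identifiers —
no liftover or re-annotation — so mutation uniqueness is keyed on the
literal `g.` string.

TP53 domain boundaries are not standardized to the residue; the package
adopts transactivation 1–61, proline-rich 62–93, DNA-binding 94–292, NLS
293–322, tetramerization 323–355, regulatory 356–393 on the canonical 393-aa
protein, overridable via the bounds table argument.

## TP53 copy-number-loss inference

Per distinct chromosome-17 event, with the TP53 locus at 17p13.1:

| event | call |
|---|---|
| −17 | loss (monosomy17) |
| del(17)(p b) terminal, b at/proximal to p13.1 | loss (del17p) |
| del(17)(p b1 p b2) spanning p13.1 | loss (del17p) |
| add(17)(p b), b at/proximal to p13.1 | loss (add17p) |
| add(17)(p b), b distal or `p?` | ambiguous (add17p) |
| i(17)(q10) / idic(17)(p…) | loss (i17q / idic17) |
| der/dic involving 17 with a p breakpoint at/proximal to p13.1 | loss (der17/dic17) |
| der/dic involving 17, no informative p breakpoint | ambiguous |
| balanced t, inv, dup, q-arm events, non-covering deletions | no contribution |

Ambiguity is deliberate where unknown-origin material may retain p13.1; such
cases are what locus FISH resolves in practice. Calls aggregate over clones
(any loss dominates, then any ambiguity, else no evidence) and are invariant
to clone order and non-17 events. When several loss mechanisms co-occur the
reported mechanism follows a fixed precedence (monosomy17 > add17p > der17 >
dic17 > del17p > i17q > idic17) so each patient is counted once in the
census; the precedence is an artifact convention, exposed as a constant. The
census reports percentages over both the loss subset and all submitted
patients, since both denominators are legitimate depending on the question.

FISH patterns are parsed as `<count><R|G>[dim]` runs (`dim` binds to the
preceding count; R = TP53 probe, G = centromere 17). Interpretation: any dim
signal → abnormal_diminished; otherwise 2R2G (or more) → normal, 1R1G →
monosomy 17, reduced R with disomic centromere → locus loss. Zero centromere
signals is an invalid pattern. Reconciliation lets FISH refine ambiguous or
evidence-free karyotype calls; status agreement is concordant (with
mechanism-level conflicts surfaced in a note, never silently resolved), and
a definite contradiction is reported as discordant with both readings
retained.

## Synthetic cohort generator

The generator emulates the statistical structure of a myeloid RC cohort; it
makes no attempt to model the biological mechanism of ring formation
(chromothripsis etc.), only observed frequencies and co-occurrences.
Defaults are the published cohort rates: complex fraction 0.90 (non-complex
split 5:4 between exactly-three and simple), multiple rings in 17.3% of
complex patients, ring origins 88.9% unknown with the mapped remainder on
chromosomes 7, 6, 3, 2 and 18, markers in 63% and double minutes in 2.2% of
complex patients, NGS available for 64.4%, TP53 mutations in 72% of
sequenced complex patients (one distinct mutation 64% / two 36%), TET2
13.8%, NRAS 12.1%, cytogenetic TP53 CNL in 54% of TP53-mutant patients with
the mechanism mix monosomy 17 0.57 / add(17p) 0.19 / der(17) 0.095 /
dic(17) 0.048 / 17p− 0.05 / i(17q) 0.047, and an 8.2% lymphoid fraction
(forced complex with exactly one unknown-origin ring). Probabilities are
validated to [0, 1] and the ring-origin distribution must sum to 1.

Structural choices that keep the truth ledger noiseless by construction:

- Complex karyotypes draw 4–12 distinct events, exactly-three draws 3,
  simple draws 2 (always including the obligatory ring); fillers resample
  until canonical tokens are distinct.
- Chromosome-17 events are injected only by the CNL-mechanism sampler, and
  random filler events avoid chromosome 17, so the intended CNL mechanism is
  exactly what the pipeline can recover.
- TP53 mutations are assigned only to complex-karyotype patients, mirroring
  the observation that non-complex RC patients lack them; non-complex
  sequenced patients receive TET2 (75%, often biallelic) or the recurrent
  IDH1 p.R132C substitution.
- Breakpoints are drawn from a bundled per-chromosome table of plausible
  major bands (approximate arm maxima, optional sub-band digit); the table
  is intentionally minimal, not an ideogram.
- TP53 spellings mix the recurrent hotspot set (p.R248W/Q/G, p.Y220C,
  p.R273H/L) with synthetic DNA-binding-domain variants; `g.` strings are
  synthetic identifiers, unique within a patient, shared across patients
  when a hotspot recurs.
- Each patient draws from `default_rng([seed, index])`, so cohorts extend
  without reshuffling existing patients and generation is byte-reproducible.
- Mosaicism: one abnormal stemline plus, for some complex patients, an
  `idem` subclone carrying one private event, plus an optional normal clone.
  Cell counts are uniform draws.

Because generation is noiseless, `ledger_recovery_report` requires exact
agreement on every discrete feature (independent-abnormality count,
complexity class, ring count and origins, marker and dmin flags, CNL status
and mechanism) and lists the offending karyotype for any mismatch.

What passing these tests shows — and does not. The generator exercises the
grammar and the counting/inference rules over realistic token combinations,
but its strings are cleaner than diagnostic-laboratory text: real karyotypes
include rarer constructs (three-way translocations, `hsr`, nested derivative
chains, transcription errors) that enter this pipeline as `other` events
rather than typed ones, and real variant tables carry annotation
inconsistencies that the opaque-identifier convention sidesteps rather than
resolves. Recovery of the synthetic ledger therefore validates internal
consistency, not concordance with a human cytogeneticist on arbitrary input.

## Problem sizes and numerical choices

The test suite runs cohorts of 100–500 patients (1,000 for the round-trip
sweep), sizes at which binomial sampling noise on the calibrated fractions
is well inside the exact-binomial 99% bounds used in the calibration check;
all suite randomness is fixed-seed. Percentages are plain `100*count/
denominator` floats; no rounding is applied internally. Degenerate inputs
fail loudly: empty karyotype strings, empty cohorts, zero-centromere FISH
patterns and out-of-range TP53 residues raise rather than default.

## Known limitations

- The ISCN grammar is scoped to hematological karyotypes; `arr`, breakage
  syntax, and full three-way rearrangement semantics are not modelled
  (three-way translocations parse, with chromosomes and breakpoints
  recorded positionally).
- CNL inference is band-resolution only: a deletion or addition whose
  breakpoint band equals the locus band is treated as removing the locus,
  which is the conservative cytogenetic reading but not guaranteed at
  sequence resolution.
- The reproduction of the published cohort's frequency tables requires the
  per-patient appendix tables, which are not redistributed here; the
  corresponding check runs once those tables are transcribed into
  `tests/data/myeloid_cohort/`.
- FISH enters only as signal-pattern strings; image-level analysis, MLPA,
  CMA and sequence-based copy-number inference are out of scope.
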