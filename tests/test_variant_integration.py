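"""Candidate-somatic filtering, mutation typing, stratification and oncoplots."""

import pytest

from ringcyto.variant_integration import (
    MutationType,
    PatientRecord,
    Tp53Domain,
    VariantCall,
    classify_mutation_type,
    filter_candidate_somatic,
    filter_with_reasons,
    mutation_tally,
    oncoplot_matrix,
    stratify_patients,
    tp53_domain_of,
)
from ringcyto.synthetic_cohort import GeneratorConfig, generate_cohort


def make_variant(**overrides) -> VariantCall:
    base = dict(
        gene="TP53",
        genomic_change="g.7577538C>T",
        protein_change="p.R248W",
        vaf=40.0,
        alt_reads_fwd=50,
        alt_reads_rev=50,
        mean_qscore=30.0,
        known_cancer_flag=True,
        damaging_flag=True,
    )
    base.update(overrides)
    return VariantCall(**base)


# One variant per criterion, plus two clean passes: the canonical filter fixture.
def eight_variant_table():
    return [
        make_variant(genomic_change="g.1A>T"),                                  # pass
        make_variant(genomic_change="g.2A>T", vaf=1.0),                         # pass (>= 1 boundary)
        make_variant(genomic_change="g.3A>T", vaf=0.5),                         # fail: VAF
        make_variant(genomic_change="g.4A>T", alt_reads_fwd=1),                 # fail: fwd strand
        make_variant(genomic_change="g.5A>T", vaf=5.0, alt_reads_fwd=10, alt_reads_rev=0),  # fail: rev strand
        make_variant(genomic_change="g.6A>T", mean_qscore=10.9),                # fail: Qscore
        make_variant(genomic_change="g.7A>T", known_cancer_flag=False),         # fail: not in COSMIC/ClinVar
        make_variant(genomic_change="g.8A>T", damaging_flag=False),             # fail: not damaging
    ]


class TestCandidateSomaticFilter:
    def test_keeps_exactly_the_passing_variants_with_reasons(self):
        table = eight_variant_table()
        result = filter_with_reasons(table)
        assert [v.genomic_change for v in result.kept] == ["g.1A>T", "g.2A>T"]
        reasons = {v.genomic_change: r for v, r in result.rejected}
        assert reasons == {
            "g.3A>T": ("vaf",),
            "g.4A>T": ("strand_fwd",),
            "g.5A>T": ("strand_rev",),
            "g.6A>T": ("qscore",),
            "g.7A>T": ("not_known_cancer",),
            "g.8A>T": ("not_damaging",),
        }

    def test_missing_qc_field_rejected_with_reason(self):
        v = make_variant(vaf=None)
        result = filter_with_reasons([v])
        assert not result.kept
        assert result.rejected[0][1] == ("missing:vaf",)

    def test_idempotence(self):
        table = eight_variant_table()
        once = filter_candidate_somatic(table)
        assert filter_candidate_somatic(once) == once

    def test_vaf_bounds_validated(self):
        with pytest.raises(ValueError):
            make_variant(vaf=120.0)


class TestMutationTypeClassification:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("p.R248W", MutationType.missense),
            ("p.Y220C", MutationType.missense),
            ("p.Arg273His", MutationType.missense),
            ("p.Q192*", MutationType.nonsense),
            ("p.R342Ter", MutationType.nonsense),
            ("p.N131fs", MutationType.frameshift),
            ("p.P58fs*10", MutationType.frameshift),  # fs wins over downstream stop
            ("p.I255del", MutationType.inframe_del),
            ("garbled//", MutationType.other),
            (None, MutationType.other),
        ],
    )
    def test_token_rules(self, protein, expected):
        v = make_variant(protein_change=protein)
        assert classify_mutation_type(v) is expected

    def test_intron_inclusion_hint(self):
        v = make_variant(protein_change=None, effect_hint="intron inclusion")
        assert classify_mutation_type(v) is MutationType.splice_or_intron


class TestTp53Domains:
    @pytest.mark.parametrize(
        "residue,domain",
        [
            (248, Tp53Domain.dna_binding),
            (273, Tp53Domain.dna_binding),
            (220, Tp53Domain.dna_binding),
            (1, Tp53Domain.transactivation),
            (61, Tp53Domain.transactivation),
            (62, Tp53Domain.proline_rich),
            (300, Tp53Domain.nls),
            (340, Tp53Domain.tetramerization),
            (393, Tp53Domain.regulatory),
        ],
    )
    def test_boundaries(self, residue, domain):
        assert tp53_domain_of(residue) is domain

    @pytest.mark.parametrize("residue", [0, -3, 394])
    def test_out_of_range(self, residue):
        with pytest.raises(ValueError):
            tp53_domain_of(residue)


def _patient(pid, variants, has_ngs=True):
    return PatientRecord(
        patient_id=pid, variants=tuple(variants) if has_ngs else None
    )


class TestStratification:
    def test_overlapping_groups_and_no_tp53_partition(self):
        p1 = _patient("A", [make_variant(gene="NRAS", genomic_change="g.n1A>T"),
                            make_variant(genomic_change="g.t1A>T")])
        p2 = _patient("B", [make_variant(gene="TET2", genomic_change="g.e1A>T"),
                            make_variant(gene="TET2", genomic_change="g.e2A>T")])
        p3 = _patient("C", [])          # sequenced, nothing kept
        p4 = _patient("D", [], has_ngs=False)  # no NGS data
        groups = stratify_patients([p1, p2, p3, p4], ["TP53", "TET2", "NRAS"])
        ids = {g: [p.patient_id for p in ps] for g, ps in groups.items()}
        assert ids["TP53"] == ["A"]
        assert ids["NRAS"] == ["A"]
        assert ids["TET2"] == ["B"]  # two TET2 variants count the patient once
        assert ids["no_TP53"] == ["B", "C"]
        sequenced = {"A", "B", "C"}
        assert set(ids["TP53"]) | set(ids["no_TP53"]) == sequenced
        assert not set(ids["TP53"]) & set(ids["no_TP53"])

    def test_filter_applied_before_grouping(self):
        failing = make_variant(vaf=0.2, genomic_change="g.low1A>T")
        groups = stratify_patients([_patient("A", [failing])], ["TP53"])
        assert [p.patient_id for p in groups["no_TP53"]] == ["A"]


class TestMutationTally:
    def test_shared_mutation_counts_total_and_unique(self):
        shared = dict(gene="IDH1", genomic_change="g.209113113G>A", protein_change="p.R132C")
        cohort = [
            _patient("A", [make_variant(**shared)]),
            _patient("B", [make_variant(**shared)]),
        ]
        tally = mutation_tally(cohort, gene="IDH1")
        assert (tally.n_mutations, tally.n_unique) == (2, 1)
        assert tally.per_type == {"missense": 2}

    def test_empty_cohort_all_zero(self):
        tally = mutation_tally([], gene="TP53")
        assert (tally.n_mutations, tally.n_unique, tally.n_patients_mutated) == (0, 0, 0)
        assert tally.per_type == {}

    def test_multiplicity_histogram(self):
        one = _patient("A", [make_variant(genomic_change="g.x1A>T")])
        two = _patient("B", [make_variant(genomic_change="g.x2A>T"),
                             make_variant(genomic_change="g.x3A>T")])
        tally = mutation_tally([one, two])
        assert tally.multiplicity_histogram == {1: 1, 2: 1}

    def test_type_counts_sum_to_total(self, small_cohort):
        _, records, _ = small_cohort
        tally = mutation_tally(records)
        assert sum(tally.per_type.values()) == tally.n_mutations

    def test_matches_generator_ledger(self, small_cohort):
        _, records, ledger = small_cohort
        tally = mutation_tally(records, gene="TP53")
        expected_total = 0
        expected_unique = set()
        expected_patients = 0
        for entry in ledger:
            kept = entry["kept_variants"] or []
            tp53 = {v["genomic_change"] for v in kept if v["gene"] == "TP53"}
            expected_total += len(tp53)
            expected_unique |= tp53
            expected_patients += bool(tp53)
        assert tally.n_mutations == expected_total
        assert tally.n_unique == len(expected_unique)
        assert tally.n_patients_mutated == expected_patients


class TestOncoplotMatrix:
    def test_single_patient_single_gene(self):
        m = oncoplot_matrix([_patient("A", [make_variant()])], ["TP53"])
        assert m.shape == (1, 1)
        assert m.loc["A", "TP53"] == "missense"

    def test_multi_hit_cell_carries_both_labels(self):
        p = _patient("A", [make_variant(genomic_change="g.a1A>T"),
                           make_variant(genomic_change="g.a2A>T", protein_change="p.Q192*")])
        m = oncoplot_matrix([p], ["TP53"])
        assert m.loc["A", "TP53"] == "missense;nonsense"

    def test_invariant_to_patient_order(self, small_cohort):
        _, records, _ = small_cohort
        genes = ["TP53", "TET2", "NRAS", "DNMT3A"]
        forward = oncoplot_matrix(records, genes)
        backward = oncoplot_matrix(list(reversed(records)), genes)
        assert forward.equals(backward)

    def test_columns_ordered_by_mutated_patient_count(self):
        cohort = [
            _patient("A", [make_variant(gene="TET2", genomic_change="g.q1A>T")]),
            _patient("B", [make_variant(gene="TET2", genomic_change="g.q2A>T")]),
            _patient("C", [make_variant(genomic_change="g.q3A>T")]),
        ]
        m = oncoplot_matrix(cohort, ["TP53", "TET2"])
        assert list(m.columns) == ["TET2", "TP53"]
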