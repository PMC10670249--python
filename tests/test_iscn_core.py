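"""ISCN parser, serializer and band-ordering behaviour."""

import re
from functools import cmp_to_key

import pytest
from hypothesis import given, settings, strategies as st

from ringcyto.iscn_core import (
    Abnormality,
    AbnormalityKind,
    BandAddress,
    IscnParseError,
    compare_bands,
    modal_number,
    parse_karyotype,
    serialize_karyotype,
)
from ringcyto.synthetic_cohort import GeneratorConfig, generate_cohort


class TestParsing:
    def test_single_clone_loss_and_ring(self):
        k = parse_karyotype("46,XY,−7,+r")
        (clone,) = k.clones
        assert modal_number(clone) == 46
        assert clone.sex_designation == "XY"
        kinds = [a.kind for a in clone.abnormalities]
        assert kinds == [AbnormalityKind.whole_loss, AbnormalityKind.ring_unknown]
        assert clone.abnormalities[0].chromosomes == ("7",)

    def test_normal_karyotype_identity(self):
        k = parse_karyotype("46,XX[15]")
        (clone,) = k.clones
        assert clone.is_normal
        assert clone.cell_count == 15
        assert clone.abnormalities == ()

    def test_mosaic_three_clone_karyotype(self):
        k = parse_karyotype(
            "46,XX,r(18)(p11.3q23)[2]/46,XX,t(7;17) (q36;q21)[2]/46,XX[15]"
        )
        assert len(k.clones) == 3
        ring = k.clones[0].abnormalities[0]
        assert ring.kind is AbnormalityKind.ring_derived
        assert ring.chromosomes == ("18",)
        assert [str(b) for b in ring.breakpoints] == ["18p11.3", "18q23"]
        trans = k.clones[1].abnormalities[0]
        assert trans.kind is AbnormalityKind.t
        assert trans.chromosomes == ("7", "17")
        assert [str(b) for b in trans.breakpoints] == ["7q36", "17q21"]
        assert [c.cell_count for c in k.clones] == [2, 2, 15]
        assert k.clones[2].is_normal

    @pytest.mark.parametrize(
        "text,expected_modal",
        [("48,XX,+4,+r", 48), ("46,XY", 46), ("45,XX,−7", 45), ("41~44,XX,+r", (41, 44))],
    )
    def test_modal_number(self, text, expected_modal):
        assert modal_number(parse_karyotype(text).clones[0]) == expected_modal

    def test_derivative_records_all_chromosomes(self):
        a = parse_karyotype("46,XY,der(5)t(5;17)(p11;q11)").clones[0].abnormalities[0]
        assert a.kind is AbnormalityKind.der
        assert set(a.chromosomes) == {"5", "17"}

    def test_uncertain_tokens_are_kept_not_dropped(self):
        k = parse_karyotype("46,XX,add(7)(q?),?del(5)(q13),zzz(9),+r")
        kinds = [a.kind for a in k.clones[0].abnormalities]
        assert kinds[:2] == [AbnormalityKind.add, AbnormalityKind.del_]
        assert kinds[2] is AbnormalityKind.other
        assert all(a.uncertain for a in k.clones[0].abnormalities[:3])

    def test_copy_multiplier_and_dmin(self):
        k = parse_karyotype("47,XX,+marx2,12dmin,+r")
        abns = {a.kind: a for a in k.clones[0].abnormalities}
        assert abns[AbnormalityKind.mar].copies == 2
        assert abns[AbnormalityKind.dmin].copies == 12

    def test_idem_expansion_superset(self):
        k = parse_karyotype("45,XX,-7[10]/46,XX,idem,+8[5]")
        stem, sub = k.clones
        stem_tokens = {a.base_token for a in stem.abnormalities}
        sub_tokens = {a.base_token for a in sub.abnormalities}
        assert stem_tokens <= sub_tokens
        assert sub.n_inherited == 1
        # inherited events precede clone-private ones
        assert sub.abnormalities[0].base_token == "-7"

    def test_composite_and_incomplete_flags(self):
        k = parse_karyotype("42~46,XX,del(5)(q13),+r,inc[cp9]")
        assert k.incomplete
        assert k.clones[0].composite
        assert k.clones[0].cell_count == 9

    @pytest.mark.parametrize("bad", ["", "   ", None])
    def test_empty_input_is_usage_error(self, bad):
        with pytest.raises(IscnParseError):
            parse_karyotype(bad)

    def test_bad_ploidy_field_names_offender(self):
        with pytest.raises(IscnParseError, match="4x"):
            parse_karyotype("4x,XX,+r")


class TestSerialization:
    def test_canonical_hyphen(self):
        assert serialize_karyotype(parse_karyotype("46,XY,−7,+r")) == "46,XY,-7,+r"

    def test_normal_clone_with_cells(self):
        assert serialize_karyotype(parse_karyotype("46,XX[15]")) == "46,XX[15]"

    def test_sign_robustness(self):
        ascii_form = "46,XY,-7,+r/45,XY,-7,-18[3]"
        unicode_form = ascii_form.replace("-", "−")
        assert parse_karyotype(ascii_form) == parse_karyotype(unicode_form)

    def test_canonical_sort_orders_sex_first_then_chromosome(self):
        k = parse_karyotype("46,XY,+8,del(5)(q13),-Y,+r,t(2;3)(q21;q25)")
        out = serialize_karyotype(k, sort=True)
        assert out == "46,XY,-Y,t(2;3)(q21;q25),del(5)(q13),+8,+r"

    def test_round_trip_on_generated_cohort(self):
        """parse(serialize(k)) == k over a seeded generator sample."""
        records, _ = generate_cohort(GeneratorConfig(n_patients=150, seed=11))
        for r in records:
            k = r.karyotype
            assert parse_karyotype(serialize_karyotype(k)) == k

    def test_cell_count_conservation(self):
        records, _ = generate_cohort(GeneratorConfig(n_patients=100, seed=3))
        for r in records:
            text = serialize_karyotype(r.karyotype)
            in_string = sum(int(m) for m in re.findall(r"\[(?:cp)?(\d+)\]", text))
            in_model = sum(c.cell_count or 0 for c in r.karyotype.clones)
            assert in_string == in_model


class TestBandOrdering:
    def test_p_arm_proximal_distal(self):
        p11_2 = BandAddress("17", "p", "11.2")
        p13_1 = BandAddress("17", "p", "13.1")
        # p11.2 is proximal (closer to the centromere): it sorts after p13.1
        assert compare_bands(p13_1, p11_2) == -1
        assert compare_bands(p11_2, p13_1) == 1
        assert compare_bands(p13_1, BandAddress("17", "p", "13.1")) == 0

    def test_sort_matches_enumerated_order(self):
        # 17p bands enumerated distal (pter) to proximal (centromere)
        enumerated = ["13.3", "13.2", "13.1", "13", "12", "11.2", "11.1", "11"]
        addrs = [BandAddress("17", "p", b) for b in enumerated]
        shuffled = addrs[::-1]
        ordered = sorted(shuffled, key=cmp_to_key(compare_bands))
        assert [a.band for a in ordered] == enumerated
        # q arm runs proximal to distal
        q = ["11.1", "11.2", "12", "21", "21.3", "22", "25.1"]
        q_addrs = [BandAddress("17", "q", b) for b in q]
        assert [a.band for a in sorted(q_addrs[::-1], key=cmp_to_key(compare_bands))] == q

    def test_cross_arm_comparison_is_domain_error(self):
        with pytest.raises(ValueError):
            compare_bands(BandAddress("17", "p", "11"), BandAddress("17", "q", "11"))
        with pytest.raises(ValueError):
            compare_bands(BandAddress("17", "p", "11"), BandAddress("5", "p", "11"))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(1, 36), st.integers(0, 3)).map(
                lambda t: f"{t[0]}.{t[1]}" if t[1] else str(t[0])
            ),
            min_size=2,
            max_size=6,
            unique=True,
        ),
        st.sampled_from(["p", "q"]),
    )
    def test_total_order_properties(self, bands, arm):
        addrs = [BandAddress("1", arm, b) for b in bands]
        for a in addrs:
            for b in addrs:
                assert compare_bands(a, b) == -compare_bands(b, a)
                if a.band == b.band:
                    assert compare_bands(a, b) == 0
        ordered = sorted(addrs, key=cmp_to_key(compare_bands))
        for x, y in zip(ordered, ordered[1:]):
            assert compare_bands(x, y) <= 0

    def test_band_serialization_round_trip(self):
        for b in ("11.3", "13.1", "23", "10"):
            addr = BandAddress("7", "q", b)
            assert str(addr) == f"7q{b}"
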