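import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdrphylo.haplotypes import (
    ALLELE_CLASSES,
    FragmentLayout,
    HaplotypeCatalog,
    LayoutError,
    assign_names,
    build_record,
    classify_allele,
    extract_features,
    group_by_intron,
    translate_codon,
)


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon,aa",
        [
            ("ATG", "M"),
            ("TTT", "F"),
            ("TTA", "L"),
            ("CAT", "H"),
            ("ACG", "T"),
            ("CAY", "H"),   # CAT/CAC both His
            ("TTY", "F"),   # TTT/TTC both Phe
            ("TAA", "*"),
            ("ATN", "?"),   # resolutions disagree
            ("A-G", "?"),   # gap
        ],
    )
    def test_standard_code_and_ambiguity(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_length_and_character_errors(self):
        with pytest.raises(ValueError):
            translate_codon("AT")
        with pytest.raises(ValueError):
            translate_codon("AXG")


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "aa918,aa1014,cls",
        [
            ("M", "L", "susceptible"),
            ("M", "F", "kdr"),
            ("M", "H", "kdr-his"),
            ("T", "F", "super-kdr"),
            ("T", "L", "other"),
            ("?", "F", "other"),
            ("?", "?", "other"),
            ("L", "L", "other"),
        ],
    )
    def test_mapping(self, aa918, aa1014, cls):
        assert classify_allele(aa918, aa1014) == cls

    @given(
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY?*"),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY?*"),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_function_onto_known_classes(self, a, b):
        assert classify_allele(a, b) in ALLELE_CLASSES


class TestLayout:
    def test_canonical_geometry_enforced(self):
        with pytest.raises(LayoutError):
            FragmentLayout(
                codon1014_offset=0, intron_start=5, intron_end=10,
                canonical_geometry=True,
            )
        FragmentLayout(
            codon1014_offset=0, intron_start=6, intron_end=10,
            canonical_geometry=True,
        )

    def test_out_of_bounds_is_config_error(self):
        lay = FragmentLayout(codon1014_offset=0, intron_start=6, intron_end=40)
        with pytest.raises(LayoutError):
            extract_features("ACGTACGTACGT", lay)


class TestExtractFeatures:
    def test_codons_read_from_offsets(self):
        lay = FragmentLayout(codon1014_offset=0, intron_start=6, intron_end=30)
        seq = "TTA" + "GGA" + "ACGT" * 6
        aa918, aa1014, intron = extract_features(seq, lay)
        assert aa1014 == "L"
        assert aa918 == "?"  # no codon-918 fragment in this layout
        assert intron == seq[6:30]

    def test_his_codon(self):
        lay = FragmentLayout(codon1014_offset=0, intron_start=6, intron_end=30)
        seq = "CAT" + "GGA" + "ACGT" * 6
        assert extract_features(seq, lay)[1] == "H"

    def test_intron_keeps_alignment_gaps(self):
        lay = FragmentLayout(codon1014_offset=0, intron_start=6, intron_end=14)
        seq = "TTAGGAAC--GTAC"
        assert extract_features(seq, lay)[2] == "AC--GTAC"


class TestGroupByIntron:
    def test_table1_grouping(self, table1_records):
        groups = group_by_intron(table1_records)
        assert len(groups) == 8
        by_label = {g[0].label: {r.label for r in g} for g in groups}
        assert {"kdr2", "super-kdr1", "kdr-his4", "v39"} in [
            set(x) for x in by_label.values()
        ]

    def test_every_superkdr_paired_with_kdr(self, table1_records):
        for grp in group_by_intron(table1_records):
            classes = {r.allele_class for r in grp}
            if "super-kdr" in classes:
                assert "kdr" in classes

    def test_is_partition(self, table1_records):
        groups = group_by_intron(table1_records)
        flat = [r.label for g in groups for r in g]
        assert sorted(flat) == sorted(r.label for r in table1_records)
        assert len(flat) == len(set(flat))

    def test_single_record(self, table1_records):
        assert len(group_by_intron(table1_records[:1])) == 1


class TestAssignNames:
    def test_discovery_order_numbering(self, table1_records):
        cat = HaplotypeCatalog()
        assign_names(table1_records, cat)
        names = cat.names
        assert names[:5] == ["kdr1", "kdr2", "kdr3", "kdr4", "kdr5"]
        assert "super-kdr3" in names
        assert "v1" in names  # susceptibles numbered from 1 in this catalog

    def test_idempotent_and_order_stable(self, table1_records):
        cat1, cat2 = HaplotypeCatalog(), HaplotypeCatalog()
        assign_names(table1_records, cat1)
        assign_names(table1_records, cat2)
        assert cat1.names == cat2.names
        # resubmission leaves the catalog unchanged
        n = len(cat1)
        assign_names(table1_records, cat1)
        assert len(cat1) == n

    def test_first_susceptible_is_v1(self, table1_layout):
        rec = build_record("x", "ATG" + "TTA" + "GGA" + "A" * 20, table1_layout)
        cat = HaplotypeCatalog()
        assert cat.assign(rec) == "v1"

    @given(picks=st.lists(st.integers(0, 7), min_size=1, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_replay_reproduces_names(self, table1_records, picks):
        seq = [table1_records[i] for i in picks]
        cat1, cat2 = HaplotypeCatalog(), HaplotypeCatalog()
        assign_names(seq, cat1)
        assign_names(seq, cat2)
        assert cat1.names == cat2.names
        assert [r.name for r in seq] == [r.name for r in seq]


def test_round_trip_build_record_deterministic(table1_records, table1_layout):
    rec = table1_records[0]
    again = build_record(rec.label, rec.sequence, table1_layout)
    assert (again.aa918, again.aa1014, again.allele_class) == (
        rec.aa918, rec.aa1014, rec.allele_class,
    )
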