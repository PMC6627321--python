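import pytest
from hypothesis import given, settings, strategies as st

from utrscope.datasets import abca1_context_table, abca1_uorf_table
from utrscope.seqio import TranscriptRecord
from utrscope.upstream_elements import (
    STOP_CODONS,
    Orf,
    OrfConfig,
    census_by_section,
    call_uorfs,
    characterize_uorf,
    classify_context,
    codon_at_offset,
    context_from_window,
    extract_context,
    find_orfs,
    has_inframe_utga,
    scan_codons,
    uorf_geometry,
)

DNA = st.text(alphabet="ACGT", min_size=3, max_size=200)

GROUP_BY_SPECIES = {
    "Human": "primates", "Macaque": "primates", "Mouse lemur": "primates",
    "Rabbit": "rodents", "Mouse": "rodents", "Squirrel": "rodents",
    "Cat": "other_placental", "Armadillo": "other_placental",
    "Tasmanian devil": "marsupials", "Opossum": "marsupials",
    "Platypus": "platypus", "Chicken": "reptiles_birds",
    "Flycatcher": "reptiles_birds", "Anole lizard": "reptiles_birds",
    "Coelacanth": "coelacanth",
}


class TestScanCodons:
    @pytest.mark.parametrize(
        "seq, codon, expected",
        [("ATGATG", "ATG", [1, 4]), ("ATGTGA", "GTG", [3]), ("AAAA", "ATG", [])],
    )
    def test_examples(self, seq, codon, expected):
        assert scan_codons(seq, codon) == expected

    @settings(max_examples=50, deadline=None)
    @given(seq=DNA, codon=st.sampled_from(["ATG", "TGA", "CTG"]))
    def test_matches_bruteforce_window_scan(self, seq, codon):
        brute = [
            i + 1
            for i in range(len(seq) - 2)
            if seq[i] == codon[0] and seq[i + 1] == codon[1] and seq[i + 2] == codon[2]
        ]
        assert scan_codons(seq, codon) == brute


class TestCensus:
    def test_junction_split_by_first_base(self):
        rec = TranscriptRecord(
            id="x", seq="ATGTAACCC", utr5_len=6, intron1_offset=3
        )
        census = census_by_section(rec)
        assert census.count("ATG", "before") == 1
        assert census.count("TAA", "after") == 1
        assert census.count("ATG", "whole") == 1

    def test_codon_straddling_utr_end_excluded(self):
        # ATG starts at utr5_len - 1: its G lies in the CDS, excluded
        rec = TranscriptRecord(id="x", seq="CCCCATGGG", utr5_len=6)
        assert census_by_section(rec).count("ATG", "whole") == 0

    def test_all_zero_when_absent(self):
        rec = TranscriptRecord(id="x", seq="ACACACACAC", utr5_len=10)
        census = census_by_section(rec)
        assert all(census.count(c, "whole") == 0 for c in census.codons)

    def test_before_plus_after_equals_whole(self, default_family):
        _, records, _, _ = default_family
        for rec in records[:10]:
            census = census_by_section(rec)
            for codon in census.codons:
                assert census.count(codon, "before") + census.count(
                    codon, "after"
                ) == census.count(codon, "whole")

    def test_planted_uatg_counted_in_after_section(self, clean_family):
        _, records, _, truth = clean_family
        for rec in records:
            positions = census_by_section(rec).positions["ATG"]["after"]
            assert truth.records[rec.id].uorf_start in positions


class TestFindOrfs:
    def test_basic_orf_with_stop(self):
        orfs = find_orfs("CCATGAAATGATT")
        assert orfs[0] == Orf(start=3, stop_end=11, has_stop=True)
        assert orfs[0].len_nt == 9

    def test_minimal_orf(self):
        assert find_orfs("ATGTAA") == [Orf(1, 6, True)]

    def test_open_orf_runs_to_last_full_codon(self):
        (orf,) = [o for o in find_orfs("CCATGAAAT") if not o.has_stop]
        assert (orf.start, orf.stop_end) == (3, 8)

    def test_min_len_filter(self):
        assert find_orfs("ATGTAA", OrfConfig(min_len_nt=7)) == []

    def test_alternate_start_codons(self):
        orfs = find_orfs("GTGTAA", OrfConfig(start_codons=("GTG",)))
        assert orfs == [Orf(1, 6, True)]

    @settings(max_examples=300, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=60))
    def test_matches_exhaustive_enumeration(self, seq):
        expected = []
        for start in range(1, len(seq) - 1):
            if seq[start - 1 : start + 2] != "ATG":
                continue
            stop_end, has_stop = None, False
            for i in range(start + 2, len(seq) - 2, 3):
                if seq[i : i + 3] in STOP_CODONS:
                    stop_end, has_stop = i + 3, True
                    break
            if not has_stop:
                stop_end = start + 3 * ((len(seq) - start + 1) // 3) - 1
            expected.append((start, stop_end, has_stop))
        got = [(o.start, o.stop_end, o.has_stop) for o in find_orfs(seq)]
        assert got == sorted(expected)


class TestUorfGeometry:
    @pytest.mark.parametrize(
        "start, stop, morf, len_nt, len_aa, gap, overlaps",
        [
            (307, 417, 396, 111, 36, -22, True),  # human
            (224, 319, 321, 96, 31, 1, False),  # mouse
            (245, 274, 297, 30, 9, 22, False),  # coelacanth
        ],
    )
    def test_reference_coordinates(
        self, start, stop, morf, len_nt, len_aa, gap, overlaps
    ):
        geom = uorf_geometry(start, stop, morf)
        assert geom["len_nt"] == len_nt
        assert geom["len_aa"] == len_aa
        assert geom["gap_to_morf"] == gap
        assert geom["overlaps_morf"] is overlaps

    def test_rejects_non_upstream_orf(self):
        with pytest.raises(ValueError):
            uorf_geometry(400, 500, 396)

    def test_full_reference_table_is_self_consistent(self):
        for row in abca1_uorf_table().itertuples():
            geom = uorf_geometry(row.uorf_start, row.uorf_stop, row.morf_start)
            assert geom["len_nt"] == row.len_nt
            assert geom["len_aa"] == row.len_aa
            assert len(row.peptide) == row.len_aa

    def test_gap_bands_by_phylogenetic_group(self):
        """Gap bands: rodents/placentals/platypus < 10, birds < 20,
        marsupials/anole/coelacanth in [20, 30]; human and rabbit overlap."""
        for row in abca1_uorf_table().itertuples():
            geom = uorf_geometry(row.uorf_start, row.uorf_stop, row.morf_start)
            gap = geom["gap_to_morf"]
            group = GROUP_BY_SPECIES[row.species]
            if row.species in ("Human", "Macaque", "Mouse lemur", "Rabbit"):
                assert geom["overlaps_morf"]
            elif group in ("rodents", "other_placental", "platypus"):
                assert 0 <= gap < 10
            elif row.species in ("Chicken", "Flycatcher"):
                assert gap < 20
            else:  # marsupials, anole lizard, coelacanth
                assert 20 <= gap <= 30

    def test_characterize_retranslates_peptide(self, clean_family):
        _, records, _, truth = clean_family
        for rec in records[:8]:
            rt = truth.records[rec.id]
            uorfs = call_uorfs(rec)
            planted = [
                u
                for u in uorfs
                if (u.start, u.stop_end) == (rt.uorf_start, rt.uorf_stop_end)
            ]
            assert len(planted) == 1
            u = planted[0]
            assert u.len_nt == u.stop_end - u.start + 1
            assert len(u.peptide) == u.len_aa == u.len_nt // 3 - 1
            assert "*" not in u.peptide
            assert u.peptide[0] == "M"

    def test_characterize_rejects_downstream_orf(self):
        rec = TranscriptRecord(
            id="x", seq="AAATGA" + "ATG" + "AAA", utr5_len=6, morf_start=7
        )
        with pytest.raises(ValueError):
            characterize_uorf(rec, Orf(8, 13, True))


class TestContexts:
    def test_window_layout_and_truncation(self):
        # ATG at position 12 of a 30-nt sequence: full 21-nt window
        seq = "AAACAGTTA" + "ATG" + "ACCAGCCAC" + "GGGGGGGGG"
        ctx = extract_context(seq, 10)
        assert ctx.window == "AAACAGTTAATGACCAGCCAC"
        assert (ctx.minus3, ctx.plus4) == ("T", "A")
        assert ctx.klass == "weak"

    def test_uatg_near_5prime_end_truncates_left(self):
        seq = "TTAATGACCAGCCACAAAA"
        ctx = extract_context(seq, 4)
        assert ctx.window == "TTAATGACCAGCCAC" and len(ctx.window) == 15

    def test_atg_at_position_one_has_no_minus3(self):
        ctx = extract_context("ATGCCCCCCCCCC", 1)
        assert ctx.minus3 is None and ctx.klass == "undetermined"

    def test_requires_atg(self):
        with pytest.raises(ValueError):
            extract_context("AAAAAA", 2)

    @pytest.mark.parametrize(
        "minus3, plus4, klass",
        [
            ("A", "G", "strong"),
            ("G", "G", "strong"),
            ("T", "A", "weak"),
            ("C", "T", "weak"),
            ("A", "A", "adequate"),
            ("T", "G", "adequate"),
        ],
    )
    def test_kozak_classes(self, minus3, plus4, klass):
        window = f"AAAAAA{minus3}AA" + "ATG" + f"{plus4}AAAAAAAA"
        assert context_from_window(window).klass == klass

    def test_reference_morf_contexts(self):
        """sATG contexts: strong from primates to anole, adequate in
        coelacanth; every uATG context is weak."""
        for row in abca1_context_table().itertuples():
            morf = context_from_window(row.morf_context)
            expected = "adequate" if row.species == "Coelacanth" else "strong"
            assert morf.klass == expected, row.species
            assert context_from_window(row.uorf_context).klass == "weak", row.species


class TestCodonAtOffset:
    def test_utga_at_minus9(self):
        # human-style sATG context embedded at morf_start 10
        seq = "TGAGGGAACATGGCTTGTTGG"
        assert codon_at_offset(seq, 10, -9) == "TGA"
        assert has_inframe_utga(seq, 10)

    def test_mouse_like_has_no_utga(self):
        seq = "TGTGGTGACATGGCTTGTTGG"
        assert codon_at_offset(seq, 10, -9) == "TGT"
        assert not has_inframe_utga(seq, 10)

    def test_offsets_are_contiguous(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert codon_at_offset(seq, 10, -3) + codon_at_offset(seq, 10, 0) == seq[6:12]

    def test_window_outside_sequence(self):
        with pytest.raises(ValueError):
            codon_at_offset("ATGAAA", 1, -9)
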