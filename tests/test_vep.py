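"""Consequence-predictor output parsing and derived encodings."""

import pytest

from snvfeat.core import VariantRecord
from snvfeat.vep import (
    AA_ALPHABET,
    ConsequenceVocabulary,
    VepRecord,
    amino_acid_block,
    consequence_onehot,
    distance_stats,
    parse_vep,
    records_for_variant,
)

HEADER = "#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tConsequence\tAmino_acids\tProtein_position\tDISTANCE\tCANONICAL\n"


def write_vep(path, rows):
    path.write_text(HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return path


class TestParse:
    def test_missense_amino_acid_split(self, tmp_path):
        p = write_vep(tmp_path / "v.tsv", [
            ("v0", "chr1:100", "G", "GENE1", "T1", "missense_variant", "R/W", "12", "-", "YES"),
        ])
        (rec,) = parse_vep(p)
        assert rec.variant_key == ("chr1", 99, "G")
        assert (rec.wt_aa, rec.mut_aa) == ("R", "W")
        assert rec.protein_pos == 12 and rec.canonical

    def test_synonymous_single_letter_means_same(self, tmp_path):
        p = write_vep(tmp_path / "v.tsv", [
            ("v0", "chr1:100", "G", "G1", "T1", "synonymous_variant", "L", "3", "-", ""),
        ])
        (rec,) = parse_vep(p)
        assert (rec.wt_aa, rec.mut_aa) == ("L", "L")

    def test_dash_distance_missing(self, tmp_path):
        p = write_vep(tmp_path / "v.tsv", [
            ("v0", "chr1:100", "G", "-", "T1", "intron_variant", "-", "-", "-", ""),
        ])
        (rec,) = parse_vep(p)
        assert rec.distance is None and rec.wt_aa is None

    def test_bad_location_raises_with_line_numbers(self, tmp_path):
        p = write_vep(tmp_path / "v.tsv", [
            ("v0", "not-a-location", "G", "-", "T1", "intron_variant", "-", "-", "10", ""),
        ])
        with pytest.raises(ValueError, match="unmappable"):
            parse_vep(p)


def rec(terms, wt=None, mut=None, dist=None, canonical=False, transcript="T1"):
    return VepRecord(("chr1", 9, "G"), transcript, terms, wt, mut, dist, canonical=canonical)


class TestConsequenceOnehot:
    VOCAB = ConsequenceVocabulary(["missense_variant", "intron_variant", "stop_gained"])

    def test_single_term(self):
        block = consequence_onehot([rec(["missense_variant"])], ("k",), self.VOCAB)
        assert list(block.values.values()) == [1, 0, 0]

    def test_no_records_all_zero(self):
        block = consequence_onehot([], ("k",), self.VOCAB)
        assert set(block.values.values()) == {0}

    def test_multi_hot_union_across_transcripts(self):
        block = consequence_onehot(
            [rec(["missense_variant"]), rec(["intron_variant"], transcript="T2")], ("k",), self.VOCAB
        )
        assert block["missense_variant"] == 1 and block["intron_variant"] == 1
        assert sum(block.values.values()) == 2  # row sum = distinct predicted terms

    def test_unknown_term_ignored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            block = consequence_onehot([rec(["weird_term"])], ("k",), self.VOCAB)
        assert sum(block.values.values()) == 0
        assert "weird_term" in caplog.text


class TestAminoAcidBlock:
    VAR = VariantRecord("chr1", 9, 10, "A", "G")

    def test_onehot_and_bed2(self):
        bed2, block = amino_acid_block([rec([], wt="R", mut="W")], self.VAR)
        assert bed2 == ("chr1", 9, 10, "R", "W")
        assert block["wt_aa_R"] == 1 and block["mut_aa_W"] == 1
        assert sum(block.values.values()) == 2
        assert len(block.values) == 2 * len(AA_ALPHABET)

    def test_synonymous_identity(self):
        _, block = amino_acid_block([rec([], wt="L", mut="L")], self.VAR)
        assert block["wt_aa_L"] == 1 and block["mut_aa_L"] == 1

    def test_non_coding_gives_na_and_zeros(self):
        bed2, block = amino_acid_block([rec([])], self.VAR)
        assert bed2[3:] == ("NA", "NA")
        assert sum(block.values.values()) == 0

    def test_canonical_transcript_wins_conflicts(self, caplog):
        records = [rec([], wt="A", mut="C"), rec([], wt="R", mut="W", canonical=True, transcript="T2")]
        with caplog.at_level("WARNING"):
            _, block = amino_acid_block(records, self.VAR)
        assert block["wt_aa_R"] == 1
        assert "conflicting" in caplog.text

    def test_at_most_one_hot_per_side(self):
        _, block = amino_acid_block([rec([], wt="G", mut="*")], self.VAR)
        wt_sum = sum(v for c, v in block.values.items() if c.startswith("wt_"))
        mut_sum = sum(v for c, v in block.values.items() if c.startswith("mut_"))
        assert wt_sum == 1 and mut_sum == 1
        assert block["mut_aa_stop"] == 1


class TestDistanceStats:
    def test_mean_max_min(self):
        block = distance_stats([rec([], dist=100), rec([], dist=200), rec([], dist=600)], ("k",))
        assert (block["dist_mean"], block["dist_max"], block["dist_min"]) == (300, 600, 100)

    def test_single_distance_collapses(self):
        block = distance_stats([rec([], dist=50)], ("k",))
        assert block["dist_mean"] == block["dist_max"] == block["dist_min"] == 50

    def test_no_distances_all_missing(self):
        block = distance_stats([rec([])], ("k",))
        assert all(v is None for v in block.values.values())

    def test_ordering_invariant(self):
        block = distance_stats([rec([], dist=d) for d in (7, 3, 11, 5)], ("k",))
        assert block["dist_min"] <= block["dist_mean"] <= block["dist_max"]


def test_records_for_variant_matches_on_position_and_alt(tmp_path):
    p = write_vep(tmp_path / "v.tsv", [
        ("v0", "chr1:100", "G", "-", "T1", "intron_variant", "-", "-", "10", ""),
        ("v1", "chr1:200", "T", "-", "T2", "intron_variant", "-", "-", "20", ""),
    ])
    records = parse_vep(p)
    var = VariantRecord("chr1", 99, 100, "A", "G")
    assert [r.transcript for r in records_for_variant(records, var)] == ["T1"]
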