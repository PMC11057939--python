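"""Peak parsing, interval overlap against an oracle, and aggregation."""

import random

import pytest

from snvfeat.core import VariantRecord
from snvfeat.peaks import (
    DEFAULT_ASSAY_GROUPS,
    Peak,
    PeakDB,
    PeakManifest,
    aggregate_block,
    build_peakdb,
    load_peak_manifest,
    overlap_query,
    read_peaks,
)

NARROW_ROW = "chr1\t0\t100\t.\t0\t.\t5.0\t3.0\t2.5\t50\n"


class TestReadPeaks:
    def test_narrow_field_mapping(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(NARROW_ROW)
        (peak,) = read_peaks(p, "narrowPeak")
        assert (peak.signal_value, peak.p_value, peak.q_value, peak.peak) == (5.0, 3.0, 2.5, 50)

    def test_broad_has_no_summit(self, tmp_path):
        p = tmp_path / "a.broadPeak"
        p.write_text("chr1\t0\t100\t.\t0\t.\t5.0\t3.0\t2.5\n")
        (peak,) = read_peaks(p, "broadPeak")
        assert peak.peak == -1

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(NARROW_ROW + "chr1\t0\t100\t.\t0\t.\t5.0\t3.0\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(p, "narrowPeak")

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t-5\t100\t.\t0\t.\t5.0\t3.0\t2.5\t50\n")
        with pytest.raises(ValueError):
            read_peaks(p, "narrowPeak")


class TestBuildDb:
    def test_concatenation_with_metadata(self, tmp_path):
        for i in (1, 2):
            (tmp_path / f"f{i}.narrowPeak").write_text(NARROW_ROW * 3)
        manifest = PeakManifest(rows=[
            (tmp_path / "f1.narrowPeak", "narrowPeak", "ACC1", "CTCF", "K562", "narrow", "dnase"),
            (tmp_path / "f2.narrowPeak", "narrowPeak", "ACC1", "CTCF", "K562", "narrow", "dnase"),
        ])
        dbs = build_peakdb(manifest)
        assert dbs["dnase"].n_peaks == 6  # replicate accessions both indexed
        hit = overlap_query(dbs["dnase"], VariantRecord("chr1", 10, 11, "A", "G"))[0]
        assert (hit.accession, hit.target, hit.biosample) == ("ACC1", "CTCF", "K562")

    def test_empty_manifest(self):
        assert build_peakdb(PeakManifest(rows=[])) == {}

    def test_unknown_group_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="not in configured groups"):
            PeakManifest(rows=[(tmp_path / "x", "narrowPeak", "A", "t", "b", "o", "mystery_assay")])

    def test_manifest_loader(self, tmp_path):
        (tmp_path / "f.narrowPeak").write_text(NARROW_ROW)
        (tmp_path / "m.tsv").write_text(
            "file\tformat\taccession\ttarget\tbiosample\toutput_type\tgroup\n"
            "f.narrowPeak\tnarrowPeak\tACC\tCTCF\tK562\tnarrow\tatac\n"
        )
        manifest = load_peak_manifest(tmp_path / "m.tsv")
        assert manifest.groups == DEFAULT_ASSAY_GROUPS
        assert build_peakdb(manifest)["atac"].n_peaks == 1


class TestOverlap:
    def make_db(self, intervals):
        db = PeakDB(group="g")
        for i, (s, e) in enumerate(intervals):
            db.add(Peak("chr1", s, e, 1.0, -1, -1, -1, order=i))
        return db

    def test_half_open_boundaries(self):
        db = self.make_db([(0, 100)])
        assert len(overlap_query(db, VariantRecord("chr1", 99, 100, "A", "G"))) == 1
        assert overlap_query(db, VariantRecord("chr1", 100, 101, "A", "G")) == []

    def test_matches_linear_scan_on_random_sets(self):
        rng = random.Random(17)
        for _ in range(100):
            intervals = []
            for _ in range(rng.randint(0, 40)):
                s = rng.randint(0, 300)
                intervals.append((s, s + rng.randint(1, 60)))
            db = self.make_db(intervals)
            for _ in range(10):
                pos = rng.randint(0, 360)
                var = VariantRecord("chr1", pos, pos + 1, "A", "G")
                expected = [i for i, (s, e) in enumerate(intervals) if s <= pos < e]
                assert [p.order for p in overlap_query(db, var)] == expected


class TestAggregate:
    def peak(self, signal, p=-1.0, q=-1.0, summit=-1):
        return Peak("chr1", 0, 100, signal, p, q, summit)

    def test_two_values(self):
        block = aggregate_block([self.peak(2.0), self.peak(4.0)], "dnase")
        assert block["dnase_signalValue_min"] == 2.0
        assert block["dnase_signalValue_max"] == 4.0
        assert block["dnase_signalValue_mean"] == 3.0
        assert block["dnase_signalValue_range"] == 2.0
        assert block["dnase_n_peaks"] == 2

    def test_single_match_range_zero(self):
        block = aggregate_block([self.peak(7.0)], "atac")
        assert block["atac_signalValue_min"] == block["atac_signalValue_mean"] == 7.0
        assert block["atac_signalValue_range"] == 0.0

    def test_no_matches(self):
        block = aggregate_block([], "eclip")
        assert block["eclip_n_peaks"] == 0
        assert block["eclip_signalValue_mean"] is None

    def test_sentinels_excluded(self):
        block = aggregate_block([self.peak(1.0, p=3.0), self.peak(2.0, p=-1.0)], "dnase")
        assert block["dnase_pValue_mean"] == 3.0  # -1 excluded, not averaged
        assert block["dnase_peak_offset_mean"] is None

    def test_permutation_invariance_and_identities(self):
        rng = random.Random(4)
        peaks = [self.peak(round(rng.uniform(0, 9), 3), p=round(rng.uniform(0, 9), 3)) for _ in range(8)]
        a = aggregate_block(peaks, "g")
        b = aggregate_block(list(reversed(peaks)), "g")
        assert a.values == b.values
        for f in ("signalValue", "pValue"):
            assert a[f"g_{f}_range"] == a[f"g_{f}_max"] - a[f"g_{f}_min"]
            assert a[f"g_{f}_min"] <= a[f"g_{f}_mean"] <= a[f"g_{f}_max"]
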