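import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliskew import (
    CdsFeature,
    FeatureTable,
    Replicon,
    Strand,
    build_position_labels,
    read_features,
    read_replicons,
    write_features_gff3,
)
from repliskew.genome_io import Topology

from conftest import random_features, random_replicon


class TestReadReplicons:
    def test_case_folding(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">r1\nacgt\n")
        (rep,) = read_replicons(p)
        assert rep.length == 4
        assert rep.sequence == "ACGT"

    def test_two_records_preserve_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">first\nACGT\n>second\nGGCC\n")
        reps = read_replicons(p)
        assert [r.id for r in reps] == ["first", "second"]

    def test_invalid_character_cites_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">r1\nACGTACXGT\n")
        with pytest.raises(ValueError, match="position 7"):
            read_replicons(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_replicons(tmp_path / "nope.fasta")

    def test_empty_record_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">r1\nACGT\n>empty\n")
        with pytest.raises(ValueError, match="empty"):
            read_replicons(p)

    def test_genbank_topology(self, tmp_path):
        gb = (
            "LOCUS       test1                8 bp    DNA     circular BCT 01-JAN-2000\n"
            "DEFINITION  test1, complete genome.\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             2..7\n"
            "ORIGIN\n"
            "        1 acgtacgt\n"
            "//\n"
        )
        p = tmp_path / "a.gb"
        p.write_text(gb)
        (rep,) = read_replicons(p, format="genbank")
        assert rep.topology is Topology.circular
        assert rep.completeness.value == "complete"


class TestReadFeatures:
    def _gff(self, tmp_path, body):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n" + body)
        return p

    def test_coordinate_conversion(self, tmp_path):
        p = self._gff(tmp_path, "r1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c1\n")
        table = read_features(p)
        (f,) = table
        assert (f.start, f.end, f.frame_offset) == (0, 9, 0)
        assert f.strand is Strand.plus

    def test_phase_maps_to_frame_offset(self, tmp_path):
        p = self._gff(tmp_path, "r1\tsrc\tCDS\t1\t9\t.\t-\t2\tID=c1\n")
        (f,) = read_features(p)
        assert f.frame_offset == 2

    def test_unknown_strand_dropped(self, tmp_path):
        body = "r1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=a\nr1\tsrc\tCDS\t11\t19\t.\t.\t0\tID=b\n"
        table = read_features(self._gff(tmp_path, body))
        assert len(table) == 1

    def test_out_of_bounds_dropped_or_strict(self, tmp_path):
        p = self._gff(tmp_path, "r1\tsrc\tCDS\t1\t99\t.\t+\t0\tID=a\n")
        assert len(read_features(p, replicon_lengths={"r1": 50})) == 0
        with pytest.raises(ValueError, match="beyond replicon length"):
            read_features(p, replicon_lengths={"r1": 50}, strict=True)

    def test_malformed_line_cites_lineno(self, tmp_path):
        p = self._gff(tmp_path, "r1\tsrc\tCDS\t1\n")
        with pytest.raises(ValueError, match=":2"):
            read_features(p)

    def test_genbank_complement(self, tmp_path):
        gb = (
            "LOCUS       r1                  30 bp    DNA     linear   BCT 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             complement(4..12)\n"
            "ORIGIN\n"
            "        1 acgtacgtac gtacgtacgt acgtacgtac\n"
            "//\n"
        )
        p = tmp_path / "a.gb"
        p.write_text(gb)
        (f,) = read_features(p, format="genbank")
        assert (f.start, f.end) == (3, 12)
        assert f.strand is Strand.minus

    def test_gff3_round_trip(self, tmp_path, rng):
        table = random_features(rng, 500, 20)
        out = tmp_path / "out.gff3"
        write_features_gff3(table, out)
        again = read_features(out)
        assert list(table) == list(again)


class TestBuildPositionLabels:
    def test_plus_strand_codon_labels(self):
        rep = Replicon("r", "ACGTAC")
        table = FeatureTable([CdsFeature("r", 0, 6, Strand.plus, 0)])
        labels = build_position_labels(rep, table)
        assert labels.codon_label.tolist() == [1, 2, 3, 1, 2, 3]

    def test_minus_strand_codon_labels(self):
        rep = Replicon("r", "ACGTAC")
        table = FeatureTable([CdsFeature("r", 0, 6, Strand.minus, 0)])
        labels = build_position_labels(rep, table)
        assert labels.codon_label.tolist() == [3, 2, 1, 3, 2, 1]

    def test_frame_offset_skips_leading_bases(self):
        rep = Replicon("r", "ACGTACGT")
        table = FeatureTable([CdsFeature("r", 0, 8, Strand.plus, 2)])
        labels = build_position_labels(rep, table)
        assert labels.codon_label.tolist() == [0, 0, 1, 2, 3, 1, 2, 3]

    def test_strand_cover(self, small_replicon, small_features):
        labels = build_position_labels(small_replicon, small_features)
        assert labels.strand_cover[:12].tolist() == [1] * 12
        assert labels.strand_cover[12:18].tolist() == [0] * 6
        assert labels.strand_cover[18:30].tolist() == [-1] * 12

    def test_opposite_strand_overlap_gives_zero_cover(self):
        rep = Replicon("r", "A" * 20)
        table = FeatureTable(
            [
                CdsFeature("r", 0, 12, Strand.plus, 0),
                CdsFeature("r", 6, 18, Strand.minus, 0),
            ]
        )
        labels = build_position_labels(rep, table)
        assert labels.strand_cover[6:12].tolist() == [0] * 6
        assert labels.strand_cover[:6].tolist() == [1] * 6
        assert labels.strand_cover[12:18].tolist() == [-1] * 6

    def test_out_of_bounds_feature(self):
        rep = Replicon("r", "ACGT")
        with pytest.raises(ValueError, match="out of bounds"):
            build_position_labels(
                rep, FeatureTable([CdsFeature("r", 0, 9, Strand.plus, 0)])
            )

    def test_id_mismatch(self):
        rep = Replicon("r", "ACGTACGT")
        with pytest.raises(ValueError, match="unknown replicon"):
            build_position_labels(
                rep, FeatureTable([CdsFeature("other", 0, 6, Strand.plus, 0)])
            )

    @staticmethod
    def _brute_force_labels(length, feats):
        """Independent per-position labeler applying the priority rule."""
        out = np.zeros(length, dtype=int)
        for p in range(length):
            candidates = []
            for f in feats:
                if not f.labels_codons:
                    continue
                if f.strand is Strand.plus:
                    lo, hi = f.start + f.frame_offset, f.end
                    if lo <= p < hi:
                        candidates.append((f, 1 + (p - lo) % 3))
                else:
                    lo, hi = f.start, f.end - f.frame_offset
                    if lo <= p < hi:
                        candidates.append((f, 1 + (hi - 1 - p) % 3))
            if candidates:
                best = max(candidates, key=lambda c: (len(c[0]), -c[0].start))
                out[p] = best[1]
        return out

    def test_overlap_priority_matches_brute_force(self, rng):
        for _ in range(20):
            length = int(rng.integers(30, 120))
            table = random_features(rng, length, int(rng.integers(1, 8)))
            rep = random_replicon(rng, length)
            labels = build_position_labels(rep, table)
            expected = self._brute_force_labels(length, list(table))
            np.testing.assert_array_equal(labels.codon_label, expected)

    def test_longer_feature_wins_on_same_strand_overlap(self):
        rep = Replicon("r", "A" * 30)
        long = CdsFeature("r", 4, 25, Strand.plus, 0)
        short = CdsFeature("r", 10, 20, Strand.plus, 0)
        labels = build_position_labels(rep, FeatureTable([short, long]))
        expected = self._brute_force_labels(30, [short, long])
        np.testing.assert_array_equal(labels.codon_label, expected)
        # the long feature's frame defines positions 10..20
        assert labels.codon_label[10] == 1 + (10 - 4) % 3

    def test_codon_count_balance_property(self, rng):
        # single CDS with length divisible by 3 has equal 1/2/3 counts
        for frame in (0, 1, 2):
            length = 60
            end = 3 + frame + 45
            table = FeatureTable([CdsFeature("rand", 3, end, Strand.plus, frame)])
            rep = random_replicon(rng, length)
            labels = build_position_labels(rep, table)
            counts = [int((labels.codon_label == k).sum()) for k in (1, 2, 3)]
            assert counts[0] == counts[1] == counts[2] == 15

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_strand_cover_sum_matches_set_computation(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(20, 100))
        table = random_features(rng, length, int(rng.integers(0, 6)))
        rep = random_replicon(rng, length)
        labels = build_position_labels(rep, table)
        plus = set()
        minus = set()
        for f in table:
            (plus if f.strand is Strand.plus else minus).update(range(f.start, f.end))
        expected = len(plus - minus) - len(minus - plus)
        assert int(labels.strand_cover.sum()) == expected
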