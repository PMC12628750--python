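from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pentaplex.longread_decompose import (
    LongReadRecord,
    Strand,
    consensus_structure,
    count_motifs,
    detect_miscall_artifact,
    extract_region_reads,
    filter_wildtype,
    segment_read,
    waterfall,
    waterfall_table,
)
from pentaplex.repeat_model import (
    ConfigurationError,
    RepeatMotif,
    canonical_key,
    config_to_sequence,
    parse_config,
    reverse_complement,
)
from pentaplex.simulate import random_flank

from .conftest import COMPOSITE, FAME3_REGION, PENTAMERS, RP_PRIMER

MOTIFS = [RepeatMotif(m) for m in ("TTTTA", "TTTCA", "TTGTA")]


def make_table(rows):
    return pd.DataFrame(rows, columns=["read_id", "seq", "contig", "start", "end", "strand"])


class TestExtractRegionReads:
    def test_overlap_included(self):
        table = make_table([("r1", "ACGTACGT", "chr5", 10356300, 10356500, "+")])
        recs = extract_region_reads(table, FAME3_REGION)
        assert [r.read_id for r in recs] == ["r1"]
        assert recs[0].mapped_strand is Strand.FORWARD

    def test_left_of_region_excluded(self):
        table = make_table([("r1", "ACGTACGT", "chr5", 10356000, 10356338, "+")])
        assert extract_region_reads(table, FAME3_REGION) == []

    def test_reverse_strand_reverse_complemented(self):
        seq = "AACCGGTTAA"
        table = make_table([("r1", seq, "chr5", 10356300, 10356500, "-")])
        recs = extract_region_reads(table, FAME3_REGION)
        assert recs[0].seq == reverse_complement(seq)
        assert recs[0].mapped_strand is Strand.REVERSE

    def test_absent_contig_warns_and_returns_empty(self, caplog):
        table = make_table([("r1", "ACGT", "chr7", 1, 100, "+")])
        with caplog.at_level("WARNING"):
            assert extract_region_reads(table, FAME3_REGION) == []
        assert "absent" in caplog.text


class TestCountMotifs:
    def test_primer_has_six_tandem_ttgta_copies(self):
        rec = LongReadRecord("primer", RP_PRIMER)
        counts = count_motifs(rec, [RepeatMotif("TTGTA")])
        assert counts.per_motif_copies[canonical_key("TTGTA")] == Fraction(6)

    def test_synthesized_four_block_configuration(self):
        cfg = parse_config(
            "(TTTTA)100-(TTTCA)100-(TTTTA)100-(TTGTA)100",
            left_flank="G" * 50,
            right_flank="C" * 50,
        )
        rec = LongReadRecord("r", config_to_sequence(cfg))
        counts = count_motifs(rec, MOTIFS)
        copies = {k: float(v) for k, v in counts.per_motif_copies.items()}
        # junction bleed of maximal runs is < 1 copy per junction
        assert copies[canonical_key("TTTTA")] == pytest.approx(200, abs=2)
        assert copies[canonical_key("TTTCA")] == pytest.approx(100, abs=2)
        assert copies[canonical_key("TTGTA")] == pytest.approx(100, abs=2)
        # 4 blocks x 100 copies x 5 bp
        assert counts.total_repeat_bp == 2000

    def test_flank_only_read(self):
        rec = LongReadRecord("r", random_flank(300, rng=np.random.default_rng(3)))
        counts = count_motifs(rec, MOTIFS)
        assert counts.total_repeat_bp < 10
        assert all(v < 2 for v in counts.per_motif_copies.values())


class TestFilterWildtype:
    def _rec(self, total):
        return count_motifs(
            LongReadRecord("r", ("TTGTA" * (total // 5 + 1))[:total] + "G" * 20), MOTIFS
        )

    def test_partition_by_threshold(self):
        recs = [self._rec(40), self._rec(900), self._rec(4500)]
        kept = filter_wildtype(recs)
        assert [r.total_repeat_bp for r in kept] == [900, 4500]

    def test_exactly_800_kept(self):
        kept = filter_wildtype([self._rec(800)])
        assert len(kept) == 1  # "<800" is strict

    def test_799_removed(self):
        assert filter_wildtype([self._rec(799)]) == []

    def test_empty_input(self):
        assert filter_wildtype([]) == []

    def test_partition_is_exact(self, rng):
        totals = [int(t) for t in rng.integers(0, 5000, size=40)]
        recs = [self._rec(t) for t in totals]
        kept = filter_wildtype(recs)
        assert [r.total_repeat_bp for r in kept] == [
            r.total_repeat_bp for r in recs if r.total_repeat_bp >= 800
        ]


class TestDetectMiscallArtifact:
    def _read(self, ttcca_copies, tttca_copies, strand):
        seq = "TTCCA" * ttcca_copies + "TTTCA" * tttca_copies
        return LongReadRecord("r", seq, strand)

    def test_reverse_strand_majority_ttcca_flagged(self):
        assert detect_miscall_artifact(self._read(80, 20, Strand.REVERSE), None)

    def test_forward_strand_never_flagged(self):
        assert not detect_miscall_artifact(self._read(80, 20, Strand.FORWARD), None)

    def test_reverse_strand_minor_ttcca_not_flagged(self):
        assert not detect_miscall_artifact(self._read(10, 90, Strand.REVERSE), None)

    def test_unknown_strand_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert not detect_miscall_artifact(self._read(80, 20, Strand.UNKNOWN), None)
        assert "unknown strand" in caplog.text

    def test_artifact_motif_must_be_in_supplied_set(self):
        with pytest.raises(ConfigurationError):
            detect_miscall_artifact(self._read(80, 20, Strand.REVERSE), MOTIFS)

    def test_no_repeat_read_not_flagged(self):
        rec = LongReadRecord("r", "GA" * 100, Strand.REVERSE)
        assert not detect_miscall_artifact(rec, None)


class TestSegmentRead:
    def test_clean_four_block_round_trip(self):
        text = "(TTTTA)100-(TTTCA)95-(TTTTA)100-(TTGTA)120"
        seg = segment_read(config_to_sequence(parse_config(text)), MOTIFS)
        assert seg.structure_string == text
        assert seg.unassigned_bp == 0

    def test_clean_round_trip_with_flanks(self):
        rng = np.random.default_rng(5)
        cfg = parse_config(
            "(TTTTA)50-(TTGTA)300",
            left_flank=random_flank(400, rng=rng),
            right_flank=random_flank(400, rng=rng),
        )
        seg = segment_read(config_to_sequence(cfg), MOTIFS)
        assert [b.motif.display for b in seg.blocks] == ["TTTTA", "TTGTA"]
        # random flank edges can be in phase with the first/last block
        # (e.g. ...GTA|TTTTA contains rotation TATTT), so allow 1 copy of fuzz
        assert seg.blocks[0].copies == pytest.approx(50, abs=1)
        assert seg.blocks[1].copies == pytest.approx(300, abs=1)
        assert seg.unassigned_bp >= 780  # flanks stay unassigned

    def test_composite_motif_supplied(self):
        seq = COMPOSITE * 50
        seg = segment_read(seq, [RepeatMotif(m) for m in ("TTTTA", "TTTCA", COMPOSITE)])
        assert seg.structure_string == f"({COMPOSITE})50"

    def test_composite_without_composite_motif(self):
        # without the 15-mer in the motif set, the tract reads as TTTTA with
        # the per-period TTTCA copies demoted to interruptions
        seq = COMPOSITE * 50
        seg = segment_read(seq, [RepeatMotif("TTTTA"), RepeatMotif("TTTCA")])
        assert all(b.motif.display == "TTTTA" for b in seg.blocks)
        ttca_interruptions = [
            b for b in seg.interruptions if b.motif.same_class("TTTCA")
        ]
        assert len(ttca_interruptions) >= 40

    def test_short_read_single_block(self):
        seg = segment_read("TTGTA" * 2, MOTIFS)
        assert len(seg.blocks) == 1
        assert seg.blocks[0].motif.display == "TTGTA"

    def test_no_repeat_read_empty(self):
        seg = segment_read("GA" * 4, MOTIFS)
        assert seg.blocks == ()
        assert seg.unassigned_bp == 8

    def test_clean_random_round_trip_property(self, rng):
        pool = list(PENTAMERS)
        for _ in range(30):
            blocks, prev = [], None
            for _ in range(int(rng.integers(2, 6))):
                m = str(rng.choice(pool))
                if prev is not None and canonical_key(m) == canonical_key(prev):
                    continue
                blocks.append((m, int(rng.integers(5, 400))))
                prev = m
            text = "-".join(f"({m}){c}" for m, c in blocks)
            seg = segment_read(
                config_to_sequence(parse_config(text)),
                [RepeatMotif(m) for m in pool],
            )
            assert seg.structure_string == text, text


class TestConsensusStructure:
    def _seg(self, read_id, spec_text):
        return segment_read(config_to_sequence(parse_config(spec_text)), MOTIFS, read_id=read_id)

    def test_unanimous(self):
        segs = [self._seg(f"r{i}", "(TTTTA)50-(TTGTA)100") for i in range(5)]
        cons = consensus_structure(segs)
        assert cons.block_order == ("TTTTA", "TTGTA")
        assert cons.median_copies == (50, 100)
        assert cons.n_discordant == 0

    def test_mode_with_discordant(self):
        segs = [self._seg(f"r{i}", "(TTTTA)50-(TTGTA)100") for i in range(4)]
        segs.append(self._seg("odd", "(TTGTA)100"))
        cons = consensus_structure(segs)
        assert cons.block_order == ("TTTTA", "TTGTA")
        assert cons.n_discordant == 1

    def test_mosaic_block_dispersion(self):
        sizes = [80, 90, 100, 110, 200]
        segs = [self._seg(f"r{i}", f"(TTTTA)50-(TTGTA){s}") for i, s in enumerate(sizes)]
        cons = consensus_structure(segs)
        assert cons.median_copies[1] == 100
        assert cons.mad_copies[1] == 10
        assert cons.mad_copies[0] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus_structure([])


class TestWaterfall:
    def _seg(self, read_id, text):
        return segment_read(config_to_sequence(parse_config(text)), MOTIFS, read_id=read_id)

    def test_sorted_by_total_bp_descending(self):
        segs = [
            self._seg("mid", "(TTTTA)100-(TTGTA)400"),  # 2500 bp
            self._seg("big", "(TTTTA)100-(TTGTA)800"),  # 4500 bp
            self._seg("small", "(TTGTA)180"),  # 900 bp
        ]
        summary = waterfall(segs)
        assert [s.read_id for s in summary.rows] == ["big", "mid", "small"]
        assert [s.total_block_bp for s in summary.rows] == [4500, 2500, 900]

    def test_single_read(self):
        summary = waterfall([self._seg("only", "(TTGTA)50")])
        assert len(summary.rows) == 1

    def test_rows_are_permutation_of_input(self, rng):
        segs = [
            self._seg(f"r{i}", f"(TTTTA){int(rng.integers(5, 300))}") for i in range(20)
        ]
        summary = waterfall(segs)
        assert sorted(s.read_id for s in summary.rows) == sorted(s.read_id for s in segs)

    def test_tsv_round_trip(self, tmp_path):
        from pentaplex.io_utils import read_tsv, write_tsv

        segs = [self._seg("a", "(TTTTA)60-(TTGTA)90"), self._seg("b", "(TTGTA)200")]
        summary = waterfall(segs)
        table = waterfall_table(summary)
        path = tmp_path / "wf.tsv"
        write_tsv(table, path, config={"test": True})
        back = read_tsv(path)
        pd.testing.assert_frame_equal(back, table)

    def test_distribution_table(self):
        segs = [self._seg("a", "(TTTTA)10-(TTGTA)50"), self._seg("b", "(TTTTA)30-(TTGTA)50")]
        dist = waterfall(segs).distribution.set_index("motif")
        assert dist.loc["TTTTA", "min_copies"] == 10
        assert dist.loc["TTTTA", "max_copies"] == 30
        assert dist.loc["TTGTA", "median_copies"] == 50
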