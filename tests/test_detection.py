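"""Read scanning, MES filtering, deduplication and coverage aggregation."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from nulloscan.detection import (
    AlignmentRecord,
    FilterConfig,
    NullomerHit,
    ReadPair,
    aggregate_coverage,
    alignment_score,
    compute_mes,
    deduplicate,
    local_align,
    passes_fusion_filters,
    passes_neoepitope_filters,
    read_sam_alignments,
    scan_read_pairs,
    write_sam,
)
from nulloscan.mapping import NullomerMappingEntry
from nulloscan.refdb import revcomp

PATTERN = "ACGTACGTACGTTGCA"


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScan:
    def test_forward_hit_on_mate1(self):
        pair = ReadPair("r1", "TT" + PATTERN + "GG", _random_seq(random.Random(0), 30))
        hits = dict(scan_read_pairs([pair], {PATTERN}))
        assert [h.nullomer for h in hits[pair]] == [PATTERN]
        assert hits[pair][0].mate == 1 and hits[pair][0].offset == 2

    def test_strandedness_contract_on_mate2(self):
        rc = revcomp(PATTERN)
        pair_rc = ReadPair("r1", "A" * 30, "TT" + rc + "GG")
        hits = dict(scan_read_pairs([pair_rc], {PATTERN}))
        assert [(h.mate, h.nullomer) for h in hits[pair_rc]] == [(2, PATTERN)]
        # the forward pattern on mate 2 must NOT match
        pair_fwd = ReadPair("r2", "A" * 30, "TT" + PATTERN + "GG")
        assert list(scan_read_pairs([pair_fwd], {PATTERN})) == []

    def test_pairs_without_hits_are_dropped(self):
        pair = ReadPair("r1", "A" * 40, "C" * 40)
        assert list(scan_read_pairs([pair], {PATTERN})) == []

    def test_mixed_length_patterns_rejected(self):
        with pytest.raises(ValueError):
            list(scan_read_pairs([], {"ACGT", "ACGTA"}))

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = random.Random(11)
        patterns = {_random_seq(rng, 16) for _ in range(20)}
        pairs = []
        for i in range(300):
            seq1, seq2 = _random_seq(rng, 80), _random_seq(rng, 80)
            if i % 3 == 0:  # plant a forward pattern on mate 1
                p = rng.choice(sorted(patterns))
                pos = rng.randrange(0, 80 - 16)
                seq1 = seq1[:pos] + p + seq1[pos + 16 :]
            if i % 5 == 0:  # plant a reverse-complement pattern on mate 2
                p = rng.choice(sorted(patterns))
                pos = rng.randrange(0, 80 - 16)
                seq2 = seq2[:pos] + revcomp(p) + seq2[pos + 16 :]
            pairs.append(ReadPair(f"r{i}", seq1, seq2))
        got = {
            (h.read_id, h.mate, h.nullomer, h.offset)
            for _pair, hits in scan_read_pairs(pairs, patterns)
            for h in hits
        }
        naive = set()
        for pair in pairs:
            for p in patterns:
                for i in range(len(pair.seq1) - 15):
                    if pair.seq1[i : i + 16] == p:
                        naive.add((pair.read_id, 1, p, i))
                rc = revcomp(p)
                for i in range(len(pair.seq2) - 15):
                    if pair.seq2[i : i + 16] == rc:
                        naive.add((pair.read_id, 2, p, i))
        assert got == naive


class TestMes:
    def test_anchor_values(self):
        assert compute_mes(35) == 64.0
        assert compute_mes(150) == 277.0

    def test_midpoint_linearity(self):
        assert compute_mes(92.5) == pytest.approx((64 + 277) / 2)

    def test_linearity_property(self):
        for a, b in [(35, 150), (40, 90), (36, 148)]:
            assert compute_mes(a) + compute_mes(b) == pytest.approx(2 * compute_mes((a + b) / 2))

    def test_slope_is_exact_rational_by_default(self):
        assert FilterConfig().mes_slope == Fraction(213, 115)

    def test_compat_slope(self):
        cfg = FilterConfig.compat_slope()
        assert cfg.mes_slope == Fraction(185, 100)
        assert compute_mes(150, cfg) == pytest.approx(1.85 * 115 + 64)


class TestAlignmentScore:
    def test_one_medium_mismatch_at_al35(self):
        assert alignment_score(35, [4]) == 64

    def test_four_mismatches_penalty15_at_al150(self):
        assert alignment_score(150, [4, 4, 4, 3]) == 277

    def test_perfect_alignment(self):
        assert alignment_score(150) == 300


class TestLocalAlign:
    def test_worked_mismatch_case(self):
        rng = random.Random(5)
        target = _random_seq(rng, 200)
        read = target[60:95]
        read = read[:17] + ("A" if read[17] != "A" else "C") + read[18:]
        rec = local_align(read, "t", target)
        assert rec.aligned_length == 35
        assert rec.alignment_score == 64  # 34 matches, one medium mismatch

    def test_perfect_150_scores_300(self):
        rng = random.Random(6)
        target = _random_seq(rng, 300)
        rec = local_align(target[50:200], "t", target)
        assert rec.aligned_length == 150
        assert rec.alignment_score == 300
        assert rec.softclip_left == rec.softclip_right == 0

    def test_softclips_are_unaligned_read_ends(self):
        rng = random.Random(7)
        target = _random_seq(rng, 200)
        junk = "A" * 12
        read = junk + target[80:140]
        rec = local_align(read, "t", target)
        assert rec.softclip_left + rec.aligned_length + rec.softclip_right == rec.read_length
        assert rec.mapq == 0


def _rec(read_id="r1", frag=("t", 0, 100, "+"), qual_sum=100, **kw):
    defaults = dict(
        mate=1, target_id="t", target_start=0, target_end=100, aligned_length=100,
        alignment_score=200, mapq=0, softclip_left=0, softclip_right=0, read_length=100,
    )
    defaults.update(kw)
    return AlignmentRecord(read_id=read_id, fragment_key=frag, qual_sum=qual_sum, **defaults)


class TestDeduplicate:
    def test_highest_quality_pair_kept(self):
        a, b = _rec("r1", qual_sum=100), _rec("r2", qual_sum=90)
        assert deduplicate([a, b]) == [a]

    def test_tie_keeps_first_in_input_order(self):
        a, b = _rec("r1", qual_sum=90), _rec("r2", qual_sum=90)
        assert deduplicate([b, a]) == [b]

    def test_distinct_fragments_both_kept(self):
        a = _rec("r1", frag=("t", 0, 100, "+"))
        b = _rec("r2", frag=("t", 5, 105, "+"))
        assert deduplicate([a, b]) == [a, b]

    def test_three_duplicates_one_survivor_and_idempotence(self):
        recs = [_rec(f"r{i}", qual_sum=q) for i, q in enumerate([50, 80, 70])]
        once = deduplicate(recs)
        assert [r.read_id for r in once] == ["r1"]
        assert deduplicate(once) == once


class TestFilterBoundaries:
    def test_softclip_exactly_one_third_retained(self):
        rec = _rec(softclip_left=30, softclip_right=20, aligned_length=100, read_length=150,
                   alignment_score=200)
        ok, _ = passes_neoepitope_filters(rec)
        assert ok

    def test_softclip_above_one_third_removed(self):
        rec = _rec(softclip_left=31, softclip_right=20, aligned_length=99, read_length=150)
        ok, reason = passes_neoepitope_filters(rec)
        assert not ok and reason == "softclip_fraction"

    def test_as_on_the_mes_line_is_accepted(self):
        rec = _rec(aligned_length=35, alignment_score=64, read_length=35, target_end=35)
        ok, _ = passes_neoepitope_filters(rec)
        assert ok

    def test_strict_mes_rejects_the_anchor(self):
        rec = _rec(aligned_length=35, alignment_score=64, read_length=35, target_end=35)
        ok, reason = passes_neoepitope_filters(rec, FilterConfig(strict_mes=True))
        assert not ok and reason == "below_mes"

    def test_mapq_branch_neoepitope(self):
        low_as = _rec(aligned_length=35, alignment_score=60, read_length=35, target_end=35)
        assert not passes_neoepitope_filters(low_as)[0]
        assert passes_neoepitope_filters(_rec(aligned_length=35, alignment_score=60, mapq=11,
                                              read_length=35, target_end=35))[0]
        assert not passes_neoepitope_filters(_rec(aligned_length=35, alignment_score=60, mapq=10,
                                                  read_length=35, target_end=35))[0]

    def test_fusion_flank_boundary(self):
        # junction at 500: span [495, 530) has exactly 5 nt on the 5' side
        keep = _rec(target_start=495, target_end=530, aligned_length=35,
                    alignment_score=70, read_length=35)
        assert passes_fusion_filters(keep, 500)[0]
        drop = _rec(target_start=496, target_end=530, aligned_length=34,
                    alignment_score=70, read_length=35)
        ok, reason = passes_fusion_filters(drop, 500)
        assert not ok and reason == "junction_flank"

    def test_mapq_branch_fusion(self):
        low_as = _rec(target_start=480, target_end=515, aligned_length=35,
                      alignment_score=10, read_length=35)
        assert not passes_fusion_filters(low_as, 500)[0]
        assert passes_fusion_filters(
            _rec(target_start=480, target_end=515, aligned_length=35, alignment_score=10,
                 mapq=31, read_length=35), 500)[0]
        assert not passes_fusion_filters(
            _rec(target_start=480, target_end=515, aligned_length=35, alignment_score=10,
                 mapq=30, read_length=35), 500)[0]

    def test_raising_as_never_flips_accept_to_reject(self):
        rng = random.Random(3)
        for _ in range(200):
            al = rng.randrange(20, 151)
            rec = _rec(aligned_length=al, alignment_score=rng.randrange(0, 310),
                       read_length=al, target_end=al,
                       softclip_left=rng.randrange(0, 10))
            accepted, _ = passes_neoepitope_filters(rec)
            better = _rec(aligned_length=al, alignment_score=rec.alignment_score + 10,
                          read_length=al, target_end=al, softclip_left=rec.softclip_left)
            if accepted:
                assert passes_neoepitope_filters(better)[0]

    def test_raising_softclip_never_flips_reject_to_accept(self):
        # clipping 5 more read bases removes >= 2 score points per base,
        # while the MES line only drops by ~1.85 per base: a rejected
        # alignment stays rejected when more of the read is clipped
        rng = random.Random(4)
        for _ in range(200):
            clip = rng.randrange(0, 60)
            rec = _rec(softclip_left=clip, aligned_length=150 - clip, read_length=150,
                       alignment_score=rng.randrange(0, 310))
            rejected = not passes_neoepitope_filters(rec)[0]
            worse = _rec(softclip_left=clip + 5, aligned_length=145 - clip, read_length=150,
                         alignment_score=rec.alignment_score - 2 * 5)
            if rejected:
                assert not passes_neoepitope_filters(worse)[0]


def _entry(nullomer, target="T1", kind="neoepitope", align="tx1"):
    return NullomerMappingEntry(nullomer=nullomer, target_kind=kind, target_id=target, align_target=align)


class TestAggregate:
    N1, N2 = "A" * 16, "C" * 16

    def _surviving(self, read_ids, target="tx1"):
        return [_rec(r, frag=(target, i, i + 100, "+"), target_id=target) for i, r in enumerate(read_ids)]

    def test_most_covered_nullomer_wins(self):
        entries = [_entry(self.N1), _entry(self.N2)]
        hits = [NullomerHit(f"r{i}", 1, self.N1, 0) for i in range(4)]
        hits += [NullomerHit(f"r{i}", 1, self.N2, 20) for i in range(2)]
        rows = aggregate_coverage(hits, self._surviving([f"r{i}" for i in range(4)]), entries)
        assert len(rows) == 1
        row = rows[0]
        assert row.best_nullomer == self.N1
        assert row.mapped_reads == 4
        assert row.max_nullomers_per_read == 2  # r0/r1 carry both nullomers

    def test_neoepitope_below_three_reads_fails(self):
        entries = [_entry(self.N1)]
        hits = [NullomerHit("r0", 1, self.N1, 0), NullomerHit("r1", 1, self.N1, 0)]
        rows = aggregate_coverage(hits, self._surviving(["r0", "r1"]), entries)
        assert rows[0].mapped_reads == 2 and not rows[0].passes

    def test_fusion_needs_two_nullomers(self):
        entries = [_entry(self.N1, target="F1", kind="fusion", align="F1")]
        hits = [NullomerHit(f"r{i}", 1, self.N1, 0) for i in range(3)]
        rows = aggregate_coverage(hits, self._surviving(["r0", "r1", "r2"], target="F1"), entries)
        assert rows[0].mapped_reads == 3
        assert not rows[0].passes  # one distinct nullomer is not enough

    def test_hit_on_foreign_target_counts_for_nothing(self):
        entries = [_entry(self.N1)]
        hits = [NullomerHit("r0", 1, self.N1, 0)]
        rows = aggregate_coverage(hits, self._surviving(["r0"], target="other_tx"), entries)
        assert rows == []


class TestSamRoundTrip:
    def test_records_survive_sam_round_trip(self, tmp_path):
        rng = random.Random(9)
        target = _random_seq(rng, 400)
        reads = {}
        records = []
        for i in range(5):
            start = 30 * i
            seq = target[start : start + 100]
            rec = local_align(seq, "tx1", target, read_id=f"r{i}", mate=1, qual="I" * 100)
            records.append(rec)
            reads[(f"r{i}", 1)] = (seq, "I" * 100)
        path = tmp_path / "out.sam"
        write_sam(records, {"tx1": target}, path, reads=reads)
        back = read_sam_alignments(path)
        assert len(back) == len(records)
        for orig, parsed in zip(records, sorted(back, key=lambda r: r.read_id)):
            assert parsed.target_id == orig.target_id
            assert parsed.target_start == orig.target_start
            assert parsed.aligned_length == orig.aligned_length
            assert parsed.alignment_score == orig.alignment_score
            assert (parsed.softclip_left, parsed.softclip_right) == (
                orig.softclip_left, orig.softclip_right)
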