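"""Fused sequence construction, junction nullomers and junction peptides."""

from __future__ import annotations

import pytest

from nulloscan.fusions import (
    CdsPlacement,
    FusedSequence,
    FusionJunction,
    build_fused_sequence,
    build_fusion_mapping,
    candidate_junction_windows,
    count_spanning_windows,
    extract_junction_nullomers,
    read_fused_fasta,
    scan_junction_neoepitopes,
    write_fused_fasta,
)
from nulloscan.refdb import (
    CodingSequence,
    GenomeOccurrenceCounter,
    KmerPresenceIndex,
    SequenceRecord,
    revcomp,
)


def _junction(pos5, strand5, pos3, strand3, chrom5="c1", chrom3="c2", **kw):
    return FusionJunction("F1", chrom5, pos5, strand5, chrom3, pos3, strand3, **kw)


class TestBuildFusedSequence:
    GENOME = [
        SequenceRecord("c1", "AAACCCGGGTTTACGTACGT"),
        SequenceRecord("c2", "TTTGGGCCCAAATGCATGCA"),
    ]

    def test_plus_plus_direct_slicing(self):
        # 5' flank: last 6 bases ending at pos5 (1-based); 3' flank: 6 from pos3
        fused = build_fused_sequence(self.GENOME, _junction(10, "+", 5, "+"), flank=6)
        assert fused.nt == self.GENOME[0].residues[4:10] + self.GENOME[1].residues[4:10]
        assert fused.junction_offset == 6

    def test_minus_strand_five_prime_is_revcomp(self):
        fused = build_fused_sequence(self.GENOME, _junction(10, "-", 5, "+"), flank=6)
        assert fused.nt[:6] == revcomp(self.GENOME[0].residues[9:15])
        assert fused.junction_offset == 6

    def test_minus_strand_three_prime_is_revcomp(self):
        fused = build_fused_sequence(self.GENOME, _junction(10, "+", 12, "-"), flank=6)
        assert fused.nt[6:] == revcomp(self.GENOME[1].residues[6:12])

    def test_truncation_at_chromosome_start(self):
        fused = build_fused_sequence(self.GENOME, _junction(3, "+", 5, "+"), flank=6)
        assert fused.junction_offset == 3
        assert fused.nt[:3] == self.GENOME[0].residues[:3]

    def test_breakpoint_outside_chromosome_names_locus(self):
        with pytest.raises(ValueError, match="F1"):
            build_fused_sequence(self.GENOME, _junction(99, "+", 5, "+"))


class TestJunctionNullomers:
    def test_candidate_window_arithmetic(self):
        fused = FusedSequence(nt="A" * 1000, junction_offset=500)
        assert len(candidate_junction_windows(fused, k=16)) == 15

    def test_unbroken_ccds_region_yields_nothing(self, pipeline):
        ccds = pipeline.ref.ccds[0]
        fused = FusedSequence(nt=ccds.nt[:100], junction_offset=50)
        assert extract_junction_nullomers(fused, pipeline.presence, pipeline.counter) == set()

    def test_matches_brute_force_oracle(self, pipeline):
        for planted in pipeline.truth.fusions:
            fused = planted.fused
            k = pipeline.presence.k
            j = fused.junction_offset
            brute = set()
            for s in range(len(fused.nt) - k + 1):
                if not (s <= j - 1 and s + k >= j + 1):
                    continue
                word = fused.nt[s : s + k]
                if word in pipeline.presence.members:
                    continue
                if pipeline.counter.count(word) > pipeline.counter.cap:
                    continue
                brute.add(word)
            assert extract_junction_nullomers(fused, pipeline.presence, pipeline.counter) == brute

    def test_every_junction_nullomer_straddles_the_junction(self, pipeline):
        for planted in pipeline.truth.fusions:
            fused = planted.fused
            j = fused.junction_offset
            five, three = fused.nt[:j], fused.nt[j:]
            for word in planted.expected_nullomers:
                assert word in fused.nt
                assert word not in five and word not in three


def _toy_coding_pair(kept5_phase: int):
    """Two genes on one chromosome; junction placed at a controlled phase."""
    import random

    rng = random.Random(42 + kept5_phase)
    from nulloscan.fixtures import _SENSE_CODONS

    nt_a = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(40))
    nt_b = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(40))
    genome = [SequenceRecord("c1", nt_a + nt_b)]
    place_a = CdsPlacement("ta", "c1", 0, "+", len(nt_a))
    place_b = CdsPlacement("tb", "c1", len(nt_a), "+", len(nt_b))
    ccds_a = CodingSequence.from_nt("ta", nt_a)
    ccds_b = CodingSequence.from_nt("tb", nt_b)
    cds_by_gene = {"GA": (place_a, ccds_a), "GB": (place_b, ccds_b)}
    kept5 = 30 + kept5_phase  # coding bases kept from the 5' gene
    c3 = 30 + kept5 % 3  # keeps the 3' gene in frame
    junction = FusionJunction(
        "F1", "c1", kept5, "+", "c1", len(nt_a) + c3 + 1, "+", gene5="GA", gene3="GB"
    )
    return genome, cds_by_gene, junction, kept5


class TestJunctionPeptides:
    @pytest.mark.parametrize("phase,expected", [(0, 8), (1, 9), (2, 9)])
    def test_spanning_window_count_by_phase(self, phase, expected):
        # between-codon junctions admit 8 spanning 9-mers, mid-codon 9
        genome, cds_by_gene, junction, kept5 = _toy_coding_pair(phase)
        proteome_empty: list[SequenceRecord] = []
        peptides, reason = scan_junction_neoepitopes(junction, cds_by_gene, proteome_empty)
        assert reason == ""
        assert len(peptides) == expected
        assert count_spanning_windows(kept5, 100) == expected

    def test_wildtype_reconstruction_gives_no_neoepitope(self):
        # fusing a gene to itself at consecutive positions recreates the
        # wildtype protein, so every window is present in the proteome
        genome, cds_by_gene, _junction, _ = _toy_coding_pair(0)
        place_a, ccds_a = cds_by_gene["GA"]
        junction = FusionJunction("F2", "c1", 30, "+", "c1", 31, "+", gene5="GA", gene3="GA")
        proteome = [SequenceRecord("ta", ccds_a.protein, "aa")]
        peptides, reason = scan_junction_neoepitopes(junction, cds_by_gene, proteome)
        assert peptides == [] and reason == ""

    def test_non_coding_junction_reports_reason(self):
        genome, cds_by_gene, junction, _ = _toy_coding_pair(0)
        bad = FusionJunction("F3", "c1", 30, "+", "c1", 999, "+", gene5="GA", gene3="GB")
        peptides, reason = scan_junction_neoepitopes(bad, cds_by_gene, [])
        assert peptides == [] and reason == "non-coding junction"

    def test_out_of_frame_junction_reports_reason(self):
        genome, cds_by_gene, junction, kept5 = _toy_coding_pair(0)
        place_b, _ = cds_by_gene["GB"]
        off = FusionJunction(
            "F4", "c1", kept5, "+", "c1", place_b.start + (kept5 % 3 + 1) % 3 + 30 + 1 + 1, "+",
            gene5="GA", gene3="GB",
        )
        peptides, reason = scan_junction_neoepitopes(off, cds_by_gene, [])
        assert reason in ("3' gene out of frame", "")
        if reason:
            assert peptides == []

    def test_start_codon_overlap_rejected(self):
        genome, cds_by_gene, _junction, _ = _toy_coding_pair(0)
        early = FusionJunction("F5", "c1", 2, "+", "c1", 123 + 31, "+", gene5="GA", gene3="GB")
        peptides, reason = scan_junction_neoepitopes(early, cds_by_gene, [])
        assert reason == "5' junction overlaps start codon"


class TestBuildFusionMapping:
    def test_junction_without_nullomer_is_dropped(self, pipeline):
        ref = pipeline.ref
        # a same-gene "fusion" at consecutive positions recreates wildtype
        place = ref.placements["t1"]
        wt_junction = FusionJunction(
            "WT1", "chr1", place.start + 50, "+", "chr1", place.start + 51, "+",
            gene5="GENE1", gene3="GENE1",
        )
        junctions = [p.junction for p in pipeline.truth.fusions] + [wt_junction]
        entries, fused_by_id, report = build_fusion_mapping(
            junctions, ref.genome, pipeline.presence, pipeline.counter
        )
        assert report.total == len(junctions)
        assert report.mapped == len(junctions) - 1
        assert ("WT1", "no_nullomer") in report.drops

    def test_duplicate_junctions_deduplicated(self, pipeline):
        junctions = [p.junction for p in pipeline.truth.fusions]
        entries, _, report = build_fusion_mapping(
            junctions + junctions, pipeline.ref.genome, pipeline.presence, pipeline.counter
        )
        assert report.total == len(junctions)

    def test_entries_list_all_surviving_nullomers(self, pipeline):
        by_fusion: dict[str, set[str]] = {}
        for entry in pipeline.fusion_entries:
            by_fusion.setdefault(entry.target_id, set()).add(entry.nullomer)
        for planted in pipeline.truth.fusions:
            assert by_fusion[planted.junction.fusion_id] == set(planted.expected_nullomers)

    def test_fused_fasta_round_trip(self, pipeline, tmp_path):
        path = tmp_path / "fused.fa"
        write_fused_fasta(pipeline.fused_by_id, path)
        back = read_fused_fasta(path)
        assert {k: (v.nt, v.junction_offset) for k, v in back.items()} == {
            k: (v.nt, v.junction_offset) for k, v in pipeline.fused_by_id.items()
        }
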