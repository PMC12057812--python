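"""Fused junction sequences, junction-spanning nullomers, junction neoepitopes.

A gene fusion is described by the genomic locus of the last transcribed base
of the 5' partner and the first transcribed base of the 3' partner.  The
builder extracts up to ``flank`` (default 500) nucleotides on each side in
transcript orientation and fuses them at the junction; length-16 windows
straddling the junction that are absent from the CCDS k-mer set (and not
excessively repeated in the genome) become the fusion's nullomers.  Where
both breakpoints fall inside annotated coding sequence, the fused coding
region is translated in the 5' partner's frame and 9-aa peptides spanning
the junction that are absent from the reference proteome are reported as
junction neoepitopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mapping import NullomerMappingEntry
from .refdb import (
    CodingSequence,
    GenomeOccurrenceCounter,
    KmerPresenceIndex,
    SequenceRecord,
    revcomp,
    translate_cds,
)

__all__ = [
    "FusionJunction",
    "FusedSequence",
    "JunctionPeptide",
    "CdsPlacement",
    "FusionBuildConfig",
    "FusionBuildReport",
    "build_fused_sequence",
    "extract_junction_nullomers",
    "scan_junction_neoepitopes",
    "build_fusion_mapping",
    "read_fusion_tsv",
    "write_fused_fasta",
    "read_fused_fasta",
]

_FUSION_TSV_COLUMNS = [
    "fusion_id",
    "chrom5",
    "pos5",
    "strand5",
    "chrom3",
    "pos3",
    "strand3",
    "gene5",
    "gene3",
]


@dataclass(frozen=True)
class FusionJunction:
    """One fusion: 5' and 3' breakpoint loci plus partner gene ids.

    Positions are 1-based in I/O (ChimerKB-style tables): ``pos5`` is the
    last transcribed base kept from the 5' partner, ``pos3`` the first base
    of the 3' partner.
    """

    fusion_id: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    gene5: str = ""
    gene3: str = ""
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for strand in (self.strand5, self.strand3):
            if strand not in ("+", "-"):
                raise ValueError(f"{self.fusion_id}: strand must be + or -, got {strand!r}")

    @property
    def meta(self) -> dict[str, str]:
        return dict(self.metadata)

    @property
    def locus5(self) -> str:
        return f"{self.chrom5}:{self.pos5}:{self.strand5}"

    @property
    def locus3(self) -> str:
        return f"{self.chrom3}:{self.pos3}:{self.strand3}"


@dataclass(frozen=True)
class FusedSequence:
    """Junction-centred fused sequence in transcript orientation.

    ``junction_offset`` is the number of nucleotides contributed by the 5'
    partner (the junction lies between offsets ``junction_offset - 1`` and
    ``junction_offset``).
    """

    nt: str
    junction_offset: int
    flank_requested: int = 500

    def __post_init__(self) -> None:
        if not (1 <= self.junction_offset <= len(self.nt) - 1):
            raise ValueError(
                f"junction offset {self.junction_offset} outside fused sequence of length {len(self.nt)}"
            )


@dataclass(frozen=True)
class JunctionPeptide:
    """A 9-aa peptide whose coding interval spans the fusion junction."""

    peptide: str
    frame: int
    spans_junction: bool = True

    def __post_init__(self) -> None:
        if len(self.peptide) != 9:
            raise ValueError(f"junction peptide must be 9 aa, got {self.peptide!r}")


@dataclass(frozen=True)
class CdsPlacement:
    """Genomic placement of a (contiguous, unspliced) coding sequence."""

    transcript_id: str
    chrom: str
    start: int  # 0-based, inclusive
    strand: str
    length: int

    @property
    def end(self) -> int:  # 0-based exclusive
        return self.start + self.length


def build_fused_sequence(
    genome: dict[str, SequenceRecord] | list[SequenceRecord],
    junction: FusionJunction,
    flank: int = 500,
) -> FusedSequence:
    """Extract and fuse the two junction flanks in transcript orientation.

    The 5' flank is the last ``flank`` transcribed nucleotides ending at the
    5' breakpoint; the 3' flank the first ``flank`` starting at the 3'
    breakpoint.  Minus-strand flanks are reverse complemented.  Flanks are
    truncated at chromosome ends; ``junction_offset`` records the actual 5'
    contribution.
    """
    by_chrom = {rec.id: rec for rec in genome} if isinstance(genome, list) else genome

    def _chrom(name: str) -> str:
        rec = by_chrom.get(name)
        if rec is None:
            raise ValueError(f"{junction.fusion_id}: chromosome {name!r} not in genome")
        return rec.residues

    seq5 = _chrom(junction.chrom5)
    seq3 = _chrom(junction.chrom3)
    p5 = junction.pos5 - 1  # 0-based coordinate of the breakpoint base
    p3 = junction.pos3 - 1
    for name, pos, seq in (("5'", p5, seq5), ("3'", p3, seq3)):
        if not (0 <= pos < len(seq)):
            raise ValueError(
                f"{junction.fusion_id}: {name} breakpoint {pos + 1} outside chromosome of length {len(seq)}"
            )
    if junction.strand5 == "+":
        five = seq5[max(0, p5 - flank + 1) : p5 + 1]
    else:
        five = revcomp(seq5[p5 : min(len(seq5), p5 + flank)])
    if junction.strand3 == "+":
        three = seq3[p3 : min(len(seq3), p3 + flank)]
    else:
        three = revcomp(seq3[max(0, p3 - flank + 1) : p3 + 1])
    return FusedSequence(nt=five + three, junction_offset=len(five), flank_requested=flank)


def extract_junction_nullomers(
    fused: FusedSequence,
    presence: KmerPresenceIndex,
    genome: GenomeOccurrenceCounter,
) -> set[str]:
    """Junction-spanning nullomers: k-windows with >=1 base on each side of
    the junction, absent from the CCDS index, genome count within cap.

    There are at most k-1 candidate windows per junction.
    """
    k = presence.k
    if len(fused.nt) < k:
        return set()
    j = fused.junction_offset
    lo = max(0, j - k + 1)
    hi = min(len(fused.nt) - k, j - 1)
    out: set[str] = set()
    for s in range(lo, hi + 1):
        word = fused.nt[s : s + k]
        if presence.is_nullomer(word) and not genome.exceeds_cap(word):
            out.add(word)
    return out


def candidate_junction_windows(fused: FusedSequence, k: int = 16) -> list[str]:
    """All k-windows spanning the junction, before any filtering."""
    j = fused.junction_offset
    lo = max(0, j - k + 1)
    hi = min(len(fused.nt) - k, j - 1)
    return [fused.nt[s : s + k] for s in range(lo, hi + 1)]


def _coding_offset(placement: CdsPlacement, chrom: str, pos1: int, strand: str) -> int | None:
    """0-based coding-sequence offset of a 1-based genomic position, or None
    if the position is outside the CDS or on the wrong chromosome/strand."""
    if chrom != placement.chrom or strand != placement.strand:
        return None
    p = pos1 - 1
    if not (placement.start <= p < placement.end):
        return None
    if placement.strand == "+":
        return p - placement.start
    return placement.end - 1 - p


def scan_junction_neoepitopes(
    junction: FusionJunction,
    cds_by_gene: dict[str, tuple[CdsPlacement, CodingSequence]],
    proteome: list[SequenceRecord],
) -> tuple[list[JunctionPeptide], str]:
    """Junction-spanning 9-aa neoepitopes of a coding-coding fusion.

    Requires: (i) both breakpoints inside coding sequence, (ii) the 5'
    breakpoint beyond the start codon, (iii) the 3' gene in its original
    reading frame after fusion.  The fused coding region is translated in
    the 5' partner's frame; every 9-aa window whose coding nucleotide
    interval strictly contains the junction and that is absent from the
    reference proteome is emitted.  Returns ``(peptides, reason)`` where a
    non-empty reason explains an empty result.
    """
    got5 = cds_by_gene.get(junction.gene5)
    got3 = cds_by_gene.get(junction.gene3)
    if got5 is None or got3 is None:
        return [], "non-coding junction"
    place5, ccds5 = got5
    place3, ccds3 = got3
    c5 = _coding_offset(place5, junction.chrom5, junction.pos5, junction.strand5)
    c3 = _coding_offset(place3, junction.chrom3, junction.pos3, junction.strand3)
    if c5 is None or c3 is None:
        return [], "non-coding junction"
    kept5 = c5 + 1  # coding nt retained from the 5' partner
    if kept5 < 3:
        return [], "5' junction overlaps start codon"
    if kept5 % 3 != c3 % 3:
        return [], "3' gene out of frame"
    fused_cds = ccds5.nt[:kept5] + ccds3.nt[c3:]
    protein, _partial = translate_cds(fused_cds) if len(fused_cds) >= 3 else ("", False)
    peptides: list[JunctionPeptide] = []
    seen: set[str] = set()
    frame = kept5 % 3
    for s in range(len(protein) - 8):
        nt_lo, nt_hi = 3 * s, 3 * s + 27
        if not (nt_lo < kept5 < nt_hi):
            continue
        pep = protein[s : s + 9]
        if pep in seen:
            continue
        seen.add(pep)
        if any(pep in rec.residues for rec in proteome):
            continue
        peptides.append(JunctionPeptide(peptide=pep, frame=frame))
    return peptides, ""


def count_spanning_windows(kept5: int, protein_len: int) -> int:
    """Number of 9-aa windows strictly containing coding position ``kept5``."""
    return sum(1 for s in range(protein_len - 8) if 3 * s < kept5 < 3 * s + 27)


@dataclass
class FusionBuildConfig:
    flank: int = 500
    k: int = 16
    genome_cap: int = 300


@dataclass
class FusionBuildReport:
    total: int = 0
    mapped: int = 0
    drops: list[tuple[str, str]] = field(default_factory=list)

    def drop(self, fusion_id: str, reason: str) -> None:
        self.drops.append((fusion_id, reason))

    def summary(self) -> str:
        lines = [f"junctions\t{self.total}", f"mapped\t{self.mapped}"]
        for fid, reason in self.drops:
            lines.append(f"dropped:{fid}\t{reason}")
        return "\n".join(lines)


def build_fusion_mapping(
    junctions: list[FusionJunction],
    genome: dict[str, SequenceRecord] | list[SequenceRecord],
    presence: KmerPresenceIndex,
    counter: GenomeOccurrenceCounter,
    cds_by_gene: dict[str, tuple[CdsPlacement, CodingSequence]] | None = None,
    proteome: list[SequenceRecord] | None = None,
    config: FusionBuildConfig | None = None,
) -> tuple[list[NullomerMappingEntry], dict[str, FusedSequence], FusionBuildReport]:
    """Build mapping entries and fused target sequences for a junction set.

    Returns the entries, the fused sequences keyed by fusion id (the
    alignment targets), and a build report.  Junctions with no surviving
    nullomer are dropped (reported, not raised); duplicates are collapsed.
    """
    config = config or FusionBuildConfig()
    report = FusionBuildReport()
    entries: list[NullomerMappingEntry] = []
    fused_by_id: dict[str, FusedSequence] = {}
    seen: set[tuple] = set()
    for junction in junctions:
        dedup_key = (junction.chrom5, junction.pos5, junction.strand5, junction.chrom3, junction.pos3, junction.strand3)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        report.total += 1
        fused = build_fused_sequence(genome, junction, flank=config.flank)
        nullomers = extract_junction_nullomers(fused, presence, counter)
        if not nullomers:
            report.drop(junction.fusion_id, "no_nullomer")
            continue
        peptides: list[JunctionPeptide] = []
        if cds_by_gene is not None and proteome is not None:
            peptides, _reason = scan_junction_neoepitopes(junction, cds_by_gene, proteome)
        meta = junction.meta
        meta["locus5"] = junction.locus5
        meta["locus3"] = junction.locus3
        fused_by_id[junction.fusion_id] = fused
        for word in sorted(nullomers):
            entries.append(
                NullomerMappingEntry(
                    nullomer=word,
                    target_kind="fusion",
                    target_id=junction.fusion_id,
                    align_target=junction.fusion_id,
                    gene_id=f"{junction.gene5}--{junction.gene3}" if junction.gene5 else "",
                    hgnc_symbol=f"{junction.gene5}--{junction.gene3}" if junction.gene5 else "",
                    neoepitopes=[p.peptide for p in peptides],
                    metadata=meta,
                    junction_offset=fused.junction_offset,
                )
            )
        report.mapped += 1
    return entries, fused_by_id, report


def read_fusion_tsv(path: str | Path) -> list[FusionJunction]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _FUSION_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in _FUSION_TSV_COLUMNS]
    junctions = []
    for row in df.itertuples(index=False):
        junctions.append(
            FusionJunction(
                fusion_id=row.fusion_id,
                chrom5=row.chrom5,
                pos5=int(row.pos5),
                strand5=row.strand5,
                chrom3=row.chrom3,
                pos3=int(row.pos3),
                strand3=row.strand3,
                gene5=row.gene5,
                gene3=row.gene3,
                metadata=tuple((c, getattr(row, c)) for c in extra if getattr(row, c)),
            )
        )
    return junctions


def write_fused_fasta(fused_by_id: dict[str, FusedSequence], path: str | Path) -> None:
    """Fused alignment targets; junction offset carried on the header."""
    with open(path, "wt") as fh:
        for fid in sorted(fused_by_id):
            fused = fused_by_id[fid]
            fh.write(f">{fid} junction_offset={fused.junction_offset}\n")
            for i in range(0, len(fused.nt), 70):
                fh.write(fused.nt[i : i + 70] + "\n")


def read_fused_fasta(path: str | Path) -> dict[str, FusedSequence]:
    fused: dict[str, FusedSequence] = {}
    name = None
    offset = None
    chunks: list[str] = []

    def _flush():
        if name is not None:
            fused[name] = FusedSequence(nt="".join(chunks), junction_offset=offset)

    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                fields = line[1:].split()
                name = fields[0]
                offset = None
                for f in fields[1:]:
                    if f.startswith("junction_offset="):
                        offset = int(f.split("=", 1)[1])
                if offset is None:
                    raise ValueError(f"{path}: header for {name!r} lacks junction_offset=")
                chunks = []
            else:
                chunks.append(line.upper())
        _flush()
    return fused
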