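"""Nullomer scanning, alignment filtering and coverage aggregation.

The detector runs in three steps over stranded paired-end reads:

1. *Scan*: each nullomer is searched on read 1 and its reverse complement on
   read 2 (the library is assumed mate-1 sense).  Matching is exact
   multi-pattern lookup over fixed-length words.
2. *Align & filter*: read pairs carrying a nullomer are locally aligned to
   the nullomer's own target sequence (coding sequence or fused junction
   sequence), duplicates are removed at the fragment level, and alignments
   pass either a mapping-quality branch or the minimum-expected-score (MES)
   branch — a linear function of aligned length, ``MES = slope*(AL-35)+64``
   with slope (277-64)/(150-35) — after a soft-clip fraction cut of 1/3.
   Fusion alignments must additionally cover at least 5 nt on both sides of
   the junction.
3. *Aggregate*: per-nullomer coverage counts distinct surviving fragments
   whose reads carry the nullomer and map to that nullomer's target; a
   target's coverage is that of its most covered nullomer.

Alignments may come from the built-in local aligner (reported with MAPQ 0,
so only the score branch applies) or from an external SAM file; the filter
logic is identical for both.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import Align

from .mapping import NullomerMappingEntry
from .refdb import revcomp

__all__ = [
    "ReadPair",
    "NullomerHit",
    "AlignmentRecord",
    "FilterConfig",
    "CoverageRow",
    "read_fastq_pairs",
    "scan_read_pairs",
    "compute_mes",
    "alignment_score",
    "local_align",
    "deduplicate",
    "passes_neoepitope_filters",
    "passes_fusion_filters",
    "aggregate_coverage",
    "run_detection",
    "write_sam",
    "read_sam_alignments",
]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


@dataclass(frozen=True)
class NullomerHit:
    """One exact nullomer occurrence on a read (forward word stored)."""

    read_id: str
    mate: int
    nullomer: str
    offset: int


@dataclass
class AlignmentRecord:
    """One aligned read against one target, with the fields the filters use."""

    read_id: str
    mate: int
    target_id: str
    target_start: int
    target_end: int
    aligned_length: int  # AL: reference-consuming aligned length
    alignment_score: int  # AS
    mapq: int
    softclip_left: int
    softclip_right: int
    read_length: int
    qual_sum: int = 0
    orientation: str = "+"
    fragment_key: tuple | None = None


@dataclass
class FilterConfig:
    """Thresholds of the detection filters (defaults match the method)."""

    mes_slope: Fraction = Fraction(277 - 64, 150 - 35)  # = 213/115
    mes_anchor_al: int = 35
    mes_anchor_as: int = 64
    strict_mes: bool = False
    softclip_max_fraction: Fraction = Fraction(1, 3)
    mapq_min_neoepitope: int = 10
    mapq_min_fusion: int = 30
    junction_min_flank: int = 5
    min_reads_neoepitope: int = 3
    min_reads_fusion: int = 2
    min_nullomers_fusion: int = 2
    # built-in local aligner scoring (AS = 2*matches - penalties)
    match_score: int = 2
    mismatch_score: int = -4
    gap_open: int = -5
    gap_extend: int = -3

    @classmethod
    def compat_slope(cls, **kwargs) -> "FilterConfig":
        """Config with the printed decimal slope 1.85 instead of 213/115."""
        return cls(mes_slope=Fraction(185, 100), **kwargs)


@dataclass
class CoverageRow:
    """Per-target detection record (one output row)."""

    sample_id: str
    target_kind: str
    target_id: str
    gene_id: str
    hgnc_symbol: str
    best_nullomer: str
    neoepitopes: list[str]
    mapped_reads: int
    max_nullomers_per_read: int
    n_detected_nullomers: int
    passes: bool
    metadata: dict[str, str] = field(default_factory=dict)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near {header.strip()!r}")
            name = header[1:].split()[0]
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield name, seq, qual


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate-synchronised read pairs from two FASTQ files."""
    it1, it2 = _iter_fastq(path1), _iter_fastq(path2)
    for rec1 in it1:
        try:
            rec2 = next(it2)
        except StopIteration:
            raise ValueError(f"{path2}: fewer reads than {path1}") from None
        if rec1[0] != rec2[0]:
            raise ValueError(f"mate id mismatch: {rec1[0]!r} vs {rec2[0]!r}")
        yield ReadPair(rec1[0], rec1[1], rec2[1], rec1[2], rec2[2])
    try:
        next(it2)
    except StopIteration:
        return
    raise ValueError(f"{path2}: more reads than {path1}")


def scan_read_pairs(
    pairs: Iterable[ReadPair], patterns: Iterable[str]
) -> Iterator[tuple[ReadPair, list[NullomerHit]]]:
    """Exact multi-pattern scan: forward words on mate 1, reverse complements
    on mate 2.  Pairs without any hit are dropped; all hits are reported.

    All patterns must share one length k; the scan is a sliding-window set
    lookup, equivalent to an Aho–Corasick automaton for equal-length
    patterns.  Windows containing N never match.
    """
    forward = set(p.upper() for p in patterns)
    if not forward:
        return
    lengths = {len(p) for p in forward}
    if len(lengths) != 1:
        raise ValueError(f"patterns must share one length, got {sorted(lengths)}")
    k = lengths.pop()
    rc_of = {revcomp(p): p for p in forward}
    for pair in pairs:
        hits: list[NullomerHit] = []
        for i in range(len(pair.seq1) - k + 1):
            window = pair.seq1[i : i + k]
            if window in forward:
                hits.append(NullomerHit(pair.read_id, 1, window, i))
        for i in range(len(pair.seq2) - k + 1):
            window = pair.seq2[i : i + k]
            if window in rc_of:
                hits.append(NullomerHit(pair.read_id, 2, rc_of[window], i))
        if hits:
            yield pair, hits


def compute_mes(aligned_length: int | float, cfg: FilterConfig | None = None) -> float:
    """Minimum expected alignment score at a given aligned length."""
    cfg = cfg or FilterConfig()
    if aligned_length < 1:
        raise ValueError("aligned length must be >= 1")
    return float(cfg.mes_slope * (Fraction(aligned_length) - cfg.mes_anchor_al) + cfg.mes_anchor_as)


def alignment_score(aligned_length: int, mismatch_penalties: Iterable[int] = ()) -> int:
    """Local alignment score under the bowtie2-style model: +2 per matched
    base, minus a per-mismatch penalty that depends on base quality (2–6;
    4 for a medium-quality base).  ``AS = 2*(AL - n_mismatch) - sum(penalties)``.

    The built-in aligner applies the fixed medium-quality penalty; this
    helper scores the general quality-weighted case.
    """
    penalties = list(mismatch_penalties)
    matches = aligned_length - len(penalties)
    if matches < 0:
        raise ValueError("more mismatches than aligned bases")
    return 2 * matches - sum(penalties)


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _nt_aligner(cfg: FilterConfig) -> Align.PairwiseAligner:
    key = (cfg.match_score, cfg.mismatch_score, cfg.gap_open, cfg.gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = cfg.match_score
        aligner.mismatch_score = cfg.mismatch_score
        # affine gap of length L costs |open| + L*|extend|
        aligner.open_gap_score = cfg.gap_open + cfg.gap_extend
        aligner.extend_gap_score = cfg.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


def local_align(
    read: str,
    target_id: str,
    target_seq: str,
    cfg: FilterConfig | None = None,
    read_id: str = "",
    mate: int = 1,
    qual: str = "",
) -> AlignmentRecord:
    """Best local alignment of a read against one target sequence.

    Soft clips are the unaligned read ends; MAPQ is fixed at 0 so built-in
    alignments are judged by the score branch of the filters only.
    """
    cfg = cfg or FilterConfig()
    aligner = _nt_aligner(cfg)
    alignment = aligner.align(target_seq, read)[0]
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return AlignmentRecord(
            read_id=read_id, mate=mate, target_id=target_id, target_start=0, target_end=0,
            aligned_length=0, alignment_score=0, mapq=0, softclip_left=0,
            softclip_right=len(read), read_length=len(read),
            qual_sum=_qual_sum(qual),
        )
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    aligned_length = sum(int(e) - int(s) for s, e in t_blocks)
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        target_id=target_id,
        target_start=t_start,
        target_end=t_end,
        aligned_length=aligned_length,
        alignment_score=int(alignment.score),
        mapq=0,
        softclip_left=q_start,
        softclip_right=len(read) - q_end,
        read_length=len(read),
        qual_sum=_qual_sum(qual),
    )


def _qual_sum(qual: str) -> int:
    return sum(ord(c) - 33 for c in qual)


def deduplicate(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Fragment-level duplicate removal (samtools-rmdup style contract).

    Among records sharing a fragment key, the read pair with the highest
    summed base quality is kept; ties keep the first pair in input order.
    Records without a fragment key pass through unchanged.
    """
    qual_by_pair: dict[tuple, int] = {}
    order_by_pair: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        if rec.fragment_key is None:
            continue
        pair = (rec.fragment_key, rec.read_id)
        qual_by_pair[pair] = qual_by_pair.get(pair, 0) + rec.qual_sum
        order_by_pair.setdefault(pair, i)
    winner: dict[tuple, tuple] = {}
    for pair, qual in qual_by_pair.items():
        fkey = pair[0]
        best = winner.get(fkey)
        cand = (-qual, order_by_pair[pair], pair[1])
        if best is None or cand < best:
            winner[fkey] = cand
    keep_pairs = {(fkey, best[2]) for fkey, best in winner.items()}
    return [
        rec
        for rec in records
        if rec.fragment_key is None or (rec.fragment_key, rec.read_id) in keep_pairs
    ]


def _softclip_ok(rec: AlignmentRecord, cfg: FilterConfig) -> bool:
    clipped = rec.softclip_left + rec.softclip_right
    return Fraction(clipped, rec.read_length) <= cfg.softclip_max_fraction


def _score_ok(rec: AlignmentRecord, cfg: FilterConfig) -> bool:
    mes = compute_mes(rec.aligned_length, cfg) if rec.aligned_length >= 1 else float("inf")
    if cfg.strict_mes:
        return rec.alignment_score > mes
    return rec.alignment_score >= mes


def passes_neoepitope_filters(rec: AlignmentRecord, cfg: FilterConfig | None = None) -> tuple[bool, str]:
    """Soft-clip cut, then MAPQ > 10 or AS >= MES(AL)."""
    cfg = cfg or FilterConfig()
    if not _softclip_ok(rec, cfg):
        return False, "softclip_fraction"
    if rec.mapq > cfg.mapq_min_neoepitope:
        return True, ""
    if _score_ok(rec, cfg):
        return True, ""
    return False, "below_mes"


def passes_fusion_filters(
    rec: AlignmentRecord, junction_offset: int, cfg: FilterConfig | None = None
) -> tuple[bool, str]:
    """Soft-clip cut, >=5 nt aligned on both junction sides, then MAPQ > 30
    or AS >= MES(AL)."""
    cfg = cfg or FilterConfig()
    if not _softclip_ok(rec, cfg):
        return False, "softclip_fraction"
    left = junction_offset - rec.target_start
    right = rec.target_end - junction_offset
    if left < cfg.junction_min_flank or right < cfg.junction_min_flank:
        return False, "junction_flank"
    if rec.mapq > cfg.mapq_min_fusion:
        return True, ""
    if _score_ok(rec, cfg):
        return True, ""
    return False, "below_mes"


@dataclass
class _TargetGroup:
    kind: str
    target_id: str
    align_target: str
    entry: NullomerMappingEntry
    nullomers: set[str] = field(default_factory=set)
    neoepitopes: list[str] = field(default_factory=list)


def _group_entries(entries: list[NullomerMappingEntry]) -> dict[str, _TargetGroup]:
    groups: dict[str, _TargetGroup] = {}
    for entry in entries:
        group = groups.get(entry.target_id)
        if group is None:
            group = _TargetGroup(entry.target_kind, entry.target_id, entry.align_target, entry)
            groups[entry.target_id] = group
        group.nullomers.add(entry.nullomer)
        for pep in entry.neoepitopes:
            if pep not in group.neoepitopes:
                group.neoepitopes.append(pep)
    return groups


def aggregate_coverage(
    hits: list[NullomerHit],
    surviving: list[AlignmentRecord],
    entries: list[NullomerMappingEntry],
    cfg: FilterConfig | None = None,
    sample_id: str = "",
) -> list[CoverageRow]:
    """Join hits to surviving alignments and roll up per-target coverage.

    A nullomer's coverage counts distinct surviving fragments (read pairs)
    with at least one mate carrying the nullomer and aligned to the
    nullomer's own target; a target's ``mapped_reads`` is the coverage of
    its most covered nullomer.  A hit whose read aligns only to a different
    target counts for nothing.
    """
    cfg = cfg or FilterConfig()
    groups = _group_entries(entries)
    survived: set[tuple[str, int, str]] = {(r.read_id, r.mate, r.target_id) for r in surviving}
    hits_by_read: dict[tuple[str, int], set[str]] = {}
    for hit in hits:
        hits_by_read.setdefault((hit.read_id, hit.mate), set()).add(hit.nullomer)

    rows: list[CoverageRow] = []
    for target_id in sorted(groups):
        group = groups[target_id]
        pairs_per_nullomer: dict[str, set[str]] = {n: set() for n in group.nullomers}
        per_read_counts: dict[tuple[str, int], int] = {}
        for (read_id, mate), words in hits_by_read.items():
            if (read_id, mate, group.align_target) not in survived:
                continue
            mine = words & group.nullomers
            if not mine:
                continue
            per_read_counts[(read_id, mate)] = len(mine)
            for word in mine:
                pairs_per_nullomer[word].add(read_id)
        coverage = {n: len(pairs) for n, pairs in pairs_per_nullomer.items()}
        detected = [n for n, c in coverage.items() if c > 0]
        if not detected:
            continue
        best = max(sorted(coverage), key=lambda n: coverage[n])
        mapped_reads = coverage[best]
        if group.kind == "fusion":
            passes = mapped_reads >= cfg.min_reads_fusion and len(detected) >= cfg.min_nullomers_fusion
        else:
            passes = mapped_reads >= cfg.min_reads_neoepitope
        entry = group.entry
        rows.append(
            CoverageRow(
                sample_id=sample_id,
                target_kind=group.kind,
                target_id=target_id,
                gene_id=entry.gene_id,
                hgnc_symbol=entry.hgnc_symbol,
                best_nullomer=best,
                neoepitopes=group.neoepitopes,
                mapped_reads=mapped_reads,
                max_nullomers_per_read=max(per_read_counts.values(), default=0),
                n_detected_nullomers=len(detected),
                passes=passes,
                metadata=dict(entry.metadata),
            )
        )
    return rows


def run_detection(
    pairs: Iterable[ReadPair],
    entries: list[NullomerMappingEntry],
    target_seqs: dict[str, str],
    junction_offsets: dict[str, int] | None = None,
    cfg: FilterConfig | None = None,
    sample_id: str = "",
    external_alignments: list[AlignmentRecord] | None = None,
    library_type: str = "fr",
) -> tuple[list[CoverageRow], list[CoverageRow], list[tuple[str, int, str, str]]]:
    """Full detection pass: scan, align (or join external alignments),
    deduplicate, filter, aggregate.

    Returns (neoepitope rows, fusion rows, reject log).  ``library_type``
    'fr' means mate 1 is sense; 'rf' swaps the mates before scanning.
    """
    cfg = cfg or FilterConfig()
    junction_offsets = junction_offsets or {}
    if library_type not in ("fr", "rf"):
        raise ValueError(f"library_type must be 'fr' or 'rf', got {library_type!r}")
    if library_type == "rf":
        pairs = (
            ReadPair(p.read_id, p.seq2, p.seq1, p.qual2, p.qual1) for p in pairs
        )

    targets_of_nullomer: dict[str, set[str]] = {}
    for entry in entries:
        targets_of_nullomer.setdefault(entry.nullomer, set()).add(entry.align_target)

    all_hits: list[NullomerHit] = []
    records: list[AlignmentRecord] = []
    external_by_key: dict[tuple[str, int, str], list[AlignmentRecord]] = {}
    if external_alignments is not None:
        for rec in external_alignments:
            external_by_key.setdefault((rec.read_id, rec.mate, rec.target_id), []).append(rec)

    for pair, hits in scan_read_pairs(pairs, targets_of_nullomer):
        all_hits.extend(hits)
        align_targets = sorted({t for h in hits for t in targets_of_nullomer[h.nullomer]})
        for target in align_targets:
            target_seq = target_seqs.get(target)
            if target_seq is None:
                continue
            if external_alignments is not None:
                mate_recs = [
                    rec
                    for mate in (1, 2)
                    for rec in external_by_key.get((pair.read_id, mate, target), [])
                ]
            else:
                mate_recs = [
                    local_align(pair.seq1, target, target_seq, cfg, pair.read_id, 1, pair.qual1),
                    local_align(revcomp(pair.seq2), target, target_seq, cfg, pair.read_id, 2, pair.qual2[::-1]),
                ]
            aligned = [r for r in mate_recs if r.aligned_length > 0]
            if not aligned:
                continue
            frag_start = min(r.target_start for r in aligned)
            frag_end = max(r.target_end for r in aligned)
            fkey = (target, frag_start, frag_end, "+")
            records.extend(replace(r, fragment_key=fkey) for r in aligned)

    records = deduplicate(records)
    surviving: list[AlignmentRecord] = []
    reject_log: list[tuple[str, int, str, str]] = []
    for rec in records:
        if rec.target_id in junction_offsets:
            ok, reason = passes_fusion_filters(rec, junction_offsets[rec.target_id], cfg)
        else:
            ok, reason = passes_neoepitope_filters(rec, cfg)
        if ok:
            surviving.append(rec)
        else:
            reject_log.append((rec.read_id, rec.mate, rec.target_id, reason))

    rows = aggregate_coverage(all_hits, surviving, entries, cfg, sample_id)
    neo_rows = [r for r in rows if r.target_kind == "neoepitope"]
    fusion_rows = [r for r in rows if r.target_kind == "fusion"]
    return neo_rows, fusion_rows, reject_log


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

#: Column order of the neoepitope report (stable interchange contract).
NEOEPITOPE_REPORT_COLUMNS = [
    "sample",
    "gene_id",
    "hgnc_symbol",
    "best_nullomer",
    "neoepitopes",
    "mapped_reads",
    "max_nullomers_per_read",
    "database",
    "gene_function",
    "wt_hla_affinities",
    "neo_hla_affinities",
    "germline_frequencies",
    "target_id",
    "n_detected_nullomers",
    "pass",
]

#: Column order of the gene-fusion report.
FUSION_REPORT_COLUMNS = [
    "sample",
    "fusion_id",
    "best_nullomer",
    "neoepitopes",
    "mapped_reads",
    "max_nullomers_per_read",
    "gene_function",
    "locus5",
    "locus3",
    "n_detected_nullomers",
    "pass",
]


def neoepitope_report(rows: list[CoverageRow]):
    """Neoepitope coverage rows as a DataFrame in the documented order."""
    import pandas as pd

    out = []
    for r in rows:
        if r.target_kind != "neoepitope":
            continue
        out.append(
            {
                "sample": r.sample_id,
                "gene_id": r.gene_id,
                "hgnc_symbol": r.hgnc_symbol,
                "best_nullomer": r.best_nullomer,
                "neoepitopes": ",".join(r.neoepitopes),
                "mapped_reads": r.mapped_reads,
                "max_nullomers_per_read": r.max_nullomers_per_read,
                "database": r.metadata.get("database", ""),
                "gene_function": r.metadata.get("gene_function", ""),
                "wt_hla_affinities": r.metadata.get("wt_hla_affinities", ""),
                "neo_hla_affinities": r.metadata.get("neo_hla_affinities", ""),
                "germline_frequencies": r.metadata.get("germline_frequencies", ""),
                "target_id": r.target_id,
                "n_detected_nullomers": r.n_detected_nullomers,
                "pass": r.passes,
            }
        )
    return pd.DataFrame(out, columns=NEOEPITOPE_REPORT_COLUMNS)


def fusion_report(rows: list[CoverageRow]):
    """Gene-fusion coverage rows as a DataFrame in the documented order."""
    import pandas as pd

    out = []
    for r in rows:
        if r.target_kind != "fusion":
            continue
        out.append(
            {
                "sample": r.sample_id,
                "fusion_id": r.target_id,
                "best_nullomer": r.best_nullomer,
                "neoepitopes": ",".join(r.neoepitopes),
                "mapped_reads": r.mapped_reads,
                "max_nullomers_per_read": r.max_nullomers_per_read,
                "gene_function": r.metadata.get("gene_function", ""),
                "locus5": r.metadata.get("locus5", ""),
                "locus3": r.metadata.get("locus3", ""),
                "n_detected_nullomers": r.n_detected_nullomers,
                "pass": r.passes,
            }
        )
    return pd.DataFrame(out, columns=FUSION_REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# SAM interchange (external-aligner path)
# ---------------------------------------------------------------------------


def write_sam(
    records: list[AlignmentRecord],
    target_seqs: dict[str, str],
    path: str | Path,
    reads: dict[tuple[str, int], tuple[str, str]] | None = None,
) -> None:
    """Write alignment records as a text SAM file (no indels: S/M CIGARs).

    ``reads`` optionally maps (read_id, mate) to (sequence, quality) in
    target orientation; absent reads are written as '*'.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in sorted(target_seqs.items())],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.reference_name = rec.target_id
            seg.reference_start = rec.target_start
            seg.mapping_quality = rec.mapq
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if rec.mate == 2:
                flag |= 0x10  # mate 2 was reverse complemented onto the target
            seg.flag = flag
            cigar = []
            if rec.softclip_left:
                cigar.append((4, rec.softclip_left))
            cigar.append((0, rec.aligned_length))
            if rec.softclip_right:
                cigar.append((4, rec.softclip_right))
            seg.cigartuples = cigar
            if reads and (rec.read_id, rec.mate) in reads:
                seq, qual = reads[(rec.read_id, rec.mate)]
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(qual)
            seg.set_tag("AS", rec.alignment_score)
            out.write(seg)


def read_sam_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Load alignments from SAM/BAM: AS from its tag, soft clips from CIGAR,
    mate from the flags.  Unmapped segments are skipped."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_name is None:
                continue
            cigar = seg.cigartuples or []
            sl = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
            sr = cigar[-1][1] if len(cigar) > 1 and cigar[-1][0] in (4, 5) else 0
            read_length = seg.infer_read_length() or (seg.query_length + 0)
            qual = seg.query_qualities
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mate=2 if seg.is_read2 else 1,
                    target_id=seg.reference_name,
                    target_start=seg.reference_start,
                    target_end=seg.reference_end or seg.reference_start,
                    aligned_length=(seg.reference_end or seg.reference_start) - seg.reference_start,
                    alignment_score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                    mapq=seg.mapping_quality,
                    softclip_left=sl,
                    softclip_right=sr,
                    read_length=read_length or 0,
                    qual_sum=int(sum(qual)) if qual is not None else 0,
                    orientation="-" if seg.is_reverse else "+",
                )
            )
    return records
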