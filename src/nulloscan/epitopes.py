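"""Build nullomer mapping entries from (wildtype, neoepitope, transcript) records.

The association runs: align neoepitope to wildtype epitope (Smith–Waterman)
to find substitution sites; exclude records with indels or more than two
substitutions; locate the wildtype epitope on the protein translation of its
coding sequence; enumerate every codon conformation of the mutated residues;
scan the mutated coding sequence around the mutated bases for length-16
CCDS-nullomers; discard nullomers occurring more than 300 times in the
genome; and emit one mapping entry per surviving (mutation group, nullomer).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .mapping import NullomerMappingEntry
from .refdb import CODONS_FOR_AA, CodingSequence, GenomeOccurrenceCounter, KmerPresenceIndex, translate_cds

__all__ = [
    "EpitopeRecord",
    "MutationAlignment",
    "CodonConformation",
    "EpitopeBuildConfig",
    "BuildReport",
    "align_epitopes",
    "classify_epitope",
    "locate_on_ccds",
    "enumerate_conformations",
    "extract_neoepitope_nullomers",
    "build_epitope_mapping",
    "read_epitope_tsv",
]

_EPITOPE_TSV_COLUMNS = ["wildtype_peptide", "neo_peptide", "transcript_id", "source_db"]


@dataclass(frozen=True)
class EpitopeRecord:
    """One (wildtype epitope, neoepitope, transcript) input row."""

    wildtype: str
    neo: str
    transcript_id: str
    source_db: str = "other"
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for name, pep in (("wildtype", self.wildtype), ("neo", self.neo)):
            if len(pep) < 8:
                raise ValueError(f"{name} epitope {pep!r} shorter than 8 aa")
            if not pep.isalpha() or not pep.isupper():
                raise ValueError(f"{name} epitope {pep!r} must be uppercase letters A-Z")

    @property
    def meta(self) -> dict[str, str]:
        return dict(self.metadata)

    def key(self) -> tuple[str, str, str]:
        return (self.wildtype, self.neo, self.transcript_id)


@dataclass
class MutationAlignment:
    """Aligned epitope pair with derived substitution/indel sites.

    ``substitution_sites`` holds 0-based positions on the *wildtype* epitope
    with the (wildtype, neo) residues at each site.
    """

    wt: str
    neo: str
    aligned_wt: str
    aligned_neo: str
    substitution_sites: list[tuple[int, str, str]]
    has_indel: bool


def _protein_aligner(gap_open: float = -10.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # biopython's open_gap_score already includes the first extension
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_epitopes(wt: str, neo: str, gap_open: float = -10.0, gap_extend: float = -1.0) -> MutationAlignment:
    """Locally align a neoepitope to its wildtype epitope.

    Equal-length pairs within two mismatches take an ungapped fast path (the
    common case for databases restricted to one or two substitutions); other
    pairs go through Smith–Waterman under BLOSUM62 with affine gaps.
    """
    if not wt or not neo:
        raise ValueError("epitopes must be non-empty")
    if len(wt) == len(neo):
        sites = [(i, a, b) for i, (a, b) in enumerate(zip(wt, neo)) if a != b]
        if len(sites) <= 2:
            return MutationAlignment(wt, neo, wt, neo, sites, has_indel=False)

    aligner = _protein_aligner(gap_open, gap_extend)
    # BLOSUM62 lacks rows for J/O/U; map them to X for scoring only
    sanitize = str.maketrans("JOU", "XXX")
    alignment = aligner.align(wt.translate(sanitize), neo.translate(sanitize))[0]
    wt_blocks, neo_blocks = alignment.aligned
    aligned_wt_parts: list[str] = []
    aligned_neo_parts: list[str] = []
    sites: list[tuple[int, str, str]] = []
    has_gap = False
    prev_wt_end: int | None = None
    prev_neo_end: int | None = None
    for (ws, we), (ns, ne) in zip(wt_blocks, neo_blocks):
        if prev_wt_end is not None:
            gap_wt = wt[prev_wt_end:ws]
            gap_neo = neo[prev_neo_end:ns]
            if gap_wt or gap_neo:
                has_gap = True
                aligned_wt_parts.append(gap_wt + "-" * len(gap_neo))
                aligned_neo_parts.append("-" * len(gap_wt) + gap_neo)
        aligned_wt_parts.append(wt[ws:we])
        aligned_neo_parts.append(neo[ns:ne])
        for offset in range(we - ws):
            a, b = wt[ws + offset], neo[ns + offset]
            if a != b:
                sites.append((ws + offset, a, b))
        prev_wt_end, prev_neo_end = we, ne
    has_indel = has_gap or len(wt) != len(neo)
    return MutationAlignment(wt, neo, "".join(aligned_wt_parts), "".join(aligned_neo_parts), sites, has_indel)


def classify_epitope(alignment: MutationAlignment, max_substitutions: int = 2) -> tuple[str, str]:
    """Accept records with 1–2 substitutions and no indel; exclude the rest."""
    if alignment.has_indel:
        return "exclude", "indel"
    if len(alignment.substitution_sites) > max_substitutions:
        return "exclude", f">{max_substitutions} substitutions"
    return "accept", ""


def locate_on_ccds(wildtype: str, ccds: CodingSequence) -> list[int]:
    """All exact-match 0-based protein offsets of the wildtype epitope."""
    offsets = []
    start = ccds.protein.find(wildtype)
    while start != -1:
        offsets.append(start)
        start = ccds.protein.find(wildtype, start + 1)
    return offsets


@dataclass
class CodonConformation:
    """One choice of codons for the mutated residues of an epitope segment.

    ``nt`` is the epitope-coding nucleotide segment with mutated codons
    substituted; ``mutated_nt_positions`` are 0-based positions within ``nt``
    that differ from the wildtype segment, and ``site_of_position`` maps each
    to its 0-based epitope substitution site.
    """

    nt: str
    mutated_nt_positions: list[int]
    site_of_position: dict[int, int]


class ConformationError(ValueError):
    """A substitution target residue has no codon (stop or ambiguous)."""


def enumerate_conformations(ccds: CodingSequence, offset: int, alignment: MutationAlignment) -> list[CodonConformation]:
    """Enumerate all codon conformations encoding the neoepitope.

    Wildtype codons are retained everywhere except at substitution sites,
    where every codon of the neo residue is tried (cartesian product across
    sites).  Every conformation translates to the neoepitope.
    """
    wt = alignment.wt
    if offset < 0 or offset + len(wt) > len(ccds.protein):
        raise ValueError(f"epitope at offset {offset} does not fit protein {ccds.transcript_id}")
    segment = ccds.nt[3 * offset : 3 * (offset + len(wt))]
    sites = alignment.substitution_sites
    choices: list[tuple[str, ...]] = []
    for _pos, _wt_aa, neo_aa in sites:
        codons = CODONS_FOR_AA.get(neo_aa)
        if not codons:
            raise ConformationError(f"no codon encodes residue {neo_aa!r}")
        choices.append(codons)
    conformations: list[CodonConformation] = []
    for combo in itertools.product(*choices) if choices else [()]:
        nt = list(segment)
        mutated: list[int] = []
        site_of: dict[int, int] = {}
        for (pos, _wt_aa, _neo_aa), codon in zip(sites, combo):
            for j, base in enumerate(codon):
                p = 3 * pos + j
                if nt[p] != base:
                    mutated.append(p)
                    site_of[p] = pos
                nt[p] = base
        conformations.append(CodonConformation("".join(nt), sorted(mutated), site_of))
    return conformations


def extract_neoepitope_nullomers(
    conformation: CodonConformation,
    ccds: CodingSequence,
    offset: int,
    presence: KmerPresenceIndex,
    genome: GenomeOccurrenceCounter,
) -> dict[str, frozenset[int]]:
    """Length-k nullomer windows witnessing the conformation's mutations.

    The conformation is embedded in its full coding-sequence context, so
    windows may extend beyond the epitope but are clipped at sequence ends.
    Returns ``word -> epitope substitution sites overlapped`` for every
    window that overlaps at least one mutated base, is absent from the CCDS
    presence index and occurs at most ``genome.cap`` times in the genome.
    """
    k = presence.k
    seg_start = 3 * offset
    mutated_nt = ccds.nt[:seg_start] + conformation.nt + ccds.nt[seg_start + len(conformation.nt) :]
    abs_positions = [(seg_start + p, conformation.site_of_position[p]) for p in conformation.mutated_nt_positions]
    if not abs_positions:
        return {}
    starts: set[int] = set()
    for p, _site in abs_positions:
        starts.update(range(max(0, p - k + 1), min(len(mutated_nt) - k, p) + 1))
    out: dict[str, frozenset[int]] = {}
    for s in sorted(starts):
        word = mutated_nt[s : s + k]
        sites = frozenset(site for p, site in abs_positions if s <= p < s + k)
        if not sites:
            continue
        if not presence.is_nullomer(word):
            continue
        if genome.exceeds_cap(word):
            continue
        out[word] = out.get(word, frozenset()) | sites
    return out


@dataclass
class EpitopeBuildConfig:
    k: int = 16
    genome_cap: int = 300
    max_substitutions: int = 2


@dataclass
class BuildReport:
    """Bookkeeping for a mapping build: what was recovered and what dropped."""

    total: int = 0
    recovered: int = 0
    drops: list[tuple[str, str]] = field(default_factory=list)

    def drop(self, record_key: str, reason: str) -> None:
        self.drops.append((record_key, reason))

    @property
    def drop_reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _key, reason in self.drops:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def summary(self) -> str:
        lines = [f"records\t{self.total}", f"recovered\t{self.recovered}"]
        for reason, n in sorted(self.drop_reasons.items()):
            lines.append(f"dropped:{reason}\t{n}")
        return "\n".join(lines)


def _change_label(abs_pos: int, wt_aa: str, neo_aa: str) -> str:
    # 1-based protein coordinates in human-readable identifiers
    return f"{wt_aa}{abs_pos + 1}{neo_aa}"


def build_epitope_mapping(
    records: list[EpitopeRecord],
    ccds_by_transcript: dict[str, CodingSequence],
    presence: KmerPresenceIndex,
    genome: GenomeOccurrenceCounter,
    config: EpitopeBuildConfig | None = None,
) -> tuple[list[NullomerMappingEntry], BuildReport]:
    """Run the full epitope→nullomer association over a record set.

    Neoepitopes produced by the same mutation group (same transcript and same
    absolute substitution set) are reported together under one target id.
    Drops are reported, never raised.
    """
    config = config or EpitopeBuildConfig()
    report = BuildReport()
    seen: set[tuple[str, str, str]] = set()
    # mutation group -> accumulated state
    groups: dict[tuple[str, frozenset], dict] = {}

    for record in records:
        if record.key() in seen:
            continue
        seen.add(record.key())
        report.total += 1
        rec_key = f"{record.transcript_id}:{record.wildtype}>{record.neo}"
        ccds = ccds_by_transcript.get(record.transcript_id)
        if ccds is None:
            report.drop(rec_key, "transcript_missing")
            continue
        alignment = align_epitopes(record.wildtype, record.neo)
        verdict, why = classify_epitope(alignment, config.max_substitutions)
        if verdict == "exclude":
            report.drop(rec_key, f"excluded ({why})")
            continue
        offsets = locate_on_ccds(record.wildtype, ccds)
        if not offsets:
            report.drop(rec_key, "wildtype_not_found")
            continue
        found_any = False
        for offset in offsets:
            try:
                conformations = enumerate_conformations(ccds, offset, alignment)
            except ConformationError as exc:
                report.drop(rec_key, f"rejected ({exc})")
                break
            words: dict[str, frozenset[int]] = {}
            for conformation in conformations:
                for word, sites in extract_neoepitope_nullomers(conformation, ccds, offset, presence, genome).items():
                    words[word] = words.get(word, frozenset()) | sites
            if not words:
                continue
            found_any = True
            changes = frozenset(
                (offset + pos, wt_aa, neo_aa) for pos, wt_aa, neo_aa in alignment.substitution_sites
            )
            gkey = (record.transcript_id, changes)
            group = groups.setdefault(
                gkey,
                {
                    "neoepitopes": [],
                    "nullomers": {},
                    "meta": record.meta,
                    "databases": [],
                    "offset": offset,
                },
            )
            if record.neo not in group["neoepitopes"]:
                group["neoepitopes"].append(record.neo)
            if record.source_db not in group["databases"]:
                group["databases"].append(record.source_db)
            for word, sites in words.items():
                group["nullomers"][word] = group["nullomers"].get(word, frozenset()) | sites
        else:
            if not found_any:
                report.drop(rec_key, "no_nullomer")
                continue
        if found_any:
            report.recovered += 1

    entries: list[NullomerMappingEntry] = []
    for (transcript_id, changes), group in groups.items():
        labels = sorted(_change_label(*change) for change in changes)
        target_id = f"{transcript_id}|{'+'.join(labels)}" if labels else transcript_id
        meta = dict(group["meta"])
        meta["database"] = ";".join(group["databases"])
        for word in sorted(group["nullomers"]):
            entries.append(
                NullomerMappingEntry(
                    nullomer=word,
                    target_kind="neoepitope",
                    target_id=target_id,
                    align_target=transcript_id,
                    gene_id=meta.get("gene_id", ""),
                    hgnc_symbol=meta.get("hgnc_symbol", ""),
                    neoepitopes=list(group["neoepitopes"]),
                    metadata={k: v for k, v in meta.items() if k not in ("gene_id", "hgnc_symbol")},
                )
            )
    entries.sort(key=NullomerMappingEntry.sort_key)
    return entries, report


def read_epitope_tsv(path: str | Path) -> list[EpitopeRecord]:
    """Read the normalized epitope TSV (wildtype_peptide, neo_peptide,
    transcript_id, source_db, plus passthrough metadata columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _EPITOPE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in _EPITOPE_TSV_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EpitopeRecord(
                wildtype=row.wildtype_peptide,
                neo=row.neo_peptide,
                transcript_id=row.transcript_id,
                source_db=row.source_db or "other",
                metadata=tuple((c, getattr(row, c)) for c in extra if getattr(row, c)),
            )
        )
    return records


def neoepitope_from_conformation(ccds: CodingSequence, offset: int, conformation: CodonConformation) -> str:
    """Translate a conformation back to its peptide (round-trip check)."""
    protein, _ = translate_cds(conformation.nt) if len(conformation.nt) >= 3 else ("", False)
    return protein
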