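"""Reference sequences and k-mer presence/occurrence indices.

Nullomer calling rests on two reference structures built here:

* :class:`KmerPresenceIndex` — the set of every length-k word present in the
  coding-sequence (CCDS) collection.  A k-mer is a *CCDS-nullomer* iff it is
  absent from this set.  Presence is forward-strand only, because coding
  sequences are stranded.
* :class:`GenomeOccurrenceCounter` — saturating occurrence counts of a word
  (and, by default, its reverse complement: transcription can originate from
  either strand) over the genome.  Nullomers occurring more than ``cap``
  (default 300) times in the genome are too repetitive to be trusted and are
  discarded by the builders.

Coordinates are 0-based half-open everywhere in this package; SAM/table I/O
converts to and from 1-based at the boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SequenceRecord",
    "CodingSequence",
    "KmerPresenceIndex",
    "GenomeOccurrenceCounter",
    "FastaFormatError",
    "load_fasta",
    "write_fasta",
    "translate_cds",
    "revcomp",
    "GENETIC_CODE",
    "CODONS_FOR_AA",
    "STOP_CODONS",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] += (_codon,)

_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ*")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with a declared alphabet ('nt' or 'aa')."""

    id: str
    residues: str
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into :class:`SequenceRecord` s.

    Residues are uppercased; record order is preserved.  Nucleotide records
    may only contain A, C, G, T, N; protein records letters A–Z and '*'.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = _NT_ALPHABET if alphabet == "nt" else _AA_ALPHABET
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaFormatError(f"{path}: record {header!r} has no sequence (line {lineno})")
        records.append(SequenceRecord(header, residues, alphabet))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence before first '>' header at line {lineno}: {line[:40]!r}"
                    )
                seq = line.upper()
                bad = set(seq) - allowed
                if bad:
                    raise FastaFormatError(
                        f"{path}: illegal {alphabet} character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
        _flush(lineno=-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate_cds(nt: str) -> tuple[str, bool]:
    """Translate a coding sequence under the standard genetic code.

    Translation stops at (and excludes) the first stop codon; codons with a
    non-ACGT base translate to 'X'.  Returns ``(protein, partial)`` where
    ``partial`` flags a trailing incomplete codon.
    """
    if len(nt) < 3:
        raise ValueError("coding sequence shorter than one codon")
    nt = nt.upper()
    aas: list[str] = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(GENETIC_CODE.get(codon, "X"))
    return "".join(aas), len(nt) % 3 != 0


@dataclass(frozen=True)
class CodingSequence:
    """A coding nucleotide sequence paired with its protein translation."""

    transcript_id: str
    nt: str
    protein: str
    partial: bool = False

    @classmethod
    def from_nt(cls, transcript_id: str, nt: str) -> "CodingSequence":
        protein, partial = translate_cds(nt)
        return cls(transcript_id, nt.upper(), protein, partial)


def _clean_windows(seq: str, k: int) -> Iterator[str]:
    """Yield every length-k window of ``seq`` containing only A/C/G/T."""
    n = len(seq)
    i = 0
    while i <= n - k:
        window = seq[i : i + k]
        # skip past the last offending base in one step
        bad = max((j for j, c in enumerate(window) if c not in "ACGT"), default=-1)
        if bad >= 0:
            i += bad + 1
            continue
        yield window
        i += 1


@dataclass
class KmerPresenceIndex:
    """Exact membership of length-k words over a stranded sequence collection.

    Words are stored in forward orientation only.  Windows containing a
    non-ACGT base (e.g. N) are never members: N cannot support exact k-mer
    identity.
    """

    k: int
    members: set[str] = field(default_factory=set)

    @classmethod
    def build(cls, seqs: Iterable[SequenceRecord | CodingSequence], k: int) -> "KmerPresenceIndex":
        if k < 1:
            raise ValueError(f"k must be positive, got {k}")
        members: set[str] = set()
        for rec in seqs:
            seq = rec.nt if isinstance(rec, CodingSequence) else rec.residues
            members.update(_clean_windows(seq.upper(), k))
        return cls(k=k, members=members)

    def __contains__(self, word: str) -> bool:
        return len(word) == self.k and word in self.members

    def is_nullomer(self, word: str) -> bool:
        """True iff ``word`` has length k, is pure ACGT and is absent."""
        if len(word) != self.k or any(c not in "ACGT" for c in word):
            return False
        return word not in self.members

    def save(self, path: str | Path) -> None:
        """Write the flat interchange format: one word per line, sorted."""
        with open(path, "wt") as fh:
            for word in sorted(self.members):
                fh.write(word + "\n")

    @classmethod
    def load(cls, path: str | Path, k: int | None = None) -> "KmerPresenceIndex":
        members = set()
        with _open_text(path) as fh:
            for line in fh:
                word = line.strip()
                if word:
                    members.add(word)
        if k is None:
            if not members:
                raise ValueError(f"{path}: empty index and no k given")
            k = len(next(iter(members)))
        bad = [w for w in members if len(w) != k]
        if bad:
            raise ValueError(f"{path}: word {bad[0]!r} has length != {k}")
        return cls(k=k, members=members)


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    start = haystack.find(needle)
    while start != -1:
        count += 1
        start = haystack.find(needle, start + 1)
    return count


@dataclass
class GenomeOccurrenceCounter:
    """Saturating occurrence counts of words over a genome.

    Counts occurrences of a word and (when ``double_stranded``) of its reverse
    complement across all records, overlapping occurrences included, saturating
    at ``cap + 1`` — callers only ever need to know whether the count exceeds
    the cap.  Results are cached per word.
    """

    genome: list[SequenceRecord]
    k: int
    cap: int = 300
    double_stranded: bool = True
    _cache: dict[str, int] = field(default_factory=dict, repr=False)

    def count(self, word: str) -> int:
        word = word.upper()
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != counter k {self.k}")
        cached = self._cache.get(word)
        if cached is not None:
            return cached
        needles = [word]
        if self.double_stranded:
            needles.append(revcomp(word))
        total = 0
        for rec in self.genome:
            for needle in needles:
                total += _count_overlapping(rec.residues, needle)
                if total > self.cap:
                    total = self.cap + 1
                    break
            if total > self.cap:
                break
        self._cache[word] = total
        return total

    def exceeds_cap(self, word: str) -> bool:
        return self.count(word) > self.cap


def count_genome_occurrences(
    word: str,
    genome: list[SequenceRecord],
    cap: int = 300,
    double_stranded: bool = True,
) -> int:
    """Functional form of :meth:`GenomeOccurrenceCounter.count`."""
    counter = GenomeOccurrenceCounter(genome=genome, k=len(word), cap=cap, double_stranded=double_stranded)
    return counter.count(word)
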