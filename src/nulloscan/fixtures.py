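"""Deterministic toy references, planted mutation databases and read simulation.

Every stage of the pipeline is testable offline against these fixtures: a
random unspliced toy genome with embedded coding genes, epitope records whose
substitutions are chosen so at least one nullomer survives (with negative
controls whose mutated k-mers are deliberately re-created elsewhere in the
coding set, so the builder must report a "no nullomer" drop), fusion
junctions with verified junction-spanning nullomers, and stranded paired-end
reads (mate 1 sense, mate 2 antisense) planted over the mutated or fused
sequences at controlled per-target coverage.

The generator emulates the *shape* of real inputs (epitope tables, junction
tables, stranded FASTQ), not their statistics: fragments are fixed-length,
qualities constant 'I' (Q40) and errors substitution-only by default, so the
aligned-length identity of alignment records holds exactly in tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .detection import ReadPair
from .epitopes import (
    EpitopeBuildConfig,
    align_epitopes,
    enumerate_conformations,
    extract_neoepitope_nullomers,
)
from .fusions import (
    CdsPlacement,
    FusedSequence,
    FusionJunction,
    build_fused_sequence,
    extract_junction_nullomers,
    scan_junction_neoepitopes,
)
from .refdb import (
    CODONS_FOR_AA,
    STOP_CODONS,
    CodingSequence,
    GenomeOccurrenceCounter,
    KmerPresenceIndex,
    SequenceRecord,
)

__all__ = [
    "ToyReference",
    "PlantedEpitope",
    "PlantedFusion",
    "TruthTable",
    "make_toy_reference",
    "plant_epitope_db",
    "plant_fusion_db",
    "simulate_reads",
    "write_fastq_pairs",
    "write_reference",
    "load_ccds_fasta",
]

_BASES = "ACGT"
_SENSE_CODONS = tuple(sorted(set(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
) - STOP_CODONS))


@dataclass
class ToyReference:
    """A toy genome with embedded, contiguous, forward-strand coding genes."""

    genome: list[SequenceRecord]
    ccds: list[CodingSequence]
    placements: dict[str, CdsPlacement]  # keyed by transcript id
    gene_of_transcript: dict[str, str]
    seed: int

    @property
    def proteome(self) -> list[SequenceRecord]:
        return [SequenceRecord(c.transcript_id, c.protein, "aa") for c in self.ccds if c.protein]

    @property
    def ccds_by_transcript(self) -> dict[str, CodingSequence]:
        return {c.transcript_id: c for c in self.ccds}

    @property
    def cds_by_gene(self) -> dict[str, tuple[CdsPlacement, CodingSequence]]:
        by_t = self.ccds_by_transcript
        return {
            gene: (self.placements[t], by_t[t])
            for t, gene in self.gene_of_transcript.items()
            if t in self.placements
        }

    def presence(self, k: int = 16) -> KmerPresenceIndex:
        return KmerPresenceIndex.build(self.ccds, k)

    def genome_counter(self, k: int = 16, cap: int = 300) -> GenomeOccurrenceCounter:
        return GenomeOccurrenceCounter(genome=self.genome, k=k, cap=cap)


def make_toy_reference(
    seed: int = 1,
    n_genes: int = 8,
    cds_len: int = 300,
    intergenic: int = 200,
) -> ToyReference:
    """Random genes embedded in a random genome (uniform base composition,
    GC ~ 0.5); byte-identical under the same seed."""
    if cds_len < 48 or cds_len % 3 != 0:
        raise ValueError("cds_len must be >= 48 and a multiple of 3")
    rng = random.Random(seed)
    chunks: list[str] = []
    ccds: list[CodingSequence] = []
    placements: dict[str, CdsPlacement] = {}
    gene_of: dict[str, str] = {}
    pos = 0
    for i in range(n_genes):
        spacer = "".join(rng.choice(_BASES) for _ in range(intergenic))
        chunks.append(spacer)
        pos += len(spacer)
        nt = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(cds_len // 3 - 1))
        transcript = f"t{i + 1}"
        ccds.append(CodingSequence.from_nt(transcript, nt))
        placements[transcript] = CdsPlacement(transcript, "chr1", pos, "+", len(nt))
        gene_of[transcript] = f"GENE{i + 1}"
        chunks.append(nt)
        pos += len(nt)
    chunks.append("".join(rng.choice(_BASES) for _ in range(intergenic)))
    genome = [SequenceRecord("chr1", "".join(chunks), "nt")]
    return ToyReference(genome=genome, ccds=ccds, placements=placements, gene_of_transcript=gene_of, seed=seed)


@dataclass
class PlantedEpitope:
    """Ground truth for one planted epitope record."""

    wildtype: str
    neo: str
    transcript_id: str
    gene: str
    offset: int  # protein offset of the epitope
    changes: tuple[tuple[int, str, str], ...]  # (abs protein pos, wt, neo)
    target_id: str
    expected_nullomers: frozenset[str]  # of the expressed conformation
    all_nullomers: frozenset[str]  # over all conformations
    mutated_ccds_nt: str  # full CCDS with the expressed conformation
    window_region: tuple[int, int]  # nt interval containing all windows
    negative: bool = False

    def tsv_row(self) -> dict[str, str]:
        return {
            "wildtype_peptide": self.wildtype,
            "neo_peptide": self.neo,
            "transcript_id": self.transcript_id,
            "source_db": "TSNAdb" if len(self.changes) == 1 else "IEDB",
            "gene_id": f"g_{self.gene}",
            "hgnc_symbol": self.gene,
            "gene_function": f"toy protein {self.gene}",
        }


@dataclass
class PlantedFusion:
    junction: FusionJunction
    fused: FusedSequence
    expected_nullomers: frozenset[str]
    junction_peptides: tuple[str, ...]

    def tsv_row(self) -> dict[str, str]:
        j = self.junction
        return {
            "fusion_id": j.fusion_id,
            "chrom5": j.chrom5,
            "pos5": str(j.pos5),
            "strand5": j.strand5,
            "chrom3": j.chrom3,
            "pos3": str(j.pos3),
            "strand3": j.strand3,
            "gene5": j.gene5,
            "gene3": j.gene3,
            "gene_function": f"toy fusion {j.gene5}--{j.gene3}",
        }


@dataclass
class TruthTable:
    epitopes: list[PlantedEpitope] = field(default_factory=list)
    fusions: list[PlantedFusion] = field(default_factory=list)

    def epitope_tsv(self) -> pd.DataFrame:
        return pd.DataFrame([p.tsv_row() for p in self.epitopes])

    def fusion_tsv(self) -> pd.DataFrame:
        return pd.DataFrame([p.tsv_row() for p in self.fusions])

    @property
    def positive_epitopes(self) -> list[PlantedEpitope]:
        return [p for p in self.epitopes if not p.negative]


def _change_label(abs_pos: int, wt_aa: str, neo_aa: str) -> str:
    return f"{wt_aa}{abs_pos + 1}{neo_aa}"


def _mutation_context(conformation, ccds: CodingSequence, offset: int, k: int) -> tuple[str, int, int]:
    """Mutated full CCDS and the nt interval holding every candidate window."""
    seg_start = 3 * offset
    mutated = ccds.nt[:seg_start] + conformation.nt + ccds.nt[seg_start + len(conformation.nt) :]
    positions = [seg_start + p for p in conformation.mutated_nt_positions]
    lo = max(0, min(positions) - (k - 1))
    hi = min(len(mutated), max(positions) + k)
    return mutated, lo, hi


def plant_epitope_db(
    ref: ToyReference,
    n_records: int = 12,
    n_negative: int = 1,
    epitope_len: int = 9,
    seed: int = 0,
    k: int = 16,
    cap: int = 300,
    read_len: int = 100,
    frag_len: int = 130,
    max_resamples: int = 500,
) -> tuple[pd.DataFrame, TruthTable]:
    """Plant epitope records with known surviving nullomers.

    Negative controls are made unrecoverable by appending a synthetic decoy
    paralog to the coding set that contains every mutated window, so the
    builder's presence index absorbs them ("no nullomer" drop).  Positive
    records are resampled until at least one nullomer survives against the
    final coding set, their window regions are disjoint per transcript, and
    their nullomer sets are pairwise disjoint.
    """
    rng = random.Random(seed)
    truth = TruthTable()
    used_regions: dict[str, list[tuple[int, int]]] = {}
    used_words: set[str] = set()
    by_transcript = ref.ccds_by_transcript
    transcripts = sorted(by_transcript)
    counter = ref.genome_counter(k=k, cap=cap)

    def _snv_codons(codon: str) -> list[tuple[str, str]]:
        """(neo_aa, codon) pairs reachable by one nucleotide substitution
        (missense only: no stop, no synonymous change)."""
        from .refdb import GENETIC_CODE

        wt_aa = GENETIC_CODE.get(codon)
        out = []
        for j in range(3):
            for base in _BASES:
                if base == codon[j]:
                    continue
                alt = codon[:j] + base + codon[j + 1 :]
                aa = GENETIC_CODE.get(alt)
                if aa is not None and aa != wt_aa:
                    out.append((aa, alt))
        return sorted(out)

    def _sample_record() -> tuple[str, int, list[tuple[int, str, str]], str, str, dict[int, str]]:
        """Plant missense single-nucleotide variants: the expressed tumor
        allele differs from the reference by one base per substituted site."""
        transcript = rng.choice(transcripts)
        ccds = by_transcript[transcript]
        protein = ccds.protein
        if len(protein) < epitope_len + 2:
            raise ValueError("protein too short for epitope planting")
        offset = rng.randrange(0, len(protein) - epitope_len + 1)
        wt = protein[offset : offset + epitope_len]
        n_subs = rng.choice((1, 1, 2))  # mostly single substitutions, some double
        sites = sorted(rng.sample(range(epitope_len), n_subs))
        neo = list(wt)
        changes = []
        expressed_codons: dict[int, str] = {}
        for site in sites:
            wt_aa = wt[site]
            codon = ccds.nt[3 * (offset + site) : 3 * (offset + site) + 3]
            options = _snv_codons(codon)
            if not options:
                return _sample_record()
            neo_aa, alt_codon = rng.choice(options)
            neo[site] = neo_aa
            changes.append((offset + site, wt_aa, neo_aa))
            expressed_codons[site] = alt_codon
        return transcript, offset, changes, wt, "".join(neo), expressed_codons

    # --- negatives first: their decoys join the coding set ---------------
    decoys: list[CodingSequence] = []
    negatives: list[PlantedEpitope] = []
    def _expressed_conformation(conformations, alignment, expressed_codons):
        for conf in conformations:
            if all(
                conf.nt[3 * site : 3 * site + 3] == expressed_codons[site]
                for site, _wt_aa, _neo_aa in alignment.substitution_sites
            ):
                return conf
        raise RuntimeError("no conformation matches the expressed codons")

    for i in range(n_negative):
        for _ in range(max_resamples):
            transcript, offset, changes, wt, neo, expressed_codons = _sample_record()
            ccds = by_transcript[transcript]
            alignment = align_epitopes(wt, neo)
            conformations = enumerate_conformations(ccds, offset, alignment)
            contexts = []
            for conf in conformations:
                mutated, lo, hi = _mutation_context(conf, ccds, offset, k)
                contexts.append(mutated[lo:hi])
            decoy = CodingSequence.from_nt(f"decoy{i + 1}", "".join(contexts))
            expressed = _expressed_conformation(conformations, alignment, expressed_codons)
            mutated, lo, hi = _mutation_context(expressed, ccds, offset, k)
            labels = sorted(_change_label(*c) for c in changes)
            negatives.append(
                PlantedEpitope(
                    wildtype=wt,
                    neo=neo,
                    transcript_id=transcript,
                    gene=ref.gene_of_transcript[transcript],
                    offset=offset,
                    changes=tuple(changes),
                    target_id=f"{transcript}|{'+'.join(labels)}",
                    expected_nullomers=frozenset(),
                    all_nullomers=frozenset(),
                    mutated_ccds_nt=mutated,
                    window_region=(lo, hi),
                    negative=True,
                )
            )
            decoys.append(decoy)
            used_regions.setdefault(transcript, []).append((lo, hi))
            break
    ref.ccds.extend(decoys)
    presence = ref.presence(k)

    # --- positives against the final coding set ---------------------------
    n_positive = n_records - n_negative
    for _ in range(n_positive):
        for attempt in range(max_resamples):
            transcript, offset, changes, wt, neo, expressed_codons = _sample_record()
            ccds = by_transcript[transcript]
            alignment = align_epitopes(wt, neo)
            conformations = enumerate_conformations(ccds, offset, alignment)
            expressed = _expressed_conformation(conformations, alignment, expressed_codons)
            mutated, lo, hi = _mutation_context(expressed, ccds, offset, k)
            if any(not (hi <= a or lo >= b) for a, b in used_regions.get(transcript, [])):
                continue
            # keep >=10 distinct fragment starts available to the simulator
            if min(lo, len(ccds.nt) - frag_len) - max(0, hi - read_len) + 1 < 10:
                continue
            expressed_words = set(extract_neoepitope_nullomers(expressed, ccds, offset, presence, counter))
            if not expressed_words:
                continue  # the expressed conformation must be detectable
            all_words: set[str] = set()
            for conf in conformations:
                all_words |= set(extract_neoepitope_nullomers(conf, ccds, offset, presence, counter))
            if all_words & used_words:
                continue
            labels = sorted(_change_label(*c) for c in changes)
            truth.epitopes.append(
                PlantedEpitope(
                    wildtype=wt,
                    neo=neo,
                    transcript_id=transcript,
                    gene=ref.gene_of_transcript[transcript],
                    offset=offset,
                    changes=tuple(changes),
                    target_id=f"{transcript}|{'+'.join(labels)}",
                    expected_nullomers=frozenset(expressed_words),
                    all_nullomers=frozenset(all_words),
                    mutated_ccds_nt=mutated,
                    window_region=(lo, hi),
                )
            )
            used_regions.setdefault(transcript, []).append((lo, hi))
            used_words |= all_words
            break
        else:
            raise RuntimeError("could not plant a recoverable epitope record; relax constraints")
    truth.epitopes.extend(negatives)
    return truth.epitope_tsv(), truth


def plant_fusion_db(
    ref: ToyReference,
    n_fusions: int = 3,
    seed: int = 0,
    flank: int = 500,
    k: int = 16,
    cap: int = 300,
    min_nullomers: int = 2,
    avoid_words: frozenset[str] = frozenset(),
    max_resamples: int = 500,
) -> tuple[pd.DataFrame, TruthTable]:
    """Plant in-frame coding-coding fusions with >= ``min_nullomers``
    junction-spanning nullomers each (resampled otherwise).

    ``avoid_words`` excludes junctions whose chimeric k-mers collide with
    words already claimed by other planted targets (e.g. epitope codon
    conformations), keeping per-target truth attribution unambiguous.
    """
    rng = random.Random(seed)
    truth = TruthTable()
    presence = ref.presence(k)
    counter = ref.genome_counter(k=k, cap=cap)
    transcripts = sorted(ref.placements)
    used: set[tuple] = set()
    claimed: set[str] = set(avoid_words)
    for i in range(n_fusions):
        for _ in range(max_resamples):
            t5, t3 = rng.sample(transcripts, 2)
            p5, p3 = ref.placements[t5], ref.placements[t3]
            kept5 = rng.randrange(30, p5.length - 30)
            if kept5 < 3:
                continue
            # keep the 3' partner in its original frame after fusion
            c3_candidates = [c for c in range(30, p3.length - 30) if c % 3 == kept5 % 3]
            c3 = rng.choice(c3_candidates)
            pos5 = p5.start + kept5  # 1-based last kept base (forward strand)
            pos3 = p3.start + c3 + 1  # 1-based first kept base
            key = (t5, t3, pos5, pos3)
            if key in used:
                continue
            junction = FusionJunction(
                fusion_id=f"FUS{i + 1}",
                chrom5="chr1",
                pos5=pos5,
                strand5="+",
                chrom3="chr1",
                pos3=pos3,
                strand3="+",
                gene5=ref.gene_of_transcript[t5],
                gene3=ref.gene_of_transcript[t3],
            )
            fused = build_fused_sequence(ref.genome, junction, flank=flank)
            nullomers = extract_junction_nullomers(fused, presence, counter)
            if len(nullomers) < min_nullomers:
                continue
            if nullomers & claimed:
                continue
            peptides, _reason = scan_junction_neoepitopes(junction, ref.cds_by_gene, ref.proteome)
            used.add(key)
            claimed |= nullomers
            truth.fusions.append(
                PlantedFusion(
                    junction=junction,
                    fused=fused,
                    expected_nullomers=frozenset(nullomers),
                    junction_peptides=tuple(p.peptide for p in peptides),
                )
            )
            break
        else:
            raise RuntimeError("could not plant a fusion with enough junction nullomers")
    return truth.fusion_tsv(), truth


def simulate_reads(
    ref: ToyReference,
    truth: TruthTable,
    coverage: int | dict[str, int] = 6,
    read_len: int = 100,
    frag_len: int = 130,
    error_rate: float = 0.0,
    seed: int = 0,
    background_pairs: int = 50,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Simulate stranded read pairs over planted targets plus background.

    Mate 1 is sense, mate 2 the reverse complement of the fragment end.
    Planted fragments are chosen at distinct starts so that mate 1 fully
    contains every candidate nullomer window of the target (so, with zero
    errors, per-target coverage equals the planted fragment count exactly).
    Background pairs come from unmutated coding sequence and carry no
    nullomer.  Returns the shuffled pairs and ``target_id -> planted
    fragment count``.
    """
    if frag_len < read_len:
        raise ValueError("frag_len must be >= read_len")
    rng = random.Random(seed)

    def cov_of(target_id: str) -> int:
        if isinstance(coverage, dict):
            return coverage.get(target_id, 0)
        return coverage

    def _mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        out = list(seq)
        for i, base in enumerate(out):
            if rng.random() < error_rate:
                out[i] = rng.choice([b for b in _BASES if b != base])
        return "".join(out)

    pairs: list[ReadPair] = []
    planted_counts: dict[str, int] = {}

    def _plant(source: str, lo: int, hi: int, n: int, prefix: str) -> int:
        """Fragments whose first ``read_len`` bases contain [lo, hi)."""
        start_lo = max(0, hi - read_len)
        start_hi = min(lo, len(source) - frag_len)
        if start_hi < start_lo:
            return 0
        choices = list(range(start_lo, start_hi + 1))
        n_eff = min(n, len(choices))
        starts = rng.sample(choices, n_eff)
        for idx, s in enumerate(sorted(starts)):
            frag = source[s : s + frag_len]
            seq1 = _mutate(frag[:read_len])
            seq2 = _mutate(_revcomp(frag[-read_len:]))
            pairs.append(ReadPair(f"{prefix}_{idx}", seq1, seq2, "I" * read_len, "I" * read_len))
        return n_eff

    for e_idx, planted in enumerate(truth.positive_epitopes):
        n = cov_of(planted.target_id)
        if n <= 0:
            continue
        lo, hi = planted.window_region
        got = _plant(planted.mutated_ccds_nt, lo, hi, n, f"ep{e_idx}")
        planted_counts[planted.target_id] = got

    for f_idx, planted in enumerate(truth.fusions):
        n = cov_of(planted.junction.fusion_id)
        if n <= 0:
            continue
        j = planted.fused.junction_offset
        k = 16
        lo = max(0, j - (k - 1))
        hi = min(len(planted.fused.nt), j + (k - 1))
        got = _plant(planted.fused.nt, lo, hi, n, f"fus{f_idx}")
        planted_counts[planted.junction.fusion_id] = got

    genes = [c for c in ref.ccds if not c.transcript_id.startswith("decoy")]
    for b in range(background_pairs):
        ccds = rng.choice(genes)
        if len(ccds.nt) < frag_len:
            continue
        s = rng.randrange(0, len(ccds.nt) - frag_len + 1)
        frag = ccds.nt[s : s + frag_len]
        pairs.append(
            ReadPair(f"bg_{b}", _mutate(frag[:read_len]), _mutate(_revcomp(frag[-read_len:])), "I" * read_len, "I" * read_len)
        )

    rng.shuffle(pairs)
    return pairs, planted_counts


def _revcomp(seq: str) -> str:
    from .refdb import revcomp

    return revcomp(seq)


def write_fastq_pairs(pairs: list[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "wt") as f1, open(path2, "wt") as f2:
        for pair in pairs:
            f1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{pair.qual1 or 'I' * len(pair.seq1)}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{pair.qual2 or 'I' * len(pair.seq2)}\n")


def write_reference(ref: ToyReference, outdir: str | Path) -> dict[str, Path]:
    """Write genome, CCDS (with placement attributes on headers) and proteome
    FASTA files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "ref_genome.fa",
        "ccds": outdir / "ref_ccds.fa",
        "proteome": outdir / "ref_proteome.fa",
    }
    with open(paths["genome"], "wt") as fh:
        for rec in ref.genome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")
    with open(paths["ccds"], "wt") as fh:
        for ccds in ref.ccds:
            place = ref.placements.get(ccds.transcript_id)
            gene = ref.gene_of_transcript.get(ccds.transcript_id, "")
            attrs = ""
            if place is not None:
                attrs = f" chrom={place.chrom} start={place.start} strand={place.strand}"
            if gene:
                attrs += f" gene={gene}"
            fh.write(f">{ccds.transcript_id}{attrs}\n")
            for i in range(0, len(ccds.nt), 70):
                fh.write(ccds.nt[i : i + 70] + "\n")
    with open(paths["proteome"], "wt") as fh:
        for rec in ref.proteome:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    return paths


def load_ccds_fasta(
    path: str | Path,
) -> tuple[dict[str, CodingSequence], dict[str, tuple[CdsPlacement, CodingSequence]]]:
    """Load a CCDS FASTA whose headers may carry ``chrom= start= strand=
    gene=`` attributes; returns (by transcript, by gene with placement)."""
    by_transcript: dict[str, CodingSequence] = {}
    by_gene: dict[str, tuple[CdsPlacement, CodingSequence]] = {}
    name = None
    attrs: dict[str, str] = {}
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        ccds = CodingSequence.from_nt(name, "".join(chunks))
        by_transcript[name] = ccds
        if {"chrom", "start", "strand"} <= attrs.keys():
            place = CdsPlacement(name, attrs["chrom"], int(attrs["start"]), attrs["strand"], len(ccds.nt))
            by_gene[attrs.get("gene", name)] = (place, ccds)

    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                fields = line[1:].split()
                name = fields[0]
                attrs = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                chunks = []
            else:
                chunks.append(line.upper())
        _flush()
    return by_transcript, by_gene
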