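# nulloscan

Nullomer-based detection of known neoepitopes and gene-fusion junctions in
stranded cell-free RNA (cfRNA) sequencing reads.

## The problem

Plasma cfRNA carries a live footprint of systemic transcription, including
transcripts from tumors — but it is heavily fragmented, of mixed tissue
origin, and sequenced at low allele coverage, which defeats conventional
variant-calling pipelines. Rather than calling variants, nulloscan turns the
problem around: it precomputes, for every *known* neoepitope-producing
mutation and every curated fusion junction, the set of **CCDS-nullomers** —
nucleotide 16-mers that occur nowhere in the consensus coding sequence
(CCDS) set but are created by that specific mutation or junction. Finding
such a word in a read is direct evidence for its mutation; the rest of the
pipeline only has to confirm that the read really maps where it should.

## Method at its core

**Database build.** Each neoepitope is aligned to its wildtype epitope
(Smith–Waterman); records with indels or more than two amino-acid
substitutions are excluded. The wildtype epitope is located on the protein
translation of its coding sequence, every codon conformation of the mutated
residues is enumerated, and each 16-nt window overlapping a mutated base is
kept as a nullomer if it is (a) absent from the CCDS k-mer set and (b)
present at most 300 times in the genome (both strands). Fusion junctions get
a 500+500 nt fused target sequence; only the ≤15 windows straddling the
junction qualify, and 9-aa junction peptides absent from the reference
proteome are reported as putative neoepitopes when both breakpoints are
coding and the 3′ gene stays in frame.

**Detection.** Nullomers are searched on read 1 and their reverse
complements on read 2 (stranded libraries, mate 1 sense). Hit pairs are
locally aligned to the nullomer's own target; after fragment-level duplicate
removal, an alignment survives if at most ⅓ of the read is soft-clipped and
either MAPQ clears a branch threshold (>10 coding, >30 fused) or the
alignment score AS reaches the **minimum expected score**

```
MES(AL) = slope · (AL − 35) + 64,   slope = (277 − 64)/(150 − 35) = 213/115 ≈ 1.85
```

a linear function of aligned length AL anchored at AS = 64 for AL = 35 (one
medium-quality mismatch, penalty 4) and AS = 277 for AL = 150 (≈4 medium
mismatches, penalty 15). This keeps short fragments — which MAPQ filters
discard wholesale — while bounding mismatch load. Fusion alignments must
additionally cover ≥5 nt on both sides of the junction. A target's coverage
is the coverage of its most covered nullomer; neoepitopes need ≥3 reads,
fusions ≥2 reads and ≥2 distinct nullomers.

**Annotation & cohorts.** Externally computed HLA-binding predictions
(%Rank < 2%) and germline allele frequencies (AF > 1e−7 missense
protein-coding ENST rows) are joined onto the mapping; per-sample coverage is
normalized as log10(1 + CPM) and targets are flagged *generic* (broad in
cases **and** controls) or *discriminative* (≥2-fold mean difference,
detected in ≥3 individuals of the enriched group).

## Worked example

`examples/02_detect_in_reads.py` builds a toy reference (8 genes in a ~4 kb
genome), plants 12 epitope records and 3 in-frame fusions, simulates
stranded read pairs at coverage 6 per target plus unmutated background, and
runs detection end to end:

```
134 read pairs scanned; 9 alignments rejected by filters

target                  reads  nullomers  pass
t1|H29R+S34T                6         30  True
t1|T65S                     6         16  True
...
t8|S64C                     6         16  True
FUS1                        6         13  True
FUS2                        6         15  True
FUS3                        6         15  True
```

Each row is one mutation group or fusion: `reads` is the post-deduplication
fragment coverage of its best nullomer, `nullomers` the distinct words
detected, and `pass` the threshold flag (≥3 reads for neoepitopes; ≥2 reads
and ≥2 nullomers for fusions). Every planted target is recovered at its
planted coverage; the background produces no rows at all, because unmutated
coding sequence cannot contain a nullomer by construction. The remaining
examples (`examples/01…05`) walk through the database build, fusion
junction handling, the MES filter and the cohort flags individually.

The same workflow is available from the shell:

```bash
nulloscan make-fixtures --seed 5 --out-dir fx
nulloscan build-epitopes --epitopes fx/epitopes.tsv --ccds fx/ref_ccds.fa \
    --genome fx/ref_genome.fa --out mapping.tsv
nulloscan build-fusions  --fusions fx/fusions.tsv --ccds fx/ref_ccds.fa \
    --genome fx/ref_genome.fa --proteome fx/ref_proteome.fa \
    --out fusion_mapping.tsv --out-fasta fused.fa
nulloscan detect --mapping mapping.tsv --mapping fusion_mapping.tsv \
    --ccds fx/ref_ccds.fa --fused-fasta fused.fa \
    --fastq1 fx/reads_1.fastq --fastq2 fx/reads_2.fastq --out-dir out
```

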