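# Methods

This note documents the model behind nulloscan, the parameters that matter,
the numerical conventions, and what the synthetic fixtures do and do not
show about real data.

## Nullomer model

A *CCDS-nullomer* is a nucleotide word of length k = 16 absent from the
consensus coding sequence collection. Because coding sequences are stranded,
CCDS presence is indexed **forward-only**; a word is a nullomer iff it is
pure A/C/G/T, of length exactly k, and not a substring of any coding
sequence. Windows containing N are never members and never match — N cannot
support exact k-mer identity.

A somatic coding mutation (or a fusion junction) rewrites a short stretch of
coding sequence and thereby typically creates words that did not previously
exist in the coding set. The database build enumerates exactly those words;
detection reduces to exact multi-pattern search plus a mapping confirmation.
k = 16 balances sensitivity (shorter words are created by more mutations)
against specificity and search speed.

Two repetition guards apply. Genome occurrence counting is
**double-stranded** (word + reverse complement, overlapping occurrences
included) because transcription can originate from either strand; it is a
package option (`double_stranded=False` reverts to forward-only, and the
count saturates at cap+1 since only the cap comparison matters). Words
occurring more than **cap = 300** times in the genome are discarded: such
words live in repeat elements whose transcription would produce false
matches.

## Epitope → nullomer association

1. Neoepitope and wildtype epitope are aligned with Smith–Waterman
   (BLOSUM62, gap open 10, gap extend 1 — the scoring is configurable; for
   equal-length pairs within two mismatches a direct comparison fast path is
   used, which is the overwhelmingly common case).
2. Records with an indel or more than two substitutions are excluded;
   accepted records carry one or two substitution sites.
3. The wildtype epitope is located on the protein translation of its coding
   sequence by exact substring search; **all** match offsets are processed.
   A record whose wildtype is absent is dropped and reported ("wildtype not
   found"), as is a record whose transcript is unknown.
4. At each substitution site every codon of the neo residue is enumerated
   (cartesian product across sites). Every conformation translates exactly
   to the neoepitope.
5. The conformation is embedded in its full coding-sequence context and
   every k-window overlapping ≥1 mutated base is tested: absent from the
   CCDS index and within the genome cap ⇒ emitted. Windows are clipped at
   sequence ends, never padded. Windows may extend beyond the epitope into
   flanking coding sequence — any narrower choice would discard k-mers that
   genuinely witness the mutation; any wider one would admit k-mers that do
   not overlap a mutated base and so cannot.
6. Neoepitopes created by the same mutation group (same transcript, same
   absolute substitution set) are reported together under one target id of
   the form `transcript|T2I` (protein positions are 0-based in code,
   1-based in identifiers and reports).

## Fusion junctions

Junction tables give, 1-based, the genomic locus of the **last transcribed
base of the 5′ partner** and the **first base of the 3′ partner**
(ChimerKB-style convention; inclusivity is configurable in principle but
this reading is the default). 500 nt ending at the 5′ breakpoint and 500 nt
starting at the 3′ breakpoint are extracted in transcript orientation
(minus-strand flanks reverse complemented) and concatenated; flanks truncate
at chromosome ends and the junction offset records the actual 5′
contribution. Only the ≤ k−1 = 15 windows with at least one base on each
side of the junction can witness the fusion; they pass the same
CCDS-absence and genome-cap filters.

Junction neoepitopes are scanned only where (i) both breakpoints are inside
annotated coding sequence, (ii) the 5′ breakpoint does not split the start
codon, and (iii) the 3′ gene remains in its original frame
(`kept5 ≡ c3 (mod 3)`). The fused coding region is translated in the 5′
frame; every 9-aa window whose coding interval strictly contains the
junction (8 windows for a between-codon junction, 9 for a mid-codon one) is
kept if absent — exact substring test — from the reference proteome,
isoforms included. Intronic/UTR fusions return an explicit "non-coding
junction" reason rather than peptides.

## Detection filters

Scanning is exact multi-pattern matching: forward words on mate 1, reverse
complements on mate 2 (stranded library, mate 1 sense; `library_type="rf"`
swaps mates). All patterns share length k, so a sliding-window set lookup is
used — equivalent to an Aho–Corasick automaton for equal-length patterns at
O(read length) per read.

Hit pairs are aligned to the hit nullomer's own target with a local aligner
scoring match +2, mismatch −4 (a "medium-quality" mismatch), gap open −5,
gap extend −3; built-in alignments carry MAPQ 0 and are therefore judged by
the score branch only. External SAM alignments (AS tag, CIGAR soft clips,
MAPQ, mate flags) pass through the identical filter logic.

* **Duplicate removal** happens first (matching the pipeline's stage
  order), at fragment granularity: among read pairs sharing (target,
  fragment start, fragment end, orientation), the pair with the highest
  summed base quality is kept; ties keep the first in input order, making
  the contract deterministic given input order.
* **Soft-clip cut:** reads with clipped fraction strictly greater than the
  exact rational 1/3 of the full read length are removed.
* **Score branch:** accept if MAPQ > 10 (coding targets) / > 30 (fused
  targets, where MAPQ is uninformative against a tiny reference), or if
  AS ≥ MES(AL) with MES(AL) = slope·(AL−35)+64. The slope is kept as the
  exact rational 213/115: both published anchors (64@35, 277@150) then sit
  exactly on the line, and since those mismatch loads are meant to be
  *allowed*, the comparison is non-strict. `strict_mes=True` and the
  compatibility slope 1.85 expose the alternative readings.
* **Junction flank:** fusion alignments must cover ≥5 reference nt on each
  side of the junction.

Per-nullomer coverage counts **distinct surviving fragments** (read pairs)
with at least one mate carrying the nullomer and aligned to that nullomer's
own target — after duplicate removal the two mates of a fragment are not
independent evidence, so fragments, not mates, are the counting unit. A
hit whose read aligns only to a different target counts for nothing. A
target's coverage is that of its most covered nullomer (ties broken
lexicographically for determinism); thresholds are ≥3 reads for
neoepitopes and ≥2 reads plus ≥2 distinct nullomers for fusions. Rows
below threshold are still reported, with a false pass flag.

## Annotation filters

Binding predictions keep rows with %Rank strictly below 2.0 (per
(peptide, allele) row; all retained predictions per epitope are
serialized); rows lacking %Rank are rejected with a warning. Germline rows
must satisfy all of: AF > 1e−7, consequence `missense_variant`, biotype
`protein_coding`, feature starting with `ENST`. Both filters are pure row
predicates — output ⊆ input, order preserved — and the metadata join is
idempotent, case-insensitive on peptides, and never drops unmatched
entries. Affinity values are serialized verbatim, no unit conversion.

## Cohort arithmetic

Per-sample normalized expression is `log10(1 + 1e6·reads/total_reads)` —
log10 of counts-per-million with a pseudocount. The per-million scale and
the pseudocount are package decisions: the normalization is stated upstream
only as "divide by total reads, scale by log10", which maps all realistic
counts to large negative numbers and makes the 0.1 expression threshold
meaningless; log10(1+CPM) maps zero to zero and keeps the threshold
interpretable. Alternative definitions are selectable in config, and the
0.1 threshold is honored only under this definition.

"Present in a sample" means ≥1 mapped read after detection thresholds.
*Generic*: prevalence > 20% **and** mean normalized expression > 0.1 in
both groups. *Discriminative* (applied after generic removal): ≥2-fold
mean-expression difference in either direction, with the enriched group
containing ≥3 individuals in which the target was detected. Both flags are
order-free functions of the per-target statistics. RPKM
(`(reads/(total/1e6))/length`) is provided for length-normalized auxiliary
features.

## Synthetic fixtures: what they show and what they do not

The toy reference embeds n = 8 random unspliced forward-strand genes of
300 nt (uniform base composition, GC ≈ 0.5) in a ~4.2 kb genome with 200 nt
spacers — large enough that 16-mers are effectively unique, small enough
that brute-force oracles run in milliseconds. Planted epitope records use
**single-nucleotide missense variants** as the expressed tumor allele (the
builder still enumerates all codon conformations), matching how point
neoepitopes arise and keeping planted reads within the mismatch budget the
MES line allows; planting resamples until at least one nullomer survives,
window regions are disjoint per transcript, and nullomer sets are pairwise
disjoint across targets (including fusions), so truth attribution is
unambiguous. Negative controls are made unrecoverable by appending a
synthetic decoy paralog containing every mutated window to the coding set,
forcing the documented "no nullomer" drop.

Simulated reads are 100 nt mates of 130 nt fragments, mate 1 sense,
constant quality 'I' (Q40), substitution errors only (rate 0 by default) —
so the identity AL + clips = read length holds exactly and planted
per-target coverage equals the fragment count. Background pairs come from
unmutated coding sequence and can never contain a nullomer, by definition.

Passing tests on these fixtures demonstrate the pipeline's logic —
soundness of every emitted nullomer, exact planted-target recovery, zero
false passes, correct boundary behaviour — but not performance on real
cfRNA, which adds spliced transcripts, non-uniform fragment lengths,
quality-dependent errors, repeat-derived transcription, microbial reads and
cross-sample batch effects. Claims about real-data sensitivity or
specificity are outside what this test bed can support.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; SAM and junction-table I/O
convert to/from 1-based. Exact rational arithmetic (`fractions.Fraction`)
is used for the MES slope and the soft-clip threshold so boundary cases are
decided exactly, never by floating-point luck. Mutations within k−1 nt of a
sequence end simply have fewer candidate windows (clipping, no padding).
Translation stops at the first stop codon, flags trailing partial codons,
and maps non-ACGT codons to 'X'; substitutions to residues without codons
(stop, 'X') reject the record with a reason. Empty FASTQ input yields empty
reports and exit 0. The detector accepts alignments from its built-in
aligner or an external SAM under one contract; round-tripping built-in
alignments through SAM reproduces identical reports on error-free reads.
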