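"""Fused junction sequences, junction-spanning nullomers, junction peptides.

A fusion is specified by the genomic locus of the last base kept from the
5' gene and the first base of the 3' gene.  Up to 500 nt on each side are
fused in transcript orientation; only 16-mers that straddle the junction
(at most 15 of them) can witness the fusion.
"""

from nulloscan import make_toy_reference
from nulloscan.fusions import FusionJunction, build_fused_sequence, extract_junction_nullomers, scan_junction_neoepitopes

ref = make_toy_reference(seed=1)
place5, place3 = ref.placements["t1"], ref.placements["t4"]
junction = FusionJunction(
    "DEMO", "chr1", place5.start + 90, "+", "chr1", place3.start + 90 + 1, "+",
    gene5="GENE1", gene3="GENE4",
)

fused = build_fused_sequence(ref.genome, junction, flank=500)
print(f"fused sequence: {len(fused.nt)} nt, junction after position {fused.junction_offset}")

nullomers = extract_junction_nullomers(fused, ref.presence(16), ref.genome_counter())
print(f"junction-spanning nullomers: {len(nullomers)} (of at most 15 candidates)")

peptides, reason = scan_junction_neoepitopes(junction, ref.cds_by_gene, ref.proteome)
print(f"junction 9-mer neoepitopes: {[p.peptide for p in peptides]}")

# Both breakpoints fall inside coding sequence and the 3' gene stays in
# frame, so up to 8 (between-codon) or 9 (mid-codon) peptide windows span
# the junction; those absent from the reference proteome are neoepitopes.
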