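"""End-to-end detection: plant mutations, simulate stranded reads, detect.

Simulated read pairs (mate 1 sense, mate 2 antisense) carry planted
neoepitope mutations at coverage 6 and fusion junctions at coverage 6;
background pairs come from unmutated coding sequence.  The detector scans
for nullomers, aligns candidate pairs to their targets, applies the MES /
soft-clip / junction-flank filters and aggregates per-target coverage.
"""

from nulloscan import make_toy_reference, plant_epitope_db, plant_fusion_db, run_detection, simulate_reads
from nulloscan.epitopes import EpitopeRecord, build_epitope_mapping
from nulloscan.fusions import FusionJunction, build_fusion_mapping

ref = make_toy_reference(seed=1)
epitope_df, truth = plant_epitope_db(ref, n_records=12, seed=1)
avoid = frozenset().union(*(p.all_nullomers for p in truth.epitopes))
fusion_df, fusion_truth = plant_fusion_db(ref, n_fusions=3, seed=1, avoid_words=avoid)
truth.fusions = fusion_truth.fusions

presence, counter = ref.presence(16), ref.genome_counter()
records = [EpitopeRecord(r.wildtype_peptide, r.neo_peptide, r.transcript_id, r.source_db)
           for r in epitope_df.itertuples(index=False)]
entries, _ = build_epitope_mapping(records, ref.ccds_by_transcript, presence, counter)
junctions = [FusionJunction(r.fusion_id, r.chrom5, int(r.pos5), r.strand5,
                            r.chrom3, int(r.pos3), r.strand3, r.gene5, r.gene3)
             for r in fusion_df.itertuples(index=False)]
fusion_entries, fused_by_id, _ = build_fusion_mapping(
    junctions, ref.genome, presence, counter, ref.cds_by_gene, ref.proteome)

pairs, planted = simulate_reads(ref, truth, coverage=6, seed=2)
target_seqs = {c.transcript_id: c.nt for c in ref.ccds}
target_seqs |= {fid: f.nt for fid, f in fused_by_id.items()}
junction_offsets = {fid: f.junction_offset for fid, f in fused_by_id.items()}

neo, fus, rejects = run_detection(
    pairs, entries + fusion_entries, target_seqs, junction_offsets, sample_id="demo")

print(f"{len(pairs)} read pairs scanned; {len(rejects)} alignments rejected by filters")
print("\ntarget                  reads  nullomers  pass")
for row in neo + fus:
    print(f"{row.target_id:<22}  {row.mapped_reads:>5}  {row.n_detected_nullomers:>9}  {row.passes}")

# 'reads' is the coverage of the target's most covered nullomer (distinct
# fragments after duplicate removal).  Neoepitopes pass at >=3 reads;
# fusions at >=2 reads AND >=2 distinct junction-spanning nullomers.
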