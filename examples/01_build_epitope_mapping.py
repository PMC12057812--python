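"""Build a nullomer mapping from epitope records on a toy reference.

Generates a small random genome with embedded coding genes, plants a dozen
(wildtype, neoepitope, transcript) records, and runs the full association:
Smith-Waterman epitope alignment, codon-conformation enumeration, length-16
nullomer extraction and genome-occurrence filtering.
"""

from nulloscan import make_toy_reference, plant_epitope_db
from nulloscan.epitopes import EpitopeRecord, build_epitope_mapping

ref = make_toy_reference(seed=1, n_genes=8, cds_len=300)
epitope_df, truth = plant_epitope_db(ref, n_records=12, seed=1)

records = [
    EpitopeRecord(r.wildtype_peptide, r.neo_peptide, r.transcript_id, r.source_db)
    for r in epitope_df.itertuples(index=False)
]
entries, report = build_epitope_mapping(
    records, ref.ccds_by_transcript, ref.presence(16), ref.genome_counter()
)

print(report.summary())
print(f"\n{len(entries)} mapping entries; first three:")
for entry in entries[:3]:
    print(f"  {entry.nullomer}  ->  {entry.target_id}  (neoepitopes: {','.join(entry.neoepitopes)})")

# Each row links one 16-nt word that exists nowhere in the coding set to the
# exact mutation that creates it: seeing that word in a read is evidence for
# the mutation, provided the read also maps to the right transcript.
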