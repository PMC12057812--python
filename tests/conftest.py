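"""Shared fixtures: one toy reference and one fully built pipeline state,
session-scoped so expensive construction happens once."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from nulloscan import (
    FusionJunction,
    make_toy_reference,
    plant_epitope_db,
    plant_fusion_db,
)
from nulloscan.epitopes import EpitopeRecord, build_epitope_mapping
from nulloscan.fusions import build_fusion_mapping

SEED = 7


@dataclass
class Pipeline:
    ref: object
    truth: object
    epitope_df: object
    fusion_df: object
    records: list
    entries: list
    report: object
    fusion_entries: list
    fused_by_id: dict
    fusion_report: object
    presence: object
    counter: object

    @property
    def all_entries(self):
        return self.entries + self.fusion_entries

    @property
    def target_seqs(self):
        seqs = {c.transcript_id: c.nt for c in self.ref.ccds}
        seqs.update({fid: f.nt for fid, f in self.fused_by_id.items()})
        return seqs

    @property
    def junction_offsets(self):
        return {fid: f.junction_offset for fid, f in self.fused_by_id.items()}


def build_pipeline(seed: int = SEED, n_records: int = 12, n_fusions: int = 3) -> Pipeline:
    ref = make_toy_reference(seed=seed, n_genes=8, cds_len=300)
    epitope_df, truth = plant_epitope_db(ref, n_records=n_records, seed=seed)
    avoid = frozenset().union(*(p.all_nullomers for p in truth.epitopes)) if truth.epitopes else frozenset()
    fusion_df, fusion_truth = plant_fusion_db(ref, n_fusions=n_fusions, seed=seed, avoid_words=avoid)
    truth.fusions = fusion_truth.fusions
    presence = ref.presence(16)
    counter = ref.genome_counter()
    records = [
        EpitopeRecord(
            r.wildtype_peptide,
            r.neo_peptide,
            r.transcript_id,
            r.source_db,
            metadata=(
                ("gene_id", r.gene_id),
                ("hgnc_symbol", r.hgnc_symbol),
                ("gene_function", r.gene_function),
            ),
        )
        for r in epitope_df.itertuples(index=False)
    ]
    entries, report = build_epitope_mapping(records, ref.ccds_by_transcript, presence, counter)
    junctions = [
        FusionJunction(
            r.fusion_id, r.chrom5, int(r.pos5), r.strand5,
            r.chrom3, int(r.pos3), r.strand3, r.gene5, r.gene3,
            metadata=(("gene_function", r.gene_function),),
        )
        for r in fusion_df.itertuples(index=False)
    ]
    fusion_entries, fused_by_id, fusion_report = build_fusion_mapping(
        junctions, ref.genome, presence, counter, ref.cds_by_gene, ref.proteome
    )
    return Pipeline(
        ref=ref, truth=truth, epitope_df=epitope_df, fusion_df=fusion_df,
        records=records, entries=entries, report=report,
        fusion_entries=fusion_entries, fused_by_id=fused_by_id,
        fusion_report=fusion_report, presence=presence, counter=counter,
    )


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    return build_pipeline()


@pytest.fixture(scope="session")
def toy_ref(pipeline):
    return pipeline.ref
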