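"""The nullomer mapping file: one row per (nullomer, target) with metadata.

A *target* is either a neoepitope-producing mutation group (all neoepitopes
created by the same amino-acid substitution(s) on the same transcript) or a
gene-fusion junction.  The mapping file links each nullomer to its target so
the detector can require that a read carrying the nullomer also aligns to
that target's own sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["NullomerMappingEntry", "write_mapping_tsv", "read_mapping_tsv", "MAPPING_COLUMNS"]

#: Stable column order of the mapping TSV (the interchange contract).
MAPPING_COLUMNS = [
    "nullomer",
    "target_kind",
    "target_id",
    "align_target",
    "gene_id",
    "hgnc_symbol",
    "neoepitopes",
    "database",
    "gene_function",
    "wt_hla_affinities",
    "neo_hla_affinities",
    "germline_frequencies",
    "junction_offset",
    "locus5",
    "locus3",
]


@dataclass
class NullomerMappingEntry:
    """One nullomer linked to the neoepitope mutation group or fusion it tags.

    ``align_target`` names the sequence reads must map to (a transcript id for
    neoepitopes, the fusion id for fusions); ``target_id`` identifies the
    reported unit (mutation group / fusion).
    """

    nullomer: str
    target_kind: str  # "neoepitope" | "fusion"
    target_id: str
    align_target: str
    gene_id: str = ""
    hgnc_symbol: str = ""
    neoepitopes: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)
    junction_offset: int | None = None  # fusions only

    def sort_key(self) -> tuple:
        return (self.target_kind, self.target_id, self.nullomer)


def write_mapping_tsv(entries: list[NullomerMappingEntry], path: str | Path, header_lines: list[str] | None = None) -> None:
    rows = []
    for e in sorted(entries, key=NullomerMappingEntry.sort_key):
        rows.append(
            {
                "nullomer": e.nullomer,
                "target_kind": e.target_kind,
                "target_id": e.target_id,
                "align_target": e.align_target,
                "gene_id": e.gene_id,
                "hgnc_symbol": e.hgnc_symbol,
                "neoepitopes": ",".join(e.neoepitopes),
                "database": e.metadata.get("database", ""),
                "gene_function": e.metadata.get("gene_function", ""),
                "wt_hla_affinities": e.metadata.get("wt_hla_affinities", ""),
                "neo_hla_affinities": e.metadata.get("neo_hla_affinities", ""),
                "germline_frequencies": e.metadata.get("germline_frequencies", ""),
                "junction_offset": "" if e.junction_offset is None else str(e.junction_offset),
                "locus5": e.metadata.get("locus5", ""),
                "locus3": e.metadata.get("locus3", ""),
            }
        )
    df = pd.DataFrame(rows, columns=MAPPING_COLUMNS)
    with open(path, "wt") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_mapping_tsv(path: str | Path) -> list[NullomerMappingEntry]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(MAPPING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mapping columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        meta = {
            key: getattr(row, key)
            for key in (
                "database",
                "gene_function",
                "wt_hla_affinities",
                "neo_hla_affinities",
                "germline_frequencies",
                "locus5",
                "locus3",
            )
            if getattr(row, key)
        }
        entries.append(
            NullomerMappingEntry(
                nullomer=row.nullomer,
                target_kind=row.target_kind,
                target_id=row.target_id,
                align_target=row.align_target,
                gene_id=row.gene_id,
                hgnc_symbol=row.hgnc_symbol,
                neoepitopes=[p for p in row.neoepitopes.split(",") if p],
                metadata=meta,
                junction_offset=int(row.junction_offset) if row.junction_offset else None,
            )
        )
    return entries
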