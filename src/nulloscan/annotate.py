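"""Retention filters for external HLA-binding and germline-frequency tables.

Binding predictions (netMHCpan-style exports) are kept when their %Rank —
the rank of the predicted affinity against random natural peptides — is
strictly below 2%.  Germline variant rows (gnomAD-style exports) are kept
when the combined allele frequency exceeds 1e-7, the consequence is a
missense variant on a protein-coding transcript, and the feature is an
Ensembl transcript id (ENST...).  Retained rows are joined onto mapping
entries by exact, case-insensitive peptide match; unmatched entries stay in
the mapping with empty annotation fields.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .mapping import NullomerMappingEntry

__all__ = [
    "read_binding_table",
    "read_germline_table",
    "filter_binding",
    "filter_germline",
    "join_metadata",
]

_RANK_ALIASES = ("percent_rank", "%Rank", "Rank", "%Rank_EL", "rank")
_PEPTIDE_ALIASES = ("peptide", "Peptide", "Epitope")
_ALLELE_ALIASES = ("allele", "MHC", "HLA", "Allele")
_AFFINITY_ALIASES = ("affinity_nm", "Aff(nM)", "affinity", "nM")

_GERMLINE_FREQ_COLUMNS = [
    "AF",
    "AF_XX",
    "AF_XY",
    "AF_afr",
    "AF_amr",
    "AF_asj",
    "AF_eas",
    "AF_fin",
    "AF_mid",
    "AF_nfe",
    "AF_sas",
]


def _find_column(df: pd.DataFrame, aliases: tuple[str, ...], what: str) -> str:
    for name in aliases:
        if name in df.columns:
            return name
    raise ValueError(f"no {what} column found (tried {aliases})")


def read_binding_table(path: str | Path) -> pd.DataFrame:
    """Normalize a binding-prediction export to columns
    peptide / allele / affinity_nm / percent_rank."""
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, comment="#")
    df = pd.DataFrame(
        {
            "peptide": raw[_find_column(raw, _PEPTIDE_ALIASES, "peptide")].astype(str).str.upper(),
            "allele": raw[_find_column(raw, _ALLELE_ALIASES, "allele")].astype(str),
            "percent_rank": pd.to_numeric(raw[_find_column(raw, _RANK_ALIASES, "%Rank")], errors="coerce"),
        }
    )
    try:
        aff = _find_column(raw, _AFFINITY_ALIASES, "affinity")
        df["affinity_nm"] = pd.to_numeric(raw[aff], errors="coerce")
    except ValueError:
        df["affinity_nm"] = float("nan")
    return df


def read_germline_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: germline table needs a 'peptide' column")
    df["peptide"] = df["peptide"].astype(str).str.upper()
    return df


def filter_binding(rows: pd.DataFrame, rank_max: float = 2.0) -> pd.DataFrame:
    """Keep predictions with %Rank strictly below ``rank_max`` (default 2%).

    Rows with a missing %Rank are rejected with a warning; all retained
    predictions per epitope are kept.  Order is preserved.
    """
    missing = rows["percent_rank"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} binding row(s) lack %Rank and were rejected")
    return rows.loc[~missing & (rows["percent_rank"] < rank_max)].copy()


def filter_germline(
    rows: pd.DataFrame,
    af_min: float = 1e-07,
    consequence: str = "missense_variant",
    biotype: str = "protein_coding",
    feature_prefix: str = "ENST",
) -> pd.DataFrame:
    """Keep germline rows meeting all four retention criteria."""
    keep = (
        (pd.to_numeric(rows["AF"], errors="coerce") > af_min)
        & (rows["consequence"].astype(str) == consequence)
        & (rows["biotype"].astype(str) == biotype)
        & rows["feature"].astype(str).str.startswith(feature_prefix)
    )
    return rows.loc[keep.fillna(False)].copy()


def _format_binding(rows: pd.DataFrame) -> str:
    parts = []
    for row in rows.itertuples(index=False):
        aff = "" if pd.isna(row.affinity_nm) else f":{row.affinity_nm:g}nM"
        parts.append(f"{row.allele}:{row.percent_rank:g}%{aff}")
    return ";".join(parts)


def _format_germline(rows: pd.DataFrame) -> str:
    parts = []
    for _, row in rows.iterrows():
        freqs = ",".join(f"{c}={row[c]:g}" for c in _GERMLINE_FREQ_COLUMNS if c in rows.columns and pd.notna(row[c]))
        grpmax = f",grpmax={row['grpmax']}" if "grpmax" in rows.columns and pd.notna(row["grpmax"]) else ""
        parts.append(freqs + grpmax)
    return ";".join(parts)


def join_metadata(
    entries: list[NullomerMappingEntry],
    binding: pd.DataFrame | None = None,
    germline: pd.DataFrame | None = None,
    wildtype_of: dict[str, str] | None = None,
) -> list[NullomerMappingEntry]:
    """Annotate mapping entries in place with retained binding and germline
    rows (peptide match, exact and case-insensitive); idempotent.

    ``wildtype_of`` maps a neoepitope to its wildtype epitope so the
    wildtype's own binding predictions can be serialized alongside.
    """
    wildtype_of = {k.upper(): v.upper() for k, v in (wildtype_of or {}).items()}
    for entry in entries:
        neos = [p.upper() for p in entry.neoepitopes]
        if binding is not None and len(binding):
            neo_rows = binding[binding["peptide"].isin(neos)]
            entry.metadata["neo_hla_affinities"] = _format_binding(neo_rows)
            wts = {wildtype_of[p] for p in neos if p in wildtype_of}
            wt_rows = binding[binding["peptide"].isin(sorted(wts))]
            entry.metadata["wt_hla_affinities"] = _format_binding(wt_rows)
        if germline is not None and len(germline):
            g_rows = germline[germline["peptide"].isin(neos)]
            entry.metadata["germline_frequencies"] = _format_germline(g_rows)
    return entries
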