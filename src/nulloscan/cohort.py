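"""Post-detection cohort arithmetic.

Per-sample read coverage of a target is normalized by library size as
``log10(1 + CPM)`` (counts per million; the pseudocount makes zero coverage
map to zero and keeps the 0.1 expression threshold meaningful).  Targets
expressed broadly in both cases and controls are flagged *generic* and are
meant to be removed from analyses; among the rest, targets with a two-fold
mean-expression difference between groups, supported by detection in at
least three individuals of the enriched group, are flagged *discriminative*.
An RPKM helper covers length-normalized expression of auxiliary features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CohortConfig",
    "SampleExpression",
    "normalized_expression",
    "flag_generic",
    "flag_discriminative",
    "rpkm",
    "cohort_summary",
]


@dataclass
class CohortConfig:
    generic_prevalence_min: float = 0.20  # per group, strict >
    generic_expression_min: float = 0.1  # mean normalized expression, strict >
    discriminative_fold: float = 2.0
    discriminative_min_individuals: int = 3


@dataclass
class SampleExpression:
    """One sample: group label, library size, per-target mapped read counts."""

    sample_id: str
    group: str  # "case" | "control"
    total_reads: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"{self.sample_id}: total_reads must be positive")


def normalized_expression(mapped_reads: int, total_reads: int) -> float:
    """log10(1 + 1e6 * mapped_reads / total_reads); zero maps to zero."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return math.log10(1.0 + 1e6 * mapped_reads / total_reads)


@dataclass
class TargetCohortStats:
    target_id: str
    prevalence_case: float
    prevalence_control: float
    mean_expr_case: float
    mean_expr_control: float
    n_detected_case: int
    n_detected_control: int


def _target_stats(target_id: str, samples: list[SampleExpression]) -> TargetCohortStats:
    by_group: dict[str, list[float]] = {"case": [], "control": []}
    detected: dict[str, int] = {"case": 0, "control": 0}
    for sample in samples:
        count = sample.counts.get(target_id, 0)
        by_group[sample.group].append(normalized_expression(count, sample.total_reads))
        if count >= 1:
            detected[sample.group] += 1
    def _mean(xs: list[float]) -> float:
        return sum(xs) / len(xs) if xs else 0.0
    n_case = len(by_group["case"])
    n_control = len(by_group["control"])
    return TargetCohortStats(
        target_id=target_id,
        prevalence_case=detected["case"] / n_case if n_case else 0.0,
        prevalence_control=detected["control"] / n_control if n_control else 0.0,
        mean_expr_case=_mean(by_group["case"]),
        mean_expr_control=_mean(by_group["control"]),
        n_detected_case=detected["case"],
        n_detected_control=detected["control"],
    )


def flag_generic(stats: TargetCohortStats, cfg: CohortConfig | None = None) -> bool:
    """Generic: prevalent (>20%) and expressed (mean > 0.1) in BOTH groups."""
    cfg = cfg or CohortConfig()
    return (
        stats.prevalence_case > cfg.generic_prevalence_min
        and stats.prevalence_control > cfg.generic_prevalence_min
        and stats.mean_expr_case > cfg.generic_expression_min
        and stats.mean_expr_control > cfg.generic_expression_min
    )


def flag_discriminative(stats: TargetCohortStats, cfg: CohortConfig | None = None) -> str:
    """'case-enriched' / 'control-enriched' / 'none' by the two-fold rule with
    the >=3-detected-individuals support requirement.  Assumes generic targets
    were already removed."""
    cfg = cfg or CohortConfig()
    if (
        stats.mean_expr_case >= cfg.discriminative_fold * stats.mean_expr_control
        and stats.mean_expr_case > 0
        and stats.n_detected_case >= cfg.discriminative_min_individuals
    ):
        return "case-enriched"
    if (
        stats.mean_expr_control >= cfg.discriminative_fold * stats.mean_expr_case
        and stats.mean_expr_control > 0
        and stats.n_detected_control >= cfg.discriminative_min_individuals
    ):
        return "control-enriched"
    return "none"


def rpkm(mapped_reads: int, total_reads: int, effective_length: float) -> float:
    """Reads per kilobase of feature per million library reads."""
    if total_reads <= 0 or effective_length <= 0:
        raise ValueError("total_reads and effective_length must be positive")
    return (mapped_reads / (total_reads / 1_000_000)) / effective_length


def cohort_summary(samples: list[SampleExpression], cfg: CohortConfig | None = None) -> pd.DataFrame:
    """Per-target cohort table with generic/discriminative flags.

    Deterministic: independent of sample order (targets sorted, statistics
    are order-free aggregates).
    """
    cfg = cfg or CohortConfig()
    groups = {s.group for s in samples}
    bad = groups - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    targets = sorted({t for s in samples for t in s.counts})
    rows = []
    for target in targets:
        stats = _target_stats(target, samples)
        generic = flag_generic(stats, cfg)
        rows.append(
            {
                "target_id": target,
                "prevalence_case": stats.prevalence_case,
                "prevalence_control": stats.prevalence_control,
                "mean_expr_case": stats.mean_expr_case,
                "mean_expr_control": stats.mean_expr_control,
                "n_detected_case": stats.n_detected_case,
                "n_detected_control": stats.n_detected_control,
                "generic": generic,
                "discriminative": "none" if generic else flag_discriminative(stats, cfg),
            }
        )
    return pd.DataFrame(rows)
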