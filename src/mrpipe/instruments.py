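"""Instrument selection: p-value threshold, greedy LD clumping, F-statistic filter.

The selection funnel mirrors standard two-sample MR practice: keep
genome-wide-associated SNPs (default p < 5e-8, relaxed thresholds of
5e-6 or 1e-5 for sparse exposures), thin them to approximate linkage
equilibrium by greedy clumping (window 10,000 kb, r² < 0.001), and drop
weak instruments by the per-SNP F statistic beta²/se² with the customary
cutoff of 10 (boundary inclusive). Every removal is attributed to one
step in an audit so counts reconcile: input = retained + Σ removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .gwas_io import GwasRecord, LdMatrix


class InstrumentError(Exception):
    """Instrument-selection failure (missing LD entries, bad thresholds)."""


@dataclass
class InstrumentSet:
    """Retained instruments plus the thresholds and audit that produced them."""

    exposure_name: str
    records: list[GwasRecord]
    p_threshold: float
    clump_r2: float
    clump_kb: int
    f_min: float
    audit: dict[str, int] = field(default_factory=dict)


def select_by_pvalue(
    records: Sequence[GwasRecord], p_threshold: float
) -> list[GwasRecord]:
    """Records with pval strictly below the threshold, input order preserved."""
    if not (0 < p_threshold < 1):
        raise InstrumentError(f"p_threshold must be in (0,1), got {p_threshold}")
    return [r for r in records if r.pval < p_threshold]


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength, F = beta² / se²."""
    if se <= 0:
        raise InstrumentError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_weak(records: Sequence[GwasRecord], f_min: float = 10.0) -> list[GwasRecord]:
    """Retain records with F ≥ f_min (values below ~10 risk weak-instrument bias)."""
    if f_min <= 0:
        raise InstrumentError(f"f_min must be > 0, got {f_min}")
    return [r for r in records if f_statistic(r.beta, r.se) >= f_min]


def _clump_order_key(rec: GwasRecord):
    # p-value ties broken by (chrom, pos, snp_id): deterministic across platforms
    return (rec.pval, rec.chrom, rec.pos, rec.snp_id)


def clump(
    records: Sequence[GwasRecord],
    ld: LdMatrix,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
) -> list[GwasRecord]:
    """Greedy LD clumping.

    Repeatedly take the remaining SNP with the smallest p-value as an
    index SNP and discard every unselected SNP on the same chromosome
    within ``clump_kb`` kilobases whose r² with the index is ≥
    ``clump_r2``. The retained set is independent of input row order.
    """
    if not (0 < clump_r2 <= 1):
        raise InstrumentError(f"clump_r2 must be in (0,1], got {clump_r2}")
    if clump_kb <= 0:
        raise InstrumentError(f"clump_kb must be positive, got {clump_kb}")
    missing = [r.snp_id for r in records if r.snp_id not in ld]
    if missing:
        raise InstrumentError(f"SNP(s) absent from LD matrix: {missing}")

    window_bp = clump_kb * 1000
    remaining = sorted(records, key=_clump_order_key)
    kept: list[GwasRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.lookup(index.snp_id, r.snp_id) >= clump_r2
            )
        ]
    # report in input order for stable downstream tables
    kept_ids = {r.snp_id for r in kept}
    return [r for r in records if r.snp_id in kept_ids]


def select_instruments(
    records: Sequence[GwasRecord],
    ld: LdMatrix,
    *,
    exposure_name: str = "exposure",
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Run the full funnel p-threshold → clump → F-filter with an audit trail."""
    n_in = len(records)
    sig = select_by_pvalue(records, p_threshold)
    clumped = clump(sig, ld, clump_r2=clump_r2, clump_kb=clump_kb)
    strong = filter_weak(clumped, f_min)
    audit = {
        "input": n_in,
        "removed_pvalue": n_in - len(sig),
        "removed_clump": len(sig) - len(clumped),
        "removed_weak": len(clumped) - len(strong),
        "retained": len(strong),
    }
    return InstrumentSet(
        exposure_name=exposure_name,
        records=strong,
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_kb=clump_kb,
        f_min=f_min,
        audit=audit,
    )


def exclude_outcome_associated(
    records: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    outcome_p_exclusion: float = 5e-8,
) -> list[GwasRecord]:
    """Drop instruments strongly associated with the outcome.

    Instruments whose outcome p-value falls below ``outcome_p_exclusion``
    plausibly act on the outcome directly and are excluded. The cutoff is
    a configurable convention (default: the genome-wide threshold).
    """
    out_p = {r.snp_id: r.pval for r in outcome}
    return [
        r
        for r in records
        if r.snp_id not in out_p or out_p[r.snp_id] >= outcome_p_exclusion
    ]
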