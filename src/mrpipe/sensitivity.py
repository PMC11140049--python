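"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q tests whether the per-SNP Wald ratios are mutually
consistent (excess heterogeneity suggests invalid instruments and gates
fixed- vs random-effects IVW); the MR-Egger intercept tests directional
pleiotropy; leave-one-out re-estimates IVW dropping each SNP in turn to
expose single-variant influence; funnel and scatter tables are the
plot-ready exports (no rendering here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EstimationError,
    MREstimate,
    PleiotropyResult,
    ivw,
    mr_egger,
    wald_ratios,
    _ivw_core,
)
from .harmonize import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "PleiotropyResult",
    "LeaveOneOutResult",
    "cochran_q",
    "egger_intercept",
    "leave_one_out",
    "funnel_data",
    "scatter_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over the per-SNP Wald ratios."""

    q: float
    df: int
    pval: float


@dataclass
class LeaveOneOutResult:
    """Per-exclusion IVW estimates plus the all-SNP row (label ``All``)."""

    table: pd.DataFrame  # columns: excluded_snp_id, beta, se, pval, model_note


def cochran_q(H: HarmonizedSet) -> HeterogeneityResult:
    """Q = Σ w_j (β_j − β_IVW)², w_j the first-order Wald weights, df = J−1."""
    if H.n_snp < 2:
        raise EstimationError(f"Cochran's Q needs at least 2 instruments, got {H.n_snp}")
    _, _, q, j = _ivw_core(H)
    df = j - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept(H: HarmonizedSet) -> PleiotropyResult:
    """The MR-Egger intercept test packaged alone (Table-3-style output)."""
    _, intercept = mr_egger(H)
    return intercept


def leave_one_out(H: HarmonizedSet, mode: str = "auto") -> LeaveOneOutResult:
    """IVW re-estimated excluding each SNP, with the full set as row ``All``.

    The fixed/random gate is re-evaluated per subset when ``mode="auto"``;
    each row's gate outcome is kept in ``model_note``.
    """
    if H.n_snp < 3:
        raise EstimationError(f"leave-one-out needs at least 3 instruments, got {H.n_snp}")
    rows = []
    for i, snp in enumerate(H.snp_ids):
        sub = H.subset([j for j in range(H.n_snp) if j != i])
        est = ivw(sub, mode=mode)
        rows.append((snp, est.beta, est.se, est.pval, est.model_note))
    full = ivw(H, mode=mode)
    rows.append(("All", full.beta, full.se, full.pval, full.model_note))
    return LeaveOneOutResult(
        pd.DataFrame(rows, columns=["excluded_snp_id", "beta", "se", "pval", "model_note"])
    )


def funnel_data(H: HarmonizedSet) -> pd.DataFrame:
    """Funnel-plot table: per-SNP Wald ratio vs precision 1/se(β_j)."""
    if H.n_snp == 0:
        raise EstimationError("funnel data requires a non-empty harmonized set")
    ratios, ses = wald_ratios(H)
    return pd.DataFrame(
        {"snp_id": list(H.snp_ids), "beta_wald": ratios, "precision": 1.0 / ses}
    )


def scatter_data(
    H: HarmonizedSet, estimates: list[MREstimate]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter-plot tables: per-SNP effect pairs and per-method fitted lines.

    Points are oriented so γ_j > 0, matching the usual presentation; each
    line's slope is the method's beta (intercept nonzero only for Egger,
    recomputed on the oriented data).
    """
    if H.n_snp == 0:
        raise EstimationError("scatter data requires a non-empty harmonized set")
    sign = np.where(H.beta_exp < 0, -1.0, 1.0)
    points = pd.DataFrame(
        {
            "snp_id": list(H.snp_ids),
            "beta_exp": H.beta_exp * sign,
            "se_exp": H.se_exp,
            "beta_out": H.beta_out * sign,
            "se_out": H.se_out,
        }
    )
    lines = []
    for est in estimates:
        if est.method == "egger":
            intercept = egger_intercept(H).intercept if H.n_snp >= 3 else 0.0
        else:
            intercept = 0.0
        lines.append((est.method, intercept, est.beta))
    return points, pd.DataFrame(lines, columns=["method", "intercept", "slope"])
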