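"""Multivariable MR and inverse-variance meta-analysis across cohorts.

MVMR regresses the outcome effects on a matrix of exposure effects (one
column per exposure, no intercept, weights 1/se_Γ²), giving each
exposure's direct effect adjusted for the others — the device used to
hold confounder exposures (lipids, weight) fixed. Cohort-level estimates
are pooled by fixed-effect inverse-variance weighting or
DerSimonian–Laird random effects, reporting Q, I² and τ².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import EstimationError, MREstimate, Z95, _make_estimate, _normal_p


class CollinearityError(EstimationError):
    """The exposure-effect design matrix is rank deficient."""


@dataclass
class MvmrInput:
    """Complete-case per-SNP effects for k exposures and one outcome."""

    snp_ids: tuple[str, ...]
    exposure_names: tuple[str, ...]
    beta_exp: np.ndarray  # (J, k)
    se_exp: np.ndarray  # (J, k)
    beta_out: np.ndarray  # (J,)
    se_out: np.ndarray  # (J,)

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        j, k = self.beta_exp.shape
        if len(self.exposure_names) != k:
            raise ValueError("exposure_names length must match beta_exp columns")
        if self.beta_out.shape != (j,) or self.se_out.shape != (j,):
            raise ValueError("outcome arrays must have one entry per SNP")
        if np.any(~np.isfinite(self.beta_exp)):
            raise ValueError("MVMR input must be complete-case (no missing exposure betas)")
        if np.any(self.se_out <= 0):
            raise ValueError("outcome standard errors must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate across k cohorts with heterogeneity statistics."""

    k: int
    pooled_beta: float
    pooled_se: float
    ci_low: float
    ci_high: float
    pval: float
    q: float
    q_pval: float
    i2: float  # percent
    tau2: float
    model: str
    pooled_or: float
    or_ci_low: float
    or_ci_high: float


def mvmr_ivw(data: MvmrInput) -> list[MREstimate]:
    """Weighted multivariable regression of Γ on the exposure-beta matrix.

    No intercept; weights 1/se_Γ²; per-exposure standard errors carry the
    multiplicative overdispersion inflation √(max(Q/(J−k), 1)), matching
    the univariable IVW convention (to which k = 1 reduces exactly).
    """
    x = data.beta_exp
    j, k = x.shape
    if j < k + 1:
        raise EstimationError(f"MVMR needs at least k+1 = {k + 1} SNPs, got {j}")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (data.exposure_names[a], data.exposure_names[b])
            for a in range(k)
            for b in range(a + 1, k)
            if abs(corr[a, b]) > 0.999
        ]
        raise CollinearityError(
            f"exposure-effect matrix rank {rank} < {k}; collinear exposures: {pairs or 'unidentified'}"
        )
    w = 1.0 / data.se_out**2
    fit = sm.WLS(data.beta_out, x, weights=w).fit()
    se_unit = fit.bse / math.sqrt(fit.scale)  # fit.scale = Q/(J-k)
    infl = math.sqrt(max(fit.scale, 1.0)) if j > k else 1.0
    out = []
    for idx, name in enumerate(data.exposure_names):
        beta = float(fit.params[idx])
        se = float(se_unit[idx] * infl)
        out.append(
            _make_estimate(
                f"mvmr_ivw[{name}]", j, beta, se, _normal_p(beta, se),
                f"k = {k} exposures",
            )
        )
    return out


def or_ci_to_beta_se(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Convert a printed OR with 95% CI to (log-odds beta, se)."""
    if min(or_, ci_low, ci_high) <= 0:
        raise ValueError("odds ratios and CI bounds must be positive")
    return math.log(or_), (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)


def meta_pool(
    estimates: Sequence[tuple[float, float]], model: str = "auto"
) -> MetaResult:
    """Pool (beta, se) study estimates by inverse-variance weighting.

    Fixed effect: weights 1/se². Random effects: DerSimonian–Laird
    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), weights 1/(se² + τ²).
    ``model="auto"`` uses fixed pooling when the heterogeneity p-value
    exceeds 0.05, random otherwise — the same gate as the IVW estimator.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown meta-analysis model: {model!r}")
    k = len(estimates)
    if k < 2:
        raise EstimationError(f"meta-analysis needs at least 2 studies, got {k}")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("study standard errors must be positive")

    w = 1.0 / se**2
    fixed_beta = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - fixed_beta) ** 2))
    df = k - 1
    q_pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))

    if model == "auto":
        model = "fixed" if q_pval > 0.05 else "random"
    if model == "fixed":
        pooled_beta, pooled_se, tau2_used = fixed_beta, math.sqrt(1.0 / np.sum(w)), 0.0
    else:
        w_r = 1.0 / (se**2 + tau2)
        pooled_beta = float(np.sum(w_r * beta) / np.sum(w_r))
        pooled_se = math.sqrt(1.0 / float(np.sum(w_r)))
        tau2_used = tau2
    lo, hi = pooled_beta - Z95 * pooled_se, pooled_beta + Z95 * pooled_se
    return MetaResult(
        k=k,
        pooled_beta=pooled_beta,
        pooled_se=pooled_se,
        ci_low=lo,
        ci_high=hi,
        pval=_normal_p(pooled_beta, pooled_se),
        q=q,
        q_pval=q_pval,
        i2=i2,
        tau2=tau2_used,
        model=model,
        pooled_or=math.exp(pooled_beta),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
    )


def meta_table(result: MetaResult, labels: Sequence[str], estimates) -> pd.DataFrame:
    """Forest-plot-shaped table: one row per study plus the pooled row."""
    rows = [
        (lab, b, s, math.exp(b), math.exp(b - Z95 * s), math.exp(b + Z95 * s))
        for lab, (b, s) in zip(labels, estimates)
    ]
    rows.append(
        (
            f"pooled ({result.model})",
            result.pooled_beta,
            result.pooled_se,
            result.pooled_or,
            result.or_ci_low,
            result.or_ci_high,
        )
    )
    return pd.DataFrame(rows, columns=["study", "beta", "se", "or", "or_ci_low", "or_ci_high"])
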