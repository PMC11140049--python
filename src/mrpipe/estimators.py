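"""Causal-effect estimators for two-sample MR.

Given J harmonized instruments with exposure effects γ_j (se_γj) and
outcome effects Γ_j (se_Γj), each estimator targets the causal effect β
on the log-odds scale:

* **Wald ratio** — per-SNP β_j = Γ_j/γ_j, se by the first-order delta
  method se_Γj/|γ_j| (second-order variant available).
* **IVW** — inverse-variance-weighted combination of Wald ratios,
  equivalent to weighted least squares of Γ on γ through the origin with
  weights 1/se_Γj². The fixed-effect variance is 1/Σw_jγ_j²; the
  random-effects (multiplicative overdispersion) variant inflates it by
  max(Q/(J−1), 1). ``mode="auto"`` picks random effects when Cochran's Q
  has p < 0.05, fixed otherwise.
* **MR-Egger** — the same weighted regression with a free intercept after
  orienting every γ_j positive; a nonzero intercept indicates directional
  horizontal pleiotropy. Inference uses the t distribution on J−2 df with
  the same overdispersion floor.
* **Weighted median** — the 50% point of the weight-ordered Wald ratios;
  consistent when invalid instruments carry under half the total weight.
  Its se comes from a seeded parametric bootstrap.
* **Maximum likelihood** — profile likelihood of the bivariate-normal
  measurement model (γ_j, Γ_j) ~ N((g_j, βg_j), diag(se²)); the per-SNP
  true effects g_j profile out in closed form, leaving a 1-D optimisation.

All estimators are invariant to SNP order and to mirrored allele
encodings, and report the odds-ratio scale alongside beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .harmonize import HarmonizedSet

#: 97.5% normal quantile, fixed for reproducibility
Z95 = 1.959964


class EstimationError(Exception):
    """Estimator cannot run (too few instruments, degenerate input)."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate, on log-odds and odds-ratio scales."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    model_note: str = ""


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test: directional-pleiotropy evidence."""

    intercept: float
    se: float
    pval: float


def _make_estimate(
    method: str, n_snp: int, beta: float, se: float, pval: float, note: str = ""
) -> MREstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MREstimate(
        method=method,
        n_snp=n_snp,
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        pval=float(pval),
        or_=math.exp(beta),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
        model_note=note,
    )


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    *,
    second_order: bool = False,
) -> tuple[float, float]:
    """Per-SNP causal estimate Γ/γ and its delta-method standard error.

    First order: se = se_Γ/|γ|. Second order adds the exposure's
    uncertainty: se = √(se_Γ²/γ² + Γ²·se_γ²/γ⁴).
    """
    if beta_exp == 0:
        raise EstimationError("beta_exp = 0: Wald ratio undefined, instrument unusable")
    if se_exp <= 0 or se_out <= 0:
        raise EstimationError("standard errors must be positive")
    ratio = beta_out / beta_exp
    if second_order:
        var = se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        return ratio, math.sqrt(var)
    return ratio, se_out / abs(beta_exp)


def wald_ratios(H: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Vector of per-SNP ratios and their first-order standard errors."""
    if np.any(H.beta_exp == 0):
        bad = [s for s, b in zip(H.snp_ids, H.beta_exp) if b == 0]
        raise EstimationError(f"beta_exp = 0 for {bad}: Wald ratios undefined")
    return H.beta_out / H.beta_exp, H.se_out / np.abs(H.beta_exp)


def _ivw_core(H: HarmonizedSet) -> tuple[float, float, float, int]:
    """(beta, fixed se, Cochran's Q, J) of the IVW fit through the origin."""
    w = 1.0 / H.se_out**2
    denom = float(np.sum(w * H.beta_exp**2))
    beta = float(np.sum(w * H.beta_exp * H.beta_out)) / denom
    se_fixed = math.sqrt(1.0 / denom)
    # Q over Wald ratios with first-order weights γ²/se_Γ² — algebraically
    # the weighted RSS of the origin regression
    q = float(np.sum(w * (H.beta_out - beta * H.beta_exp) ** 2))
    return beta, se_fixed, q, H.n_snp


def ivw(H: HarmonizedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode`` is ``"fixed"``, ``"random"`` (multiplicative overdispersion,
    inflation floored at 1) or ``"auto"``: random effects when Cochran's
    Q has p < 0.05, fixed otherwise.
    """
    if mode not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown IVW mode: {mode!r}")
    if H.n_snp == 0:
        raise EstimationError("IVW requires at least one instrument")
    beta, se_fixed, q, j = _ivw_core(H)

    if j < 2:
        use_random, se, note = False, se_fixed, "fixed (single instrument)"
    else:
        q_p = float(stats.chi2.sf(q, j - 1))
        if mode == "auto":
            use_random = q_p < 0.05
            note = f"auto: Q p = {q_p:.4g} -> {'random' if use_random else 'fixed'} effects"
        else:
            use_random = mode == "random"
            note = f"{mode} effects (Q p = {q_p:.4g})"
        se = se_fixed * math.sqrt(max(q / (j - 1), 1.0)) if use_random else se_fixed
    return _make_estimate(
        "ivw_random" if use_random else "ivw_fixed",
        j, beta, se, _normal_p(beta, se), note,
    )


def mr_egger(
    H: HarmonizedSet, overdispersion: str = "multiplicative"
) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    Each SNP is oriented so γ_j > 0 (both betas flipped where needed),
    then Γ is regressed on γ with a free intercept and weights 1/se_Γ²;
    p-values use t on J−2 df.

    ``overdispersion`` controls the residual scaling of the standard
    errors: ``"multiplicative"`` (default) is classical weighted least
    squares — SEs scale by √(Q_egger/(J−2)) — under which the intercept
    test has exact type-I calibration when instruments are valid;
    ``"floored"`` never deflates, scaling by √(max(Q_egger/(J−2), 1)) as
    the common R implementations do, which is conservative under the
    null but never anti-conservative under underdispersion.
    """
    if overdispersion not in ("multiplicative", "floored"):
        raise ValueError(f"unknown overdispersion rule: {overdispersion!r}")
    j = H.n_snp
    if j < 3:
        raise EstimationError(f"MR-Egger needs at least 3 instruments, got {j}")
    sign = np.where(H.beta_exp < 0, -1.0, 1.0)
    gx, gy = H.beta_exp * sign, H.beta_out * sign
    w = 1.0 / H.se_out**2
    fit = sm.WLS(gy, sm.add_constant(gx), weights=w).fit()
    # fit.scale = Q_egger/(J-2)
    if overdispersion == "floored" and fit.scale < 1.0:
        se_unit = fit.bse / math.sqrt(fit.scale) if fit.scale > 0 else fit.bse
        se0, se1 = float(se_unit[0]), float(se_unit[1])
    else:
        se0, se1 = float(fit.bse[0]), float(fit.bse[1])
    b0, b1 = float(fit.params[0]), float(fit.params[1])

    def _t_p(b: float, se: float) -> float:
        if se == 0:
            return 1.0 if b == 0 else 5e-324
        return max(float(2.0 * stats.t.sf(abs(b) / se, j - 2)), 5e-324)

    p_slope = _t_p(b1, se1)
    p_int = _t_p(b0, se0)
    slope = _make_estimate(
        "egger", j, b1, se1, p_slope, f"intercept p = {p_int:.4g}"
    )
    return slope, PleiotropyResult(intercept=b0, se=se0, pval=p_int)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def weighted_median(
    H: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP Wald ratios are weighted by the inverse of their first-order
    variance; the estimate interpolates the weighted empirical CDF at
    cumulative standardized weight 0.5. The bootstrap redraws (γ_j, Γ_j)
    from normals centred at the observations and must be seeded for
    reproducible reports.
    """
    if H.n_snp < 3:
        raise EstimationError(f"weighted median needs at least 3 instruments, got {H.n_snp}")
    ratios, ses = wald_ratios(H)
    beta = _weighted_median_point(ratios, 1.0 / ses**2)

    rng = np.random.default_rng(seed)
    gx = rng.normal(H.beta_exp, H.se_exp, size=(n_boot, H.n_snp))
    gy = rng.normal(H.beta_out, H.se_out, size=(n_boot, H.n_snp))
    gx = np.where(gx == 0, np.finfo(float).tiny, gx)
    r = gy / gx
    w = gx**2 / H.se_out**2
    order = np.argsort(r, axis=1, kind="stable")
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    cum = np.cumsum(w_s, axis=1) - 0.5 * w_s
    p = cum / np.sum(w_s, axis=1, keepdims=True)
    boots = np.array(
        [np.interp(0.5, p[i], r_s[i]) for i in range(n_boot)]
    )
    se = float(np.std(boots, ddof=1))
    return _make_estimate(
        "weighted_median", H.n_snp, beta, se, _normal_p(beta, se),
        f"bootstrap n = {n_boot}",
    )


def _profile_neg2ll(beta: float, H: HarmonizedSet) -> float:
    # per-SNP true effects g_j profiled out in closed form; variances are
    # known constants so no log-determinant term varies with beta
    var = H.se_out**2 + beta**2 * H.se_exp**2
    return float(np.sum((H.beta_out - beta * H.beta_exp) ** 2 / var))


def max_likelihood(H: HarmonizedSet) -> MREstimate:
    """Maximum-likelihood estimate under the bivariate-normal model.

    Observed (γ_j, Γ_j) are independent normals with means (g_j, βg_j)
    and known SDs; the g_j maximise out per SNP in closed form and β is
    found by 1-D numerical minimisation of the profile deviance. The
    standard error comes from the numerical observed information.
    """
    if H.n_snp == 0:
        raise EstimationError("maximum likelihood requires at least one instrument")
    # deviance flattens to a constant as |beta| -> inf, so locate the
    # interior minimum on a coarse grid first, then refine
    start, _, _, _ = _ivw_core(H)
    half = 10.0 * (abs(start) + 1.0)
    for _ in range(3):
        grid = np.linspace(start - half, start + half, 801)
        vals = np.array([_profile_neg2ll(float(b), H) for b in grid])
        i = int(np.argmin(vals))
        if 0 < i < len(grid) - 1:
            break
        half *= 10.0
    else:
        raise EstimationError(
            "ML optimisation failed: no interior minimum of the profile "
            f"deviance within beta = {start} +/- {half / 10.0}"
        )
    res = optimize.minimize_scalar(
        _profile_neg2ll,
        args=(H,),
        bounds=(float(grid[i - 1]), float(grid[i + 1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success or not math.isfinite(res.x):
        raise EstimationError(f"ML optimisation failed: {res}")
    beta = float(res.x)
    h = max(1e-6, 1e-5 * abs(beta))
    d2 = (
        _profile_neg2ll(beta + h, H)
        - 2.0 * _profile_neg2ll(beta, H)
        + _profile_neg2ll(beta - h, H)
    ) / h**2
    info = d2 / 2.0  # -2logL -> information is half the curvature
    if info <= 0:
        raise EstimationError("non-positive observed information at the ML optimum")
    se = 1.0 / math.sqrt(info)
    return _make_estimate("max_likelihood", H.n_snp, beta, se, _normal_p(beta, se))


def estimate_all(
    H: HarmonizedSet,
    *,
    ivw_mode: str = "auto",
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MREstimate]:
    """The full estimator battery, degrading gracefully below per-method minimums."""
    out = [ivw(H, mode=ivw_mode), max_likelihood(H)]
    if H.n_snp >= 3:
        out.append(weighted_median(H, n_boot=n_boot, seed=seed))
        slope, _ = mr_egger(H)
        out.append(slope)
    return out
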