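"""Two-step mediation MR: indirect effects and mediated proportions.

Step one estimates the exposure→mediator effect a (instrumenting the
exposure); step two the mediator→outcome effect b (instrumenting the
mediator). The indirect effect through the mediator is a·b, and the
mediated proportion is a·b divided by the total exposure→outcome effect.
Standard errors for the product and the ratio come from the first-order
delta method, treating the component estimates as independent — the
standard approximation when all three come from separate two-sample
fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .estimators import EstimationError, Z95, ivw
from .gwas_io import GwasRecord, LdMatrix
from .harmonize import harmonize
from .instruments import select_instruments

logger = logging.getLogger("mrpipe")


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of a total effect into indirect (via one mediator) and rest."""

    mediator: str
    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    beta_total: float
    se_total: float
    indirect: float
    indirect_se: float
    proportion: float
    proportion_se: float
    proportion_ci_low: float
    proportion_ci_high: float


def two_step_mediation(
    beta_em: float,
    se_em: float,
    beta_mo: float,
    se_mo: float,
    beta_total: float,
    se_total: float,
    *,
    mediator: str = "mediator",
) -> MediationResult:
    """Combine the three MR estimates into indirect effect and proportion.

    indirect = a·b with delta-method se √(a²·se_b² + b²·se_a²);
    proportion = indirect / total with se
    √(se_ind²/total² + ind²·se_total²/total⁴) and a symmetric 95% CI.
    """
    for name, s in (("se_em", se_em), ("se_mo", se_mo), ("se_total", se_total)):
        if s <= 0:
            raise ValueError(f"{name} must be positive, got {s}")
    if abs(beta_total) <= 1e-12:
        raise EstimationError("total effect is (numerically) zero: proportion undefined")
    indirect = beta_em * beta_mo
    indirect_se = math.sqrt(beta_em**2 * se_mo**2 + beta_mo**2 * se_em**2)
    proportion = indirect / beta_total
    proportion_se = math.sqrt(
        indirect_se**2 / beta_total**2
        + indirect**2 * se_total**2 / beta_total**4
    )
    return MediationResult(
        mediator=mediator,
        beta_em=beta_em,
        se_em=se_em,
        beta_mo=beta_mo,
        se_mo=se_mo,
        beta_total=beta_total,
        se_total=se_total,
        indirect=indirect,
        indirect_se=indirect_se,
        proportion=proportion,
        proportion_se=proportion_se,
        proportion_ci_low=proportion - Z95 * proportion_se,
        proportion_ci_high=proportion + Z95 * proportion_se,
    )


def mediated_proportion_from_ors(or_em: float, or_mo: float, or_total: float) -> float:
    """Mediated proportion recomputed from printed odds ratios.

    ln(OR_exposure→mediator)·ln(OR_mediator→outcome)/ln(OR_total); the
    fraction of the total log-odds effect flowing through the mediator.
    """
    if min(or_em, or_mo, or_total) <= 0:
        raise ValueError("odds ratios must be positive")
    if or_total == 1.0:
        raise EstimationError("total OR = 1: proportion undefined")
    return math.log(or_em) * math.log(or_mo) / math.log(or_total)


@dataclass
class MediatorDataset:
    """One candidate mediator's GWAS summary data and LD for its instruments."""

    name: str
    records: Sequence[GwasRecord]
    ld: LdMatrix


def _ivw_step(
    exposure_records: Sequence[GwasRecord],
    exposure_ld: LdMatrix,
    outcome_records: Sequence[GwasRecord],
    *,
    p_threshold: float,
    clump_r2: float,
    clump_kb: int,
    f_min: float,
    ivw_mode: str,
    exposure_name: str,
    outcome_name: str,
):
    inst = select_instruments(
        exposure_records,
        exposure_ld,
        exposure_name=exposure_name,
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_kb=clump_kb,
        f_min=f_min,
    )
    if not inst.records:
        raise EstimationError(f"{exposure_name}: no instruments survive selection")
    H = harmonize(
        inst.records,
        outcome_records,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
    if H.n_snp == 0:
        raise EstimationError(f"{exposure_name}: no instruments survive harmonization")
    return ivw(H, mode=ivw_mode)


def screen_mediators(
    exposure_records: Sequence[GwasRecord],
    exposure_ld: LdMatrix,
    mediators: Sequence[MediatorDataset],
    outcome_records: Sequence[GwasRecord],
    *,
    beta_total: float,
    se_total: float,
    exposure_p_threshold: float = 5e-6,
    mediator_p_threshold: float = 1e-5,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    f_min: float = 10.0,
    ivw_mode: str = "auto",
    step_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a mediator panel by two-step MR against a known total effect.

    For each mediator: exposure→mediator MR (instrumenting the exposure
    at ``exposure_p_threshold``) and mediator→outcome MR (instrumenting
    the mediator at the relaxed ``mediator_p_threshold``). Mediators with
    both step p-values below ``step_alpha`` and an indirect effect
    concordant in sign with the total effect are retained. Returns
    (full table, retained table); mediators whose instruments vanish are
    skipped with a log entry and appear in the full table with
    ``status="skipped"``.

    No multiplicity correction is applied across the panel by default;
    apply Bonferroni/BH on the returned p-value columns if desired.
    """
    rows = []
    for med in mediators:
        try:
            em = _ivw_step(
                exposure_records,
                exposure_ld,
                med.records,
                p_threshold=exposure_p_threshold,
                clump_r2=clump_r2,
                clump_kb=clump_kb,
                f_min=f_min,
                ivw_mode=ivw_mode,
                exposure_name="exposure",
                outcome_name=med.name,
            )
            mo = _ivw_step(
                med.records,
                med.ld,
                outcome_records,
                p_threshold=mediator_p_threshold,
                clump_r2=clump_r2,
                clump_kb=clump_kb,
                f_min=f_min,
                ivw_mode=ivw_mode,
                exposure_name=med.name,
                outcome_name="outcome",
            )
        except EstimationError as exc:
            logger.info("screen_mediators: skipping %s: %s", med.name, exc)
            rows.append(
                {"mediator": med.name, "status": "skipped", "note": str(exc)}
            )
            continue
        res = two_step_mediation(
            em.beta, em.se, mo.beta, mo.se, beta_total, se_total, mediator=med.name
        )
        both_sig = em.pval < step_alpha and mo.pval < step_alpha
        concordant = res.indirect * beta_total > 0
        rows.append(
            {
                "mediator": med.name,
                "status": "retained" if (both_sig and concordant) else "dropped",
                "beta_em": em.beta,
                "se_em": em.se,
                "p_em": em.pval,
                "or_em": em.or_,
                "beta_mo": mo.beta,
                "se_mo": mo.se,
                "p_mo": mo.pval,
                "or_mo": mo.or_,
                "indirect": res.indirect,
                "indirect_se": res.indirect_se,
                "proportion": res.proportion,
                "proportion_ci_low": res.proportion_ci_low,
                "proportion_ci_high": res.proportion_ci_high,
                "note": "",
            }
        )
    full = pd.DataFrame(rows)
    if full.empty:
        full = pd.DataFrame(columns=["mediator", "status"])
    retained = full[full.get("status", pd.Series(dtype=str)) == "retained"].copy()
    if "proportion" in retained.columns and not retained.empty:
        retained = retained.sort_values("proportion", ascending=False, kind="stable")
    n_skip = int((full["status"] == "skipped").sum()) if "status" in full else 0
    if n_skip:
        logger.info("screen_mediators: %d mediator(s) skipped", n_skip)
    return full, retained
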