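"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator realises exactly the measurement model the estimators
assume: each SNP j has a true exposure effect g_j ~ N(0, gamma_sd²); the
observed exposure effect is γ_j ~ N(g_j, se_γj²) and the observed
outcome effect is Γ_j ~ N(β·g_j + α_j, se_Γj²), where β is the causal
effect on the log-odds scale and α_j is a horizontal-pleiotropy effect
carried by a configurable fraction of invalid instruments. Standard
errors follow the standard allele-frequency approximation
se = 1/√(2·maf·(1−maf)·n). LD is simulated at the r² summary level only
(block-constant matrices), since clumping consumes r² directly.

Directional pleiotropy is defined in the oriented frame: α_j is drawn
with nonzero mean on the exposure-increasing allele (multiplied by
sign(g_j)), so invalid instruments push every Wald ratio the same way —
the violation MR-Egger's intercept is designed to detect. Balanced
pleiotropy is zero-mean on either frame.

Default parameters mirror the headline study conditions: a causal
effect of 0.077 log-odds (OR 1.08) of anorexia nervosa on sepsis, an
exposure GWAS of ~72,500 samples (PGC-scale) and an outcome GWAS of
~486,500 (UK-Biobank-scale), with instrument effects sized so selected
SNPs are strong (typical F well above 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import GwasRecord, LdMatrix

_MIN_P = 1e-300  # keep generated p-values inside (0, 1]

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one two-sample dataset pair.

    ``pleiotropy`` is ``"none"``, ``"balanced"`` (α ~ N(0, sd²)) or
    ``"directional"`` (α ~ sign(g)·N(mean, sd²)); ``prop_invalid`` is the
    fraction of SNPs carrying α. ``ld_blocks = (count, size, r2)`` puts
    the first count·size SNPs into LD blocks of constant within-block r²;
    remaining SNPs are mutually independent.
    """

    n_snp: int = 50
    n_exp: int = 72_500
    n_out: int = 486_500
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_true: float = 0.077
    gamma_sd: float = 0.05
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    ld_blocks: tuple[int, int, float] = (0, 1, 0.0)
    palindromic_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1 or self.n_exp < 2 or self.n_out < 2:
            raise ValueError("n_snp and sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy model: {self.pleiotropy!r}")
        if not (0 <= self.prop_invalid < 1):
            raise ValueError("prop_invalid must be in [0, 1)")
        if not (0 <= self.palindromic_frac <= 1):
            raise ValueError("palindromic_frac must be in [0, 1]")
        count, size, r2 = self.ld_blocks
        if count * size > self.n_snp:
            raise ValueError("ld_blocks cover more SNPs than n_snp")
        if not (0 <= r2 <= 1):
            raise ValueError("within-block r2 must be in [0, 1]")


@dataclass
class SimTruth:
    """The generating parameters behind one simulated dataset pair."""

    beta_true: float
    g: np.ndarray  # true instrument effects
    alpha: np.ndarray  # per-SNP pleiotropic effects (0 on valid SNPs)
    valid: np.ndarray  # bool per SNP
    block: np.ndarray  # LD-block index, -1 for singletons
    snp_ids: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P)


def _records(
    ids: Sequence[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    alleles: Sequence[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[GwasRecord]:
    p = _pvals(beta, se)
    return [
        GwasRecord(
            snp_id=ids[i],
            chrom=str(chrom[i]),
            pos=int(pos[i]),
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(maf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pval=float(p[i]),
            n=float(n),
        )
        for i in range(len(ids))
    ]


def _layout(n_snp: int, ld_blocks: tuple[int, int, float], rng: np.random.Generator):
    """Chromosome/position layout and block assignment.

    Block members sit 1 kb apart; separate blocks (and singletons) are
    placed 50 Mb apart cycling over chromosomes 1–22, far outside any
    sensible clumping window.
    """
    count, size, _ = ld_blocks
    block = np.full(n_snp, -1, dtype=int)
    chrom = np.empty(n_snp, dtype=object)
    pos = np.empty(n_snp, dtype=int)
    region = 0
    i = 0
    for b in range(count):
        for k in range(size):
            block[i] = b
            chrom[i] = str(region % 22 + 1)
            pos[i] = 1_000_000 + (region // 22) * 50_000_000 + k * 1000
            i += 1
        region += 1
    while i < n_snp:
        chrom[i] = str(region % 22 + 1)
        pos[i] = 1_000_000 + (region // 22) * 50_000_000
        region += 1
        i += 1
    return chrom, pos, block


def _block_ld(ids: Sequence[str], block: np.ndarray, within_r2: float) -> LdMatrix:
    k = len(ids)
    r2 = np.eye(k)
    for b in np.unique(block[block >= 0]):
        idx = np.where(block == b)[0]
        for a in idx:
            for c in idx:
                if a != c:
                    r2[a, c] = within_r2
    return LdMatrix(snp_ids=tuple(ids), r2=r2)


def _alleles(n_snp: int, palindromic_frac: float, rng: np.random.Generator):
    is_pal = rng.random(n_snp) < palindromic_frac
    out = []
    for flag in is_pal:
        pool = _PALINDROMIC_PAIRS if flag else _NONPALINDROMIC_PAIRS
        out.append(pool[rng.integers(len(pool))])
    return out


def _draw_alpha(cfg: SimConfig, g: np.ndarray, valid: np.ndarray, rng) -> np.ndarray:
    alpha = np.zeros(len(g))
    invalid = ~valid
    if cfg.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_sd, invalid.sum())
    elif cfg.pleiotropy == "directional":
        raw = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, invalid.sum())
        alpha[invalid] = raw * np.sign(g[invalid])
    return alpha


def simulate_two_sample(
    config: SimConfig,
) -> tuple[list[GwasRecord], list[GwasRecord], LdMatrix, SimTruth]:
    """Draw one paired exposure/outcome summary-statistics dataset.

    Fully reproducible from ``config.seed``; both datasets share SNP
    ids, positions, alleles and allele frequencies (one source
    population, consistent strand).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snp
    ids = tuple(f"rs{i + 1}" for i in range(n))
    chrom, pos, block = _layout(n, config.ld_blocks, rng)
    alleles = _alleles(n, config.palindromic_frac, rng)
    maf = rng.uniform(*config.maf_range, size=n)

    g = rng.normal(0.0, config.gamma_sd, n)
    n_invalid = int(round(config.prop_invalid * n))
    valid = np.ones(n, dtype=bool)
    if n_invalid:
        valid[rng.choice(n, size=n_invalid, replace=False)] = False
    alpha = _draw_alpha(config, g, valid, rng)

    se_exp = _se(maf, config.n_exp)
    se_out = _se(maf, config.n_out)
    gamma_obs = rng.normal(g, se_exp)
    big_gamma_obs = rng.normal(config.beta_true * g + alpha, se_out)

    exposure = _records(ids, chrom, pos, alleles, maf, gamma_obs, se_exp, config.n_exp)
    outcome = _records(ids, chrom, pos, alleles, maf, big_gamma_obs, se_out, config.n_out)
    ld = _block_ld(ids, block, config.ld_blocks[2])
    truth = SimTruth(
        beta_true=config.beta_true,
        g=g,
        alpha=alpha,
        valid=valid,
        block=block,
        snp_ids=ids,
    )
    return exposure, outcome, ld, truth


@dataclass
class MediationSim:
    """Three linked summary datasets realising an exposure→mediator→outcome chain."""

    exposure: list[GwasRecord]
    mediator: list[GwasRecord]
    outcome: list[GwasRecord]
    exposure_ld: LdMatrix
    mediator_ld: LdMatrix
    truth: SimTruth


def simulate_mediation_triplet(
    config: SimConfig,
    mediator_config: SimConfig | None = None,
    *,
    a: float,
    b: float,
    c_direct: float,
) -> MediationSim:
    """Simulate linked exposure, mediator and outcome GWAS datasets.

    The exposure's instruments (from ``config``) act on the mediator
    with effect ``a`` and on the outcome with the total effect
    ``c_direct + a·b``; the mediator's own instruments (from
    ``mediator_config``, defaulting to ``config`` with a shifted seed)
    act on the outcome with effect ``b``. The true mediated proportion
    a·b/(a·b + c_direct) is recorded in the returned truth.
    """
    config.validate()
    if mediator_config is None:
        mediator_config = replace(config, seed=config.seed + 1_000_003)
    mediator_config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_654_321]))

    nx, nm = config.n_snp, mediator_config.n_snp
    ids_x = tuple(f"rsX{i + 1}" for i in range(nx))
    ids_m = tuple(f"rsM{i + 1}" for i in range(nm))
    chrom_x, pos_x, block_x = _layout(nx, config.ld_blocks, rng)
    chrom_m, pos_m, block_m = _layout(nm, mediator_config.ld_blocks, rng)
    # keep mediator SNPs clear of exposure regions
    pos_m = pos_m + 25_000_000
    alleles_x = _alleles(nx, config.palindromic_frac, rng)
    alleles_m = _alleles(nm, mediator_config.palindromic_frac, rng)
    maf_x = rng.uniform(*config.maf_range, size=nx)
    maf_m = rng.uniform(*mediator_config.maf_range, size=nm)

    g_x = rng.normal(0.0, config.gamma_sd, nx)  # exposure-instrument effects
    h_m = rng.normal(0.0, mediator_config.gamma_sd, nm)  # mediator-instrument effects
    total = c_direct + a * b

    se_x_exp = _se(maf_x, config.n_exp)
    se_x_med = _se(maf_x, mediator_config.n_exp)
    se_x_out = _se(maf_x, config.n_out)
    se_m_med = _se(maf_m, mediator_config.n_exp)
    se_m_out = _se(maf_m, config.n_out)

    exposure = _records(
        ids_x, chrom_x, pos_x, alleles_x, maf_x,
        rng.normal(g_x, se_x_exp), se_x_exp, config.n_exp,
    )
    mediator = _records(
        tuple(ids_x) + tuple(ids_m),
        np.concatenate([chrom_x, chrom_m]),
        np.concatenate([pos_x, pos_m]),
        list(alleles_x) + list(alleles_m),
        np.concatenate([maf_x, maf_m]),
        np.concatenate(
            [rng.normal(a * g_x, se_x_med), rng.normal(h_m, se_m_med)]
        ),
        np.concatenate([se_x_med, se_m_med]),
        mediator_config.n_exp,
    )
    outcome = _records(
        tuple(ids_x) + tuple(ids_m),
        np.concatenate([chrom_x, chrom_m]),
        np.concatenate([pos_x, pos_m]),
        list(alleles_x) + list(alleles_m),
        np.concatenate([maf_x, maf_m]),
        np.concatenate(
            [rng.normal(total * g_x, se_x_out), rng.normal(b * h_m, se_m_out)]
        ),
        np.concatenate([se_x_out, se_m_out]),
        config.n_out,
    )

    exposure_ld = _block_ld(ids_x, block_x, config.ld_blocks[2])
    mediator_ld = _block_ld(
        tuple(ids_x) + tuple(ids_m),
        np.concatenate([block_x, np.where(block_m >= 0, block_m + max(block_x.max() + 1, 0) + 1, -1)]),
        mediator_config.ld_blocks[2],
    )
    truth = SimTruth(
        beta_true=total,
        g=np.concatenate([g_x, h_m]),
        alpha=np.zeros(nx + nm),
        valid=np.ones(nx + nm, dtype=bool),
        block=np.concatenate([block_x, block_m]),
        snp_ids=tuple(ids_x) + tuple(ids_m),
        extras={
            "a": a,
            "b": b,
            "c_direct": c_direct,
            "total": total,
            "proportion": (a * b) / total if total != 0 else float("nan"),
        },
    )
    return MediationSim(exposure, mediator, outcome, exposure_ld, mediator_ld, truth)
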