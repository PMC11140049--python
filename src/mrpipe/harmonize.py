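"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs each SNP's exposure effect (γ) and outcome effect (Γ)
expressed for the same effect allele. Datasets may state effects on
opposite alleles (sign flip), on opposite strands (complement), or be
ambiguous: palindromic A/T and C/G variants look identical on both
strands and can only be oriented by comparing effect-allele frequencies,
or else must be dropped. Every input instrument receives exactly one
action tag, so retained + dropped = instruments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import GwasRecord

logger = logging.getLogger("mrpipe")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: action tags, in precedence order of how they are decided
ACTIONS = (
    "aligned",
    "flipped",
    "palindromic_inferred",
    "dropped_palindromic",
    "dropped_missing",
    "dropped_mismatch",
)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A,T} or {C,G}; multi-base alleles are not assessable."""
    if len(a1) != 1 or len(a2) != 1:
        return False
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    return allele.upper().translate(_COMPLEMENT)


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effect pairs, ready for estimation.

    Arrays cover the retained SNPs only; ``actions`` tags every input
    instrument (retained and dropped). ``eaf_*`` hold NaN when unknown.
    """

    exposure_name: str
    outcome_name: str
    snp_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray
    eaf_out: np.ndarray
    actions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.snp_ids = tuple(self.snp_ids)
        k = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} length does not match {k} snp ids")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("retained rows must have positive standard errors")

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        *,
        snp_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (synthetic / test use)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        k = beta_exp.shape[0]
        ids = tuple(snp_ids) if snp_ids is not None else tuple(f"rs{i+1}" for i in range(k))
        nan = np.full(k, np.nan)
        return cls(
            exposure_name,
            outcome_name,
            ids,
            beta_exp,
            se_exp,
            beta_out,
            se_out,
            nan.copy(),
            nan.copy(),
            actions={s: "aligned" for s in ids},
        )

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        """The set restricted to the given positional indices."""
        idx = np.asarray(keep, dtype=int)
        ids = tuple(self.snp_ids[i] for i in idx)
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            ids,
            self.beta_exp[idx],
            self.se_exp[idx],
            self.beta_out[idx],
            self.se_out[idx],
            self.eaf_exp[idx],
            self.eaf_out[idx],
            actions={s: self.actions.get(s, "aligned") for s in ids},
        )

    def to_frame(self) -> pd.DataFrame:
        """The exchange-format table (one row per retained SNP)."""
        return pd.DataFrame(
            {
                "snp_id": list(self.snp_ids),
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
                "eaf_exp": self.eaf_exp,
                "eaf_out": self.eaf_out,
                "action": [self.actions[s] for s in self.snp_ids],
            }
        )


def _nominal_alignment(exp: GwasRecord, out: GwasRecord) -> str | None:
    """How the outcome's stated alleles relate to the exposure's.

    Returns ``"same"``, ``"swapped"`` or ``None`` (irreconcilable),
    trying the literal alleles first and their strand complement second.
    """
    e1, e2 = exp.effect_allele, exp.other_allele
    for o1, o2 in (
        (out.effect_allele, out.other_allele),
        (_complement(out.effect_allele), _complement(out.other_allele)),
    ):
        if (o1, o2) == (e1, e2):
            return "same"
        if (o1, o2) == (e2, e1):
            return "swapped"
    return None


def harmonize(
    instruments: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    eaf_ambiguity_band: float = 0.08,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Instruments absent from the outcome dataset are dropped
    (``dropped_missing``). Same-allele pairs pass through (``aligned``);
    swapped alleles flip the outcome beta's sign and complement its EAF
    (``flipped``); strand-complement representations are complemented
    first. Palindromic SNPs are oriented by EAF when both frequencies
    are known and lie outside ``0.5 ± eaf_ambiguity_band``
    (``palindromic_inferred``), otherwise dropped
    (``dropped_palindromic``).
    """
    if not (0 <= eaf_ambiguity_band < 0.5):
        raise ValueError(f"eaf_ambiguity_band must be in [0, 0.5), got {eaf_ambiguity_band}")
    out_by_id = {r.snp_id: r for r in outcome}
    actions: dict[str, str] = {}
    rows: list[tuple] = []

    for exp in instruments:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            actions[exp.snp_id] = "dropped_missing"
            continue
        if out.chrom != exp.chrom or out.pos != exp.pos:
            logger.warning(
                "harmonize: %s position disagrees between datasets "
                "(%s:%d vs %s:%d); matched by id",
                exp.snp_id, exp.chrom, exp.pos, out.chrom, out.pos,
            )
        rel = _nominal_alignment(exp, out)
        if rel is None:
            actions[exp.snp_id] = "dropped_mismatch"
            logger.info("harmonize: %s alleles irreconcilable (%s/%s vs %s/%s)",
                        exp.snp_id, exp.effect_allele, exp.other_allele,
                        out.effect_allele, out.other_allele)
            continue

        if rel == "same":
            beta_out, eaf_out, action = out.beta, out.eaf, "aligned"
        else:
            beta_out = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            action = "flipped"

        if exp.is_single_base and is_palindromic(exp.effect_allele, exp.other_allele):
            # letters cannot orient a palindrome; fall back to frequency
            lo, hi = 0.5 - eaf_ambiguity_band, 0.5 + eaf_ambiguity_band
            if (
                exp.eaf is None
                or eaf_out is None
                or lo <= exp.eaf <= hi
                or lo <= eaf_out <= hi
            ):
                actions[exp.snp_id] = "dropped_palindromic"
                continue
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            action = "palindromic_inferred"

        actions[exp.snp_id] = action
        rows.append(
            (
                exp.snp_id,
                exp.beta,
                exp.se,
                beta_out,
                out.se,
                math.nan if exp.eaf is None else exp.eaf,
                math.nan if eaf_out is None else eaf_out,
            )
        )

    ids = tuple(r[0] for r in rows)
    arr = np.array([r[1:] for r in rows], dtype=float).reshape(len(rows), 6)
    return HarmonizedSet(
        exposure_name,
        outcome_name,
        ids,
        arr[:, 0],
        arr[:, 1],
        arr[:, 2],
        arr[:, 3],
        arr[:, 4],
        arr[:, 5],
        actions=actions,
    )
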