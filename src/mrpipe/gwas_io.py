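"""Reading, validating and writing GWAS summary statistics and LD matrices.

Summary statistics travel as delimited text with one row per SNP. The
canonical dialect is tab-separated, UTF-8, ``.`` decimal, with a mandatory
header ``SNP CHR POS EA OA EAF BETA SE P [N]``; comma-separated files are
auto-detected from the header line. Arbitrary column names are supported
through a ``column_map`` from canonical names to file names. Missing
effect-allele frequency is encoded ``NA``; beta, se and p may not be
missing. Positions are 1-based base pairs and treated as opaque
coordinates within a dataset (no liftover, no build checks).

LD is an explicit input: a labelled square matrix of pairwise r² values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrpipe")

#: canonical column order of the summary-statistics TSV
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
_MANDATORY = ("SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P")

_VALID_BASES = frozenset("ACGT")


class GwasIoError(Exception):
    """Base class for summary-statistics I/O failures."""


class ConfigurationError(GwasIoError):
    """A mandatory column is absent after applying the column map."""


class ValidationError(GwasIoError):
    """A row violates a record invariant in strict mode."""


class FormatError(GwasIoError):
    """The file is not in the documented shape (e.g. non-square LD matrix)."""


@dataclass(frozen=True, slots=True)
class GwasRecord:
    """One SNP's association summary.

    ``beta`` is the additive per-effect-allele effect (log-odds for binary
    traits), ``se`` its standard error, ``pval`` the association p-value.
    ``eaf`` is the effect-allele frequency, ``None`` when unreported.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any invariant fails."""
        if not self.snp_id:
            raise ValidationError("empty snp_id")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: non-finite beta")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf outside [0,1]: {self.eaf}")
        ea, oa = self.effect_allele, self.other_allele
        if not ea or not oa:
            raise ValidationError(f"{self.snp_id}: empty allele")
        if ea == oa:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical ({ea})")
        for a in (ea, oa):
            if not set(a) <= _VALID_BASES:
                raise ValidationError(f"{self.snp_id}: allele {a!r} not over A/C/G/T")

    @property
    def is_single_base(self) -> bool:
        """True when both alleles are single bases (palindromy assessable)."""
        return len(self.effect_allele) == 1 and len(self.other_allele) == 1

    def mirrored(self) -> "GwasRecord":
        """The same association expressed on the other allele.

        Swaps effect/other alleles, negates beta and complements the
        frequency; the record describes the identical signal.
        """
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class LdMatrix:
    """Square symmetric matrix of pairwise r² over labelled SNPs."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray
    _index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if m.shape != (k, k):
            raise FormatError(f"LD matrix shape {m.shape} does not match {k} SNP ids")
        if len(set(self.snp_ids)) != k:
            raise ValidationError("duplicate SNP ids in LD matrix")
        if np.any((m < 0) | (m > 1)):
            bad = m[(m < 0) | (m > 1)].flat[0]
            raise ValidationError(f"r² value outside [0,1]: {bad}")
        if not np.allclose(m, m.T, atol=1e-8, rtol=0):
            raise ValidationError("LD matrix asymmetric beyond 1e-8")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12, rtol=0):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        # symmetrize residual <1e-8 noise so downstream lookups are exact
        object.__setattr__(self, "r2", (m + m.T) / 2.0)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.snp_ids)})

    def lookup(self, a: str, b: str) -> float:
        """Pairwise r² between two SNPs by id."""
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def _parse_float(value, what: str, row: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: unparseable {what}: {value!r}") from None


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> list[GwasRecord]:
    """Read a summary-statistics table into validated records.

    Parameters
    ----------
    path
        Tab- or comma-separated text file with a header (auto-detected).
    column_map
        Mapping from canonical column names (``SNP``, ``BETA``, ...) to
        the names used in the file; unmapped canonical names are looked
        up verbatim.
    strict
        In strict mode a row violating a record invariant raises
        :class:`ValidationError` naming the row; in lenient mode the row
        is dropped and the drop count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map or {})
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    def col(name: str) -> str:
        return cmap.get(name, name)

    missing = [col(c) for c in _MANDATORY if col(c) not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mandatory column(s) missing after mapping: {missing}; "
            f"file has {list(df.columns)}"
        )
    has_eaf = col("EAF") in df.columns
    has_n = col("N") in df.columns

    records: list[GwasRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        d = dict(zip(df.columns, row))
        label = f"{i} (snp {d.get(col('SNP'), '?')})"
        try:
            eaf_raw = d[col("EAF")] if has_eaf else "NA"
            n_raw = d[col("N")] if has_n else "NA"
            rec = GwasRecord(
                snp_id=str(d[col("SNP")]),
                chrom=str(d[col("CHR")]),
                pos=int(float(d[col("POS")])),
                effect_allele=str(d[col("EA")]).upper(),
                other_allele=str(d[col("OA")]).upper(),
                eaf=None if eaf_raw in ("NA", "", "nan") else _parse_float(eaf_raw, "EAF", label),
                beta=_parse_float(d[col("BETA")], "BETA", label),
                se=_parse_float(d[col("SE")], "SE", label),
                pval=_parse_float(d[col("P")], "P", label),
                n=None if n_raw in ("NA", "", "nan") else float(n_raw),
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path} row {label}: {exc}") from None
                raise ValidationError(f"{path} row {label}: {exc}") from None
            n_dropped += 1
            continue
        records.append(rec)

    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate snp_id(s): {dupes[:5]}")
    if n_dropped:
        logger.info("read_summary_stats: dropped %d invalid row(s) from %s", n_dropped, path)
    return records


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return repr(float(x))  # shortest round-tripping decimal text


def write_summary_stats(records: Sequence[GwasRecord], path: str | Path) -> None:
    """Write records as canonical TSV; numeric text round-trips exactly."""
    path = Path(path)
    for rec in records:
        rec.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        _fmt(r.n),
                    )
                )
                + "\n"
            )


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a labelled square r² matrix (TSV, row and column SNP labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row labels differ from column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry in LD matrix: {exc}") from None
    return LdMatrix(snp_ids=tuple(str(s) for s in df.index), r2=values)


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    """Write an LD matrix as labelled TSV (inverse of :func:`read_ld_matrix`)."""
    pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids)).to_csv(
        path, sep="\t"
    )
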