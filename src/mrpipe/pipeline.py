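"""End-to-end orchestration: forward/reverse MR, MVMR, meta-analysis, mediation.

A run reads summary-statistics files named in a flat configuration,
executes select → clump → F-filter → outcome-exclusion → harmonize →
estimator battery → sensitivity suite, and writes report tables:
a machine table at full precision plus a human table rounded to two
decimals on the OR scale, so paper-style presentation and exact testing
coexist. Every report embeds the package version, a configuration hash,
the seed and per-stage audit counts; two runs with equal inputs produce
byte-identical outputs.

Significance is flagged at raw two-sided p < 0.05 with no multiplicity
correction across exposures by default (Benjamini–Hochberg is available
on the returned tables via ``statsmodels.stats.multitest`` if wanted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import gwas_io
from .estimators import EstimationError, estimate_all, ivw
from .gwas_io import read_ld_matrix, read_summary_stats
from .harmonize import harmonize
from .instruments import exclude_outcome_associated, select_instruments
from .mediation import MediatorDataset, screen_mediators
from .multivar_meta import MvmrInput, meta_pool, meta_table, mvmr_ivw, or_ci_to_beta_se
from .sensitivity import cochran_q, egger_intercept, funnel_data, leave_one_out, scatter_data

logger = logging.getLogger("mrpipe")


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in a config file are errors."""

    exposure_path: str = ""
    outcome_path: str = ""
    ld_path: str = ""
    outcome_ld_path: str = ""  # needed for direction=both / reverse
    outcome_paths: list[str] = field(default_factory=list)  # reverse batch
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    direction: str = "forward"
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_min: float = 10.0
    outcome_p_exclusion: float = 5e-8
    eaf_ambiguity_band: float = 0.08
    ivw_mode: str = "auto"
    n_boot: int = 1000
    seed: int | None = None
    out_dir: str = "mr_out"
    # MVMR
    exposure_paths: list[str] = field(default_factory=list)
    exposure_names: list[str] = field(default_factory=list)
    # meta / mediation manifests
    meta_manifest: str = ""
    mediator_manifest: str = ""
    mediator_p_threshold: float = 1e-5

    def validate(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigError(f"direction must be forward|reverse|both, got {self.direction!r}")
        for name, value, lo, hi in (
            ("p_threshold", self.p_threshold, 0.0, 1.0),
            ("clump_r2", self.clump_r2, 0.0, 1.0),
            ("outcome_p_exclusion", self.outcome_p_exclusion, 0.0, 1.0),
            ("mediator_p_threshold", self.mediator_p_threshold, 0.0, 1.0),
            ("eaf_ambiguity_band", self.eaf_ambiguity_band, -1e-9, 0.5),
        ):
            if not (lo < value <= hi) and not (name == "eaf_ambiguity_band" and value == 0):
                raise ConfigError(f"{name} = {value} outside its documented range")
        if self.clump_kb <= 0 or self.f_min <= 0 or self.n_boot < 1:
            raise ConfigError("clump_kb, f_min and n_boot must be positive")
        if self.ivw_mode not in ("auto", "fixed", "random"):
            raise ConfigError(f"ivw_mode must be auto|fixed|random, got {self.ivw_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _estimates_frames(estimates) -> tuple[pd.DataFrame, pd.DataFrame]:
    machine = pd.DataFrame(
        [
            {
                "method": e.method,
                "n_snp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "or": e.or_,
                "or_ci_low": e.or_ci_low,
                "or_ci_high": e.or_ci_high,
                "model_note": e.model_note,
            }
            for e in estimates
        ]
    )
    human = machine[["method", "n_snp"]].copy()
    human["OR (95% CI)"] = [
        f"{e.or_:.2f} ({e.or_ci_low:.2f}-{e.or_ci_high:.2f})" for e in estimates
    ]
    human["p"] = [f"{e.pval:.3f}" for e in estimates]
    human["significant"] = [e.pval < 0.05 for e in estimates]
    return machine, human


def _audit_payload(config: RunConfig, stages: dict) -> dict:
    from . import __version__

    return {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": stages,
    }


def run_mr(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """One exposure→outcome analysis with the full estimator and sensitivity battery.

    Returns the report bundle as a dict of DataFrames/objects and, when
    an output directory is given (or set in the config), writes the
    report tables there. With fewer than 3 surviving instruments the run
    degrades to IVW/ML only, with a warning in the audit.
    """
    config.validate()
    exposure = read_summary_stats(config.exposure_path)
    outcome = read_summary_stats(config.outcome_path)
    ld = read_ld_matrix(config.ld_path)

    inst = select_instruments(
        exposure,
        ld,
        exposure_name=config.exposure_name,
        p_threshold=config.p_threshold,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
        f_min=config.f_min,
    )
    kept = exclude_outcome_associated(inst.records, outcome, config.outcome_p_exclusion)
    stages = dict(inst.audit)
    stages["removed_outcome_associated"] = len(inst.records) - len(kept)

    H = harmonize(
        kept,
        outcome,
        config.eaf_ambiguity_band,
        exposure_name=config.exposure_name,
        outcome_name=config.outcome_name,
    )
    action_counts = pd.Series(list(H.actions.values())).value_counts().to_dict()
    stages["harmonize_actions"] = {k: int(v) for k, v in sorted(action_counts.items())}
    stages["analyzed"] = H.n_snp
    if H.n_snp == 0:
        raise EstimationError("no instruments survive harmonization")

    warnings = []
    if H.n_snp < 3:
        warnings.append(
            f"only {H.n_snp} instrument(s) survive: degraded mode, IVW/ML only"
        )
        logger.warning(warnings[-1])
    estimates = estimate_all(
        H, ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=config.seed
    )
    machine, human = _estimates_frames(estimates)

    sens_row = {"exposure": config.exposure_name, "outcome": config.outcome_name}
    if H.n_snp >= 2:
        het = cochran_q(H)
        sens_row.update(Q=het.q, Q_df=het.df, Q_p=het.pval)
    if H.n_snp >= 3:
        pleio = egger_intercept(H)
        sens_row.update(
            egger_intercept=pleio.intercept,
            intercept_se=pleio.se,
            intercept_p=pleio.pval,
        )
    sensitivity = pd.DataFrame([sens_row])

    bundle = {
        "harmonized": H.to_frame(),
        "estimates": machine,
        "estimates_human": human,
        "sensitivity": sensitivity,
        "funnel": funnel_data(H),
        "audit": _audit_payload(config, stages) | {"warnings": warnings},
    }
    points, lines = scatter_data(H, estimates)
    bundle["scatter_points"], bundle["scatter_lines"] = points, lines
    if H.n_snp >= 3:
        bundle["leave_one_out"] = leave_one_out(H, mode=config.ivw_mode).table

    out = Path(out_dir) if out_dir is not None else (
        Path(config.out_dir) if config.out_dir else None
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                _write_tsv(obj, out / f"{name}.tsv")
        with open(out / "audit.json", "w", encoding="utf-8") as fh:
            json.dump(bundle["audit"], fh, indent=1, sort_keys=True)
    return bundle


def _swapped(config: RunConfig, outcome_path: str, outcome_name: str) -> RunConfig:
    return dataclasses.replace(
        config,
        exposure_path=config.outcome_path,
        exposure_name=config.outcome_name,
        outcome_path=outcome_path,
        outcome_name=outcome_name,
        ld_path=config.outcome_ld_path or config.ld_path,
        direction="forward",
        out_dir="",
    )


def run_reverse(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Reverse MR: instrument the original outcome against one or more outcomes.

    Produces a one-row-per-outcome table (nSNPs, IVW OR/CI/p, Cochran's
    Q, Egger intercept) shaped like a reverse-direction summary table.
    """
    config.validate()
    targets = config.outcome_paths or [config.exposure_path]
    names = (
        [Path(p).stem for p in config.outcome_paths]
        if config.outcome_paths
        else [config.exposure_name]
    )
    rows, bundles = [], {}
    for path, name in zip(targets, names):
        sub = _swapped(config, path, name)
        if not Path(path).exists():
            raise ConfigError(f"reverse MR outcome dataset not found: {path} ({name})")
        bundle = run_mr(sub, out_dir=None)
        bundles[name] = bundle
        est = bundle["estimates"]
        ivw_row = est[est.method.str.startswith("ivw")].iloc[0]
        srow = bundle["sensitivity"].iloc[0].to_dict()
        rows.append(
            {
                "exposure": sub.exposure_name,
                "outcome": name,
                "n_snp": int(ivw_row.n_snp),
                "ivw_beta": ivw_row.beta,
                "ivw_or": ivw_row["or"],
                "ivw_or_ci_low": ivw_row.or_ci_low,
                "ivw_or_ci_high": ivw_row.or_ci_high,
                "ivw_p": ivw_row.pval,
                "Q": srow.get("Q"),
                "Q_p": srow.get("Q_p"),
                "egger_intercept": srow.get("egger_intercept"),
                "intercept_p": srow.get("intercept_p"),
                "significant": ivw_row.pval < 0.05,
            }
        )
    table = pd.DataFrame(rows)
    out = Path(out_dir) if out_dir is not None else (
        Path(config.out_dir) if config.out_dir else None
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(table, out / "reverse_mr.tsv")
    return {"table": table, "bundles": bundles}


def run_meta(manifest_path: str | Path, model: str = "auto", out_dir: str | Path | None = None) -> dict:
    """Pool per-cohort estimates from a manifest TSV.

    The manifest needs ``study`` plus either ``beta``/``se`` columns or
    ``or``/``or_ci_low``/``or_ci_high`` (converted via logs). Malformed
    rows raise with their row number.
    """
    df = pd.read_csv(manifest_path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if "study" not in df.columns:
        raise ConfigError(f"{manifest_path}: manifest needs a 'study' column")
    estimates, labels = [], []
    for i, row in df.iterrows():
        try:
            if "beta" in df.columns and pd.notna(row.get("beta")):
                pair = (float(row["beta"]), float(row["se"]))
            else:
                pair = or_ci_to_beta_se(
                    float(row["or"]), float(row["or_ci_low"]), float(row["or_ci_high"])
                )
            if pair[1] <= 0:
                raise ValueError(f"non-positive se {pair[1]}")
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{manifest_path} row {i + 2}: {exc}") from None
        estimates.append(pair)
        labels.append(str(row["study"]))
    pooled = meta_pool(estimates, model=model)
    both = {
        m: meta_pool(estimates, model=m) for m in ("fixed", "random")
    }
    forest = meta_table(pooled, labels, estimates)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(forest, out / "meta_forest.tsv")
        with open(out / "meta_result.json", "w", encoding="utf-8") as fh:
            json.dump(
                {m: dataclasses.asdict(r) for m, r in ({"selected": pooled} | both).items()},
                fh, indent=1, sort_keys=True,
            )
    return {"result": pooled, "fixed": both["fixed"], "random": both["random"], "forest": forest}


def run_mvmr(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Multivariable MR over the configured exposure set.

    Instrument assembly: union of each exposure's instruments, re-clumped
    jointly against the shared LD matrix, harmonized to the outcome, then
    complete-case on every exposure's effect (every SNP must be present
    in every exposure dataset).
    """
    config.validate()
    if len(config.exposure_paths) < 2:
        raise ConfigError("MVMR needs at least 2 exposure_paths")
    names = config.exposure_names or [Path(p).stem for p in config.exposure_paths]
    if len(names) != len(config.exposure_paths):
        raise ConfigError("exposure_names length must match exposure_paths")
    datasets = [read_summary_stats(p) for p in config.exposure_paths]
    outcome = read_summary_stats(config.outcome_path)
    ld = read_ld_matrix(config.ld_path)

    union: dict[str, gwas_io.GwasRecord] = {}
    for recs in datasets:
        inst = select_instruments(
            recs,
            ld,
            p_threshold=config.p_threshold,
            clump_r2=config.clump_r2,
            clump_kb=config.clump_kb,
            f_min=config.f_min,
        )
        for r in inst.records:
            union.setdefault(r.snp_id, r)
    from .instruments import clump as _clump

    joint = _clump(list(union.values()), ld, config.clump_r2, config.clump_kb)
    by_id = [{r.snp_id: r for r in recs} for recs in datasets]
    complete = [r for r in joint if all(r.snp_id in d for d in by_id)]
    H = harmonize(complete, outcome, config.eaf_ambiguity_band)
    if H.n_snp < len(names) + 1:
        raise EstimationError(
            f"MVMR needs at least {len(names) + 1} complete-case SNPs, got {H.n_snp}"
        )
    # exposure effects aligned to each dataset's stated effect allele of the
    # harmonized exposure record (the first exposure anchors orientation)
    beta_exp, se_exp = [], []
    anchor = {r.snp_id: r for r in complete}
    for snp in H.snp_ids:
        row_b, row_s = [], []
        for d in by_id:
            rec = d[snp]
            sign = 1.0 if rec.effect_allele == anchor[snp].effect_allele else -1.0
            row_b.append(sign * rec.beta)
            row_s.append(rec.se)
        beta_exp.append(row_b)
        se_exp.append(row_s)
    data = MvmrInput(
        snp_ids=H.snp_ids,
        exposure_names=tuple(names),
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=H.beta_out,
        se_out=H.se_out,
    )
    estimates = mvmr_ivw(data)
    machine, human = _estimates_frames(estimates)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(machine, out / "mvmr_estimates.tsv")
        _write_tsv(human, out / "mvmr_estimates_human.tsv")
    return {"estimates": machine, "estimates_human": human, "n_snp": H.n_snp}


def run_mediation(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Two-step mediation screen over a mediator-panel manifest.

    The manifest is a TSV of (mediator_id, stats_path, ld_path). The
    total effect is the forward IVW estimate recomputed from the
    configured exposure/outcome pair.
    """
    config.validate()
    manifest = pd.read_csv(config.mediator_manifest, sep="\t")
    required = {"mediator_id", "stats_path", "ld_path"}
    if not required <= set(manifest.columns):
        raise ConfigError(
            f"{config.mediator_manifest}: manifest needs columns {sorted(required)}"
        )
    exposure = read_summary_stats(config.exposure_path)
    outcome = read_summary_stats(config.outcome_path)
    ld = read_ld_matrix(config.ld_path)
    inst = select_instruments(
        exposure,
        ld,
        p_threshold=config.p_threshold,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
        f_min=config.f_min,
    )
    H = harmonize(inst.records, outcome, config.eaf_ambiguity_band)
    total = ivw(H, mode=config.ivw_mode)
    mediators = [
        MediatorDataset(
            name=str(row.mediator_id),
            records=read_summary_stats(row.stats_path),
            ld=read_ld_matrix(row.ld_path),
        )
        for row in manifest.itertuples(index=False)
    ]
    full, retained = screen_mediators(
        exposure,
        ld,
        mediators,
        outcome,
        beta_total=total.beta,
        se_total=total.se,
        exposure_p_threshold=config.p_threshold,
        mediator_p_threshold=config.mediator_p_threshold,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
        f_min=config.f_min,
        ivw_mode=config.ivw_mode,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(full, out / "mediation_full.tsv")
        _write_tsv(retained, out / "mediation_retained.tsv")
    return {"full": full, "retained": retained, "total": total}
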