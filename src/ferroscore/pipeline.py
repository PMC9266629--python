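"""End-to-end orchestration: score -> RFL -> survival scan -> screen ->
recurrence/Jaccard -> risk model, from a config file to a report bundle.

Cohorts are processed independently, then merged for the cross-cohort
recurrence and Jaccard stages (the per-cancer-then-pan-cancer flow).  A
cohort whose RFL fails validation (|r| < 0.2 against either component) is
excluded from the survival and screen stages with a logged notice.  All
outputs are TSV plus a plain-text run log and a manifest; reruns on the
same config and seed are byte-identical (the log carries no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geneset import GeneSetPair, build_pair, read_gmt, read_whitelist, write_gmt
from .io import (
    read_clinical_tsv,
    read_expression_tsv,
    write_clinical_tsv,
    write_expression_tsv,
)
from .rfl import assign_groups, compute_rfl, validate_rfl
from .screen import (
    correlate_genes,
    jaccard_matrix,
    recurrent_genes,
    select_correlated,
)
from .simulate import SimParams, generate_cohort, with_seed
from .ssgsea import SsgseaParams, score_matrix
from .survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    risk_score,
    roc_auc,
    scan_cutoff,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for a missing or ill-typed config field (named in message)."""


@dataclass
class PipelineConfig:
    mode: str = "synthetic-demo"            # or "real-data"
    seed: int = 0
    outdir: str = "ferroscore_out"
    # real-data inputs
    gmt: str | None = None
    whitelist: str | None = None
    cohorts: list[dict] = field(default_factory=list)  # {name, expression, clinical}
    # synthetic-demo inputs
    n_cohorts: int = 9
    sim: dict = field(default_factory=dict)            # SimParams overrides
    # analysis parameters
    alpha: float = 0.25
    normalize: bool = False
    threshold_r: float = 0.3
    threshold_p: float = 0.05
    scan_lo: float = 0.10
    scan_hi: float = 0.90
    min_cohorts: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        for key in raw:
            if key not in known:
                raise ConfigError(f"{path}: unknown config field {key!r}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic-demo", "real-data"):
            raise ConfigError(f"mode must be synthetic-demo or real-data, got {self.mode!r}")
        if not (0 < self.scan_lo < self.scan_hi < 1):
            raise ConfigError("scan window requires 0 < scan_lo < scan_hi < 1")
        if self.mode == "real-data":
            if not self.gmt:
                raise ConfigError("real-data mode requires field 'gmt'")
            if not self.cohorts:
                raise ConfigError("real-data mode requires field 'cohorts'")
            for c in self.cohorts:
                for key in ("name", "expression", "clinical"):
                    if key not in c:
                        raise ConfigError(f"cohort entry missing field {key!r}")
                for key in ("expression", "clinical"):
                    if not Path(c[key]).exists():
                        raise ConfigError(f"cohort {c['name']}: path {c[key]} does not exist")
            if not Path(self.gmt).exists():
                raise ConfigError(f"gmt path {self.gmt} does not exist")
            if self.whitelist and not Path(self.whitelist).exists():
                raise ConfigError(f"whitelist path {self.whitelist} does not exist")


def _setup_run_logger(path: Path) -> logging.Handler:
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler.setLevel(logging.INFO)
    root = logging.getLogger("ferroscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _write_tsv(df: pd.DataFrame, path: Path, outputs: list[Path], **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    outputs.append(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    The report bundle contains, per cohort: the activity table, validation
    summary, cutoff-scan trace, per-group Kaplan–Meier tables and the gene
    screen; across cohorts: Jaccard matrices, the recurrence table and a
    risk-model summary; plus ``run.log`` and ``manifest.tsv``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    handler = _setup_run_logger(outdir / "run.log")
    try:
        logger.info("ferroscore %s", __version__)
        logger.info(
            "config: %s",
            sorted((k, v) for k, v in vars(config).items() if k != "outdir"),
        )
        cohorts, pair = _load_cohorts(config, outdir, outputs)
        logger.info(
            "signature pair: %d drivers, %d suppressors (excluded overlap %d, "
            "non-whitelist %d)",
            len(pair.drivers), len(pair.suppressors),
            len(pair.excluded_overlap), len(pair.excluded_noncoding),
        )
        results = {}
        for name, (expr, clin) in cohorts.items():
            results[name] = _run_cohort(config, name, expr, clin, pair, outdir, outputs)
        _run_cross_cohort(config, cohorts, results, outdir, outputs)
        manifest = pd.DataFrame(
            {"path": sorted(str(p.relative_to(outdir)) for p in outputs)}
        )
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        logger.info("wrote %d output files", len(outputs) + 2)
    finally:
        logging.getLogger("ferroscore").removeHandler(handler)
        handler.close()
    return outdir


def _load_cohorts(
    config: PipelineConfig, outdir: Path, outputs: list[Path]
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], GeneSetPair]:
    """Load or generate cohorts; synthetic inputs are round-tripped through
    the on-disk formats so the demo exercises the real readers."""
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    if config.mode == "synthetic-demo":
        base = SimParams(**{**config.sim, "seed": config.seed})
        seeds = np.random.SeedSequence(config.seed).generate_state(config.n_cohorts)
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        gmt_path = None
        for i, s in enumerate(seeds):
            name = f"cohort{i + 1:02d}"
            sim = generate_cohort(with_seed(base, int(s) % (2**31)))
            cdir = indir / name
            cdir.mkdir(exist_ok=True)
            write_expression_tsv(sim.expression, cdir / "expression.tsv")
            write_clinical_tsv(sim.clinical, cdir / "clinical.tsv")
            outputs.extend([cdir / "expression.tsv", cdir / "clinical.tsv"])
            if gmt_path is None:
                gmt_path = indir / "signatures.gmt"
                write_gmt([sim.pair.drivers, sim.pair.suppressors], gmt_path)
                outputs.append(gmt_path)
            cohorts[name] = (
                read_expression_tsv(cdir / "expression.tsv"),
                read_clinical_tsv(cdir / "clinical.tsv"),
            )
            logger.info("%s: generated %d genes x %d samples",
                        name, *cohorts[name][0].shape)
        sets = read_gmt(gmt_path)
    else:
        for entry in config.cohorts:
            cohorts[entry["name"]] = (
                read_expression_tsv(entry["expression"]),
                read_clinical_tsv(entry["clinical"]),
            )
        sets = read_gmt(config.gmt)
    if len(sets) < 2:
        raise ConfigError("GMT must contain driver and suppressor sets")
    whitelist = read_whitelist(config.whitelist) if config.whitelist else None
    pair = build_pair(sets[0], sets[1], whitelist)
    return cohorts, pair


def _run_cohort(
    config: PipelineConfig,
    name: str,
    expr: pd.DataFrame,
    clin: pd.DataFrame,
    pair: GeneSetPair,
    outdir: Path,
    outputs: list[Path],
) -> dict:
    cdir = outdir / name
    cdir.mkdir(exist_ok=True)
    params = SsgseaParams(alpha=config.alpha, normalize=config.normalize)
    scores = score_matrix(expr, [pair.drivers, pair.suppressors], params)
    table = compute_rfl(scores.iloc[0], scores.iloc[1])
    n_def = int(table["rfl"].notna().sum())
    logger.info("%s: RFL defined for %d of %d samples", name, n_def, len(table))

    validation = validate_rfl(table)
    pd.DataFrame(
        {
            "r_drive": [validation.r_drive], "p_drive": [validation.p_drive],
            "r_suppress": [validation.r_suppress],
            "p_suppress": [validation.p_suppress],
            "passed": [validation.passed],
        }
    ).to_csv(cdir / "validation.tsv", sep="\t", index=False, float_format="%.10g")
    outputs.append(cdir / "validation.tsv")

    result: dict = {"validation": validation, "table": table}
    if not validation.passed:
        logger.info("%s: RFL validation failed; cohort excluded from "
                    "survival and screen stages", name)
        _write_tsv(table, cdir / "activity.tsv", outputs, index_label="sample_id")
        return result

    rfl_series = table["rfl"]
    records = clin.loc[rfl_series.index]
    scan = scan_cutoff(rfl_series, records, lo=config.scan_lo, hi=config.scan_hi)
    table = table.copy()
    table["group"] = assign_groups(rfl_series, scan.best_cutoff)
    _write_tsv(table, cdir / "activity.tsv", outputs, index_label="sample_id")
    _write_tsv(scan.scanned, cdir / "cutoff_scan.tsv", outputs, index=False)
    logger.info(
        "%s: best cutoff %.6g (log-rank P %.3g, HR high vs low %.3g)",
        name, scan.best_cutoff, scan.best_p, scan.hazard_ratio,
    )
    for grp in ("high", "low"):
        members = table.index[table["group"] == grp]
        km = km_estimate(records.loc[members])
        _write_tsv(km, cdir / f"km_{grp}.tsv", outputs, index=False)

    # the screen looks for NEW RFL-correlated genes: the signature genes that
    # define the score are excluded from the candidate universe
    signature = pair.drivers.genes | pair.suppressors.genes
    candidates = expr.drop(index=[g for g in expr.index if g in signature])
    screen = correlate_genes(
        candidates, rfl_series, cohort=name,
        threshold_r=config.threshold_r, threshold_p=config.threshold_p,
    )
    _write_tsv(screen.table, cdir / "screen.tsv", outputs, index_label="gene")
    pos, neg = select_correlated(screen, config.threshold_r, config.threshold_p)
    logger.info("%s: screen found %d positive / %d negative genes",
                name, len(pos), len(neg))
    result.update(
        {"scan": scan, "screen": screen, "positive": pos, "negative": neg,
         "records": records, "expr": expr}
    )
    return result


def _run_cross_cohort(
    config: PipelineConfig,
    cohorts: dict,
    results: dict,
    outdir: Path,
    outputs: list[Path],
) -> None:
    screened = {n: r for n, r in results.items() if "positive" in r}
    if len(screened) >= 2:
        jac_pos = jaccard_matrix({n: r["positive"] for n, r in screened.items()})
        jac_neg = jaccard_matrix({n: r["negative"] for n, r in screened.items()})
        _write_tsv(jac_pos, outdir / "jaccard_positive.tsv", outputs)
        _write_tsv(jac_neg, outdir / "jaccard_negative.tsv", outputs)
    if len(screened) < config.min_cohorts:
        logger.info(
            "recurrence stage skipped: %d screened cohorts < min_cohorts %d",
            len(screened), config.min_cohorts,
        )
        return
    recurrence = recurrent_genes(
        {n: (r["positive"], r["negative"]) for n, r in screened.items()},
        min_cohorts=config.min_cohorts,
    )
    _write_tsv(recurrence, outdir / "recurrence.tsv", outputs)
    selected = recurrence.index[recurrence["selected"]].tolist()
    logger.info("recurrence: %d genes selected in >=%d cohorts",
                len(selected), config.min_cohorts)
    if not selected:
        logger.info("risk-model stage skipped: no recurrent genes")
        return

    rows = []
    for name, r in screened.items():
        expr, records = r["expr"], r["records"]
        X = expr.loc[selected].T
        df = pd.concat([records[["time", "event"]], X], axis=1)
        # small ridge penalty: recurrent genes all track RFL, so the panel
        # is collinear and an unpenalized fit need not converge
        fit = cox_fit(df, covariates=selected, penalizer=0.1)
        rm = risk_score(fit, X)
        high = rm.group == "high"
        if high.sum() == 0 or (~high).sum() == 0:
            logger.info("%s: degenerate risk grouping; skipped", name)
            continue
        chi2, p = logrank_test(records[high.to_numpy()], records[(~high).to_numpy()])
        auc = roc_auc(rm.risk_score, records["event"])
        rows.append((name, len(selected), float(rm.risk_score.mean()),
                     chi2, p, auc,
                     int(records.loc[high.to_numpy(), "event"].sum()),
                     int(records.loc[(~high).to_numpy(), "event"].sum())))
        _write_tsv(
            pd.DataFrame({"risk_score": rm.risk_score, "group": rm.group}),
            outdir / name / "risk_scores.tsv", outputs, index_label="sample_id",
        )
    summary = pd.DataFrame(
        rows, columns=["cohort", "n_genes", "mean_rs", "logrank_chi2",
                       "logrank_p", "auc", "events_high_rs", "events_low_rs"],
    )
    _write_tsv(summary, outdir / "risk_model.tsv", outputs, index=False)
    logger.info("risk model fitted in %d cohorts", len(summary))
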