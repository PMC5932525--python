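"""End-to-end orchestration: (synthetic) data -> normalization ->
differential expression -> clustering QC -> optional MRM concordance.

The pipeline is configured with a :class:`PipelineConfig`, loadable from
YAML or JSON.  Inputs are either on-disk tables (``design`` plus
``reporter_tables``) or a ``synthetic`` block mirroring the generator's
parameters; all outputs are written to ``outdir`` in the io module's
dialects, together with a JSON run log recording configuration, seed and
stage row counts so the presence-filter arithmetic can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, io
from .design import BatchDesign
from .diffexp import run_comparisons, volcano_table
from .mrmval import protein_group_l2r, quantify_peptides, sign_concordance
from .normalize import ReporterTable, assemble_matrix, normalize_batch
from .qccluster import cluster_samples, qc_report
from .synthdata import (
    GeneratorParams,
    SyntheticTruth,
    generate_cohort,
    generate_design,
    parse_comparison,
)
from .diffexp import presence_filter

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any computation when the configuration is invalid."""


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Exactly one input source must be given: file paths (``design`` and
    ``reporter_tables``) or a ``synthetic`` mapping of generator
    parameters.  Thresholds follow the conventional defaults: proteins
    must be present in >= 70 % of every group's samples, and both
    differential-expression p-values must fall below 0.05.
    """

    design: str | None = None
    reporter_tables: Sequence[str] = ()
    synthetic: Mapping[str, Any] | None = None
    mrm: str | None = None
    mrm_comparison: str | None = None
    presence_threshold: float = 0.7
    alpha: float = 0.05
    normality_alpha: float = 0.05
    comparisons: Sequence[str] = ("G1-Ctrl", "G2-Ctrl", "G1-G2")
    linkage: str = "average"
    bh_correction: bool = False
    outdir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        for name in ("presence_threshold", "alpha", "normality_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (name == "presence_threshold" and v == 1.0):
                raise ConfigError(f"{name} must lie in (0, 1): {v}")
        has_files = self.design is not None and len(self.reporter_tables) > 0
        if has_files == (self.synthetic is not None):
            raise ConfigError(
                "configure exactly one input source: design+reporter_tables or synthetic"
            )
        if self.mrm is not None and self.mrm_comparison is None:
            raise ConfigError("mrm input requires mrm_comparison (e.g. 'G1-Ctrl')")


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    design: BatchDesign
    matrix: pd.DataFrame
    filtered: pd.DataFrame
    stats: Mapping[str, pd.DataFrame]
    qc: pd.DataFrame
    truth: SyntheticTruth | None = None
    concordance: Any = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _synthetic_params(cfg: PipelineConfig) -> GeneratorParams:
    params_kw = dict(cfg.synthetic or {})
    params_kw.setdefault("seed", cfg.seed)
    try:
        return GeneratorParams(**params_kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"synthetic block: {exc}") from exc


def _synthetic_inputs(
    params: GeneratorParams,
) -> tuple[BatchDesign, list[ReporterTable], SyntheticTruth]:
    design = generate_design(
        params.n_batches, params.channels_per_batch, params.groups, params.seed
    )
    tables, truth = generate_cohort(design, params)
    return design, tables, truth


def _check_comparisons(cfg: PipelineConfig, groups) -> None:
    comps = list(cfg.comparisons) + ([cfg.mrm_comparison] if cfg.mrm_comparison else [])
    for comp in comps:
        for g in parse_comparison(comp):
            if g not in groups:
                raise ConfigError(
                    f"comparison {comp!r} references group {g!r} not among {list(groups)}"
                )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every configured stage and write all artifacts.

    Stage order: simulate (if configured) -> normalize -> presence
    filter -> per-comparison statistics -> clustering QC -> MRM
    concordance (if configured).  Any stage failure aborts with a
    stage-named error; outputs are written only after their stage
    completed.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, Any] = {}

    def _write(name: str, fn, *args) -> None:
        path = outdir / name
        fn(*args, path)
        outputs[name] = path

    # ---- inputs ----------------------------------------------------------
    truth = None
    if cfg.synthetic is not None:
        params = _synthetic_params(cfg)
        _check_comparisons(cfg, params.groups)
        design, raw_tables, truth = _stage("simulate", _synthetic_inputs, params)
        _write("design.tsv", io.write_design, design)
        for t in raw_tables:
            _write(f"reporter_{t.batch}.tsv", io.write_reporter_table, t)
        _write("truth.tsv", io.write_truth, truth)
    else:
        design = _stage("read", io.read_design, cfg.design)
        _check_comparisons(cfg, design.groups)
        raw_tables = _stage("read", io.read_reporter_tables, list(cfg.reporter_tables))
    counts["n_batches"] = len(raw_tables)
    counts["n_samples"] = len(design.samples)

    # ---- normalize -------------------------------------------------------
    norm_tables = [_stage("normalize", normalize_batch, t) for t in raw_tables]
    for t in norm_tables:
        _write(f"normalized_{t.batch}.tsv", io.write_reporter_table, t)
    matrix = _stage("normalize", assemble_matrix, norm_tables, design)
    _write("expression_matrix.tsv", io.write_matrix, matrix)
    counts["n_proteins_assembled"] = int(matrix.shape[0])

    # ---- presence filter + differential expression -----------------------
    filtered, presence = _stage(
        "diffexp", presence_filter, matrix, design, cfg.presence_threshold
    )
    counts["n_proteins_retained"] = int(filtered.shape[0])
    stats = _stage(
        "diffexp",
        run_comparisons,
        filtered,
        design,
        list(cfg.comparisons),
        cfg.alpha,
        cfg.normality_alpha,
        cfg.bh_correction,
    )
    for comp, table in stats.items():
        _write(f"stats_{comp}.tsv", io.write_stats, table)
        _write(f"volcano_{comp}.tsv", io.write_matrix, volcano_table(table))
        counts[f"n_significant_{comp}"] = int(table["significant"].sum())

    # ---- clustering QC ---------------------------------------------------
    dendro = _stage("qc", cluster_samples, filtered, cfg.linkage)
    qc = _stage(
        "qc",
        qc_report,
        dendro,
        design.sample_batches,
        design.sample_groups,
        len(design.batches),
        len(design.groups),
        200,
        cfg.seed,
    )
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n", encoding="utf-8")
    outputs["dendrogram.nwk"] = outdir / "dendrogram.nwk"
    qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False,
              float_format=io.FLOAT_FORMAT)
    outputs["qc_report.tsv"] = outdir / "qc_report.tsv"

    # ---- optional MRM concordance ----------------------------------------
    concordance = None
    if cfg.mrm is not None:
        mrm_table = _stage("mrm", io.read_mrm, cfg.mrm)
        ga, gb = parse_comparison(cfg.mrm_comparison)
        quants = _stage("mrm", quantify_peptides, mrm_table)
        mrm_l2r = _stage("mrm", protein_group_l2r, quants, ga, gb)
        itraq_l2r = stats[cfg.mrm_comparison]["l2r_centered"].dropna()
        concordance = _stage("mrm", sign_concordance, itraq_l2r, mrm_l2r)
        _write("concordance.tsv", io.write_concordance, concordance.detail)
        counts["mrm_concordant"] = concordance.k
        counts["mrm_compared"] = concordance.n

    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(dataclasses.asdict(cfg)),
        "counts": counts,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
    outputs["run_log.json"] = outdir / "run_log.json"

    return PipelineResult(
        design=design, matrix=matrix, filtered=filtered, stats=stats, qc=qc,
        truth=truth, concordance=concordance, outputs=outputs,
    )


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
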