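"""End-to-end orchestration of the discovery cascade and the stratification
analyses, with YAML configuration, structured stage logging and reporting.

The discovery cascade runs, in order: knockdown intersection -> cell-line
specificity -> peak-to-TSS assignment / direct-target calling -> repeat
annotation -> tumor-type specificity (primary tumors, then metastases) ->
normal-tissue screen. Stage order follows the study design: expression
filters narrow the space before ChIP integration, and type-specificity acts
on the direct-target survivors. Each stage logs one structured line with
input/output counts, making the audit trail a first-class artifact, and any
stage failure aborts the run with the stage name (fail-fast; downstream
filters are meaningless on partial survivors).

Every report records a hash of the configuration; derived inputs (e.g. a
signature file produced by a discovery run) embed the same hash, and re-use
under a different configuration is refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import cohorts as co
from . import genomic as ge
from . import stratify as st
from .errors import FusionTargetError, ValidationError
from .io import read_fasta

logger = logging.getLogger(__name__)

_SYNTH_FILES = {
    "expr_kd": "expr_kd.tsv",
    "expr_lines": "expr_lines.tsv",
    "expr_tumors": "expr_tumors.tsv",
    "expr_met": "expr_met.tsv",
    "expr_normals": "expr_normals.tsv",
    "labels": "labels.tsv",
    "genome_fasta": "genome.fa",
    "annotation": "annotation.tsv",
    "peaks_bed": "peaks_fusion_on.bed",
}


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    ``data_dir`` may point at a directory in the synthetic generator's
    layout; individual path fields override file-by-file. Threshold defaults
    are the study's printed values: expression gate > 1 FPKM, fold gate
    >= 2, TSS window +-100 kb, >= 5 consecutive motif copies, network edge
    threshold r >= 0.5, enrichment calls at NES > 1.5 and q < 0.05.
    """

    data_dir: str | None = None
    expr_kd: str | None = None
    expr_lines: str | None = None
    expr_tumors: str | None = None
    expr_met: str | None = None
    expr_normals: str | None = None
    labels: str | None = None
    genome_fasta: str | None = None
    annotation: str | None = None
    peaks_bed: str | None = None
    signature_file: str | None = None
    outdir: str = "fusiontarget_out"

    target_type: str = "EwS"
    direction: str = "down"
    min_expr: float = 1.0
    min_fold: float = 2.0
    pseudocount: float = 0.01
    max_fpkm_lines: float = 1.0
    window_bp: int = 100_000
    motif: str = "GGAA"
    min_repeats: int = 5
    fpkm_thr_types: float = 1.0
    max_other_types: int = 1
    type_stat: str = "median"
    tissue_fpkm_thr: float = 1.0
    max_tissues: int = 1
    apply_tissue_filter: bool = True
    kd_ctrl_suffix: str = "_shControl"
    kd_kd_suffix: str = "_shFusion"

    r_min: float = 0.5
    nes_min: float = 1.5
    q_max: float = 0.05
    n_perm: int = 1000
    metric: str = "zscore"

    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValidationError("min_fold must be >= 1")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be > 0")
        if self.min_repeats < 1:
            raise ValidationError("min_repeats must be >= 1")
        if not -1 <= self.r_min <= 1.0001:
            # r_min above 1 yields an edgeless network, which is legal
            if self.r_min < -1:
                raise ValidationError("r_min must be >= -1")
        if not 0 < self.q_max <= 1:
            raise ValidationError("q_max must lie in (0, 1]")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.direction not in ("down", "up"):
            raise ValidationError("direction must be 'down' or 'up'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def resolve(self, key: str) -> Path:
        explicit = getattr(self, key)
        if explicit is not None:
            return Path(explicit)
        if self.data_dir is None:
            raise ValidationError(f"no path for {key!r} and no data_dir set")
        return Path(self.data_dir) / _SYNTH_FILES[key]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DiscoveryReport:
    """Stage-by-stage audit of one discovery run."""

    stages: list[dict] = field(default_factory=list)
    repeat_fraction: float | None = None
    final: co.GeneSet = co.GeneSet(genes=())
    tissue_report: pd.DataFrame | None = None
    config_hash: str = ""
    seed: int = 0
    timestamp: str = ""

    def add_stage(self, name: str, n_in: int, result: co.GeneSet) -> co.GeneSet:
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_out": len(result), "genes": list(result.genes)}
        )
        logger.info("stage=%s n_in=%d n_out=%d", name, n_in, len(result))
        return result

    def write(self, outdir: str | os.PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "repeat_fraction_ge_threshold": self.repeat_fraction,
            "stages": [
                {k: v for k, v in s.items() if k != "genes"} | {"n_genes": len(s["genes"])}
                for s in self.stages
            ],
            "final_candidates": list(self.final.genes),
        }
        with open(out / "discovery_report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for s in self.stages:
            co.GeneSet(
                genes=tuple(s["genes"]), provenance=(s["stage"],)
            ).to_tsv(out / f"genes_{s['stage']}.tsv", config_hash=self.config_hash)
        self.final.to_tsv(out / "final_candidates.tsv", config_hash=self.config_hash)
        if self.tissue_report is not None:
            self.tissue_report.to_csv(out / "tissue_screen.tsv", sep="\t")


def _infer_kd_pairs(expr: co.ExpressionMatrix, ctrl_suffix: str, kd_suffix: str) -> list[tuple[str, str]]:
    pairs = []
    for s in expr.sample_ids:
        if s.endswith(ctrl_suffix):
            partner = s[: -len(ctrl_suffix)] + kd_suffix
            if partner in expr.sample_ids:
                pairs.append((s, partner))
    if not pairs:
        raise ValidationError(
            f"could not infer knockdown pairs from suffixes "
            f"{ctrl_suffix!r}/{kd_suffix!r}"
        )
    return pairs


def _load_cohort(config: PipelineConfig, key: str) -> co.ExpressionMatrix:
    return co.load_expression(config.resolve(key), config.resolve("labels"))


def run_discovery(config: PipelineConfig, write: bool = True) -> DiscoveryReport:
    """Execute the full discovery cascade; returns (and writes) the report."""
    report = DiscoveryReport(
        config_hash=config.config_hash,
        seed=config.seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    def _stage(name, fn):
        try:
            return fn()
        except FusionTargetError as exc:
            raise FusionTargetError(f"stage {name!r} failed: {exc}") from exc

    kd = _stage("load_kd", lambda: _load_cohort(config, "expr_kd"))
    pairs = _infer_kd_pairs(kd, config.kd_ctrl_suffix, config.kd_kd_suffix)
    n_total = len(kd.gene_ids)
    regulated = _stage(
        "common_regulated",
        lambda: co.common_regulated(
            kd,
            pairs,
            direction=config.direction,  # type: ignore[arg-type]
            min_expr=config.min_expr,
            min_fold=config.min_fold,
            pseudocount=config.pseudocount,
        ),
    )
    report.add_stage("common_regulated", n_total, regulated)

    lines = _stage("load_lines", lambda: _load_cohort(config, "expr_lines"))
    specific = _stage(
        "specificity_lines",
        lambda: co.specificity_filter_lines(
            regulated, lines, target_type=config.target_type, max_fpkm=config.max_fpkm_lines
        ),
    )
    report.add_stage("specificity_lines", len(regulated), specific)

    ann = _stage("load_annotation", lambda: ge.GenomeAnnotation.from_tsv(config.resolve("annotation")))
    peaks = _stage(
        "load_peaks", lambda: ge.PeakSet.from_bed(config.resolve("peaks_bed"), "fusion")
    )
    assignment = ge.assign_peaks_to_tss(peaks, ann, window_bp=config.window_bp)
    direct = _stage("direct_targets", lambda: ge.direct_targets(specific, assignment))
    report.add_stage("direct_targets", len(specific), direct)

    genome = _stage("load_genome", lambda: read_fasta(config.resolve("genome_fasta")))
    bound_names = sorted({p for g in direct.genes for p in assignment.get(g, [])})
    bound = ge.PeakSet(
        intervals=peaks.intervals[peaks.intervals["name"].isin(bound_names)].reset_index(
            drop=True
        ),
        source_condition=peaks.source_condition,
    )
    repeats = _stage(
        "annotate_repeats",
        lambda: ge.annotate_repeats(
            bound, genome, motif=config.motif, min_repeats=config.min_repeats
        ),
    )
    report.repeat_fraction = repeats.fraction_ge_threshold
    logger.info(
        "stage=annotate_repeats regions=%d fraction_ge_%d=%.3f",
        len(repeats.table),
        config.min_repeats,
        report.repeat_fraction,
    )

    tumors = _stage("load_tumors", lambda: _load_cohort(config, "expr_tumors"))
    after_tumors = _stage(
        "specificity_types_tumors",
        lambda: co.specificity_filter_types(
            direct,
            tumors,
            target_type=config.target_type,
            fpkm_thr=config.fpkm_thr_types,
            max_other_types=config.max_other_types,
            type_stat=config.type_stat,  # type: ignore[arg-type]
        ),
    )
    report.add_stage("specificity_types_tumors", len(direct), after_tumors)

    met = _stage("load_met", lambda: _load_cohort(config, "expr_met"))
    after_met = _stage(
        "specificity_types_met",
        lambda: co.specificity_filter_types(
            after_tumors,
            met,
            target_type=config.target_type,
            fpkm_thr=config.fpkm_thr_types,
            max_other_types=config.max_other_types,
            type_stat=config.type_stat,  # type: ignore[arg-type]
        ),
    )
    report.add_stage("specificity_types_met", len(after_tumors), after_met)

    normals = _stage("load_normals", lambda: _load_cohort(config, "expr_normals"))
    screened, tissue_report = _stage(
        "tissue_screen",
        lambda: co.tissue_screen(
            after_met,
            normals,
            fpkm_thr=config.tissue_fpkm_thr,
            max_tissues=config.max_tissues,
            type_stat=config.type_stat,  # type: ignore[arg-type]
        ),
    )
    report.tissue_report = tissue_report
    final = screened if config.apply_tissue_filter else after_met
    report.add_stage("tissue_screen", len(after_met), screened)
    report.final = final

    if write:
        report.write(config.outdir)
    return report


@dataclass
class StratificationReport:
    """Network, per-sample enrichment calls and specificity heatmap."""

    network_stats: dict = field(default_factory=dict)
    calls: pd.DataFrame | None = None
    heatmap: st.SpecificityResult | None = None
    config_hash: str = ""
    seed: int = 0
    timestamp: str = ""

    def write(self, outdir: str | os.PathLike, graph=None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if graph is not None:
            st.write_graphml(graph, out / "network.graphml")
        if self.calls is not None:
            self.calls.to_csv(out / "stratification_calls.tsv", sep="\t")
        if self.heatmap is not None:
            self.heatmap.neglog10p.to_csv(out / "specificity_neglog10p.tsv", sep="\t")
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "network": self.network_stats,
            "n_called": int(self.calls["call"].sum()) if self.calls is not None else 0,
        }
        with open(out / "stratification_report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_signature(config: PipelineConfig) -> co.GeneSet:
    if config.signature_file is None:
        raise ValidationError("stratification needs signature_file (or a GeneSet argument)")
    sig, embedded_hash = co.GeneSet.from_tsv(config.signature_file)
    if embedded_hash is not None and embedded_hash != config.config_hash:
        raise ValidationError(
            f"signature file {config.signature_file!r} was produced under config "
            f"{embedded_hash}, not the current {config.config_hash}; refusing to mix"
        )
    return sig


def run_stratification(
    config: PipelineConfig,
    signature: co.GeneSet | None = None,
    write: bool = True,
) -> StratificationReport:
    """Correlation network + per-sample enrichment + specificity heatmap
    on the metastasis cohort, for a given signature."""
    if signature is None:
        signature = _load_signature(config)
    if len(signature) < 2:
        raise ValidationError("signature must contain >= 2 genes (correlation undefined)")
    met = _load_cohort(config, "expr_met")

    report = StratificationReport(
        config_hash=config.config_hash,
        seed=config.seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    cm = st.correlation_matrix(met, signature)
    graph = st.build_network(cm, met.labels, r_min=config.r_min)
    report.network_stats = st.component_stats(graph, config.target_type)
    logger.info("stage=network %s", report.network_stats)

    report.calls = st.stratify_cohort(
        met,
        signature,
        nes_min=config.nes_min,
        q_max=config.q_max,
        n_perm=config.n_perm,
        seed=config.seed,
        metric=config.metric,  # type: ignore[arg-type]
    )
    logger.info("stage=stratify n_called=%d", int(report.calls["call"].sum()))

    report.heatmap = st.specificity_heatmap(met, config.target_type, signature)

    if write:
        report.write(config.outdir, graph=graph)
    return report
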