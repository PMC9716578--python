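"""Seeded synthetic multi-cohort generator with planted fusion-target structure.

The generator emulates the data landscape the discovery cascade operates on:
paired shControl/shFusion knockdown FPKM matrices for a few EwS cell lines,
a typed pan-cancer cell-line cohort (CCLE-like), a typed primary-tumor
cohort (TCGA-like), a metastasis cohort containing a small planted EwS
subset (MET500-like), a typed normal-tissue cohort (GTEx-like), fusion-bound
peak sets sitting on planted GGAA microsatellite runs near the planted
targets' TSSs, and H3K27ac-style coverage tracks that gain signal at those
regions when the fusion is active.

Planted targets behave like oncofusion-dependent, tumor-type-exclusive
genes: expressed log-normally in EwS-labelled samples around a shared
per-gene mean, silenced (0 FPKM) in every non-EwS sample — the targets model
developmentally silent genes awakened only by the fusion — and knocked down
by 2^kd_log2_effect in shFusion samples. Background genes share a
cohort-independent log-normal baseline with per-sample jitter.

Background sequence is rejection-sampled so that no run of >= 3 motif copies
(on either strand) occurs outside the planted repeat regions, making repeat
recovery exact. Every output is a pure function of the config (including its
seed): rerunning with the same config reproduces byte-identical files.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ftio
from .cohorts import ExpressionMatrix
from .errors import GenerationError, ValidationError
from .genomic import CoverageTrack, GenomeAnnotation, PeakSet, reverse_complement

# distinct RNG streams per operation so each op is independently deterministic
_STREAM_PLANTED = 101
_STREAM_GENOME = 102
_STREAM_BASELINE = 103
_STREAM_COHORTS = 104

# isolation pad around planted TSSs: keeps the planted peak outside every
# other gene's +-100 kb window (and vice versa)
_PLANTED_PAD = 110_000
_DECOY_TAIL = 210_000
_PEAK_PAD = 200  # clean background flanking the planted run inside its peak
_TRACK_BASE = 1.0
_TRACK_PEAK = 20.0
_TRACK_FLANK = 2500

EWS_LABEL = "EwS"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study; defaults are the desk-scale design.

    Cohort sizes mirror the shape of the public compendia at desk scale:
    1,000 genes with 30 planted fusion targets, 3 knockdown cell-line pairs,
    60 cell lines over 12 cancer types, 120 typed tumors, 60 metastases of
    which 11 are EwS, and 12 normal tissues. FPKM is simulated directly on
    the log2 scale. All sizes and effect parameters are overridable.
    """

    n_genes: int = 1000
    n_planted_targets: int = 30
    n_kd_cell_lines: int = 3
    n_pancancer_lines: int = 60
    n_cancer_types: int = 12
    n_tumor_samples: int = 120
    n_met_samples: int = 60
    n_met_ews: int = 11
    n_normal_tissues: int = 12
    n_normal_samples_per_tissue: int = 5
    baseline_log2fpkm_mean: float = 3.0
    baseline_log2fpkm_sd: float = 0.8
    planted_log2fpkm_mean: float = 5.0
    planted_log2fpkm_sd: float = 1.0
    kd_log2_effect: float = 4.0
    noise_sd: float = 0.4
    genome_len_per_gene: int = 2000
    planted_repeat_len: int = 9
    peak_window_offset_bp: int = 6700
    genes_per_chrom: int = 50
    n_decoy_peaks: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_planted_targets": self.n_planted_targets,
            "n_kd_cell_lines": self.n_kd_cell_lines,
            "n_pancancer_lines": self.n_pancancer_lines,
            "n_cancer_types": self.n_cancer_types,
            "n_tumor_samples": self.n_tumor_samples,
            "n_met_samples": self.n_met_samples,
            "n_met_ews": self.n_met_ews,
            "n_normal_tissues": self.n_normal_tissues,
            "n_normal_samples_per_tissue": self.n_normal_samples_per_tissue,
            "genome_len_per_gene": self.genome_len_per_gene,
            "genes_per_chrom": self.genes_per_chrom,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        if self.n_planted_targets >= self.n_genes:
            raise ValidationError("n_planted_targets must be < n_genes")
        if self.n_met_ews >= self.n_met_samples:
            raise ValidationError("n_met_ews must be < n_met_samples")
        if self.kd_log2_effect < 1:
            raise ValidationError(
                f"kd_log2_effect must be >= 1 (so planted targets clear the "
                f">=2-fold filter), got {self.kd_log2_effect}"
            )
        if self.planted_repeat_len < 5:
            raise ValidationError("planted_repeat_len must be >= 5")
        if not 0 < self.peak_window_offset_bp < 100_000:
            raise ValidationError("peak_window_offset_bp must lie in (0, 100000)")
        if self.n_cancer_types < 2:
            raise ValidationError("need >= 2 cancer types")
        if self.noise_sd < 0 or self.baseline_log2fpkm_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """The planted structure the recovery tests check against."""

    planted_target_genes: tuple[str, ...] = ()
    planted_peak_regions: list[dict] = field(default_factory=list)
    planted_repeat_counts: dict[str, int] = field(default_factory=dict)
    decoy_peak_regions: list[dict] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = asdict(self)
        payload["planted_target_genes"] = list(self.planted_target_genes)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_target_genes"] = tuple(payload["planted_target_genes"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# shared deterministic draws


def gene_ids(config: SynthConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def planted_gene_indices(config: SynthConfig) -> np.ndarray:
    """The planted-target gene indices; a pure function of the config."""
    rng = np.random.default_rng([config.seed, _STREAM_PLANTED])
    idx = rng.choice(config.n_genes, size=config.n_planted_targets, replace=False)
    return np.sort(idx)


def _cancer_type_labels(config: SynthConfig) -> list[str]:
    return [EWS_LABEL] + [f"Cancer{i:02d}" for i in range(1, config.n_cancer_types)]


def _tissue_labels(config: SynthConfig) -> list[str]:
    return [f"Tissue{i:02d}" for i in range(1, config.n_normal_tissues + 1)]


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=n)].copy()


def _scrub_motif_runs(
    arr: np.ndarray, motif: str, rng: np.random.Generator, chrom: str, max_rounds: int = 25
) -> None:
    """Mutate bases until no run of >= 3 tandem motif copies (either strand)
    remains; bounded retries, else a generation error naming the chromosome."""
    patterns = [
        re.compile(b"(?:%s){3,}" % motif.encode("ascii")),
        re.compile(b"(?:%s){3,}" % reverse_complement(motif).encode("ascii")),
    ]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(max_rounds):
        data = arr.tobytes()
        hits = [m for pat in patterns for m in pat.finditer(data)]
        if not hits:
            return
        for m in hits:
            pos = m.start() + len(motif) // 2
            current = arr[pos]
            choices = alphabet[alphabet != current]
            arr[pos] = rng.choice(choices)
    raise GenerationError(
        f"rejection sampling failed to clear motif runs on chromosome {chrom!r}"
    )


def make_genome(
    config: SynthConfig, motif: str = "GGAA"
) -> tuple[dict[str, str], GenomeAnnotation, GroundTruth]:
    """Generate the genome FASTA, TSS annotation and planted-structure truth.

    Genes are laid out ~genes_per_chrom per chromosome. Background genes
    occupy ``genome_len_per_gene`` bp slots; planted targets get wide
    isolation pads so their peak is within +-100 kb of exactly one TSS. Each
    planted target carries a run of ``planted_repeat_len`` exact motif
    copies ``peak_window_offset_bp`` upstream of its TSS (strand-aware),
    held by a peak region padded with clean background. A gene-desert tail
    on the first ``n_decoy_peaks`` chromosomes hosts decoy peaks > 100 kb
    from every TSS.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    ids = gene_ids(config)
    planted = set(planted_gene_indices(config).tolist())
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    run_bp = config.planted_repeat_len * len(motif)
    records = []  # gene layout
    genes_on: dict[str, list[dict]] = {}
    chrom_lens: dict[str, int] = {}
    n_chroms = -(-config.n_genes // config.genes_per_chrom)
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 0
        entries = []
        for gi in range(
            c * config.genes_per_chrom, min((c + 1) * config.genes_per_chrom, config.n_genes)
        ):
            if gi in planted:
                tss = cursor + _PLANTED_PAD
                cursor = tss + _PLANTED_PAD
            else:
                tss = cursor + config.genome_len_per_gene // 2
                cursor += config.genome_len_per_gene
            entries.append({"gene_id": ids[gi], "tss": tss, "strand": strands[gi], "idx": gi})
            records.append(
                {"gene_id": ids[gi], "chrom": chrom, "tss": tss, "strand": strands[gi]}
            )
        genes_on[chrom] = entries
        chrom_lens[chrom] = cursor + (_DECOY_TAIL if c < config.n_decoy_peaks else 0)

    truth = GroundTruth(planted_target_genes=tuple(ids[i] for i in sorted(planted)))
    sequences: dict[str, str] = {}
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        length = chrom_lens[chrom]
        arr = _random_bases(rng, length)
        _scrub_motif_runs(arr, motif, rng, chrom)
        for entry in genes_on[chrom]:
            if entry["idx"] not in planted:
                continue
            tss = entry["tss"]
            if entry["strand"] == "+":
                run_start = tss - config.peak_window_offset_bp - run_bp
            else:
                run_start = tss + config.peak_window_offset_bp
            run_end = run_start + run_bp
            arr[run_start:run_end] = np.frombuffer(
                (motif * config.planted_repeat_len).encode("ascii"), dtype=np.uint8
            )
            # block accidental extension of the planted run at either edge
            flank = np.frombuffer(b"CTAG", dtype=np.uint8)
            arr[run_start - 4 : run_start] = flank
            arr[run_end : run_end + 4] = flank
            peak_name = f"peak_{entry['gene_id']}"
            region = {
                "chrom": chrom,
                "start": int(run_start - _PEAK_PAD),
                "end": int(run_end + _PEAK_PAD),
                "name": peak_name,
            }
            truth.planted_peak_regions.append(region)
            truth.planted_repeat_counts[peak_name] = config.planted_repeat_len
        if c < config.n_decoy_peaks:
            decoy_start = length - 60_000
            truth.decoy_peak_regions.append(
                {
                    "chrom": chrom,
                    "start": int(decoy_start),
                    "end": int(decoy_start + 400),
                    "name": f"decoy_{chrom}",
                }
            )
        sequences[chrom] = arr.tobytes().decode("ascii")
        truth.chrom_lengths[chrom] = length

    annotation = GenomeAnnotation(table=pd.DataFrame(records))
    return sequences, annotation, truth


# ---------------------------------------------------------------------------
# cohorts


def _cohort_matrix(
    config: SynthConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    types: list[str],
    cohort_name: str,
    baseline: np.ndarray,
    planted_means: np.ndarray,
    planted_idx: np.ndarray,
    kd_samples: set[str] | None = None,
) -> ExpressionMatrix:
    ids = gene_ids(config)
    n_g, n_s = config.n_genes, len(sample_ids)
    log2 = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    values = np.power(2.0, log2)
    is_ews = np.array([t == EWS_LABEL for t in types])
    planted_noise = rng.normal(0.0, config.noise_sd, size=(len(planted_idx), n_s))
    planted_log2 = planted_means[:, None] + planted_noise
    if kd_samples:
        kd_mask = np.array([s in kd_samples for s in sample_ids])
        planted_log2[:, kd_mask] -= config.kd_log2_effect
    planted_vals = np.power(2.0, planted_log2)
    planted_vals[:, ~is_ews] = 0.0  # silent outside EwS
    values[planted_idx, :] = planted_vals
    df = pd.DataFrame(values, index=ids, columns=sample_ids)
    labels = pd.DataFrame(
        {"cohort": cohort_name, "type_label": types}, index=pd.Index(sample_ids, name="sample_id")
    )
    return ExpressionMatrix(values=df, labels=labels)


def make_cohorts(config: SynthConfig) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Generate the five expression cohorts plus the planted-gene truth.

    Cohorts: ``kd`` (paired shControl/shFusion per EwS cell line), ``lines``
    (typed pan-cancer cell lines incl. EwS lines), ``tumors`` (typed
    pan-cancer primaries, no EwS), ``met`` (metastases with ``n_met_ews``
    EwS samples), ``normals`` (typed normal tissues).
    """
    ids = gene_ids(config)
    planted_idx = planted_gene_indices(config)
    base_rng = np.random.default_rng([config.seed, _STREAM_BASELINE])
    baseline = base_rng.normal(
        config.baseline_log2fpkm_mean, config.baseline_log2fpkm_sd, size=config.n_genes
    )
    planted_means = base_rng.normal(
        config.planted_log2fpkm_mean, config.planted_log2fpkm_sd, size=len(planted_idx)
    )
    rng = np.random.default_rng([config.seed, _STREAM_COHORTS])
    cohorts: dict[str, ExpressionMatrix] = {}

    # knockdown pairs: EwS cell lines, shControl vs shFusion
    kd_samples, kd_types = [], []
    for i in range(1, config.n_kd_cell_lines + 1):
        kd_samples += [f"CL{i}_shControl", f"CL{i}_shFusion"]
        kd_types += [EWS_LABEL, EWS_LABEL]
    cohorts["kd"] = _cohort_matrix(
        config, rng, kd_samples, kd_types, "kd", baseline, planted_means, planted_idx,
        kd_samples={s for s in kd_samples if s.endswith("_shFusion")},
    )

    cancer_types = _cancer_type_labels(config)
    line_types = [cancer_types[i % len(cancer_types)] for i in range(config.n_pancancer_lines)]
    line_ids = [f"LINE_{t}_{i:03d}" for i, t in enumerate(line_types)]
    cohorts["lines"] = _cohort_matrix(
        config, rng, line_ids, line_types, "lines", baseline, planted_means, planted_idx
    )

    non_ews = cancer_types[1:]
    tumor_types = [non_ews[i % len(non_ews)] for i in range(config.n_tumor_samples)]
    tumor_ids = [f"TUM_{t}_{i:03d}" for i, t in enumerate(tumor_types)]
    cohorts["tumors"] = _cohort_matrix(
        config, rng, tumor_ids, tumor_types, "tumors", baseline, planted_means, planted_idx
    )

    n_other = config.n_met_samples - config.n_met_ews
    met_types = [EWS_LABEL] * config.n_met_ews + [
        non_ews[i % len(non_ews)] for i in range(n_other)
    ]
    met_ids = [f"MET_{i:03d}_{t}" for i, t in enumerate(met_types)]
    cohorts["met"] = _cohort_matrix(
        config, rng, met_ids, met_types, "met", baseline, planted_means, planted_idx
    )

    tissues = _tissue_labels(config)
    norm_types = [t for t in tissues for _ in range(config.n_normal_samples_per_tissue)]
    norm_ids = [f"NORM_{t}_{i:03d}" for i, t in enumerate(norm_types)]
    cohorts["normals"] = _cohort_matrix(
        config, rng, norm_ids, norm_types, "normals", baseline, planted_means, planted_idx
    )

    truth = GroundTruth(planted_target_genes=tuple(ids[i] for i in planted_idx))
    return cohorts, truth


def kd_pairs(config: SynthConfig) -> list[tuple[str, str]]:
    """The (shControl, shFusion) sample pairs of the ``kd`` cohort."""
    return [
        (f"CL{i}_shControl", f"CL{i}_shFusion") for i in range(1, config.n_kd_cell_lines + 1)
    ]


# ---------------------------------------------------------------------------
# peaks and coverage tracks


def make_peaks_and_tracks(
    config: SynthConfig, annotation: GenomeAnnotation, truth: GroundTruth
) -> tuple[dict[str, PeakSet], dict[str, CoverageTrack]]:
    """Fusion-on/off peak sets and H3K27ac-like coverage tracks.

    ``fusion_on`` contains one peak per planted repeat region plus decoy
    peaks far (> 100 kb) from any TSS; ``fusion_off`` keeps only the decoys.
    Coverage is a flat background with elevated signal in +-2.5 kb of the
    planted regions under ``fusion_on``; library size is the track's total
    signal, recorded for rpm normalization.
    """
    planted_df = pd.DataFrame(truth.planted_peak_regions, columns=["chrom", "start", "end", "name"])
    decoy_df = pd.DataFrame(truth.decoy_peak_regions, columns=["chrom", "start", "end", "name"])
    on = PeakSet(
        intervals=pd.concat([planted_df, decoy_df], ignore_index=True),
        source_condition="fusion_on",
    )
    off = PeakSet(intervals=decoy_df.copy(), source_condition="fusion_off")

    def _flat_track() -> list[dict]:
        return [
            {"chrom": chrom, "start": 0, "end": length, "value": _TRACK_BASE}
            for chrom, length in truth.chrom_lengths.items()
        ]

    on_rows: list[dict] = []
    elevated = planted_df.sort_values(["chrom", "start"])
    for chrom, length in truth.chrom_lengths.items():
        cursor = 0
        for rec in elevated[elevated["chrom"] == chrom].itertuples(index=False):
            lo = max(0, rec.start - _TRACK_FLANK)
            hi = min(length, rec.end + _TRACK_FLANK)
            if lo > cursor:
                on_rows.append({"chrom": chrom, "start": cursor, "end": lo, "value": _TRACK_BASE})
            on_rows.append({"chrom": chrom, "start": lo, "end": hi, "value": _TRACK_PEAK})
            cursor = hi
        if cursor < length:
            on_rows.append({"chrom": chrom, "start": cursor, "end": length, "value": _TRACK_BASE})

    tracks = {
        "fusion_on": CoverageTrack(table=pd.DataFrame(on_rows)),
        "fusion_off": CoverageTrack(table=pd.DataFrame(_flat_track())),
    }
    return {"fusion_on": on, "fusion_off": off}, tracks


# ---------------------------------------------------------------------------
# one-call generation and serialisation


@dataclass
class SynthDataset:
    """Everything one synthetic study comprises, plus its ground truth."""

    config: SynthConfig
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    truth: GroundTruth
    cohorts: dict[str, ExpressionMatrix]
    peaks: dict[str, PeakSet]
    tracks: dict[str, CoverageTrack]

    def write(self, outdir: str | os.PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ftio.write_fasta(self.sequences, out / "genome.fa")
        self.annotation.to_tsv(out / "annotation.tsv")
        self.truth.to_json(out / "ground_truth.json")
        label_frames = []
        for name, expr in self.cohorts.items():
            expr.to_tsv(out / f"expr_{name}.tsv")
            lab = expr.labels.loc[expr.sample_ids].copy()
            label_frames.append(lab)
        labels = pd.concat(label_frames)
        labels.index.name = "sample_id"
        labels.to_csv(out / "labels.tsv", sep="\t")
        for cond, ps in self.peaks.items():
            ps.to_bed(out / f"peaks_{cond}.bed")
        for cond, tr in self.tracks.items():
            tr.to_bedgraph(out / f"track_{cond}.bedgraph")


def generate(config: SynthConfig | None = None) -> SynthDataset:
    """Run all three generator operations for one config."""
    config = config or SynthConfig()
    sequences, annotation, truth_genome = make_genome(config)
    cohorts, truth_cohorts = make_cohorts(config)
    truth = GroundTruth(
        planted_target_genes=truth_cohorts.planted_target_genes,
        planted_peak_regions=truth_genome.planted_peak_regions,
        planted_repeat_counts=truth_genome.planted_repeat_counts,
        decoy_peak_regions=truth_genome.decoy_peak_regions,
        chrom_lengths=truth_genome.chrom_lengths,
    )
    peaks, tracks = make_peaks_and_tracks(config, annotation, truth)
    return SynthDataset(
        config=config,
        sequences=sequences,
        annotation=annotation,
        truth=truth,
        cohorts=cohorts,
        peaks=peaks,
        tracks=tracks,
    )
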