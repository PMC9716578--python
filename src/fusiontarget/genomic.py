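"""Interval arithmetic, peak-to-TSS assignment, microsatellite scanning and
tag-density profiles.

Coordinate conventions: all intervals are 0-based half-open. Two intervals
overlap when they share at least one base. The TSS window for direct-target
calling is realised as ``[tss - w, tss + w + 1)`` so that a peak touching
exactly +-w bp from the TSS still counts as "within" the window.

The microsatellite scanner counts exact, uninterrupted tandem copies of a
motif (default GGAA); partial or mismatched copies never extend a run, and
``N`` never matches. Oncofusion binding to the microsatellite is
strand-agnostic, so by default the reverse complement is scanned too and the
larger run is reported (ties resolved to ``+``).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as ftio
from .cohorts import GeneSet
from .errors import MalformedIntervalError, ValidationError

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenomeAnnotation:
    """One TSS record per gene: gene_id, chrom, tss (0-based), strand."""

    table: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        req = ["gene_id", "chrom", "tss", "strand"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation lacks columns {missing}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene record {dup!r}")
        if (self.table["tss"] < 0).any():
            bad = self.table.loc[self.table["tss"] < 0, "gene_id"].iloc[0]
            raise ValidationError(f"negative TSS for gene {bad!r}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GenomeAnnotation":
        df = ftio.read_annotation(path).rename(columns={"tss_0based": "tss"})
        return cls(table=df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        ftio.write_annotation(self.table.rename(columns={"tss": "tss_0based"}), path)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass
class PeakSet:
    """Genomic intervals (possibly overlapping) from one ChIP condition."""

    intervals: pd.DataFrame  # columns: chrom, start, end, name
    source_condition: str = ""

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end", "name"]
        missing = [c for c in req if c not in self.intervals.columns]
        if missing:
            raise ValidationError(f"peak table lacks columns {missing}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            name = self.intervals.loc[bad, "name"].iloc[0]
            raise MalformedIntervalError(f"peak {name!r} has start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path: str | os.PathLike, source_condition: str = "") -> "PeakSet":
        df = ftio.read_bed(path)[["chrom", "start", "end", "name"]]
        return cls(intervals=df, source_condition=source_condition)

    def to_bed(self, path: str | os.PathLike) -> None:
        ftio.write_bed(self.intervals, path)


@dataclass
class RepeatAnnotation:
    """Per-region maximal tandem-repeat runs and the summary fraction.

    ``fraction_ge_threshold`` is the fraction of regions whose maximal run
    reaches ``min_repeats`` motif copies.
    """

    table: pd.DataFrame  # index: region name; columns: max_run, strand_of_max
    motif: str
    min_repeats: int

    def fraction_ge(self, k: int) -> float:
        if len(self.table) == 0:
            return 0.0
        return float((self.table["max_run"] >= k).mean())

    @property
    def fraction_ge_threshold(self) -> float:
        return self.fraction_ge(self.min_repeats)

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out.index.name = "region"
        out.to_csv(path, sep="\t")


@dataclass
class CoverageTrack:
    """Step-function per-base coverage with its library size (total tags).

    ``table`` holds sorted, non-overlapping (chrom, start, end, value) rows;
    ``value`` is raw tag count per bp. ``library_size`` defaults to the
    track's own total signal; pre-normalized tracks may declare 1e6.
    """

    table: pd.DataFrame
    library_size: float | None = None

    def __post_init__(self) -> None:
        if (self.table["value"] < 0).any():
            raise ValidationError("coverage values must be >= 0")
        if self.library_size is None:
            spans = self.table["end"] - self.table["start"]
            self.library_size = float((self.table["value"] * spans).sum())

    @classmethod
    def from_bedgraph(
        cls, path: str | os.PathLike, library_size: float | None = None
    ) -> "CoverageTrack":
        return cls(table=ftio.read_bedgraph(path), library_size=library_size)

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        ftio.write_bedgraph(self.table, path)


@dataclass
class DensityProfile:
    """Total rpm per region (+- flank), with per-condition aggregation."""

    table: pd.DataFrame  # index region name; columns raw, rpm
    condition: str = ""
    flank_bp: int = 0

    def mean_rpm(self) -> float:
        return float(self.table["rpm"].mean())

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out.index.name = "region"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# interval operations


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """True iff the two 0-based half-open intervals share >= 1 base.

    Intervals on different chromosomes never overlap. A single shared base
    counts; abutting half-open intervals ([100,200) vs [200,300)) do not.
    """
    for iv in (a, b):
        if iv[1] >= iv[2]:
            raise MalformedIntervalError(f"malformed interval {iv}")
    if a[0] != b[0]:
        return False
    return min(a[2], b[2]) - max(a[1], b[1]) >= 1


def assign_peaks_to_tss(
    peaks: PeakSet, ann: GenomeAnnotation, window_bp: int = 100_000
) -> dict[str, list[str]]:
    """Map each gene to the peaks overlapping its +-window_bp TSS window.

    A peak may be assigned to several genes; gene strand is ignored (the
    window is undirected). Genes on chromosomes absent from the peak set get
    an empty list (logged once).
    """
    if window_bp <= 0:
        raise ValidationError(f"window_bp must be > 0, got {window_bp}")
    assignment: dict[str, list[str]] = {g: [] for g in ann.gene_ids}
    peak_chroms = peaks.intervals.groupby("chrom", sort=False)
    missing_chroms = set()
    for chrom, genes in ann.table.groupby("chrom", sort=False):
        if chrom not in peak_chroms.groups:
            missing_chroms.add(str(chrom))
            continue
        sub = peak_chroms.get_group(chrom)
        p_start = sub["start"].to_numpy()
        p_end = sub["end"].to_numpy()
        p_name = sub["name"].to_numpy()
        tss = genes["tss"].to_numpy()
        win_start = tss - window_bp
        win_end = tss + window_bp + 1  # inclusive +-window_bp
        # overlap >= 1bp: peak.start < win_end and peak.end > win_start
        hits = (p_start[None, :] < win_end[:, None]) & (p_end[None, :] > win_start[:, None])
        for row, gene in enumerate(genes["gene_id"]):
            assignment[gene] = sorted(p_name[hits[row]])
    if missing_chroms:
        logger.warning(
            "no peaks on chromosome(s) %s; their genes receive no assignment",
            ",".join(sorted(missing_chroms)),
        )
    return assignment


def direct_targets(candidates: GeneSet, assignment: Mapping[str, list[str]]) -> GeneSet:
    """Candidates with at least one assigned fusion peak near their TSS."""
    kept = [g for g in candidates.genes if assignment.get(g)]
    return candidates.with_genes(kept, "direct_targets")


# ---------------------------------------------------------------------------
# microsatellite scanning


def _max_run_forward(seq: str, motif: str) -> int:
    """Longest count of exact tandem copies of motif in seq (one strand)."""
    n, m = len(seq), len(motif)
    if n < m:
        return 0
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mot = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    occ = np.ones(n - m + 1, dtype=bool)
    for k in range(m):
        occ &= a[k : n - m + 1 + k] == mot[k]
    if not occ.any():
        return 0
    # dynamic program per phase class: run ending at i extends run at i - m
    runs = occ.astype(np.int64)
    for i in range(m, n - m + 1):
        if occ[i]:
            runs[i] = runs[i - m] + 1
    return int(runs.max())


def max_tandem_repeat(
    seq: str, motif: str = "GGAA", both_strands: bool = True
) -> tuple[int, str]:
    """Maximal run of exact, uninterrupted tandem motif copies in ``seq``.

    Returns ``(max_run, strand)``. With ``both_strands`` the reverse
    complement is scanned as well and the larger run wins; ties go to ``+``.
    The empty sequence yields ``(0, '+')``.
    """
    if not motif:
        raise ValidationError("motif must be non-empty")
    seq = seq.upper()
    fwd = _max_run_forward(seq, motif.upper())
    if not both_strands:
        return fwd, "+"
    rev = _max_run_forward(reverse_complement(seq), motif.upper())
    if rev > fwd:
        return rev, "-"
    return fwd, "+"


def annotate_repeats(
    peaks: PeakSet,
    genome: Mapping[str, str],
    motif: str = "GGAA",
    min_repeats: int = 5,
    flank_bp: int = 0,
) -> RepeatAnnotation:
    """Scan each peak's sequence (optionally +- flank) for tandem motif runs."""
    rows = []
    for rec in peaks.intervals.itertuples(index=False):
        if rec.chrom not in genome:
            raise ValidationError(f"peak {rec.name!r}: unknown chromosome {rec.chrom!r}")
        chrom_seq = genome[rec.chrom]
        if rec.end > len(chrom_seq):
            raise ValidationError(
                f"peak {rec.name!r} exceeds chromosome {rec.chrom!r} length"
            )
        start = max(0, rec.start - flank_bp)
        end = min(len(chrom_seq), rec.end + flank_bp)
        run, strand = max_tandem_repeat(chrom_seq[start:end], motif=motif)
        rows.append({"region": rec.name, "max_run": run, "strand_of_max": strand})
    table = pd.DataFrame(rows, columns=["region", "max_run", "strand_of_max"])
    table = table.set_index("region")
    return RepeatAnnotation(table=table, motif=motif, min_repeats=min_repeats)


# ---------------------------------------------------------------------------
# tag density


def tag_density(
    track: CoverageTrack, regions: PeakSet, flank_bp: int = 2500
) -> DensityProfile:
    """Total library-normalized tag density (rpm) per region +- flank.

    rpm = (raw coverage sum over [start - flank, end + flank)) /
    library_size * 1e6. Windows are clipped at position 0; coverage outside
    the track's intervals is zero by definition.
    """
    if not track.library_size or track.library_size <= 0:
        raise ValidationError("coverage track has zero library size")
    by_chrom = {
        str(chrom): (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(float),
        )
        for chrom, sub in track.table.groupby("chrom", sort=False)
    }
    rows = []
    for rec in regions.intervals.itertuples(index=False):
        w_start = max(0, rec.start - flank_bp)
        w_end = rec.end + flank_bp
        raw = 0.0
        if rec.chrom in by_chrom:
            s, e, v = by_chrom[rec.chrom]
            ov = np.minimum(e, w_end) - np.maximum(s, w_start)
            np.clip(ov, 0, None, out=ov)
            raw = float((ov * v).sum())
        rows.append({"region": rec.name, "raw": raw, "rpm": raw / track.library_size * 1e6})
    table = pd.DataFrame(rows, columns=["region", "raw", "rpm"]).set_index("region")
    return DensityProfile(table=table, condition=regions.source_condition, flank_bp=flank_bp)
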