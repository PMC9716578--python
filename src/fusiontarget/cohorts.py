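"""Expression cohorts and the expression-based filter cascade.

The discovery pipeline narrows a candidate gene list through a sequence of
FPKM filters: genes consistently regulated by knockdown of the oncofusion,
genes silent (<= 1 FPKM) in every non-target cancer cell line, genes
expressed in at most one tumor type across pan-cancer cohorts, and finally a
normal-tissue screen. Each filter is a pure function
``GeneSet -> GeneSet`` over an :class:`ExpressionMatrix`; provenance of
applied filters is threaded through the :class:`GeneSet`.

Threshold semantics follow the conventions of the underlying study design:
expression gates are strict (``> 1 FPKM``), fold-change gates are inclusive
(``>= 2-fold``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

TypeStat = Literal["median", "mean", "any-sample"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """A genes x samples FPKM matrix with per-sample cohort/type labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample; entries are
        non-negative FPKM.
    labels
        DataFrame indexed by sample id with columns ``cohort`` and
        ``type_label``. Every sample in ``values`` must be labelled.
    """

    values: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).rename("gene_id")
        self.values.columns = self.values.columns.astype(str).rename(None)
        self.labels.index = self.labels.index.astype(str).rename("sample_id")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        missing = self.values.columns.difference(self.labels.index)
        if len(missing):
            raise ValidationError(f"sample {missing[0]!r} has no label")
        for col in ("cohort", "type_label"):
            if col not in self.labels.columns:
                raise ValidationError(f"labels table lacks column {col!r}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            gi, si = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"NaN FPKM at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def type_of(self, sample_id: str) -> str:
        return str(self.labels.loc[sample_id, "type_label"])

    def samples_of_type(self, type_label: str) -> list[str]:
        mask = self.labels["type_label"] == type_label
        keep = self.labels.index[mask]
        return [s for s in self.values.columns if s in set(keep)]

    def to_tsv(self, path: str | os.PathLike, labels_path: str | os.PathLike | None = None) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if labels_path is not None:
            lab = self.labels.loc[self.values.columns].copy()
            lab.index.name = "sample_id"
            lab.to_csv(labels_path, sep="\t")


def load_expression(path: str | os.PathLike, labels_path: str | os.PathLike) -> ExpressionMatrix:
    """Load an FPKM TSV (first column gene_id) plus its sample label table."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels.index = labels.index.astype(str)
    try:
        return ExpressionMatrix(values=values, labels=labels)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class GeneSet:
    """An ordered, de-duplicated gene list with filter provenance."""

    genes: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    @classmethod
    def from_iterable(cls, genes: Iterable[str], provenance: Sequence[str] = ()) -> "GeneSet":
        return cls(genes=tuple(sorted(set(map(str, genes)))), provenance=tuple(provenance))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def with_genes(self, genes: Iterable[str], step: str) -> "GeneSet":
        kept = set(genes)
        return GeneSet(
            genes=tuple(g for g in self.genes if g in kept),
            provenance=self.provenance + (step,),
        )

    def to_tsv(self, path: str | os.PathLike, config_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            fh.write("gene_id\tprovenance\n")
            prov = "|".join(self.provenance)
            for g in self.genes:
                fh.write(f"{g}\t{prov}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> tuple["GeneSet", str | None]:
        """Read a gene list TSV; returns the set and any embedded config hash."""
        config_hash = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# config_hash="):
                config_hash = first.strip().split("=", 1)[1]
                header = fh.readline()
            else:
                header = first
            cols = header.rstrip("\n").split("\t")
            genes = []
            prov: tuple[str, ...] = ()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genes.append(parts[0])
                if len(cols) > 1 and len(parts) > 1 and parts[1]:
                    prov = tuple(parts[1].split("|"))
        return cls(genes=tuple(genes), provenance=prov), config_hash


# ---------------------------------------------------------------------------
# filters


def _require_samples(expr: ExpressionMatrix, samples: Iterable[str]) -> None:
    known = set(expr.sample_ids)
    for s in samples:
        if s not in known:
            raise ValidationError(f"unknown sample id {s!r}")


def common_regulated(
    kd: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    direction: Literal["down", "up"] = "down",
    min_expr: float = 1.0,
    min_fold: float = 2.0,
    pseudocount: float = 0.01,
) -> GeneSet:
    """Genes consistently regulated by knockdown in every control/KD pair.

    For ``direction="down"`` a gene qualifies in a pair when control
    FPKM > ``min_expr`` and ``(ctrl + eps) / (kd + eps) >= min_fold``; the
    result is the intersection over all pairs ("commonly" regulated).
    ``direction="up"`` mirrors this with the KD sample as the expressed side.
    """
    if not pairs:
        raise ValidationError("need at least one (control, knockdown) pair")
    if min_fold < 1:
        raise ValidationError(f"min_fold must be >= 1, got {min_fold}")
    if direction not in ("down", "up"):
        raise ValidationError(f"direction must be 'down' or 'up', got {direction!r}")
    _require_samples(kd, [s for pair in pairs for s in pair])

    eps = float(pseudocount)
    keep = np.ones(len(kd.gene_ids), dtype=bool)
    for ctrl, kdn in pairs:
        c = kd.values[ctrl].to_numpy(float)
        k = kd.values[kdn].to_numpy(float)
        if direction == "down":
            keep &= (c > min_expr) & ((c + eps) / (k + eps) >= min_fold)
        else:
            keep &= (k > min_expr) & ((k + eps) / (c + eps) >= min_fold)
    genes = kd.gene_ids[keep]
    return GeneSet.from_iterable(genes, provenance=(f"common_{direction}regulated",))


def fold_change_table(
    kd: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-pair log2((ctrl+eps)/(kd+eps)) and control FPKM, for reporting."""
    _require_samples(kd, [s for pair in pairs for s in pair])
    eps = float(pseudocount)
    out = {}
    for ctrl, kdn in pairs:
        c = kd.values[ctrl].to_numpy(float)
        k = kd.values[kdn].to_numpy(float)
        out[f"log2fc_{ctrl}_vs_{kdn}"] = np.log2((c + eps) / (k + eps))
        out[f"ctrl_fpkm_{ctrl}"] = c
    return pd.DataFrame(out, index=kd.gene_ids)


def specificity_filter_lines(
    candidates: GeneSet,
    lines: ExpressionMatrix,
    target_type: str,
    max_fpkm: float = 1.0,
) -> GeneSet:
    """Drop genes expressed above ``max_fpkm`` in ANY non-target cell line."""
    if target_type not in set(lines.labels["type_label"]):
        raise ValidationError(f"target type {target_type!r} absent from labels")
    non_target = [s for s in lines.sample_ids if lines.type_of(s) != target_type]
    present = [g for g in candidates.genes if g in lines.gene_ids]
    if non_target and present:
        sub = lines.values.loc[present, non_target]
        ok = sub.max(axis=1) <= max_fpkm  # strict > max_fpkm removes
        kept = set(sub.index[ok])
    else:
        kept = set(present)
    # genes absent from the matrix cannot be shown expressed anywhere: keep
    kept |= set(candidates.genes) - set(present)
    return candidates.with_genes(kept, "specificity_lines")


def _type_expression(
    cohort: ExpressionMatrix, genes: Sequence[str], fpkm_thr: float, type_stat: TypeStat
) -> pd.DataFrame:
    """Boolean genes x types table: does the type 'express' the gene."""
    if type_stat not in ("median", "mean", "any-sample"):
        raise ValidationError(f"unknown type_stat {type_stat!r}")
    types = sorted(set(cohort.labels.loc[cohort.sample_ids, "type_label"]))
    cols = {}
    for t in types:
        sub = cohort.values.loc[list(genes), cohort.samples_of_type(t)]
        if type_stat == "median":
            stat = sub.median(axis=1)
        elif type_stat == "mean":
            stat = sub.mean(axis=1)
        else:
            stat = sub.max(axis=1)
        cols[t] = stat > fpkm_thr
    return pd.DataFrame(cols, index=list(genes))


def specificity_filter_types(
    candidates: GeneSet,
    cohort: ExpressionMatrix,
    target_type: str | None = None,
    fpkm_thr: float = 1.0,
    max_other_types: int = 1,
    type_stat: TypeStat = "median",
) -> GeneSet:
    """Drop genes expressed (per ``type_stat``) in more than ``max_other_types``
    tumor types, counting all types including the target's own."""
    if cohort.labels.loc[cohort.sample_ids, "type_label"].nunique() < 2:
        raise ValidationError("type-specificity filter needs >= 2 type labels")
    present = [g for g in candidates.genes if g in cohort.gene_ids]
    expressed = _type_expression(cohort, present, fpkm_thr, type_stat)
    n_types = expressed.sum(axis=1)
    kept = set(n_types.index[n_types <= max_other_types])
    kept |= set(candidates.genes) - set(present)
    return candidates.with_genes(kept, "specificity_types")


def tissue_screen(
    candidates: GeneSet,
    normals: ExpressionMatrix,
    fpkm_thr: float = 1.0,
    max_tissues: int = 1,
    type_stat: TypeStat = "median",
) -> tuple[GeneSet, pd.DataFrame]:
    """Annotate candidates by the normal tissues expressing them.

    Returns the genes expressed in at most ``max_tissues`` tissues (the
    screened set) together with a per-gene report naming each expressing
    tissue; no gene is dropped silently — the report covers every candidate.
    """
    present = [g for g in candidates.genes if g in normals.gene_ids]
    expressed = _type_expression(normals, present, fpkm_thr, type_stat)
    rows = []
    for g in candidates.genes:
        if g in expressed.index:
            tissues = sorted(expressed.columns[expressed.loc[g]])
        else:
            tissues = []
        rows.append(
            {
                "gene_id": g,
                "n_expressing_tissues": len(tissues),
                "expressing_tissues": ",".join(tissues),
                "flagged": len(tissues) > max_tissues,
            }
        )
    report = pd.DataFrame(
        rows, columns=["gene_id", "n_expressing_tissues", "expressing_tissues", "flagged"]
    ).set_index("gene_id")
    kept = report.index[~report["flagged"]]
    return candidates.with_genes(kept, "tissue_screen"), report
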