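"""Signature-based cohort analysis.

Three analyses hang off a discovered gene signature:

* a sample-sample Pearson correlation network over the signature genes'
  log2(FPKM+1), thresholded at r >= r_min (default 0.5), exported as graphml;
* per-sample gene-set enrichment: each sample's transcriptome is ranked by a
  cross-sample z-score, the weighted Kolmogorov-Smirnov running-sum
  enrichment score (weight p = 1) is computed for the signature, and
  significance is assessed against a gene-set permutation null (random
  same-size gene sets), yielding a normalized enrichment score (NES),
  a permutation p-value and Benjamini-Hochberg q across samples;
* a per-gene specificity heatmap of -log10 p from Welch two-sample t tests
  of the target type against every other type, on log2(FPKM+1).

The gene-set permutation null is a deliberate surrogate for phenotype
permutation, which is undefined for single-sample calls: NES is the observed
ES divided by the mean |null ES| of the same sign, and the permutation p is
(1 + #{same-sign null as or more extreme}) / (1 + #same-sign null).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohorts import ExpressionMatrix, GeneSet
from .errors import ValidationError


def _log2p1(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


# ---------------------------------------------------------------------------
# correlation network


@dataclass
class CorrelationMatrix:
    """Pairwise sample Pearson r over the signature genes' log2(FPKM+1)."""

    r: pd.DataFrame  # samples x samples
    constant_samples: tuple[str, ...] = ()

    @property
    def sample_ids(self) -> pd.Index:
        return self.r.index


def correlation_matrix(expr: ExpressionMatrix, signature: GeneSet | Sequence[str]) -> CorrelationMatrix:
    """Sample-sample Pearson correlation restricted to the signature genes.

    Samples whose signature vector is constant carry no correlation
    information; their rows/columns are set to 0 and they are flagged in
    ``constant_samples`` (the diagonal is 1 only for non-constant samples).
    """
    genes = [g for g in signature if g in expr.gene_ids]
    if len(genes) < 2:
        raise ValidationError(
            f"need >= 2 signature genes present in the matrix, got {len(genes)}"
        )
    if len(expr.sample_ids) < 2:
        raise ValidationError("need >= 2 samples")
    x = _log2p1(expr.values.loc[genes]).to_numpy(float)  # genes x samples
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, np.where(constant, 0.0, 1.0))
    samples = expr.sample_ids
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=samples, columns=samples),
        constant_samples=tuple(samples[constant]),
    )


def build_network(
    cm: CorrelationMatrix,
    labels: pd.DataFrame | Mapping[str, str],
    r_min: float = 0.5,
) -> nx.Graph:
    """Threshold the correlation matrix into a sample graph.

    Every sample becomes a node (isolated nodes are retained) annotated with
    its cohort/type label; edges connect pairs with r >= r_min, weighted by r.
    """
    g = nx.Graph(threshold=float(r_min))
    if isinstance(labels, pd.DataFrame):
        lab = {
            s: (str(labels.loc[s, "cohort"]), str(labels.loc[s, "type_label"]))
            for s in cm.sample_ids
        }
    else:
        lab = {s: ("", str(labels[s])) for s in cm.sample_ids}
    for s in cm.sample_ids:
        cohort, type_label = lab[s]
        g.add_node(s, cohort=cohort, type_label=type_label)
    rmat = cm.r.to_numpy()
    samples = list(cm.sample_ids)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if rmat[i, j] >= r_min:
                g.add_edge(samples[i], samples[j], weight=float(rmat[i, j]))
    return g


def component_stats(g: nx.Graph, target_label: str) -> dict:
    """Connectivity summary of the thresholded network for one type label.

    Reports the largest number of target-labelled samples sharing one
    connected component, the number of target<->non-target edges, and the
    fraction of target pairs joined by a direct edge (clique fraction).
    """
    target_nodes = [n for n, d in g.nodes(data=True) if d.get("type_label") == target_label]
    largest = 0
    for comp in nx.connected_components(g):
        largest = max(largest, len(comp & set(target_nodes)))
    largest = max(largest, 1 if target_nodes else 0)
    cross = sum(
        1
        for u, v in g.edges
        if (g.nodes[u]["type_label"] == target_label)
        != (g.nodes[v]["type_label"] == target_label)
    )
    n_t = len(target_nodes)
    n_pairs = n_t * (n_t - 1) // 2
    direct = sum(
        1
        for i in range(n_t)
        for j in range(i + 1, n_t)
        if g.has_edge(target_nodes[i], target_nodes[j])
    )
    return {
        "n_target_nodes": n_t,
        "largest_target_component": largest,
        "cross_label_edges": cross,
        "target_clique_fraction": direct / n_pairs if n_pairs else 1.0,
    }


def write_graphml(g: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# per-sample ranking and weighted-KS enrichment


def rank_sample(
    expr: ExpressionMatrix,
    sample_id: str,
    metric: Literal["zscore", "log2fpkm"] = "zscore",
) -> pd.Series:
    """Rank one sample's genes for enrichment analysis (descending metric).

    The default metric is the cross-sample z-score of log2(FPKM+1):
    z_gs = (x_gs - mean_g) / sd_g with moments taken across samples, so a
    gene scores highly in the samples where it is unusually expressed.
    Zero-variance genes get z = 0. Ties are broken lexicographically by
    gene id for determinism.
    """
    if sample_id not in expr.sample_ids:
        raise ValidationError(f"unknown sample {sample_id!r}")
    if metric == "zscore":
        if len(expr.sample_ids) < 3:
            raise ValidationError("z-score ranking needs >= 3 samples")
        x = _log2p1(expr.values)
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        z = (x[sample_id] - mu) / sd
        z[sd == 0] = 0.0
        values = z
    elif metric == "log2fpkm":
        values = _log2p1(expr.values)[sample_id]
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    order = pd.DataFrame({"v": values, "g": values.index.astype(str)})
    order = order.sort_values(["v", "g"], ascending=[False, True], kind="mergesort")
    ranked = order["v"].copy()
    ranked.index = order["g"]
    ranked.name = sample_id
    return ranked


def _running_sum(
    metric: np.ndarray, hit: np.ndarray, weight_p: float
) -> np.ndarray:
    """Weighted-KS running sum over a ranked list (hit: boolean per rank)."""
    n = metric.size
    n_set = int(hit.sum())
    if n_set == 0 or n_set == n:
        raise ValidationError("gene set must hit a strict, non-empty subset of ranks")
    w = np.where(hit, np.abs(metric) ** weight_p, 0.0)
    denom = w.sum()
    if denom == 0:
        # all hit metrics are exactly zero: fall back to unweighted KS
        w = hit / n_set
        denom = 1.0
    return np.cumsum(w / denom - (~hit) / (n - n_set))


def enrichment_score(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Signed weighted-KS enrichment score of a gene set in a ranked list.

    The running sum increments at set members by |metric|^p (normalized so
    hits total +1) and decrements at non-members by 1/(N - n_set); ES is the
    running-sum value of maximal absolute deviation, keeping its sign.
    """
    members = set(map(str, gene_set))
    hit = ranked.index.isin(members)
    if not hit.any():
        raise ValidationError("gene set has empty intersection with the ranked list")
    run = _running_sum(ranked.to_numpy(float), hit, weight_p)
    es_idx = int(np.argmax(np.abs(run)))
    return float(run[es_idx]), run


@dataclass
class EnrichmentResult:
    """Per-ranking enrichment call with its permutation null summary."""

    es: float
    nes: float
    p_perm: float
    running_score: np.ndarray
    n_perm: int
    q: float | None = None
    call: bool | None = None


def _null_es(
    metric: np.ndarray,
    n_set: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float,
) -> np.ndarray:
    """Vectorized ES of ``n_perm`` random same-size gene sets."""
    n = metric.size
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_set]
    hit = np.zeros((n_perm, n), dtype=bool)
    hit[np.arange(n_perm)[:, None], picks] = True
    absw = np.abs(metric) ** weight_p
    w = hit * absw
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = hit[zero] / n_set
        denom[zero] = 1.0
    run = np.cumsum(w / denom - (~hit) / (n - n_set), axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), idx]


def nes_permutation(
    ranked: pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Normalize an enrichment score against a gene-set permutation null.

    Null ES values come from random gene sets of the same size drawn from
    the ranked list. NES divides the observed ES by the mean |null ES| of
    the same sign; the permutation p-value is
    (1 + #{same-sign null with |ES_null| >= |ES|}) / (1 + #same-sign null),
    so p >= 1/(n_perm + 1) always. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    metric = ranked.to_numpy(float)
    if np.all(metric == 0):
        raise ValidationError("degenerate ranking: all metrics are zero")
    es, run = enrichment_score(ranked, gene_set, weight_p=weight_p)
    n_set = int(ranked.index.isin(set(map(str, gene_set))).sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _null_es(metric, n_set, n_perm, rng, weight_p)
    if es == 0:
        return EnrichmentResult(es=0.0, nes=0.0, p_perm=1.0, running_score=run, n_perm=n_perm)
    same_sign = null[np.sign(null) == np.sign(es)]
    if same_sign.size == 0:
        nes = 0.0
        p = 1.0 / 1.0
    else:
        nes = es / np.abs(same_sign).mean()
        p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (1.0 + same_sign.size)
    return EnrichmentResult(es=es, nes=float(nes), p_perm=float(p), running_score=run, n_perm=n_perm)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stratify_cohort(
    expr: ExpressionMatrix,
    signature: GeneSet | Sequence[str],
    nes_min: float = 1.5,
    q_max: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    metric: Literal["zscore", "log2fpkm"] = "zscore",
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Per-sample signature enrichment calls across a cohort.

    Each sample is ranked, scored against the signature, and assigned a
    permutation NES/p; p-values are BH-adjusted across samples and a sample
    is called positive when NES > nes_min and q < q_max. Per-sample RNG
    streams are spawned from the single seed, so results do not depend on
    sample order.
    """
    if len(expr.sample_ids) < 10:
        raise ValidationError("cohort stratification needs >= 10 samples")
    genes = [g for g in signature if g in expr.gene_ids]
    if len(genes) == 0:
        raise ValidationError("signature absent from the expression matrix")
    children = np.random.SeedSequence(seed).spawn(len(expr.sample_ids))
    rows = []
    for sample, child in zip(expr.sample_ids, children):
        ranked = rank_sample(expr, sample, metric=metric)
        res = nes_permutation(
            ranked, genes, n_perm=n_perm, seed=np.random.default_rng(child), weight_p=weight_p
        )
        rows.append(
            {
                "sample_id": sample,
                "type_label": expr.type_of(sample),
                "es": res.es,
                "nes": res.nes,
                "p_perm": res.p_perm,
            }
        )
    calls = pd.DataFrame(rows).set_index("sample_id")
    calls["q"] = bh_adjust(calls["p_perm"].to_numpy())
    calls["call"] = (calls["nes"] > nes_min) & (calls["q"] < q_max)
    return calls


def load_ranking(path: str | os.PathLike) -> pd.Series:
    """Load an externally pre-ranked list (two-column TSV: gene, metric)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "metric"])
    ranked = pd.Series(df["metric"].to_numpy(float), index=df["gene"].astype(str))
    return ranked.sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# specificity heatmap


@dataclass
class SpecificityResult:
    """Welch t statistics for target-vs-type contrasts, per gene."""

    t: pd.DataFrame  # genes x types
    p: pd.DataFrame
    neglog10p: pd.DataFrame
    target_label: str


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t and two-sided p.

    Identical degenerate groups (both constant, equal means) give t = 0,
    p = 1 rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def specificity_heatmap(
    expr: ExpressionMatrix,
    target_label: str,
    genes: GeneSet | Sequence[str],
) -> SpecificityResult:
    """-log10 p heatmap of target-vs-each-other-type Welch t tests.

    Tests operate on log2(FPKM+1). Types with fewer than 2 samples yield
    NaN cells (flagged missing) rather than an error for the whole matrix.
    """
    gene_list = [g for g in genes if g in expr.gene_ids]
    if not gene_list:
        raise ValidationError("no signature genes present in the matrix")
    target_samples = expr.samples_of_type(target_label)
    if len(target_samples) < 2:
        raise ValidationError(f"target type {target_label!r} has < 2 samples")
    log_vals = _log2p1(expr.values.loc[gene_list])
    other_types = sorted(
        t for t in set(expr.labels.loc[expr.sample_ids, "type_label"]) if t != target_label
    )
    t_mat = pd.DataFrame(index=gene_list, columns=other_types, dtype=float)
    p_mat = pd.DataFrame(index=gene_list, columns=other_types, dtype=float)
    for typ in other_types:
        samples = expr.samples_of_type(typ)
        if len(samples) < 2:
            continue  # flagged missing (NaN)
        for g in gene_list:
            t, p = welch_t(
                log_vals.loc[g, target_samples].to_numpy(),
                log_vals.loc[g, samples].to_numpy(),
            )
            t_mat.loc[g, typ] = t
            p_mat.loc[g, typ] = p
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p_mat.astype(float))
    return SpecificityResult(t=t_mat, p=p_mat, neglog10p=neglog, target_label=target_label)
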