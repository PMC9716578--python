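# Methods

This note documents the models, conventions and design choices behind
`fusiontarget`: what the synthetic study emulates, how every threshold is
interpreted, how the enrichment statistics are defined, and what the passing
tests do and do not establish about real data.

## The discovery cascade

The cascade narrows a candidate gene set through independent, composable
filters over FPKM expression matrices and fusion ChIP-seq peaks. Filters
are pure functions `GeneSet -> GeneSet`; the applied-filter history travels
with the set (a `provenance` tuple) and is written into every output TSV.

Threshold semantics are fixed and covered by boundary tests:

| gate | rule | boundary behavior |
|---|---|---|
| expression | FPKM > 1 | exactly 1.0 fails the gate (and therefore *survives* specificity screens) |
| fold change | (ctrl + ε)/(kd + ε) ≥ 2 | exactly 2-fold passes |
| TSS window | ±100 kb, realized as [tss − w, tss + w + 1) | a peak touching exactly ±100 kb is "within" |
| peak overlap | ≥ 1 shared base, 0-based half-open | abutting intervals ([a,b) vs [b,c)) do not overlap |
| repeat count | ≥ 5 exact tandem copies | interrupted or partial copies never extend a run |
| type exclusivity | expressed in ≤ 1 type | "expressed in more than one type" removes |

Choices where the underlying convention was genuinely open:

* **Fold-change pseudocount** ε = 0.01 FPKM guards against division by
  zero. With the ≥ 2-fold gate and the > 1 FPKM control gate, ε at this
  magnitude cannot flip a call at default thresholds.
* **"Commonly" regulated** means the strict intersection across all
  knockdown pairs; no voting scheme is provided.
* **Type-level expression** in the tumor-exclusivity filter summarizes a
  type's samples by their **median** by default (robust to single outlier
  samples); `mean` and `any-sample` are exposed for sensitivity analysis.
* **Cell-line screen scope**: lines of the target type are excluded from
  the "non-target" screen by their type label, not by hard-coded names, so
  the caller controls whether target-type lines inside a compendium count
  as background.
* **Normal-tissue screen**: annotates every candidate with its expressing
  tissues and flags those above `max_tissues` (default 1); the pipeline
  applies the flag as a filter by default (`apply_tissue_filter`), keeping
  single-tissue "marginal expression" genes.
* **Stage order** follows the discovery narrative: expression filters, then
  ChIP integration, then type-specificity on the survivors (primary tumors
  before metastases), then the tissue screen. The pipeline is fail-fast: a
  stage error aborts the run with the stage name, since later filters are
  meaningless on partial survivors.
* **Repeat scanning scope**: the peak interval exactly, with an optional
  `flank_bp` to extend to a broader regulatory element.

## Genomic conventions

All intervals are 0-based half-open (BED native). The microsatellite
scanner counts maximal runs of exact, uninterrupted tandem motif copies at
any phase, scanning both strands by default (fusion binding to the repeat
is strand-agnostic); ties between strands resolve to `+`, and `N` never
matches. Tag density is the raw coverage sum over [start − flank,
end + flank), clipped at position 0, scaled by the track's library size to
reads per million; a track's library size defaults to its own total signal
(CPM-style self-normalization), and pre-normalized tracks may declare 1e6.

## Per-sample enrichment

The per-sample call uses the weighted Kolmogorov–Smirnov running-sum
statistic with weight p = 1: walking down the ranked list, set members add
|metric|^p (normalized so hits sum to +1) and non-members subtract
1/(N − n_set); ES is the running-sum value of maximal absolute deviation,
signed. If every hit metric is exactly zero the hit weights degenerate and
the statistic falls back to the unweighted KS form.

Two pieces are deliberate surrogates, because a per-sample call admits no
phenotype permutation:

* **Ranking metric** — the cross-sample z-score of log2(FPKM+1)
  (sample-sd, ddof = 1), so a gene scores highly exactly in the samples
  where it is unusually expressed; zero-variance genes get z = 0 and ties
  break lexicographically by gene id for determinism. Raw log2 expression
  is available as an alternative metric.
* **Null model** — gene-set permutation: `n_perm` random same-size gene
  sets re-scored on the same ranked list. NES = ES / mean(|null ES| of the
  observed sign); p = (1 + #{same-sign null with |ES_null| ≥ |ES|}) /
  (1 + #same-sign null), so p ≥ 1/(n_perm + 1) and p-values are valid by
  construction. The calibration test confirms empirical type-I error at
  α = 0.05 within 3 binomial standard errors over 500 random-set draws.

p-values are Benjamini–Hochberg adjusted **across the samples of one
cohort run**, and a sample is called positive when NES > 1.5 and q < 0.05.
`n_perm = 1000` is the default: with ~half the null sharing the observed
sign, the attainable p floor (~0.002) leaves comfortable BH headroom at
q < 0.05 for a cohort of 60 samples. Per-sample RNG streams are spawned
from one integer seed, so results are independent of sample order and
fully reproducible.

All correlations and t tests operate on log2(FPKM+1) — conventional
variance stabilization for FPKM. The correlation network keeps every
sample as a node, adds edges at r ≥ r_min (default 0.5; the inclusive
boundary is the adopted convention), and sets r = 0 with a flag for
samples whose signature vector is constant — correlation carries no
information there. The specificity heatmap uses the Welch
(unequal-variance) t test; identical degenerate groups yield t = 0, p = 1,
and types with fewer than 2 samples produce flagged-missing (NaN) cells
rather than failing the whole matrix.

## The synthetic study

The generator emulates, at desk scale, the data landscape of a
fusion-target screen: 1,000 genes with 30 planted fusion targets; 3
knockdown cell-line pairs; 60 cell lines over 12 cancer types (EwS among
them); 120 typed primary tumors (no EwS, as in primary pan-cancer
compendia); 60 metastases including 11 EwS; 12 normal tissues × 5 samples.
These sizes — and every effect parameter — live in `SynthConfig`.

Generative model, chosen once:

* **FPKM is simulated directly on the log2 scale** (log-normal), not via
  read counts, because every downstream rule is stated in FPKM units. The
  distributional form is a modelling choice, not an inference about the
  real cohorts.
* **Background genes**: per-gene baseline b_g ~ N(3, 0.8) log2-FPKM shared
  across cohorts, with N(0, 0.4) per-sample jitter.
* **Planted targets**: per-gene mean m_g ~ N(5, 1) shared across all
  EwS-labelled samples (this shared profile is what creates the r ≥ 0.5
  EwS clique), the same N(0, 0.4) jitter, knockdown dividing FPKM by
  2^4, and **exactly zero FPKM in every non-EwS sample**. The zero models
  a developmentally silenced gene awakened only by the fusion, and makes
  the planted structure exactly recoverable: constant signature vectors
  give r = 0 (flagged), so spurious cross-edges cannot arise from
  finite-signature sampling noise. A sub-1-FPKM expression leak would
  leave every filter's behavior unchanged but turns network recovery into
  a coin flip at realistic signature sizes.
* **Genome**: ~50 genes per chromosome, 2 kb background gene slots. Each
  planted target sits in a ±110 kb isolation pad so its enhancer peak
  (a 9-copy GGAA run placed 6.7 kb upstream of the TSS, strand-aware,
  inside a ±200 bp peak) is within ±100 kb of exactly one TSS. Background
  sequence is rejection-sampled (bounded retries, then an error naming the
  chromosome) to contain no run of ≥ 3 motif copies on either strand, and
  planted runs are flanked by fixed non-extending bases — so repeat
  recovery is exact with zero false positives. Decoy peaks live in
  210 kb gene-desert tails, > 100 kb from every TSS.
* **Coverage tracks** are noise-free step functions: baseline 1 everywhere,
  value 20 within ±2.5 kb of planted regions under `fusion_on`; the
  fusion-off track is flat. Tag-density comparisons need only the ordering,
  which the step heights fix by construction.
* **Knockdown pairs carry no replicates** — the cascade consumes fold
  change only, never dispersion.

Effect sizes were fixed once against the design requirement that every
planted target pass, and every background gene fail, each filter with
per-gene probability ≥ 0.999 (verified empirically over 20 seeds): with
jitter sd 0.4, a log2 knockdown effect of 4 puts the weakest observed pair
more than 5 jitter-sds above the 2-fold gate, and a baseline of N(3, 0.8)
puts the background genes that could slip through the median-based
type filter (b_g ≲ 0) nearly 4 sds below the mean.

**What passing recovery tests show — and what they do not.** Exact
recovery on this generator demonstrates that the implementation applies
every rule correctly under conditions where the rules *should* separate
signal perfectly. It does not estimate the screen's sensitivity or
specificity on real cohorts, where expression leaks across types, fold
changes are graded, peaks are noisy, and microsatellite lengths are
polymorphic. The generator deliberately omits read-level noise, GC and
mappability structure, copy-number effects and fusion-breakpoint
simulation.

## Numerical and determinism notes

* Identical config (including seed) reproduces byte-identical FASTA, BED,
  bedGraph, TSV and graphml outputs; floats are serialized with pandas'
  shortest round-trip repr, so written matrices reload exactly.
* The generator's three operations draw from separate, fixed RNG streams
  keyed on `[seed, stream]`, so genome, cohorts and peaks are individually
  deterministic and mutually consistent (the planted-gene draw is a pure
  function of the config).
* `argmax` over the running sum takes the first position at ties; gene
  rank ties break lexicographically; strand ties break to `+`.
* Problem sizes used by the shipped checks: discovery recovery over 20
  seeds at the default scale; stratification recovery over 20 seeds at
  n_perm = 1000; oracle equivalence on 1,000 random 300-nt sequences, a
  200-peak × 50-gene assignment instance, and N = 10 enrichment lists;
  calibration over 500 draws at n_perm = 200.

## Known limitations

* The gene-set permutation NES is not comparable to phenotype-permutation
  NES values from the standard GSEA tool; thresholds tuned for one do not
  transfer to the other.
* The type-exclusivity filter's median summary can mask bimodal expression
  within a type; `any-sample` mode is the conservative alternative.
* Tag-density profiles sum total rpm per region; no per-base metaprofile
  shape is produced.
* Very small cohorts (< 10 samples) are rejected for stratification rather
  than called with unstable BH adjustment.
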