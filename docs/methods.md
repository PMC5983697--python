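# Methods

## Scope and model

`tftarget` integrates four evidence streams to nominate direct
transcriptional targets of a regulator: ChIP-seq binding position relative
to transcription start sites (TSS), response to overexpression and
knockdown of the regulator, co-expression with the regulator across a tumor
cohort, and a median-bifurcation survival analysis of the candidates. The
package makes no attempt to model read-level data: peaks are consumed as
intervals, expression as gene×sample matrices, survival as (time, event)
pairs.

## Coordinate and distance conventions

All intervals are 0-based half-open internally; GTF (1-based inclusive) is
converted on read and back on write, and the conversion is an exact
round-trip for both strands. A gene's TSS is `start` on the + strand and
`end − 1` on the − strand.

The peak-to-TSS distance d is computed from a configurable reference point —
midpoint (default), summit, or the TSS-closest edge; published analyses
rarely state which was used, and the choice shifts |d| by at most half a
peak width. The raw offset p − TSS is flipped for − strand genes; under the
default `upstream_negative` convention a peak upstream of the TSS in the
gene's reading direction has d < 0. The opposite convention is provided
because some published tables print upstream distances as positive.
Ties between equidistant TSSs resolve to the lexicographically smallest
gene id; a gene's best distance resolves a ±d tie to the upstream (negative)
value. Both rules exist purely for determinism.

"Promoter-bound" means |d| ≤ w with w = 2000 bp inclusive, the conventional
"within 2 kb of the TSS" window; w is a parameter everywhere it appears.

Peak pooling across cell lines offers `union_merge` (concatenate, sort,
merge intervals with gap ≤ `merge_gap`; default gap 0 also merges touching
intervals) and `intersection` (merged loci overlapped by at least one peak
from every input set). Merged loci are disjoint by construction and
preserve base coverage at gap 0. Note that pooling deliberately collapses
repeated binding at the same promoter into one locus, so the promoter
fraction of *pooled* loci is lower than that of raw simulated peaks; the
calibration claim below refers to the unpooled peak set.

## Expression statistics

Perturbation ratios are (mean treatment + ε)/(mean control + ε) per gene on
the linear scale, ε = 1.0 by default. Group means with a pseudocount were
chosen because published target tables give plain ratios without an
estimator; ε stabilizes low-expression genes and keeps all-zero genes at
ratio 1. Matrices carry an explicit scale tag (`linear` or `log2p1`) and are
back-transformed before averaging when needed.

Cross-contrast concordance pairs (log₂ OE/Ctr, −log₂ KD/Ctr) per gene; the
knockdown axis is flipped so that concordant regulation (up under
overexpression, down under knockdown) scores positive, and Pearson r of the
point cloud is the summary. An unflipped mode exists for diagnostics.

Cohort correlation is Pearson on log₂(x+1) values (the common convention
for TCGA-style matrices); Spearman is available behind a flag. Zero-variance
genes yield NaN markers that never count as zeros and never pass thresholds.

## Candidate selection

The rule is a literal disjunction:

* `consistent_change`: OE/Ctr ≥ 1.5 **and** KD/Ctr ≤ 0.75;
* `high_correlation`: |r| ≥ 0.20 (absolute value — strongly anticorrelated
  genes are plausible repression targets).

A gene is selected iff at least one disjunct holds (and, optionally, it is
promoter-bound; off by default because bona fide long-range targets sit
hundreds of kb from the nearest TSS). The three thresholds are not derived
from first principles: they are calibrated so that the canonical worked
example — three published candidate rows with (KD/Ctr, OE/Ctr, r) =
(0.66, 1.90, 0.29), (1.06, 2.10, 0.24) and (0.77, 1.01, −0.32) — is
selected in full, with only the first row qualifying via
`consistent_change`. All three are configurable. The rank score
|log₂ OE| + |log₂ KD| + |r| orders the output table and never changes
membership.

Selection is monotone by construction: tightening any threshold can only
shrink the candidate set (property-tested).

## Survival analysis

Per gene, shared samples are bifurcated at the median expression (even n:
mean of the central pair); ties go to the low group. A constant expression
vector is a degenerate split and is reported as skipped rather than tested.
The Kaplan–Meier estimator and the standard pooled-hypergeometric log-rank
test are implemented directly; at each distinct event time j,
E₁ⱼ = dⱼ·n₁ⱼ/nⱼ and Vⱼ = dⱼ·(n₁ⱼ/nⱼ)(1−n₁ⱼ/nⱼ)(nⱼ−dⱼ)/(nⱼ−1) (Vⱼ = 0 when
nⱼ = 1), with the statistic (Σ(O₁ⱼ−E₁ⱼ))²/ΣVⱼ referred to χ²₁.

The hazard ratio is the O/E estimator (O₁/E₁)/(O₂/E₂) rather than a Cox
fit: it is the standard display statistic for two-group median-split
screens, is defined whenever all four terms are positive (otherwise an
explicit NaN marker), and is fully checkable by hand. An approximate CI uses
var(log HR) ≈ 1/E₁ + 1/E₂. Both estimator and test are cross-checked
against lifelines in the test suite; lifelines is never used in the
implementation itself.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating study:

* **Annotation** — 2000 genes over 4×10 Mb chromosomes, uniform distinct
  TSSs, Bernoulli(½) strands, 1–50 kb bodies.
* **Truth** — ⌈5%⌉ of genes are true targets; 80% positively regulated,
  the rest repressed (the published candidate table contains both signs).
* **Peaks** — 3086 loci; with probability w = 0.665 a locus midpoint sits at
  a true-target TSS plus a N(0, 600 bp) offset truncated at ±2 kb, otherwise
  uniform background ≥ 10 kb from every TSS. Truncation means the planted
  weight *equals* the expected promoter fraction (no leakage), so the
  binomial calibration test is sharp: at n = 3086 the observed fraction
  stays within 3·√(w(1−w)/n) ≈ 2.5 percentage points of w.
* **Contrasts** — baselines log₂-uniform on [3, 10]; replicate noise
  N(0, 0.5) in log₂ over 3 treatment + 3 control samples; positive targets
  ×2.0 under overexpression and ×0.5 under knockdown (inverted for
  repression targets). In the noiseless limit with ε = 0 the ratio recovers
  the planted fold exactly.
* **Cohort** — 100 samples; regulator ~ N(8, 1) in log₂; each target is
  baseline + β·(regulator − 8) + N(0, 0.5) with β set so the population
  correlation is ±0.5; |ρ| = 1 is supported as an exact deterministic limit.
  Values are clipped at 0 to stay on the log₂(x+1) scale, which is only
  material for extreme parameter choices.
* **Survival** — the reporter gene (first positively regulated target) is
  median-split; low-expression samples draw exponential event times at
  hazard 1/1000 per day × HR 0.4, high samples at 1/1000; independent
  exponential censoring per group tuned to a 30% censored fraction. The
  convention plants the hazard multiplier on the low group, so HR
  (low vs high) below 1 is the recovery signature.

Each output draws from its own named random substream derived from the
master seed (`SeedSequence([seed, crc32(label)])`), so adding a generator
never perturbs another's output, and one seed reproduces every file
byte-for-byte.

What the simulator does **not** emulate: probe effects, batch structure,
copy-number or subtype confounding, correlated background co-expression
modules, overdispersed counts, or informative censoring. Passing recovery
tests therefore demonstrates correctness of the pipeline's logic under its
own assumptions, not performance on real cohorts, where correlated
backgrounds will inflate the high-correlation disjunct further.

## Expected error rates at the default thresholds

With cohort n = 100, the null distribution of Pearson r gives
P(|r| ≥ 0.20) = 2·P(t₉₈ > 0.2·√98/√0.96) ≈ 4.6%, and the joint ratio rule
adds roughly another 1.2% (two independent one-sided tails of the log-ratio
noise at sd ≈ 0.42 log₂ units), so about 5.7% of non-targets are expected to
enter the candidate list — the disjunctive rule trades precision for recall
exactly as its published motivation intends. Sensitivity at the planted
effect sizes is essentially 100% (the correlation disjunct alone has power
≈ 1 against |ρ| = 0.5 at n = 100). Users wanting a tighter list should raise
`abs_r_min` (e.g. 0.3 halves the correlation-driven false positives at a
negligible sensitivity cost at these effect sizes) or set
`require_promoter=True`.

## Numerical and determinism notes

* Ratios are guarded by the pseudocount; log₂ of a ratio is therefore
  always finite.
* Undefined quantities (zero-variance correlations, HR with a zero O/E
  term, zero log-rank variance) are explicit NaN markers, never silently 0.
* TSV writers use repr-based float formatting and readers parse with exact
  round-trip precision, so write→read is an identity for every table.
* Reports and logs contain no timestamps or absolute paths; a rerun of
  `run_all` with the same config and seed is byte-identical.
* Problem sizes in the test suite (e.g. 20 oracle instances of 1000×200,
  1000 null replicates for the log-rank type-I check, 200 replicates of
  n = 200 for hazard-ratio recovery, 5 seeds for calibration and recovery
  averages) were chosen to make the Monte-Carlo bands sharp at desk scale;
  all are stated in the tests themselves.
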