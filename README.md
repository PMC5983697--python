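# tftarget

Integrative calling of direct transcription-factor target genes from public
genomics data, with a planted-truth simulator for end-to-end validation.

## The problem

Deciding which genes a DNA-binding regulator *directly* controls requires
combining several weak, noisy lines of evidence: where the factor binds
(ChIP-seq peaks relative to transcription start sites), how transcripts
respond when the factor is perturbed (overexpression and knockdown
contrasts), whether a gene's expression tracks the regulator across a tumor
cohort, and whether candidate targets carry clinical signal (survival
differences between expression-defined patient groups). `tftarget`
implements this integration as a tested, reusable pipeline for analysts who
have peak calls, expression matrices and clinical tables in hand — the
motivating use case being BRCA1 target discovery in breast cancer from
ENCODE-style ChIP compendia, GEO perturbation series and TCGA cohorts.

## The method

1. **Peak-to-TSS annotation.** Peaks from multiple cell lines are pooled
   (union-merge or intersection of merged loci). Each locus is assigned to
   the gene minimizing |p − TSS| on its chromosome, where p is the locus
   midpoint (or summit / nearest edge). The signed distance d is oriented by
   the gene's reading direction — upstream is negative by default. The
   promoter fraction is #{|d| ≤ w}/#assigned with w = 2 kb.
2. **Perturbation response.** Per-gene ratios
   (mean treatment + ε)/(mean control + ε) on the linear scale for an
   overexpression (OE/Ctr) and a knockdown (KD/Ctr) contrast; cross-dataset
   concordance is the Pearson r of (log₂ OE/Ctr, −log₂ KD/Ctr) pairs, so a
   gene induced by overexpression and repressed by knockdown scores positive.
3. **Cohort co-expression.** Pearson r between each gene and the regulator
   on log₂(x+1) expression across tumor samples.
4. **Disjunctive selection.** A gene is a candidate target iff it shows
   *consistent perturbation change* (OE/Ctr ≥ 1.5 and KD/Ctr ≤ 0.75) **or**
   *high cohort correlation* (|r| ≥ 0.20); promoter occupancy (|d| ≤ 2 kb)
   is annotated and can be required, but is off by default because genuine
   long-range targets (hundreds of kb) would otherwise be lost.
5. **Survival.** Per gene, the cohort is bifurcated at median expression;
   Kaplan–Meier curves, the 1-df log-rank test
   χ² = (Σ(O₁ⱼ−E₁ⱼ))²/ΣVⱼ and the O/E hazard ratio
   HR = (O₁/E₁)/(O₂/E₂) compare the halves.

A `2^−ΔΔCt` utility for relative qPCR quantification is included for
validating candidates at the bench.

The simulator (`tftarget.simulate`) generates every input with planted
ground truth — a gene annotation, loci placed near planted-target TSSs with
probability w on a uniform background, contrast matrices with planted folds,
a cohort with planted regulator correlations, and survival times with
group-dependent hazards — so the whole pipeline is testable without any
external download, and recovery of the planted targets can be scored exactly.

## Worked example

```python
from tftarget import (SimulationConfig, simulate_all, assign_nearest_tss,
                      promoter_fraction, promoter_occupancy, ContrastSpec,
                      compute_ratio, regulator_correlation, SelectionParams,
                      select_candidates)

cfg = SimulationConfig(seed=42)          # 2000 genes, 3086 loci, w=0.665
data = simulate_all(cfg)

assigned = assign_nearest_tss(data["peaks"], data["genes"])
frac = promoter_fraction(assigned, window=2000)
print(f"{frac.n_within}/{frac.n_assigned} loci within 2 kb of a TSS "
      f"({100 * frac.fraction:.1f}%)")

occ = promoter_occupancy(assigned, window=2000, genes=data["genes"])
oe = compute_ratio(data["oe"], ContrastSpec("overexpression",
                   ("OE_T1", "OE_T2", "OE_T3"), ("OE_C1", "OE_C2", "OE_C3")))
kd = compute_ratio(data["kd"], ContrastSpec("knockdown",
                   ("KD_T1", "KD_T2", "KD_T3"), ("KD_C1", "KD_C2", "KD_C3")))
corr = regulator_correlation(data["cohort"], "REG1")

records = select_candidates(occ, oe, kd, corr, SelectionParams())
truth = data["manifest"].true_targets
hits = sum(r.gene_id in truth for r in records)
print(f"{len(records)} candidate targets selected; "
      f"{hits}/{len(truth)} planted targets recovered")
```

prints

```
2048/3086 loci within 2 kb of a TSS (66.4%)
204 candidate targets selected; 100/100 planted targets recovered
```

66.4% of loci fall in the ±2 kb promoter window (the generator planted a
weight of 0.665); all 100 planted targets are recovered, along with a tail
of false positives admitted by the |r| ≥ 0.20 disjunct at cohort size 100
(see `docs/methods.md`). Each record carries the candidate-table row: signed
distance to TSS, KD/Ctr, OE/Ctr, cohort r, and which disjunct(s) selected it.

The same run is available from the shell:

```sh
tftarget run-all --config config.yaml --outdir out/
```

with `config.yaml` containing `seed: 42` and a `simulate: {}` section (or an
`inputs:` section pointing at your own GTF/narrowPeak/TSV files). The output
directory gets every stage table (assignments, histogram, occupancy,
contrasts, concordance, correlation, candidates, survival) plus
`report.json`; reruns are byte-identical.

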