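"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a gene
annotation, ChIP-seq loci enriched near the TSSs of a planted target set on a
uniform background, overexpression and knockdown contrast matrices with planted
fold effects, a tumor-cohort matrix in which targets co-express with the
regulator at a planted correlation, and a clinical table whose hazards depend
on a reporter gene's median-split group.  A manifest records every planted
value so recovery can be scored exactly.

Randomness: each output draws from its own named substream derived from the
master seed (zlib.crc32 of the label mixed into the seed sequence), so adding
one generator never perturbs another's stream.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneModel,
    Peak,
    write_clinical,
    write_expression,
    write_gene_models,
    write_peaks,
)

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "substream",
    "simulate_annotation",
    "plant_truth",
    "simulate_peaks",
    "simulate_contrasts",
    "simulate_cohort",
    "simulate_survival",
    "simulate_all",
    "write_manifest",
    "read_manifest",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible random stream for one named output."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the scale of a
    four-cell-line ChIP compendium (~3086 loci, two-thirds promoter-proximal),
    ~2x/0.5x perturbation folds and a 100-tumor cohort."""

    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    target_fraction: float = 0.05
    n_peaks: int = 3086
    promoter_peak_weight: float = 0.665
    promoter_offset_sd: float = 600.0
    oe_fold: float = 2.0
    kd_fold: float = 0.5
    n_perturb_replicates: int = 3
    cohort_n: int = 100
    target_correlation: float = 0.5
    expression_noise_sd: float = 0.5
    survival_n: int = 200
    true_hr_low_expression: float = 0.4
    censoring_rate: float = 0.3
    positive_regulation_fraction: float = 0.8
    regulator_gene_id: str = "REG1"
    peak_width: int = 200
    background_tss_clearance: int = 10_000
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    baseline_event_rate: float = 1.0 / 1000.0  # per day, high-expression group

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_peaks": self.n_peaks,
            "n_perturb_replicates": self.n_perturb_replicates,
            "cohort_n": self.cohort_n,
            "survival_n": self.survival_n,
            "peak_width": self.peak_width,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        for name, val in {
            "target_fraction": self.target_fraction,
            "promoter_peak_weight": self.promoter_peak_weight,
            "censoring_rate": self.censoring_rate,
            "positive_regulation_fraction": self.positive_regulation_fraction,
        }.items():
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.oe_fold <= 0 or self.kd_fold <= 0:
            raise ValueError("fold effects must be positive")
        if abs(self.target_correlation) > 1:
            raise ValueError("target_correlation must be in [-1, 1]")


@dataclass
class TruthManifest:
    """Planted per-gene ground truth plus the full generating configuration."""

    config: SimulationConfig
    genes: pd.DataFrame  # index gene_id; columns below
    regulator_gene_id: str
    reporter_gene: str | None = None

    COLUMNS = (
        "is_true_target",
        "regulation_sign",
        "baseline_log2",
        "planted_peak_distance",
        "planted_oe_effect",
        "planted_kd_effect",
        "planted_correlation",
    )

    @property
    def true_targets(self) -> list[str]:
        return list(self.genes.index[self.genes["is_true_target"]])

    @property
    def non_targets(self) -> list[str]:
        return list(self.genes.index[~self.genes["is_true_target"]])


# ---------------------------------------------------------------------------
# annotation and truth


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place genes uniformly with distinct TSSs; strands are Bernoulli(1/2).

    Gene bodies are 1-50 kb; the TSS is pinned at the strand-appropriate end
    and clipped bodies never move it.  Deterministic given the seed.
    """
    rng = substream(config.seed, "annotation")
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    if max(per_chrom) > config.chrom_length_bp // 2:
        raise ValueError("genes too dense to place without TSS collisions")
    genes: list[GeneModel] = []
    width = len(str(config.n_genes))
    gidx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n = per_chrom[c]
        tss = rng.choice(config.chrom_length_bp, size=n, replace=False)
        tss.sort()
        strands = rng.random(n) < 0.5
        lengths = rng.integers(1_000, 50_001, size=n)
        for t, plus, length in zip(tss, strands, lengths):
            gidx += 1
            gid = f"G{gidx:0{width}d}"
            t, length = int(t), int(length)
            if plus:
                start, end, strand = t, min(t + length, config.chrom_length_bp), "+"
                if end == start:
                    end = start + 1
            else:
                start, end, strand = max(t + 1 - length, 0), t + 1, "-"
            genes.append(GeneModel(gene_id=gid, symbol=gid, chrom=chrom, strand=strand, start=start, end=end))
    return genes


def plant_truth(config: SimulationConfig, genes) -> TruthManifest:
    """Choose the planted target set, regulation signs and per-gene effects."""
    rng = substream(config.seed, "truth")
    gene_ids = [g.gene_id for g in genes]
    n_targets = math.ceil(config.target_fraction * len(gene_ids))
    target_ids = set(rng.choice(gene_ids, size=n_targets, replace=False))
    rows = {}
    lo, hi = config.baseline_log2_range
    for gid in gene_ids:
        is_target = gid in target_ids
        sign = 0
        if is_target:
            sign = 1 if rng.random() < config.positive_regulation_fraction else -1
        rows[gid] = {
            "is_true_target": is_target,
            "regulation_sign": sign,
            "baseline_log2": float(rng.uniform(lo, hi)),
            "planted_peak_distance": np.nan,
            "planted_oe_effect": config.oe_fold**sign if is_target else 1.0,
            "planted_kd_effect": config.kd_fold**sign if is_target else 1.0,
            "planted_correlation": sign * config.target_correlation if is_target else 0.0,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[gene_ids]
    df.index.name = "gene_id"
    positives = sorted(gid for gid in target_ids if rows[gid]["regulation_sign"] > 0)
    reporter = positives[0] if positives else (sorted(target_ids)[0] if target_ids else None)
    return TruthManifest(
        config=config, genes=df, regulator_gene_id=config.regulator_gene_id, reporter_gene=reporter
    )


# ---------------------------------------------------------------------------
# peaks


def _truncated_normal(rng, sd: float, bound: float) -> float:
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return x


def simulate_peaks(config: SimulationConfig, genes, manifest: TruthManifest) -> list[Peak]:
    """Plant n_peaks loci: promoter-proximal near true-target TSSs, else background.

    With probability ``promoter_peak_weight`` a peak's midpoint sits at a true
    target's TSS plus a zero-mean normal offset truncated to +-2 kb (so the
    planted weight equals the expected promoter fraction exactly); otherwise
    the midpoint is uniform, at least ``background_tss_clearance`` bp from
    every TSS.  Planted distances are recorded in the manifest.
    """
    rng = substream(config.seed, "peaks")
    targets = manifest.true_targets
    if config.promoter_peak_weight > 0 and not targets:
        raise ValueError("promoter_peak_weight > 0 but no true targets planted")
    gene_by_id = {g.gene_id: g for g in genes}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}
    chroms = sorted(tss_by_chrom)

    half = config.peak_width // 2
    peaks: list[Peak] = []
    planted: dict[str, float] = {}
    for i in range(config.n_peaks):
        if rng.random() < config.promoter_peak_weight:
            gid = targets[rng.integers(len(targets))]
            gene = gene_by_id[gid]
            offset = int(round(_truncated_normal(rng, config.promoter_offset_sd, 2000)))
            mid = gene.tss + offset
            mid = min(max(mid, half), config.chrom_length_bp - half)
            chrom = gene.chrom
            prev = planted.get(gid)
            if prev is None or abs(offset) < abs(prev):
                planted[gid] = offset
        else:
            while True:
                chrom = chroms[rng.integers(len(chroms))]
                mid = int(rng.integers(half, config.chrom_length_bp - half))
                tss = tss_by_chrom[chrom]
                j = int(np.searchsorted(tss, mid))
                near = min(
                    abs(mid - int(tss[k])) for k in (j - 1, j) if 0 <= k < len(tss)
                )
                if near >= config.background_tss_clearance:
                    break
        peaks.append(
            Peak(
                chrom=chrom,
                start=mid - half,
                end=mid + half,
                name=f"peak_{i + 1}",
                signal=float(np.round(rng.uniform(1, 20), 3)),
                summit_offset=half,
                source_label="sim",
            )
        )
    for gid, offset in planted.items():
        manifest.genes.at[gid, "planted_peak_distance"] = float(offset)
    return peaks


# ---------------------------------------------------------------------------
# expression


def _contrast_matrix(config, manifest, rng, prefix: str, fold_col: str, regulator_fold: float):
    k = config.n_perturb_replicates
    samples = [f"{prefix}_T{i + 1}" for i in range(k)] + [f"{prefix}_C{i + 1}" for i in range(k)]
    base = manifest.genes["baseline_log2"].to_numpy()
    folds = manifest.genes[fold_col].to_numpy()
    n_genes = len(base)
    log2 = np.tile(base[:, None], (1, 2 * k)) + rng.normal(0, config.expression_noise_sd, (n_genes, 2 * k))
    log2[:, :k] += np.log2(folds)[:, None]
    reg_row = 8.0 + rng.normal(0, config.expression_noise_sd, 2 * k)
    reg_row[:k] += np.log2(regulator_fold)
    values = np.exp2(np.vstack([log2, reg_row[None, :]]))
    index = list(manifest.genes.index) + [config.regulator_gene_id]
    df = pd.DataFrame(values, index=pd.Index(index, name="gene_id"), columns=samples)
    return ExpressionMatrix(df, scale="linear")


def simulate_contrasts(config: SimulationConfig, manifest: TruthManifest):
    """Overexpression and knockdown matrices (linear scale) with planted folds.

    Replicate noise is normal in log2 with sd ``expression_noise_sd``; positive
    targets are multiplied by oe_fold under overexpression and kd_fold under
    knockdown (inverted for negative-regulation targets).  The regulator itself
    is included as a strongly shifted row in each matrix.
    """
    rng_oe = substream(config.seed, "contrast_oe")
    rng_kd = substream(config.seed, "contrast_kd")
    oe = _contrast_matrix(config, manifest, rng_oe, "OE", "planted_oe_effect", 4.0)
    kd = _contrast_matrix(config, manifest, rng_kd, "KD", "planted_kd_effect", 0.25)
    return oe, kd


def simulate_cohort(config: SimulationConfig, manifest: TruthManifest) -> ExpressionMatrix:
    """Tumor-cohort matrix (log2p1 scale) with planted regulator correlations.

    The regulator is N(8, 1) across samples; each true target g follows
    x_g = baseline_g + beta_g * (regulator - 8) + noise with beta_g set so the
    population correlation equals +-target_correlation; non-targets are
    independent noise around their baselines.
    """
    rng = substream(config.seed, "cohort")
    n = config.cohort_n
    samples = [f"S{i + 1:03d}" for i in range(n)]
    reg = rng.normal(8.0, 1.0, n)
    sigma_eps = config.expression_noise_sd
    rho = config.target_correlation
    base = manifest.genes["baseline_log2"].to_numpy()
    signs = manifest.genes["regulation_sign"].to_numpy()
    is_target = manifest.genes["is_true_target"].to_numpy()
    noise = rng.normal(0, sigma_eps, (len(base), n))
    values = base[:, None] + noise
    rows = np.where(is_target)[0]
    if abs(rho) == 1:
        # deterministic limit: targets track the regulator exactly
        values[rows] = base[rows, None] + signs[rows, None] * (reg - 8.0)[None, :]
    elif rho != 0:
        beta = (abs(rho) / math.sqrt(1 - rho**2)) * sigma_eps  # sigma_reg = 1
        values[rows] += (signs[rows, None] * beta) * (reg - 8.0)[None, :]
    values = np.vstack([values, reg[None, :]])
    values = np.clip(values, 0.0, None)  # log2p1 scale is nonnegative
    index = list(manifest.genes.index) + [config.regulator_gene_id]
    df = pd.DataFrame(values, index=pd.Index(index, name="gene_id"), columns=samples)
    return ExpressionMatrix(df, scale="log2p1")


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    config: SimulationConfig, manifest: TruthManifest, cohort: ExpressionMatrix
) -> ClinicalTable:
    """Clinical table whose hazards depend on the reporter gene's median split.

    Samples in the below-median half of the reporter's cohort expression draw
    exponential event times at ``baseline_event_rate * true_hr_low_expression``;
    the high half at the baseline rate.  Censoring is an independent
    exponential per group tuned so the expected censored fraction equals
    ``censoring_rate`` (0 means no censoring).  Uses the first
    min(survival_n, cohort_n) cohort samples.
    """
    rng = substream(config.seed, "survival")
    reporter = manifest.reporter_gene
    if reporter is None:
        raise ValueError("no reporter gene available (no planted targets)")
    samples = cohort.sample_ids[: min(config.survival_n, len(cohort.sample_ids))]
    vals = cohort.values.loc[reporter, samples].astype(float)
    split = float(np.median(vals.to_numpy()))
    low_mask = (vals <= split).to_numpy()
    lam_high = config.baseline_event_rate
    lam_low = lam_high * config.true_hr_low_expression
    lam = np.where(low_mask, lam_low, lam_high)
    event_time = rng.exponential(1.0 / lam)
    c = config.censoring_rate
    if c > 0:
        lam_c = lam * c / (1 - c)
        censor_time = rng.exponential(1.0 / lam_c)
    else:
        censor_time = np.full(len(samples), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    df = pd.DataFrame({"sample": samples, "time": np.round(time, 3), "event": event})
    df.loc[df["time"] <= 0, "time"] = 0.001  # guard against zero after rounding
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# manifest I/O and the one-call generator

_MANIFEST_KEYS = ("config", "regulator_gene_id", "reporter_gene", "genes")


def _jsonify(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    if isinstance(value, (np.bool_, bool)):
        return bool(value)
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        return float(value)
    return value


def write_manifest(manifest: TruthManifest, path) -> None:
    payload = {
        "config": dataclasses.asdict(manifest.config),
        "regulator_gene_id": manifest.regulator_gene_id,
        "reporter_gene": manifest.reporter_gene,
        "genes": {
            gid: {col: _jsonify(row[col]) for col in TruthManifest.COLUMNS}
            for gid, row in manifest.genes.iterrows()
        },
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> TruthManifest:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    missing = [k for k in _MANIFEST_KEYS if k not in payload]
    if missing:
        raise ValueError(f"manifest missing keys: {missing}")
    cfg_dict = dict(payload["config"])
    if "baseline_log2_range" in cfg_dict:
        cfg_dict["baseline_log2_range"] = tuple(cfg_dict["baseline_log2_range"])
    config = SimulationConfig(**cfg_dict)
    genes = pd.DataFrame.from_dict(payload["genes"], orient="index")
    missing_cols = [c for c in TruthManifest.COLUMNS if c not in genes.columns]
    if missing_cols:
        raise ValueError(f"manifest gene records missing fields: {missing_cols}")
    genes = genes[list(TruthManifest.COLUMNS)].sort_index()
    genes.index.name = "gene_id"
    genes["planted_peak_distance"] = genes["planted_peak_distance"].astype(float)
    return TruthManifest(
        config=config,
        genes=genes,
        regulator_gene_id=payload["regulator_gene_id"],
        reporter_gene=payload["reporter_gene"],
    )


def simulate_all(config: SimulationConfig, outdir=None):
    """Generate every pipeline input; optionally write the standard file set.

    Returns a dict with genes, peaks, oe/kd matrices, cohort, clinical and the
    truth manifest.  When ``outdir`` is given, writes genes.gtf,
    peaks.narrowPeak, expr_oe.tsv, expr_kd.tsv, cohort.tsv, clinical.tsv and
    truth.json there.
    """
    genes = simulate_annotation(config)
    manifest = plant_truth(config, genes)
    peaks = simulate_peaks(config, genes, manifest)
    oe, kd = simulate_contrasts(config, manifest)
    cohort = simulate_cohort(config, manifest)
    clinical = simulate_survival(config, manifest, cohort)
    out = {
        "genes": genes,
        "peaks": peaks,
        "oe": oe,
        "kd": kd,
        "cohort": cohort,
        "clinical": clinical,
        "manifest": manifest,
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(genes, outdir / "genes.gtf")
        write_peaks(peaks, outdir / "peaks.narrowPeak")
        write_expression(oe, outdir / "expr_oe.tsv")
        write_expression(kd, outdir / "expr_kd.tsv")
        write_expression(cohort, outdir / "cohort.tsv")
        write_clinical(clinical, outdir / "clinical.tsv")
        write_manifest(manifest, outdir / "truth.json")
    return out
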