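"""End-to-end orchestration: peak pooling -> nearest-TSS annotation ->
perturbation contrasts -> cohort correlation -> candidate selection ->
survival screen, driven by one YAML/JSON config and fully reproducible.

Every stage logs its input/output row counts; the final ``report.json``
summarizes the promoter fraction, cross-contrast concordance, candidate
counts per selection basis and survival hits.  Reports contain no timestamps
or absolute paths, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_io, peak_tss, selection as selection_mod, survival as survival_mod
from .expression import (
    ContrastSpec,
    compute_ratio,
    cross_contrast_concordance,
    regulator_correlation,
)
from .simulate import SimulationConfig, simulate_all

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "validate_config", "load_config", "run_all"]

logger = logging.getLogger(__name__)

KNOWN_TOP_KEYS = {
    "seed",
    "simulate",
    "inputs",
    "contrasts",
    "regulator",
    "peaks",
    "selection",
    "survival",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every problem found."""


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``inputs`` (paths for
    genes/peaks/expr_oe/expr_kd/cohort/clinical, plus ``contrasts`` sample
    groups and the ``regulator`` id) must be provided.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict | None = None
    contrasts: dict | None = None
    regulator: str | None = None
    pool_mode: str = "union_merge"
    merge_gap: int = 0
    reference_point: str = "midpoint"
    sign_convention: str = "upstream_negative"
    promoter_window: int = 2000
    hist_bin_width: int = 500
    hist_max_bp: int = 10000
    pseudocount: float = 1.0
    correlation_method: str = "pearson"
    selection: selection_mod.SelectionParams = field(default_factory=selection_mod.SelectionParams)
    survival_alpha: float = 0.05
    run_survival: bool = True

    def to_echo_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "inputs": self.inputs,
            "contrasts": self.contrasts,
            "regulator": self.regulator,
            "peaks": {
                "pool_mode": self.pool_mode,
                "merge_gap": self.merge_gap,
                "reference_point": self.reference_point,
                "sign_convention": self.sign_convention,
                "promoter_window": self.promoter_window,
                "hist_bin_width": self.hist_bin_width,
                "hist_max_bp": self.hist_max_bp,
            },
            "expression": {
                "pseudocount": self.pseudocount,
                "correlation_method": self.correlation_method,
            },
            "selection": dataclasses.asdict(self.selection),
            "survival": {"alpha": self.survival_alpha, "enabled": self.run_survival},
        }
        return d


_REQUIRED_INPUT_KEYS = ("genes", "peaks", "expr_oe", "expr_kd", "cohort", "clinical")


def _parse_config_dict(raw: dict):
    """Build a PipelineConfig from a raw mapping, collecting all errors."""
    errors: list[str] = []
    warnings: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"], warnings
    for key in raw:
        if key not in KNOWN_TOP_KEYS:
            warnings.append(f"unknown config key {key!r} ignored")

    cfg = PipelineConfig()
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
    else:
        cfg.seed = seed

    sim_raw = raw.get("simulate")
    inputs = raw.get("inputs")
    if sim_raw is None and inputs is None:
        errors.append("config must provide either a 'simulate' section or an 'inputs' section")
    if sim_raw is not None:
        try:
            sim_raw = dict(sim_raw)
            sim_raw.setdefault("seed", cfg.seed)
            cfg.simulate = SimulationConfig(**sim_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate section: {exc}")
    if inputs is not None:
        missing = [k for k in _REQUIRED_INPUT_KEYS if k not in inputs]
        if missing:
            errors.append(f"inputs section missing keys: {missing}")
        else:
            cfg.inputs = dict(inputs)
            paths = [inputs[k] for k in _REQUIRED_INPUT_KEYS if k != "peaks"]
            peak_paths = inputs["peaks"]
            if isinstance(peak_paths, (str, Path)):
                peak_paths = [peak_paths]
            cfg.inputs["peaks"] = list(peak_paths)
            for p in list(paths) + list(peak_paths):
                if not Path(p).exists():
                    errors.append(f"input path does not exist: {p}")
        if raw.get("regulator") is None:
            errors.append("inputs mode requires a 'regulator' gene id")
        if raw.get("contrasts") is None:
            errors.append("inputs mode requires a 'contrasts' section with oe/kd sample groups")
        else:
            for label in ("oe", "kd"):
                block = raw["contrasts"].get(label)
                if not block or "treatment" not in block or "control" not in block:
                    errors.append(f"contrasts.{label} must define 'treatment' and 'control' sample lists")
    cfg.regulator = raw.get("regulator")
    cfg.contrasts = raw.get("contrasts")

    peaks_opts = raw.get("peaks", {}) or {}
    cfg.pool_mode = peaks_opts.get("pool_mode", cfg.pool_mode)
    if cfg.pool_mode not in ("union_merge", "intersection"):
        errors.append(f"peaks.pool_mode must be union_merge or intersection, got {cfg.pool_mode!r}")
    cfg.merge_gap = peaks_opts.get("merge_gap", cfg.merge_gap)
    cfg.reference_point = peaks_opts.get("reference_point", cfg.reference_point)
    if cfg.reference_point not in peak_tss.REFERENCE_POINTS:
        errors.append(f"peaks.reference_point must be one of {peak_tss.REFERENCE_POINTS}")
    cfg.sign_convention = peaks_opts.get("sign_convention", cfg.sign_convention)
    if cfg.sign_convention not in peak_tss.SIGN_CONVENTIONS:
        errors.append(f"peaks.sign_convention must be one of {peak_tss.SIGN_CONVENTIONS}")
    cfg.promoter_window = peaks_opts.get("window", cfg.promoter_window)
    cfg.hist_bin_width = peaks_opts.get("hist_bin_width", cfg.hist_bin_width)
    cfg.hist_max_bp = peaks_opts.get("hist_max_bp", cfg.hist_max_bp)

    sel_raw = raw.get("selection", {}) or {}
    try:
        cfg.selection = selection_mod.SelectionParams(**sel_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"selection section: {exc}")

    surv_raw = raw.get("survival", {}) or {}
    cfg.survival_alpha = surv_raw.get("alpha", cfg.survival_alpha)
    cfg.run_survival = surv_raw.get("enabled", cfg.run_survival)
    if not (0 < cfg.survival_alpha < 1):
        errors.append(f"survival.alpha must be in (0,1), got {cfg.survival_alpha!r}")
    return cfg, errors, warnings


def validate_config(path):
    """Parse and validate a YAML/JSON config file.

    All problems are collected and reported together (never fail-fast);
    unknown keys are warnings, not errors.  Returns (config, warnings) or
    raises :class:`ConfigError` listing every error.
    """
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from None
    cfg, errors, warnings = _parse_config_dict(raw if raw is not None else {})
    for w in warnings:
        logger.warning(w)
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg, warnings


def load_config(source) -> PipelineConfig:
    """Accept a PipelineConfig, a raw dict, or a path to a config file."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, dict):
        cfg, errors, _ = _parse_config_dict(source)
        if errors:
            raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
        return cfg
    cfg, _ = validate_config(source)
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _round(x, digits=6):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return None
    return round(float(x), digits)


def run_all(config, outdir) -> dict:
    """Execute the full pipeline into ``outdir`` and return the report dict.

    Stages: (simulate) -> pool_peaks -> assign_nearest_tss -> histogram &
    promoter fraction -> occupancy -> contrasts -> concordance -> cohort
    correlation -> select_candidates -> survival screen on selected genes.
    Any stage error aborts with the stage name; partial outputs are retained.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tftarget")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report: dict = {"config": cfg.to_echo_dict(), "stages": {}}
    try:
        logger.info("resolved config: %s", json.dumps(cfg.to_echo_dict(), sort_keys=True, default=str))

        # -- inputs ---------------------------------------------------------
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            data = _stage("simulate")(simulate_all)(sim_cfg, outdir / "inputs")
            genes = data["genes"]
            peak_sets = [data["peaks"]]
            oe_matrix, kd_matrix = data["oe"], data["kd"]
            cohort, clinical = data["cohort"], data["clinical"]
            manifest = data["manifest"]
            regulator = manifest.regulator_gene_id
            k = sim_cfg.n_perturb_replicates
            contrasts = {
                "oe": {
                    "treatment": [f"OE_T{i + 1}" for i in range(k)],
                    "control": [f"OE_C{i + 1}" for i in range(k)],
                },
                "kd": {
                    "treatment": [f"KD_T{i + 1}" for i in range(k)],
                    "control": [f"KD_C{i + 1}" for i in range(k)],
                },
            }
            report["stages"]["simulate"] = {
                "n_genes": len(genes),
                "n_peaks": len(data["peaks"]),
                "n_true_targets": int(manifest.genes["is_true_target"].sum()),
                "reporter_gene": manifest.reporter_gene,
            }
        else:
            rd = _stage("read_inputs")
            genes = rd(genome_io.read_gene_models)(cfg.inputs["genes"], format="gtf")
            peak_sets = [
                rd(genome_io.read_peaks)(p, format=str(p).endswith(".narrowPeak") and "narrowPeak" or "bed",
                                         source_label=str(Path(p).stem))
                for p in cfg.inputs["peaks"]
            ]
            oe_matrix = rd(genome_io.read_expression)(cfg.inputs["expr_oe"], scale=cfg.inputs.get("expr_scale", "linear"))
            kd_matrix = rd(genome_io.read_expression)(cfg.inputs["expr_kd"], scale=cfg.inputs.get("expr_scale", "linear"))
            cohort = rd(genome_io.read_expression)(cfg.inputs["cohort"], scale=cfg.inputs.get("cohort_scale", "log2p1"))
            clinical = rd(genome_io.read_clinical)(cfg.inputs["clinical"])
            regulator = cfg.regulator
            contrasts = cfg.contrasts

        # -- peaks ----------------------------------------------------------
        pooled = _stage("pool_peaks")(peak_tss.pool_peaks)(peak_sets, mode=cfg.pool_mode, merge_gap=cfg.merge_gap)
        logger.info("pool_peaks: %d input peaks -> %d pooled loci", sum(map(len, peak_sets)), len(pooled))
        assigned = _stage("assign_nearest_tss")(peak_tss.assign_nearest_tss)(
            pooled, genes, reference_point=cfg.reference_point, sign_convention=cfg.sign_convention
        )
        assigned.to_frame().to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        hist = _stage("distance_histogram")(peak_tss.distance_histogram)(assigned, cfg.hist_bin_width, cfg.hist_max_bp)
        hist.to_frame().to_csv(outdir / "histogram.tsv", sep="\t", index=False)
        frac = _stage("promoter_fraction")(peak_tss.promoter_fraction)(assigned, cfg.promoter_window)
        occupancy = _stage("promoter_occupancy")(peak_tss.promoter_occupancy)(
            assigned, cfg.promoter_window, genes=genes
        )
        occupancy.to_csv(outdir / "occupancy.tsv", sep="\t")
        report["stages"]["peaks"] = {
            "n_pooled_loci": len(pooled),
            "n_assigned": frac.n_assigned,
            "n_unassigned": frac.n_unassigned,
            "promoter_fraction": _round(frac.fraction),
            "promoter_window": cfg.promoter_window,
            "n_upstream": hist.n_upstream,
            "n_downstream": hist.n_downstream,
        }

        # -- expression -----------------------------------------------------
        oe_spec = ContrastSpec("overexpression", tuple(contrasts["oe"]["treatment"]), tuple(contrasts["oe"]["control"]))
        kd_spec = ContrastSpec("knockdown", tuple(contrasts["kd"]["treatment"]), tuple(contrasts["kd"]["control"]))
        oe_res = _stage("contrast_oe")(compute_ratio)(oe_matrix, oe_spec, pseudocount=cfg.pseudocount)
        kd_res = _stage("contrast_kd")(compute_ratio)(kd_matrix, kd_spec, pseudocount=cfg.pseudocount)
        oe_res.table.to_csv(outdir / "contrast_oe.tsv", sep="\t")
        kd_res.table.to_csv(outdir / "contrast_kd.tsv", sep="\t")
        conc = _stage("concordance")(cross_contrast_concordance)(oe_res, kd_res)
        conc.points.to_csv(outdir / "concordance.tsv", sep="\t")
        corr = _stage("correlation")(regulator_correlation)(cohort, regulator, method=cfg.correlation_method)
        corr.table.to_csv(outdir / "correlation.tsv", sep="\t")
        report["stages"]["expression"] = {
            "n_genes_oe": len(oe_res.table),
            "n_genes_kd": len(kd_res.table),
            "concordance_r": _round(conc.r),
            "n_concordance_genes": conc.n_genes,
            "regulator": regulator,
            "n_cohort_samples": int(corr.table["n"].iloc[0]),
        }

        # -- selection ------------------------------------------------------
        records = _stage("select_candidates")(selection_mod.select_candidates)(
            occupancy, oe_res, kd_res, corr, cfg.selection
        )
        selection_mod.write_candidate_table(records, outdir / "candidates.tsv")
        basis_counts = {
            "consistent_change": sum(selection_mod.CONSISTENT_CHANGE in r.selection_basis for r in records),
            "high_correlation": sum(selection_mod.HIGH_CORRELATION in r.selection_basis for r in records),
            "both": sum(len(r.selection_basis) == 2 for r in records),
        }
        report["stages"]["selection"] = {
            "n_candidates": len(records),
            "basis_counts": basis_counts,
            "thresholds": dataclasses.asdict(cfg.selection),
        }

        # -- survival -------------------------------------------------------
        if cfg.run_survival:
            screen_genes = [r.gene_id for r in records if r.gene_id in cohort.gene_ids]
            if screen_genes:
                screen = _stage("survival_screen")(survival_mod.survival_screen)(cohort, clinical, screen_genes)
                screen.to_csv(outdir / "survival.tsv", sep="\t")
                tested = screen[screen["skip_reason"] == ""]
                hits = tested[tested["p"] < cfg.survival_alpha]
                report["stages"]["survival"] = {
                    "n_tested": len(tested),
                    "n_skipped": int((screen["skip_reason"] != "").sum()),
                    "n_hits": len(hits),
                    "alpha": cfg.survival_alpha,
                    "hit_genes": sorted(hits.index.tolist()),
                }
            else:
                report["stages"]["survival"] = {"n_tested": 0, "n_skipped": 0, "n_hits": 0,
                                                "alpha": cfg.survival_alpha, "hit_genes": []}

        with open(outdir / "report.json", "wt", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        logger.info("pipeline complete; report written")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
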