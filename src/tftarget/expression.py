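"""Perturbation fold-change ratios, cross-dataset concordance, cohort correlation
and the 2^-ddCt qPCR utility.

Contrast ratios are treatment/control means on the linear scale with an additive
pseudocount; cohort co-expression with the regulator is Pearson correlation on
log2(x+1) values (Spearman available).  Undefined quantities (zero variance)
propagate as NaN markers, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ExpressionMatrix

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "CorrelationResult",
    "ConcordanceResult",
    "compute_ratio",
    "cross_contrast_concordance",
    "regulator_correlation",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Treatment vs control sample groups for a perturbation contrast."""

    label: str  # "overexpression" or "knockdown"
    treatment_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        t, c = set(self.treatment_samples), set(self.control_samples)
        if not t or not c:
            raise ValueError("treatment and control sample sets must be non-empty")
        if t & c:
            raise ValueError(f"samples in both groups: {sorted(t & c)}")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = (set(self.treatment_samples) | set(self.control_samples)) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"contrast samples absent from matrix: {sorted(missing)}")


@dataclass
class ContrastResult:
    """Per-gene treatment/control ratios for one contrast (linear scale)."""

    label: str
    table: pd.DataFrame  # index gene_id, columns ratio, log2_ratio
    pseudocount: float

    @property
    def ratio(self) -> pd.Series:
        return self.table["ratio"]

    @property
    def log2_ratio(self) -> pd.Series:
        return self.table["log2_ratio"]


@dataclass
class CorrelationResult:
    """Per-gene correlation with the regulator across a cohort.

    ``r`` is NaN for genes whose expression has zero variance (undefined, not 0).
    """

    regulator: str
    table: pd.DataFrame  # index gene_id, columns r, n
    method: str = "pearson"

    @property
    def r(self) -> pd.Series:
        return self.table["r"]


@dataclass
class ConcordanceResult:
    """Paired per-gene perturbation responses and their Pearson correlation.

    ``points`` holds (oe_log2, kd_axis) per shared gene, where kd_axis is
    -log2(KD/Ctr) when the knockdown axis is flipped so that concordant
    regulation scores positive.
    """

    points: pd.DataFrame
    r: float
    n_genes: int
    kd_flipped: bool = True


def compute_ratio(
    matrix: ExpressionMatrix, contrast: ContrastSpec, pseudocount: float = 1.0
) -> ContrastResult:
    """Per-gene ratio (mean(treatment)+eps) / (mean(control)+eps) on the linear scale."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    contrast.validate_against(matrix)
    lin = matrix.to_linear().values
    mt = lin[list(contrast.treatment_samples)].mean(axis=1)
    mc = lin[list(contrast.control_samples)].mean(axis=1)
    ratio = (mt + pseudocount) / (mc + pseudocount)
    table = pd.DataFrame({"ratio": ratio, "log2_ratio": np.log2(ratio)})
    table.index.name = "gene_id"
    return ContrastResult(label=contrast.label, table=table, pseudocount=pseudocount)


def cross_contrast_concordance(
    oe: ContrastResult, kd: ContrastResult, flip_kd: bool = True
) -> ConcordanceResult:
    """Concordance of overexpression vs knockdown responses over shared genes.

    Pairs (log2(OE/Ctr), -log2(KD/Ctr)) per gene — the knockdown axis is
    flipped (default) so a gene induced by overexpression and repressed by
    knockdown scores positive on both axes.  Pearson r of the point cloud is
    returned; zero variance on either axis yields a NaN marker.
    """
    shared = oe.table.index.intersection(kd.table.index)
    shared = shared[oe.table.loc[shared, "ratio"].notna() & kd.table.loc[shared, "ratio"].notna()]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes with defined ratios, got {len(shared)}")
    x = oe.table.loc[shared, "log2_ratio"].to_numpy()
    y = kd.table.loc[shared, "log2_ratio"].to_numpy()
    if flip_kd:
        y = -y
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    points = pd.DataFrame({"oe_log2": x, "kd_axis": y}, index=shared)
    points.index.name = "gene_id"
    return ConcordanceResult(points=points, r=r, n_genes=len(shared), kd_flipped=flip_kd)


def regulator_correlation(
    matrix: ExpressionMatrix, regulator_gene: str, method: str = "pearson"
) -> CorrelationResult:
    """Correlation of every gene with the regulator across cohort samples.

    Computed on log2(x+1) values.  Genes with zero variance get NaN.  The
    regulator correlates with itself at exactly 1 when its variance is nonzero.
    """
    if regulator_gene not in matrix.gene_ids:
        raise ValueError(f"regulator {regulator_gene!r} absent from matrix")
    if len(matrix.sample_ids) < 3:
        raise ValueError("need >=3 samples for cohort correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    vals = matrix.to_log2p1().values.to_numpy(dtype=float)
    if method == "spearman":
        vals = stats.rankdata(vals, axis=1)
    reg = vals[matrix.gene_ids.index(regulator_gene)]
    n = vals.shape[1]
    regc = reg - reg.mean()
    reg_ss = float(regc @ regc)
    centered = vals - vals.mean(axis=1, keepdims=True)
    gene_ss = (centered**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ regc) / np.sqrt(gene_ss * reg_ss)
    r = np.where((gene_ss == 0) | (reg_ss == 0), np.nan, np.clip(r, -1.0, 1.0))
    if reg_ss > 0:
        r[matrix.gene_ids.index(regulator_gene)] = 1.0
    table = pd.DataFrame({"r": r, "n": n}, index=pd.Index(matrix.gene_ids, name="gene_id"))
    return CorrelationResult(regulator=regulator_gene, table=table, method=method)


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the treated condition minus the same
    difference in the control condition; the fold change is 2^-ddCt.
    """
    cts = (ct_target_treated, ct_reference_treated, ct_target_control, ct_reference_control)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_reference_treated) - (ct_target_control - ct_reference_control)
    return float(2.0 ** (-ddct))
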