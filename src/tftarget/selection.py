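"""Disjunctive candidate-target selection.

A gene becomes a candidate direct target of the regulator if it shows either
a consistent perturbation response (induced by overexpression AND repressed by
knockdown) or a high absolute cohort correlation with the regulator.  Promoter
occupancy is an optional additional gate: published target tables retain
long-range loci hundreds of kb from the TSS, so it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ContrastResult, CorrelationResult

__all__ = [
    "SelectionParams",
    "CandidateRecord",
    "classify_direction",
    "select_candidates",
    "write_candidate_table",
    "read_candidate_table",
]

logger = logging.getLogger(__name__)

CONSISTENT_CHANGE = "consistent_change"
HIGH_CORRELATION = "high_correlation"


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the disjunctive selection rule.

    oe_up_min / kd_down_max bound the perturbation ratios a positive target
    must reach; abs_r_min bounds |cohort r|; promoter_window defines "bound";
    require_promoter additionally gates selection on promoter occupancy.
    """

    oe_up_min: float = 1.5
    kd_down_max: float = 0.75
    abs_r_min: float = 0.20
    promoter_window: int = 2000
    require_promoter: bool = False

    def __post_init__(self) -> None:
        if not self.oe_up_min > 1:
            raise ValueError("oe_up_min must be > 1")
        if not (0 < self.kd_down_max < 1):
            raise ValueError("kd_down_max must be in (0, 1)")
        if not (0 <= self.abs_r_min <= 1):
            raise ValueError("abs_r_min must be in [0, 1]")
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be positive")


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the candidate-target table."""

    gene_id: str
    best_distance: int | None
    promoter_bound: bool
    kd_ratio: float
    oe_ratio: float
    cohort_r: float
    selection_basis: frozenset[str]
    rank_score: float


def classify_direction(oe_ratio: float, kd_ratio: float, params: SelectionParams) -> str:
    """Classify a gene's perturbation response direction.

    positive_target: induced by overexpression and repressed by knockdown;
    negative_target: the mirror image; unchanged: both ratios inside the
    (kd_down_max, oe_up_min) band around 1; otherwise inconsistent.
    """
    if oe_ratio <= 0 or kd_ratio <= 0:
        raise ValueError("ratios must be positive")
    if oe_ratio >= params.oe_up_min and kd_ratio <= params.kd_down_max:
        return "positive_target"
    if oe_ratio <= 1 / params.oe_up_min and kd_ratio >= 1 / params.kd_down_max:
        return "negative_target"
    band = (params.kd_down_max, params.oe_up_min)
    if band[0] < oe_ratio < band[1] and band[0] < kd_ratio < band[1]:
        return "unchanged"
    return "inconsistent"


def select_candidates(
    occupancy: pd.DataFrame,
    oe: ContrastResult,
    kd: ContrastResult,
    corr: CorrelationResult,
    params: SelectionParams = SelectionParams(),
) -> list[CandidateRecord]:
    """Apply the disjunctive rule over genes shared by all four inputs.

    ``occupancy`` is the per-gene table from :func:`tftarget.peak_tss.promoter_occupancy`.
    Genes absent from any expression input are excluded (their count is logged).
    Records are sorted by rank_score (|log2 OE| + |log2 KD| + |r|) descending,
    ties by gene_id; the score orders the table but never changes membership.
    """
    shared = (
        occupancy.index.intersection(oe.table.index)
        .intersection(kd.table.index)
        .intersection(corr.table.index)
    )
    universe = occupancy.index.union(oe.table.index).union(kd.table.index).union(corr.table.index)
    n_excluded = len(universe) - len(shared)
    if n_excluded:
        logger.info("select_candidates: %d genes absent from >=1 input excluded", n_excluded)
    if len(shared) == 0:
        raise ValueError("no genes shared across occupancy and expression inputs")

    records: list[CandidateRecord] = []
    for gid in shared:
        oe_ratio = float(oe.table.at[gid, "ratio"])
        kd_ratio = float(kd.table.at[gid, "ratio"])
        r = float(corr.table.at[gid, "r"])
        basis = set()
        if oe_ratio >= params.oe_up_min and kd_ratio <= params.kd_down_max:
            basis.add(CONSISTENT_CHANGE)
        if np.isfinite(r) and abs(r) >= params.abs_r_min:
            basis.add(HIGH_CORRELATION)
        bound = bool(occupancy.at[gid, "bound"])
        if not basis:
            continue
        if params.require_promoter and not bound:
            continue
        best = occupancy.at[gid, "best_distance"]
        best_distance = None if pd.isna(best) else int(best)
        score = abs(np.log2(oe_ratio)) + abs(np.log2(kd_ratio)) + (abs(r) if np.isfinite(r) else 0.0)
        records.append(
            CandidateRecord(
                gene_id=gid,
                best_distance=best_distance,
                promoter_bound=bound,
                kd_ratio=kd_ratio,
                oe_ratio=oe_ratio,
                cohort_r=r,
                selection_basis=frozenset(basis),
                rank_score=float(score),
            )
        )
    records.sort(key=lambda rec: (-rec.rank_score, rec.gene_id))
    return records


def candidates_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "best_distance": r.best_distance if r.best_distance is not None else pd.NA,
            "promoter_bound": r.promoter_bound,
            "kd_ratio": r.kd_ratio,
            "oe_ratio": r.oe_ratio,
            "cohort_r": r.cohort_r,
            "selection_basis": ",".join(sorted(r.selection_basis)),
            "rank_score": r.rank_score,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "best_distance",
            "promoter_bound",
            "kd_ratio",
            "oe_ratio",
            "cohort_r",
            "selection_basis",
            "rank_score",
        ],
    )
    df["best_distance"] = df["best_distance"].astype("Int64")
    return df


def write_candidate_table(records, path) -> None:
    """Write candidates as a TSV mirroring the published table layout.

    Columns: gene, distance-to-TSS, KD/Ctr, OE/Ctr, cohort r, plus the
    selection basis and rank score.  Deterministic ordering, fixed precision.
    """
    df = candidates_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def read_candidate_table(path) -> list[CandidateRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        records.append(
            CandidateRecord(
                gene_id=row["gene_id"],
                best_distance=None if pd.isna(row["best_distance"]) else int(row["best_distance"]),
                promoter_bound=bool(row["promoter_bound"]),
                kd_ratio=float(row["kd_ratio"]),
                oe_ratio=float(row["oe_ratio"]),
                cohort_r=float(row["cohort_r"]),
                selection_basis=frozenset(str(row["selection_basis"]).split(",")),
                rank_score=float(row["rank_score"]),
            )
        )
    return records
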