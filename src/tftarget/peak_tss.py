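"""Peak pooling and nearest-TSS assignment with signed distances.

The distance ``d`` between a peak's reference point and the nearest gene's TSS
is oriented by the gene's reading direction: under the default
``upstream_negative`` convention a peak upstream of the TSS has ``d < 0``.
The opposite convention is provided because published target tables sometimes
print upstream distances as positive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Peak

__all__ = [
    "PeakAssignment",
    "AssignmentSet",
    "DistanceHistogram",
    "PromoterFraction",
    "pool_peaks",
    "assign_nearest_tss",
    "distance_histogram",
    "promoter_fraction",
    "promoter_occupancy",
]

REFERENCE_POINTS = ("midpoint", "summit", "nearest_edge")
SIGN_CONVENTIONS = ("upstream_negative", "upstream_positive")


@dataclass(frozen=True)
class PeakAssignment:
    """A peak linked to its nearest gene with a signed, strand-oriented distance."""

    peak: Peak
    gene_id: str
    distance: int
    reference_point: str


@dataclass
class AssignmentSet:
    """Nearest-TSS assignments plus the peaks that could not be assigned.

    Peaks on chromosomes absent from the annotation are kept in ``unassigned``
    rather than silently dropped.
    """

    assignments: list[PeakAssignment]
    unassigned: list[Peak]

    def distances(self) -> np.ndarray:
        return np.array([a.distance for a in self.assignments], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peak": a.peak.name,
                "chrom": a.peak.chrom,
                "start": a.peak.start,
                "end": a.peak.end,
                "gene_id": a.gene_id,
                "distance": a.distance,
                "reference_point": a.reference_point,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(
            rows,
            columns=["peak", "chrom", "start", "end", "gene_id", "distance", "reference_point"],
        )


@dataclass
class DistanceHistogram:
    """Signed peak-to-TSS distance histogram over symmetric bins around zero."""

    bin_width: int
    max_bp: int
    counts: dict[float, int]  # keyed by signed bin midpoint
    n_out_of_range: int
    n_upstream: int
    n_downstream: int
    n_zero: int
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        mids = sorted(self.counts)
        return pd.DataFrame({"bin_midpoint": mids, "count": [self.counts[m] for m in mids]})


@dataclass
class PromoterFraction:
    fraction: float
    n_within: int
    n_assigned: int
    n_unassigned: int
    window: int


def pool_peaks(peak_sets, mode: str = "union_merge", merge_gap: int = 0) -> list[Peak]:
    """Pool several peak sets into one collection of disjoint, sorted loci.

    ``union_merge`` concatenates all sets and merges intervals whose gap is
    <= ``merge_gap`` (overlapping or touching intervals merge at gap 0).
    ``intersection`` keeps only merged loci that overlap at least one peak
    from every input set.
    """
    peak_sets = [list(ps) for ps in peak_sets]
    if not peak_sets or all(len(ps) == 0 for ps in peak_sets):
        raise ValueError("pool_peaks requires at least one non-empty peak set")
    if mode not in ("union_merge", "intersection"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")

    by_chrom: dict[str, list[tuple[int, int, int, float]]] = defaultdict(list)
    for set_idx, ps in enumerate(peak_sets):
        for p in ps:
            by_chrom[p.chrom].append((p.start, p.end, set_idx, p.signal))

    merged: list[Peak] = []
    counter = 0
    for chrom in sorted(by_chrom):
        intervals = sorted(by_chrom[chrom])
        cur_start, cur_end, cur_sets, cur_sig = (
            intervals[0][0],
            intervals[0][1],
            {intervals[0][2]},
            intervals[0][3],
        )
        blocks = []
        for start, end, set_idx, sig in intervals[1:]:
            if start - cur_end <= merge_gap:
                cur_end = max(cur_end, end)
                cur_sets.add(set_idx)
                cur_sig = max(cur_sig, sig)
            else:
                blocks.append((cur_start, cur_end, cur_sets, cur_sig))
                cur_start, cur_end, cur_sets, cur_sig = start, end, {set_idx}, sig
        blocks.append((cur_start, cur_end, cur_sets, cur_sig))
        for start, end, sets_hit, sig in blocks:
            if mode == "intersection" and len(sets_hit) < len(peak_sets):
                continue
            counter += 1
            merged.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"locus_{counter}",
                    signal=sig,
                    source_label="pooled",
                )
            )
    return merged


def _reference_points(peak: Peak, reference_point: str) -> list[int]:
    """Candidate reference coordinates for a peak; nearest_edge yields both edges."""
    if reference_point == "midpoint":
        return [peak.midpoint]
    if reference_point == "summit":
        if peak.summit_offset is None:
            return [peak.midpoint]  # fall back when no summit was called
        return [peak.start + peak.summit_offset]
    if reference_point == "nearest_edge":
        return [peak.start, peak.end - 1]
    raise ValueError(f"unknown reference_point {reference_point!r}")


def _nearest_gene(tss_sorted: np.ndarray, order: np.ndarray, genes_on_chrom, p: int):
    """Gene minimizing |p - tss|; ties broken by lexicographically smallest gene_id.

    Returns (gene, raw_offset).
    """
    i = int(np.searchsorted(tss_sorted, p))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(tss_sorted):
            d = abs(p - int(tss_sorted[j]))
            if best is None or d < best:
                best = d
    # all genes achieving |p - tss| == best (several genes may share a TSS)
    lo = int(np.searchsorted(tss_sorted, p - best, side="left"))
    hi = int(np.searchsorted(tss_sorted, p + best, side="right"))
    candidates = [genes_on_chrom[order[k]] for k in range(lo, hi) if abs(p - int(tss_sorted[k])) == best]
    gene = min(candidates, key=lambda g: g.gene_id)
    return gene, p - gene.tss


def assign_nearest_tss(
    peaks,
    genes,
    reference_point: str = "midpoint",
    sign_convention: str = "upstream_negative",
) -> AssignmentSet:
    """Assign each peak to the nearest TSS on its chromosome with a signed distance.

    The peak's reference coordinate ``p`` is its midpoint ``(start+end)//2``,
    its summit, or the TSS-closest edge.  The raw offset ``p - tss`` is
    oriented by the gene's strand (flipped on -), then by the sign convention.
    Equidistant TSSs break ties toward the lexicographically smallest gene_id;
    for ``nearest_edge``, an exact tie between the two edges prefers the
    upstream (negative-``d``) one, then the start edge.
    """
    genes = list(genes)
    peaks = list(peaks)
    if not genes:
        raise ValueError("no gene models supplied")
    if reference_point not in REFERENCE_POINTS:
        raise ValueError(f"unknown reference_point {reference_point!r}")
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(f"unknown sign_convention {sign_convention!r}")

    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    index: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
    for chrom, glist in by_chrom.items():
        tss = np.array([g.tss for g in glist], dtype=np.int64)
        order = np.argsort(tss, kind="stable")
        index[chrom] = (tss[order], order, glist)

    if peaks and not any(p.chrom in index for p in peaks):
        raise ValueError("peaks and gene models share no chromosome")

    assignments: list[PeakAssignment] = []
    unassigned: list[Peak] = []
    flip = -1 if sign_convention == "upstream_positive" else 1
    for peak in peaks:
        if peak.chrom not in index:
            unassigned.append(peak)
            continue
        tss_sorted, order, glist = index[peak.chrom]
        best = None  # (abs_d, gene_id, signed_d, gene)
        for p in _reference_points(peak, reference_point):
            gene, raw = _nearest_gene(tss_sorted, order, glist, p)
            oriented = raw if gene.strand == "+" else -raw
            d = flip * oriented
            key = (abs(d), gene.gene_id, d > 0)
            if best is None or key < best[0]:
                best = (key, d, gene)
        _, d, gene = best
        assignments.append(
            PeakAssignment(peak=peak, gene_id=gene.gene_id, distance=int(d), reference_point=reference_point)
        )
    return AssignmentSet(assignments=assignments, unassigned=unassigned)


def distance_histogram(assignments: AssignmentSet, bin_width: int, max_bp: int) -> DistanceHistogram:
    """Histogram of signed distances over half-open bins [k*w, (k+1)*w) in [-max_bp, max_bp)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_bp % bin_width != 0:
        raise ValueError("max_bp must be a multiple of bin_width")
    d = assignments.distances()
    n_bins_side = max_bp // bin_width
    counts: dict[float, int] = {}
    for k in range(-n_bins_side, n_bins_side):
        lo = k * bin_width
        counts[lo + bin_width / 2] = 0
    in_range = (d >= -max_bp) & (d < max_bp)
    for val in d[in_range]:
        k = int(np.floor(val / bin_width))
        counts[k * bin_width + bin_width / 2] += 1
    return DistanceHistogram(
        bin_width=bin_width,
        max_bp=max_bp,
        counts=counts,
        n_out_of_range=int((~in_range).sum()),
        n_upstream=int((d < 0).sum()),
        n_downstream=int((d > 0).sum()),
        n_zero=int((d == 0).sum()),
        n_total=len(d),
    )


def promoter_fraction(assignments: AssignmentSet, window: int = 2000) -> PromoterFraction:
    """Fraction of assigned peaks whose |d| <= window (inclusive).

    Unassigned peaks are excluded from the denominator but reported.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    d = assignments.distances()
    if len(d) == 0:
        raise ValueError("no assigned peaks; promoter fraction undefined")
    n_within = int((np.abs(d) <= window).sum())
    return PromoterFraction(
        fraction=n_within / len(d),
        n_within=n_within,
        n_assigned=len(d),
        n_unassigned=len(assignments.unassigned),
        window=window,
    )


def promoter_occupancy(assignments: AssignmentSet, window: int = 2000, genes=None) -> pd.DataFrame:
    """Per-gene promoter-occupancy table.

    ``bound`` is True iff at least one assignment to the gene has |d| <= window.
    ``best_distance`` is the assignment of minimal |d| (a tie between +d and -d
    resolves to the upstream, negative one).  Genes passed via ``genes`` that
    received no assignment appear with bound=False and missing best_distance.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    per_gene: dict[str, list[int]] = defaultdict(list)
    for a in assignments.assignments:
        per_gene[a.gene_id].append(a.distance)
    gene_ids = sorted(per_gene)
    if genes is not None:
        gene_ids = sorted({g.gene_id for g in genes} | set(per_gene))
    rows = []
    for gid in gene_ids:
        dists = per_gene.get(gid)
        if not dists:
            rows.append({"gene_id": gid, "bound": False, "best_distance": pd.NA})
            continue
        best = min(dists, key=lambda d: (abs(d), d))  # tie -> negative (upstream)
        rows.append(
            {
                "gene_id": gid,
                "bound": bool(min(abs(d) for d in dists) <= window),
                "best_distance": best,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "bound", "best_distance"])
    df["best_distance"] = df["best_distance"].astype("Int64")
    return df.set_index("gene_id")
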