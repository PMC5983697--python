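"""Median-bifurcation survival analysis: Kaplan-Meier curves, the log-rank
test, and an observed/expected hazard-ratio estimate.

A cohort is split at the median expression of one gene (ties go to the low
group) and overall survival of the two halves is compared.  The hazard ratio
is the O/E estimator (O1/E1)/(O2/E2) from the log-rank table, the standard
display statistic for this kind of two-group screen; no Cox model is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ClinicalTable, ExpressionMatrix

__all__ = [
    "GroupedSurvival",
    "LogRankResult",
    "median_split",
    "km_curve",
    "logrank_test",
    "survival_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupedSurvival:
    """Two disjoint (time, event) groups split at an expression median."""

    low: pd.DataFrame  # columns: time, event
    high: pd.DataFrame
    split_value: float
    n_dropped: int = 0  # samples present in only one of expression/clinical


@dataclass
class LogRankResult:
    """Two-group log-rank test with O/E decomposition and an O/E hazard ratio.

    ``hazard_ratio_low_vs_high`` and ``statistic`` are NaN when undefined
    (a zero observed/expected count, or zero variance).
    """

    statistic: float
    p_value: float
    observed_low: float
    expected_low: float
    observed_high: float
    expected_high: float
    hazard_ratio_low_vs_high: float
    variance: float

    def hr_confidence_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        """Approximate CI for the O/E hazard ratio via var(log HR) ~ 1/E1 + 1/E2."""
        if not np.isfinite(self.hazard_ratio_low_vs_high):
            return (float("nan"), float("nan"))
        se = np.sqrt(1.0 / self.expected_low + 1.0 / self.expected_high)
        z = stats.norm.ppf(1 - alpha / 2)
        log_hr = np.log(self.hazard_ratio_low_vs_high)
        return (float(np.exp(log_hr - z * se)), float(np.exp(log_hr + z * se)))


def median_split(expression_values: pd.Series, clinical: ClinicalTable) -> GroupedSurvival:
    """Bifurcate a cohort at the median expression of one gene.

    ``expression_values`` is keyed by sample id.  Samples with value <= median
    form the low group.  Samples present in only one input are dropped (count
    recorded); an all-identical expression vector is a degenerate split and
    raises.
    """
    clin = clinical.data.set_index("sample")
    shared = expression_values.index.intersection(clin.index)
    n_dropped = (len(expression_values) - len(shared)) + (len(clin) - len(shared))
    if n_dropped:
        logger.info("median_split: %d samples present in only one input dropped", n_dropped)
    if len(shared) < 2:
        raise ValueError("need >=2 samples shared between expression and clinical inputs")
    vals = expression_values.loc[shared].astype(float)
    if vals.nunique() == 1:
        raise ValueError("all expression values identical: degenerate median split")
    split = float(np.median(vals.to_numpy()))
    low_ids = vals.index[vals <= split]
    high_ids = vals.index[vals > split]
    if len(low_ids) == 0 or len(high_ids) == 0:
        raise ValueError("degenerate median split: one group is empty")
    low = clin.loc[low_ids, ["time", "event"]].reset_index(drop=True)
    high = clin.loc[high_ids, ["time", "event"]].reset_index(drop=True)
    return GroupedSurvival(low=low, high=high, split_value=split, n_dropped=n_dropped)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    At each distinct event time t with d_t events among n_t at risk,
    S <- S * (1 - d_t / n_t).  Censored subjects leave the risk set after
    their recorded time.  Returns a step table (time, survival) starting at
    (0, 1); survival is monotone non-increasing within [0, 1].
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need >=1 subject")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    out_t, out_s = [0.0], [1.0]
    s = 1.0
    n_at_risk = times.size
    i = 0
    while i < times.size:
        t = times[i]
        j = i
        d = 0
        while j < times.size and times[j] == t:
            d += events[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out_t.append(float(t))
            out_s.append(s)
        n_at_risk -= j - i
        i = j
    return pd.DataFrame({"time": out_t, "survival": out_s})


def _logrank_table(t1, e1, t2, e2):
    """Pooled O1, E1, V sums over distinct event times (group 1 = low)."""
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    e1, e2 = np.asarray(e1, dtype=int), np.asarray(e2, dtype=int)
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o1 = e1_exp = v = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        n = n1 + n2
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        d2 = int(((t2 == t) & (e2 == 1)).sum())
        d = d1 + d2
        o1 += d1
        e1_exp += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1_exp, v, float(e1.sum() + e2.sum())


def logrank_test(grouped: GroupedSurvival) -> LogRankResult:
    """Two-group log-rank test on a median-bifurcated cohort.

    At each distinct pooled event time j: E1j = dj * n1j / nj and
    Vj = dj * (n1j/nj) * (1 - n1j/nj) * (nj - dj) / (nj - 1); the statistic is
    (sum(O1j - E1j))^2 / sum(Vj), chi-square with 1 df.  The hazard ratio is
    (O1/E1)/(O2/E2), low vs high, NaN when any O or E term is zero.
    """
    if len(grouped.low) == 0 or len(grouped.high) == 0:
        raise ValueError("both groups must be non-empty")
    o1, e1, v, total_events = _logrank_table(
        grouped.low["time"], grouped.low["event"], grouped.high["time"], grouped.high["event"]
    )
    if total_events == 0:
        raise ValueError("no events in either group; log-rank test undefined")
    o2 = total_events - o1
    e2 = total_events - e1
    if v > 0:
        statistic = (o1 - e1) ** 2 / v
        p_value = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic = float("nan")
        p_value = float("nan")
    if min(o1, o2, e1, e2) > 0:
        hr = (o1 / e1) / (o2 / e2)
    else:
        hr = float("nan")
    return LogRankResult(
        statistic=float(statistic),
        p_value=p_value,
        observed_low=float(o1),
        expected_low=float(e1),
        observed_high=float(o2),
        expected_high=float(e2),
        hazard_ratio_low_vs_high=float(hr),
        variance=float(v),
    )


def survival_screen(
    matrix: ExpressionMatrix, clinical: ClinicalTable, genes=None
) -> pd.DataFrame:
    """Median-split + log-rank per gene.

    Returns a table (gene_id, n_low, n_high, statistic, p, hr, skip_reason);
    genes whose split is degenerate are reported with the reason instead of
    being dropped.
    """
    if genes is None:
        genes = matrix.gene_ids
    missing = [g for g in genes if g not in matrix.gene_ids]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    rows = []
    for gid in genes:
        vals = matrix.values.loc[gid]
        try:
            grouped = median_split(vals, clinical)
            res = logrank_test(grouped)
            rows.append(
                {
                    "gene_id": gid,
                    "n_low": len(grouped.low),
                    "n_high": len(grouped.high),
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "hr": res.hazard_ratio_low_vs_high,
                    "skip_reason": "",
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "gene_id": gid,
                    "n_low": 0,
                    "n_high": 0,
                    "statistic": float("nan"),
                    "p": float("nan"),
                    "hr": float("nan"),
                    "skip_reason": str(exc),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_low", "n_high", "statistic", "p", "hr", "skip_reason"]
    ).set_index("gene_id")
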