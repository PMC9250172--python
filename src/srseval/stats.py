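"""Paired statistical comparison of two planning techniques across a cohort.

Implements the paired two-tailed Wilcoxon signed-rank test (exact p by
enumeration of sign assignments for small effective n, normal approximation
with tie and continuity correction otherwise), per-metric cohort summary
tables with means/medians/ranges per arm, counts of which arm is lower,
median percent differences, and stratification by lesion count or total
tumor volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .dosimetry import PlanMetrics

__all__ = [
    "CohortRecord",
    "ComparisonResult",
    "wilcoxon_signed_rank",
    "percent_difference",
    "stratify",
    "compare_metric",
    "summarize_cohort",
    "DEFAULT_METRICS",
    "render_table",
]

#: Metric-name → attribute on PlanMetrics, in report order.
DEFAULT_METRICS: tuple[tuple[str, str], ...] = (
    ("coverage_percent", "coverage_percent"),
    ("ci", "ci"),
    ("gi", "gi"),
    ("ptv_mean_Gy", "ptv_mean_Gy"),
    ("d2_cumulative_Gy", "d2_cumulative_Gy"),
    ("brain_mean_Gy", "brain_mean_Gy"),
    ("v12_cm3", "v12_cm3"),
    ("v10_cm3", "v10_cm3"),
    ("v8_cm3", "v8_cm3"),
    ("v5_cm3", "v5_cm3"),
    ("hippocampus_L_mean_Gy", "hippocampus_L_mean_Gy"),
    ("hippocampus_R_mean_Gy", "hippocampus_R_mean_Gy"),
)


@dataclass
class CohortRecord:
    """One patient's paired plan metrics (technique A vs technique B)."""

    patient_id: str
    lesion_count: int
    total_gtv_cm3: float
    total_ptv_cm3: float
    metrics_a: PlanMetrics
    metrics_b: PlanMetrics

    def __post_init__(self) -> None:
        if self.lesion_count < 1:
            raise ValueError("lesion_count must be >= 1")

    def value(self, attr: str, arm: str) -> float | None:
        m = self.metrics_a if arm == "a" else self.metrics_b
        return getattr(m, attr)


@dataclass
class ComparisonResult:
    """Paired comparison of one metric across the cohort."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    wilcoxon_statistic: float
    p_value: float
    n_effective: int
    summary_a: dict
    summary_b: dict
    percent_difference_median: float
    count_a_lower: int
    count_b_lower: int
    ties: int

    @property
    def n(self) -> int:
        return len(self.values_a)


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

_EXACT_N_MAX = 12


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the sign pattern, zeros already removed."""
    ranks = rankdata(np.abs(d))  # midranks for ties
    return ranks, np.sign(d)


def _exact_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed p by exhaustive enumeration of all sign assignments.

    Enumerates W+ over all 2^n assignments of signs to the (mid)ranks and
    doubles the smaller tail (capped at 1), which handles tied ranks
    correctly where tabulated null distributions do not.
    """
    n = len(ranks)
    # W+ distribution via subset sums: iterate ranks, convolving outcomes
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    total = sums.size
    eps = 1e-9
    p_ge = np.count_nonzero(sums >= w_plus - eps) / total
    p_le = np.count_nonzero(sums <= w_plus + eps) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def _approx_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= ((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    # continuity correction shrinks |diff| by 0.5
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Paired two-tailed Wilcoxon signed-rank test.

    Zero differences are discarded (Wilcoxon's original treatment); |d|
    are ranked with midranks for ties; the statistic is W+ = sum of ranks
    of positive differences of ``a − b``.  ``mode``:

    * ``"exact"`` — enumeration of all sign assignments (any n);
    * ``"approx"`` — normal approximation with tie and continuity
      correction;
    * ``"auto"`` — exact for effective n ≤ 12, approximate otherwise.

    Returns ``(W+, two-tailed p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 0.0, 1.0
    if d.size < 2:
        warnings.warn("fewer than 2 nonzero differences; p = 1.0", stacklevel=2)
        ranks, signs = _signed_ranks(d)
        return float(ranks[signs > 0].sum()), 1.0
    ranks, signs = _signed_ranks(d)
    w_plus = float(ranks[signs > 0].sum())
    if mode == "exact" or (mode == "auto" and d.size <= _EXACT_N_MAX):
        p = _exact_two_tailed_p(ranks, w_plus)
    else:
        p = _approx_two_tailed_p(ranks, w_plus)
    return w_plus, p


def percent_difference(a: float, b: float) -> float:
    """Percent difference 100·(b − a)/b, with the b arm as denominator.

    By convention ``a`` is the steep-gradient (DCAT-like) arm and ``b``
    the shallower (VMAT-like) arm, so a positive value means the a arm is
    lower.  Undefined for b = 0.
    """
    if b == 0:
        raise ValueError("percent difference undefined for b = 0")
    return 100.0 * (b - a) / b


# --------------------------------------------------------------------------
# cohort summaries
# --------------------------------------------------------------------------

def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def compare_metric(
    records: list[CohortRecord], metric: str, attr: str | None = None,
    mode: str = "auto",
) -> ComparisonResult | None:
    """Paired comparison of one metric; None if no record carries it."""
    attr = attr or metric
    pairs = [
        (r.value(attr, "a"), r.value(attr, "b"))
        for r in records
        if r.value(attr, "a") is not None and r.value(attr, "b") is not None
    ]
    if not pairs:
        return None
    va = np.array([p[0] for p in pairs], dtype=float)
    vb = np.array([p[1] for p in pairs], dtype=float)
    d = va - vb
    n_eff = int(np.count_nonzero(d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = wilcoxon_signed_rank(va, vb, mode=mode)
    pct = [percent_difference(x, y) for x, y in pairs if y != 0]
    return ComparisonResult(
        metric=metric,
        values_a=va,
        values_b=vb,
        wilcoxon_statistic=stat,
        p_value=p,
        n_effective=n_eff,
        summary_a=_summary(va),
        summary_b=_summary(vb),
        percent_difference_median=float(np.median(pct)) if pct else 0.0,
        count_a_lower=int(np.count_nonzero(d < 0)),
        count_b_lower=int(np.count_nonzero(d > 0)),
        ties=int(np.count_nonzero(d == 0)),
    )


def stratify(
    records: list[CohortRecord],
    rule: str = "lesion_count",
    lesion_boundary: int = 10,
    gtv_threshold_cm3: float = 2.0,
) -> dict[str, list[CohortRecord]]:
    """Split a cohort into disjoint exhaustive strata.

    ``rule="lesion_count"``: patients with ≤ boundary lesions vs more
    (the clinical "2–10 vs > 10" split).  ``rule="total_gtv"``: total GTV
    below vs at-or-above a volume threshold.  ``rule="all"``: the identity
    partition.
    """
    if not records:
        raise ValueError("cannot stratify an empty cohort")
    if rule == "lesion_count":
        lo = [r for r in records if r.lesion_count <= lesion_boundary]
        hi = [r for r in records if r.lesion_count > lesion_boundary]
        return {f"2-{lesion_boundary} lesions": lo, f">{lesion_boundary} lesions": hi}
    if rule == "total_gtv":
        lo = [r for r in records if r.total_gtv_cm3 < gtv_threshold_cm3]
        hi = [r for r in records if r.total_gtv_cm3 >= gtv_threshold_cm3]
        return {
            f"total GTV <{gtv_threshold_cm3:g} cm3": lo,
            f"total GTV >={gtv_threshold_cm3:g} cm3": hi,
        }
    if rule == "all":
        return {"all": list(records)}
    raise ValueError(f"unknown stratification rule {rule!r}")


def summarize_cohort(
    records: list[CohortRecord],
    metrics: tuple[tuple[str, str], ...] = DEFAULT_METRICS,
    strata: dict[str, list[CohortRecord]] | None = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-metric, per-stratum paired summary table.

    One row per (stratum, metric): n, mean (SD), median, range per arm,
    Wilcoxon two-tailed p, how many patients each arm is lower in, and the
    median percent difference.  Row order is deterministic (strata in
    insertion order, metrics in the given order) and invariant to patient
    order.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    if strata is None:
        strata = {"all": list(records)}
    rows = []
    for sname, srecs in strata.items():
        for metric, attr in metrics:
            if not srecs:
                rows.append({"stratum": sname, "metric": metric, "n": 0})
                continue
            res = compare_metric(srecs, metric, attr, mode=mode)
            if res is None:
                rows.append({"stratum": sname, "metric": metric, "n": 0})
                continue
            rows.append(
                {
                    "stratum": sname,
                    "metric": metric,
                    "n": res.n,
                    "mean_a": res.summary_a["mean"],
                    "sd_a": res.summary_a["sd"],
                    "median_a": res.summary_a["median"],
                    "min_a": res.summary_a["min"],
                    "max_a": res.summary_a["max"],
                    "mean_b": res.summary_b["mean"],
                    "sd_b": res.summary_b["sd"],
                    "median_b": res.summary_b["median"],
                    "min_b": res.summary_b["min"],
                    "max_b": res.summary_b["max"],
                    "wilcoxon_statistic": res.wilcoxon_statistic,
                    "p_value": res.p_value,
                    "n_effective": res.n_effective,
                    "count_a_lower": res.count_a_lower,
                    "count_b_lower": res.count_b_lower,
                    "ties": res.ties,
                    "percent_difference_median": res.percent_difference_median,
                }
            )
    return pd.DataFrame(rows)


def render_table(report: pd.DataFrame, arm_a: str = "A", arm_b: str = "B") -> str:
    """Plain-text rendering of a summary table, one block per stratum."""
    lines = []
    for sname, sub in report.groupby("stratum", sort=False):
        lines.append(f"=== {sname} ===")
        lines.append(
            f"{'metric':<24}{arm_a + ' mean(SD)/median':>28}"
            f"{arm_b + ' mean(SD)/median':>28}{'p':>10}{'%diff':>8}"
        )
        for _, row in sub.iterrows():
            if row.get("n", 0) == 0:
                lines.append(f"{row['metric']:<24}{'(empty stratum)':>28}")
                continue
            a_txt = f"{row['mean_a']:.2f} ({row['sd_a']:.2f}) / {row['median_a']:.2f}"
            b_txt = f"{row['mean_b']:.2f} ({row['sd_b']:.2f}) / {row['median_b']:.2f}"
            lines.append(
                f"{row['metric']:<24}{a_txt:>28}{b_txt:>28}"
                f"{row['p_value']:>10.4f}{row['percent_difference_median']:>8.1f}"
            )
        lines.append("")
    return "\n".join(lines)
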