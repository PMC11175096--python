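"""Cohort statistics: paired pre/post tests and PROM correlations.

Because the movement-quality parameters are generally non-normal in small
cohorts, the analysis is rank-based throughout: Wilcoxon signed-rank tests
compare baseline against follow-up for each of the five parameters, and
Spearman rank correlations relate each follow-up parameter to follow-up
disability (Quick DASH total) and pain severity (Quick DASH item 9).
Correlation strength is labelled by |rs|: [0, 0.25) little-to-no,
[0.25, 0.5) fair, [0.5, 0.75) moderate-to-good, [0.75, 1] good-to-excellent
(left-closed bands; the band edges themselves fall upward).  Alpha defaults
to 0.05 and no multiplicity adjustment is applied by default; Holm
adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "CorrelationResult",
    "CohortStats",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "classify_strength",
    "normality_report",
    "run_group_analysis",
    "STRENGTH_BANDS",
]

STRENGTH_BANDS = (
    (0.00, 0.25, "little-to-no"),
    (0.25, 0.50, "fair"),
    (0.50, 0.75, "moderate-to-good"),
    (0.75, 1.00 + 1e-12, "good-to-excellent"),
)

#: exact null distribution is used up to this many nonzero differences
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank result for one movement-quality parameter."""

    metric: str
    n_pairs: int
    n_zero_dropped: int
    statistic: float
    p_value: float
    median_difference: float
    method: str  # "exact" | "approx" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of one parameter with one PROM."""

    prom: str  # "disability" | "pain"
    metric: str
    n: int
    rs: float
    p_value: float
    strength: str
    significant: bool


@dataclass
class CohortStats:
    """Bundle of all paired comparisons and correlations for a cohort."""

    paired: list[PairedComparison] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    alpha: float = 0.05
    n_subjects: int = 0

    def paired_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.paired])

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.correlations])


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, metric: str = ""
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention) and their count
    reported.  The exact null distribution is used when the effective n is
    <= 25 and there are no tied |differences|; otherwise the normal
    approximation with tie and continuity corrections.  If every difference
    is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 1")
    d = y - x
    nz = d != 0
    n_eff = int(nz.sum())
    n_zero = len(d) - n_eff
    if n_eff == 0:
        return PairedComparison(
            metric=metric,
            n_pairs=len(d),
            n_zero_dropped=n_zero,
            statistic=0.0,
            p_value=1.0,
            median_difference=0.0,
            method="degenerate",
        )
    dd = d[nz]
    has_ties = len(np.unique(np.abs(dd))) < len(dd)
    if n_eff <= EXACT_N_MAX and not has_ties:
        method = "exact"
        res = sps.wilcoxon(dd, zero_method="wilcox", method="exact")
    else:
        method = "approx"
        res = sps.wilcoxon(dd, zero_method="wilcox", correction=True, method="approx")
    return PairedComparison(
        metric=metric,
        n_pairs=len(d),
        n_zero_dropped=n_zero,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(d)),
        method=method,
    )


def spearman_rho(
    x: np.ndarray,
    y: np.ndarray,
    prom: str = "",
    metric: str = "",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Mid-ranks make the estimate tie-safe.  Zero rank variance in either
    argument (a constant input) is undefined and raised as an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    rs = float(res.statistic)
    p = float(res.pvalue)
    return CorrelationResult(
        prom=prom,
        metric=metric,
        n=len(x),
        rs=rs,
        p_value=p,
        strength=classify_strength(rs),
        significant=bool(p < alpha),
    )


def classify_strength(rs: float) -> str:
    """Correlation-strength label from |rs| (left-closed bands)."""
    a = abs(float(rs))
    if a > 1:
        raise ValueError(f"|rs| must be <= 1, got {rs}")
    for lo, hi, label in STRENGTH_BANDS:
        if lo <= a < hi:
            return label
    return STRENGTH_BANDS[-1][2]  # a == 1 within fp slack


def normality_report(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Descriptive normality screen (Shapiro–Wilk + skewness/kurtosis).

    Purely informational: the analysis is fixed as non-parametric and this
    report never switches the tests.  It replaces a by-eye histogram /
    Q-Q inspection with a reproducible table.
    """
    rows = []
    for name, v in values.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append({"variable": name, "n": len(v), "shapiro_w": np.nan,
                         "shapiro_p": np.nan, "skewness": np.nan, "kurtosis": np.nan})
            continue
        w, p = sps.shapiro(v)
        rows.append(
            {
                "variable": name,
                "n": len(v),
                "shapiro_w": float(w),
                "shapiro_p": float(p),
                "skewness": float(sps.skew(v)),
                "kurtosis": float(sps.kurtosis(v)),
            }
        )
    return pd.DataFrame(rows)


def run_group_analysis(
    records: list,
    alpha: float = 0.05,
    holm: bool = False,
) -> CohortStats:
    """Full cohort analysis over complete subject records.

    Produces one paired baseline-vs-follow-up comparison per movement-
    quality parameter and, at the follow-up timepoint only, Spearman
    correlations of each parameter with disability (Quick DASH total) and
    pain (item 9).  Subjects missing a value for a given analysis are
    dropped pairwise-complete, so one failed metric does not remove a
    subject from the others.  ``holm`` optionally applies Holm step-down
    adjustment within each of the two analysis families.
    """
    from .metrics import METRIC_NAMES  # avoid cycle at import time

    usable = [r for r in records if r.included and r.baseline is not None
              and r.followup is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 complete included subjects, got {len(usable)}"
        )
    out = CohortStats(alpha=alpha, n_subjects=len(usable))
    for name in METRIC_NAMES:
        pre = np.array([getattr(r.baseline, name) for r in usable], dtype=float)
        post = np.array([getattr(r.followup, name) for r in usable], dtype=float)
        ok = np.isfinite(pre) & np.isfinite(post)
        out.paired.append(wilcoxon_signed_rank(pre[ok], post[ok], metric=name))
    prom_values = {
        "disability": np.array(
            [r.followup_quickdash for r in usable], dtype=float
        ),
        "pain": np.array([r.followup_pain for r in usable], dtype=float),
    }
    for prom_name, prom in prom_values.items():
        for name in METRIC_NAMES:
            vals = np.array([getattr(r.followup, name) for r in usable], dtype=float)
            ok = np.isfinite(vals) & np.isfinite(prom)
            try:
                res = spearman_rho(prom[ok], vals[ok], prom=prom_name,
                                   metric=name, alpha=alpha)
            except ValueError:  # zero rank variance: undefined, flagged
                res = CorrelationResult(
                    prom=prom_name, metric=name, n=int(ok.sum()),
                    rs=float("nan"), p_value=float("nan"),
                    strength="undefined", significant=False,
                )
            out.correlations.append(res)
    if holm:
        _holm_adjust(out)
    return out


def _holm_adjust(stats: CohortStats) -> None:
    """Holm step-down within each family; updates significance in place."""
    for family in (stats.paired, stats.correlations):
        ps = np.array([f.p_value for f in family])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * ps[i])
            adj[i] = min(1.0, running)
        for i, f in enumerate(family):
            object.__setattr__(f, "p_value", float(adj[i]))
            if isinstance(f, CorrelationResult):
                object.__setattr__(f, "significant", bool(adj[i] < stats.alpha))
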