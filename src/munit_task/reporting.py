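"""Session-level summaries and report statistics.

Aggregates per-trial metrics into per-target hit rates, unintended-hit
rates (which may exceed 100% because re-entries count separately),
performance medians and quartiles, and direct-movement fractions; and
wraps the nonparametric report statistics (two-sided Wilcoxon signed-rank,
Friedman with Bonferroni-corrected post-hoc Wilcoxon, Spearman
correlation).  The original study's linear mixed model for threshold
differences is replaced here by a paired Wilcoxon on per-session mean
differences — an explicit substitute, not a reimplementation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TARGET_IDS

__all__ = ["SessionSummary", "StatResult", "FriedmanResult",
           "summarize_session", "wilcoxon_paired", "friedman_test",
           "spearman_corr"]


@dataclass(frozen=True)
class StatResult:
    name: str
    statistic: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float
    n: int
    posthoc: List[StatResult] = field(default_factory=list)


@dataclass(frozen=True)
class SessionSummary:
    """Per-target aggregates of one session."""

    per_target: Dict[str, Dict[str, float]]
    n_trials: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_target).T


def summarize_session(metrics: pd.DataFrame) -> SessionSummary:
    """Aggregate a per-trial metrics table (see
    :func:`munit_task.metrics.session_metrics`)."""
    if len(metrics) == 0:
        raise ValueError("no trials to summarise")
    per_target: Dict[str, Dict[str, float]] = {}
    for tid in TARGET_IDS:
        sub = metrics[metrics["target"] == tid]
        if len(sub) == 0:
            warnings.warn(f"no trials for target {tid}; omitted")
            continue
        n = len(sub)
        entry = {
            "n_trials": float(n),
            "target_hit_rate": 100.0 * sub["target_hit"].sum() / n,
            "angle_hit_rate": 100.0 * sub["angle_hit"].sum() / n,
            "performance_median": float(sub["normalized"].median()),
            "performance_q25": float(sub["normalized"].quantile(0.25)),
            "performance_q75": float(sub["normalized"].quantile(0.75)),
        }
        direct = sub["direct"].dropna()
        if len(direct):
            entry["direct_fraction"] = 100.0 * direct.astype(bool).sum() / len(direct)
        for col in metrics.columns:
            if col.startswith("unintended_"):
                entry[f"{col}_rate"] = 100.0 * float(sub[col].sum()) / n
        per_target[tid] = entry
    return SessionSummary(per_target=per_target, n_trials=len(metrics))


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    stat, p = stats.wilcoxon(x, y, zero_method="zsplit",
                             alternative="two-sided")
    return StatResult("wilcoxon_signed_rank", float(stat), float(p), x.size)


def friedman_test(*samples: Sequence[float],
                  posthoc: bool = True) -> FriedmanResult:
    """Friedman test across repeated measures, with Bonferroni-corrected
    pairwise Wilcoxon post-hoc tests."""
    arrs = [np.asarray(s, dtype=float) for s in samples]
    if len(arrs) < 3:
        raise ValueError("Friedman test needs at least 3 samples")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("paired samples must have equal length")
    stat, p = stats.friedmanchisquare(*arrs)
    tests: List[StatResult] = []
    if posthoc:
        k = len(arrs) * (len(arrs) - 1) // 2
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                t = wilcoxon_paired(arrs[i], arrs[j])
                tests.append(StatResult(f"wilcoxon_{i}_vs_{j}", t.statistic,
                                        min(1.0, t.pvalue * k), t.n))
    return FriedmanResult(statistic=float(stat), pvalue=float(p), n=n,
                          posthoc=tests)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    rho, p = stats.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), x.size)
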