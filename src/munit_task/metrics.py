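"""Trial-level analyses of the cursor task.

Implements the distance-angle performance metric with best/worst
normalisation, the nearest miss, unintended target and angle hits, the
direct-movement classification, the three-stage characteristic forces and
the within-session learning correlation.

The per-buffer performance summand is ``(d/dmax)^2 + (phi/phimax)^2``
where ``d`` is the cursor-to-target-centre distance and ``phi`` the
absolute cursor-target angle in degrees (``phi := phimax`` at the origin);
the trial score is the sum over all recorded buffers (lower is better) and
is normalised to [0, 1] by per-target worst (origin-hold for the full
20 s) and best (idealised discharge pattern) scores.  Because the typeset
formula is ambiguous about a per-buffer square root, a root-sum-square
variant is available through ``variant="rss"``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpikeTrain
from .engine import (REGION_ANGLE, REGION_TARGET, BufferConfig,
                     SessionRecord, SessionTrial, TargetGeometry, TrialRecord,
                     buffer_rates, cursor_angle_deg, cursor_positions,
                     point_region_test, run_trial, trailing_mean)
from .recruitment import force_at_event

__all__ = [
    "PerformanceResult", "StageForces", "performance_raw",
    "performance_bounds", "performance_normalized", "evaluate_performance",
    "nearest_miss", "unintended_hits", "classify_direct", "stage_forces",
    "learning_correlation", "session_metrics",
]

VARIANTS = ("sum", "rss")


@dataclass(frozen=True)
class PerformanceResult:
    """Raw and normalised performance of one trial."""

    raw: float
    best_raw: float
    worst_raw: float
    normalized: float


@dataclass(frozen=True)
class StageForces:
    """Characteristic forces (%MVC) of the three-stage TIII strategy:
    stage-1 peak with both units active, stage-2 minimum with only the
    higher-threshold unit firing, stage-3 hold force preceding the hit."""

    f1: float
    f2: float
    f3: float


def _per_buffer_scores(positions: np.ndarray, geom: TargetGeometry,
                       variant: str = "sum") -> np.ndarray:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    c = geom.center_arr
    d = np.hypot(pos[:, 0] - c[0], pos[:, 1] - c[1]) / geom.dmax
    phi = np.array([cursor_angle_deg(p, geom) for p in pos]) / geom.phi_max
    s = d ** 2 + phi ** 2
    return np.sqrt(s) if variant == "rss" else s


def performance_raw(trial: TrialRecord, geom: TargetGeometry,
                    variant: str = "sum") -> float:
    """Raw performance score: per-buffer distance/angle summands summed
    over all buffers from target onset to trial end (lower is better)."""
    if trial.n_buffers < 1:
        raise ValueError("trial must contain at least one buffer")
    return float(_per_buffer_scores(trial.positions, geom, variant).sum())


def performance_bounds(geom: TargetGeometry, cfg: BufferConfig,
                       variant: str = "sum") -> Tuple[float, float]:
    """Per-target (best_raw, worst_raw) normalisation bounds.

    Worst: cursor held at the origin for the entire timeout.  Best: the
    deterministic trajectory obtained by feeding constant per-buffer rates
    matching the target centre through the cursor engine until the trial
    engine reports the hit.
    """
    origin = np.zeros((cfg.timeout_buffers, 2))
    worst = float(_per_buffer_scores(origin, geom, variant).sum())
    n = cfg.timeout_buffers + 2 * cfg.hold_buffers
    rates = np.tile(np.asarray(geom.center, dtype=float), (n, 1))
    stream = cursor_positions(rates, ref_rates=(1.0, 1.0), gains=(1.0, 1.0),
                              cfg=cfg)
    trial = run_trial(stream, geom, cfg)
    if not trial.target_hit:
        raise ValueError("idealised trajectory failed to hit the target; "
                         "engine configuration is inconsistent")
    best = performance_raw(trial, geom, variant)
    if not best < worst:
        raise ValueError("degenerate performance bounds")
    return best, worst


def performance_normalized(raw: float, bounds: Tuple[float, float]) -> float:
    """Scale a raw score to [0, 1]: ``(worst - raw) / (worst - best)``,
    clipped (an erratic real trajectory can transiently exceed the
    origin-hold worst case)."""
    best, worst = bounds
    if not worst > best:
        raise ValueError("worst_raw must exceed best_raw")
    return float(np.clip((worst - raw) / (worst - best), 0.0, 1.0))


def evaluate_performance(trial: TrialRecord, geom: TargetGeometry,
                         cfg: BufferConfig,
                         variant: str = "sum") -> PerformanceResult:
    raw = performance_raw(trial, geom, variant)
    best, worst = performance_bounds(geom, cfg, variant)
    return PerformanceResult(raw=raw, best_raw=best, worst_raw=worst,
                             normalized=performance_normalized(raw, (best, worst)))


def nearest_miss(trial: TrialRecord, geom: TargetGeometry,
                 cfg: BufferConfig) -> Optional[np.ndarray]:
    """Average cursor position over the 875 ms (hold-length) window with
    the shortest distance to the target centre; earliest window on ties.
    Only defined for trials without a target hit; ``None`` when the trial
    is shorter than the hold window."""
    if trial.target_hit:
        raise ValueError("nearest miss is undefined for hit trials")
    w = cfg.hold_buffers
    if trial.n_buffers < w:
        return None
    means = trailing_mean(trial.positions, w)[w - 1:]
    c = geom.center_arr
    d = np.hypot(means[:, 0] - c[0], means[:, 1] - c[1])
    return means[int(np.argmin(d))].copy()


def unintended_hits(trial: TrialRecord, geoms: Dict[str, TargetGeometry],
                    cfg: BufferConfig) -> Dict[str, Dict[str, int]]:
    """Counts of unintended hits per unselected target.

    A hit is a maximal in-region excursion lasting at least the hold
    window; re-entries count separately.  Counted independently for the
    target discs and the angle wedges (the disc counts as inside its
    wedge)."""
    out: Dict[str, Dict[str, int]] = {}
    for tid, geom in geoms.items():
        if tid == trial.target_id:
            continue
        regions = [point_region_test(p, geom) for p in trial.positions]
        in_target = np.array([r == REGION_TARGET for r in regions])
        in_wedge = np.array([r in (REGION_TARGET, REGION_ANGLE)
                             for r in regions])
        out[tid] = {"target": _count_long_runs(in_target, cfg.hold_buffers),
                    "angle": _count_long_runs(in_wedge, cfg.hold_buffers)}
    return out


def _count_long_runs(mask: np.ndarray, min_len: int) -> int:
    if mask.size == 0:
        return 0
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int(np.sum((ends - starts) >= min_len))


def classify_direct(trial: TrialRecord,
                    trains: Sequence[SpikeTrain]) -> Optional[bool]:
    """Direct-movement classification of a successful TI or TIII attempt.

    A TI attempt is direct iff MU2 discharged zero spikes from target onset
    to the qualifying (target or angle) hit; a TIII attempt iff MU1
    discharged zero spikes.  Returns ``None`` for TII or for trials without
    at least an angle hit (not applicable).
    """
    if trial.target_id == "TI":
        other = trains[1]
    elif trial.target_id == "TIII":
        other = trains[0]
    else:
        return None
    hit_b = (trial.target_hit_buffer if trial.target_hit
             else trial.angle_hit_buffer)
    if hit_b is None:
        return None
    t_end = float(trial.t[hit_b])
    return other.count_between(trial.onset_time, t_end) == 0


def stage_forces(st: SessionTrial, cfg: BufferConfig,
                 rate_thresh: float = 5.0,
                 window: float = 100.0) -> Optional[StageForces]:
    """Characteristic forces of an indirect TIII target hit.

    f1: 100 ms mean force centred at the maximum force while both units'
    trailing 1 s rates exceed ``rate_thresh``; f2: 100 ms mean at the
    minimum force in the MU1-silent / MU2-firing epoch after the
    both-active epoch; f3: mean force over the hold period preceding the
    hit.  ``None`` when a required epoch is absent (e.g. a direct hit with
    no both-active phase, or no target hit at all).
    """
    trial = st.trial
    if trial.target_id != "TIII" or not trial.target_hit:
        return None
    hit_b_abs = st.onset_buffer + trial.target_hit_buffer
    avg = st.stream.avg_rates[:hit_b_abs + 1]
    t_buf = st.stream.t[:hit_b_abs + 1]
    active1 = avg[:, 0] > rate_thresh
    active2 = avg[:, 1] > rate_thresh
    both = active1 & active2
    if not both.any():
        return None
    force_at_buffers = st.force.value_at(t_buf)
    cand = np.flatnonzero(both)
    b1 = int(cand[np.argmax(force_at_buffers[cand])])
    # end of the both-active run containing the force maximum
    run_end = b1
    while run_end + 1 < both.size and both[run_end + 1]:
        run_end += 1
    after = np.arange(both.size) > run_end
    m2 = (~active1) & active2 & after
    if not m2.any():
        return None
    cand2 = np.flatnonzero(m2)
    b2 = int(cand2[np.argmin(force_at_buffers[cand2])])
    f1 = force_at_event(st.force, float(t_buf[b1]), window=window)
    f2 = force_at_event(st.force, float(t_buf[b2]), window=window)
    t_hit = float(trial.t[trial.target_hit_buffer])
    t_hold0 = t_hit - cfg.hold_buffers * cfg.buffer_s
    i0 = int(np.ceil((t_hold0 - st.force.t0) * st.force.fs - 1e-9))
    i1 = int(np.floor((t_hit - st.force.t0) * st.force.fs + 1e-9))
    f3 = float(st.force.values[max(i0, 0):i1 + 1].mean())
    return StageForces(f1=f1, f2=f2, f3=f3)


def learning_correlation(performances: Sequence[float]) -> float:
    """Spearman rank correlation between trial index and performance
    (within-session learning)."""
    perf = np.asarray(performances, dtype=float)
    if perf.size < 3:
        raise ValueError("need at least 3 trials")
    if np.allclose(perf, perf[0]):
        warnings.warn("constant performances; correlation undefined, "
                      "returning 0")
        return 0.0
    rho, _ = stats.spearmanr(np.arange(perf.size), perf)
    return float(rho)


def session_metrics(session: SessionRecord,
                    geoms: Dict[str, TargetGeometry],
                    variant: str = "sum") -> pd.DataFrame:
    """Per-trial metrics table for a closed-loop session."""
    cfg = session.cfg
    bounds = {tid: performance_bounds(g, cfg, variant)
              for tid, g in geoms.items()}
    rows = []
    for k, st in enumerate(session.trials):
        trial = st.trial
        geom = geoms[trial.target_id]
        raw = performance_raw(trial, geom, variant)
        norm = performance_normalized(raw, bounds[trial.target_id])
        nm = (nearest_miss(trial, geom, cfg)
              if not trial.target_hit else None)
        direct = classify_direct(trial, st.trains)
        sf = stage_forces(st, cfg)
        unint = unintended_hits(trial, geoms, cfg)
        row = {
            "trial_id": k, "target": trial.target_id,
            "outcome": trial.outcome,
            "target_hit": trial.target_hit, "angle_hit": trial.angle_hit,
            "raw": raw, "normalized": norm,
            "nearest_miss_x": None if nm is None else float(nm[0]),
            "nearest_miss_y": None if nm is None else float(nm[1]),
            "direct": direct,
            "f1": None if sf is None else sf.f1,
            "f2": None if sf is None else sf.f2,
            "f3": None if sf is None else sf.f3,
            "n_buffers": trial.n_buffers,
        }
        for tid, counts in unint.items():
            row[f"unintended_{tid}_target"] = counts["target"]
            row[f"unintended_{tid}_angle"] = counts["angle"]
        rows.append(row)
    return pd.DataFrame(rows)
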