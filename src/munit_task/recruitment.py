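"""Recruitment/de-recruitment threshold estimation from force ramps.

Operationalises the ramp analysis: the onset of MU activity is the first
spike that begins a run of at least two discharges at 5 pps or above
(inter-spike interval <= 200 ms); the offset is the last discharge before
the unit stays silent for at least 1.5 s; threshold forces are 100 ms
window averages centred on those events; units are ranked by ascending
onset force; reference discharge rates come from the 10 %MVC plateau.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ForceTrace, SpikeTrain

__all__ = [
    "ThresholdEstimate", "detect_onset", "detect_offset", "force_at_event",
    "rank_pool", "estimate_reference_rate", "select_pairs", "PairSelection",
    "emg_envelope", "pre_post_change", "thresholds_table",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per-unit ramp estimates: event times, threshold forces, rank and
    reference rate (pps at the 10 %MVC plateau)."""

    unit_id: str
    t_on: float
    f_on: float
    rank: int
    t_off: Optional[float] = None
    f_off: Optional[float] = None
    ref_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_off is not None and not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")


def detect_onset(train: SpikeTrain, rate_thresh: float = 5.0) -> Optional[float]:
    """Time of the first spike starting a run of >= 2 spikes with
    ISI <= ``1/rate_thresh``; ``None`` if no such run exists."""
    t = train.times
    if t.size < 2:
        warnings.warn(f"unit {train.unit_id}: fewer than 2 spikes, no onset")
        return None
    isi = np.diff(t)
    qualifying = np.flatnonzero(isi <= 1.0 / rate_thresh)
    if qualifying.size == 0:
        return None
    return float(t[qualifying[0]])


def detect_offset(train: SpikeTrain, horizon_end: float,
                  silence: float = 1.5) -> Optional[float]:
    """Time of the last spike of the final activation episode: the last
    discharge followed by a silent gap of at least ``silence`` seconds
    (the gap to ``horizon_end`` counts)."""
    t = train.times
    if t.size == 0:
        return None
    gaps = np.diff(np.concatenate([t, [horizon_end]]))
    qualifying = np.flatnonzero(gaps >= silence)
    if qualifying.size == 0:
        return None
    return float(t[qualifying[-1]])


def force_at_event(force: ForceTrace, t: float, window: float = 100.0) -> float:
    """Mean force in a closed ``window``-ms interval centred on ``t``."""
    half = window / 1000.0 / 2.0
    lo, hi = t - half, t + half
    if lo < force.t0 - 1e-9:
        raise ValueError(
            f"window overhangs trace start by {force.t0 - lo:.4f} s")
    last = force.t0 + (len(force) - 1) / force.fs
    if hi > last + 1e-9:
        raise ValueError(f"window overhangs trace end by {hi - last:.4f} s")
    i0 = int(np.ceil((lo - force.t0) * force.fs - 1e-9))
    i1 = int(np.floor((hi - force.t0) * force.fs + 1e-9))
    return float(force.values[i0:i1 + 1].mean())


def estimate_reference_rate(train: SpikeTrain,
                            plateau: Tuple[float, float]) -> float:
    """Mean discharge rate over the plateau interval: spike count divided
    by interval length (pps)."""
    t0, t1 = plateau
    if t1 - t0 < 1.0:
        raise ValueError("plateau interval must cover at least 1 s")
    n = train.count_between(t0, t1)
    rate = n / (t1 - t0)
    if n == 0:
        warnings.warn(
            f"unit {train.unit_id}: silent during plateau, unusable as a "
            "feedback source")
    return float(rate)


def rank_pool(trains: Sequence[SpikeTrain], force: ForceTrace,
              plateau: Optional[Tuple[float, float]] = None,
              rate_thresh: float = 5.0, silence: float = 1.5,
              window: float = 100.0) -> List[ThresholdEstimate]:
    """Estimate per-unit thresholds on a ramp trial and rank the pool.

    Ranks are 1..K by ascending onset force, ties broken by earlier onset
    time and then unit id.  Units without a detectable onset are excluded
    (with a warning).  Offsets are filled where the 1.5 s silence rule
    succeeds and the force window fits inside the trace.
    """
    horizon = force.t0 + force.duration
    rows = []
    for tr in trains:
        t_on = detect_onset(tr, rate_thresh=rate_thresh)
        if t_on is None:
            warnings.warn(f"unit {tr.unit_id}: no onset detected, excluded")
            continue
        f_on = force_at_event(force, t_on, window=window)
        t_off = detect_offset(tr, horizon_end=horizon, silence=silence)
        f_off = None
        if t_off is not None and t_off <= t_on:
            t_off = None
        if t_off is not None:
            try:
                f_off = force_at_event(force, t_off, window=window)
            except ValueError:
                f_off = None
        ref = estimate_reference_rate(tr, plateau) if plateau else None
        rows.append((tr.unit_id, t_on, f_on, t_off, f_off, ref))
    if not rows:
        raise ValueError("no unit with a detectable onset")
    rows.sort(key=lambda r: (r[2], r[1], r[0]))
    return [
        ThresholdEstimate(unit_id=uid, t_on=t_on, f_on=f_on, rank=i + 1,
                          t_off=t_off, f_off=f_off, ref_rate=ref)
        for i, (uid, t_on, f_on, t_off, f_off, ref) in enumerate(rows)]


@dataclass(frozen=True)
class PairSelection:
    """Selected MU pairs for the three task conditions.

    Condition I uses the pair from the first-recruited half of the pool,
    condition II the pair from the last-recruited half, condition III pools
    MU1 of the low pair with MU2 of the high pair.  Within each pair MU1 is
    the lower-threshold unit.
    """

    condition_i: Tuple[ThresholdEstimate, ThresholdEstimate]
    condition_ii: Tuple[ThresholdEstimate, ThresholdEstimate]

    @property
    def condition_iii(self) -> Tuple[ThresholdEstimate, ThresholdEstimate]:
        return (self.condition_i[0], self.condition_ii[1])

    def pair(self, condition: str):
        key = condition.upper().replace("CONDITION_", "")
        return {"I": self.condition_i, "II": self.condition_ii,
                "III": self.condition_iii}[key]


def select_pairs(pool: Sequence[ThresholdEstimate], seed: int = 0) -> PairSelection:
    """Select one similar-threshold pair from each recruitment-order half.

    The ranked pool is split into first/last recruited halves (an odd unit
    goes to the first half).  Candidate pairs are adjacent-rank pairs
    within each half; a seeded random choice is weighted toward the
    smallest onset-force difference.
    """
    est = sorted(pool, key=lambda e: e.rank)
    if len(est) < 4:
        raise ValueError("pair selection requires at least 4 ranked units")
    rng = np.random.default_rng(seed)
    k = len(est)
    first = est[:(k + 1) // 2]
    last = est[(k + 1) // 2:]

    def choose(half):
        cands = list(zip(half, half[1:]))
        dif = np.array([b.f_on - a.f_on for a, b in cands])
        w = 1.0 / (dif + 0.1)
        w /= w.sum()
        return cands[int(rng.choice(len(cands), p=w))]

    return PairSelection(condition_i=choose(first), condition_ii=choose(last))


def emg_envelope(raw: np.ndarray, fs: float, cutoff_hz: float = 10.0,
                 order: int = 4,
                 bipolar_pairs: Optional[Sequence[Tuple[int, int]]] = None
                 ) -> np.ndarray:
    """Global-EMG envelope: optional bipolar derivation, full-wave
    rectification, zero-phase Butterworth low-pass.

    ``raw`` is ``(n_samples,)`` or ``(n_samples, n_channels)``.  Zero-phase
    (forward-backward) filtering avoids group delay in the 100 ms window
    reads; an online causal implementation would lag instead.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    x = np.asarray(raw, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x.T).T  # (n, c)
    if bipolar_pairs is not None:
        x = np.stack([x[:, i] - x[:, j] for i, j in bipolar_pairs], axis=1)
        squeeze = False
    rect = np.abs(x)
    b, a = sps.butter(order, cutoff_hz / (fs / 2.0), btype="low")
    env = sps.filtfilt(b, a, rect, axis=0)
    return env[:, 0] if squeeze else env


def pre_post_change(values_pre: Dict[str, float], values_post: Dict[str, float],
                    kind: str = "envelope") -> pd.DataFrame:
    """Per-unit pre/post comparison of event-locked measurements.

    For envelopes the change is ``100 * (post - pre) / pre`` percent; for
    force it is the absolute difference in %MVC.  Units missing from either
    side, or with a zero pre value in the percent mode, are excluded with a
    warning.
    """
    if kind not in ("envelope", "force"):
        raise ValueError("kind must be 'envelope' or 'force'")
    rows = []
    for uid in values_pre:
        if uid not in values_post:
            warnings.warn(f"unit {uid}: missing post value, excluded")
            continue
        pre, post = values_pre[uid], values_post[uid]
        if kind == "envelope":
            if pre == 0:
                warnings.warn(f"unit {uid}: zero pre value, excluded")
                continue
            change = 100.0 * (post - pre) / pre
        else:
            change = post - pre
        rows.append({"unit_id": uid, "pre": pre, "post": post, "change": change})
    df = pd.DataFrame(rows, columns=["unit_id", "pre", "post", "change"])
    df.attrs["kind"] = kind
    df.attrs["mean_change"] = float(df["change"].mean()) if len(df) else float("nan")
    return df


def thresholds_table(estimates: Sequence[ThresholdEstimate]) -> pd.DataFrame:
    """Thresholds as a tidy table (unit_id, rank, t_on, f_on, t_off, f_off,
    ref_rate)."""
    return pd.DataFrame(
        [{"unit_id": e.unit_id, "rank": e.rank, "t_on": e.t_on, "f_on": e.f_on,
          "t_off": e.t_off, "f_off": e.f_off, "ref_rate": e.ref_rate}
         for e in sorted(estimates, key=lambda e: e.rank)])
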