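"""Two-source decomposition validation.

Matches discharges between two decompositions of the same motor-unit
activity (e.g. online surface decomposition vs offline intramuscular
decomposition) within a 1 ms tolerance, computes the rate of agreement
(RoA) globally and per contraction phase, and pairs units across sources
by the correlation of their spike-triggered-average (STA) waveforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import SpikeTrain
from .synth import EmgRecording

__all__ = [
    "DischargeMatching", "RoAResult", "StaWaveform", "UnitMatch",
    "match_discharges", "rate_of_agreement", "roa_by_phase", "sta_waveform",
    "match_units",
]


@dataclass(frozen=True)
class DischargeMatching:
    """One-to-one discharge matching between two spike trains.

    ``pairs`` holds matched (time_A, time_B) tuples with
    ``|time_A - time_B| <= tolerance``; the unmatched arrays hold the
    leftover discharge times of each source.
    """

    pairs: np.ndarray          # (n, 2)
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray
    tolerance_ms: float

    @property
    def n_common(self) -> int:
        return int(self.pairs.shape[0])


@dataclass(frozen=True)
class RoAResult:
    """Rate of agreement: percentage of discharges identified by both
    sources, ``100 * common / (common + A-only + B-only)``."""

    n_common: int
    n_a_only: int
    n_b_only: int
    per_phase: Dict[str, float] = field(default_factory=dict)

    @property
    def roa(self) -> float:
        total = self.n_common + self.n_a_only + self.n_b_only
        return 100.0 * self.n_common / total


@dataclass(frozen=True)
class StaWaveform:
    """Spike-triggered average of a multichannel signal around a unit's
    discharges: the estimate of its action-potential waveform shape."""

    unit_id: str
    waveform: np.ndarray   # (window_samples, n_channels)
    fs: float
    window_ms: float
    n_triggers: int
    n_skipped: int = 0


@dataclass(frozen=True)
class UnitMatch:
    unit_a: str
    unit_b: str
    correlation: float


def match_discharges(a: SpikeTrain, b: SpikeTrain,
                     tol: float = 1.0) -> DischargeMatching:
    """Greedy chronological one-to-one matching within ``tol`` ms.

    Walks both trains front to back and pairs the nearest candidates
    within tolerance, never reusing a spike.  Identical to the optimal
    bipartite matching whenever all inter-spike intervals exceed twice the
    tolerance (true for physiological trains at a 1 ms tolerance).
    """
    tol_s = tol / 1000.0
    ta, tb = a.times, b.times
    i = j = 0
    pairs: List[Tuple[float, float]] = []
    ua: List[float] = []
    ub: List[float] = []
    while i < ta.size and j < tb.size:
        dt = ta[i] - tb[j]
        if abs(dt) <= tol_s:
            # prefer the closer of the current and next opposing spike
            if (j + 1 < tb.size and abs(ta[i] - tb[j + 1]) < abs(dt)
                    and abs(ta[i] - tb[j + 1]) <= tol_s):
                ub.append(tb[j])
                j += 1
                continue
            pairs.append((float(ta[i]), float(tb[j])))
            i += 1
            j += 1
        elif ta[i] < tb[j]:
            ua.append(float(ta[i]))
            i += 1
        else:
            ub.append(float(tb[j]))
            j += 1
    ua.extend(float(t) for t in ta[i:])
    ub.extend(float(t) for t in tb[j:])
    return DischargeMatching(
        pairs=np.asarray(pairs, dtype=float).reshape(-1, 2),
        unmatched_a=np.asarray(ua), unmatched_b=np.asarray(ub),
        tolerance_ms=tol)


def rate_of_agreement(m: DischargeMatching) -> RoAResult:
    """Rate of agreement of a discharge matching (percent)."""
    total = m.n_common + m.unmatched_a.size + m.unmatched_b.size
    if total == 0:
        raise ValueError("no discharges to agree on")
    return RoAResult(n_common=m.n_common, n_a_only=int(m.unmatched_a.size),
                     n_b_only=int(m.unmatched_b.size))


def roa_by_phase(m: DischargeMatching,
                 phases: Sequence[Tuple[str, float, float]]) -> RoAResult:
    """Rate of agreement computed separately per contraction phase.

    ``phases`` are disjoint labelled ``(label, t0, t1)`` intervals
    (half-open).  Matched pairs are assigned by their source-A time,
    unmatched discharges by their own time; discharges outside all phases
    are reported under ``"outside"``.
    """
    labels = [p[0] for p in phases]
    counts = {lab: [0, 0, 0] for lab in labels}
    counts["outside"] = [0, 0, 0]

    def phase_of(t: float) -> str:
        for lab, t0, t1 in phases:
            if t0 <= t < t1:
                return lab
        return "outside"

    for t_a, _ in m.pairs:
        counts[phase_of(t_a)][0] += 1
    for t in m.unmatched_a:
        counts[phase_of(t)][1] += 1
    for t in m.unmatched_b:
        counts[phase_of(t)][2] += 1
    per_phase: Dict[str, float] = {}
    for lab, (nc, na, nb) in counts.items():
        tot = nc + na + nb
        if lab == "outside" and tot == 0:
            continue
        per_phase[lab] = 100.0 * nc / tot if tot else float("nan")
    glob = rate_of_agreement(m)
    return RoAResult(n_common=glob.n_common, n_a_only=glob.n_a_only,
                     n_b_only=glob.n_b_only, per_phase=per_phase)


def sta_waveform(signal: EmgRecording, train: SpikeTrain,
                 window_ms: float = 50.0,
                 min_triggers: int = 10) -> StaWaveform:
    """Spike-triggered average of a multichannel signal.

    Averages signal segments of ``window_ms`` centred on each discharge;
    triggers whose window clips a signal edge are skipped and counted.
    """
    data = signal.data
    n = data.shape[0]
    half = int(round(window_ms / 2.0 / 1000.0 * signal.fs))
    idx = np.round((train.times - signal.t0) * signal.fs).astype(int)
    ok = (idx >= half) & (idx < n - half)
    usable = idx[ok]
    if usable.size < min_triggers:
        raise ValueError(
            f"only {usable.size} usable triggers (minimum {min_triggers})")
    acc = np.zeros((2 * half + 1, data.shape[1]))
    for i in usable:
        acc += data[i - half:i + half + 1]
    return StaWaveform(unit_id=train.unit_id, waveform=acc / usable.size,
                       fs=signal.fs, window_ms=window_ms,
                       n_triggers=int(usable.size),
                       n_skipped=int(idx.size - usable.size))


def _flat(w: StaWaveform) -> np.ndarray:
    x = w.waveform.ravel(order="F").astype(float)
    return x - x.mean()


def match_units(wavs_a: Sequence[StaWaveform], wavs_b: Sequence[StaWaveform],
                corr_thresh: float = 0.9) -> List[UnitMatch]:
    """Pair units across sources by STA-waveform correlation.

    Correlations are computed on channel-concatenated, mean-removed
    waveforms; candidate pairs above ``corr_thresh`` are resolved to a
    one-to-one assignment greedily by descending correlation.
    """
    if not wavs_a or not wavs_b:
        return []
    shape = wavs_a[0].waveform.shape
    for w in list(wavs_a) + list(wavs_b):
        if w.waveform.shape != shape:
            raise ValueError("waveform window/channel layouts differ")
    cands: List[Tuple[float, int, int]] = []
    for i, wa in enumerate(wavs_a):
        xa = _flat(wa)
        for j, wb in enumerate(wavs_b):
            xb = _flat(wb)
            denom = np.linalg.norm(xa) * np.linalg.norm(xb)
            corr = float(np.dot(xa, xb) / denom) if denom > 0 else 0.0
            if corr >= corr_thresh:
                cands.append((corr, i, j))
    cands.sort(reverse=True)
    used_a: set = set()
    used_b: set = set()
    out: List[UnitMatch] = []
    for corr, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(UnitMatch(unit_a=wavs_a[i].unit_id,
                             unit_b=wavs_b[j].unit_id, correlation=corr))
    return out
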