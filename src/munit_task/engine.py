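"""Buffered closed-loop cursor task engine.

The acquisition front-end delivers data in buffers of 256 samples at
2048 Hz (125 ms).  Per buffer, each unit's discharge rate is the spike
count in that buffer; the displayed rate is the trailing 8-buffer (1 s)
mean, normalised by the unit's reference rate at 10 %MVC and multiplied by
a gain; the cursor position is the trailing 6-buffer (750 ms) moving
average of the normalised rates.  The two trailing means cascade into an
effective 13-buffer (1625 ms) window.  A target hit requires 7 consecutive
in-target buffers (875 ms); an angle hit 7 consecutive buffers inside the
cropped wedge around the target direction; a trial times out after 20 s.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import DriveTrace, ForceTrace, SpikeTrain
from .synth import (MotorUnitParams, MotorUnitPool, simulate_force,
                    simulate_spikes, three_stage_policy)

__all__ = [
    "BufferConfig", "TargetGeometry", "CursorStream", "TrialRecord",
    "SessionTrial", "SessionRecord", "standard_targets", "buffer_rates",
    "trailing_mean", "cursor_positions", "point_region_test", "run_trial",
    "run_session", "calibrate_gains", "model_reference_rates",
    "default_policies", "constant_level_drive", "steady_normalized_rates",
    "REGION_TARGET", "REGION_ANGLE", "REGION_NEITHER", "TARGET_IDS",
]

REGION_TARGET = "target"
REGION_ANGLE = "angle"
REGION_NEITHER = "neither"
TARGET_IDS = ("TI", "TII", "TIII")


@dataclass(frozen=True)
class BufferConfig:
    """Timing of the buffered task engine (defaults: the study protocol)."""

    samples_per_buffer: int = 256
    fs: float = 2048.0
    rate_window_buffers: int = 8
    cursor_ma_buffers: int = 6
    hold_buffers: int = 7
    timeout_s: float = 20.0
    rest_s: float = 2.0

    def __post_init__(self) -> None:
        if self.samples_per_buffer <= 0 or self.fs <= 0:
            raise ValueError("samples_per_buffer and fs must be positive")
        if self.hold_buffers != self.cursor_ma_buffers + 1:
            # stated protocol relation ("one buffer size longer than the
            # moving average"); checked, not forced
            warnings.warn("hold_buffers != cursor_ma_buffers + 1")

    @property
    def buffer_s(self) -> float:
        return self.samples_per_buffer / self.fs

    @property
    def timeout_buffers(self) -> int:
        return int(round(self.timeout_s / self.buffer_s))

    @property
    def hold_s(self) -> float:
        return self.hold_buffers * self.buffer_s

    @property
    def effective_window_s(self) -> float:
        """Support of the cascaded trailing means (impulse response)."""
        return (self.rate_window_buffers + self.cursor_ma_buffers - 1) \
            * self.buffer_s


@dataclass(frozen=True)
class TargetGeometry:
    """One target disc plus its angle wedge in normalised-rate space.

    The wedge is the unbounded cone from the origin tangent to the target
    circle, cropped by the inner circle of radius ``inner_crop``; its
    half-angle is ``arcsin(radius / ||center||)``.  ``dmax`` and
    ``phi_max`` normalise the performance metric (distance between the TI
    and TIII centres and 90 deg for the on-axis targets; distance
    origin-to-centre and 45 deg for the diagonal target TII).
    """

    target_id: str
    center: Tuple[float, float]
    dmax: float
    phi_max: float
    radius: float = 0.1
    inner_crop: float = 0.4

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def center_norm(self) -> float:
        return float(np.hypot(*self.center))

    @property
    def wedge_half_angle_deg(self) -> float:
        return math.degrees(math.asin(self.radius / self.center_norm))


def standard_targets(radius: float = 0.1,
                     inner_crop: float = 0.4) -> Dict[str, TargetGeometry]:
    """The three study targets: TI=(1,0), TII=(1,1), TIII=(0,1)."""
    d_ti_tiii = math.sqrt(2.0)
    return {
        "TI": TargetGeometry("TI", (1.0, 0.0), dmax=d_ti_tiii, phi_max=90.0,
                             radius=radius, inner_crop=inner_crop),
        "TII": TargetGeometry("TII", (1.0, 1.0), dmax=math.sqrt(2.0),
                              phi_max=45.0, radius=radius,
                              inner_crop=inner_crop),
        "TIII": TargetGeometry("TIII", (0.0, 1.0), dmax=d_ti_tiii,
                               phi_max=90.0, radius=radius,
                               inner_crop=inner_crop),
    }


def buffer_rates(train: SpikeTrain, cfg: BufferConfig, horizon: float,
                 t0: float = 0.0) -> np.ndarray:
    """Per-buffer discharge rates (pps) over ``[t0, t0 + horizon)``.

    Buffer ``b`` covers ``[t0 + b*D, t0 + (b+1)*D)``; a spike exactly on a
    boundary belongs to the later buffer.
    """
    delta = cfg.buffer_s
    n_buffers = int(math.floor(horizon / delta + 1e-9))
    if n_buffers < 1:
        raise ValueError("horizon must cover at least one buffer")
    idx = np.floor((train.times - t0) / delta + 1e-12).astype(int)
    idx = idx[(idx >= 0) & (idx < n_buffers)]
    counts = np.bincount(idx, minlength=n_buffers)
    return counts / delta


def trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Trailing mean including the current sample, with shorter windows
    during warm-up (mean over the available samples)."""
    x = np.asarray(x, dtype=float)
    c = np.cumsum(x, axis=0)
    shifted = np.zeros_like(c)
    if x.shape[0] > w:
        shifted[w:] = c[:-w]
    sums = c - shifted
    n = np.minimum(np.arange(1, x.shape[0] + 1), w)
    if x.ndim > 1:
        n = n[:, None]
    return sums / n


@dataclass(frozen=True)
class CursorStream:
    """Per-buffer engine state: raw rates, trailing-average rates,
    normalised (gained) rates and cursor positions.  ``t`` holds the end
    time of each buffer."""

    raw_rates: np.ndarray    # (n_buffers, 2) pps
    avg_rates: np.ndarray    # trailing rate_window mean, pps
    norm_rates: np.ndarray   # gain * avg / ref
    positions: np.ndarray    # trailing cursor_ma mean of norm_rates
    t: np.ndarray
    cfg: BufferConfig

    def __len__(self) -> int:
        return self.positions.shape[0]


def cursor_positions(rates: np.ndarray, ref_rates: Sequence[float],
                     gains: Sequence[float], cfg: BufferConfig,
                     t0: float = 0.0) -> CursorStream:
    """Cursor stream from per-buffer rates of the two feedback units.

    Per axis: trailing ``rate_window_buffers`` mean of the raw rates,
    normalised by the unit's reference rate at 10 %MVC and scaled by the
    gain, then a trailing ``cursor_ma_buffers`` moving average.  No
    clamping: the normalised space is unbounded upward.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[1] != 2:
        raise ValueError("rates must be (n_buffers, 2)")
    ref = np.asarray(ref_rates, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference rates must be positive")
    g = np.asarray(gains, dtype=float)
    avg = trailing_mean(rates, cfg.rate_window_buffers)
    norm = g * avg / ref
    pos = trailing_mean(norm, cfg.cursor_ma_buffers)
    t = t0 + (np.arange(rates.shape[0]) + 1) * cfg.buffer_s
    return CursorStream(raw_rates=rates, avg_rates=avg, norm_rates=norm,
                        positions=pos, t=t, cfg=cfg)


def point_region_test(p: Sequence[float], geom: TargetGeometry) -> str:
    """Region label of a cursor position: ``target`` if inside the target
    disc, else ``angle`` if inside the cropped wedge, else ``neither``.
    Boundaries count as inside; the origin is ``neither``."""
    p = np.asarray(p, dtype=float)
    c = geom.center_arr
    if np.hypot(*(p - c)) <= geom.radius + 1e-12:
        return REGION_TARGET
    r = float(np.hypot(*p))
    if r == 0.0 or r < geom.inner_crop - 1e-12:
        return REGION_NEITHER
    cosang = float(np.dot(p, c)) / (r * geom.center_norm)
    ang = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
    if ang <= geom.wedge_half_angle_deg + 1e-9:
        return REGION_ANGLE
    return REGION_NEITHER


def cursor_angle_deg(p: Sequence[float], geom: TargetGeometry) -> float:
    """Absolute angle (degrees) between the cursor vector and the target
    direction; a cursor at the origin scores ``phi_max``."""
    p = np.asarray(p, dtype=float)
    r = float(np.hypot(*p))
    if r == 0.0:
        return geom.phi_max
    cosang = float(np.dot(p, geom.center_arr)) / (r * geom.center_norm)
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


@dataclass(frozen=True)
class TrialRecord:
    """One trial: the cursor-stream slice from target onset to trial end
    (hit or timeout) plus the hit/timeout events (buffer indices are
    relative to the onset)."""

    target_id: str
    positions: np.ndarray
    regions: Tuple[str, ...]
    t: np.ndarray
    onset_time: float
    angle_hit_buffer: Optional[int]
    target_hit_buffer: Optional[int]
    timeout: bool
    truncated: bool = False

    @property
    def n_buffers(self) -> int:
        return self.positions.shape[0]

    @property
    def target_hit(self) -> bool:
        return self.target_hit_buffer is not None

    @property
    def angle_hit(self) -> bool:
        return self.angle_hit_buffer is not None

    @property
    def outcome(self) -> str:
        if self.target_hit:
            return "target_hit"
        if self.angle_hit:
            return "angle_hit"
        return "timeout" if self.timeout else "truncated"


def run_trial(stream: CursorStream, geom: TargetGeometry, cfg: BufferConfig,
              onset_buffer: int = 0) -> TrialRecord:
    """Run the trial state machine over a cursor stream.

    Scanning starts at ``onset_buffer`` (target appearance).  A target hit
    is granted at the ``hold_buffers``-th consecutive in-target buffer and
    ends the trial; an angle hit at the ``hold_buffers``-th consecutive
    buffer inside the wedge (the target disc counts as inside) and the
    trial continues; the trial times out after ``timeout_s``.
    """
    pos = stream.positions[onset_buffer:onset_buffer + cfg.timeout_buffers]
    n_avail = pos.shape[0]
    if n_avail < 1:
        raise ValueError("stream does not cover the trial onset")
    regions: List[str] = []
    tc = ac = 0
    angle_hit = target_hit = None
    end = n_avail - 1
    for i in range(n_avail):
        reg = point_region_test(pos[i], geom)
        regions.append(reg)
        tc = tc + 1 if reg == REGION_TARGET else 0
        ac = ac + 1 if reg in (REGION_TARGET, REGION_ANGLE) else 0
        if angle_hit is None and ac == cfg.hold_buffers:
            angle_hit = i
        if tc == cfg.hold_buffers:
            target_hit = i
            end = i
            break
    truncated = target_hit is None and n_avail < cfg.timeout_buffers
    timeout = target_hit is None and not truncated
    n = end + 1
    onset_time = float(stream.t[onset_buffer] - cfg.buffer_s)
    return TrialRecord(
        target_id=geom.target_id, positions=pos[:n],
        regions=tuple(regions[:n]),
        t=stream.t[onset_buffer:onset_buffer + n], onset_time=onset_time,
        angle_hit_buffer=angle_hit, target_hit_buffer=target_hit,
        timeout=timeout, truncated=truncated)


# ---------------------------------------------------------------------------
# closed-loop sessions

@dataclass(frozen=True)
class SessionTrial:
    """One closed-loop trial with everything the analyses need: the trial
    record, the pair's spike trains, the force trace, the full cursor
    stream (including the pre-onset rest) and the drive that produced it."""

    trial: TrialRecord
    trains: Tuple[SpikeTrain, SpikeTrain]
    force: ForceTrace
    stream: CursorStream
    drive: DriveTrace
    onset_buffer: int


@dataclass(frozen=True)
class SessionRecord:
    """A full session: trials in randomised target order."""

    trials: Tuple[SessionTrial, ...]
    target_order: Tuple[str, ...]
    pair: Tuple[MotorUnitParams, MotorUnitParams]
    ref_rates: Tuple[float, float]
    gains: Tuple[float, float]
    cfg: BufferConfig
    seed: int


def model_reference_rates(pair: Sequence[MotorUnitParams],
                          level: float = 10.0) -> Tuple[float, float]:
    """Model-implied reference rates at the plateau force level."""
    return tuple(u.rate_at(level) for u in pair)


def calibrate_gains(pair: Sequence[MotorUnitParams],
                    ref_rates: Sequence[float],
                    clip: Tuple[float, float] = (0.5, 5.0)
                    ) -> Tuple[float, float]:
    """Familiarisation-phase gain calibration.

    Gains are set so that each unit's attainable steady discharge rate in
    its target regime maps onto normalised rate 1: for MU1 the rate just
    below MU2's recruitment threshold (sole-MU1 regime, target TI), for MU2
    the sustained recruitment-floor rate (sole-MU2 regime, target TIII).
    Emulates the manual gain adjustment of the original familiarisation.
    """
    mu1, mu2 = pair
    r1 = mu1.rate_at(max(mu1.theta_on, mu2.theta_on - 1e-6))
    g1 = ref_rates[0] / r1
    g2 = ref_rates[1] / mu2.r_min
    lo, hi = clip
    return (float(min(max(g1, lo), hi)), float(min(max(g2, lo), hi)))


def steady_normalized_rates(level: float, pair: Sequence[MotorUnitParams],
                            ref_rates: Sequence[float],
                            gains: Sequence[float]) -> np.ndarray:
    """Steady-state normalised rates when the drive is held at ``level``
    after a monotone rise from rest (a unit is active iff the level reached
    its recruitment threshold)."""
    u = np.zeros(2)
    for i, unit in enumerate(pair):
        if level >= unit.theta_on:
            u[i] = gains[i] * unit.rate_at(level) / ref_rates[i]
    return u


def constant_level_drive(level: float, hold: float, fs: float = 2048.0,
                         slope: float = 2.0) -> DriveTrace:
    """Rise at ``slope`` %MVC/s to ``level``, hold, and return to zero."""
    rise = level / slope
    total = rise + hold + rise
    n = int(round(total * fs))
    t = np.arange(n) / fs
    v = np.interp(t, [0.0, rise, rise + hold, total], [0.0, level, level, 0.0])
    return DriveTrace(fs=fs, values=v)


def _best_constant_level(target_center: Sequence[float],
                         pair: Sequence[MotorUnitParams],
                         ref_rates: Sequence[float],
                         gains: Sequence[float],
                         max_level: float = 12.0) -> float:
    grid = np.arange(0.05, max_level, 0.025)
    c = np.asarray(target_center, dtype=float)
    best, best_score = grid[0], np.inf
    for lv in grid:
        u = steady_normalized_rates(lv, pair, ref_rates, gains)
        score = float(np.hypot(*(u - c)))
        if score < best_score - 1e-12:
            best, best_score = lv, score
    return float(best)


def default_policies(pair: Sequence[MotorUnitParams],
                     ref_rates: Sequence[float], gains: Sequence[float],
                     cfg: BufferConfig, fs: float = 2048.0
                     ) -> Dict[str, Callable[[np.random.Generator], DriveTrace]]:
    """Idealised drive policies per target.

    TI and TII hold the constant drive level whose steady normalised rates
    are closest to the target centre.  TIII uses the three-stage strategy
    when the pair's de-recruitment order makes it feasible, and otherwise
    falls back to the (generally unsuccessful) constant-level strategy.
    """
    geoms = standard_targets()
    hold = cfg.timeout_s

    def const_policy(tid: str) -> Callable:
        level = _best_constant_level(geoms[tid].center, pair, ref_rates, gains)

        def policy(rng: np.random.Generator) -> DriveTrace:
            return constant_level_drive(level, hold, fs=fs)
        return policy

    policies = {"TI": const_policy("TI"), "TII": const_policy("TII")}
    profile = three_stage_policy(pair, dwell=2.5, fs=fs)
    if profile.feasible:
        def tiii_policy(rng: np.random.Generator,
                        _drive=profile.drive) -> DriveTrace:
            return _drive
        policies["TIII"] = tiii_policy
    else:
        policies["TIII"] = const_policy("TIII")
    return policies


def run_session(pair: Sequence[MotorUnitParams], cfg: BufferConfig,
                seed: int, ref_rates: Optional[Sequence[float]] = None,
                gains: Optional[Sequence[float]] = None,
                policies: Optional[Dict[str, Callable]] = None,
                repeats: int = 10, force_noise_sd: float = 0.0,
                drive_fs: float = 2048.0,
                geoms: Optional[Dict[str, TargetGeometry]] = None
                ) -> SessionRecord:
    """Closed-loop session: each target presented ``repeats`` times in
    seeded randomised order, with a 2 s rest at the origin before every
    target onset.

    Per trial the policy's drive (prepended with the rest) feeds the pool
    simulator; buffered rates of the selected pair feed the cursor engine;
    the trial state machine produces the record.
    """
    pair = tuple(pair)
    if len(pair) != 2:
        raise ValueError("run_session needs exactly two units")
    geoms = geoms or standard_targets()
    if ref_rates is None:
        ref_rates = model_reference_rates(pair)
    if gains is None:
        gains = calibrate_gains(pair, ref_rates)
    rng = np.random.default_rng(seed)
    order = list(np.repeat(TARGET_IDS, repeats))
    rng.shuffle(order)
    if policies is None:
        policies = default_policies(pair, ref_rates, gains, cfg, fs=drive_fs)
    mini_pool = MotorUnitPool(tuple(sorted(pair, key=lambda u: u.theta_on)))
    rest_n = int(round(cfg.rest_s * drive_fs))
    min_len_s = cfg.rest_s + cfg.timeout_s + cfg.buffer_s
    trials: List[SessionTrial] = []
    for tid in order:
        tseed = int(rng.integers(2 ** 31))
        body = policies[tid](np.random.default_rng(tseed))
        values = np.concatenate([np.zeros(rest_n), body.values])
        need = int(round(min_len_s * drive_fs))
        if values.size < need:
            values = np.concatenate([values, np.zeros(need - values.size)])
        drive = DriveTrace(fs=drive_fs, values=values)
        sim = simulate_spikes(mini_pool, drive, seed=tseed)
        force = simulate_force(drive, noise_sd=force_noise_sd, seed=tseed + 1)
        horizon = drive.duration
        tr1 = sim.train(pair[0].unit_id)
        tr2 = sim.train(pair[1].unit_id)
        rates = np.stack([buffer_rates(tr1, cfg, horizon),
                          buffer_rates(tr2, cfg, horizon)], axis=1)
        stream = cursor_positions(rates, ref_rates, gains, cfg)
        onset_buffer = int(round(cfg.rest_s / cfg.buffer_s))
        trial = run_trial(stream, geoms[tid], cfg, onset_buffer=onset_buffer)
        trials.append(SessionTrial(trial=trial, trains=(tr1, tr2),
                                   force=force, stream=stream, drive=drive,
                                   onset_buffer=onset_buffer))
    return SessionRecord(trials=tuple(trials), target_order=tuple(order),
                         pair=pair, ref_rates=tuple(float(r) for r in ref_rates),
                         gains=tuple(float(g) for g in gains), cfg=cfg,
                         seed=seed)
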