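"""Synthetic motoneuron-pool generator.

Everything the analysis pipeline consumes can be generated here: a pool of
motor units with size-principle recruitment thresholds and per-unit
de-recruitment hysteresis, trapezoidal force-ramp drive profiles, renewal
spike trains driven by a common input, force traces, EMG-like signals, a
corrupted second spike source for two-source validation, and the
three-stage drive policy that recruits both units of a pair and then
silences the lower-threshold one.

The generator is an emulation of reported population statistics, not a
biophysical model: rate coding is linear above threshold with a hard
saturation, hysteresis is a static per-unit de-recruitment threshold
standing in for history-dependent excitability (persistent inward
currents), and force equals drive plus low-pass filtered noise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import DriveTrace, ForceTrace, SpikeTrain, MIN_SPIKE_SEPARATION_S

__all__ = [
    "MotorUnitParams", "MotorUnitPool", "SimulationConfig", "ConfigurationError",
    "SimulationResult", "ThreeStageProfile", "EmgRecording",
    "build_pool", "make_ramp_drive", "make_random_drive", "simulate_spikes",
    "simulate_force", "simulate_global_emg", "simulate_unit_emg",
    "corrupt_two_source", "three_stage_policy",
]

#: lower clip for de-recruitment thresholds, %MVC (keeps theta_off > 0 while
#: leaving the sign of the hysteresis draw untouched)
THETA_OFF_FLOOR = 0.05


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class MotorUnitParams:
    """Ground-truth parameters of one simulated motor unit.

    ``theta_on``/``theta_off`` are the recruitment and de-recruitment
    thresholds in %MVC (``theta_off`` may be above or below ``theta_on``;
    the hysteresis sign is free).  While active the unit fires at
    ``min(r_sat, r_min + rate_gain * max(0, drive - theta_on))`` pps, i.e.
    linear rate coding above threshold with hard saturation, floored at the
    recruitment rate ``r_min``.  ``isi_cov`` is the coefficient of variation
    of the inter-spike intervals.
    """

    unit_id: str
    theta_on: float
    theta_off: float
    r_min: float
    rate_gain: float
    r_sat: float
    isi_cov: float = 0.1

    def __post_init__(self) -> None:
        if self.theta_on <= 0:
            raise ConfigurationError("theta_on must be positive")
        if self.theta_off <= 0:
            raise ConfigurationError("theta_off must be positive")
        if self.r_min <= 0:
            raise ConfigurationError("r_min must be positive")
        if self.r_sat < self.r_min:
            raise ConfigurationError("r_sat must be >= r_min")
        if self.isi_cov < 0:
            raise ConfigurationError("isi_cov must be >= 0")

    def rate_at(self, drive_value: float) -> float:
        """Instantaneous discharge rate (pps) while the unit is active."""
        return min(self.r_sat,
                   self.r_min + self.rate_gain * max(0.0, drive_value - self.theta_on))


@dataclass(frozen=True)
class MotorUnitPool:
    """A pool of motor units ordered by ascending recruitment threshold."""

    units: Tuple[MotorUnitParams, ...]

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise ConfigurationError("pool must contain at least one unit")
        th = [u.theta_on for u in self.units]
        if any(b < a for a, b in zip(th, th[1:])):
            raise ConfigurationError("units must be ordered by theta_on")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, i):
        return self.units[i]

    @property
    def theta_on(self) -> np.ndarray:
        return np.array([u.theta_on for u in self.units])

    @property
    def theta_off(self) -> np.ndarray:
        return np.array([u.theta_off for u in self.units])


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the pool generator.

    Defaults restate the emulation targets: ~11 reliably decomposed units
    per session, recruitment thresholds inside the 10 %MVC ramp range, and
    a de-recruitment threshold on average 1.11 %MVC below the recruitment
    one with a 2.44 %MVC spread (so roughly two thirds of units are
    de-recruited below their recruitment threshold and one third above).
    """

    n_units: int = 11
    threshold_range: Tuple[float, float] = (1.0, 9.0)
    hysteresis_mean: float = -1.11
    hysteresis_sd: float = 2.44
    drive_noise_sd: float = 0.0
    force_noise_sd: float = 0.1
    isi_cov: float = 0.1
    r_min_range: Tuple[float, float] = (7.0, 9.0)
    rate_gain_range: Tuple[float, float] = (0.3, 0.6)
    r_sat_increment_range: Tuple[float, float] = (3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigurationError("n_units must be >= 2")
        lo, hi = self.threshold_range
        if not (0.0 < lo < hi < 100.0):
            raise ConfigurationError("threshold_range must lie inside (0, 100)")
        if self.hysteresis_sd < 0 or self.drive_noise_sd < 0 or self.force_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.isi_cov < 0:
            raise ConfigurationError("isi_cov must be >= 0")


def build_pool(config: SimulationConfig) -> MotorUnitPool:
    """Draw a motor-unit pool from a :class:`SimulationConfig`.

    Recruitment thresholds are uniform in ``threshold_range`` and sorted
    ascending (size principle).  De-recruitment thresholds are
    ``theta_on + N(hysteresis_mean, hysteresis_sd)`` clipped at a small
    positive floor.  Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.threshold_range
    theta_on = np.sort(rng.uniform(lo, hi, config.n_units))
    if config.hysteresis_sd > 0:
        draw = rng.normal(config.hysteresis_mean, config.hysteresis_sd,
                          config.n_units)
    else:
        draw = np.full(config.n_units, config.hysteresis_mean)
    theta_off = np.maximum(theta_on + draw, THETA_OFF_FLOOR)
    r_min = rng.uniform(*config.r_min_range, config.n_units)
    gain = rng.uniform(*config.rate_gain_range, config.n_units)
    r_sat = r_min + rng.uniform(*config.r_sat_increment_range, config.n_units)
    units = tuple(
        MotorUnitParams(unit_id=f"mu{i + 1:02d}", theta_on=float(theta_on[i]),
                        theta_off=float(theta_off[i]), r_min=float(r_min[i]),
                        rate_gain=float(gain[i]), r_sat=float(r_sat[i]),
                        isi_cov=config.isi_cov)
        for i in range(config.n_units))
    return MotorUnitPool(units)


def make_ramp_drive(slope: float, plateau_level: float, plateau_dur: float,
                    fs: float = 2048.0, rest_s: float = 0.0) -> DriveTrace:
    """Trapezoidal ramp drive: linear rise from 0 at ``slope`` %MVC/s,
    plateau at ``plateau_level``, symmetric fall, optional rest tail.

    Duration (without the rest tail) is ``2 * plateau_level / slope +
    plateau_dur`` seconds.
    """
    if slope <= 0:
        raise ConfigurationError("slope must be positive")
    if plateau_level <= 0:
        raise ConfigurationError("plateau_level must be positive")
    if plateau_dur < 0:
        raise ConfigurationError("plateau_dur must be >= 0")
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    rise = plateau_level / slope
    total = 2 * rise + plateau_dur + rest_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    xp = [0.0, rise, rise + plateau_dur, 2 * rise + plateau_dur, total]
    fp = [0.0, plateau_level, plateau_level, 0.0, 0.0]
    return DriveTrace(fs=fs, values=np.interp(t, xp, fp))


def make_random_drive(rng: np.random.Generator, duration: float = 22.0,
                      max_level: float = 12.0, n_knots: int = 6,
                      fs: float = 512.0) -> DriveTrace:
    """Random piecewise-linear drive starting and ending at zero.

    Used to exercise the pool under arbitrary force trajectories (e.g. the
    impossibility suite for direct TIII movements).
    """
    if duration <= 0 or n_knots < 1:
        raise ConfigurationError("need positive duration and >= 1 knot")
    knots_t = np.sort(rng.uniform(0.0, duration, n_knots))
    knots_v = rng.uniform(0.0, max_level, n_knots)
    xp = np.concatenate([[0.0], knots_t, [duration]])
    fp = np.concatenate([[0.0], knots_v, [0.0]])
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return DriveTrace(fs=fs, values=np.interp(t, xp, fp))


# ---------------------------------------------------------------------------
# spike simulation

def _activation_epochs(values: np.ndarray, fs: float, theta_on: float,
                       theta_off: float) -> List[Tuple[int, int]]:
    """Activation epochs (sample index pairs, half-open) of one unit.

    A unit activates at an upward crossing of ``theta_on``.  While active
    the de-recruitment level is ``theta_off`` once the drive has reached
    ``theta_off`` since activation ("armed"; always immediate when
    ``theta_off <= theta_on``) and ``theta_on`` otherwise.  This expresses
    both hysteresis signs without sample-rate chatter: a unit whose
    elevated de-recruitment threshold is never reached by the drive simply
    de-recruits at its recruitment threshold.
    """
    v = values
    n = v.size
    above = v >= theta_on
    ups = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if above.size and above[0]:
        ups = np.concatenate([[0], ups]) if (ups.size == 0 or ups[0] != 0) else ups
    epochs: List[Tuple[int, int]] = []
    cursor = 0
    for a in ups:
        if a < cursor:
            continue
        seg = v[a:]
        peak = np.maximum.accumulate(seg)
        level = np.where(peak >= theta_off, theta_off, theta_on)
        below = seg < level
        hits = np.flatnonzero(below)
        if hits.size == 0:
            epochs.append((int(a), n))
            break
        d = int(a + hits[0])
        epochs.append((int(a), d))
        cursor = d
    return epochs


@dataclass(frozen=True)
class SimulationResult:
    """Output of :func:`simulate_spikes`.

    ``trains`` are per-unit spike trains, ``epochs`` per-unit activation
    intervals in seconds, and ``rates`` the per-unit instantaneous rate
    trace on the drive grid (0 pps while inactive).
    """

    trains: Tuple[SpikeTrain, ...]
    epochs: Dict[str, List[Tuple[float, float]]]
    rates: Dict[str, np.ndarray]
    drive: DriveTrace

    def train(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    @property
    def rate_matrix(self) -> np.ndarray:
        return np.stack([self.rates[tr.unit_id] for tr in self.trains])


#: relative lower clip of a renewal inter-spike interval (fraction of mean)
ISI_FLOOR_FRACTION = 0.2


def _renewal_spikes(unit: MotorUnitParams, drive: DriveTrace,
                    t0: float, t1: float,
                    rng: np.random.Generator) -> List[float]:
    """Renewal spikes over one activation epoch, first spike at onset."""
    values = drive.values
    fs = drive.fs
    n = values.size

    def v_at(t: float) -> float:
        i = int(round((t - drive.t0) * fs))
        return values[min(max(i, 0), n - 1)]

    spikes = [t0]
    t = t0
    cov = unit.isi_cov
    while True:
        rate = unit.rate_at(v_at(t))
        mean = 1.0 / rate
        if cov > 0:
            isi = mean * max(ISI_FLOOR_FRACTION, 1.0 + cov * rng.standard_normal())
        else:
            isi = mean
        t = t + isi
        if t > t1 + 1e-9:
            break
        spikes.append(t)
    return spikes


def simulate_spikes(pool: MotorUnitPool, drive: DriveTrace,
                    seed: int = 0) -> SimulationResult:
    """Simulate the pool's discharge activity under a common drive.

    Per unit: deterministic activation epochs (size-principle recruitment
    with de-recruitment hysteresis, see :func:`_activation_epochs`), then a
    renewal process inside each epoch with ISI mean ``1/rate`` and
    coefficient of variation ``isi_cov``.  Seeded and reproducible.
    """
    if len(pool) == 0:
        raise ConfigurationError("empty pool")
    if drive.duration < 1.0:
        raise ConfigurationError("drive must cover at least 1 s")
    rng = np.random.default_rng(seed)
    unit_rngs = rng.spawn(len(pool))
    trains: List[SpikeTrain] = []
    epochs: Dict[str, List[Tuple[float, float]]] = {}
    rates: Dict[str, np.ndarray] = {}
    fs = drive.fs
    for unit, urng in zip(pool, unit_rngs):
        eps = _activation_epochs(drive.values, fs, unit.theta_on, unit.theta_off)
        times: List[float] = []
        active = np.zeros(len(drive), dtype=bool)
        for a, b in eps:
            active[a:b] = True
            t0 = drive.t0 + a / fs
            t1 = drive.t0 + b / fs
            times.extend(_renewal_spikes(unit, drive, t0, t1, urng))
        rate_tr = np.where(
            active,
            np.minimum(unit.r_sat,
                       unit.r_min + unit.rate_gain
                       * np.maximum(0.0, drive.values - unit.theta_on)),
            0.0)
        trains.append(SpikeTrain(unit.unit_id, np.asarray(times)))
        epochs[unit.unit_id] = [(drive.t0 + a / fs, drive.t0 + b / fs)
                                for a, b in eps]
        rates[unit.unit_id] = rate_tr
    return SimulationResult(trains=tuple(trains), epochs=epochs, rates=rates,
                            drive=drive)


def simulate_force(drive: DriveTrace, noise_sd: float = 0.0, seed: int = 0,
                   cutoff_hz: float = 5.0) -> ForceTrace:
    """Force = drive + zero-mean low-pass (< ``cutoff_hz``) noise."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if noise_sd == 0:
        return ForceTrace(fs=drive.fs, values=drive.values.copy(), t0=drive.t0)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(len(drive))
    b, a = sps.butter(4, cutoff_hz / (drive.fs / 2.0), btype="low")
    coloured = sps.filtfilt(b, a, white)
    coloured -= coloured.mean()
    sd = coloured.std()
    if sd > 0:
        coloured *= noise_sd / sd
    return ForceTrace(fs=drive.fs, values=drive.values + coloured, t0=drive.t0)


@dataclass(frozen=True)
class EmgRecording:
    """Multichannel EMG-like signal on a uniform grid."""

    fs: float
    channels: Tuple[str, ...]
    data: np.ndarray  # (n_samples, n_channels)
    t0: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[1] != len(self.channels):
            raise ValueError("data must be (n_samples, n_channels)")
        object.__setattr__(self, "data", d)


#: summed pool rate (pps) mapping to unit carrier amplitude
EMG_ACTIVITY_SCALE = 100.0


def simulate_global_emg(rates: np.ndarray, fs: float,
                        channels: Sequence[str] = ("TA", "FL", "GL", "GM"),
                        noise_sd: float = 0.0, seed: int = 0) -> EmgRecording:
    """Interference-EMG stand-in: a zero-mean carrier amplitude-modulated by
    the summed unit activity, plus additive noise.

    ``rates`` is ``(n_units, n_samples)`` of instantaneous rates (pps); the
    rectified low-passed envelope of the output is monotone in the summed
    activity.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    activity = rates.sum(axis=0) / EMG_ACTIVITY_SCALE
    rng = np.random.default_rng(seed)
    n = activity.size
    data = np.empty((n, len(channels)))
    for k in range(len(channels)):
        carrier = rng.standard_normal(n)
        noise = noise_sd * rng.standard_normal(n) if noise_sd > 0 else 0.0
        data[:, k] = activity * carrier + noise
    return EmgRecording(fs=fs, channels=tuple(channels), data=data)


def simulate_unit_emg(trains: Sequence[SpikeTrain], fs: float, duration: float,
                      n_channels: int = 4, noise_sd: float = 0.0,
                      seed: int = 0, waveform_ms: float = 10.0):
    """Waveform-bearing surface-EMG stand-in for spike-triggered averaging.

    Each unit contributes a fixed biphasic multichannel action-potential
    waveform at every discharge time.  Returns ``(recording, waveforms)``
    where ``waveforms`` maps unit id to its ground-truth ``(L, n_channels)``
    waveform.  This is deliberately too simple for blind-source-separation
    testing; it only supports averaging/correlation analyses.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    L = int(round(waveform_ms / 1000.0 * fs))
    L += (L + 1) % 2  # odd length, centred on the trigger
    half = L // 2
    tt = np.arange(L) - half
    base = np.sin(2 * np.pi * tt / L) * np.hanning(L)
    data = np.zeros((n, n_channels))
    waveforms: Dict[str, np.ndarray] = {}
    for tr in trains:
        amps = rng.uniform(0.5, 1.5, n_channels) * rng.choice([-1.0, 1.0], n_channels)
        shifts = rng.integers(-half // 2, half // 2 + 1, n_channels)
        wav = np.stack([np.roll(base, int(s)) * a for s, a in zip(shifts, amps)],
                       axis=1)
        waveforms[tr.unit_id] = wav
        idx = np.round(tr.times * fs).astype(int)
        idx = idx[(idx >= half) & (idx < n - half)]
        for i in idx:
            data[i - half:i + half + 1] += wav
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    channels = tuple(f"ch{c + 1}" for c in range(n_channels))
    return EmgRecording(fs=fs, channels=channels, data=data), waveforms


def corrupt_two_source(train: SpikeTrain, jitter_sd: float = 0.0,
                       p_miss: float = 0.0, p_extra: float = 0.0,
                       seed: int = 0) -> SpikeTrain:
    """Corrupted copy of a spike train emulating a second decomposition.

    Each discharge is deleted independently with probability ``p_miss``;
    survivors are jittered by zero-mean Gaussian noise with SD ``jitter_sd``
    (milliseconds); spurious discharges are inserted uniformly over the
    train's span at an expected count of ``p_extra * n``.
    """
    if not (0 <= p_miss < 1):
        raise ConfigurationError("p_miss must be in [0, 1)")
    if p_extra < 0 or jitter_sd < 0:
        raise ConfigurationError("p_extra and jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = train.times
    keep = rng.random(t.size) >= p_miss
    out = t[keep]
    if jitter_sd > 0 and out.size:
        out = out + rng.normal(0.0, jitter_sd / 1000.0, out.size)
    if p_extra > 0 and t.size >= 2:
        n_extra = rng.poisson(p_extra * t.size)
        extras = rng.uniform(t[0], t[-1], n_extra)
        out = np.concatenate([out, extras])
    out = np.sort(out)
    out = out[out >= 0]
    if out.size > 1:  # drop near-duplicates produced by jitter/insertion
        keep2 = np.concatenate([[True],
                                np.diff(out) >= MIN_SPIKE_SEPARATION_S])
        out = out[keep2]
    return SpikeTrain(train.unit_id, out)


@dataclass(frozen=True)
class ThreeStageProfile:
    """Drive profile of the three-stage TIII strategy.

    Stage 1 recruits both units of the pair (rise above the higher
    recruitment threshold), stage 2 lowers the drive into the interval where
    only the higher-threshold unit keeps firing, stage 3 raises it slightly
    while staying below the lower-threshold unit's re-recruitment level.
    ``feasible`` is False when no stage-2 level exists (the pair's
    de-recruitment order is not reversed); the profile is still simulable.
    """

    drive: DriveTrace
    feasible: bool
    levels: Tuple[float, float, float]
    stage_windows: Dict[str, Tuple[float, float]]


def three_stage_policy(pair: Sequence[MotorUnitParams], overshoot: float = 1.0,
                       dwell: float = 2.5, fs: float = 2048.0,
                       transition_slope: float = 2.0,
                       dwell2: float = 1.0,
                       dwell3: float = 6.0) -> ThreeStageProfile:
    """Piecewise-linear drive implementing the three-stage TIII strategy.

    ``pair`` must be ordered by recruitment threshold (MU1 first).  The
    stage-2 level must silence MU1 while keeping MU2 firing, which requires
    ``theta_off(MU1) > theta_off(MU2)`` (reversed de-recruitment order).
    The drive visits the stage-2 minimum only briefly (``dwell2``) and
    holds the slightly raised stage-3 level (``dwell3``) until the hit, as
    in the described strategy ("reduce to a minimum, then slightly
    increase again").
    """
    mu1, mu2 = pair
    if mu1.theta_on > mu2.theta_on:
        raise ConfigurationError("pair must be ordered by theta_on (MU1 first)")
    lo = max(mu2.theta_off, 0.0)
    hi = min(mu1.theta_off, mu1.theta_on)
    feasible = hi - lo > 1e-9
    l1 = mu2.theta_on + overshoot
    if feasible:
        l2 = lo + 0.2 * (hi - lo)
        l3 = lo + 0.6 * (hi - lo)
    else:
        l2 = lo + 0.1
        l3 = l2
    sl = transition_slope
    pts_t = [0.0]
    pts_v = [0.0]

    def seg(level: float, hold: float) -> Tuple[float, float]:
        t_arr = pts_t[-1] + abs(level - pts_v[-1]) / sl
        pts_t.append(t_arr)
        pts_v.append(level)
        pts_t.append(t_arr + hold)
        pts_v.append(level)
        return t_arr, t_arr + hold

    w1 = seg(l1, dwell)
    w2 = seg(l2, dwell2)
    w3 = seg(l3, dwell3)
    seg(0.0, 0.5)
    total = pts_t[-1]
    n = int(round(total * fs))
    t = np.arange(n) / fs
    drive = DriveTrace(fs=fs, values=np.interp(t, pts_t, pts_v))
    return ThreeStageProfile(
        drive=drive, feasible=feasible, levels=(l1, l2, l3),
        stage_windows={"stage1": w1, "stage2": w2, "stage3": w3})
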