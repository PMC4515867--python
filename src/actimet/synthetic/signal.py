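"""Synthetic raw wrist-accelerometer recordings with analytic ground truth.

The generator emulates the measurement regime the processing chain is built
for: a triaxial wrist device worn continuously for several whole days,
storing gravity-unit samples at a nominal rate, with per-axis gain/offset
miscalibration, sensor noise, scheduled MVPA bouts and device-removal
(nonwear) intervals.

Activity is synthesized in the ENMO domain and lifted to three axes by
placing a magnitude of ``1 g + ENMO`` along a unit orientation vector:

* awake time: the orientation rotates slowly in a random plane, so worn
  time always shows large per-axis ranges;
* sleep: piecewise-constant random postures (changing every
  ``posture_period_min``) at magnitude exactly 1 g — these are the static
  periods autocalibration feeds on, and the posture jumps are what keeps
  the SD/range nonwear detector from mistaking quiet sleep for nonwear;
* nonwear: an exactly constant (noise-free) gravity vector by default,
  with optional jitter for harder test cases.

Because every level is piecewise constant on the epoch grid, the weekly
summaries a perfect pipeline would produce (ENMO after ideal same-clock-time
imputation, bouted MVPA minutes, wear mask) have closed forms, returned as
:class:`SignalTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..accelerometry import (
    BLOCK_LENGTH_S,
    BLOCKS_PER_DAY,
    DEFAULT_MVPA_SETTINGS,
    MG_PER_G,
    SECONDS_PER_DAY,
    RawRecording,
)

__all__ = ["SignalProfile", "SignalTruth", "generate_raw_recording",
           "random_study_profile"]


class ProfileError(ValueError):
    """Raised when a SignalProfile is internally inconsistent."""


@dataclass(frozen=True)
class SignalProfile:
    """Recipe for one synthetic recording.

    MVPA bouts are ``(day, start_hour, duration_min, level_mg)`` and
    nonwear intervals ``(day, start_hour, duration_min)``; clock hours are
    fractional (10.5 = 10:30). Nonwear intervals must sit on the 15-min
    block grid and must not share a clock slot with any bout on any day,
    which keeps the imputation ground truth exact.
    """

    days: int = 8
    sampling_rate_hz: float = 87.5
    sleep_window: tuple[float, float] = (23.0, 7.0)  # start, end clock hour
    sleep_enmo_mg: float = 0.0
    background_enmo_mg: float = 30.0
    mvpa_bouts: tuple[tuple[int, float, float, float], ...] = ()
    nonwear_intervals: tuple[tuple[int, float, float], ...] = ()
    axis_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_offset_g: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_g: float = 0.003
    nonwear_jitter_g: float = 0.0
    posture_period_min: float = 20.0
    rotation_period_s: float = 600.0
    start_weekday: int = 0
    seed: int = 0

    def validate(self, epoch_length_s: float, max_bout_window_min: float) -> None:
        p = self
        if p.days < 1:
            raise ProfileError("need at least one day")
        if p.sampling_rate_hz <= 0:
            raise ProfileError("sampling_rate_hz must be positive")
        if abs(p.sampling_rate_hz * SECONDS_PER_DAY -
               round(p.sampling_rate_hz * SECONDS_PER_DAY)) > 1e-6:
            raise ProfileError("sampling rate must give whole samples per day")
        for v in (p.sleep_enmo_mg, p.background_enmo_mg):
            if not np.isfinite(v) or v < 0:
                raise ProfileError("ENMO levels must be finite and nonnegative")
        if not all(np.isfinite(p.axis_gain)) or not all(np.isfinite(p.axis_offset_g)):
            raise ProfileError("calibration distortion must be finite")
        if p.noise_sd_g < 0 or p.nonwear_jitter_g < 0:
            raise ProfileError("noise SDs must be nonnegative")

        spans: dict[int, list[tuple[float, float, str]]] = {}
        for day, start_h, dur_min, level in p.mvpa_bouts:
            if dur_min <= 0:
                raise ProfileError("bout durations must be positive")
            if level < 0:
                raise ProfileError("bout levels must be nonnegative")
            start_s = start_h * 3600.0
            end_s = start_s + dur_min * 60.0
            if not (0 <= day < p.days) or end_s > SECONDS_PER_DAY:
                raise ProfileError("bouts must lie within a single recorded day")
            if abs(start_s / epoch_length_s - round(start_s / epoch_length_s)) > 1e-9 \
                    or abs(dur_min * 60 / epoch_length_s -
                           round(dur_min * 60 / epoch_length_s)) > 1e-9:
                raise ProfileError("bouts must align to the epoch grid")
            if self._in_sleep(start_s) or self._in_sleep(end_s - 1e-6):
                raise ProfileError("bouts must not overlap the sleep window")
            spans.setdefault(day, []).append((start_s, end_s, "bout"))
        for day, start_h, dur_min in p.nonwear_intervals:
            if dur_min <= 0:
                raise ProfileError("nonwear durations must be positive")
            start_s = start_h * 3600.0
            end_s = start_s + dur_min * 60.0
            if not (0 <= day < p.days) or end_s > SECONDS_PER_DAY:
                raise ProfileError("nonwear must lie within a single recorded day")
            if start_s % BLOCK_LENGTH_S or (dur_min * 60) % BLOCK_LENGTH_S:
                raise ProfileError("nonwear intervals must align to 15-min blocks")
            # clock-time overlap with bouts on ANY day would make the
            # imputation/MVPA truth depend on detector behaviour
            for bday, bstart, bdur, _ in p.mvpa_bouts:
                bs, be = bstart * 3600.0, bstart * 3600.0 + bdur * 60.0
                if start_s < be and bs < end_s:
                    raise ProfileError(
                        "nonwear interval shares a clock slot with a bout "
                        f"(day {day} nonwear vs day {bday} bout)")
            spans.setdefault(day, []).append((start_s, end_s, "nonwear"))
        for day, items in spans.items():
            items.sort()
            for (s0, e0, k0), (s1, e1, k1) in zip(items, items[1:]):
                if s1 < e0:
                    raise ProfileError(f"overlapping {k0}/{k1} intervals on day {day}")
                if k0 == k1 == "bout" and s1 - e0 < max_bout_window_min * 60:
                    raise ProfileError(
                        f"bouts on day {day} closer than the longest bout window")

    def _in_sleep(self, second_of_day: float) -> bool:
        start, end = self.sleep_window
        h = (second_of_day / 3600.0) % 24
        if start <= end:
            return start <= h < end
        return h >= start or h < end


@dataclass
class SignalTruth:
    """Ground truth implied by a :class:`SignalProfile`."""

    wear: np.ndarray                      # (days, 96) bool
    weekly_enmo_mg: float
    bouted_mvpa_min_per_week: dict[tuple[float, int], float]
    day_enmo_mg: np.ndarray               # after ideal imputation
    day_mvpa_min: dict[tuple[float, int], np.ndarray]
    day_weekday: np.ndarray
    included: bool

    @property
    def wear_fraction(self) -> float:
        return float(self.wear.mean())


# ---------------------------------------------------------------------------


def _sleep_sample_mask_bounds(profile: SignalProfile) -> list[tuple[float, float]]:
    """Sleep intervals in absolute seconds over the whole recording."""
    start_h, end_h = profile.sleep_window
    out: list[tuple[float, float]] = []
    total = profile.days * SECONDS_PER_DAY
    if start_h <= end_h:
        for d in range(profile.days):
            out.append((d * SECONDS_PER_DAY + start_h * 3600,
                        d * SECONDS_PER_DAY + end_h * 3600))
    else:
        # crosses midnight: merge evening-of-day-d with morning-of-day-d+1
        if end_h > 0:
            out.append((0.0, end_h * 3600))
        for d in range(profile.days):
            lo = d * SECONDS_PER_DAY + start_h * 3600
            hi = min((d + 1) * SECONDS_PER_DAY + end_h * 3600, total)
            out.append((lo, min(hi, total)))
    return [(lo, hi) for lo, hi in out if hi > lo]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _fill_epoch_levels(profile: SignalProfile, epoch_length_s: float) -> np.ndarray:
    """True ENMO level (mg) per epoch, (days, epochs_per_day)."""
    epd = int(round(SECONDS_PER_DAY / epoch_length_s))
    levels = np.full((profile.days, epd), profile.background_enmo_mg, dtype=float)
    hours = (np.arange(epd) + 0.5) * epoch_length_s / 3600.0
    start_h, end_h = profile.sleep_window
    sleep = (start_h <= hours) & (hours < end_h) if start_h <= end_h \
        else (hours >= start_h) | (hours < end_h)
    levels[:, sleep] = profile.sleep_enmo_mg
    for day, start_h_b, dur_min, level in profile.mvpa_bouts:
        k0 = int(round(start_h_b * 3600 / epoch_length_s))
        k1 = k0 + int(round(dur_min * 60 / epoch_length_s))
        levels[day, k0:k1] = level
    return levels


def _true_wear(profile: SignalProfile) -> np.ndarray:
    wear = np.ones((profile.days, BLOCKS_PER_DAY), dtype=bool)
    for day, start_h, dur_min in profile.nonwear_intervals:
        b0 = int(round(start_h * 3600 / BLOCK_LENGTH_S))
        b1 = b0 + int(round(dur_min * 60 / BLOCK_LENGTH_S))
        wear[day, b0:b1] = False
    return wear


def _collapse(values: np.ndarray, weekdays: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # duplicate-weekday averaging (first/last occurrence), kept local so the
    # truth computation does not lean on the code path it validates
    vals = values.astype(float).copy()
    keep = np.ones(len(vals), dtype=bool)
    for wd in range(7):
        occ = np.nonzero(weekdays == wd)[0]
        if len(occ) >= 2:
            vals[occ[0]] = 0.5 * (values[occ[0]] + values[occ[-1]])
            keep[occ[1:]] = False
    return vals[keep], weekdays[keep]


def _weekly(day_values: np.ndarray, weekdays: np.ndarray) -> float:
    vals, wds = _collapse(day_values, weekdays)
    weekend = wds >= 5
    if not weekend.any() or weekend.all():
        return float("nan")  # profile spans no full week; not includable
    return float((5.0 * vals[~weekend].mean() + 2.0 * vals[weekend].mean()) / 7.0)


def _compute_truth(
    profile: SignalProfile,
    epoch_length_s: float,
    mvpa_settings: Sequence[tuple[float, float]],
    frac: float,
) -> SignalTruth:
    levels = _fill_epoch_levels(profile, epoch_length_s)
    wear = _true_wear(profile)
    epb = int(round(BLOCK_LENGTH_S / epoch_length_s))
    arr = levels.reshape(profile.days, BLOCKS_PER_DAY, epb)

    # ideal imputation: nonwear blocks take the per-epoch mean over worn days
    col_n = wear.sum(axis=0)
    col_sum = np.where(wear[:, :, None], arr, 0.0).sum(axis=0)
    imputed = arr.copy()
    rows, cols = np.nonzero(~wear & (col_n > 0)[None, :])
    imputed[rows, cols] = (col_sum / np.maximum(col_n, 1)[:, None])[cols]
    lost = ~wear & (col_n == 0)[None, :]
    imputed[lost] = np.nan
    day_enmo = np.nanmean(imputed.reshape(profile.days, -1), axis=1)

    weekdays = (profile.start_weekday + np.arange(profile.days)) % 7
    weekly_enmo = _weekly(day_enmo, weekdays)

    day_mvpa: dict[tuple[float, int], np.ndarray] = {}
    weekly_mvpa: dict[tuple[float, int], float] = {}
    for threshold, bout_len in mvpa_settings:
        key = (float(threshold), int(bout_len))
        w_epochs = int(round(bout_len * 60 / epoch_length_s))
        need = frac * w_epochs - 1e-9
        per_day = np.zeros(profile.days)
        for day, start_h, dur_min, level in profile.mvpa_bouts:
            dur_epochs = int(round(dur_min * 60 / epoch_length_s))
            if level >= threshold and dur_epochs >= need:
                per_day[day] += dur_min
        day_mvpa[key] = per_day
        weekly_mvpa[key] = _weekly(per_day, weekdays)

    wear_hours = wear.sum(axis=1) * BLOCK_LENGTH_S / 3600.0
    valid = wear_hours >= 16.0
    weekend = weekdays >= 5
    included = int((valid & ~weekend).sum()) >= 2 and int((valid & weekend).sum()) >= 2

    return SignalTruth(
        wear=wear,
        weekly_enmo_mg=weekly_enmo,
        bouted_mvpa_min_per_week=weekly_mvpa,
        day_enmo_mg=day_enmo,
        day_mvpa_min=day_mvpa,
        day_weekday=weekdays,
        included=included,
    )


def random_study_profile(seed: int, *, days: int = 8,
                         sampling_rate_hz: float = 25.0) -> SignalProfile:
    """A randomized but valid study-like profile for recovery experiments.

    Bouts (0–2 per day, 6–40 min, 110–180 mg) occupy morning slots; nonwear
    removals (two per recording, 1–3 h, block-aligned) occupy afternoon
    slots, so they never share a clock slot with a bout. Calibration error
    (up to ±2% gain, ±15 mg offset) and sensor noise are always present.
    """
    rng = np.random.default_rng(seed)
    bouts: list[tuple[int, float, float, float]] = []
    for day in range(days):
        n_b = int(rng.integers(0, 3))
        for slot in (8.5, 11.0)[:n_b]:
            dur = float(rng.choice([6, 12, 15, 20, 30, 40]))
            level = float(rng.choice([110.0, 125.0, 150.0, 180.0]))
            bouts.append((day, slot, dur, level))
    nonwear = []
    for day in rng.choice(days, size=2, replace=False):
        start = float(rng.choice([15.0, 16.5, 18.0, 19.5]))
        dur = float(rng.choice([60, 120, 180]))
        nonwear.append((int(day), start, dur))
    return SignalProfile(
        days=days,
        sampling_rate_hz=sampling_rate_hz,
        background_enmo_mg=float(rng.uniform(20.0, 45.0)),
        mvpa_bouts=tuple(bouts),
        nonwear_intervals=tuple(nonwear),
        axis_gain=tuple(1.0 + rng.uniform(-0.02, 0.02, 3)),
        axis_offset_g=tuple(rng.uniform(-0.015, 0.015, 3)),
        start_weekday=int(rng.integers(0, 7)),
        seed=int(rng.integers(0, 2 ** 31)),
    )


# ---------------------------------------------------------------------------


def generate_raw_recording(
    profile: SignalProfile,
    *,
    epoch_length_s: float = 5.0,
    mvpa_settings: Sequence[tuple[float, float]] = DEFAULT_MVPA_SETTINGS,
    bout_fraction: float = 0.8,
    participant_id: str | None = None,
) -> tuple[RawRecording, SignalTruth]:
    """Synthesize one raw recording and its analytic ground truth.

    The recording starts exactly at midnight and spans ``profile.days``
    whole days. Two calls with the same profile (same seed) are
    byte-identical.
    """
    max_window = max((b for _, b in mvpa_settings), default=10)
    profile.validate(epoch_length_s, max_window)
    rng = np.random.default_rng(profile.seed)
    fs = profile.sampling_rate_hz
    n = int(round(profile.days * SECONDS_PER_DAY * fs))

    def srange(lo_s: float, hi_s: float) -> slice:
        return slice(int(math.ceil(lo_s * fs - 1e-6)),
                     min(int(math.ceil(hi_s * fs - 1e-6)), n))

    # per-sample true ENMO level (mg)
    e = np.full(n, profile.background_enmo_mg, dtype=np.float32)
    for lo, hi in _sleep_sample_mask_bounds(profile):
        e[srange(lo, hi)] = profile.sleep_enmo_mg
    for day, start_h, dur_min, level in profile.mvpa_bouts:
        lo = day * SECONDS_PER_DAY + start_h * 3600
        e[srange(lo, lo + dur_min * 60)] = level

    # orientation: slow rotation in a random plane while awake
    basis = np.linalg.qr(rng.standard_normal((3, 3)))[0][:, :2]
    # the awake rotation repeats every rotation period: build one period
    # and tile it, which is much cheaper than trig over every sample
    p_samp = int(round(profile.rotation_period_s * fs))
    phase = np.arange(p_samp, dtype=np.float64) * (2 * np.pi / p_samp)
    c, s = np.cos(phase).astype(np.float32), np.sin(phase).astype(np.float32)
    reps = -(-n // p_samp)
    u = np.empty((n, 3), dtype=np.float32)
    for axis in range(3):
        one = c * np.float32(basis[axis, 0]) + s * np.float32(basis[axis, 1])
        u[:, axis] = np.tile(one, reps)[:n]
    del phase, c, s

    # sleep: piecewise-constant random postures on a fixed clock grid
    period_s = profile.posture_period_min * 60.0
    for lo, hi in _sleep_sample_mask_bounds(profile):
        edge = math.floor(lo / period_s) * period_s
        while edge < hi:
            nxt = edge + period_s
            sl = srange(max(lo, edge), min(hi, nxt))
            if sl.stop > sl.start:
                u[sl] = _random_unit(rng).astype(np.float32)
            edge = nxt

    gain = np.asarray(profile.axis_gain, dtype=np.float32)
    offset = np.asarray(profile.axis_offset_g, dtype=np.float32)
    e *= np.float32(1.0 / MG_PER_G)
    e += np.float32(1.0)
    v = u
    v *= e[:, None]
    del e, u
    v *= gain
    v += offset
    if profile.noise_sd_g > 0:
        noise = rng.standard_normal((n, 3), dtype=np.float32)
        noise *= np.float32(profile.noise_sd_g)
        v += noise
        del noise

    # nonwear: device at rest — constant gravity vector through the same
    # distortion, noise-free by default
    for day, start_h, dur_min in profile.nonwear_intervals:
        lo = day * SECONDS_PER_DAY + start_h * 3600
        sl = srange(lo, lo + dur_min * 60)
        still = _random_unit(rng).astype(np.float32) * gain + offset
        v[sl] = still
        if profile.nonwear_jitter_g > 0:
            jit = rng.standard_normal((sl.stop - sl.start, 3), dtype=np.float32)
            v[sl] += jit * np.float32(profile.nonwear_jitter_g)

    rec = RawRecording(v, fs, 0.0, profile.start_weekday, participant_id)
    truth = _compute_truth(profile, epoch_length_s, mvpa_settings, bout_fraction)
    return rec, truth
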