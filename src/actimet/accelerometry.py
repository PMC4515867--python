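"""Raw wrist-accelerometry processing.

Turns a raw triaxial recording (g units) into per-participant weekly
physical-activity summaries: mean ENMO (Euclidean Norm Minus One g,
negatives truncated, in milligravity) and bouted moderate-to-vigorous
physical activity (MVPA) minutes per week.

Processing chain (in the order the functions are meant to be called):

1.  :func:`autocalibrate` — estimate per-axis gain/offset from static
    periods and correct the signal if the calibration error warrants it.
2.  :func:`compute_enmo` — per-sample ENMO averaged into fixed epochs on a
    midnight-aligned day grid (data outside the first/last midnight are
    discarded).
3.  :func:`detect_nonwear` — SD/range nonwear detection on 60-min moving
    windows with 15-min increments.
4.  :func:`impute_nonwear` — replace nonwear blocks by the same-clock-time
    mean over other worn days.
5.  :func:`select_valid_days` — >=16 h/d wear; inclusion needs >=2 valid
    weekdays and >=2 valid weekend days; at most 8 measured days.
6.  :func:`collapse_duplicate_days` / :func:`weekly_average` — duplicate
    weekday names averaged (first and last occurrence), then the weekly
    mean is (5 * weekday mean + 2 * weekend mean) / 7.
7.  :func:`detect_mvpa_bouts` / :func:`meets_who` — fractional-threshold
    moving-window bout detection and the WHO >=150 min/wk flag.

:func:`summarize_recording` chains all of the above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MG_PER_G = 1000.0
SECONDS_PER_DAY = 86400
BLOCK_LENGTH_S = 900          # 15-min nonwear/imputation blocks
BLOCKS_PER_DAY = SECONDS_PER_DAY // BLOCK_LENGTH_S
WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: (threshold mg, bout length min) settings used throughout: the main
#: 100 mg / 10 min rule plus the 1-min-bout and 120-mg sensitivity variants.
DEFAULT_MVPA_SETTINGS: tuple[tuple[float, int], ...] = (
    (100.0, 10),
    (100.0, 1),
    (120.0, 10),
    (120.0, 1),
)

WHO_MVPA_MIN_PER_WEEK = 150.0


class RecordingError(ValueError):
    """Raised for structurally invalid raw recordings or parameters."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawRecording:
    """Uniformly sampled triaxial acceleration in gravity (g) units.

    Parameters
    ----------
    xyz:
        ``(n_samples, 3)`` array of x/y/z acceleration in g.
    sampling_rate_hz:
        Nominal sampling rate (87.5 Hz for the emulated device; any
        positive rate with an integer number of samples per day works).
    start_time_s:
        Seconds elapsed since the midnight that opens "day 0" of the
        recording's civil clock. Timestamps are implicit:
        ``start_time_s + i / sampling_rate_hz``.
    start_weekday:
        Weekday of day 0 (0 = Monday ... 6 = Sunday).
    """

    xyz: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    start_weekday: int = 0
    participant_id: str | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise RecordingError(f"xyz must be (n, 3); got {xyz.shape}")
        if not self.sampling_rate_hz > 0:
            raise RecordingError("sampling_rate_hz must be positive")
        if not np.isfinite(xyz).all():
            raise RecordingError("acceleration values must be finite")
        if not 0 <= self.start_weekday <= 6:
            raise RecordingError("start_weekday must be in 0..6")
        object.__setattr__(self, "xyz", xyz)

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Timestamps in seconds since day-0 midnight (strictly increasing)."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class CalibrationParams:
    """Estimated sensor distortion (observed = gain * true + offset)."""

    gain: np.ndarray
    offset_g: np.ndarray
    residual_error_mg: float
    residual_before_mg: float
    n_static_windows: int
    converged: bool
    corrected: bool

    @classmethod
    def identity(cls, residual: float = float("nan"), n_windows: int = 0,
                 converged: bool = False) -> "CalibrationParams":
        return cls(np.ones(3), np.zeros(3), residual, residual, n_windows,
                   converged, corrected=False)


@dataclass
class EpochSeries:
    """ENMO (mg) per fixed epoch on a midnight-aligned whole-day grid.

    ``enmo_mg`` has shape (n_days, epochs_per_day); NaN marks epochs that
    are missing (nonwear that could not be imputed).
    """

    enmo_mg: np.ndarray
    epoch_length_s: float
    day_weekday: np.ndarray  # weekday index per day, 0=Mon

    def __post_init__(self) -> None:
        self.enmo_mg = np.asarray(self.enmo_mg, dtype=float)
        self.day_weekday = np.asarray(self.day_weekday, dtype=int)
        if self.enmo_mg.ndim != 2:
            raise RecordingError("enmo_mg must be 2-D (days x epochs)")
        if SECONDS_PER_DAY % self.epoch_length_s:
            raise RecordingError("epoch length must divide the day exactly")
        if self.n_days and self.enmo_mg.shape[1] != SECONDS_PER_DAY / self.epoch_length_s:
            raise RecordingError("epochs do not tile whole days")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.enmo_mg, initial=0.0) < 0:
                raise RecordingError("ENMO must be nonnegative")

    @property
    def n_days(self) -> int:
        return self.enmo_mg.shape[0]

    @property
    def epochs_per_day(self) -> int:
        return self.enmo_mg.shape[1]

    @property
    def is_weekend(self) -> np.ndarray:
        return self.day_weekday >= 5


@dataclass
class WearMask:
    """Wear flag per 15-min block, aligned to the EpochSeries day grid."""

    wear: np.ndarray  # (n_days, BLOCKS_PER_DAY) bool
    day_weekday: np.ndarray

    def __post_init__(self) -> None:
        self.wear = np.asarray(self.wear, dtype=bool)
        self.day_weekday = np.asarray(self.day_weekday, dtype=int)
        if self.wear.ndim != 2 or (self.wear.size and self.wear.shape[1] != BLOCKS_PER_DAY):
            raise RecordingError("wear mask must be (days, 96)")

    @property
    def n_days(self) -> int:
        return self.wear.shape[0]

    @property
    def wear_hours_per_day(self) -> np.ndarray:
        return self.wear.sum(axis=1) * (BLOCK_LENGTH_S / 3600.0)


@dataclass
class DaySelection:
    """Validity decision: which days are valid and whether the participant
    meets the >=2 valid weekdays AND >=2 valid weekend days inclusion rule."""

    valid: np.ndarray
    included: bool
    n_valid_weekdays: int
    n_valid_weekend_days: int


@dataclass
class WeeklySummary:
    """Per-participant weekly activity metrics."""

    weekly_mean_enmo_mg: float
    mvpa_min_per_week: dict[tuple[float, int], float]
    meets_who: dict[tuple[float, int], bool]
    n_valid_weekdays: int
    n_valid_weekend_days: int
    imputed_fraction: float
    calibration: CalibrationParams | None = None
    wear_mask: "WearMask | None" = None

    def __post_init__(self) -> None:
        for setting, minutes in self.mvpa_min_per_week.items():
            if not 0 <= minutes <= 7 * 24 * 60:
                raise RecordingError(f"impossible MVPA minutes {minutes} at {setting}")
        if not 0 <= self.imputed_fraction <= 1:
            raise RecordingError("imputed_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# day grid helpers
# ---------------------------------------------------------------------------


def _full_day_span(rec: RawRecording) -> tuple[int, int, int]:
    """(first sample index, number of whole days, calendar index of first day).

    Whole days run midnight-to-midnight on the recording's civil clock;
    samples before the first or after the last midnight are dropped.
    """
    fs = rec.sampling_rate_hz
    t0 = rec.start_time_s
    first_mid = math.ceil(t0 / SECONDS_PER_DAY - 1e-9) * SECONDS_PER_DAY
    t_end = t0 + rec.n_samples / fs
    last_mid = math.floor(t_end / SECONDS_PER_DAY + 1e-9) * SECONDS_PER_DAY
    n_days = max(0, int(round((last_mid - first_mid) / SECONDS_PER_DAY)))
    if n_days == 0:
        return 0, 0, 0
    i0 = int(math.ceil((first_mid - t0) * fs - 1e-6))
    return i0, n_days, int(round(first_mid / SECONDS_PER_DAY))


def _segment_starts(n_samples: int, fs: float, segment_s: float,
                    n_segments: int) -> np.ndarray:
    """Sample index opening each segment of length ``segment_s`` seconds."""
    k = np.arange(n_segments)
    return np.ceil(k * segment_s * fs - 1e-6).astype(np.int64)


def day_weekdays(rec: RawRecording) -> np.ndarray:
    """Weekday index of each whole day retained by the midnight trim."""
    _, n_days, day0 = _full_day_span(rec)
    return (rec.start_weekday + day0 + np.arange(n_days)) % 7


# ---------------------------------------------------------------------------
# autocalibration
# ---------------------------------------------------------------------------


def autocalibrate(
    rec: RawRecording,
    *,
    window_s: float = 10.0,
    sd_threshold_mg: float = 13.0,
    min_static_windows: int = 20,
    max_static_windows: int = 2000,
    error_tolerance_mg: float = 2.0,
    max_iter: int = 100,
) -> tuple[RawRecording, CalibrationParams]:
    """Estimate and, if necessary, correct per-axis gain/offset error.

    Static windows (all three axis SDs below ``sd_threshold_mg`` over
    ``window_s``-second non-overlapping windows) should have vector
    magnitude exactly 1 g; deviations are attributed to a per-axis linear
    distortion ``observed = gain * true + offset`` which is estimated by
    iteratively regressing each axis of the unit-sphere projection of the
    (partially corrected) static points on the observed static points.
    Correction is applied only when the initial residual exceeds
    ``error_tolerance_mg`` ("corrected if necessary").

    Returns the (possibly corrected) recording and the estimated params.
    With fewer than ``min_static_windows`` usable windows the recording is
    returned untouched with identity params and ``converged=False``.
    """
    if rec.duration_s < 3600:
        raise RecordingError("autocalibration needs at least 1 h of data")
    fs = rec.sampling_rate_hz
    w = max(1, int(round(window_s * fs)))
    n_win = rec.n_samples // w
    view = rec.xyz[: n_win * w].reshape(n_win, w, 3)
    means = view.mean(axis=1, dtype=np.float64)
    sds = view.std(axis=1, dtype=np.float64)
    static = (sds < sd_threshold_mg / MG_PER_G).all(axis=1)
    radii = np.linalg.norm(means, axis=1)
    static &= np.abs(radii - 1.0) < 0.25
    pts = means[static]
    if len(pts) > max_static_windows:
        idx = np.linspace(0, len(pts) - 1, max_static_windows).astype(int)
        pts = pts[idx]
    n_static = len(pts)
    if n_static < min_static_windows:
        logger.warning(
            "autocalibrate: only %d static windows (< %d); returning identity",
            n_static, min_static_windows)
        return rec, CalibrationParams.identity(n_windows=n_static)

    def residual_mg(p: np.ndarray) -> float:
        return float(np.abs(np.linalg.norm(p, axis=1) - 1.0).mean() * MG_PER_G)

    res_before = residual_mg(pts)
    if res_before <= error_tolerance_mg:
        # already calibrated well enough; no correction necessary
        return rec, CalibrationParams(
            np.ones(3), np.zeros(3), res_before, res_before, n_static,
            converged=True, corrected=False)

    scale = np.ones(3)
    shift = np.zeros(3)
    prev = res_before
    for _ in range(max_iter):
        corrected = pts * scale + shift
        target = corrected / np.linalg.norm(corrected, axis=1, keepdims=True)
        for axis in range(3):
            design = np.column_stack([pts[:, axis], np.ones(n_static)])
            coef, *_ = np.linalg.lstsq(design, target[:, axis], rcond=None)
            scale[axis], shift[axis] = coef
        res = residual_mg(pts * scale + shift)
        if abs(prev - res) < 1e-10:
            break
        prev = res
    res_after = residual_mg(pts * scale + shift)
    converged = res_after < res_before
    if not converged:  # fit made things worse: keep the data untouched
        logger.warning("autocalibrate: fit did not improve residual; identity kept")
        return rec, CalibrationParams.identity(res_before, n_static, converged=False)
    xyz = rec.xyz * scale.astype(rec.xyz.dtype) + shift.astype(rec.xyz.dtype)
    params = CalibrationParams(
        gain=1.0 / scale,
        offset_g=-shift / scale,
        residual_error_mg=res_after,
        residual_before_mg=res_before,
        n_static_windows=n_static,
        converged=True,
        corrected=True,
    )
    return RawRecording(xyz, fs, rec.start_time_s, rec.start_weekday,
                        rec.participant_id), params


# ---------------------------------------------------------------------------
# ENMO
# ---------------------------------------------------------------------------


def sample_enmo_mg(xyz: np.ndarray) -> np.ndarray:
    """Per-sample ENMO: max(||(x, y, z)|| - 1 g, 0), in milligravity."""
    xyz = np.asarray(xyz)
    # column-wise accumulation in float64: fast and avoids a (n, 3) copy
    acc = xyz[:, 0].astype(np.float64)
    acc *= acc
    for axis in (1, 2):
        col = xyz[:, axis].astype(np.float64)
        col *= col
        acc += col
    np.sqrt(acc, out=acc)
    acc -= 1.0
    np.maximum(acc, 0.0, out=acc)
    acc *= MG_PER_G
    return acc


def compute_enmo(rec: RawRecording, epoch_length_s: float = 5.0) -> EpochSeries:
    """Average per-sample ENMO into epochs on the whole-day grid.

    Recordings shorter than one full midnight-to-midnight day yield an
    empty series (the participant is excluded upstream).
    """
    if SECONDS_PER_DAY % epoch_length_s:
        raise RecordingError("epoch length must divide 86400 s exactly")
    i0, n_days, _ = _full_day_span(rec)
    epd = int(round(SECONDS_PER_DAY / epoch_length_s))
    if n_days == 0:
        logger.warning("recording %s shorter than one full day; excluded",
                       rec.participant_id)
        return EpochSeries(np.empty((0, epd)), epoch_length_s, np.empty(0, int))
    fs = rec.sampling_rate_hz
    n_keep = int(round(n_days * SECONDS_PER_DAY * fs))
    enmo = sample_enmo_mg(rec.xyz[i0: i0 + n_keep])
    starts = _segment_starts(n_keep, fs, epoch_length_s, n_days * epd)
    sums = np.add.reduceat(enmo, starts)
    counts = np.diff(np.append(starts, n_keep))
    values = (sums / counts).reshape(n_days, epd)
    return EpochSeries(values, epoch_length_s, day_weekdays(rec))


# ---------------------------------------------------------------------------
# nonwear
# ---------------------------------------------------------------------------


def detect_nonwear(
    rec: RawRecording,
    *,
    sd_threshold_mg: float = 13.0,
    range_threshold_mg: float = 50.0,
    min_quiet_axes: int = 2,
    window_blocks: int = 4,
) -> WearMask:
    """Classify 15-min blocks as wear/nonwear from axis SD and value range.

    Moving 60-min windows (``window_blocks`` consecutive 15-min blocks,
    advancing one block at a time) are classified as nonwear when at least
    ``min_quiet_axes`` of the three axes have both SD below
    ``sd_threshold_mg`` and value range below ``range_threshold_mg``.
    A block is nonwear iff at least one window containing it is nonwear:
    windows overlapping genuine movement are never quiet, so this recovers
    block-aligned nonwear intervals without dilating into worn time.
    """
    i0, n_days, _ = _full_day_span(rec)
    wdays = day_weekdays(rec)
    if n_days == 0:
        return WearMask(np.empty((0, BLOCKS_PER_DAY), bool), wdays)
    fs = rec.sampling_rate_hz
    n_keep = int(round(n_days * SECONDS_PER_DAY * fs))
    xyz = rec.xyz[i0: i0 + n_keep]
    n_blocks = n_days * BLOCKS_PER_DAY
    starts = _segment_starts(n_keep, fs, BLOCK_LENGTH_S, n_blocks)
    ends = np.append(starts[1:], n_keep)
    counts = (ends - starts).astype(np.float64)

    sums = np.empty((n_blocks, 3))
    sq = np.empty((n_blocks, 3))
    mins = np.empty((n_blocks, 3))
    maxs = np.empty((n_blocks, 3))
    for axis in range(3):
        col = xyz[:, axis].astype(np.float64)
        sums[:, axis] = np.add.reduceat(col, starts)
        sq[:, axis] = np.add.reduceat(col * col, starts)
        mins[:, axis] = np.minimum.reduceat(col, starts)
        maxs[:, axis] = np.maximum.reduceat(col, starts)

    w = min(window_blocks, n_blocks)
    kernel = np.ones(w)

    def roll(a: np.ndarray) -> np.ndarray:
        return np.convolve(a, kernel, mode="valid")

    n_windows = n_blocks - w + 1
    win_nonwear = np.zeros(n_windows, dtype=bool)
    quiet_axes = np.zeros(n_windows, dtype=int)
    for axis in range(3):
        n = roll(counts)
        s = roll(sums[:, axis])
        s2 = roll(sq[:, axis])
        var = np.maximum(s2 / n - (s / n) ** 2, 0.0)
        sd = np.sqrt(var)
        lo = np.minimum.reduce([mins[k: k + n_windows, axis] for k in range(w)])
        hi = np.maximum.reduce([maxs[k: k + n_windows, axis] for k in range(w)])
        quiet = (sd < sd_threshold_mg / MG_PER_G) & (hi - lo < range_threshold_mg / MG_PER_G)
        quiet_axes += quiet
    win_nonwear = quiet_axes >= min_quiet_axes

    block_nonwear = np.zeros(n_blocks, dtype=bool)
    for k in range(w):  # window j covers blocks j .. j+w-1
        block_nonwear[k: k + n_windows] |= win_nonwear
    return WearMask(~block_nonwear.reshape(n_days, BLOCKS_PER_DAY), wdays)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_nonwear(es: EpochSeries, mask: WearMask) -> tuple[EpochSeries, float]:
    """Replace nonwear blocks by the same-clock-time mean over other days.

    Each epoch inside a nonwear 15-min block is replaced by the mean of the
    same-clock-time epoch over the days where that block is worn. Blocks
    with no worn counterpart on any other day stay missing (NaN) and are
    excluded from day means downstream. Worn epochs are never touched, so
    re-running the imputation is a no-op.

    Returns the imputed series and the fraction of the observation period
    that was replaced.
    """
    if es.n_days != mask.n_days:
        raise RecordingError("EpochSeries and WearMask cover different spans")
    if es.n_days < 2:
        raise RecordingError("imputation needs at least 2 days")
    epb = int(round(BLOCK_LENGTH_S / es.epoch_length_s))
    arr = es.enmo_mg.reshape(es.n_days, BLOCKS_PER_DAY, epb)
    worn = mask.wear
    out = arr.copy()
    out[~worn] = np.nan

    worn3 = worn[:, :, None]
    with np.errstate(invalid="ignore"):
        col_sum = np.where(worn3, arr, 0.0).sum(axis=0)
        col_n = worn.sum(axis=0)
        col_mean = np.where(col_n[:, None] > 0, col_sum / np.maximum(col_n, 1)[:, None], np.nan)

    imputable = ~worn & (col_n > 0)[None, :]
    days_idx, block_idx = np.nonzero(imputable)
    out[days_idx, block_idx] = col_mean[block_idx]
    unimputable = ~worn & (col_n == 0)[None, :]
    if unimputable.any():
        bad = sorted(set(np.nonzero(unimputable)[1]))
        logger.warning("blocks %s are nonwear on every day: left missing", bad)
    imputed_fraction = float(imputable.sum() / worn.size) if worn.size else 0.0
    new = EpochSeries(out.reshape(es.n_days, -1), es.epoch_length_s,
                      es.day_weekday.copy())
    return new, imputed_fraction


# ---------------------------------------------------------------------------
# validity, duplicate days, weekly rescaling
# ---------------------------------------------------------------------------


def select_valid_days(
    mask: WearMask,
    *,
    min_wear_hours: float = 16.0,
    min_weekdays: int = 2,
    min_weekend_days: int = 2,
    max_days: int = 8,
) -> DaySelection:
    """Apply the >=16 h/d validity and 2+2 valid-day inclusion rules.

    Only the first ``max_days`` measured days are considered (a week of
    wear plus one duplicated day). The >= comparisons are inclusive.
    """
    hours = mask.wear_hours_per_day
    valid = hours >= min_wear_hours - 1e-9
    valid[max_days:] = False
    weekend = mask.day_weekday >= 5
    n_wd = int((valid & ~weekend).sum())
    n_we = int((valid & weekend).sum())
    included = n_wd >= min_weekdays and n_we >= min_weekend_days
    return DaySelection(valid, included, n_wd, n_we)


def collapse_duplicate_days(
    day_values: np.ndarray, day_weekday: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average the first and last occurrence of a repeated weekday name.

    An 8-day measurement contains one weekday twice (e.g. two Tuesdays a
    week apart); their day means are averaged to represent a unique day.
    """
    day_values = np.asarray(day_values, dtype=float)
    day_weekday = np.asarray(day_weekday, dtype=int)
    keep = np.ones(len(day_values), dtype=bool)
    values = day_values.copy()
    for wd in range(7):
        occ = np.nonzero(day_weekday == wd)[0]
        if len(occ) >= 2:
            first, last = occ[0], occ[-1]
            values[first] = 0.5 * (day_values[first] + day_values[last])
            keep[occ[1:]] = False
    return values[keep], day_weekday[keep]


def weekly_average(weekday_mean: float, weekend_mean: float) -> float:
    """(5 * weekday mean + 2 * weekend mean) / 7.

    Used for both the weekly acceleration (mg) and MVPA minutes per week.
    """
    if weekday_mean is None or weekend_mean is None or \
            not (np.isfinite(weekday_mean) and np.isfinite(weekend_mean)):
        raise RecordingError("weekday and weekend means must both be defined")
    return (5.0 * weekday_mean + 2.0 * weekend_mean) / 7.0


# ---------------------------------------------------------------------------
# MVPA bouts
# ---------------------------------------------------------------------------


def detect_mvpa_bouts(
    es: EpochSeries,
    threshold_mg: float,
    bout_min: float,
    frac: float = 0.8,
    mode: str = "qualifying_supra",
) -> np.ndarray:
    """Bouted MVPA minutes per day with a fractional moving-window rule.

    A moving window of ``bout_min`` minutes (slid epoch by epoch within
    each day) qualifies when the fraction of its epochs at or above
    ``threshold_mg`` is >= ``frac`` (inclusive). MVPA time is, by default,
    the total duration of epochs that are themselves >= the threshold and
    fall inside at least one qualifying window (``mode="qualifying_supra"``);
    ``mode="union"`` instead counts the full union of qualifying windows,
    including sub-threshold epochs they contain.

    Missing (NaN) epochs count as below threshold.
    """
    if threshold_mg <= 0:
        raise RecordingError("threshold_mg must be positive")
    if not 0 < frac <= 1:
        raise RecordingError("frac must be in (0, 1]")
    if mode not in ("qualifying_supra", "union"):
        raise RecordingError(f"unknown bout mode {mode!r}")
    w = int(round(bout_min * 60 / es.epoch_length_s))
    if w < 1:
        raise RecordingError("bout length shorter than one epoch")
    minutes = np.zeros(es.n_days)
    need = frac * w - 1e-9
    for d in range(es.n_days):
        above = es.enmo_mg[d] >= threshold_mg  # NaN compares False
        n = len(above)
        if n < w:
            continue
        cs = np.concatenate([[0], np.cumsum(above)])
        win_counts = cs[w:] - cs[:-w]
        qualifying = win_counts >= need
        covered = np.zeros(n, dtype=bool)
        starts = np.nonzero(qualifying)[0]
        if len(starts):
            delta = np.zeros(n + 1, dtype=int)
            delta[starts] += 1
            delta[starts + w] -= 1
            covered = np.cumsum(delta[:-1]) > 0
        counted = covered if mode == "union" else (covered & above)
        minutes[d] = counted.sum() * es.epoch_length_s / 60.0
    return minutes


def meets_who(mvpa_min_per_week: float) -> bool:
    """True iff weekly MVPA reaches the WHO 2.5 h (150 min) recommendation."""
    return bool(mvpa_min_per_week >= WHO_MVPA_MIN_PER_WEEK)


# ---------------------------------------------------------------------------
# end-to-end per-recording summary
# ---------------------------------------------------------------------------


def summarize_recording(
    rec: RawRecording,
    *,
    epoch_length_s: float = 5.0,
    mvpa_settings: Sequence[tuple[float, float]] = DEFAULT_MVPA_SETTINGS,
    bout_fraction: float = 0.8,
    bout_mode: str = "qualifying_supra",
    calibrate: bool = True,
    mvpa_after_imputation: bool = True,
    nonwear_kwargs: Mapping | None = None,
) -> tuple[WeeklySummary | None, str]:
    """Run the full chain on one recording.

    Returns ``(summary, "ok")`` or ``(None, reason)`` when the recording is
    excluded (too short, or too few valid days).
    """
    params: CalibrationParams | None = None
    if calibrate:
        rec, params = autocalibrate(rec)
    es = compute_enmo(rec, epoch_length_s)
    if es.n_days == 0:
        return None, "shorter than one full day"
    mask = detect_nonwear(rec, **(nonwear_kwargs or {}))
    selection = select_valid_days(mask)
    if not selection.included:
        return None, (f"insufficient valid days "
                      f"({selection.n_valid_weekdays} weekday, "
                      f"{selection.n_valid_weekend_days} weekend)")
    es_raw = es
    es, imputed_fraction = impute_nonwear(es, mask)

    valid = selection.valid
    wd = es.day_weekday
    weekend = wd >= 5

    def rescale(day_values: np.ndarray) -> float:
        vals, wds = collapse_duplicate_days(day_values[valid], wd[valid])
        wknd = wds >= 5
        return weekly_average(vals[~wknd].mean(), vals[wknd].mean())

    day_enmo = np.nanmean(es.enmo_mg, axis=1)
    weekly_enmo = rescale(day_enmo)

    bout_source = es if mvpa_after_imputation else es_raw
    mvpa: dict[tuple[float, int], float] = {}
    who: dict[tuple[float, int], bool] = {}
    for threshold, bout_len in mvpa_settings:
        key = (float(threshold), int(bout_len))
        per_day = detect_mvpa_bouts(bout_source, threshold, bout_len,
                                    frac=bout_fraction, mode=bout_mode)
        weekly = rescale(per_day)
        mvpa[key] = weekly
        who[key] = meets_who(weekly)

    summary = WeeklySummary(
        weekly_mean_enmo_mg=weekly_enmo,
        mvpa_min_per_week=mvpa,
        meets_who=who,
        n_valid_weekdays=selection.n_valid_weekdays,
        n_valid_weekend_days=selection.n_valid_weekend_days,
        imputed_fraction=imputed_fraction,
        calibration=params,
        wear_mask=mask,
    )
    return summary, "ok"
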