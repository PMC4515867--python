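"""Unit and property tests for the raw-signal processing chain."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from actimet import accelerometry as acc
from actimet.synthetic import SignalProfile, generate_raw_recording
from tests.conftest import constant_recording, make_recording


# ---------------------------------------------------------------------------
# ENMO
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("vector, expected_mg", [
    ((0.0, 0.0, 1.0), 0.0),            # resting at exactly 1 g
    ((0.0, 0.0, 1.1), 100.0),          # ||v|| - 1 = 0.1 g
    ((0.6, 0.0, 0.8), 0.0),            # unit vector off-axis
    ((0.0, 0.0, 0.5), 0.0),            # negative ENMO rounded to zero
])
def test_enmo_constant_vectors(vector, expected_mg):
    rec = constant_recording(vector, days=1.0, fs=1.0)
    es = acc.compute_enmo(rec, epoch_length_s=60.0)
    assert es.n_days == 1
    np.testing.assert_allclose(es.enmo_mg, expected_mg, atol=1e-9)


def test_enmo_matches_per_sample_oracle(busy_recording):
    """Epoch means equal a groupby oracle that bypasses the epoching path."""
    rec, _ = busy_recording
    es = acc.compute_enmo(rec, epoch_length_s=5.0)
    # oracle: per-sample ENMO assigned to epochs by timestamp, pandas mean
    t = rec.times()
    enmo = acc.sample_enmo_mg(rec.xyz)
    keep = (t >= 0) & (t < es.n_days * 86400)
    idx = np.floor(t[keep] / 5.0).astype(int)
    oracle = pd.Series(enmo[keep]).groupby(idx).mean().to_numpy()
    np.testing.assert_allclose(es.enmo_mg.ravel(), oracle, rtol=1e-9)


def test_enmo_axis_permutation_invariance(busy_recording):
    rec, _ = busy_recording
    es = acc.compute_enmo(rec)
    permuted = acc.RawRecording(rec.xyz[:, [2, 0, 1]], rec.sampling_rate_hz,
                                rec.start_time_s, rec.start_weekday)
    es_p = acc.compute_enmo(permuted)
    # identical up to floating-point summation order
    np.testing.assert_allclose(es.enmo_mg, es_p.enmo_mg, rtol=1e-12, atol=1e-12)


def test_enmo_nonnegative_and_day_grid(clean_recording, clean_profile):
    rec, _ = clean_recording
    es = acc.compute_enmo(rec)
    assert es.n_days == clean_profile.days
    assert es.epochs_per_day == 86400 / 5
    assert np.nanmin(es.enmo_mg) >= 0


def test_enmo_background_and_sleep_levels(clean_recording, clean_profile):
    """With no noise and identity calibration, every epoch equals its
    injected level (background when awake, sleep level overnight)."""
    rec, _ = clean_recording
    es = acc.compute_enmo(rec)
    hours = (np.arange(es.epochs_per_day) + 0.5) * es.epoch_length_s / 3600
    sleep = (hours >= 23.0) | (hours < 7.0)
    np.testing.assert_allclose(es.enmo_mg[:, ~sleep],
                               clean_profile.background_enmo_mg, atol=1e-2)
    np.testing.assert_allclose(es.enmo_mg[:, sleep],
                               clean_profile.sleep_enmo_mg, atol=1e-2)


def test_enmo_trims_to_midnights():
    """Samples before the first and after the last midnight are dropped."""
    rng = np.random.default_rng(0)
    fs = 1.0
    n = int(86400 * 2)  # starts at 06:00, so only one full day survives
    xyz = np.tile([0.0, 0.0, 1.1], (n, 1)) + rng.normal(0, 1e-4, (n, 3))
    rec = make_recording(xyz, fs, start_s=6 * 3600.0)
    es = acc.compute_enmo(rec, epoch_length_s=60.0)
    assert es.n_days == 1
    np.testing.assert_allclose(es.enmo_mg, 100.0, atol=1.0)


def test_enmo_short_recording_is_empty():
    rec = constant_recording((0, 0, 1), days=0.5, fs=1.0)
    es = acc.compute_enmo(rec)
    assert es.n_days == 0


# ---------------------------------------------------------------------------
# autocalibration
# ---------------------------------------------------------------------------


def test_autocalibrate_identity_on_calibrated_recording(clean_recording):
    rec, _ = clean_recording
    _, params = acc.autocalibrate(rec)
    assert params.converged
    assert not params.corrected          # residual already under tolerance
    np.testing.assert_allclose(params.gain, 1.0, atol=5e-3)
    np.testing.assert_allclose(params.offset_g, 0.0, atol=5e-3)
    assert params.residual_error_mg < 2.0


def test_autocalibrate_recovers_known_distortion():
    prof = SignalProfile(days=3, sampling_rate_hz=10.0, seed=3,
                         axis_gain=(1.02, 1.0, 1.0))
    rec, _ = generate_raw_recording(prof)
    corrected, params = acc.autocalibrate(rec)
    assert params.corrected and params.converged
    np.testing.assert_allclose(params.gain, [1.02, 1.0, 1.0], atol=0.005)
    # corrected static periods sit back on the unit sphere
    assert params.residual_error_mg < 1.0
    es = acc.compute_enmo(corrected)
    assert abs(np.nanmean(es.enmo_mg) - np.nanmean(
        acc.compute_enmo(generate_raw_recording(
            SignalProfile(days=3, sampling_rate_hz=10.0, seed=3))[0]).enmo_mg)) < 1.0


def test_autocalibrate_no_static_windows_returns_identity():
    """Continuous vigorous movement: no static windows, identity params."""
    rng = np.random.default_rng(1)
    n = 2 * 3600 * 10
    xyz = rng.normal(0, 0.5, (n, 3)) + [0, 0, 1.0]
    rec = make_recording(xyz, fs=10.0)
    out, params = acc.autocalibrate(rec)
    assert not params.converged
    assert not params.corrected
    np.testing.assert_array_equal(params.gain, 1.0)
    assert out.xyz is rec.xyz


def test_autocalibrate_requires_one_hour():
    rec = constant_recording((0, 0, 1), days=0.01, fs=10.0)
    with pytest.raises(acc.RecordingError):
        acc.autocalibrate(rec)


# ---------------------------------------------------------------------------
# nonwear detection
# ---------------------------------------------------------------------------


def test_nonwear_fully_constant_day():
    rec = constant_recording((0.1, 0.2, 0.97), days=2.0, fs=1.0)
    mask = acc.detect_nonwear(rec)
    assert not mask.wear.any()
    np.testing.assert_array_equal(mask.wear_hours_per_day, 0.0)


def test_nonwear_continuous_movement_is_wear():
    rng = np.random.default_rng(2)
    xyz = rng.normal(0, 0.3, (2 * 86400, 3)) + [0, 0, 1]
    mask = acc.detect_nonwear(make_recording(xyz, fs=1.0))
    assert mask.wear.all()


def test_nonwear_recovers_injected_removal(busy_recording):
    """Injected removals flagged with high overlap, nothing else flagged."""
    rec, truth = busy_recording
    cal, _ = acc.autocalibrate(rec)
    mask = acc.detect_nonwear(cal)
    det, true = ~mask.wear, ~truth.wear
    union = (det | true).sum()
    jaccard = (det & true).sum() / union
    assert jaccard >= 0.8


def test_nonwear_quiet_sleep_is_wear(clean_recording):
    """Noise-free sleep with posture changes must not be called nonwear."""
    rec, truth = clean_recording
    mask = acc.detect_nonwear(rec)
    assert mask.wear.all()


def test_nonwear_jittered_removal_still_detected():
    prof = SignalProfile(days=2, sampling_rate_hz=10.0, seed=9,
                         nonwear_intervals=((0, 12.0, 120.0),),
                         nonwear_jitter_g=0.005)
    rec, truth = generate_raw_recording(prof)
    mask = acc.detect_nonwear(rec)
    det, true = ~mask.wear, ~truth.wear
    assert (det & true).sum() / (det | true).sum() >= 0.8


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _series(values_by_day, epoch_s=900.0):
    """EpochSeries with one epoch per 15-min block for readable tests."""
    arr = np.asarray(values_by_day, dtype=float)
    return acc.EpochSeries(arr, epoch_s, np.arange(arr.shape[0]) % 7)


def test_impute_no_nonwear_is_identity(clean_recording):
    rec, _ = clean_recording
    es = acc.compute_enmo(rec)
    mask = acc.detect_nonwear(rec)
    out, frac = acc.impute_nonwear(es, mask)
    assert frac == 0.0
    np.testing.assert_array_equal(out.enmo_mg, es.enmo_mg)


def test_impute_uses_other_day_mean():
    """Nonwear block replaced by the mean over the other, worn days."""
    days, bpd = 4, acc.BLOCKS_PER_DAY
    values = np.zeros((days, bpd))
    block = 56  # 14:00
    values[:, block] = [20.0, 30.0, 999.0, 40.0]  # day 2 nonwear
    es = _series(values)
    wear = np.ones((days, bpd), dtype=bool)
    wear[2, block] = False
    out, frac = acc.impute_nonwear(es, acc.WearMask(wear, es.day_weekday))
    assert out.enmo_mg[2, block] == pytest.approx(30.0)  # mean(20, 30, 40)
    # worn values untouched
    assert out.enmo_mg[0, block] == 20.0
    assert frac == pytest.approx(1 / (days * bpd))


def test_impute_idempotent_and_unimputable_left_missing():
    days, bpd = 3, acc.BLOCKS_PER_DAY
    values = np.full((days, bpd), 10.0)
    es = _series(values)
    wear = np.ones((days, bpd), dtype=bool)
    wear[:, 10] = False          # nonwear on every day: unimputable
    wear[0, 20] = False          # imputable
    mask = acc.WearMask(wear, es.day_weekday)
    out1, frac1 = acc.impute_nonwear(es, mask)
    out2, frac2 = acc.impute_nonwear(out1, mask)
    assert np.isnan(out1.enmo_mg[:, 10]).all()
    assert out1.enmo_mg[0, 20] == pytest.approx(10.0)
    np.testing.assert_array_equal(np.nan_to_num(out1.enmo_mg, nan=-1),
                                  np.nan_to_num(out2.enmo_mg, nan=-1))
    assert frac1 == frac2


def test_impute_fraction_matches_injected_truth(busy_recording):
    rec, truth = busy_recording
    cal, _ = acc.autocalibrate(rec)
    es = acc.compute_enmo(cal)
    mask = acc.detect_nonwear(cal)
    _, frac = acc.impute_nonwear(es, mask)
    injected = 1.0 - truth.wear_fraction
    assert abs(frac - injected) <= 5e-4  # within 0.05 percentage points


def test_impute_requires_two_days():
    es = _series(np.full((1, acc.BLOCKS_PER_DAY), 5.0))
    mask = acc.WearMask(np.ones((1, acc.BLOCKS_PER_DAY), bool), es.day_weekday)
    with pytest.raises(acc.RecordingError):
        acc.impute_nonwear(es, mask)


# ---------------------------------------------------------------------------
# validity and weekly rescaling
# ---------------------------------------------------------------------------


def _mask_with_hours(hours, weekdays):
    wear = np.zeros((len(hours), acc.BLOCKS_PER_DAY), dtype=bool)
    for d, h in enumerate(hours):
        wear[d, : int(round(h * 4))] = True
    return acc.WearMask(wear, np.asarray(weekdays))


@pytest.mark.parametrize("hours, weekdays, included, n_wd, n_we", [
    ([24] * 8, [0, 1, 2, 3, 4, 5, 6, 0], True, 6, 2),     # all valid
    ([24, 24, 24, 24, 24, 24, 15, 24], [0, 1, 2, 3, 4, 5, 6, 0], False, 6, 1),
    ([15.75, 16.0, 24, 24, 24, 24, 24, 24], [0, 1, 2, 3, 4, 5, 6, 0], True, 5, 2),
])
def test_select_valid_days_rules(hours, weekdays, included, n_wd, n_we):
    sel = acc.select_valid_days(_mask_with_hours(hours, weekdays))
    assert sel.included is included
    assert sel.n_valid_weekdays == n_wd
    assert sel.n_valid_weekend_days == n_we


def test_16h_boundary_is_inclusive():
    # wear time is block-quantized: 63 blocks = 15.75 h < 16 h <= 64 blocks
    sel = acc.select_valid_days(_mask_with_hours([15.75, 16.0], [0, 1]))
    np.testing.assert_array_equal(sel.valid, [False, True])


def test_max_eight_days_considered():
    sel = acc.select_valid_days(_mask_with_hours([24] * 10, list(range(7)) + [0, 1, 2]))
    assert sel.valid[8:].sum() == 0
    assert sel.valid[:8].all()


def test_collapse_duplicate_days():
    values, weekdays = acc.collapse_duplicate_days(
        np.array([20.0, 1, 2, 3, 4, 5, 6, 30.0]),
        np.array([1, 2, 3, 4, 5, 6, 0, 1]))  # two Tuesdays: 20 and 30
    assert len(values) == 7
    assert values[0] == pytest.approx(25.0)
    assert (np.sort(weekdays) == np.arange(7)).all()


def test_collapse_no_duplicates_unchanged():
    v = np.array([1.0, 2, 3, 4, 5])
    w = np.array([0, 1, 2, 5, 6])
    values, weekdays = acc.collapse_duplicate_days(v, w)
    np.testing.assert_array_equal(values, v)
    np.testing.assert_array_equal(weekdays, w)


def test_collapse_equal_duplicates_idempotent():
    values, _ = acc.collapse_duplicate_days(np.array([7.0, 7.0]), np.array([3, 3]))
    assert values.tolist() == [7.0]


def test_weekly_average_formula():
    assert acc.weekly_average(25.0, 18.0) == pytest.approx(23.0)
    assert acc.weekly_average(13.7, 13.7) == pytest.approx(13.7)


@given(wd=hst.floats(0, 500), we=hst.floats(0, 500))
@settings(max_examples=100, derandomize=True)
def test_weekly_average_is_5_2_multiset_mean(wd, we):
    oracle = np.mean([wd] * 5 + [we] * 2)
    result = acc.weekly_average(wd, we)
    assert result == pytest.approx(oracle, abs=1e-9)
    assert min(wd, we) - 1e-9 <= result <= max(wd, we) + 1e-9


def test_weekly_average_rejects_missing():
    with pytest.raises(acc.RecordingError):
        acc.weekly_average(float("nan"), 10.0)


# ---------------------------------------------------------------------------
# MVPA bouts
# ---------------------------------------------------------------------------


def _bout_series(enmo_by_epoch, epoch_s=5.0):
    arr = np.asarray(enmo_by_epoch, dtype=float)[None, :]
    pad = int(86400 / epoch_s) - arr.shape[1]
    arr = np.pad(arr, ((0, 0), (0, pad)))
    return acc.EpochSeries(arr, epoch_s, np.array([0]))


def bout_minutes_oracle(enmo, threshold, bout_min, frac=0.8, epoch_s=5.0,
                        mode="qualifying_supra"):
    """Exhaustive all-windows scan, plain Python."""
    above = [bool(v >= threshold) for v in enmo]
    w = int(round(bout_min * 60 / epoch_s))
    n = len(above)
    covered = [False] * n
    for start in range(n - w + 1):
        window = above[start: start + w]
        if sum(window) >= frac * w - 1e-9:
            for k in range(start, start + w):
                covered[k] = True
    if mode == "union":
        counted = covered
    else:
        counted = [c and a for c, a in zip(covered, above)]
    return sum(counted) * epoch_s / 60.0


def test_bout_ten_contiguous_minutes():
    enmo = np.zeros(600)
    enmo[100: 100 + 120] = 150.0  # 10 min of 5-s epochs at 150 mg
    es = _bout_series(enmo)
    assert acc.detect_mvpa_bouts(es, 100.0, 10)[0] == pytest.approx(10.0)


def test_bout_fraction_boundary_96_of_120():
    """Exactly 80% above threshold qualifies; 95/120 does not."""
    def series(k):
        enmo = np.zeros(2000)
        enmo[100: 100 + k] = 150.0        # contiguous run of k epochs
        return _bout_series(enmo)

    # run of 96: the window [100, 220) holds exactly 96 above -> qualifies
    assert acc.detect_mvpa_bouts(series(96), 100.0, 10)[0] == pytest.approx(8.0)
    # run of 95: no 120-epoch window reaches 96 above -> nothing qualifies
    assert acc.detect_mvpa_bouts(series(95), 100.0, 10)[0] == 0.0


def test_bout_nine_minutes_follows_fraction_rule():
    """An isolated 9-min run is 90% of a 10-min window, so it qualifies
    under the 80% rule; at 1-min bouts it scores the same 9 minutes."""
    enmo = np.zeros(600)
    enmo[120: 120 + 108] = 150.0  # 9 min
    es = _bout_series(enmo)
    assert acc.detect_mvpa_bouts(es, 100.0, 10)[0] == pytest.approx(9.0)
    assert acc.detect_mvpa_bouts(es, 100.0, 1)[0] == pytest.approx(9.0)


def test_bout_union_mode_counts_window_spans():
    enmo = np.zeros(600)
    enmo[120: 120 + 108] = 150.0
    es = _bout_series(enmo)
    union = acc.detect_mvpa_bouts(es, 100.0, 10, mode="union")[0]
    assert union == pytest.approx(bout_minutes_oracle(
        es.enmo_mg[0], 100.0, 10, mode="union"))
    assert union >= 9.0


def test_bout_detector_matches_bruteforce_oracle():
    """Vectorized detector == exhaustive window scan on random series."""
    rng = np.random.default_rng(42)
    for trial in range(300):
        n = int(rng.integers(1, 300))
        enmo = rng.choice([0.0, 50.0, 110.0, 150.0], size=n,
                          p=[0.4, 0.2, 0.2, 0.2])
        arr = np.zeros((1, 17280))
        arr[0, :n] = enmo
        es = acc.EpochSeries(arr, 5.0, np.array([0]))
        for threshold, bout in ((100.0, 10), (100.0, 1), (120.0, 2)):
            for mode in ("qualifying_supra", "union"):
                got = acc.detect_mvpa_bouts(es, threshold, bout, mode=mode)[0]
                want = bout_minutes_oracle(arr[0], threshold, bout, mode=mode)
                assert got == pytest.approx(want), (trial, threshold, bout, mode)


def test_bout_monotonicity_on_synthetic_subjects(busy_recording):
    """120 mg never beats 100 mg; 10-min bouts never beat 1-min bouts."""
    rec, _ = busy_recording
    cal, _ = acc.autocalibrate(rec)
    es, _ = acc.impute_nonwear(acc.compute_enmo(cal), acc.detect_nonwear(cal))
    m100_10 = acc.detect_mvpa_bouts(es, 100.0, 10)
    m100_1 = acc.detect_mvpa_bouts(es, 100.0, 1)
    m120_10 = acc.detect_mvpa_bouts(es, 120.0, 10)
    m120_1 = acc.detect_mvpa_bouts(es, 120.0, 1)
    assert (m120_10 <= m100_10 + 1e-9).all()
    assert (m120_1 <= m100_1 + 1e-9).all()
    assert (m100_10 <= m100_1 + 1e-9).all()
    assert (m120_10 <= m120_1 + 1e-9).all()


def test_bout_parameter_validation(clean_recording):
    rec, _ = clean_recording
    es = acc.compute_enmo(rec)
    with pytest.raises(acc.RecordingError):
        acc.detect_mvpa_bouts(es, 0.0, 10)
    with pytest.raises(acc.RecordingError):
        acc.detect_mvpa_bouts(es, 100.0, 10, frac=1.5)


@pytest.mark.parametrize("minutes, expected", [
    (150.0, True), (149.9, False), (0.0, False), (1000.0, True)])
def test_meets_who_accelerometer(minutes, expected):
    assert acc.meets_who(minutes) is expected


# ---------------------------------------------------------------------------
# end-to-end per-recording summary
# ---------------------------------------------------------------------------


def test_summary_recovers_generator_truth(busy_recording):
    rec, truth = busy_recording
    summary, reason = acc.summarize_recording(rec)
    assert reason == "ok"
    assert abs(summary.weekly_mean_enmo_mg - truth.weekly_enmo_mg) < 1.0
    for key, true_minutes in truth.bouted_mvpa_min_per_week.items():
        assert abs(summary.mvpa_min_per_week[key] - true_minutes) < 1.0
    assert summary.n_valid_weekdays >= 2 and summary.n_valid_weekend_days >= 2


def test_summary_excludes_short_recording():
    rec = constant_recording((0, 0, 1), days=0.9, fs=1.0)
    summary, reason = acc.summarize_recording(rec, calibrate=False)
    assert summary is None
    assert "day" in reason
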