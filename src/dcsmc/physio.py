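"""End-tidal CO2 and transcranial-Doppler waveform processing, lag-optimised
calibration, and the session-level statistics used alongside the DCS fits.

The capnograph trace oscillates with breathing; the end-tidal partial
pressure is tracked by its upper envelope, and the hypercapnia response
DeltaPETCO2 is that envelope minus its baseline mean.  Doppler velocity
traces carry cardiac pulsatility; upper and lower envelopes are low-passed
at 0.01 Hz, normalised to their baseline means and averaged into one
percent-change MCAV timecourse.  A lag-optimised ordinary least squares
regression of MCAV on time-shifted DeltaPETCO2 (lags 1..10 s over the
60-250 s interval) yields the calibration used to synthesise an expected
Doppler response, eTCD = 3.2 * DeltaPETCO2 - 0.4, for sessions without
Doppler recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.stats import linregress

__all__ = [
    "PhysioTrace",
    "CalibrationModel",
    "envelope",
    "process_petco2",
    "process_tcd",
    "lag_calibration",
    "synthesize_etcd",
    "relative_change",
    "group_average_trimmed",
    "ScreenReport",
    "screen_measurement",
    "ETCD_SLOPE",
    "ETCD_INTERCEPT",
]

#: Group-calibrated affine relation between MCAV percent change and
#: DeltaPETCO2 (mmHg): slope %/mmHg and intercept %.
ETCD_SLOPE = 3.2
ETCD_INTERCEPT = -0.4


@dataclass
class PhysioTrace:
    """Uniformly sampled physiological waveform."""

    time: np.ndarray
    values: np.ndarray
    sampling_rate_hz: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape or self.time.ndim != 1:
            raise ValueError("time and values must be 1-d arrays of equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


@dataclass
class CalibrationModel:
    """Lag-optimised linear calibration MCAV%% ~ DeltaPETCO2."""

    slope: float            # %/mmHg
    intercept: float        # %
    lag_s: float
    r2: float
    r2_by_lag: dict[float, float] = field(default_factory=dict)
    #: best lag when the regressor is left unfiltered (diagnostic)
    lag_unfiltered_s: float | None = None

    def predict(self, dpetco2: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(dpetco2, float) + self.intercept


def envelope(trace: PhysioTrace, side: str = "upper",
             min_cycle_s: float = 2.0) -> PhysioTrace:
    """Envelope through local extrema separated by at least ``min_cycle_s``.

    Extrema are linearly interpolated back onto the original time grid;
    beyond the first/last extremum the envelope holds the nearest extremum
    value.  Low-prominence wiggles (noise riding on the opposite phase of
    the oscillation) are not envelope support points: a peak must rise at
    least 5% of the trace's range above its surroundings.  A trace with no
    qualifying extrema (e.g. constant) is returned unchanged.
    """
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    if trace.duration_s < 3.0 * min_cycle_s:
        raise ValueError("trace shorter than three oscillation cycles")
    v = trace.values if side == "upper" else -trace.values
    distance = max(int(round(min_cycle_s * trace.sampling_rate_hz)), 1)
    span = float(np.ptp(v))
    kwargs = {"distance": distance}
    if span > 0:
        kwargs["prominence"] = 0.05 * span
    peaks, _ = find_peaks(v, **kwargs)
    if peaks.size == 0:
        return PhysioTrace(trace.time.copy(), trace.values.copy(),
                           trace.sampling_rate_hz, trace.channel)
    env = np.interp(trace.time, trace.time[peaks], trace.values[peaks])
    return PhysioTrace(trace.time.copy(), env, trace.sampling_rate_hz,
                       f"{trace.channel}:{side}-env")


def _baseline_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time >= window[0]) & (time <= window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    return mask


def process_petco2(trace: PhysioTrace,
                   baseline_window: tuple[float, float] = (0.0, 60.0),
                   min_cycle_s: float = 2.0) -> PhysioTrace:
    """DeltaPETCO2 (mmHg): upper envelope minus its baseline mean."""
    env = envelope(trace, "upper", min_cycle_s)
    base = env.values[_baseline_mask(env.time, baseline_window)].mean()
    return PhysioTrace(env.time, env.values - base, env.sampling_rate_hz,
                       "dPETCO2")


def _lowpass(values: np.ndarray, fs: float, cutoff_hz: float = 0.01) -> np.ndarray:
    # zero-phase second-order Butterworth; forward-backward to avoid phase
    # lag that would corrupt the lag search
    b, a = butter(2, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, values)


def process_tcd(
    lmca: PhysioTrace | None,
    rmca: PhysioTrace | None,
    baseline_window: tuple[float, float] = (0.0, 60.0),
    min_cycle_s: float = 0.5,
    lowpass_hz: float = 0.01,
) -> PhysioTrace:
    """Percent-change MCAV timecourse from one or both Doppler sides.

    Per side: upper and lower cardiac envelopes, 0.01-Hz zero-phase lowpass,
    division by the envelope's own baseline mean, conversion to percent
    change; all available envelopes are then averaged.
    """
    sides = [t for t in (lmca, rmca) if t is not None]
    if not sides:
        raise ValueError("at least one of lmca/rmca must be provided")
    envs = []
    for t in sides:
        for side in ("upper", "lower"):
            e = envelope(t, side, min_cycle_s)
            filt = _lowpass(e.values, e.sampling_rate_hz, lowpass_hz)
            base = filt[_baseline_mask(e.time, baseline_window)].mean()
            if base <= 0:
                raise ValueError("non-positive baseline MCAV")
            envs.append((filt / base - 1.0) * 100.0)
    mean = np.mean(envs, axis=0)
    ref = sides[0]
    return PhysioTrace(ref.time.copy(), mean, ref.sampling_rate_hz, "dMCAV_pct")


def shift_trace(values: np.ndarray, time: np.ndarray, lag_s: float) -> np.ndarray:
    """Advance a series by ``lag_s``: output(t) = input(t + lag)."""
    return np.interp(time + lag_s, time, values)


def lag_calibration(
    tcd_pct: PhysioTrace,
    dpetco2: PhysioTrace,
    lags_s: Sequence[float] = tuple(range(1, 11)),
    interval_s: tuple[float, float] = (60.0, 250.0),
    match_filter_hz: float | None = 0.01,
) -> CalibrationModel:
    """Lag-optimised OLS calibration of MCAV%% against DeltaPETCO2.

    For each candidate lag the DeltaPETCO2 series is advanced by the lag,
    both series are restricted to ``interval_s`` on the Doppler time grid,
    and MCAV%% is regressed on the shifted DeltaPETCO2; the lag with the
    highest r^2 wins.  Constant (degenerate) regressors are skipped.

    The Doppler percent-change series has passed a 0.01-Hz lowpass;
    regressing a filtered response on an unfiltered regressor attenuates
    the slope, so by default the shifted regressor is passed through the
    same zero-phase filter (``match_filter_hz``; set None to disable).
    The best lag of the unfiltered regression is kept as a diagnostic.
    """
    t = tcd_pct.time
    mask = (t >= interval_s[0]) & (t <= interval_s[1])
    if not mask.any():
        raise ValueError(f"interval {interval_s} contains no samples")
    y = tcd_pct.values[mask]

    def search(filtered: bool):
        best = None
        r2_by_lag: dict[float, float] = {}
        for lag in lags_s:
            x_full = np.interp(t + lag, dpetco2.time, dpetco2.values)
            if filtered:
                x_full = _lowpass(x_full, tcd_pct.sampling_rate_hz,
                                  match_filter_hz)
            x = x_full[mask]
            if np.ptp(x) == 0:
                continue
            fit = linregress(x, y)
            r2 = float(fit.rvalue ** 2)
            r2_by_lag[float(lag)] = r2
            if best is None or r2 > best[0]:
                best = (r2, float(lag), float(fit.slope), float(fit.intercept))
        return best, r2_by_lag

    use_filter = match_filter_hz is not None
    best, r2_by_lag = search(use_filter)
    if best is None:
        raise ValueError("all candidate lags had degenerate regressors")
    r2, lag, slope, intercept = best
    lag_unfiltered = None
    if use_filter:
        raw_best, _ = search(False)
        lag_unfiltered = raw_best[1] if raw_best is not None else None
    return CalibrationModel(slope=slope, intercept=intercept, lag_s=lag,
                            r2=r2, r2_by_lag=r2_by_lag,
                            lag_unfiltered_s=lag_unfiltered)


def synthesize_etcd(dpetco2: np.ndarray,
                    slope: float = ETCD_SLOPE,
                    intercept: float = ETCD_INTERCEPT) -> np.ndarray:
    """Expected Doppler percent change from DeltaPETCO2 (mmHg)."""
    return slope * np.asarray(dpetco2, dtype=float) + intercept


def relative_change(series: np.ndarray, baseline_mask: np.ndarray) -> np.ndarray:
    """Relative change in percent: ((x / baseline_mean) - 1) * 100."""
    series = np.asarray(series, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if not baseline_mask.any():
        raise ValueError("empty baseline window")
    base = np.nanmean(series[baseline_mask])
    if not np.isfinite(base) or base <= 0:
        raise ValueError(f"baseline mean must be positive, got {base}")
    return (series / base - 1.0) * 100.0


def group_average_trimmed(
    timecourses: Sequence[np.ndarray],
) -> dict[str, np.ndarray]:
    """Outlier-trimmed group statistics per timepoint.

    At each timepoint the single highest and single lowest values are
    dropped, then the mean, standard error and 25th/75th percentiles
    (linear interpolation between order statistics) of the remainder are
    returned.
    """
    arr = np.asarray(timecourses, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 timecourses on a common grid")
    srt = np.sort(arr, axis=0)
    trimmed = srt[1:-1, :]
    mean = trimmed.mean(axis=0)
    if trimmed.shape[0] > 1:
        se = trimmed.std(axis=0, ddof=1) / np.sqrt(trimmed.shape[0])
    else:
        se = np.zeros(arr.shape[1])
    q25 = np.percentile(trimmed, 25, axis=0)
    q75 = np.percentile(trimmed, 75, axis=0)
    return {"mean": mean, "se": se, "q25": q25, "q75": q75}


@dataclass
class ScreenReport:
    """Outcome of the measurement-screening gates with reasons."""

    passed: bool
    reasons: list[str]
    flags: dict[str, bool]


def screen_measurement(
    count_rate_30mm_hz: float,
    baseline_cov: float,
    time_s: np.ndarray,
    drbfi_5mm_pct: np.ndarray,
    drbfi_long_pct: np.ndarray,
    co2_end_s: float,
    min_count_rate_hz: float = 5000.0,
    max_baseline_cov: float = 0.25,
    scalp_drift_pct: float = 20.0,
    persist_s: float = 30.0,
    peak_time_diff_s: float = 10.0,
    recovery_diff_pct: float = 10.0,
) -> ScreenReport:
    """Apply the session-quality and contamination-evidence gates.

    Gates: (1) count rate per fibre at 30 mm at least ``min_count_rate_hz``;
    (2) baseline coefficient of variation strictly below 25%; (3) a
    significant (>20%) and persistent scalp BFi increase (above threshold
    for at least ``persist_s`` consecutive seconds after the end of CO2);
    (4) a long-separation profile distinct from the 5-mm one (peak times
    differing by >= 10 s or end-of-session recovery differing by >= 10
    percentage points).  Returns per-gate flags and reason strings.
    """
    time_s = np.asarray(time_s, float)
    d5 = np.asarray(drbfi_5mm_pct, float)
    dl = np.asarray(drbfi_long_pct, float)
    if time_s.shape != d5.shape or time_s.shape != dl.shape:
        raise ValueError("time and timecourse arrays must share a grid")
    reasons: list[str] = []
    flags: dict[str, bool] = {}

    flags["count-rate"] = bool(count_rate_30mm_hz >= min_count_rate_hz)
    if not flags["count-rate"]:
        reasons.append(
            f"count-rate: {count_rate_30mm_hz:.0f}/s at 30 mm below the "
            f"{min_count_rate_hz:.0f}/s/fibre minimum")

    flags["baseline-cov"] = bool(baseline_cov < max_baseline_cov)
    if not flags["baseline-cov"]:
        reasons.append(
            f"baseline-cov: CoV {baseline_cov:.1%} not strictly below "
            f"{max_baseline_cov:.0%}")

    # persistent scalp drift after the CO2 period
    post = time_s >= co2_end_s
    above = (d5 > scalp_drift_pct) & post
    persistent = False
    if above.any():
        dt = np.median(np.diff(time_s)) if time_s.size > 1 else np.inf
        run = 0
        for a in above:
            run = run + 1 if a else 0
            if run * dt >= persist_s:
                persistent = True
                break
    flags["scalp-drift"] = persistent
    if not persistent:
        reasons.append(
            f"scalp-drift: no sustained 5-mm increase above "
            f"{scalp_drift_pct:.0f}% for {persist_s:.0f}s after CO2 end")

    peak_diff = abs(time_s[np.argmax(dl)] - time_s[np.argmax(d5)])
    recovery_diff = abs(dl[-1] - d5[-1])
    flags["distinct-profile"] = bool(peak_diff >= peak_time_diff_s
                                     or recovery_diff >= recovery_diff_pct)
    if not flags["distinct-profile"]:
        reasons.append(
            f"distinct-profile: long separation mirrors 5 mm (peak diff "
            f"{peak_diff:.0f}s, recovery diff {recovery_diff:.1f} pp) — "
            f"likely low brain sensitivity")

    return ScreenReport(passed=all(flags.values()), reasons=reasons, flags=flags)
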