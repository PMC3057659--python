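"""Raw waveform to per-step pulse strengths H1..H5.

The chain mirrors how multi-pressure tonometry data are reduced in
practice: split the recording into its five hold-down-pressure plateaus,
align the baseline within each plateau with a 5th-order polynomial,
ensemble-average the beats, and read off the peak-to-trough amplitude of
the averaged beat as the pulse strength H for that step.  The resulting
(P1..P5, H1..H5) profile is the P-H curve that the depth coefficients
consume.

Baseline alignment comes in two flavours (``anchor``):

``"samples"``
    Subtract the least-squares polynomial fit of the raw samples.  Simple,
    but on a clean beat train the fit partially tracks the beats
    themselves and removes a fraction of a percent of pulse amplitude.

``"feet"`` (pipeline default)
    Two-stage: subtract the sample-wise fit, then fit a second polynomial
    through the diastolic feet of the detected beats and subtract that
    too.  The feet trace the true baseline, so a clean beat train (and
    any polynomial drift sampled at the feet) is restored exactly; this
    is the usual practice for pulse/PPG baseline wander removal.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import find_peaks, medfilt

from .records import (
    LOCATIONS,
    N_STEPS,
    Location,
    RawPulseRecord,
    StepStrengthProfile,
)

#: Nominal hold-down pressure setpoints of the measuring device (mmHg),
#: used when a record carries explicit step boundaries but no pressure trace.
DEFAULT_STEP_PRESSURES = (37.0, 73.0, 108.0, 143.0, 181.0)

#: Settle time (s) discarded at both ends of each plateau before beat analysis.
SETTLE_TIME_S = 0.25

DEFAULT_HR_BOUNDS = (40.0, 180.0)  # plausible heart-rate band, beats/min


class SegmentationError(ValueError):
    """Pressure trace does not contain exactly five detectable plateaus."""


class BeatDetectionError(ValueError):
    """Too few beats detected in a plateau for ensemble averaging."""


def segment_steps(
    record: RawPulseRecord,
    *,
    min_plateau_s: float = 1.0,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Locate the five pressure-step plateaus of a record.

    Explicit ``step_boundaries`` on the record always win; otherwise
    plateaus are detected by thresholding the absolute first difference
    of a median-filtered pressure trace.

    Returns
    -------
    intervals : list of (start, stop)
        Five disjoint half-open sample intervals, ordered by increasing
        mean pressure.
    pressures : ndarray
        Mean hold-down pressure of each interval (mmHg).
    """
    if record.step_boundaries is not None:
        intervals = [(int(a), int(b)) for a, b in record.step_boundaries]
        if len(intervals) != N_STEPS:
            raise SegmentationError(
                f"expected {N_STEPS} step boundaries, got {len(intervals)}"
            )
    else:
        intervals = _detect_plateaus(
            record.pressure_trace, record.sampling_rate, min_plateau_s
        )

    pressures = _interval_pressures(record, intervals)
    order = np.argsort(pressures)
    intervals = [intervals[i] for i in order]
    pressures = pressures[order]

    for (a0, b0), (a1, b1) in zip(intervals[:-1], intervals[1:]):
        if max(a0, a1) < min(b0, b1):
            raise SegmentationError("step intervals overlap")
    return intervals, pressures


def _detect_plateaus(
    trace: np.ndarray, fs: float, min_plateau_s: float
) -> list[tuple[int, int]]:
    k = int(0.25 * fs) // 2 * 2 + 1  # odd median-filter kernel, ~0.25 s
    smooth = medfilt(trace, k) if trace.size > k else trace.copy()
    span = float(smooth.max() - smooth.min())
    if span <= 0:
        raise SegmentationError("pressure trace is constant; found 1 plateau, expected 5")
    thr = 0.02 * span
    stable = np.abs(np.diff(smooth)) <= thr
    # maximal runs of stable samples, long enough to be a held pressure step
    edges = np.flatnonzero(np.diff(stable.astype(int)))
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges + 1, stable.size]
    min_len = int(min_plateau_s * fs)
    intervals = [
        (int(a), int(b) + 1)
        for a, b in zip(starts, stops)
        if stable[a] and (b - a) >= min_len
    ]
    if len(intervals) != N_STEPS:
        raise SegmentationError(
            f"expected {N_STEPS} pressure plateaus, found {len(intervals)}"
        )
    return intervals


def _interval_pressures(
    record: RawPulseRecord, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    if record.pressure_trace is not None:
        return np.array(
            [float(record.pressure_trace[a:b].mean()) for a, b in intervals]
        )
    return np.asarray(DEFAULT_STEP_PRESSURES, dtype=float)


def detect_beats(
    samples: np.ndarray,
    sampling_rate: float,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
) -> np.ndarray:
    """Indices of systolic peaks, constrained to the heart-rate band.

    Local-maxima picking with a minimum peak distance of one beat at the
    upper heart-rate bound and a prominence threshold of 25% of the
    segment peak-to-trough.
    """
    samples = np.asarray(samples, dtype=float)
    span = float(samples.max() - samples.min())
    if span <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(60.0 / hr_bounds[1] * sampling_rate)))
    peaks, _ = find_peaks(samples, distance=distance, prominence=0.25 * span)
    return peaks


def detrend_baseline(
    samples: np.ndarray,
    order: int = 5,
    *,
    anchor: str = "samples",
    sampling_rate: Optional[float] = None,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
) -> np.ndarray:
    """Remove the baseline of one plateau segment by polynomial alignment.

    With ``anchor="samples"`` the least-squares polynomial fit of the
    samples is subtracted.  With ``anchor="feet"`` (requires
    ``sampling_rate``) a second polynomial through the diastolic beat
    feet is subtracted on top, which leaves the pulsatile component
    untouched; see the module docstring.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size <= order + 1:
        raise ValueError(
            f"segment of {samples.size} samples is too short for an "
            f"order-{order} baseline fit"
        )
    fit = Polynomial.fit(np.arange(samples.size), samples, order)
    residual = samples - fit(np.arange(samples.size))
    if anchor == "samples":
        return residual
    if anchor != "feet":
        raise ValueError(f"unknown anchor {anchor!r}; expected 'samples' or 'feet'")
    if sampling_rate is None:
        raise ValueError("anchor='feet' requires sampling_rate")
    return _foot_align(samples, residual, order, sampling_rate, hr_bounds)


def _foot_align(
    samples: np.ndarray,
    residual: np.ndarray,
    order: int,
    fs: float,
    hr_bounds: tuple[float, float],
) -> np.ndarray:
    """Subtract a polynomial fitted through the diastolic beat feet.

    Beats are detected on the sample-wise detrended copy (robust against
    large drift), but the baseline polynomial is fitted to foot values
    of the *original* segment: on drift-free data the feet are constant,
    so the pulsatile amplitude is preserved exactly however few beats
    the plateau holds.
    """
    peaks = detect_beats(residual, fs, hr_bounds)
    if peaks.size < 2:
        return residual  # no beat structure: sample-wise fit is all we can do
    period = int(np.median(np.diff(peaks)))
    # one pre-systolic foot per beat: the minimum shortly before each peak
    # sits on the diastolic floor at a consistent beat phase; search the
    # original samples, whose floor is genuinely flat between beats
    feet = []
    lookback = int(round(0.45 * period))
    for p in peaks:
        lo = p - lookback
        if lo >= 0:
            feet.append(lo + int(np.argmin(samples[lo:p])))
    if len(feet) < 2:
        return residual
    feet_arr = np.array(sorted(set(feet)), dtype=int)

    half = max(1, int(round(0.025 * fs)))  # +-25 ms window tames sample noise
    foot_vals = np.array(
        [
            samples[max(0, f - half) : min(samples.size, f + half + 1)].mean()
            for f in feet_arr
        ]
    )
    deg = min(order, feet_arr.size - 1)
    base = Polynomial.fit(feet_arr.astype(float), foot_vals, deg)
    return samples - base(np.arange(samples.size, dtype=float))


def average_beat(
    samples: np.ndarray,
    sampling_rate: float,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
) -> np.ndarray:
    """Ensemble-average the beats of a baseline-corrected plateau segment.

    Beats are aligned on their systolic peaks and averaged point-wise
    over a fixed window of one median beat period (40% before the peak,
    60% after); beats whose window would run off the segment are
    discarded.
    """
    samples = np.asarray(samples, dtype=float)
    peaks = detect_beats(samples, sampling_rate, hr_bounds)
    if peaks.size < 2:
        raise BeatDetectionError(
            f"only {peaks.size} beat(s) detected; >= 2 required for averaging"
        )
    period = int(round(float(np.median(np.diff(peaks)))))
    before, after = int(round(0.4 * period)), int(round(0.6 * period))
    windows = [
        samples[p - before : p + after]
        for p in peaks
        if p - before >= 0 and p + after <= samples.size
    ]
    if len(windows) < 2:
        raise BeatDetectionError(
            f"only {len(windows)} complete beat window(s); >= 2 required"
        )
    return np.mean(windows, axis=0)


def pulse_strength(beat: np.ndarray) -> float:
    """Pulse strength H of an averaged beat: its peak-to-trough amplitude."""
    beat = np.asarray(beat, dtype=float)
    if beat.size == 0:
        raise ValueError("averaged beat is empty")
    return float(beat.max() - beat.min())


def build_profile(
    record: RawPulseRecord,
    *,
    poly_order: int = 5,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
    settle_s: float = SETTLE_TIME_S,
    anchor: str = "feet",
) -> StepStrengthProfile:
    """Full reduction of one record: (P1..P5, H1..H5).

    Chains ``segment_steps`` -> ``detrend_baseline`` -> ``average_beat``
    -> ``pulse_strength`` per pressure step, discarding ``settle_s``
    seconds at both plateau ends before beat analysis.
    """
    intervals, pressures = segment_steps(record)
    trim = int(round(settle_s * record.sampling_rate))
    strengths = np.empty(N_STEPS)
    for i, (a, b) in enumerate(intervals):
        seg = record.samples[a + trim : b - trim] if b - a > 2 * trim else record.samples[a:b]
        try:
            corrected = detrend_baseline(
                seg,
                poly_order,
                anchor=anchor,
                sampling_rate=record.sampling_rate,
                hr_bounds=hr_bounds,
            )
            beat = average_beat(corrected, record.sampling_rate, hr_bounds)
        except (ValueError, BeatDetectionError) as exc:
            raise type(exc)(f"pressure step {i + 1}: {exc}") from exc
        strengths[i] = pulse_strength(beat)
    return StepStrengthProfile(
        location=record.location,
        pressures=pressures,
        strengths=strengths,
        subject_id=record.subject_id,
    )


def location_average(
    profiles: Sequence[StepStrengthProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Average the P-H profiles of the three palpation locations.

    Returns the element-wise mean pressures and mean strengths, i.e.
    H_i = (H_Chon,i + H_Gwan,i + H_Cheok,i) / 3.
    """
    by_loc = {p.location: p for p in profiles}
    missing = [loc.value for loc in LOCATIONS if loc not in by_loc]
    if missing or len(profiles) != len(LOCATIONS):
        raise ValueError(
            f"need exactly one profile per location; missing: {missing or 'none'}, "
            f"got {len(profiles)} profiles"
        )
    pressures = np.mean([by_loc[loc].pressures for loc in LOCATIONS], axis=0)
    strengths = np.mean([by_loc[loc].strengths for loc in LOCATIONS], axis=0)
    return pressures, strengths


def h_max(strengths: np.ndarray) -> float:
    """Maximum pulse strength over the five pressure steps."""
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size != N_STEPS:
        raise ValueError(f"expected {N_STEPS} strengths, got {strengths.size}")
    return float(strengths.max())
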