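"""Synthetic pulse waveforms and cohorts with known ground truth.

The generator emulates a five-step hold-down-pressure tonometry session:
each subject carries a unimodal P-H envelope (a Gaussian bell in
pressure) whose peak location encodes pulse depth — a floating pulse
peaks well below, a sunken pulse well above, the mid-range hold-down
pressure.  Waveforms are a periodic two-Gaussian beat train scaled so
its peak-to-trough equals the envelope value at the step pressure, plus
a hold-down-pressure DC offset, a respiration sinusoid, slow random
drift, and white noise.

Group defaults are calibrated so that the cohort-level group means of
the strength-ratio depth coefficient (variant v2) land on the reference
anchors 0.54 (floating) and 0.63 (sunken); the calibration is the exact
closed form in :func:`calibrate_peak_pressure`.  Heart rate, maximal
pulse strength and the optional covariates follow the same reference
cohort's group summaries.

Randomness is a single integer seed driving a hierarchical
``SeedSequence`` stream (cohort -> subject -> location), so any subject
or location is reproducible independently of the rest of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    LOCATIONS,
    N_STEPS,
    Location,
    PulseClass,
    RawPulseRecord,
    StepStrengthProfile,
    SubjectMeasurement,
)

#: Hold-down pressure per step, mean and SD over subjects/locations (mmHg).
STEP_PRESSURE_MEANS = (37.0, 73.0, 108.0, 143.0, 181.0)
STEP_PRESSURE_SDS = (6.0, 10.0, 13.0, 17.0, 21.0)

#: Cohort-level calibration anchors for the v2 depth coefficient.
CFS_V2_ANCHORS = {"floating": 0.54, "sunken": 0.63}


def calibrate_peak_pressure(
    target_cfs: float,
    width: float,
    p_shallow: float = STEP_PRESSURE_MEANS[0],
    p_deep: float = STEP_PRESSURE_MEANS[3],
    var_shallow: float = STEP_PRESSURE_SDS[0] ** 2,
    var_deep: float = STEP_PRESSURE_SDS[3] ** 2,
) -> float:
    """Envelope peak pressure whose expected v2 coefficient hits a target.

    With a Gaussian envelope of width ``w`` peaking at ``mu``, the v2
    coefficient is a logistic function of ``ln(H_deep / H_shallow)``.
    Taking expectations over the step-pressure sampling noise gives

        E[ln(H_deep/H_shallow)]
            = ((P1 - P4)(P1 + P4 - 2 mu) + (Var P1 - Var P4)) / (2 w^2),

    which this function inverts for ``mu`` at the requested coefficient.
    """
    if not 0 < target_cfs < 1:
        raise ValueError("target coefficient must lie strictly inside (0, 1)")
    logit = math.log(target_cfs / (1.0 - target_cfs))
    return (p_shallow + p_deep) / 2.0 - (
        2.0 * width**2 * logit - (var_shallow - var_deep)
    ) / (2.0 * (p_shallow - p_deep))


@dataclass(frozen=True)
class GroupParams:
    """Per-group subject-level parameter distributions (mean, SD)."""

    peak_pressure_mean: float  # mmHg; envelope argmax
    peak_pressure_sd: float
    amplitude_mean: float  # device units; envelope height
    amplitude_sd: float
    heart_rate_mean: float  # beats/min
    heart_rate_sd: float
    covariate_means: dict[str, float] = field(default_factory=dict)
    covariate_sds: dict[str, float] = field(default_factory=dict)


ENVELOPE_WIDTH_DEFAULT = 70.0  # mmHg; sets how peaked the P-H curve is


def _default_groups() -> dict[PulseClass, GroupParams]:
    w = ENVELOPE_WIDTH_DEFAULT
    return {
        PulseClass.FLOATING: GroupParams(
            peak_pressure_mean=calibrate_peak_pressure(CFS_V2_ANCHORS["floating"], w),
            peak_pressure_sd=15.0,
            amplitude_mean=157.6,
            amplitude_sd=39.2,
            heart_rate_mean=81.6,
            heart_rate_sd=13.5,
            covariate_means={"bmi": 20.4, "systolic_bp": 118.0, "avg_bp": 82.2},
            covariate_sds={"bmi": 2.0, "systolic_bp": 16.6, "avg_bp": 10.2},
        ),
        PulseClass.SUNKEN: GroupParams(
            peak_pressure_mean=calibrate_peak_pressure(CFS_V2_ANCHORS["sunken"], w),
            peak_pressure_sd=20.0,
            amplitude_mean=146.9,
            amplitude_sd=35.3,
            heart_rate_mean=78.6,
            heart_rate_sd=11.5,
            covariate_means={"bmi": 23.1, "systolic_bp": 121.6, "avg_bp": 86.6},
            covariate_sds={"bmi": 3.1, "systolic_bp": 15.2, "avg_bp": 11.1},
        ),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic device and cohort."""

    step_pressure_means: tuple = STEP_PRESSURE_MEANS
    step_pressure_sds: tuple = STEP_PRESSURE_SDS
    envelope_width: float = ENVELOPE_WIDTH_DEFAULT  # mmHg
    groups: dict[PulseClass, GroupParams] = field(default_factory=_default_groups)
    location_jitter_sd: float = 5.0  # mmHg; per-location envelope-peak offset
    measurement_noise_cv: float = 0.10  # device repeatability, ~10% covariance
    sampling_rate: float = 200.0  # Hz
    step_duration_s: float = 5.0  # pressure held constant for 5 s
    respiration_freq: float = 0.25  # Hz, ~15 breaths/min
    respiration_amplitude: float = 0.05  # fraction of envelope amplitude
    drift_amplitude: float = 0.05  # fraction of envelope amplitude
    noise_sd: float = 0.02  # fraction of envelope amplitude
    pressure_dc_gain: float = 1.0  # device units of sensor offset per mmHg

    def __post_init__(self) -> None:
        if len(self.step_pressure_means) != N_STEPS:
            raise ValueError(f"need {N_STEPS} step pressures")
        if any(s < 0 for s in self.step_pressure_sds):
            raise ValueError("step pressure SDs must be >= 0")
        if self.envelope_width <= 0:
            raise ValueError("envelope width must be > 0")
        for g in self.groups.values():
            if g.amplitude_mean <= 0 or g.heart_rate_mean <= 0:
                raise ValueError("amplitudes and heart rates must be > 0")
            if not 0 < self.respiration_freq < g.heart_rate_mean / 60.0:
                raise ValueError(
                    "respiration frequency must sit below the heart-rate band"
                )
        if min(self.noise_sd, self.drift_amplitude, self.respiration_amplitude) < 0:
            raise ValueError("noise fractions must be >= 0")

    def noiseless(self) -> "GeneratorParams":
        """Copy with every waveform disturbance switched off."""
        return replace(
            self,
            measurement_noise_cv=0.0,
            respiration_amplitude=0.0,
            drift_amplitude=0.0,
            noise_sd=0.0,
        )


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level latent draw shared by all of a subject's records."""

    subject_id: str
    group: PulseClass
    peak_pressure: float
    amplitude: float
    heart_rate: float
    location_peak_pressures: dict[Location, float]


@dataclass(frozen=True)
class GroundTruth:
    """Exact envelope evaluations used to build one location's record."""

    subject_id: str
    group: PulseClass
    location: Location
    peak_pressure: float
    step_pressures: np.ndarray
    injected_strengths: np.ndarray


def strength_envelope(
    pressure, peak_pressure: float, width: float, amplitude: float
):
    """Gaussian P-H envelope: H = A * exp(-(P - P_peak)^2 / (2 w^2))."""
    if width <= 0 or amplitude <= 0:
        raise ValueError("width and amplitude must be > 0")
    p = np.asarray(pressure, dtype=float)
    out = amplitude * np.exp(-((p - peak_pressure) ** 2) / (2.0 * width**2))
    return float(out) if np.isscalar(pressure) else out


def _truncated_normal(rng: np.random.Generator, mean, sd, lower=1e-6) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    return float(max(mean, lower))  # pathological params: fall back to the mean


def draw_subject(
    group: PulseClass,
    params: GeneratorParams,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> SubjectParams:
    """Sample one subject's latent envelope and physiology."""
    g = params.groups[PulseClass(group)]
    mu = _truncated_normal(rng, g.peak_pressure_mean, g.peak_pressure_sd)
    amp = _truncated_normal(rng, g.amplitude_mean, g.amplitude_sd)
    hr = _truncated_normal(rng, g.heart_rate_mean, g.heart_rate_sd, lower=40.0)
    loc_peaks = {
        loc: mu + rng.normal(0.0, params.location_jitter_sd) for loc in LOCATIONS
    }
    return SubjectParams(
        subject_id=subject_id,
        group=PulseClass(group),
        peak_pressure=mu,
        amplitude=amp,
        heart_rate=hr,
        location_peak_pressures=loc_peaks,
    )


def _step_pressures(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Sample the five applied pressures, kept increasing with >= 5 mmHg gaps."""
    p = rng.normal(params.step_pressure_means, params.step_pressure_sds)
    p.sort()
    for i in range(1, N_STEPS):
        p[i] = max(p[i], p[i - 1] + 5.0)
    return p


def _beat_template(n_period: int) -> np.ndarray:
    """One beat on the sample grid, unit peak-to-trough, flat diastolic floor.

    A systolic peak plus a smaller dicrotic bump, both Gaussian.  Peak
    positions and widths are chosen so both tails decay below 1e-8 of
    the amplitude at the period boundaries: the waveform is then
    continuous across beats and its diastolic floor is flat, which keeps
    the beat train exactly periodic on the grid.
    """
    tau = np.arange(n_period) / n_period
    beat = np.exp(-((tau - 0.30) ** 2) / (2 * 0.05**2)) + 0.35 * np.exp(
        -((tau - 0.55) ** 2) / (2 * 0.07**2)
    )
    return beat / (beat.max() - beat.min())


def simulate_record(
    subject: SubjectParams,
    location: Location,
    params: Optional[GeneratorParams] = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[RawPulseRecord, GroundTruth]:
    """Synthesize one location's raw five-step waveform.

    The beat period is quantized to an integer number of samples so that
    every beat hits the grid at identical phases; without this a clean
    record could not reproduce its injected strengths to numerical
    precision through the averaging chain.
    """
    params = params or GeneratorParams()
    location = Location(location)
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n_step = int(round(params.step_duration_s * fs))
    n_period = max(2, int(round(fs * 60.0 / subject.heart_rate)))
    template = _beat_template(n_period)

    pressures = _step_pressures(params, rng)
    mu_loc = subject.location_peak_pressures[location]
    injected = strength_envelope(
        pressures, mu_loc, params.envelope_width, subject.amplitude
    )

    segments = []
    trace = []
    for p_step, h in zip(pressures, injected):
        n_rep = n_step // n_period + 2
        beats = np.tile(template, n_rep)[:n_step] * h
        t = np.arange(n_step) / fs
        resp = (
            params.respiration_amplitude
            * subject.amplitude
            * np.sin(2 * np.pi * params.respiration_freq * t + rng.uniform(0, 2 * np.pi))
        )
        drift = _slow_drift(
            n_step, fs, params.drift_amplitude * subject.amplitude, rng
        )
        noise = rng.normal(0.0, params.noise_sd * subject.amplitude, n_step)
        dc = params.pressure_dc_gain * p_step
        segments.append(beats + resp + drift + noise + dc)
        trace.append(np.full(n_step, p_step))

    record = RawPulseRecord(
        samples=np.concatenate(segments),
        sampling_rate=fs,
        location=location,
        subject_id=subject.subject_id,
        pressure_trace=np.concatenate(trace),
    )
    truth = GroundTruth(
        subject_id=subject.subject_id,
        group=subject.group,
        location=location,
        peak_pressure=mu_loc,
        step_pressures=pressures,
        injected_strengths=injected,
    )
    return record, truth


def _slow_drift(
    n: int, fs: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Sum of three sub-0.1 Hz sinusoids with random phases and frequencies."""
    if amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.02, 0.10)
        out += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    peak = np.abs(out).max()
    return out / peak * amplitude if peak > 0 else out


def simulate_subject_measurement(
    subject: SubjectParams,
    params: GeneratorParams,
    rng: np.random.Generator,
    covariates: bool = True,
) -> tuple[SubjectMeasurement, list[GroundTruth]]:
    """Profile-level measurement: envelope draws + device repeatability noise.

    Skips waveform synthesis: measured strengths are the injected
    envelope values perturbed by multiplicative lognormal noise with the
    device's ~10% repeatability coefficient of variation.
    """
    profiles = {}
    truths = []
    for loc in LOCATIONS:
        pressures = _step_pressures(params, rng)
        h_true = strength_envelope(
            pressures,
            subject.location_peak_pressures[loc],
            params.envelope_width,
            subject.amplitude,
        )
        noise = (
            np.exp(rng.normal(0.0, params.measurement_noise_cv, N_STEPS))
            if params.measurement_noise_cv > 0
            else 1.0
        )
        profiles[loc] = StepStrengthProfile(
            location=loc,
            pressures=pressures,
            strengths=h_true * noise,
            subject_id=subject.subject_id,
        )
        truths.append(
            GroundTruth(
                subject_id=subject.subject_id,
                group=subject.group,
                location=loc,
                peak_pressure=subject.location_peak_pressures[loc],
                step_pressures=pressures,
                injected_strengths=h_true,
            )
        )
    cov = {}
    if covariates:
        g = params.groups[subject.group]
        for name, m in g.covariate_means.items():
            cov[name] = float(rng.normal(m, g.covariate_sds.get(name, 0.0)))
        cov["heart_rate"] = subject.heart_rate
    meas = SubjectMeasurement(
        subject_id=subject.subject_id,
        profiles=profiles,
        covariates=cov,
        reference_label=subject.group,
    )
    return meas, truths


def simulate_cohort(
    n_floating: int,
    n_sunken: int,
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    covariates: bool = True,
) -> tuple[list[SubjectMeasurement], pd.DataFrame]:
    """Generate a labelled cohort of profile-level measurements.

    Returns the measurements (reference_label = generating group) and a
    long-format ground-truth table with one row per subject, location
    and pressure step.
    """
    if n_floating < 0 or n_sunken < 0 or n_floating + n_sunken < 1:
        raise ValueError("cohort needs at least one subject")
    params = params or GeneratorParams()
    groups = [PulseClass.FLOATING] * n_floating + [PulseClass.SUNKEN] * n_sunken
    streams = np.random.SeedSequence(seed).spawn(len(groups))
    measurements: list[SubjectMeasurement] = []
    rows = []
    for i, (group, ss) in enumerate(zip(groups, streams)):
        rng = np.random.default_rng(ss)
        subject = draw_subject(group, params, rng, subject_id=f"S{i:04d}")
        meas, truths = simulate_subject_measurement(subject, params, rng, covariates)
        measurements.append(meas)
        for tr in truths:
            for step in range(N_STEPS):
                rows.append(
                    {
                        "subject_id": tr.subject_id,
                        "group": tr.group.value,
                        "location": tr.location.value,
                        "step": step + 1,
                        "pressure_mmhg": tr.step_pressures[step],
                        "injected_strength": tr.injected_strengths[step],
                        "measured_strength": float(
                            meas.profiles[tr.location].strengths[step]
                        ),
                        "peak_pressure_mmhg": tr.peak_pressure,
                    }
                )
    return measurements, pd.DataFrame(rows)
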