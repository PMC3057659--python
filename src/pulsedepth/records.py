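"""Domain containers for multi-pressure radial-pulse records.

A measurement session applies five increasing hold-down pressures to the
radial artery at each of the three classical palpation positions (Chon,
Gwan, Cheok) and records the pulsatile waveform for ~5 s per pressure step.
The containers here carry that data from raw waveform to the per-step
pulse-strength profile consumed by the depth coefficients.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

N_STEPS = 5  #: hold-down pressure steps applied by the device


class Location(str, enum.Enum):
    """Palpation position along the distal radial artery."""

    CHON = "Chon"
    GWAN = "Gwan"
    CHEOK = "Cheok"


LOCATIONS = (Location.CHON, Location.GWAN, Location.CHEOK)


class PulseClass(str, enum.Enum):
    """Depth category of a pulse."""

    FLOATING = "floating"
    SUNKEN = "sunken"
    MIDDLE_DEPTH = "middle_depth"


@dataclass
class RawPulseRecord:
    """Single-channel pulse waveform over five hold-down-pressure steps.

    Parameters
    ----------
    samples : ndarray
        Sensor amplitude, device-specific units.
    sampling_rate : float
        Sampling frequency in Hz; must be positive.
    location : Location
        Palpation position the sensor was placed on.
    subject_id : str
        Opaque subject identifier.
    pressure_trace : ndarray, optional
        Per-sample hold-down pressure in mmHg.  Either this or
        ``step_boundaries`` must be present for segmentation.
    step_boundaries : sequence of (start, stop), optional
        Five half-open sample-index intervals, one per pressure step.
        When supplied they take precedence over plateau detection.
    """

    samples: np.ndarray
    sampling_rate: float
    location: Location
    subject_id: str = ""
    pressure_trace: Optional[np.ndarray] = None
    step_boundaries: Optional[Sequence[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.location = Location(self.location)
        if self.pressure_trace is not None:
            self.pressure_trace = np.asarray(self.pressure_trace, dtype=float)
            if self.pressure_trace.shape != self.samples.shape:
                raise ValueError("pressure_trace must align sample-for-sample with samples")
        if self.step_boundaries is not None:
            self.step_boundaries = [(int(a), int(b)) for a, b in self.step_boundaries]
        if self.pressure_trace is None and self.step_boundaries is None:
            raise ValueError("record needs a pressure_trace or explicit step_boundaries")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class StepStrengthProfile:
    """P-H curve data for one location: pressures P1..P5 and strengths H1..H5.

    Pressures are in mmHg and strictly increasing; strengths are
    non-negative amplitudes in device-specific units.
    """

    location: Location
    pressures: np.ndarray
    strengths: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.location = Location(self.location)
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.pressures.shape != (N_STEPS,) or self.strengths.shape != (N_STEPS,):
            raise ValueError(
                f"profile needs exactly {N_STEPS} (pressure, strength) pairs, "
                f"got {self.pressures.size} pressures / {self.strengths.size} strengths"
            )
        if not np.all(np.diff(self.pressures) > 0):
            raise ValueError("pressures must be strictly increasing")
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be non-negative")


@dataclass
class SubjectMeasurement:
    """One subject's three-location profiles plus optional covariates."""

    subject_id: str
    profiles: dict[Location, StepStrengthProfile]
    covariates: dict[str, float] = field(default_factory=dict)
    reference_label: Optional[PulseClass] = None

    def __post_init__(self) -> None:
        self.profiles = {Location(k): v for k, v in self.profiles.items()}
        missing = [loc.value for loc in LOCATIONS if loc not in self.profiles]
        if missing:
            raise ValueError(f"missing profile(s) for location(s): {', '.join(missing)}")
        if len(self.profiles) != len(LOCATIONS):
            raise ValueError("exactly one profile per location is required")
        if self.reference_label is not None:
            self.reference_label = PulseClass(self.reference_label)
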