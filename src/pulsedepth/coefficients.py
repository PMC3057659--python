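"""Depth coefficients for the floating/sunken pulse scale.

Both coefficients map a P-H curve (pulse strength H versus hold-down
pressure P) onto a depth score C_fs in [0, 1]: 0 means the pulse is
strongest under light pressure (floating-like), 1 means strongest under
heavy pressure (sunken-like).

The interpolation-based coefficient locates the pressure P_opt at which
an interpolated P-H curve peaks and normalises its position,

    C_fs = (P_opt - P_0) / (P_max - P_0),

while the strength-ratio coefficient compares the pulse strength at a
shallow and a deep pressure step directly,

    C_fs = 1/2 * (1 + (H_deep - H_shallow) / (H_deep + H_shallow))
         = H_deep / (H_shallow + H_deep),

which emulates a clinician pressing lightly and then firmly and judging
which feels stronger.  Two step selections are supported:

* ``v1``: H_shallow = (H1 + H2)/2,  H_deep = (H4 + H5)/2
* ``v2``: H_shallow = H1,           H_deep = H4
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .preprocess import location_average
from .records import SubjectMeasurement

VARIANTS = ("v1", "v2")


@dataclass(frozen=True)
class CfsCoefficient:
    """A depth score in [0, 1] with provenance of how it was computed."""

    value: float
    method: str  # "lee" | "new"
    variant: Optional[str] = None  # "v1" | "v2" for method="new"
    shallow_strength: Optional[float] = None
    deep_strength: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"C_fs must lie in [0, 1], got {self.value}")


def cfs_lee(pressures: np.ndarray, strengths: np.ndarray) -> CfsCoefficient:
    """Interpolated-argmax depth coefficient.

    The discrete (P, H) points are interpolated with a shape-preserving
    piecewise cubic (PCHIP), whose maximum P_opt on [P_0, P_max] is found
    exactly from the stationary points of the cubic pieces.  PCHIP does
    not overshoot, so the argmax cannot be an interpolation artifact.
    Ties take the smallest P_opt (biasing toward floating).
    """
    pressures = np.asarray(pressures, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    if pressures.size < 3 or pressures.size != strengths.size:
        raise ValueError("need >= 3 (P, H) points of equal length")
    if not np.all(np.diff(pressures) > 0):
        raise ValueError("pressures must be strictly increasing")

    curve = PchipInterpolator(pressures, strengths)
    candidates = np.concatenate(
        [pressures, curve.derivative().roots(extrapolate=False)]
    )
    candidates = np.sort(candidates)
    values = curve(candidates)
    best = values.max()
    # smallest pressure achieving the maximum (within numerical slack)
    p_opt = float(candidates[values >= best - 1e-12 * max(1.0, abs(best))][0])
    p0, pmax = float(pressures[0]), float(pressures[-1])
    value = float(np.clip((p_opt - p0) / (pmax - p0), 0.0, 1.0))
    return CfsCoefficient(value=value, method="lee")


def select_strengths(strengths: np.ndarray, variant: str) -> tuple[float, float]:
    """(H_shallow, H_deep) for the requested step-selection variant."""
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size != 5:
        raise ValueError(f"expected 5 strengths, got {strengths.size}")
    if variant == "v1":
        return (
            float((strengths[0] + strengths[1]) / 2.0),
            float((strengths[3] + strengths[4]) / 2.0),
        )
    if variant == "v2":
        return float(strengths[0]), float(strengths[3])
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def cfs_new(
    h_shallow: float, h_deep: float, variant: Optional[str] = None
) -> CfsCoefficient:
    """Strength-ratio depth coefficient H_deep / (H_shallow + H_deep)."""
    if h_shallow < 0 or h_deep < 0:
        raise ValueError("pulse strengths must be non-negative")
    total = h_shallow + h_deep
    if total == 0:
        raise ValueError(
            "both H_shallow and H_deep are zero: no pulse detected, "
            "depth coefficient undefined"
        )
    return CfsCoefficient(
        value=float(h_deep / total),
        method="new",
        variant=variant,
        shallow_strength=float(h_shallow),
        deep_strength=float(h_deep),
    )


def cfs_for_subject(
    measurement: SubjectMeasurement,
    method: str = "new",
    variant: str = "v2",
) -> CfsCoefficient:
    """Depth coefficient from a subject's three-location measurement.

    Strengths are first averaged over Chon, Gwan and Cheok (matching the
    clinician's simultaneous three-finger palpation), then fed to the
    requested coefficient.
    """
    pressures, strengths = location_average(list(measurement.profiles.values()))
    if method == "lee":
        return cfs_lee(pressures, strengths)
    if method == "new":
        h_shallow, h_deep = select_strengths(strengths, variant)
        return cfs_new(h_shallow, h_deep, variant)
    raise ValueError(f"unknown method {method!r}; expected 'lee' or 'new'")
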