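"""CSV/JSON dialects and the end-to-end pipeline driver.

No domain-standard interchange format exists for multi-pressure pulse
records, so the package uses plain UTF-8 CSV with explicit headers:

* waveform: ``time_s, amplitude[, pressure_mmHg]``, one file per
  subject-location, optionally with a JSON sidecar (same stem, ``.json``)
  carrying ``step_boundaries`` and ``step_pressures``;
* profiles: ``subject_id, location, step, pressure_mmHg, strength``;
* coefficients: ``subject_id, method, variant, h_shallow, h_deep, cfs``;
* labels: ``subject_id, label`` with lowercase
  ``floating | sunken | middle_depth``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify, coefficients, concordance, synthetic
from .records import (
    LOCATIONS,
    Location,
    PulseClass,
    RawPulseRecord,
    StepStrengthProfile,
    SubjectMeasurement,
)

#: Relative sampling-period jitter above which a waveform file is rejected.
#: Device clocks wander by well under 1%; anything past a couple of percent
#: indicates dropped samples or a corrupted time column.
MAX_TIME_JITTER = 0.02


def read_waveform_csv(
    path: str | Path,
    location: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> RawPulseRecord:
    """Read one subject-location waveform CSV (plus optional JSON sidecar).

    The sampling rate is inferred from the median time step; the time
    column must be monotone with relative jitter below
    :data:`MAX_TIME_JITTER`.  ``location`` and ``subject_id`` default to
    parsing the filename stem as ``<subject>_<location>``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path.name}: time_s must be strictly increasing")
    med = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - med)) / med)
    if jitter > MAX_TIME_JITTER:
        raise ValueError(
            f"{path.name}: irregular sampling (jitter {jitter:.1%} exceeds "
            f"{MAX_TIME_JITTER:.0%}); resample before analysis"
        )

    if location is None or subject_id is None:
        parts = path.stem.rsplit("_", 1)
        if subject_id is None:
            subject_id = parts[0]
        if location is None and len(parts) == 2:
            location = parts[1]
    if location is None:
        raise ValueError(f"{path.name}: location not given and not in filename")

    boundaries = None
    pressures = df["pressure_mmHg"].to_numpy(dtype=float) if "pressure_mmHg" in df else None
    sidecar = path.with_suffix(".json")
    if pressures is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        boundaries = [tuple(b) for b in meta["step_boundaries"]]

    return RawPulseRecord(
        samples=df["amplitude"].to_numpy(dtype=float),
        sampling_rate=1.0 / med,
        location=Location(location),
        subject_id=subject_id,
        pressure_trace=pressures,
        step_boundaries=boundaries,
    )


def write_waveform_csv(record: RawPulseRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.samples.size) / record.sampling_rate
    cols = {"time_s": t, "amplitude": record.samples}
    if record.pressure_trace is not None:
        cols["pressure_mmHg"] = record.pressure_trace
    pd.DataFrame(cols).to_csv(path, index=False)
    if record.step_boundaries is not None:
        path.with_suffix(".json").write_text(
            json.dumps({"step_boundaries": [list(b) for b in record.step_boundaries]})
        )


def profiles_to_frame(profiles: Sequence[StepStrengthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for step in range(p.pressures.size):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "location": p.location.value,
                    "step": step + 1,
                    "pressure_mmHg": p.pressures[step],
                    "strength": p.strengths[step],
                }
            )
    return pd.DataFrame(rows)


def frame_to_measurements(
    df: pd.DataFrame, labels: Optional[pd.DataFrame] = None
) -> list[SubjectMeasurement]:
    """Assemble per-subject measurements from a long-format profile table."""
    label_map = {}
    if labels is not None:
        label_map = dict(zip(labels["subject_id"], labels["label"]))
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        profiles = {}
        for loc_name, gl in g.groupby("location"):
            gl = gl.sort_values("step")
            profiles[Location(loc_name)] = StepStrengthProfile(
                location=Location(loc_name),
                pressures=gl["pressure_mmHg"].to_numpy(),
                strengths=gl["strength"].to_numpy(),
                subject_id=str(sid),
            )
        out.append(
            SubjectMeasurement(
                subject_id=str(sid),
                profiles=profiles,
                reference_label=label_map.get(sid),
            )
        )
    return out


def measurements_to_frame(measurements: Sequence[SubjectMeasurement]) -> pd.DataFrame:
    return profiles_to_frame(
        [p for m in measurements for p in (m.profiles[loc] for loc in LOCATIONS)]
    )


@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline run."""

    out_dir: Path
    n_floating: int = 49
    n_sunken: int = 72
    profiles_csv: Optional[Path] = None  # read instead of simulating
    labels_csv: Optional[Path] = None
    method: str = "new"
    variant: str = "v2"
    c_f: float = 0.58
    c_s: float = 0.68
    grid_step: float = classify.DEFAULT_GRID_STEP
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("c_f", "c_s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.c_f > self.c_s:
            raise ValueError(f"c_f must be <= c_s, got ({self.c_f}, {self.c_s})")
        if self.profiles_csv is not None:
            self.profiles_csv = Path(self.profiles_csv)
            if not self.profiles_csv.exists():
                raise FileNotFoundError(self.profiles_csv)


def cfs_frame(
    measurements: Sequence[SubjectMeasurement], method: str, variant: str
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        coef = coefficients.cfs_for_subject(m, method=method, variant=variant)
        rows.append(
            {
                "subject_id": m.subject_id,
                "method": coef.method,
                "variant": coef.variant or "",
                "h_shallow": coef.shallow_strength,
                "h_deep": coef.deep_strength,
                "cfs": coef.value,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) a cohort, score it, classify it, and summarise.

    Writes ``profiles.csv``, ``cfs.csv``, ``labels.csv`` and
    ``stats.json`` under ``config.out_dir`` and returns the in-memory
    results keyed by the same names.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)

    if config.profiles_csv is not None:
        prof_df = pd.read_csv(config.profiles_csv)
        labels_df = pd.read_csv(config.labels_csv) if config.labels_csv else None
        measurements = frame_to_measurements(prof_df, labels_df)
    else:
        measurements, _truth = synthetic.simulate_cohort(
            config.n_floating, config.n_sunken, seed=config.seed
        )
        prof_df = measurements_to_frame(measurements)

    cfs_df = cfs_frame(measurements, config.method, config.variant)
    labels = [
        classify.classify_dual(v, config.c_f, config.c_s) for v in cfs_df["cfs"]
    ]
    labels_df = pd.DataFrame(
        {"subject_id": cfs_df["subject_id"], "label": [l.value for l in labels]}
    )

    stats: dict = {
        "n_subjects": len(measurements),
        "selection_rate": classify.selection_rate(labels),
        "thresholds": {"c_f": config.c_f, "c_s": config.c_s},
    }
    refs = [m.reference_label for m in measurements]
    if all(r is not None for r in refs):
        decided = [
            (lab, ref)
            for lab, ref in zip(labels, refs)
            if lab is not PulseClass.MIDDLE_DEPTH
        ]
        if decided:
            tab = concordance.agreement_table(*zip(*decided))
            stats["decided"] = {
                "n": tab.total,
                "accuracy": concordance.accuracy(tab),
                "mcc": concordance.mcc(tab),
            }
        ref_float = [r is PulseClass.FLOATING for r in refs]
        vals = cfs_df["cfs"].to_numpy()
        ga, gb = vals[np.array(ref_float)], vals[~np.array(ref_float)]
        if ga.size >= 2 and gb.size >= 2:
            ts = concordance.welch_ttest(ga, gb, covariate=f"cfs_{config.variant}")
            stats["cfs_ttest"] = {
                "mean_floating": ts.mean_a,
                "mean_sunken": ts.mean_b,
                "t": ts.t_statistic,
                "p": ts.p_value,
            }

    prof_df.to_csv(config.out_dir / "profiles.csv", index=False)
    cfs_df.to_csv(config.out_dir / "cfs.csv", index=False)
    labels_df.to_csv(config.out_dir / "labels.csv", index=False)
    (config.out_dir / "stats.json").write_text(json.dumps(stats, indent=2))
    return {
        "profiles": prof_df,
        "cfs": cfs_df,
        "labels": labels_df,
        "stats": stats,
    }
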