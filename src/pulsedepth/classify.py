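"""Threshold rules turning a depth coefficient into a pulse class.

Three rules are provided:

* single threshold C*: C_fs <= C* -> floating, else sunken;
* dual thresholds C_f* <= C_s*: C_fs <= C_f* -> floating,
  C_fs > C_s* -> sunken, the band in between left to a third outcome;
* the three-class reading of the dual rule, where the in-between band is
  the middle-depth pulse group.

The dual rule trades coverage for accuracy: widening the band rejects
more subjects (lower selection rate) but the decisions that remain agree
better with the reference rater.  The sweep utilities enumerate the
threshold grid(s), tabulate concordance with a reference labelling, and
extract the accuracy-versus-selection-rate frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import AgreementTable, mcc as _mcc
from .records import PulseClass

DEFAULT_GRID_STEP = 0.01  # thresholds are conventionally quoted to 2 decimals


def classify_single(cfs: float, c_star: float) -> PulseClass:
    """Single-threshold rule; the boundary C_fs = C* belongs to floating."""
    _check_unit_interval(cfs, "cfs")
    return PulseClass.FLOATING if cfs <= c_star else PulseClass.SUNKEN


def classify_dual(cfs: float, c_f: float, c_s: float) -> PulseClass:
    """Dual-threshold rule with a middle-depth band (C_f* < C_fs <= C_s*).

    Reduces exactly to ``classify_single`` when ``c_f == c_s``.
    """
    _check_unit_interval(cfs, "cfs")
    if c_f > c_s:
        raise ValueError(f"c_f must be <= c_s, got ({c_f}, {c_s})")
    if cfs <= c_f:
        return PulseClass.FLOATING
    if cfs > c_s:
        return PulseClass.SUNKEN
    return PulseClass.MIDDLE_DEPTH


def selection_rate(labels: Sequence[PulseClass]) -> float:
    """Fraction of subjects given a floating or sunken decision."""
    labels = [PulseClass(l) for l in labels]
    if not labels:
        raise ValueError("empty label sequence")
    decided = sum(l is not PulseClass.MIDDLE_DEPTH for l in labels)
    return decided / len(labels)


@dataclass
class SweepResult:
    """Grid evaluation of a threshold rule against reference labels."""

    table: pd.DataFrame
    best_accuracy: pd.DataFrame  # all grid points tying for maximal accuracy
    best_mcc: Optional[pd.DataFrame] = None  # single-threshold sweeps only
    frontier: Optional[pd.DataFrame] = None  # dual-threshold sweeps only


def _grid(step: float) -> np.ndarray:
    if not 0 < step <= 1:
        raise ValueError(f"grid_step must be in (0, 1], got {step}")
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def _prepare(cfs_values, reference_labels) -> tuple[np.ndarray, np.ndarray]:
    cfs = np.asarray(cfs_values, dtype=float)
    ref = [PulseClass(l) for l in reference_labels]
    if cfs.size != len(ref) or cfs.size == 0:
        raise ValueError("cfs values and reference labels must align and be non-empty")
    if any(l is PulseClass.MIDDLE_DEPTH for l in ref):
        raise ValueError("reference labels must be binary floating/sunken")
    if np.any((cfs < 0) | (cfs > 1)):
        raise ValueError("cfs values must lie in [0, 1]")
    ref_floating = np.array([l is PulseClass.FLOATING for l in ref])
    return cfs, ref_floating


def sweep_single(
    cfs_values: Sequence[float],
    reference_labels: Sequence,
    grid_step: float = DEFAULT_GRID_STEP,
) -> SweepResult:
    """Evaluate the single-threshold rule on a C* grid over [0, 1].

    For every grid threshold the predictions are cross-tabulated against
    the reference labels; the table rows carry the concordant floating
    and sunken counts, accuracy and MCC.  All grid points tying for the
    maximal accuracy (and MCC) are reported; the smallest threshold is
    the primary by convention.
    """
    cfs, ref_floating = _prepare(cfs_values, reference_labels)
    grid = _grid(grid_step)
    n = cfs.size

    pred_floating = cfs[None, :] <= grid[:, None]  # (n_grid, n_subjects)
    a = (pred_floating & ref_floating).sum(axis=1)
    d = (~pred_floating & ~ref_floating).sum(axis=1)
    b = (pred_floating & ~ref_floating).sum(axis=1)  # predicted floating, ref sunken
    c = (~pred_floating & ref_floating).sum(axis=1)
    acc = (a + d) / n
    mcc_vals = np.array(
        [_mcc(AgreementTable(int(ai), int(bi), int(ci), int(di)))
         for ai, bi, ci, di in zip(a, b, c, d)]
    )
    table = pd.DataFrame(
        {
            "c_star": grid,
            "n_decided": n,
            "n_concordant_floating": a,
            "n_concordant_sunken": d,
            "accuracy": acc,
            "mcc": mcc_vals,
            "selection_rate": 1.0,
        }
    )
    best_acc = table[table["accuracy"] == table["accuracy"].max()].reset_index(drop=True)
    best_mcc = table[table["mcc"] == table["mcc"].max()].reset_index(drop=True)
    return SweepResult(table=table, best_accuracy=best_acc, best_mcc=best_mcc)


def sweep_dual(
    cfs_values: Sequence[float],
    reference_labels: Sequence,
    grid_step: float = DEFAULT_GRID_STEP,
) -> SweepResult:
    """Evaluate the dual-threshold rule on all grid pairs C_f* <= C_s*.

    Because the floating decision depends only on C_f* and the sunken
    decision only on C_s*, counts separate into per-threshold cumulative
    tallies combined over the upper-triangular pair grid.  MCC is not
    reported: with an undetermined band it is poorly defined.

    The ``frontier`` table gives, for every achievable number of decided
    subjects, the maximal concordant count and a pair achieving it
    (smallest (c_f, c_s) lexicographically among ties).
    """
    cfs, ref_floating = _prepare(cfs_values, reference_labels)
    grid = _grid(grid_step)
    n = cfs.size

    below = cfs[None, :] <= grid[:, None]
    n_float = below.sum(axis=1)  # decided floating at c_f
    conc_float = (below & ref_floating).sum(axis=1)
    n_sunk = n - n_float  # decided sunken at c_s (cfs > c_s)
    conc_sunk = ((~below) & (~ref_floating)).sum(axis=1)

    i_f, i_s = np.triu_indices(grid.size)
    decided = n_float[i_f] + n_sunk[i_s]
    concordant = conc_float[i_f] + conc_sunk[i_s]
    with np.errstate(invalid="ignore"):
        acc = np.where(decided > 0, concordant / np.maximum(decided, 1), np.nan)
    table = pd.DataFrame(
        {
            "c_f": grid[i_f],
            "c_s": grid[i_s],
            "n_decided": decided,
            "n_concordant_floating": conc_float[i_f],
            "n_concordant_sunken": conc_sunk[i_s],
            "accuracy": acc,
            "selection_rate": decided / n,
        }
    )

    with_dec = table.dropna(subset=["accuracy"])
    best = with_dec[with_dec["accuracy"] == with_dec["accuracy"].max()]
    # primary tie-break: decide as many subjects as possible
    best = best.sort_values(
        ["selection_rate", "c_f", "c_s"], ascending=[False, True, True]
    ).reset_index(drop=True)

    work = table.assign(
        n_concordant=table["n_concordant_floating"] + table["n_concordant_sunken"]
    ).sort_values(["n_decided", "c_f", "c_s"], ignore_index=True)
    idx = work.groupby("n_decided")["n_concordant"].idxmax()
    frontier = work.loc[idx].reset_index(drop=True)
    return SweepResult(table=table, best_accuracy=best, frontier=frontier)


def _check_unit_interval(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
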