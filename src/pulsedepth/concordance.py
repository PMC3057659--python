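"""Agreement and group-comparison statistics.

Covers the validation arithmetic around the depth classifier: 2x2
agreement tables between two raters (or rater versus algorithm), their
accuracy and Matthews correlation coefficient (MCC), Pearson correlation
between coefficient variants, and two-sample T-tests between the
floating and sunken pulse groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import PulseClass

_BINARY = (PulseClass.FLOATING, PulseClass.SUNKEN)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-tabulation of two binary (floating/sunken) label sets.

    Orientation is fixed: ``a`` both-floating, ``b`` rater1-sunken &
    rater2-floating, ``c`` rater1-floating & rater2-sunken, ``d``
    both-sunken.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GroupStats:
    """Two-group summary plus the T-test comparing their means."""

    covariate: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float


def _as_binary(labels: Sequence) -> list[PulseClass]:
    out = [PulseClass(l) for l in labels]
    bad = [l.value for l in out if l not in _BINARY]
    if bad:
        raise ValueError(f"labels must be binary floating/sunken; got {bad[:3]}")
    return out


def agreement_table(labels_a: Sequence, labels_b: Sequence) -> AgreementTable:
    """Cross-tabulate two equal-length binary label sequences.

    ``labels_a`` plays rater 1, ``labels_b`` rater 2.
    """
    la, lb = _as_binary(labels_a), _as_binary(labels_b)
    if len(la) != len(lb):
        raise ValueError(f"label sequences differ in length: {len(la)} vs {len(lb)}")
    a = b = c = d = 0
    for x, y in zip(la, lb):
        if x is PulseClass.FLOATING and y is PulseClass.FLOATING:
            a += 1
        elif x is PulseClass.SUNKEN and y is PulseClass.FLOATING:
            b += 1
        elif x is PulseClass.FLOATING and y is PulseClass.SUNKEN:
            c += 1
        else:
            d += 1
    return AgreementTable(a, b, c, d)


def accuracy(table: AgreementTable) -> float:
    """Fraction of concordant pairs, (a + d) / total."""
    if table.total == 0:
        raise ValueError("empty agreement table")
    return (table.a + table.d) / table.total


def mcc(table: AgreementTable) -> float:
    """Matthews correlation coefficient of a 2x2 table.

    (ad - bc) / sqrt((a+b)(a+c)(d+b)(d+c)); defined as 0 when any
    marginal is zero (the conventional limit).
    """
    if table.total == 0:
        raise ValueError("empty agreement table")
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (a + c) * (d + b) * (d + c)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / np.sqrt(denom))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def welch_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    covariate: str = "",
    *,
    equal_var: bool = False,
) -> GroupStats:
    """Two-sample T-test between two groups (Welch by default).

    Welch's unequal-variance form is the default because the group
    standard deviations of real pulse cohorts differ visibly; pass
    ``equal_var=True`` for the pooled form.  P-values are two-sided.
    """
    ga = np.asarray(group_a, dtype=float)
    gb = np.asarray(group_b, dtype=float)
    if ga.size < 2 or gb.size < 2:
        raise ValueError("each group needs >= 2 observations for a T-test")
    res = stats.ttest_ind(ga, gb, equal_var=equal_var)
    return GroupStats(
        covariate=covariate,
        n_a=int(ga.size),
        n_b=int(gb.size),
        mean_a=float(ga.mean()),
        mean_b=float(gb.mean()),
        sd_a=float(ga.std(ddof=1)),
        sd_b=float(gb.std(ddof=1)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
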