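"""Method-agreement and association statistics for paired quantifications.

Bland–Altman analysis (bias, 1.96-SD limits of agreement, coefficient of
variation), Pearson association with a least-squares line, and descriptive
cohort summaries.  Inferential modelling (mixed models, multiplicity
corrections) is intentionally out of scope; outputs are descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "AssociationResult",
    "bland_altman",
    "association",
    "cohort_summary",
]


@dataclass
class PairedMeasurements:
    """Per-subject paired scalars from two methods (e.g. enhanced area %
    by dS/S0 and by LGE)."""

    method_a: np.ndarray
    method_b: np.ndarray
    subject_ids: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise StatisticsError("methods must be equal-length 1-D sequences")
        if self.method_a.size < 2:
            raise StatisticsError(f"need >= 2 pairs, got {self.method_a.size}")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise StatisticsError("paired measurements must be finite")
        if not list(self.subject_ids):
            self.subject_ids = [str(i) for i in range(self.method_a.size)]

    @property
    def n(self) -> int:
        return int(self.method_a.size)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary.  ``cov`` is SD(differences) divided by the
    grand mean of per-pair means; NaN when that grand mean is zero."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    cov: float
    n: int
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class AssociationResult:
    r: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland–Altman agreement between two methods.

    Differences d = a - b; bias = mean(d); limits of agreement
    bias +/- 1.96 * sample SD(d); coefficient of variation
    CoV = SD(d) / grand mean of per-pair means (NaN and flagged when the
    grand mean is zero).  The per-pair (mean, difference) table used for
    plotting is returned alongside.
    """
    d = pairs.method_a - pairs.method_b
    m = (pairs.method_a + pairs.method_b) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    grand_mean = float(np.mean(m))
    cov = sd / grand_mean if grand_mean != 0 else math.nan
    table = pd.DataFrame(
        {"subject": list(pairs.subject_ids), "mean": m, "difference": d}
    )
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        cov=cov,
        n=pairs.n,
        table=table,
    )


def association(pairs: PairedMeasurements) -> AssociationResult:
    """Pearson correlation and least-squares line of method A on method B."""
    if pairs.n < 3:
        raise StatisticsError(f"association needs >= 3 pairs, got {pairs.n}")
    if np.std(pairs.method_a) == 0 or np.std(pairs.method_b) == 0:
        raise StatisticsError("association undefined for zero-variance input")
    fit = sps.linregress(pairs.method_b, pairs.method_a)
    return AssociationResult(
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=pairs.n,
    )


def cohort_summary(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive per-group table (mean, sample SD, n) plus pairwise mean
    differences.

    Groups with a single observation report NaN SD; empty groups appear
    with n = 0 and NaN statistics rather than raising.  The pairwise block
    lists mean(group_i) - mean(group_j) for every ordered pair i < j.
    """
    rows = []
    means: dict[str, float] = {}
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        mean = float(np.mean(v)) if v.size else math.nan
        means[name] = mean
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "mean": mean,
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else math.nan,
            }
        )
    summary = pd.DataFrame(rows)
    names = list(groups)
    diffs = [
        {
            "group_a": a,
            "group_b": b,
            "mean_difference": means[a] - means[b],
        }
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    summary.attrs["pairwise_differences"] = pd.DataFrame(
        diffs, columns=["group_a", "group_b", "mean_difference"]
    )
    return summary
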