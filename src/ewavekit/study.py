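"""Reproducibility statistics between two repeated analyses.

Each case contributes one value per analysis (the per-patient mean of its
beats); agreement between the two analyses is summarized by the coefficient
of variation of the paired differences, the intraclass correlation
coefficient and the absolute percentage difference.  Parameters that are
negative by definition (the damping index) report CV and percentage
difference as positive magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import StatisticsError

__all__ = [
    "PairedMeasurements",
    "ICCResult",
    "coefficient_of_variation",
    "icc",
    "percentage_difference",
]


@dataclass
class PairedMeasurements:
    """Per-case values from two analyses of the same cases, paired by id."""

    labels: Sequence
    a: np.ndarray
    b: np.ndarray
    parameter: str = ""
    units: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.labels = list(self.labels)
        if not (len(self.labels) == len(self.a) == len(self.b)):
            raise StatisticsError("labels, a and b must have equal lengths")
        if len(self.a) < 2:
            raise StatisticsError("need at least 2 paired cases")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class ICCResult:
    """ICC value with the two-way ANOVA variance components it came from."""

    value: float
    form: str
    msr: float  # between-subjects mean square
    msc: float  # between-raters mean square
    mse: float  # residual mean square
    n: int
    k: int


def coefficient_of_variation(pairs: PairedMeasurements) -> float:
    """CV of the between-analysis differences, %.

    100 × SD(a − b) / mean of all values (both analyses pooled), reported as
    a positive magnitude even for negative-valued parameters.  The SD uses
    the n − 1 denominator.  Identical analyses give 0 %.
    """
    grand_mean = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    if grand_mean == 0:
        raise StatisticsError("grand mean is zero; CV undefined")
    sd_diff = float(np.std(pairs.a - pairs.b, ddof=1))
    return abs(100.0 * sd_diff / grand_mean)


def icc(pairs: PairedMeasurements, form: str = "ICC(2,1)") -> ICCResult:
    """Intraclass correlation coefficient between the two analyses.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measures — both the cases and the analyses (raters) are treated
    as random draws.  ``form="ICC(3,1)"`` gives the two-way mixed,
    consistency form.  Computed from the balanced two-way ANOVA mean
    squares, which are returned alongside the value.
    """
    y = np.column_stack([pairs.a, pairs.b])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        raise StatisticsError("zero total variance; ICC undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unsupported ICC form {form!r}")
    if denom == 0:
        raise StatisticsError("degenerate ANOVA; ICC undefined")
    return ICCResult(value=float((msr - mse) / denom), form=form,
                     msr=msr, msc=msc, mse=mse, n=n, k=k)


def percentage_difference(pairs: PairedMeasurements) -> tuple[float, float]:
    """Mean and SD of the per-case absolute percentage difference.

    Per case: 100·|a − b| / ((a + b)/2).  Cases whose pairwise mean is zero
    are excluded with a warning (the ratio is undefined there).  The SD uses
    the n − 1 denominator and is NaN when only one case remains.
    """
    means = (pairs.a + pairs.b) / 2.0
    ok = means != 0
    if not ok.all():
        excluded = [pairs.labels[i] for i in np.nonzero(~ok)[0]]
        warnings.warn(
            f"percentage_difference: excluded cases with zero pairwise mean: "
            f"{excluded}")
    if not ok.any():
        raise StatisticsError("all pairwise means are zero")
    d = 100.0 * np.abs(pairs.a[ok] - pairs.b[ok]) / np.abs(means[ok])
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1)) if d.size > 1 else float("nan")
    return mean, sd
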