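"""Validation statistics: mean +/- SD, Pearson correlation, Bland-Altman.

Conventions used throughout: the sample standard deviation (n-1 denominator);
two-sided Pearson p-value from the exact t distribution with n-2 degrees of
freedom; Bland-Altman limits of agreement at bias +/- 1.96 x SD of the paired
differences, paired by artery label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import PairingError, ValidationError


@dataclass
class PairedMeasurements:
    """Matched measurements from two readers (or series), one per label."""

    labels: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.labels) == len(self.a) == len(self.b)):
            raise ValidationError("labels, a and b must have equal lengths")
        if len(self.labels) < 2:
            raise ValidationError("need at least two paired measurements")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("pair labels must be unique")

    @classmethod
    def from_labeled(
        cls,
        labels_a: Sequence[str],
        a: Sequence[float],
        labels_b: Sequence[str],
        b: Sequence[float],
    ) -> "PairedMeasurements":
        """Align two labelled series by label; any mismatch is a pairing error."""
        if sorted(labels_a) != sorted(labels_b):
            only_a = sorted(set(labels_a) - set(labels_b))
            only_b = sorted(set(labels_b) - set(labels_a))
            raise PairingError(
                f"reader labels do not match (only in A: {only_a}, only in B: {only_b})"
            )
        lookup = dict(zip(labels_b, b))
        return cls(labels=list(labels_a), a=list(a), b=[lookup[l] for l in labels_a])


@dataclass
class AgreementResult:
    """Bland-Altman summary: bias, SD of differences, limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_half_width: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_half_width": self.loa_half_width,
            "n": self.n,
        }


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n}


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("sample SD undefined for fewer than two values")
    return float(v.mean()), float(v.std(ddof=1))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the exact two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal lengths")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs at least three pairs")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValidationError("correlation undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland-Altman agreement over matched pairs.

    Returns bias (mean of a-b), sample SD of the differences, and the 95%
    limits of agreement bias -/+ 1.96*SD, along with the per-pair (mean,
    difference) points for plotting.
    """
    diffs = pairs.a - pairs.b
    means = (pairs.a + pairs.b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half = 1.96 * sd
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half,
        loa_high=bias + half,
        loa_half_width=half,
        n=len(diffs),
        means=means,
        diffs=diffs,
    )


def loa_as_pct_of_reference(agr: AgreementResult, reference_cm3: float) -> float:
    """Limits-of-agreement half-width as a percentage of a reference volume
    (typically the cohort's mean preoperative total volume)."""
    if not reference_cm3 > 0:
        raise ValidationError("reference volume must be positive")
    return 100.0 * agr.loa_half_width / reference_cm3


def bland_altman_plot(agr: AgreementResult, path: str | Path) -> None:
    """Optional plot artifact: points at (mean, difference), dashed bias and
    limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(agr.means, agr.diffs, s=18, color="black")
    ax.axhline(agr.bias, color="tab:blue", linestyle="--", label=f"bias = {agr.bias:.2f}")
    for y in (agr.loa_low, agr.loa_high):
        ax.axhline(y, color="tab:orange", linestyle="--")
    ax.set_xlabel("mean of readers (cm$^3$)")
    ax.set_ylabel("difference (cm$^3$)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
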