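"""Paired-method agreement statistics for two quantification series.

Implements the comparison battery used when judging whether two imaging
methods (e.g. a native 2D acquisition and a resliced 3D acquisition)
measure the same quantity: Student's paired two-tailed t-test, Pearson
correlation, Bland-Altman bias with 95% limits of agreement
(bias +/- 1.96 * sample SD of the differences), the Wilcoxon
matched-pairs signed-rank test, and an exact-binomial McNemar test for
paired binary detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import StatsError

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "bland_altman",
    "paired_tests",
    "agreement_report",
    "mcnemar_exact",
    "LOA_MULTIPLIER",
]

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement


@dataclass
class PairedSeries:
    """Paired measurements of one metric by two methods on the same subjects.

    Subjects with a missing value in either series are dropped and counted
    in ``n_dropped``.
    """

    x: np.ndarray
    y: np.ndarray
    labels: list = field(default_factory=list)
    metric: str = ""
    unit: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise StatsError("x and y must be 1D arrays of equal length")
        labels = list(self.labels) if self.labels else list(range(len(x)))
        if len(labels) != len(x):
            raise StatsError("labels must match series length")
        keep = np.isfinite(x) & np.isfinite(y)
        self.n_dropped = int(np.sum(~keep))
        self.x = x[keep]
        self.y = y[keep]
        self.labels = [l for l, k in zip(labels, keep) if k]
        if len(self.x) < 3:
            raise StatsError(f"need >= 3 complete pairs, have {len(self.x)}")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    r: float
    r_p: float
    t_stat: float
    t_p: float
    wilcoxon_p: float
    n: int
    pairs: pd.DataFrame  # columns: label, mean, difference


def bland_altman(series: PairedSeries) -> tuple[float, float, float, pd.DataFrame]:
    """Bias, 95% limits of agreement, and the per-pair (mean, difference) table.

    bias = mean(x - y); LoA = bias -/+ 1.96 * sample SD of the differences.
    The table holds, per pair, the mean of the two methods (x-axis of a
    Bland-Altman plot) against their difference (y-axis).
    """
    d = series.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    pairs = pd.DataFrame(
        {
            "label": series.labels,
            "mean": (series.x + series.y) / 2.0,
            "difference": d,
        }
    )
    return bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, pairs


def paired_tests(
    series: PairedSeries,
) -> tuple[float, float, float, float, float]:
    """(t statistic, t p-value, Pearson r, r p-value, Wilcoxon p-value).

    Two-tailed paired t-test; Pearson correlation of x against y (raises on
    a constant series, where r is undefined); Wilcoxon matched-pairs
    signed-rank with Pratt handling of zero differences — exact null
    distribution for n <= 25 when no zero differences are present, normal
    approximation with continuity correction otherwise.
    """
    x, y = series.x, series.y
    d = series.differences
    if np.allclose(d, 0):
        # degenerate identical series: t undefined (0/0) -> no evidence of bias
        t_stat, t_p, w_p = 0.0, 1.0, 1.0
    else:
        t_res = sps.ttest_rel(x, y)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        has_zeros = bool(np.any(d == 0))
        if series.n <= 25 and not has_zeros:
            w_res = sps.wilcoxon(x, y, zero_method="pratt", method="exact")
        else:
            w_res = sps.wilcoxon(
                x, y, zero_method="pratt", correction=True, method="approx"
            )
        w_p = float(w_res.pvalue)
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("Pearson r undefined for a constant series")
    r_res = sps.pearsonr(x, y)
    return t_stat, t_p, float(r_res.statistic), float(r_res.pvalue), w_p


def agreement_report(series: PairedSeries) -> AgreementReport:
    """Full agreement battery for one paired metric."""
    bias, lo, hi, pairs = bland_altman(series)
    t_stat, t_p, r, r_p, w_p = paired_tests(series)
    return AgreementReport(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        r=r,
        r_p=r_p,
        t_stat=t_stat,
        t_p=t_p,
        wilcoxon_p=w_p,
        n=series.n,
        pairs=pairs,
    )


def mcnemar_exact(detect_x: np.ndarray, detect_y: np.ndarray) -> float:
    """Exact-binomial McNemar p-value for paired binary detections.

    Compares two methods' ability to detect a finding (e.g. papillary
    infarction) in the same subjects; only the discordant pairs inform the
    test.
    """
    dx = np.asarray(detect_x, dtype=bool)
    dy = np.asarray(detect_y, dtype=bool)
    if dx.shape != dy.shape or dx.ndim != 1:
        raise StatsError("detection vectors must be 1D of equal length")
    table = np.array(
        [
            [np.sum(dx & dy), np.sum(dx & ~dy)],
            [np.sum(~dx & dy), np.sum(~dx & ~dy)],
        ]
    )
    return float(_sm_mcnemar(table, exact=True).pvalue)
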