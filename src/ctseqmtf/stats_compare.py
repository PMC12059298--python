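"""Validation statistics for paired resolution measurements.

Method-vs-method and parameter-vs-MTF Pearson correlations, mean +/- SD
aggregation over consecutive slices, and mean absolute relative differences,
applied to the packaged per-slice 50%/10% MTF comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series_io import ValidationFixture, load_table2_fixture

__all__ = [
    "PairedSeries",
    "pearson",
    "mean_abs_rel_diff",
    "summarize",
    "validate_against_fixture",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired reference/test measurements sharing labels."""

    labels: tuple
    ref_values: np.ndarray
    test_values: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.ref_values, dtype=np.float64)
        test = np.asarray(self.test_values, dtype=np.float64)
        if not (len(self.labels) == ref.size == test.size):
            raise ValueError("labels, ref and test must have equal length")
        if ref.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(test))):
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "ref_values", ref)
        object.__setattr__(self, "test_values", test)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length arrays of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def mean_abs_rel_diff(ref, test) -> float:
    """Mean of |test - ref| / |ref|, as a percentage."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.size != test.size or ref.size == 0:
        raise ValueError("ref and test must be equal-length and non-empty")
    if np.any(ref == 0):
        raise ValueError("relative difference undefined for zero reference values")
    return float(np.mean(np.abs(test - ref) / np.abs(ref)) * 100.0)


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n - 1 denominator)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if values.size < 2:
        raise ValueError("sample standard deviation needs >= 2 values")
    return float(values.mean()), float(values.std(ddof=1))


def validate_against_fixture(fixture: ValidationFixture | None = None) -> dict:
    """Correlation/difference report over the packaged comparison table.

    Pearson correlations between the two single-image methods (50% and 10%
    MTF), between tube current and each method's metrics, and the mean
    absolute relative difference between methods at both MTF levels; all
    rounded to 2 decimals, matching the precision of printed comparisons.
    """
    if fixture is None:
        fixture = load_table2_fixture()
    df = fixture.dataframe
    ma = df["tube_current_ma"].to_numpy(float)
    i50 = df["indoqct_mtf50_lp_cm"].to_numpy(float)
    i10 = df["indoqct_mtf10_lp_cm"].to_numpy(float)
    s50 = df["single_mtf50_lp_cm"].to_numpy(float)
    s10 = df["single_mtf10_lp_cm"].to_numpy(float)
    report = {
        "pearson_mtf50_methods": pearson(i50, s50),
        "pearson_mtf10_methods": pearson(i10, s10),
        "pearson_tube_current_indoqct_mtf50": pearson(ma, i50),
        "pearson_tube_current_indoqct_mtf10": pearson(ma, i10),
        "pearson_tube_current_single_mtf50": pearson(ma, s50),
        "pearson_tube_current_single_mtf10": pearson(ma, s10),
        "mean_abs_rel_diff_mtf50_percent": mean_abs_rel_diff(i50, s50),
        "mean_abs_rel_diff_mtf10_percent": mean_abs_rel_diff(i10, s10),
    }
    return {k: round(v, 2) for k, v in report.items()}
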