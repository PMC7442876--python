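"""Pointwise paired testing and empirical quantile bands over a cohort.

All operations consume a cohort of :class:`DifferenceProfile` objects and
work on the stacked ``n_subjects x 768`` matrix of OS-minus-OD differences.
Paired t-tests of thickness between the eyes reduce to one-sample t-tests
of the difference against zero; p-values are Bonferroni-adjusted by the
number of scanning locations (768), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import N_LOCATIONS, DifferenceProfile, location_angles

__all__ = [
    "PointwiseTestResult",
    "QuantileBands",
    "stack_deltas",
    "pointwise_paired_tests",
    "global_difference",
    "empirical_quantiles",
]

ALPHA = 0.05


def stack_deltas(diffs: list[DifferenceProfile]) -> np.ndarray:
    """Stack a cohort into an (n_subjects, 768) difference matrix."""
    if not diffs:
        raise ValueError("empty cohort")
    return np.vstack([d.delta for d in diffs])


@dataclass
class PointwiseTestResult:
    """Per-location paired t-test results (length-768 arrays)."""

    mean_delta: np.ndarray  # um
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray  # Bonferroni x768, capped at 1
    significant: np.ndarray  # p_adj < 0.05
    degenerate: np.ndarray  # zero-variance locations

    @property
    def fraction_significant(self) -> float:
        return float(self.significant.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": location_angles(),
                "mean_delta_um": self.mean_delta,
                "t_stat": self.t_stat,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
                "degenerate": self.degenerate,
            }
        )


@dataclass
class QuantileBands:
    """Per-location sample quantiles of the interocular difference."""

    probs: np.ndarray  # (k,)
    values: np.ndarray  # (768, k), nondecreasing along axis 1

    def to_frame(self) -> pd.DataFrame:
        cols = {f"q{p:g}": self.values[:, j] for j, p in enumerate(self.probs)}
        return pd.DataFrame({"angle_deg": location_angles(), **cols})


def pointwise_paired_tests(diffs: list[DifferenceProfile]) -> PointwiseTestResult:
    """Two-sided one-sample t-test of the difference against 0 per location.

    Degenerate locations (zero variance across subjects) are flagged and
    reported with ``p_adj = 1`` rather than a spurious infinite t-statistic.
    """
    deltas = stack_deltas(diffs)
    n = deltas.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    degenerate = sd == 0.0

    t_stat = np.zeros(N_LOCATIONS)
    p_raw = np.ones(N_LOCATIONS)
    ok = ~degenerate
    if ok.any():
        res = stats.ttest_1samp(deltas[:, ok], popmean=0.0, axis=0)
        t_stat[ok] = res.statistic
        p_raw[ok] = res.pvalue
    p_adj = np.minimum(1.0, N_LOCATIONS * p_raw)
    p_adj[degenerate] = 1.0
    significant = (p_adj < ALPHA) & ~degenerate
    return PointwiseTestResult(mean, t_stat, p_raw, p_adj, significant, degenerate)


def global_difference(diffs: list[DifferenceProfile]) -> tuple[float, float, float]:
    """Global interocular difference: per-subject mean over all 768 locations,
    then a one-sample t-test against 0.

    Returns ``(mean, t, p)`` with mean in um under the OS-minus-OD sign
    convention (a cohort in which right eyes are thicker yields a negative
    mean).
    """
    deltas = stack_deltas(diffs)
    if deltas.shape[0] < 3:
        raise ValueError(f"need at least 3 subjects, got {deltas.shape[0]}")
    subject_means = deltas.mean(axis=1)
    mean = float(subject_means.mean())
    if subject_means.std(ddof=1) == 0.0:
        return mean, 0.0, 1.0
    res = stats.ttest_1samp(subject_means, popmean=0.0)
    return mean, float(res.statistic), float(res.pvalue)


def empirical_quantiles(diffs: list[DifferenceProfile], probs) -> QuantileBands:
    """Per-location sample quantiles (linear interpolation of order
    statistics, the type-7 convention)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0 or np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probs must lie strictly in (0, 1)")
    if np.any(np.diff(probs) < 0):
        raise ValueError("probs must be sorted ascending")
    deltas = stack_deltas(diffs)
    values = np.quantile(deltas, probs, axis=0, method="linear").T  # (768, k)
    return QuantileBands(probs=probs, values=values)
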