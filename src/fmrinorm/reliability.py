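"""Test-retest reliability of deviation maps.

Three per-voxel measures across two sessions of the same subjects:
ICC(3,1) — two-way mixed-effects, single measurement, *consistency*
intraclass correlation, ``(MSR - MSE) / (MSR + (k-1) MSE)`` with k = 2
sessions; the within-subject mean difference with a paired t-test; and the
between-session Pearson correlation.  All three are vectorised over voxels.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .normative import DeviationMap


def _check_pair(dev_test: DeviationMap, dev_retest: DeviationMap) -> None:
    if dev_test.subject_ids != dev_retest.subject_ids:
        raise ValueError("sessions must cover the same subjects in the same order")
    if dev_test.Z.shape != dev_retest.Z.shape:
        raise ValueError("sessions must have matching shapes")
    if dev_test.Z.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")


def icc_map(dev_test: DeviationMap, dev_retest: DeviationMap) -> np.ndarray:
    """Per-voxel ICC(3,1) between the two sessions.

    Computed from two-way ANOVA mean squares with subjects as rows and the
    two sessions as columns.  Equals 1 when the sessions are identical and
    is invariant to a constant session offset (consistency form).
    """
    _check_pair(dev_test, dev_retest)
    x = np.stack([dev_test.Z, dev_retest.Z])  # (k, n, V)
    k, n, _ = x.shape
    grand = x.mean(axis=(0, 1))
    subj_mean = x.mean(axis=0)  # (n, V)
    sess_mean = x.mean(axis=1)  # (k, V)
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((sess_mean - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / (msr + (k - 1) * mse)
    return icc


def paired_difference_map(
    dev_test: DeviationMap,
    dev_retest: DeviationMap,
    alpha: float = 0.05,
    diff_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Session change per voxel: mean (retest - test) and paired-t p-values.

    Returns the mean-difference map, the two-sided p map, and summary
    fractions: voxels significant at ``alpha`` (uncorrected) and voxels with
    ``|mean diff| > diff_threshold`` (half a Z-score by default).  Voxels
    with zero difference variance get NaN p-values and are excluded from the
    significant fraction's denominator.
    """
    _check_pair(dev_test, dev_retest)
    d = dev_retest.Z - dev_test.Z
    n = d.shape[0]
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd_d == 0, np.nan, p)
    defined = np.isfinite(p)
    summary = {
        "alpha": alpha,
        "p_correction": "uncorrected",
        "frac_significant": float(np.mean(p[defined] < alpha)) if defined.any() else np.nan,
        "frac_large_diff": float(np.mean(np.abs(mean_d) > diff_threshold)),
        "n_undefined": int((~defined).sum()),
    }
    return mean_d, p, summary


def retest_correlation_map(
    dev_test: DeviationMap, dev_retest: DeviationMap
) -> np.ndarray:
    """Per-voxel Pearson correlation of deviations across subjects between
    sessions; NaN where either session has zero variance at the voxel."""
    _check_pair(dev_test, dev_retest)
    a = dev_test.Z - dev_test.Z.mean(axis=0)
    b = dev_retest.Z - dev_retest.Z.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (a * b).mean(axis=0) / np.where(sa * sb == 0, np.nan, sa * sb)
    return rho


@dataclasses.dataclass
class ReliabilityReport:
    """Bundle of the three per-voxel reliability measures plus summaries."""

    icc: np.ndarray
    mean_diff: np.ndarray
    paired_t_p: np.ndarray
    pearson_rho: np.ndarray
    frac_significant: float
    frac_large_diff: float
    alpha: float
    diff_threshold: float
    p_correction: str = "uncorrected"

    def correlation_display_mask(self, threshold: float = 0.3) -> np.ndarray:
        """Voxels whose between-session rho^2 exceeds ``threshold``."""
        return self.pearson_rho**2 > threshold


def reliability_report(
    dev_test: DeviationMap,
    dev_retest: DeviationMap,
    alpha: float = 0.05,
    diff_threshold: float = 0.5,
) -> ReliabilityReport:
    """Compute ICC(3,1), paired differences and retest correlations together."""
    icc = icc_map(dev_test, dev_retest)
    mean_d, p, summary = paired_difference_map(
        dev_test, dev_retest, alpha=alpha, diff_threshold=diff_threshold
    )
    rho = retest_correlation_map(dev_test, dev_retest)
    return ReliabilityReport(
        icc=icc,
        mean_diff=mean_d,
        paired_t_p=p,
        pearson_rho=rho,
        frac_significant=summary["frac_significant"],
        frac_large_diff=summary["frac_large_diff"],
        alpha=alpha,
        diff_threshold=diff_threshold,
    )
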