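"""Normative probability maps: thresholding, deviation counts and burden tests.

A subject's normative probability map (NPM) is their deviation Z-map
thresholded at ``|Z| > t`` (default t = 2.6, i.e. one-sided p < .005 under a
standard normal).  Per-subject counts of supra-threshold voxels give the
deviation burden; per-voxel percentages of deviating subjects give the
sample frequency maps; burdens of two cohorts are compared with a two-sided
Mann-Whitney U test.
"""
from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .normative import DeviationMap

DEFAULT_THRESHOLD = 2.6


def threshold_npm(dev: DeviationMap, t: float = DEFAULT_THRESHOLD) -> DeviationMap:
    """Zero all deviations with ``|Z| <= t``; supra-threshold values keep sign.

    The inequality is strict: a score exactly at the threshold is below it.
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    Z = np.where(np.abs(dev.Z) > t, dev.Z, 0.0)
    return DeviationMap(Z, list(dev.subject_ids), dev.contrast)


@dataclasses.dataclass
class NPMSummary:
    """Per-subject extreme-deviation counts and per-voxel sample frequencies."""

    threshold: float
    n_pos: np.ndarray  # (n,) voxels with Z > +t per subject
    n_neg: np.ndarray  # (n,) voxels with Z < -t per subject
    pct_pos: np.ndarray  # (V,) % of sample with Z > +t at the voxel
    pct_neg: np.ndarray  # (V,)
    subject_ids: list[str]
    group_pct: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_total(self) -> np.ndarray:
        return self.n_pos + self.n_neg


def summarise_npm(
    dev: DeviationMap,
    t: float = DEFAULT_THRESHOLD,
    group_labels: Mapping[str, Sequence[str]] | None = None,
) -> NPMSummary:
    """Count extreme deviations per subject and per voxel.

    ``group_labels`` maps a label (e.g. a diagnosis) to the subject ids that
    carry it; subjects may appear under several labels, and each label gets
    its own (pct_pos, pct_neg) frequency maps over its subjects.
    """
    pos = dev.Z > t
    neg = dev.Z < -t
    summary = NPMSummary(
        threshold=t,
        n_pos=pos.sum(axis=1),
        n_neg=neg.sum(axis=1),
        pct_pos=100.0 * pos.mean(axis=0),
        pct_neg=100.0 * neg.mean(axis=0),
        subject_ids=list(dev.subject_ids),
    )
    if group_labels is not None:
        index = {s: i for i, s in enumerate(dev.subject_ids)}
        groups = {}
        for label, ids in group_labels.items():
            unknown = [s for s in ids if s not in index]
            if unknown:
                raise ValueError(f"group {label!r}: unknown subject ids {unknown[:5]}")
            rows = [index[s] for s in ids]
            groups[label] = (
                100.0 * pos[rows].mean(axis=0),
                100.0 * neg[rows].mean(axis=0),
            )
        summary.group_pct = groups
    return summary


@dataclasses.dataclass
class BurdenComparison:
    """Two-sided Mann-Whitney comparison of per-subject deviation burdens."""

    u_stat: float  # U of the first group
    p_value: float
    n1: int
    n2: int
    median_a: float
    median_b: float
    method: str  # "exact" or "normal"


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of the C(n, n1) group labelings,
    valid with mid-rank ties (the rank vector is fixed; only membership varies)."""
    n = len(ranks)
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dist = np.abs(u_obs - mu) - 1e-9
    hits = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dist:
            hits += 1
    return hits / comb(n, n1)


def compare_burden(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> BurdenComparison:
    """Compare deviation burdens of two cohorts (e.g. patients vs reference).

    Uses mid-ranks for ties; exact enumeration when ``min(n1, n2) <= 8``,
    otherwise a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if np.all(pooled == pooled[0]):
        warnings.warn("all burden values identical in both groups", stacklevel=2)
        return BurdenComparison(
            u_a, 1.0, n1, n2, float(np.median(a)), float(np.median(b)), "degenerate"
        )

    if min(n1, n2) <= 8:
        p = _exact_two_sided_p(ranks, n1, u_a)
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        mu = n1 * n2 / 2.0
        z = (abs(u_a - mu) - 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * stats.norm.sf(z))
        method = "normal"
    return BurdenComparison(
        u_a, float(p), n1, n2, float(np.median(a)), float(np.median(b)), method
    )


def exclude_voxels(dev: DeviationMap, voxel_indices: np.ndarray) -> DeviationMap:
    """Drop a voxel subset (e.g. an unstable signal-dropout region) before
    counting, keeping the remaining voxels' order."""
    keep = np.ones(dev.Z.shape[1], dtype=bool)
    keep[np.asarray(voxel_indices, dtype=int)] = False
    return DeviationMap(dev.Z[:, keep], list(dev.subject_ids), dev.contrast)
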