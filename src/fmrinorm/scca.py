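"""Sparse canonical correlation between symptom domains and deviation maps.

Follows the penalised matrix decomposition formulation: given centred data
matrices X (n x p symptom-domain scores) and Y (n x q voxel deviations),
find weight vectors u, v maximising ``u' X' Y v`` subject to
``||u||_2 <= 1``, ``||v||_2 <= 1``, ``||u||_1 <= c1`` and ``||v||_1 <= c2``.
The solution alternates closed-form updates
``u <- normalise(soft_threshold(X'Y v, delta_u))`` (delta found by bisection
so the L1 bound holds, 0 when the unconstrained update is already feasible)
and symmetrically for v, initialised at the leading singular pair of
``X'Y`` — deterministic, with a non-decreasing objective.

The default penalties mirror the study's heuristics on the PMD scale where
the sparsity fraction multiplies the L1 feasibility cap sqrt(dim):
``c1 = 0.9 sqrt(p)`` (light regularisation of the factor side) and
``c2 = 0.1 sqrt(q)`` (heavy regularisation of the voxel side, selecting no
more than ~10% of voxels in practice).

Generalisation is assessed by repeated 70/30 train-test splits and
significance by permuting the rows of X around the whole split procedure.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_U = 0.9  # fraction of sqrt(p): light regularisation
DEFAULT_PENALTY_V = 0.1  # fraction of sqrt(q): heavy regularisation
_L1_TOL = 1e-8


@dataclasses.dataclass
class SCCAInput:
    """Paired views: factor scores / diagnosis indicators X and deviations Y.

    ``voxel_indices`` maps Y's columns back to voxels of the full mask so a
    fitted v can be written out as a map after region masking.
    """

    X: np.ndarray  # (n, p)
    Y: np.ndarray  # (n, q)
    x_names: list[str] | None = None
    voxel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.voxel_indices is None:
            self.voxel_indices = np.arange(self.Y.shape[1])

    @property
    def n(self) -> int:
        return self.X.shape[0]


def apply_region_mask(inp: SCCAInput, mask: np.ndarray) -> SCCAInput:
    """Restrict Y to a voxel subset (boolean over current columns or index
    array); voxel bookkeeping is composed so v can be mapped back."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.size != inp.Y.shape[1]:
            raise ValueError("boolean mask length must match Y columns")
        cols = np.nonzero(mask)[0]
    else:
        cols = mask.astype(int)
        if cols.size and (cols.min() < 0 or cols.max() >= inp.Y.shape[1]):
            raise ValueError("mask indices outside Y columns")
    if cols.size == 0:
        raise ValueError("region mask selects no voxels")
    return SCCAInput(
        inp.X, inp.Y[:, cols], inp.x_names, np.asarray(inp.voxel_indices)[cols]
    )


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise ``sign(a) * max(|a| - delta, 0)``."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_constrained_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 soft-thresholded version of ``a`` with ``||.||_1 <= c``.

    delta = 0 when the plain normalisation is already feasible; otherwise
    delta is found by bisection (the L1 norm after thresholding and
    renormalising decreases monotonically in delta).
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    u = a / norm
    if np.abs(u).sum() <= c + _L1_TOL:
        return u
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(100):
        delta = 0.5 * (lo + hi)
        s = soft_threshold(a, delta)
        ns = np.linalg.norm(s)
        l1 = np.abs(s).sum() / ns if ns > 0 else 0.0
        if l1 > c:
            lo = delta
        else:
            hi = delta
        if hi - lo <= _L1_TOL * max(hi, 1.0):
            break
    s = soft_threshold(a, hi)
    ns = np.linalg.norm(s)
    if ns == 0:  # c below the single-coordinate limit: keep the largest entry
        j = int(np.argmax(np.abs(a)))
        s = np.zeros_like(a)
        s[j] = np.sign(a[j])
        return s
    return s / ns


@dataclasses.dataclass
class SCCAResult:
    """Weight vectors and objective of one sparse CCA fit."""

    u: np.ndarray  # (p,)
    v: np.ndarray  # (q,)
    objective: float  # u' X'Y v at return
    c1: float
    c2: float
    n_iter: int
    converged: bool

    @property
    def v_nonzero_fraction(self) -> float:
        return float(np.mean(self.v != 0))


def default_bounds(p: int, q: int) -> tuple[float, float]:
    """The study's penalty heuristics on the PMD scale, clipped to [1, sqrt(dim)]."""
    c1 = np.clip(DEFAULT_PENALTY_U * np.sqrt(p), 1.0, np.sqrt(p))
    c2 = np.clip(DEFAULT_PENALTY_V * np.sqrt(q), 1.0, np.sqrt(q))
    return float(c1), float(c2)


def fit_scca(
    inp: SCCAInput,
    c1: float | None = None,
    c2: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> SCCAResult:
    """Alternating penalised maximisation of ``u' X'Y v`` on centred views.

    Deterministic: v starts at the leading right singular vector of ``X'Y``.
    The objective never decreases across iterations; convergence is declared
    at relative objective change below ``tol``.  The sign convention makes
    u's largest-magnitude entry positive.
    """
    X, Y = inp.X, inp.Y
    p, q = X.shape[1], Y.shape[1]
    d1, d2 = default_bounds(p, q)
    if c1 is None:
        c1 = d1
    if c2 is None:
        c2 = d2
    if not 1.0 <= c1 <= np.sqrt(p) + _L1_TOL:
        raise ValueError(f"c1 must lie in [1, sqrt(p)={np.sqrt(p):.3f}], got {c1}")
    if not 1.0 <= c2 <= np.sqrt(q) + _L1_TOL:
        raise ValueError(f"c2 must lie in [1, sqrt(q)={np.sqrt(q):.3f}], got {c2}")

    C = X.T @ Y  # (p, q)
    if not np.any(C):
        warnings.warn("X'Y is identically zero; returning zero weights", stacklevel=2)
        return SCCAResult(np.zeros(p), np.zeros(q), 0.0, c1, c2, 0, True)

    # init: leading right singular vector of C (p is small, svd is cheap)
    _, _, vt = np.linalg.svd(C, full_matrices=False)
    v = vt[0]
    u = np.zeros(p)
    obj_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _l1_constrained_unit(C @ v, c1)
        v = _l1_constrained_unit(C.T @ u, c2)
        obj = float(u @ C @ v)
        if np.isfinite(obj_prev) and abs(obj - obj_prev) <= tol * max(abs(obj_prev), 1e-12):
            converged = True
            break
        obj_prev = obj
    else:
        logger.warning("SCCA did not converge in %d iterations", max_iter)
    obj = float(u @ C @ v)
    j = int(np.argmax(np.abs(u))) if np.any(u) else 0
    if u[j] < 0:
        u, v = -u, -v
    return SCCAResult(u, v, obj, float(c1), float(c2), it, converged)


# ---------------------------------------------------------------------------
# cross-validated generalisation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVResult:
    split_r: list[float]
    mean_test_r: float
    n_splits: int
    train_frac: float


def _centre(train: np.ndarray, test: np.ndarray, scale: bool):
    mu = train.mean(axis=0)
    tr, te = train - mu, test - mu
    if scale:
        sd = tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        tr, te = tr / sd, te / sd
    return tr, te


def cv_scca(
    inp: SCCAInput,
    c1: float | None = None,
    c2: float | None = None,
    n_splits: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    scale: bool = False,
) -> CVResult:
    """Out-of-sample canonical correlation over repeated 70/30 splits.

    Each split centres X and Y on the training rows only, fits the sparse
    weights on the training rows, and correlates the held-out projections
    ``X_test u`` and ``Y_test v``.  Degenerate splits (zero test variance)
    are skipped and logged.
    """
    n = inp.n
    n_test = n - int(round(train_frac * n))
    if n_test < 5:
        raise ValueError("test split would have fewer than 5 rows")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    rs: list[float] = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr_rows, te_rows = perm[: n - n_test], perm[n - n_test:]
        Xtr, Xte = _centre(inp.X[tr_rows], inp.X[te_rows], scale)
        Ytr, Yte = _centre(inp.Y[tr_rows], inp.Y[te_rows], scale)
        res = fit_scca(SCCAInput(Xtr, Ytr), c1, c2)
        a, b = Xte @ res.u, Yte @ res.v
        if a.std() == 0 or b.std() == 0:
            logger.warning("degenerate test split skipped")
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    return CVResult(rs, float(np.mean(rs)) if rs else np.nan, n_splits, train_frac)


@dataclasses.dataclass
class PermutationResult:
    p_value: float
    observed_mean_r: float
    null_mean_r: np.ndarray
    n_perm: int


def permutation_test_scca(
    inp: SCCAInput,
    c1: float | None = None,
    c2: float | None = None,
    n_perm: int = 1000,
    n_splits: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    scale: bool = False,
) -> PermutationResult:
    """Permutation inference wrapping the whole cross-validation procedure.

    Each permutation shuffles the rows of X (breaking the X-Y pairing),
    reruns ``cv_scca`` — including fresh splits — and records the mean test
    correlation; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2
        )
    observed = cv_scca(inp, c1, c2, n_splits, train_frac, seed, scale).mean_test_r
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(inp.n)
        shuffled = SCCAInput(inp.X[perm], inp.Y, inp.x_names, inp.voxel_indices)
        null[i] = cv_scca(
            shuffled, c1, c2, n_splits, train_frac,
            seed=int(rng.integers(0, 2**31 - 1)), scale=scale,
        ).mean_test_r
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return PermutationResult(p, observed, null, n_perm)
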