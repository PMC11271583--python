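"""Voxel-wise Bayesian linear regression normative models.

For each voxel the (training-standardised) response vector :math:`y` is
modelled as :math:`y = Xw + \\varepsilon` with an isotropic Gaussian prior
:math:`w \\sim N(0, \\alpha^{-1} I)` and noise
:math:`\\varepsilon \\sim N(0, \\beta^{-1} I)`.  The hyperparameters
:math:`(\\alpha, \\beta)` are set per voxel by maximising the log marginal
likelihood (evidence), giving the posterior

.. math::

    S = (\\alpha I + \\beta X^T X)^{-1}, \\qquad m = \\beta S X^T y,

a predictive mean :math:`x_*^T m` and predictive variance
:math:`\\beta^{-1} + x_*^T S x_*`.  A subject's deviation Z-score is the
observed minus predicted activation scaled by the predictive SD, so on
well-specified held-out data it is standard normal per voxel.

Because the design matrix is shared by all voxels, the fit is vectorised
through a single eigendecomposition of :math:`X^T X`: with
:math:`X^T X = Q \\Lambda Q^T` all per-voxel posterior quantities are
diagonal in the eigenbasis.

Evidence maximisation uses EM-style updates
(:math:`\\alpha \\leftarrow p/(m^T m + \\mathrm{tr}\\,S)`,
:math:`\\beta \\leftarrow n/(\\|y - Xm\\|^2 + \\mathrm{tr}(X^T X S))`),
which never decrease the evidence.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ActivationDataset, VolumeImage, load_mask, load_volume, extract_masked, write_map

# covariate schema: every column the reference model conditions on
CONTINUOUS_COVARIATES = ("age", "icv", "tr", "n_volumes", "task_length", "n_blocks")
BINARY_COVARIATES = ("sex", "multiband")
CATEGORICAL_COVARIATES = ("instruction", "stimulus", "site")


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def stratified_half_split(
    cov: pd.DataFrame, seed: int
) -> tuple[list[str], list[str]]:
    """Random half split of subjects, stratified by site.

    Within each site a random permutation is split as evenly as possible;
    for odd counts the training half receives the extra subject.  The two
    id lists partition the cohort.  Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    train: list[str] = []
    test: list[str] = []
    for site in sorted(cov["site"].unique()):
        ids = cov.loc[cov["site"] == site, "subject_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"site {site!r} has fewer than 2 subjects")
        perm = rng.permutation(len(ids))
        n_train = (len(ids) + 1) // 2
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return train, test


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DesignMatrix:
    """Numeric, standardised design with its training statistics.

    Continuous columns are standardised on *training* statistics (mean/sd
    with denominator n); binary flags are 0/1; each categorical covariate is
    dummy coded with the full indicator set (no reference level — the sites
    are treated symmetrically and the ridge prior handles the resulting
    collinearity with the intercept).
    """

    matrix: np.ndarray  # (n, p)
    column_names: list[str]
    standardisation: dict[str, tuple[float, float]]  # continuous col -> (mean, sd)
    categories: dict[str, list[str]]  # categorical col -> training levels
    site_dummy_columns: list[str]
    subject_ids: list[str]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def training_stats(self) -> dict:
        return {
            "standardisation": dict(self.standardisation),
            "categories": {k: list(v) for k, v in self.categories.items()},
        }


def build_design(
    df: pd.DataFrame,
    continuous: Sequence[str],
    binary: Sequence[str] = (),
    categorical: Sequence[str] = (),
    training: "DesignMatrix | Mapping | None" = None,
    subject_ids: Sequence[str] | None = None,
    site_column: str = "site",
) -> DesignMatrix:
    """Encode an arbitrary covariate frame (intercept + standardised columns).

    ``training`` may be a fitted :class:`DesignMatrix` (or its
    ``training_stats()`` dict) whose statistics and category levels are
    reused, as required when encoding a test cohort.
    """
    needed = [*continuous, *binary, *categorical]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    for col in needed:
        vals = df[col]
        if vals.isna().any():
            raise ValueError(f"covariate {col!r} has missing values")

    if training is None:
        standardisation = {}
        for col in continuous:
            x = df[col].to_numpy(float)
            mu, sd = float(x.mean()), float(x.std())
            standardisation[col] = (mu, sd if sd > 0 else 1.0)
        categories = {
            col: sorted(str(v) for v in df[col].unique()) for col in categorical
        }
    else:
        src = training.training_stats() if isinstance(training, DesignMatrix) else training
        standardisation = {k: tuple(v) for k, v in src["standardisation"].items()}
        categories = {k: list(v) for k, v in src["categories"].items()}

    names = ["intercept"]
    cols = [np.ones(len(df))]
    for col in continuous:
        mu, sd = standardisation[col]
        x = df[col].to_numpy(float)
        if not np.isfinite(x).all():
            raise ValueError(f"covariate {col!r} has non-finite values")
        cols.append((x - mu) / sd)
        names.append(col)
    for col in binary:
        x = df[col].to_numpy(float)
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError(f"binary covariate {col!r} must be 0/1")
        cols.append(x)
        names.append(col)
    site_dummies: list[str] = []
    for col in categorical:
        levels = categories[col]
        seen = {str(v) for v in df[col].unique()}
        unseen = seen - set(levels)
        if unseen:
            raise ValueError(f"unseen {col} level(s) at encoding time: {sorted(unseen)}")
        for level in levels:
            name = f"{col}_{level}"
            cols.append((df[col].astype(str) == level).to_numpy(float))
            names.append(name)
            if col == site_column:
                site_dummies.append(name)
    if subject_ids is None:
        subject_ids = (
            list(df["subject_id"]) if "subject_id" in df.columns
            else [str(i) for i in range(len(df))]
        )
    return DesignMatrix(
        np.column_stack(cols), names, standardisation, categories,
        site_dummies, list(subject_ids),
    )


def encode_design(
    cov: pd.DataFrame, training: DesignMatrix | Mapping | None = None
) -> DesignMatrix:
    """Encode the reference-model covariate schema (age, sex, ICV, site, and
    the acquisition/task parameters) into a numeric design."""
    return build_design(
        cov,
        continuous=CONTINUOUS_COVARIATES,
        binary=BINARY_COVARIATES,
        categorical=CATEGORICAL_COVARIATES,
        training=training,
    )


def raw_covariate_columns(cov: pd.DataFrame) -> pd.DataFrame:
    """Raw (unstandardised) numeric covariate columns for structure
    coefficients: continuous values, 0/1 flags, and full dummy sets."""
    out = {}
    for col in CONTINUOUS_COVARIATES + BINARY_COVARIATES:
        out[col] = cov[col].to_numpy(float)
    for col in CATEGORICAL_COVARIATES:
        for level in sorted(str(v) for v in cov[col].unique()):
            out[f"{col}_{level}"] = (cov[col].astype(str) == level).to_numpy(float)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NormativeModelFit:
    """Per-voxel BLR posterior in the eigenbasis of ``X^T X``.

    ``coef`` holds the posterior weight means (standardised response scale);
    the posterior covariance of voxel ``v`` is
    ``Q diag(1/(alpha_v + beta_v * eigvals)) Q^T``.
    """

    column_names: list[str]
    training_stats: dict
    eigvals: np.ndarray  # (p,)
    eigvecs: np.ndarray  # (p, p), Q
    alpha: np.ndarray  # (V,) prior precisions
    beta: np.ndarray  # (V,) noise precisions
    coef: np.ndarray  # (p, V) posterior weight means, standardised space
    y_mean: np.ndarray  # (V,)
    y_sd: np.ndarray  # (V,)
    n_train: int
    converged: np.ndarray  # (V,) bool
    n_iter: int
    evidence: np.ndarray  # (V,) final log evidence
    evidence_path: list[np.ndarray] | None = None

    @property
    def not_converged(self) -> np.ndarray:
        """Indices of voxels whose evidence optimisation hit the iteration cap."""
        return np.nonzero(~self.converged)[0]

    def coefficients_raw(self) -> pd.DataFrame:
        """Posterior weight means de-standardised to raw covariate/response units."""
        stats_ = self.training_stats["standardisation"]
        w = self.coef * self.y_sd  # response de-standardisation
        rows = {}
        intercept = self.y_mean + w[self.column_names.index("intercept")].copy()
        for j, name in enumerate(self.column_names):
            if name == "intercept":
                continue
            if name in stats_:
                mu, sd = stats_[name]
                rows[name] = w[j] / sd
                intercept = intercept - w[j] * mu / sd
            else:
                rows[name] = w[j]
        rows["intercept"] = intercept
        return pd.DataFrame(rows)


def log_evidence(
    X: np.ndarray, y: np.ndarray, alpha: float, beta: float
) -> float:
    """Exact Gaussian-BLR log marginal likelihood for one voxel (standardised y)."""
    n, p = X.shape
    lam, Q = np.linalg.eigh(X.T @ X)
    b = Q.T @ (X.T @ y)
    denom = alpha + beta * lam
    mt = beta * b / denom
    mm = float(mt @ mt)
    rss = float(y @ y - 2 * mt @ b + (lam * mt) @ mt)
    return float(
        0.5
        * (
            p * np.log(alpha)
            + n * np.log(beta)
            - beta * rss
            - alpha * mm
            - np.log(denom).sum()
            - n * np.log(2 * np.pi)
        )
    )


def fit_blr(
    design: DesignMatrix,
    data: ActivationDataset,
    rtol: float = 1e-6,
    max_iter: int = 200,
    fixed_alpha: float | None = None,
    fixed_beta: float | None = None,
    keep_path: bool = False,
) -> NormativeModelFit:
    """Fit independent evidence-maximised BLR models at every voxel.

    Responses are standardised per voxel on the training sample; hyper-
    parameters start at ``alpha = beta = 1`` and follow EM updates until the
    relative evidence change drops below ``rtol`` (or ``max_iter``; any voxel
    still moving is flagged and keeps its last iterate).  ``fixed_alpha`` /
    ``fixed_beta`` pin a hyperparameter (e.g. a tiny ``fixed_alpha``
    approximates the flat-prior / least-squares limit).
    """
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n_subjects > p_design, got n={n}, p={p}")
    Y = data.data
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0)
    zero_var = y_sd == 0
    if zero_var.any():
        raise ValueError(
            f"{int(zero_var.sum())} voxels have zero training variance"
        )
    Ys = (Y - y_mean) / y_sd

    lam, Q = np.linalg.eigh(X.T @ X)
    lam = np.clip(lam, 0.0, None)  # guard tiny negative round-off
    B = Q.T @ (X.T @ Ys)  # (p, V)
    yty = np.einsum("nv,nv->v", Ys, Ys)

    V = Y.shape[1]
    alpha = np.full(V, 1.0 if fixed_alpha is None else fixed_alpha)
    beta = np.full(V, 1.0 if fixed_beta is None else fixed_beta)
    ev_prev = np.full(V, -np.inf)
    converged = np.zeros(V, dtype=bool)
    path: list[np.ndarray] = []

    def posterior(alpha, beta):
        denom = alpha[None, :] + beta[None, :] * lam[:, None]  # (p, V)
        mt = beta[None, :] * B / denom
        mm = np.einsum("pv,pv->v", mt, mt)
        rss = yty - 2 * np.einsum("pv,pv->v", mt, B) + np.einsum(
            "p,pv,pv->v", lam, mt, mt
        )
        rss = np.clip(rss, 1e-12, None)
        return denom, mt, mm, rss

    it = 0
    for it in range(1, max_iter + 1):
        denom, mt, mm, rss = posterior(alpha, beta)
        ev = 0.5 * (
            p * np.log(alpha)
            + n * np.log(beta)
            - beta * rss
            - alpha * mm
            - np.log(denom).sum(axis=0)
            - n * np.log(2 * np.pi)
        )
        if keep_path:
            path.append(ev.copy())
        newly = np.isfinite(ev_prev) & (
            np.abs(ev - ev_prev) <= rtol * np.abs(ev_prev)
        )
        converged |= newly
        ev_prev = ev
        if converged.all():
            break
        tr_S = (1.0 / denom).sum(axis=0)
        tr_XXS = (lam[:, None] / denom).sum(axis=0)
        upd = ~converged
        if fixed_alpha is None:
            alpha[upd] = p / np.clip(mm[upd] + tr_S[upd], 1e-12, None)
        if fixed_beta is None:
            beta[upd] = n / np.clip(rss[upd] + tr_XXS[upd], 1e-12, None)

    denom, mt, mm, rss = posterior(alpha, beta)
    coef = Q @ mt
    return NormativeModelFit(
        column_names=list(design.column_names),
        training_stats=design.training_stats(),
        eigvals=lam,
        eigvecs=Q,
        alpha=alpha,
        beta=beta,
        coef=coef,
        y_mean=y_mean,
        y_sd=y_sd,
        n_train=n,
        converged=converged,
        n_iter=it,
        evidence=ev_prev,
        evidence_path=path if keep_path else None,
    )


def _check_design(fit: NormativeModelFit, design: DesignMatrix) -> None:
    if list(design.column_names) != list(fit.column_names):
        raise ValueError(
            "design columns do not match the fit "
            f"({design.column_names} vs {fit.column_names})"
        )


def predict_blr(
    fit: NormativeModelFit, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance, (n, V) each, in response (z-stat) units.

    The variance is the full predictive variance: noise ``1/beta`` plus the
    parameter-uncertainty quadratic form ``x* S x*``, de-standardised by the
    squared training response SD.
    """
    _check_design(fit, design)
    T = design.matrix @ fit.eigvecs  # (n, p)
    denom = fit.alpha[None, :] + fit.beta[None, :] * fit.eigvals[:, None]  # (p, V)
    mt = fit.eigvecs.T @ fit.coef  # coef back in eigenbasis
    mean_s = T @ mt
    var_s = (T**2) @ (1.0 / denom) + 1.0 / fit.beta[None, :]
    mean = mean_s * fit.y_sd + fit.y_mean
    var = var_s * fit.y_sd**2
    return mean, var


@dataclasses.dataclass
class DeviationMap:
    """Subjects x voxels deviation Z-scores against a reference model."""

    Z: np.ndarray  # (n, V)
    subject_ids: list[str]
    contrast: str = "faces>shapes"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.isfinite(self.Z).all():
            raise ValueError("deviation Z-scores must be finite")


def compute_deviations(
    fit: NormativeModelFit, design: DesignMatrix, data: ActivationDataset
) -> DeviationMap:
    """Deviation Z = (observed - predicted) / predictive SD, per subject/voxel."""
    mean, var = predict_blr(fit, design)
    if np.any(var <= 0):
        raise ValueError("non-positive predictive variance")
    Z = (data.data - mean) / np.sqrt(var)
    return DeviationMap(Z, list(data.subject_ids), data.contrast)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationReport:
    """Held-out fit metrics per voxel.

    ``explained_variance = 1 - Var(y - yhat)/Var(y)`` (may be negative),
    ``smse = MSE/Var(y)``, skew is adjusted Fisher-Pearson sample skewness of
    the deviation Z-scores and kurtosis is excess (0 for a Gaussian).
    Voxels with zero test variance are NaN and listed in ``undefined``.
    """

    explained_variance: np.ndarray
    smse: np.ndarray
    skew: np.ndarray
    kurtosis: np.ndarray
    undefined: np.ndarray  # voxel indices where metrics are not defined

    def summary(self) -> dict:
        ok = np.ones(len(self.explained_variance), dtype=bool)
        ok[self.undefined] = False
        return {
            "max_explained_variance": float(np.max(self.explained_variance[ok])),
            "median_explained_variance": float(np.median(self.explained_variance[ok])),
            "frac_abs_skew_below_1": float(np.mean(np.abs(self.skew[ok]) < 1)),
            "median_kurtosis": float(np.median(self.kurtosis[ok])),
            "n_undefined": int(self.undefined.size),
        }


def evaluate_model(
    fit: NormativeModelFit, design_test: DesignMatrix, data_test: ActivationDataset
) -> EvaluationReport:
    """Evaluate a fitted model on a held-out cohort."""
    mean, var = predict_blr(fit, design_test)
    y = data_test.data
    resid = y - mean
    var_y = y.var(axis=0)
    undefined = np.nonzero(var_y == 0)[0]
    safe = np.where(var_y == 0, np.nan, var_y)
    ev = 1.0 - resid.var(axis=0) / safe
    smse = (resid**2).mean(axis=0) / safe
    Z = resid / np.sqrt(var)
    skew = stats.skew(Z, axis=0, bias=False)
    kurt = stats.kurtosis(Z, axis=0, fisher=True, bias=False)
    if undefined.size:
        skew = skew.copy()
        kurt = kurt.copy()
        skew[undefined] = np.nan
        kurt[undefined] = np.nan
    return EvaluationReport(ev, smse, skew, kurt, undefined)


# ---------------------------------------------------------------------------
# structure coefficients
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StructureCoefficientMap:
    """Per-covariate maps of correlations with the model's predictions.

    ``rho[j, v]`` is the Pearson correlation between raw covariate ``j`` and
    the predicted activation at voxel ``v``; ``rho_squared`` is its square.
    Structure coefficients attribute model predictions to individual input
    variables even when the inputs are collinear, where regression weights
    are unstable.
    """

    columns: list[str]
    rho: np.ndarray  # (k, V)
    rho_squared: np.ndarray
    undefined_columns: list[str]

    def display_mask(self, threshold: float = 0.3) -> np.ndarray:
        """Boolean (k, V) mask of coefficients with rho^2 above ``threshold``."""
        return self.rho_squared > threshold


def structure_coefficients(
    raw_columns: pd.DataFrame, predictions: np.ndarray
) -> StructureCoefficientMap:
    """Correlate each raw input variable with the predicted activation.

    ``predictions`` should come from :func:`predict_blr` on the evaluation
    cohort.  Zero-variance columns (and zero-variance voxels) yield NaN and
    are flagged rather than silently zeroed.
    """
    pred = np.asarray(predictions, dtype=float)
    names = list(raw_columns.columns)
    Xr = raw_columns.to_numpy(dtype=float)
    n = Xr.shape[0]
    if pred.shape[0] != n:
        raise ValueError("predictions and covariates disagree on n_subjects")
    xc = Xr - Xr.mean(axis=0)
    pc = pred - pred.mean(axis=0)
    xs = xc.std(axis=0)
    ps = pc.std(axis=0)
    undefined = [names[j] for j in np.nonzero(xs == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc.T @ pc) / n / np.outer(
            np.where(xs == 0, np.nan, xs), np.where(ps == 0, np.nan, ps)
        )
    return StructureCoefficientMap(names, rho, rho**2, undefined)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_fit(fit: NormativeModelFit, out_dir: str | Path, mask: VolumeImage) -> None:
    """Serialise a fit as JSON scalars plus per-voxel NIfTI parameter maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "column_names": fit.column_names,
        "training_stats": fit.training_stats,
        "eigvals": fit.eigvals.tolist(),
        "eigvecs": fit.eigvecs.tolist(),
        "n_train": fit.n_train,
        "n_iter": fit.n_iter,
    }
    (out / "fit.json").write_text(json.dumps(meta, indent=1))
    for name, arr in (
        ("alpha", fit.alpha), ("beta", fit.beta),
        ("y_mean", fit.y_mean), ("y_sd", fit.y_sd),
        ("evidence", fit.evidence),
        ("converged", fit.converged.astype(float)),
    ):
        write_map(arr, mask, out / f"{name}.nii.gz")
    from .io import write_stack

    write_stack(fit.coef, mask, out / "coef.nii.gz")


def load_fit(in_dir: str | Path, mask: VolumeImage) -> NormativeModelFit:
    inp = Path(in_dir)
    meta = json.loads((inp / "fit.json").read_text())

    def vol(name):
        return extract_masked(load_volume(inp / f"{name}.nii.gz").data, mask.data)

    import nibabel as nib

    coef4d = np.asarray(nib.load(str(inp / "coef.nii.gz")).dataobj, dtype=float)
    from .io import mask_index

    idx = mask_index(mask.data)
    coef = coef4d.reshape(-1, coef4d.shape[3], order="F")[idx].T
    return NormativeModelFit(
        column_names=meta["column_names"],
        training_stats=meta["training_stats"],
        eigvals=np.array(meta["eigvals"]),
        eigvecs=np.array(meta["eigvecs"]),
        alpha=vol("alpha"),
        beta=vol("beta"),
        coef=coef,
        y_mean=vol("y_mean"),
        y_sd=vol("y_sd"),
        n_train=int(meta["n_train"]),
        converged=vol("converged") > 0.5,
        n_iter=int(meta["n_iter"]),
        evidence=vol("evidence"),
    )
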