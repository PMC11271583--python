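"""Synthetic multi-site cohorts for exercising the normative-modelling pipeline.

The generator emulates the statistical structure the analysis assumes without
claiming a biological generative model: a 6-site reference cohort whose
acquisition and task-design parameters are constant within site (hence
perfectly collinear with the site indicator), site-specific age ranges and
sex balance, spatially smooth voxel-wise covariate effects with
heteroskedastic Gaussian noise, a clinical cohort whose deviations load
sparsely on latent symptom-domain factors, and retest sessions with added
session noise plus a localised signal-dropout region of inflated
instability.

Every generator is bit-reproducible given its spec and a seed.  Per-stage
random streams are derived from the master seed with fixed offsets.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import ActivationDataset, VolumeImage, mask_index

# fixed offsets for per-stage seed streams derived from one master seed
_STREAM_COVARIATES = 1
_STREAM_TRUTH = 2
_STREAM_ACTIVATION = 3
_STREAM_CLINICAL = 4
_STREAM_RETEST = 5
_STREAM_CLINICAL_FACTORS = 6

FACTOR_NAMES = (
    "negative_valence",
    "cognitive_function",
    "social_processes",
    "arousal_inhibition",
)

DIAGNOSIS_NAMES = ("mood_disorder", "adhd", "asd", "anxiety_disorder")
# marginal prevalences in the clinical cohort (multi-label; loosely matching
# a naturalistic out-patient sample dominated by mood disorder)
_DIAGNOSIS_PREVALENCE = (0.64, 0.30, 0.23, 0.26)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclasses.dataclass
class SiteSpec:
    """One acquisition site: demographics plus site-constant scan/task setup."""

    site_id: str
    n_subjects: int
    age_range: tuple[float, float]  # years
    female_fraction: float
    tr: float  # seconds
    multiband: bool
    n_volumes: int
    task_length: float  # seconds
    n_blocks: int
    instruction: str  # {"match_faces", "match_expression"}
    stimulus: str  # {"NimStim", "Ekman", "other"}

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"{self.site_id}: n_subjects must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError(f"{self.site_id}: female_fraction outside [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError(f"{self.site_id}: age_range min must be < max")


# Six-site reference cohort: relative sample sizes, age ranges, sex balance
# and scan/task setup patterned on the large EFMT consortia (HCP Young Adult,
# HCP Development, UK Biobank, AOMIC PIOP2, DNS, and a small clinical-site
# reference arm), with sample sizes scaled down by 1/20 to desk scale.
_DEFAULT_SITE_TABLE = (
    ("hcp_ya", 1044, (22.0, 37.0), 0.537, 0.72, True, 176, 150.0, 3, "match_faces", "NimStim"),
    ("hcp_dev", 201, (8.0, 21.0), 0.547, 0.80, True, 178, 150.0, 3, "match_faces", "NimStim"),
    ("ukb", 5000, (46.0, 82.0), 0.499, 0.735, True, 332, 240.0, 5, "match_faces", "NimStim"),
    ("aomic_piop2", 200, (18.0, 26.0), 0.570, 2.00, False, 135, 290.0, 4, "match_expression", "other"),
    ("dns", 1246, (18.0, 23.0), 0.567, 2.00, False, 195, 280.0, 4, "match_faces", "Ekman"),
    ("clinical_ref", 37, (20.0, 74.0), 0.567, 1.00, True, 150, 150.0, 2, "match_expression", "NimStim"),
)


def default_sites(n_scale: float = 1.0) -> list[SiteSpec]:
    """The default 6-site reference cohort (full-size counts / 20 * n_scale).

    ``n_scale=1`` yields 386 subjects in total; each site keeps at least two
    subjects so a stratified half split stays estimable.
    """
    sites = []
    for sid, n_full, ages, ff, tr, mb, nvol, tlen, nblk, instr, stim in _DEFAULT_SITE_TABLE:
        n = max(2, round(n_full / 20 * n_scale))
        sites.append(SiteSpec(sid, n, ages, ff, tr, mb, nvol, tlen, nblk, instr, stim))
    return sites


def default_mask(
    shape: tuple[int, int, int] = (20, 20, 24), voxel_size: float = 2.0
) -> VolumeImage:
    """Ellipsoidal brain-like mask (~5,000 voxels at the default grid)."""
    half = (np.array(shape) - 1) / 2.0
    coords = np.indices(shape)
    r2 = sum(((coords[a] - half[a]) / (half[a] + 0.5)) ** 2 for a in range(3))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return VolumeImage(r2 <= 1.0, affine, space_tag="synthetic")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def sample_covariates(sites: Sequence[SiteSpec], seed: int) -> pd.DataFrame:
    """Draw a per-subject covariate table from the site specifications.

    Ages are uniform within each site's range, sex is Bernoulli at the site's
    female fraction (1 = female), intracranial volume is log-normal
    (log-mean 14.2, log-sd 0.07, i.e. ~1.5e6 mm^3), and all acquisition/task
    columns are copied verbatim from the site spec (site-constant).
    """
    if len(sites) < 2:
        raise ValueError("at least 2 sites are required")
    rng = _rng(seed, _STREAM_COVARIATES)
    return pd.concat(
        [_site_frame(site, rng) for site in sites], ignore_index=True
    )


def _site_frame(site: SiteSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = site.n_subjects
    return pd.DataFrame(
        {
            "subject_id": [f"{site.site_id}-{i:05d}" for i in range(n)],
            "site": site.site_id,
            "age": rng.uniform(*site.age_range, size=n),
            "sex": (rng.random(n) < site.female_fraction).astype(int),
            "icv": np.exp(rng.normal(14.2, 0.07, size=n)),
            "tr": site.tr,
            "multiband": int(site.multiband),
            "n_volumes": site.n_volumes,
            "task_length": site.task_length,
            "n_blocks": site.n_blocks,
            "instruction": site.instruction,
            "stimulus": site.stimulus,
        }
    )


def sample_clinical_covariates(n_patients: int, seed: int) -> pd.DataFrame:
    """Covariates of a single-site clinical cohort scanned at the reference
    cohort's clinical site (so its site level is known to the fitted model)."""
    ref = next(s for s in default_sites() if s.site_id == "clinical_ref")
    site = dataclasses.replace(
        ref, n_subjects=n_patients, age_range=(20.0, 70.0), female_fraction=0.42
    )
    rng = _rng(seed, _STREAM_COVARIATES + 100)
    frame = _site_frame(site, rng)
    frame["subject_id"] = [f"patient-{i:05d}" for i in range(n_patients)]
    return frame


def generator_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """The raw design the truth model is keyed to.

    Columns: intercept, centred age ((age-45)/20), sex, centred log-ICV
    ((log icv - 14.2)/0.07), and one indicator per site.  Acquisition/task
    parameters are site-constant, so their generative effects are carried by
    the site indicators.
    """
    cols = {
        "intercept": np.ones(len(cov)),
        "age": (cov["age"].to_numpy(float) - 45.0) / 20.0,
        "sex": cov["sex"].to_numpy(float),
        "icv": (np.log(cov["icv"].to_numpy(float)) - 14.2) / 0.07,
    }
    for sid in sorted(cov["site"].unique()):
        cols[f"site_{sid}"] = (cov["site"] == sid).to_numpy(float)
    return np.column_stack(list(cols.values())), list(cols)


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TruthModel:
    """Ground-truth voxel-wise linear effects used only to generate data.

    ``weights[j, v]`` is the effect (z-stat units per unit of design column
    ``columns[j]``) at voxel ``v``; ``noise_sd[v]`` the subject-level noise
    SD.  Weight maps are spatially smooth at correlation length
    ``smoothness`` voxels.
    """

    columns: list[str]
    weights: np.ndarray  # (p, V)
    noise_sd: np.ndarray  # (V,)
    mask: VolumeImage
    smoothness: float = 3.0

    def __post_init__(self) -> None:
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive everywhere")
        if self.weights.shape[0] != len(self.columns):
            raise ValueError("weights rows must match columns")


def smooth_masked_field(
    mask: VolumeImage, rng: np.random.Generator, smoothness: float
) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field restricted to the mask."""
    field = gaussian_filter(rng.standard_normal(mask.shape), sigma=smoothness)
    vals = field.reshape(-1, order="F")[mask_index(mask.data)]
    sd = vals.std()
    return vals / (sd if sd > 0 else 1.0)


# effect-size scale (z-stat units) per generator design column class
_WEIGHT_SCALES = {"intercept": 1.0, "age": 0.4, "sex": 0.15, "icv": 0.1, "site": 0.3}


def make_truth_model(
    sites: Sequence[SiteSpec],
    mask: VolumeImage,
    seed: int,
    smoothness: float = 3.0,
    noise_log_sd: float = 0.25,
) -> TruthModel:
    """Draw smooth per-covariate weight maps and a heteroskedastic noise field.

    Weight maps are Gaussian-filtered white noise (correlation length
    ``smoothness`` voxels) scaled per covariate class; the noise SD is the
    exponential of a smooth field (median 1 z-unit, log-sd ``noise_log_sd``).
    """
    rng = _rng(seed, _STREAM_TRUTH)
    columns = ["intercept", "age", "sex", "icv"] + [
        f"site_{s.site_id}" for s in sorted(sites, key=lambda s: s.site_id)
    ]
    weights = np.empty((len(columns), int(mask.data.sum())))
    for j, name in enumerate(columns):
        scale = _WEIGHT_SCALES["site" if name.startswith("site_") else name]
        weights[j] = scale * smooth_masked_field(mask, rng, smoothness)
    noise_sd = np.exp(noise_log_sd * smooth_masked_field(mask, rng, smoothness))
    return TruthModel(columns, weights, noise_sd, mask, smoothness)


def truth_signal(cov: pd.DataFrame, truth: TruthModel) -> np.ndarray:
    """Deterministic design x weights part of the generative model, (n, V).

    The design is evaluated against the truth model's own column keys, so a
    cohort covering a subset of the truth's sites is fine; a site unknown to
    the truth model is a key mismatch.
    """
    known_sites = {c[len("site_"):] for c in truth.columns if c.startswith("site_")}
    unknown = set(cov["site"].unique()) - known_sites
    if unknown:
        raise ValueError(f"design/truth key mismatch: unknown sites {sorted(unknown)}")
    base, base_cols = generator_design(cov)
    lookup = dict(zip(base_cols, base.T))
    n = len(cov)
    matrix = np.column_stack(
        [lookup.get(name, np.zeros(n)) for name in truth.columns]
    )
    missing = [c for c in base_cols if c not in truth.columns]
    if missing:
        raise ValueError(f"design/truth key mismatch: truth lacks {missing}")
    return matrix @ truth.weights


def generate_activation(
    cov: pd.DataFrame, truth: TruthModel, seed: int, contrast: str = "faces>shapes"
) -> ActivationDataset:
    """Reference-cohort activation: signal + heteroskedastic Gaussian noise."""
    signal = truth_signal(cov, truth)
    rng = _rng(seed, _STREAM_ACTIVATION)
    noise = rng.standard_normal(signal.shape) * truth.noise_sd
    return ActivationDataset(
        signal + noise, truth.mask, list(cov["subject_id"]), contrast
    )


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClinicalEffectSpec:
    """Sparse latent symptom-factor effects added on top of the reference model.

    Each of the ``n_factors`` latent domains loads on at most 10% of voxels
    (``loading_maps``, unit L2 norm each); patient factor scores are drawn
    from N(0, ``factor_cov``) and shift activation by
    ``effect_scale * sum_k factor_k * loading_map_k``.
    """

    n_patients: int
    loading_maps: np.ndarray  # (n_factors, V)
    effect_scale: float = 1.0
    factor_cov: np.ndarray | None = None  # (n_factors, n_factors)
    diagnoses: pd.DataFrame | None = None  # per-patient multi-label indicators

    def __post_init__(self) -> None:
        self.loading_maps = np.atleast_2d(np.asarray(self.loading_maps, float))
        k, V = self.loading_maps.shape
        nnz = (self.loading_maps != 0).sum(axis=1)
        if np.any(nnz > 0.10 * V):
            raise ValueError("each loading map may use at most 10% of voxels")
        if self.factor_cov is None:
            self.factor_cov = np.eye(k)
        self.factor_cov = np.asarray(self.factor_cov, float)
        if not np.allclose(np.diag(self.factor_cov), 1.0):
            raise ValueError("factor_cov must have unit diagonal")
        try:
            np.linalg.cholesky(self.factor_cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("factor_cov must be positive definite") from err

    @property
    def n_factors(self) -> int:
        return self.loading_maps.shape[0]


def default_factor_cov(k: int = 4, rho: float = 0.3) -> np.ndarray:
    """Exchangeable correlation between symptom domains (they co-occur)."""
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def sample_diagnoses(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Multi-label diagnosis indicators; every patient gets >= 1 label."""
    mat = np.column_stack(
        [rng.random(n) < p for p in _DIAGNOSIS_PREVALENCE]
    ).astype(int)
    none = mat.sum(axis=1) == 0
    mat[none, rng.integers(0, mat.shape[1], size=int(none.sum()))] = 1
    return pd.DataFrame(mat, columns=list(DIAGNOSIS_NAMES))


def make_clinical_spec(
    mask: VolumeImage,
    seed: int,
    n_patients: int = 217,
    n_factors: int = 4,
    effect_scale: float = 1.0,
    sparsity: float = 0.05,
    factor_cov: np.ndarray | None = None,
) -> ClinicalEffectSpec:
    """Build sparse, spatially compact loading blobs for each symptom domain."""
    rng = _rng(seed, _STREAM_CLINICAL)
    idx = mask_index(mask.data)
    coords = np.array(
        np.unravel_index(idx, mask.shape, order="F"), dtype=float
    ).T  # (V, 3)
    V = len(idx)
    m = max(1, int(round(sparsity * V)))
    loadings = np.zeros((n_factors, V))
    for k in range(n_factors):
        centre = coords[rng.integers(0, V)]
        d2 = ((coords - centre) ** 2).sum(axis=1)
        keep = np.argsort(d2)[:m]  # the m nearest in-mask voxels: one blob
        prof = np.exp(-d2[keep] / (2.0 * max(d2[keep].max(), 1.0) / 4.0))
        loadings[k, keep] = prof / np.linalg.norm(prof)
    if factor_cov is None:
        factor_cov = default_factor_cov(n_factors)
    return ClinicalEffectSpec(
        n_patients=n_patients,
        loading_maps=loadings,
        effect_scale=effect_scale,
        factor_cov=factor_cov,
        diagnoses=sample_diagnoses(n_patients, rng),
    )


def inject_clinical_effects(
    base: ActivationDataset, spec: ClinicalEffectSpec, seed: int
) -> tuple[ActivationDataset, pd.DataFrame]:
    """Add sparse factor-driven deviations to a clinical cohort's activation.

    Returns the shifted dataset and the patients' symptom-domain factor table
    (columns named after the four transdiagnostic domains when k = 4).
    Covariates are untouched: only activation values change.
    """
    if spec.n_patients != base.n_subjects:
        raise ValueError(
            f"spec.n_patients={spec.n_patients} but dataset has {base.n_subjects}"
        )
    rng = _rng(seed, _STREAM_CLINICAL_FACTORS)
    L = np.linalg.cholesky(spec.factor_cov)
    factors = rng.standard_normal((base.n_subjects, spec.n_factors)) @ L.T
    shifted = base.data + spec.effect_scale * factors @ spec.loading_maps
    names = (
        list(FACTOR_NAMES)
        if spec.n_factors == len(FACTOR_NAMES)
        else [f"factor_{k}" for k in range(spec.n_factors)]
    )
    table = pd.DataFrame(factors, columns=names)
    table.insert(0, "subject_id", base.subject_ids)
    return (
        ActivationDataset(shifted, base.mask, list(base.subject_ids), base.contrast),
        table,
    )


# ---------------------------------------------------------------------------
# retest sessions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RetestSpec:
    """Session-to-session perturbation for test-retest simulations."""

    session_noise_sd: float = 0.0  # z-units, added in quadrature everywhere
    dropout_region: np.ndarray | None = None  # voxel indices (canonical order)
    dropout_extra_sd: float = 0.0  # extra z-units inside the dropout region

    def __post_init__(self) -> None:
        if self.session_noise_sd < 0 or self.dropout_extra_sd < 0:
            raise ValueError("session noise SDs must be nonnegative")
        if self.dropout_region is not None:
            self.dropout_region = np.asarray(self.dropout_region, dtype=int)


def make_dropout_region(
    mask: VolumeImage, seed: int, fraction: float = 0.03
) -> np.ndarray:
    """A compact blob of in-mask voxel indices emulating vmPFC signal dropout."""
    rng = _rng(seed, _STREAM_RETEST)
    idx = mask_index(mask.data)
    coords = np.array(np.unravel_index(idx, mask.shape, order="F"), float).T
    centre = coords[rng.integers(0, len(idx))]
    d2 = ((coords - centre) ** 2).sum(axis=1)
    m = max(1, int(round(fraction * len(idx))))
    return np.sort(np.argsort(d2)[:m])


def generate_retest(
    cov: pd.DataFrame,
    truth: TruthModel,
    spec: RetestSpec,
    seed: int,
    contrast: str = "faces>shapes",
) -> ActivationDataset:
    """One scanning session of the same subjects: identical true signal,
    independent noise of SD sqrt(noise_sd^2 + session_noise_sd^2), with
    ``dropout_extra_sd`` added in quadrature inside the dropout region.

    With ``session_noise_sd = dropout_extra_sd = 0`` and the same seed this
    reproduces :func:`generate_activation` exactly.
    """
    signal = truth_signal(cov, truth)
    var = truth.noise_sd**2 + spec.session_noise_sd**2
    if spec.dropout_region is not None:
        if spec.dropout_region.size and (
            spec.dropout_region.min() < 0
            or spec.dropout_region.max() >= signal.shape[1]
        ):
            raise ValueError("dropout_region outside the mask voxel range")
        var = var.copy()
        var[spec.dropout_region] += spec.dropout_extra_sd**2
    rng = _rng(seed, _STREAM_ACTIVATION)
    noise = rng.standard_normal(signal.shape) * np.sqrt(var)
    return ActivationDataset(
        signal + noise, truth.mask, list(cov["subject_id"]), contrast
    )


def make_reference(
    seed: int,
    n_scale: float = 1.0,
    mask: VolumeImage | None = None,
    sites: Sequence[SiteSpec] | None = None,
) -> tuple[pd.DataFrame, TruthModel, ActivationDataset]:
    """Convenience: covariates, truth model and activation for the default cohort."""
    if sites is None:
        sites = default_sites(n_scale)
    if mask is None:
        mask = default_mask()
    cov = sample_covariates(sites, seed)
    truth = make_truth_model(sites, mask, seed)
    data = generate_activation(cov, truth, seed)
    return cov, truth, data
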