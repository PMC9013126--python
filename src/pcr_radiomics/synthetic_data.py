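"""Synthetic phantoms and simulated cohorts.

Phantoms emulate the staging-T2 setting in the narrow sense that matters for
the pipeline: a 3-D intensity grid with anisotropic spacing (fine in-plane
pixels, thick slices) containing an ellipsoidal tumour ROI whose intensity
histogram has controllable skewness (via a monotone sinh skewing map) over a
smoothed noise background.  They carry no MR physics (no coil bias, no
Rician noise) and no anatomy.

Cohorts are drawn from the validation-cohort covariate margins (cT, cN,
field-strength split); pCR labels are generated either from the model itself
(Bernoulli at the predicted probability) or to hit an exact positive count.
A fast tabular-only mode samples the two radiomic features directly from
plausible ranges so statistical experiments run without images; the imaging
path is exercised by smaller fixtures.

All randomness fans out from a single seed through per-patient
``SeedSequence`` spawn keys, so cohorts are reproducible under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomSpecError
from .imaging_io import CohortTable, ImageVolume, ROIMask
from .model import ModelSpec, PatientRecord, predict_pcr_probability
from .radiomics import FeatureConfig, compute_signature_features

# Validation-cohort covariate margins: cT 6/34/19, cN 25/24/10, 1.5T:3T 32:27
DEFAULT_CT_PROBS = (0.102, 0.576, 0.322)
DEFAULT_CN_PROBS = (0.424, 0.407, 0.169)
DEFAULT_FS_PROBS = (32 / 59, 27 / 59)

# Feature ranges for tabular simulation (synthetic convention): chosen so the
# model's predicted probabilities span roughly (0.01, 0.9) and a 16.9%
# prevalence is attainable.
SKEWNESS_RANGE = (-1.5, 1.5)
ENTROPY_RANGE = (1.0, 5.0)

LABEL_MODES = ("model-bernoulli", "fixed-prevalence")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and seed of one synthetic volume/ROI pair."""

    shape: tuple[int, int, int] = (48, 48, 12)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    roi_center_mm: tuple[float, float, float] = (12.0, 12.0, 18.0)
    roi_semiaxes_mm: tuple[float, float, float] = (7.0, 6.0, 10.0)
    noise_scale: float = 1.0
    skew_lambda: float = 0.0
    smoothing_mm: float = 1.0
    background_level: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        dx, dy, _ = self.spacing
        if min(self.roi_semiaxes_mm) <= 2.0 * max(dx, dy):
            raise PhantomSpecError("ROI semi-axes must exceed 2x the in-plane spacing")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for c, a, e in zip(self.roi_center_mm, self.roi_semiaxes_mm, extent):
            if c - a < 0 or c + a > e:
                raise PhantomSpecError(
                    f"ROI (centre {self.roi_center_mm} mm, semi-axes "
                    f"{self.roi_semiaxes_mm} mm) clips the {extent} mm grid"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a simulated validation cohort."""

    n: int = 59
    ct_probs: tuple[float, float, float] = DEFAULT_CT_PROBS
    cn_probs: tuple[float, float, float] = DEFAULT_CN_PROBS
    fs_probs: tuple[float, float] = DEFAULT_FS_PROBS
    skewness_range: tuple[float, float] = SKEWNESS_RANGE
    entropy_range: tuple[float, float] = ENTROPY_RANGE
    label_mode: str = "model-bernoulli"
    n_positive: int | None = None  # used in fixed-prevalence mode
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (("ct_probs", self.ct_probs), ("cn_probs", self.cn_probs),
                            ("fs_probs", self.fs_probs)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")
        if self.label_mode not in LABEL_MODES:
            raise ValueError(f"label_mode must be one of {LABEL_MODES}")
        if self.label_mode == "fixed-prevalence":
            if self.n_positive is None or not 0 < self.n_positive < self.n:
                raise ValueError("fixed-prevalence mode needs 0 < n_positive < n")

    def to_dict(self) -> dict:
        return asdict(self)


def _smooth_standard_field(rng, shape, spacing, smoothing_mm):
    """Gaussian-smoothed white noise, re-standardised to unit variance."""
    raw = rng.standard_normal(shape)
    sig = [smoothing_mm / s for s in spacing]
    f = ndimage.gaussian_filter(raw, sigma=sig, mode="wrap")
    sd = f.std()
    if sd == 0:  # smoothing length >> grid: fall back to raw noise
        return raw
    return (f - f.mean()) / sd


def ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = spec.roi_center_mm
    ax, ay, az = spec.roi_semiaxes_mm
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask]:
    """Deterministic phantom: smoothed background plus skew-controlled ROI.

    ROI voxels are a smoothed unit-variance field passed through the
    monotone map u -> sinh(lambda + u) - sinh(lambda); lambda = 0 yields a
    symmetric histogram, positive/negative lambda positive/negative skew.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    background = spec.background_level + spec.noise_scale * _smooth_standard_field(
        rng, spec.shape, spec.spacing, spec.smoothing_mm
    )
    roi_field = _smooth_standard_field(rng, spec.shape, spec.spacing, spec.smoothing_mm)
    lam = spec.skew_lambda
    roi_tex = np.sinh(lam + roi_field) - np.sinh(lam)
    mask = ellipsoid_mask(spec)
    voxels = background.copy()
    voxels[mask] = spec.background_level + 3.0 * spec.noise_scale + spec.noise_scale * roi_tex[mask]
    volume = ImageVolume(voxels=voxels, spacing=spec.spacing,
                         meta={"phantom_seed": spec.seed})
    return volume, ROIMask(voxels=mask, spacing=spec.spacing)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_covariates(rng, spec: CohortSpec):
    ct = int(rng.choice([2, 3, 4], p=spec.ct_probs))
    cn = int(rng.choice([0, 1, 2], p=spec.cn_probs))
    fs = float(rng.choice([1.5, 3.0], p=spec.fs_probs))
    return ct, cn, fs


def _assign_labels(rng, spec: CohortSpec, probs: np.ndarray) -> np.ndarray:
    if spec.label_mode == "model-bernoulli":
        return (rng.random(spec.n) < probs).astype(int)
    # fixed prevalence: exact count, positives drawn without replacement with
    # probability proportional to the model score (keeps discriminative signal)
    labels = np.zeros(spec.n, dtype=int)
    p = probs / probs.sum()
    idx = rng.choice(spec.n, size=spec.n_positive, replace=False, p=p)
    labels[idx] = 1
    return labels


def sample_cohort(
    spec: CohortSpec,
    model: ModelSpec,
    with_images: bool = False,
    phantom_shape: tuple[int, int, int] = (48, 48, 12),
    feature_config: FeatureConfig | None = None,
) -> tuple[CohortTable, list]:
    """Draw a cohort; returns (table, phantoms).

    In tabular-only mode (default) the radiomic features are sampled
    directly from the configured ranges and ``phantoms`` is empty.  With
    ``with_images=True`` each patient gets a phantom whose texture is drawn
    per-patient; features (hence scores and labels) come from actual
    extraction on the phantom, so the table is consistent with what the
    imaging pipeline will re-extract.
    """
    spec.validate()
    label_rng = _patient_rng(spec.seed, spec.n)  # reserved stream for labels
    rows = []
    phantoms = []
    cfg = feature_config or FeatureConfig()
    for i in range(spec.n):
        rng = _patient_rng(spec.seed, i)
        ct, cn, fs = _draw_covariates(rng, spec)
        if with_images:
            extent = tuple(n * s for n, s in zip(phantom_shape, PhantomSpec().spacing))
            pspec = PhantomSpec(
                shape=phantom_shape,
                roi_center_mm=tuple(e / 2.0 for e in extent),
                roi_semiaxes_mm=tuple(0.3 * e for e in extent),
                skew_lambda=float(rng.uniform(-1.0, 1.0)),
                noise_scale=float(rng.uniform(0.5, 2.0)),
                smoothing_mm=float(rng.uniform(0.6, 1.5)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, msk = make_phantom(pspec)
            fv = compute_signature_features(vol, msk, cfg)
            skw, ent = fv.skewness, fv.entropy
            phantoms.append((pspec, vol, msk))
        else:
            skw = float(rng.uniform(*spec.skewness_range))
            ent = float(rng.uniform(*spec.entropy_range))
        rec = PatientRecord(id=f"P{i:04d}", cT=ct, cN=cn, skewness=skw,
                            entropy=ent, field_strength=fs)
        rec.score = predict_pcr_probability(rec, model)
        rows.append(rec.to_row())
    df = pd.DataFrame(rows)
    probs = df["score"].to_numpy()
    df["pcr_label"] = _assign_labels(label_rng, spec, probs)
    return CohortTable(df), phantoms


def parameter_recovery_experiment(n: int, seed: int, model: ModelSpec,
                                  level: float = 0.95) -> pd.DataFrame:
    """Simulate a tabular cohort from the model and refit by logistic MLE.

    Returns one row per coefficient with the fitted estimate, its Wald
    interval at ``level`` and whether the interval covers the generating
    value.  Non-convergence is flagged in a ``converged`` column.
    """
    import statsmodels.api as sm

    if n < 500:
        raise ValueError("parameter recovery needs n >= 500")
    spec = CohortSpec(n=n, label_mode="model-bernoulli", seed=seed)
    table, _ = sample_cohort(spec, model)
    df = table.df
    X = sm.add_constant(df[["cT", "cN", "skewness", "entropy"]].to_numpy())
    y = df["pcr_label"].to_numpy()
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    converged = bool(fit.mle_retvals.get("converged", True))
    ci = fit.conf_int(alpha=1.0 - level)
    truth = [model.intercept, model.coef_cT, model.coef_cN,
             model.coef_skewness, model.coef_entropy]
    names = ["intercept", "coef_cT", "coef_cN", "coef_skewness", "coef_entropy"]
    rows = []
    for k, (name, true_val) in enumerate(zip(names, truth)):
        lo, hi = ci[k]
        rows.append({
            "coefficient": name,
            "true": true_val,
            "estimate": float(fit.params[k]),
            "se": float(fit.bse[k]),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
            "covered": bool(lo <= true_val <= hi),
            "converged": converged,
        })
    return pd.DataFrame(rows)
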