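"""Synthetic patients and cohorts for exercising the full pipeline.

No public imaging/outcome data accompany the method, so every stage is
validated against phantoms with known ground truth:

* a hemispherical breast protruding from a body slab on a regular CT grid;
* tissue structure from a smoothed Gaussian random field thresholded at the
  fat-fraction quantile, so the ground-truth fat/fibroglandular masks hit a
  requested fat fraction while the correlation length controls how
  "scattered" versus "heterogeneous" the texture looks;
* per-tissue Gaussian HU sampling calibrated to the four density
  archetypes (fatty / scattered / heterogeneously dense / extremely dense);
  the archetype fat/fibroglandular HU means and SDs follow published
  per-cluster CT statistics of segmented breast tissue, e.g. fat
  N(−110, 5) and fibroglandular N(−52, 12) HU for the fatty archetype;
* dose fields = prescribed base + optional linear gradient + optional
  Gaussian boost hotspot centred in a chosen tissue;
* ordinal toxicity outcomes drawn from a proportional-odds latent model on
  chosen (standardized) covariates, observed twice — clinician and patient
  reports are independent noisy observations of the same latent severity.

Archetype fat fractions, breast radii, dose heterogeneity and outcome
coefficients are generator defaults chosen for realism, not measured
values.  Everything is deterministic given the seed, and each cohort ships
its machine-readable truth (tissue masks, generating coefficients) so
tests can score recovery against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .association import ENDPOINTS, TIMEPOINTS, merge_outcome_columns
from .clustering import DENSITY_LABELS
from .dosimetry import FractionationScheme, dose_metrics, eqd2_convert
from .features import FeatureVector, first_order_features
from .tissue import classify_breast
from .volumes import DoseGrid, GeometryError, ImageVolume, StructureMask, crop_from_skin

# Per-archetype calibration.  HU (mean, sd) pairs follow the published
# ipsilateral per-cluster tissue statistics; fat_fraction, correlation
# length and volume scale are invented defaults that reproduce the
# qualitative ordering (fatty = largest, most uniform; extremely dense =
# smallest, highest median).
ARCHETYPES: dict[str, dict] = {
    "fatty": {
        "fat_hu": (-110.0, 5.0),
        "fibro_hu": (-52.0, 12.0),
        "fat_fraction": 0.90,
        "correlation_length_mm": 8.0,
        "volume_scale": 1.00,
    },
    "scattered": {
        "fat_hu": (-105.0, 7.0),
        "fibro_hu": (-33.0, 10.0),
        "fat_fraction": 0.72,
        "correlation_length_mm": 3.0,
        "volume_scale": 0.88,
    },
    "heterogeneously_dense": {
        "fat_hu": (-101.0, 7.0),
        "fibro_hu": (-13.0, 11.0),
        "fat_fraction": 0.55,
        "correlation_length_mm": 6.0,
        "volume_scale": 0.76,
    },
    "extremely_dense": {
        "fat_hu": (-76.0, 25.0),
        "fibro_hu": (9.0, 15.0),
        "fat_fraction": 0.35,
        "correlation_length_mm": 4.0,
        "volume_scale": 0.64,
    },
}

AIR_HU = -1000.0
SOFT_TISSUE_HU = 30.0
CLIP_HU = 800.0
DEFAULT_GRADE_CUTPOINTS = (0.5, 2.0, 3.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tissue statistics for one synthetic patient."""

    shape: tuple[int, int, int] = (28, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    breast_radius_mm: float = 38.0
    archetype: str = "fatty"
    fat_fraction: float | None = None  # defaults to the archetype value
    fat_hu: tuple[float, float] | None = None
    fibro_hu: tuple[float, float] | None = None
    correlation_length_mm: float | None = None
    n_clips: int = 0
    clip_hu: float = CLIP_HU

    def resolved(self) -> dict:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype '{self.archetype}'")
        arch = ARCHETYPES[self.archetype]
        d = {
            "fat_hu": self.fat_hu or arch["fat_hu"],
            "fibro_hu": self.fibro_hu or arch["fibro_hu"],
            "fat_fraction": self.fat_fraction
            if self.fat_fraction is not None
            else arch["fat_fraction"],
            "correlation_length_mm": self.correlation_length_mm
            or arch["correlation_length_mm"],
        }
        if not (0 < d["fat_fraction"] < 1):
            raise ValueError("fat_fraction must lie in (0, 1)")
        if d["fat_hu"][1] < 0 or d["fibro_hu"][1] < 0:
            raise ValueError("HU SDs must be >= 0")
        if d["fat_hu"][0] >= d["fibro_hu"][0]:
            raise ValueError("fat mean HU must be below fibroglandular mean HU")
        return d


@dataclass
class SyntheticPatient:
    patient_id: str
    spec: PhantomSpec
    ct: ImageVolume
    body: StructureMask
    breast: StructureMask
    fat_truth: StructureMask
    fibro_truth: StructureMask
    dose: DoseGrid | None = None
    covariates: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)


def _smooth_field(shape, spacing, correlation_length_mm, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma_vox = [max(correlation_length_mm / s, 1e-6) for s in spacing]
    return ndimage.gaussian_filter(noise, sigma=sigma_vox)


def generate_breast_phantom(
    spec: PhantomSpec, seed: int, patient_id: str = "P0000"
) -> SyntheticPatient:
    """Build the imaging part of a synthetic patient.

    The breast is the protruding half of a sphere sitting on a body slab;
    tissue labels come from thresholding a smooth random field at the
    fat-fraction quantile of its in-breast values, so the achieved ground
    truth fraction matches the target to within ±0.5 %.
    """
    params = spec.resolved()
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing

    zc = (nz - 1) / 2 * sz
    xc = (nx - 1) / 2 * sx
    y_surface = 0.62 * (ny - 1) * sy  # slab occupies y >= y_surface
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx

    slab = np.broadcast_to(y >= y_surface, spec.shape)
    r2 = (z - zc) ** 2 + (y - y_surface) ** 2 + (x - xc) ** 2
    sphere = r2 <= spec.breast_radius_mm**2
    breast = sphere & (y < y_surface)
    body = slab | breast
    if not breast.any():
        raise GeometryError("breast radius too small for the grid")

    field3d = _smooth_field(spec.shape, spec.spacing, params["correlation_length_mm"], rng)
    in_breast = field3d[breast]
    thr = np.quantile(in_breast, params["fat_fraction"])
    fat = breast & (field3d <= thr)
    achieved = fat.sum() / breast.sum()
    if abs(achieved - params["fat_fraction"]) > 0.005:
        raise ValueError(
            f"fat fraction {params['fat_fraction']:.3f} unreachable "
            f"(achieved {achieved:.3f}); correlation length too long for this breast"
        )
    fibro = breast & ~fat

    hu = np.full(spec.shape, AIR_HU, dtype=np.float64)
    hu[slab & ~breast] = SOFT_TISSUE_HU + rng.normal(0, 10, size=int((slab & ~breast).sum()))
    mu_f, sd_f = params["fat_hu"]
    mu_g, sd_g = params["fibro_hu"]
    hu[fat] = mu_f + (rng.normal(0, sd_f, size=int(fat.sum())) if sd_f > 0 else 0.0)
    hu[fibro] = mu_g + (rng.normal(0, sd_g, size=int(fibro.sum())) if sd_g > 0 else 0.0)
    if spec.n_clips > 0:
        idx = np.flatnonzero(breast)
        chosen = rng.choice(idx, size=min(spec.n_clips, idx.size), replace=False)
        hu.flat[chosen] = spec.clip_hu

    ct = ImageVolume(voxels=hu, spacing=spec.spacing)
    return SyntheticPatient(
        patient_id=patient_id,
        spec=spec,
        ct=ct,
        body=StructureMask.from_reference("body", body, ct),
        breast=StructureMask.from_reference("breast", breast, ct),
        fat_truth=StructureMask.from_reference("fat_truth", fat, ct),
        fibro_truth=StructureMask.from_reference("fibro_truth", fibro, ct),
    )


def generate_dose(
    patient: SyntheticPatient,
    base_gy: float = 40.05,
    n_fractions: int = 15,
    gradient_gy: float = 0.0,
    boost_gy: float = 0.0,
    boost_tissue: str = "fibroglandular",
    boost_sigma_mm: float = 12.0,
    seed: int | None = None,
) -> DoseGrid:
    """Dose field = base + optional linear x-gradient across the breast +
    optional Gaussian boost hotspot centred in the requested tissue."""
    spec = patient.spec
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    x = np.arange(nx)[None, None, :] * sx
    dosef = np.full(spec.shape, float(base_gy))
    if gradient_gy:
        xb = x.ravel()[patient.breast.voxels.any(axis=(0, 1))]
        lo, hi = (xb.min(), xb.max()) if xb.size else (x.min(), x.max())
        frac = np.clip((x - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
        dosef = dosef + gradient_gy * np.broadcast_to(frac, spec.shape)
    if boost_gy:
        tissue = patient.fat_truth if boost_tissue == "fat" else patient.fibro_truth
        if tissue.is_empty():
            raise GeometryError(f"no '{boost_tissue}' tissue to centre the boost in")
        com = np.array(ndimage.center_of_mass(tissue.voxels))
        idx = np.argwhere(tissue.voxels)
        centre = idx[np.argmin(((idx - com) ** 2).sum(axis=1))]
        if not patient.breast.voxels[tuple(centre)]:
            raise GeometryError("boost hotspot centre fell outside the breast")
        zz = (np.arange(nz)[:, None, None] - centre[0]) * sz
        yy = (np.arange(ny)[None, :, None] - centre[1]) * sy
        xx = (np.arange(nx)[None, None, :] - centre[2]) * sx
        dosef = dosef + boost_gy * np.exp(
            -(zz**2 + yy**2 + xx**2) / (2 * boost_sigma_mm**2)
        )
    dose = DoseGrid(
        voxels=dosef, spacing=spec.spacing, origin=patient.ct.origin, fractions=n_fractions
    )
    patient.dose = dose
    return dose


# ---------------------------------------------------------------------------
# proportional-odds outcome simulation


def simulate_ordinal_outcomes(
    x: np.ndarray,
    beta: np.ndarray,
    cutpoints: tuple[float, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Grades 0..len(cutpoints) from the latent model x @ beta + logistic noise."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    latent = x @ np.asarray(beta, dtype=float) + rng.logistic(size=len(x))
    return np.searchsorted(np.asarray(cutpoints, dtype=float), latent)


def _misgrade(grades: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Independent reporting noise: with probability ``prob`` shift ±1."""
    flip = rng.random(grades.shape) < prob
    shift = rng.choice([-1, 1], size=grades.shape)
    return np.clip(grades + flip * shift, 0, 3)


# ---------------------------------------------------------------------------
# feature-level cohort (fast; for clustering studies)

# (median HU, IQR HU, uniformity) archetype centroids and within-archetype
# SDs, matching the reported per-cluster ipsilateral characteristics
# (fatty: median −108 ± 5 HU, IQR 25 ± 7 HU, uniformity 0.40 ± 0.01;
# heterogeneously dense widest IQR / lowest uniformity; extremely dense
# highest median).
FEATURE_CENTROIDS = {
    "fatty": (-108.0, 25.0, 0.40),
    "scattered": (-88.0, 42.0, 0.30),
    "heterogeneously_dense": (-65.0, 58.0, 0.21),
    "extremely_dense": (-38.0, 48.0, 0.26),
}
FEATURE_SDS = (5.0, 7.0, 0.01)
VOLUME_MEANS_CM3 = {  # volume-density coupling: fatty breasts are largest
    "fatty": 1000.0,
    "scattered": 820.0,
    "heterogeneously_dense": 660.0,
    "extremely_dense": 520.0,
}


def generate_feature_cohort(
    n_patients: int,
    seed: int,
    proportions: dict[str, float] | None = None,
    separation: float = 1.0,
) -> tuple[list[FeatureVector], list[str], np.ndarray]:
    """Sample (median, IQR, uniformity) vectors directly from the archetype
    centroids, with breast volumes coupled to density.

    ``separation`` scales each centroid's offset from the grand centroid;
    values >= 3 make the four groups separated by >= 10 within-group SDs in
    feature space, the regime where clustering recovery should be exact.
    Returns (features, true archetype labels, volumes in cm³).
    """
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = {k: 0.25 for k in DENSITY_LABELS}
    if abs(sum(proportions.values()) - 1.0) > 1e-9 or min(proportions.values()) < 0:
        raise ValueError("archetype proportions must be non-negative and sum to 1")
    labels = rng.choice(
        list(proportions.keys()), size=n_patients, p=list(proportions.values())
    )
    grand = np.mean([FEATURE_CENTROIDS[k] for k in DENSITY_LABELS], axis=0)
    features, volumes = [], []
    for lab in labels:
        c = grand + separation * (np.array(FEATURE_CENTROIDS[lab]) - grand)
        m, iqr, u = rng.normal(c, FEATURE_SDS)
        features.append(
            FeatureVector(median=m, iqr=max(iqr, 1.0), uniformity=float(np.clip(u, 0.02, 1.0)))
        )
        volumes.append(rng.normal(VOLUME_MEANS_CM3[lab], 0.12 * VOLUME_MEANS_CM3[lab]))
    return features, list(labels), np.asarray(volumes)


# ---------------------------------------------------------------------------
# full imaging cohort


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Outcome coefficients apply to z-scored covariates in a
    proportional-odds latent model; they are per endpoint, e.g.
    ``{"pain": {"fat_mean_gy": 1.0, "age": 0.3}}``.  Toxicity declines at
    later timepoints via ``timepoint_offsets`` on the latent scale.
    """

    n_patients: int = 100
    proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shape: tuple[int, int, int] = (26, 44, 44)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    base_radius_mm: float = 34.0
    crop_margin_mm: float = 5.0
    base_dose_gy: float = 40.05
    base_dose_jitter: float = 0.02  # relative spread of the planned mean dose
    n_fractions: int = 15
    dose_gradient_gy: float = 3.0  # per-patient amplitude ~ U(0.5, 1.5) x this
    boost_probability: float = 0.5
    boost_gy: float = 10.0
    # the tumour bed (boost centre) falls in either tissue
    boost_in_fat_probability: float = 0.5
    outcome_coefficients: dict = field(
        default_factory=lambda: {
            "pain": {"fat_mean_gy": 1.0, "age": 0.3},
            "oedema": {"breast_volume_cm3": 0.6, "fat_uniformity": -0.6},
            "atrophy": {"fg_mean_gy": 0.8, "age": 0.3},
            "induration": {"fg_mean_gy": 1.0, "boost": 0.4},
        }
    )
    grade_cutpoints: tuple[float, ...] = DEFAULT_GRADE_CUTPOINTS
    timepoint_offsets: tuple[float, ...] = (0.0, -0.5, -1.0)
    misgrade_probability: float = 0.15


def generate_cohort(
    spec: CohortSpec, seed: int, keep_patients: bool = False
) -> tuple[pd.DataFrame, dict, list[SyntheticPatient]]:
    """Generate a full synthetic cohort and its analysis table.

    Every patient gets a CT phantom, skin-cropped breast mask, a
    heterogeneous dose field, composition and dose metrics computed by the
    pipeline itself (mixture segmentation + dosimetry on the cropped
    breast), and ordinal outcomes drawn from the proportional-odds truth on
    the z-scored covariates.  Returns (cohort table, truth dict, patients);
    patients are only retained when ``keep_patients`` is true.
    """
    rng = np.random.default_rng(seed)
    if abs(sum(spec.proportions) - 1.0) > 1e-9 or min(spec.proportions) < 0:
        raise ValueError("archetype proportions must be non-negative and sum to 1")
    labels = rng.choice(list(DENSITY_LABELS), size=spec.n_patients, p=spec.proportions)
    scheme = FractionationScheme(n_fractions=spec.n_fractions)

    rows, patients = [], []
    for i, archetype in enumerate(labels):
        pid = f"P{i:04d}"
        arch = ARCHETYPES[archetype]
        radius = spec.base_radius_mm * arch["volume_scale"] ** (1 / 3) * rng.uniform(0.95, 1.05)
        pspec = PhantomSpec(
            shape=spec.shape,
            spacing=spec.spacing,
            breast_radius_mm=radius,
            archetype=archetype,
        )
        patient = generate_breast_phantom(pspec, seed=int(rng.integers(2**31)), patient_id=pid)
        boost = bool(rng.random() < spec.boost_probability)
        boost_tissue = "fat" if rng.random() < spec.boost_in_fat_probability else "fibroglandular"
        dose = generate_dose(
            patient,
            base_gy=spec.base_dose_gy * rng.normal(1.0, spec.base_dose_jitter),
            n_fractions=spec.n_fractions,
            gradient_gy=spec.dose_gradient_gy * rng.uniform(0.5, 1.5),
            boost_gy=spec.boost_gy if boost else 0.0,
            boost_tissue=boost_tissue,
        )
        cropped = crop_from_skin(patient.breast, patient.body, spec.crop_margin_mm)
        fv = first_order_features(patient.ct, cropped)
        fit, thr, seg = classify_breast(patient.ct, cropped, min_voxels=200)
        eqd2 = eqd2_convert(dose, scheme)

        row = {
            "patient_id": pid,
            "archetype": archetype,
            "age": float(np.clip(rng.normal(60, 9), 30, 85)),
            "boost": int(boost),
            "breast_volume_cm3": cropped.volume_cm3(),
            "median_hu": fv.median,
            "iqr_hu": fv.iqr,
            "uniformity": fv.uniformity,
            "fat_pct": seg.fat_pct,
            "fg_pct": seg.fibro_pct,
        }
        for name, mask in [
            ("breast", cropped),
            ("fat", seg.fat),
            ("fg", seg.fibroglandular),
        ]:
            if mask.is_empty():
                row[f"{name}_mean_gy"] = np.nan
                row[f"{name}_max_gy"] = np.nan
                row[f"{name}_uniformity"] = np.nan
                continue
            m_phys = dose_metrics(dose, mask)
            m_eqd2 = dose_metrics(eqd2, mask, dose_kind="EQD2")
            row[f"{name}_mean_gy"] = m_phys.mean
            row[f"{name}_max_gy"] = m_phys.max
            row[f"{name}_uniformity"] = m_phys.uniformity
            row[f"{name}_mean_eqd2"] = m_eqd2.mean
            row[f"{name}_max_eqd2"] = m_eqd2.max
        rows.append(row)
        patient.covariates = row
        if keep_patients:
            patients.append(patient)

    df = pd.DataFrame(rows)

    # outcomes from the proportional-odds truth on z-scored covariates
    for endpoint in ENDPOINTS:
        coefs = spec.outcome_coefficients.get(endpoint, {})
        if coefs:
            x = np.column_stack(
                [
                    (df[v] - df[v].mean()) / max(df[v].std(ddof=0), 1e-9)
                    for v in coefs
                ]
            )
            beta = np.array(list(coefs.values()))
        else:
            x = np.zeros((len(df), 1))
            beta = np.zeros(1)
        for tp, offset in zip(TIMEPOINTS, spec.timepoint_offsets):
            latent = x @ beta + offset + rng.logistic(size=len(df))
            true_grade = np.searchsorted(np.asarray(spec.grade_cutpoints), latent)
            df[f"{endpoint}_{tp}_cro"] = _misgrade(true_grade, spec.misgrade_probability, rng)
            df[f"{endpoint}_{tp}_pro"] = _misgrade(true_grade, spec.misgrade_probability, rng)
    df = merge_outcome_columns(df)

    truth = {
        "seed": seed,
        "archetypes": list(map(str, labels)),
        "outcome_coefficients": spec.outcome_coefficients,
        "grade_cutpoints": list(spec.grade_cutpoints),
        "timepoint_offsets": list(spec.timepoint_offsets),
        "misgrade_probability": spec.misgrade_probability,
    }
    return df, truth, patients


def write_cohort(df: pd.DataFrame, truth: dict, out_dir) -> None:
    """Write the cohort CSV and its machine-readable truth JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "cohort.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
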