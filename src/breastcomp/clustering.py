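"""Global breast-density classification.

A cohort of (median, IQR, uniformity) feature vectors is z-scored and
partitioned into four clusters with k-means, by design mirroring the four
BI-RADS density categories.  Clusters are then named by ascending centroid
median HU — the fattiest (lowest-HU, most uniform) cluster first — giving
``fatty``, ``scattered``, ``heterogeneously_dense``, ``extremely_dense``.
Agreement between two labelings of the same patients (e.g. clusterings of
the treated and untreated breast) is summarized with a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .features import FeatureVector

DENSITY_LABELS = ("fatty", "scattered", "heterogeneously_dense", "extremely_dense")
DEFAULT_SEED = 20140
DEFAULT_RESTARTS = 10
N_CLUSTERS = 4
FEATURE_NAMES = ("median_hu", "iqr_hu", "uniformity")


@dataclass(frozen=True)
class ClusterModel:
    """Fitted 4-cluster k-means in standardized feature space."""

    centroids: np.ndarray  # (4, 3) in z-scored space
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    inertia: float
    seed: int
    restarts: int
    # raw cluster index -> density label, filled by name_clusters
    label_order: tuple[str, ...] | None = None

    def centroids_raw(self) -> np.ndarray:
        """Centroids back on the original feature scale (HU, HU, fraction)."""
        return self.centroids * self.feature_sd + self.feature_mean

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_sd

    def predict(self, features: list[FeatureVector]) -> np.ndarray:
        """Nearest-centroid projection of new feature vectors (raw indices)."""
        x = self.standardize(np.array([f.as_array() for f in features]))
        d2 = ((x[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def to_dict(self) -> dict:
        return {
            "centroids_standardized": self.centroids.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "feature_names": list(FEATURE_NAMES),
            "inertia": self.inertia,
            "seed": self.seed,
            "restarts": self.restarts,
            "label_order": list(self.label_order) if self.label_order else None,
        }


def _feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    x = np.array([f.as_array() for f in features], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values in cohort")
    return x


def cluster_cohort(
    features: list[FeatureVector],
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> tuple[ClusterModel, np.ndarray]:
    """Fit k-means (k=4) on z-scored features; returns model + raw indices.

    Deterministic for a fixed seed; the best of ``restarts`` k-means++
    initializations (lowest inertia) is kept.
    """
    x = _feature_matrix(features)
    if len(x) < N_CLUSTERS:
        raise ValueError(f"need at least {N_CLUSTERS} patients, got {len(x)}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        names = ", ".join(FEATURE_NAMES[i] for i in degenerate)
        raise ValueError(f"zero-variance feature(s): {names}")
    z = (x - mean) / sd
    km = KMeans(n_clusters=N_CLUSTERS, n_init=restarts, random_state=seed, init="k-means++")
    raw = km.fit_predict(z)
    model = ClusterModel(
        centroids=km.cluster_centers_,
        feature_mean=mean,
        feature_sd=sd,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )
    return model, raw


def name_clusters(model: ClusterModel, raw_indices: np.ndarray) -> tuple[ClusterModel, list[str]]:
    """Map raw cluster indices to density names by ascending centroid median
    HU (ties broken by descending uniformity).  Returns the model with its
    label order recorded, plus one label per patient."""
    raw_centroids = model.centroids_raw()
    medians = raw_centroids[:, 0]
    uniformities = raw_centroids[:, 2]
    if np.allclose(medians, medians[0]) and np.allclose(uniformities, uniformities[0]):
        raise ValueError("degenerate model: identical centroids")
    order = np.lexsort((-uniformities, medians))  # ascending median, desc uniformity
    labels_by_raw = {int(raw): DENSITY_LABELS[rank] for rank, raw in enumerate(order)}
    named = ClusterModel(
        centroids=model.centroids,
        feature_mean=model.feature_mean,
        feature_sd=model.feature_sd,
        inertia=model.inertia,
        seed=model.seed,
        restarts=model.restarts,
        label_order=tuple(labels_by_raw[i] for i in range(N_CLUSTERS)),
    )
    return named, [labels_by_raw[int(i)] for i in raw_indices]


def classify_cohort(
    features: list[FeatureVector],
    patient_ids: list[str] | None = None,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
    side: str = "ipsilateral",
) -> tuple[ClusterModel, pd.DataFrame]:
    """cluster_cohort + name_clusters, returning an assignments table."""
    model, raw = cluster_cohort(features, seed=seed, restarts=restarts)
    model, labels = name_clusters(model, raw)
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(len(features))]
    table = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "side": side,
            "label": labels,
            "cluster_index": raw.astype(int),
        }
    )
    return model, table


def project_assignments(
    model: ClusterModel, features: list[FeatureVector], patient_ids: list[str], side: str
) -> pd.DataFrame:
    """Assign new feature vectors through an already-fitted, named model."""
    if model.label_order is None:
        raise ValueError("model has no label order; run name_clusters first")
    raw = model.predict(features)
    labels = [model.label_order[int(i)] for i in raw]
    return pd.DataFrame(
        {"patient_id": patient_ids, "side": side, "label": labels, "cluster_index": raw}
    )


def compare_clusterings(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Confusion matrix (rows = labels in ``a``, columns = labels in ``b``)
    plus per-class agreement and overall accuracy, over the shared patients.

    Both inputs are assignment tables with ``patient_id`` and ``label``.
    Raises if the patient sets differ.
    """
    ids_a, ids_b = set(a["patient_id"]), set(b["patient_id"])
    if ids_a != ids_b:
        missing = sorted((ids_a ^ ids_b))[:10]
        raise ValueError(f"patient sets differ, e.g. {missing}")
    merged = a.merge(b, on="patient_id", suffixes=("_a", "_b"))
    matrix = pd.crosstab(
        merged["label_a"], merged["label_b"], dropna=False
    ).reindex(index=DENSITY_LABELS, columns=DENSITY_LABELS, fill_value=0)
    diag = np.diag(matrix.values)
    row_sums = matrix.values.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row_sums > 0, diag / np.maximum(row_sums, 1), np.nan)
    accuracy = diag.sum() / matrix.values.sum()
    return {
        "confusion_matrix": matrix,
        "per_class_agreement": dict(zip(DENSITY_LABELS, per_class)),
        "accuracy": float(accuracy),
        "n": int(matrix.values.sum()),
    }
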