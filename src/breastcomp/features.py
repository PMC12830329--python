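"""First-order intensity features of a masked CT region.

Three features drive the global density classification: the median and
interquartile range of the in-mask HU values, and the histogram uniformity

    uniformity = sum_i p(i)^2,    p(i) = count_i / n_total,

computed over a uniform-width intensity histogram.  Uniformity is 1 when
all voxels fall in one bin and 1/n for n equally populated bins, so fatty
(homogeneous) breasts score high and mixed-density breasts score low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import ImageVolume, StructureMask

DEFAULT_HU_BIN_WIDTH = 25.0


@dataclass(frozen=True)
class IntensityHistogram:
    """Uniform-width histogram of masked voxel values."""

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # non-negative ints, sum == n_total
    n_total: int

    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_total

    def uniformity(self) -> float:
        p = self.probabilities()
        return float(np.sum(p * p))


@dataclass(frozen=True)
class FeatureVector:
    """median/IQR in HU, uniformity dimensionless in (0, 1]."""

    median: float
    iqr: float
    uniformity: float

    @property
    def uniformity_pct(self) -> float:
        return 100.0 * self.uniformity

    def as_array(self) -> np.ndarray:
        return np.array([self.median, self.iqr, self.uniformity])


def masked_values(volume: ImageVolume, mask: StructureMask) -> np.ndarray:
    mask.check_congruent(volume)
    if mask.is_empty():
        raise ValueError(f"mask '{mask.name}' is empty")
    return np.asarray(volume.voxels[mask.voxels], dtype=np.float64)


def histogram_of_values(values: np.ndarray, bin_width: float) -> IntensityHistogram:
    """Bin raw values into uniform-width bins aligned to multiples of the
    bin width, spanning the observed range."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=np.float64)
    lo = np.floor(values.min() / bin_width) * bin_width
    # half-open bins [edge, edge + width): a maximum on an edge opens a new bin
    n_bins = int(np.floor((values.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return IntensityHistogram(bin_edges=edges, counts=counts, n_total=int(values.size))


def compute_histogram(
    volume: ImageVolume, mask: StructureMask, bin_width: float = DEFAULT_HU_BIN_WIDTH
) -> IntensityHistogram:
    """Intensity histogram of the masked voxels (uniform bin width in HU)."""
    return histogram_of_values(masked_values(volume, mask), bin_width)


def first_order_features(
    volume: ImageVolume, mask: StructureMask, bin_width: float = DEFAULT_HU_BIN_WIDTH
) -> FeatureVector:
    """Median, IQR and uniformity of the masked HU distribution.

    Median and IQR are computed on the raw voxel values with
    linear-interpolation quantiles; uniformity on the binned histogram.
    """
    values = masked_values(volume, mask)
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    hist = histogram_of_values(values, bin_width)
    return FeatureVector(median=float(q50), iqr=float(q75 - q25), uniformity=hist.uniformity())


def feature_table(
    rows: list[tuple[str, str, ImageVolume, StructureMask]],
    bin_width: float = DEFAULT_HU_BIN_WIDTH,
) -> pd.DataFrame:
    """Feature table with one row per (patient, structure).

    ``rows`` holds (patient_id, structure_name, volume, mask) tuples.
    """
    records = []
    for patient_id, structure, volume, mask in rows:
        fv = first_order_features(volume, mask, bin_width)
        records.append(
            {
                "patient_id": patient_id,
                "structure": structure,
                "n_voxels": mask.count(),
                "median_hu": fv.median,
                "iqr_hu": fv.iqr,
                "uniformity": fv.uniformity,
            }
        )
    return pd.DataFrame.from_records(records)
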