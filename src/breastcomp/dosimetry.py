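"""Substructure dosimetry: EQD2 conversion and per-structure dose metrics.

Physical dose D delivered in n fractions (per-voxel fraction dose
d = D / n) is converted to the equivalent dose in 2 Gy fractions with the
linear-quadratic model,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),

with alpha/beta = 1.7 Gy by default (late breast effects).  Per structure
the mean, maximum and uniformity of both physical dose and EQD2 are
reported; uniformity is the same sum-of-squared-probabilities statistic
used for CT intensities, computed on a uniform-width dose histogram
(default 0.25 Gy bins).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from warnings import warn

import numpy as np
import pandas as pd

from .features import histogram_of_values
from .tissue import TissueSegmentation
from .volumes import DoseGrid, StructureMask

DEFAULT_ALPHA_BETA = 1.7
DEFAULT_DOSE_BIN_WIDTH_GY = 0.25


@dataclass(frozen=True)
class FractionationScheme:
    n_fractions: int
    alpha_beta: float = DEFAULT_ALPHA_BETA

    def __post_init__(self):
        if self.n_fractions is None or int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be a positive integer (no silent default)")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")


@dataclass(frozen=True)
class DoseMetrics:
    structure: str
    dose_kind: str  # "physical" or "EQD2"
    mean: float
    max: float
    uniformity: float
    n_voxels: int


def eqd2_convert(dose: DoseGrid, scheme: FractionationScheme | None = None) -> DoseGrid:
    """Voxelwise linear-quadratic conversion of physical dose to EQD2.

    The fraction count comes from ``scheme`` or, failing that, from the
    grid itself; zero dose maps exactly to zero.  For a plan with a
    sequential boost stored as a separate grid, convert each phase with its
    own fractionation and sum the resulting EQD2 grids.
    """
    if scheme is None:
        if dose.fractions is None:
            raise ValueError("n_fractions unknown: attach it to the DoseGrid or pass a scheme")
        scheme = FractionationScheme(n_fractions=dose.fractions)
    n = int(scheme.n_fractions)
    ab = float(scheme.alpha_beta)
    d_per_fx = dose.voxels / n
    eqd2 = dose.voxels * (d_per_fx + ab) / (2.0 + ab)
    return replace(dose, voxels=eqd2, fractions=n)


def dose_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    bin_width_gy: float = DEFAULT_DOSE_BIN_WIDTH_GY,
    dose_kind: str = "physical",
) -> DoseMetrics:
    """Mean, max and histogram uniformity of the masked dose values.

    Mean and max are taken on raw voxel doses; uniformity on a
    uniform-width histogram of them.
    """
    mask.check_congruent(dose)
    if mask.is_empty():
        raise ValueError(f"mask '{mask.name}' is empty")
    values = dose.voxels[mask.voxels]
    hist = histogram_of_values(values, bin_width_gy)
    return DoseMetrics(
        structure=mask.name,
        dose_kind=dose_kind,
        mean=float(values.mean()),
        max=float(values.max()),
        uniformity=hist.uniformity(),
        n_voxels=int(values.size),
    )


def substructure_dose_report(
    dose: DoseGrid,
    segmentation: TissueSegmentation,
    breast: StructureMask,
    scheme: FractionationScheme,
    bin_width_gy: float = DEFAULT_DOSE_BIN_WIDTH_GY,
) -> list[DoseMetrics]:
    """Dose metrics for the complete breast and each tissue substructure,
    in both physical dose and EQD2.  Empty substructures are skipped with
    a warning."""
    eqd2 = eqd2_convert(dose, scheme)
    structures = [
        breast,
        segmentation.fat,
        segmentation.fibroglandular,
        segmentation.unclassified,
    ]
    out: list[DoseMetrics] = []
    for mask in structures:
        if mask.is_empty():
            warn(f"substructure '{mask.name}' is empty; metrics omitted", stacklevel=2)
            continue
        out.append(dose_metrics(dose, mask, bin_width_gy, dose_kind="physical"))
        out.append(dose_metrics(eqd2, mask, bin_width_gy, dose_kind="EQD2"))
    return out


def metrics_table(metrics: list[DoseMetrics], patient_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "structure": m.structure,
                "dose_kind": m.dose_kind,
                "n_voxels": m.n_voxels,
                "mean_gy": m.mean,
                "max_gy": m.max,
                "uniformity": m.uniformity,
            }
            for m in metrics
        ]
    )
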