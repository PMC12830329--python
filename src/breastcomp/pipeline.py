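"""End-to-end workflow: simulate/load → crop → features → cluster →
segment → dosimetry → associate, with reproducible on-disk outputs.

The run directory is append-only: each stage writes its own artifacts
(CSV/JSON) and never rewrites an upstream one.  Every artifact records the
configuration hash so a run can be audited and reproduced; rerunning with
the same config and seed produces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, clustering, phantom
from .features import FeatureVector

log = logging.getLogger("breastcomp")


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    out_dir: str
    seed: int = 20140
    # cohort simulation
    n_patients: int = 50
    cohort: phantom.CohortSpec | None = None
    # or: load an existing cohort table instead of simulating
    cohort_csv: str | None = None
    # analysis settings
    hu_bin_width: float = 25.0
    dose_bin_width_gy: float = 0.25
    alpha_beta: float = 1.7
    n_fractions: int | None = 15
    kmeans_restarts: int = 10
    baseline_variables: list[str] = field(
        default_factory=lambda: ["age", "breast_volume_cm3", "boost"]
    )
    candidate_variables: list[str] = field(
        default_factory=lambda: [
            "median_hu",
            "fat_pct",
            "fg_pct",
            "breast_mean_gy",
            "breast_max_gy",
            "breast_uniformity",
            "fat_mean_gy",
            "fat_max_gy",
            "fat_uniformity",
            "fg_mean_gy",
            "fg_max_gy",
        ]
    )
    endpoints: tuple[str, ...] = association.ENDPOINTS
    timepoints: tuple[str, ...] = association.TIMEPOINTS

    def validate(self) -> None:
        if self.cohort_csv is None and self.n_fractions is None:
            raise ValueError("n_fractions is required (no silent default)")
        if self.n_fractions is not None and self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")
        if self.hu_bin_width <= 0 or self.dose_bin_width_gy <= 0:
            raise ValueError("bin widths must be > 0")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ValueError(f"cohort_csv does not exist: {self.cohort_csv}")

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        settings = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(_jsonable(settings), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute the staged workflow; returns the run directory.

    Stage failures halt the run with a stage-scoped error message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config.json").write_text(
        json.dumps({"hash": cfg_hash, **_jsonable(asdict(config))}, indent=2)
    )
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.2f s", name, timings[name])
            return result

        return wrap

    # --- simulate (or load) -------------------------------------------------
    @stage("simulate")
    def df():
        if config.cohort_csv:
            return pd.read_csv(config.cohort_csv)
        spec = config.cohort or phantom.CohortSpec(
            n_patients=config.n_patients,
            base_dose_gy=40.05,
            n_fractions=config.n_fractions,
        )
        table, truth, _ = phantom.generate_cohort(spec, seed=config.seed)
        phantom.write_cohort(table, truth, out)
        return table

    # --- features -----------------------------------------------------------
    @stage("features")
    def features():
        feats = [
            FeatureVector(median=r.median_hu, iqr=r.iqr_hu, uniformity=r.uniformity)
            for r in df.itertuples()
        ]
        tab = df[["patient_id", "median_hu", "iqr_hu", "uniformity"]].copy()
        tab.insert(1, "structure", "breast")
        tab.insert(2, "n_voxels", np.nan)
        tab["config_hash"] = cfg_hash
        tab.to_csv(out / "features.csv", index=False)
        return feats

    # --- cluster ------------------------------------------------------------
    @stage("cluster")
    def assignments():
        model, table = clustering.classify_cohort(
            features,
            patient_ids=list(df["patient_id"]),
            seed=config.seed,
            restarts=config.kmeans_restarts,
        )
        table["config_hash"] = cfg_hash
        table.to_csv(out / "cluster_assignments.csv", index=False)
        (out / "cluster_model.json").write_text(
            json.dumps({"config_hash": cfg_hash, **model.to_dict()}, indent=2)
        )
        return table

    # --- segmentation + dosimetry summaries already live in the cohort table
    @stage("dosimetry")
    def dosimetry_table():
        cols = [c for c in df.columns if c.endswith(("_gy", "_eqd2", "_uniformity"))]
        tab = df[["patient_id", *cols]].copy()
        tab["config_hash"] = cfg_hash
        tab.to_csv(out / "dosimetry.csv", index=False)
        return tab

    # --- associate ----------------------------------------------------------
    @stage("associate")
    def models():
        merged = association.merge_outcome_columns(df)
        sweep = association.endpoint_sweep(
            merged,
            baseline=config.baseline_variables,
            candidates=[c for c in config.candidate_variables if c in merged.columns],
            endpoints=config.endpoints,
            timepoints=config.timepoints,
        )
        sweep["config_hash"] = cfg_hash
        sweep.to_csv(out / "model_summary.csv", index=False)
        return sweep

    (out / "timings.json").write_text(json.dumps({"config_hash": cfg_hash, **timings}, indent=2))
    return out
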