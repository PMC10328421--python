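"""Top-level per-subject and cohort pipelines with provenance logging.

``run_subject`` composes the preprocessing and quantification stages in
their canonical order — register T2 to T1, denoise, generate/erode the WM
mask, uniformize WM intensity, difference map, threshold, per-slice
clustering, grading — and emits a JSON report. ``run_cohort`` merges
per-subject results into a cohort table and runs the group statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import build_report
from .image import BinaryMask, ImageVolume, RigidTransform
from .preprocess import (
    denoise_adaptive,
    erode_mask,
    resample_to,
    rigid_register,
    segment_wm_fallback,
    uniformize_wm,
)
from .quantify import NeighborhoodSpec, quantify_subject


class ConfigurationError(ValueError):
    """Pipeline configuration is incomplete or inconsistent."""


@dataclass
class PipelineConfig:
    """Settings of a single-subject run. Defaults are the canonical
    analysis parameters: detection threshold 60 on a WM-median-1000 scale,
    1-voxel 3D erosion, in-plane 8-neighbor difference ring."""

    subject_id: str = "subject"
    threshold: float = 60.0
    uniformize_target: float = 1000.0
    erosion_iterations: int = 1
    erosion_mode: str = "3d"  # "3d" | "inplane"
    neighborhood_mode: str = "inplane"  # "inplane" | "3d"
    neighborhood_radius: int = 1
    include_outside_mask_neighbors: bool = True
    denoise: bool = True
    registration: str = "auto"  # "auto" | "identity"
    allow_wm_fallback: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ConfigurationError("threshold must be finite")
        if self.erosion_iterations < 0:
            raise ConfigurationError("erosion_iterations must be >= 0")

    def neighborhood(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(
            mode=self.neighborhood_mode,
            radius=self.neighborhood_radius,
            include_outside_mask=self.include_outside_mask_neighbors,
        )


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class SubjectOutput:
    report: dict
    pvs_mask: BinaryMask
    eroded_wm: BinaryMask
    t2_uniformized: ImageVolume
    transform: RigidTransform


def run_subject(
    t1: ImageVolume,
    t2: ImageVolume,
    wm_mask: BinaryMask | None = None,
    config: PipelineConfig | None = None,
    transform: RigidTransform | None = None,
) -> SubjectOutput:
    """Execute the full per-subject pipeline; deterministic given inputs.

    ``wm_mask`` should be an externally produced white-matter mask on the
    T1 grid; when absent and ``config.allow_wm_fallback`` is set, a
    phantom-grade intensity-clustering segmentation of T1 is used instead.
    ``transform`` bypasses registration with a known T2->T1 alignment.
    """
    cfg = config or PipelineConfig()
    provenance: dict = {
        "software": f"pvsquant {__version__}",
        "settings": dataclasses.asdict(cfg),
        "inputs": {
            "t1_checksum": _checksum(t1.data),
            "t2_checksum": _checksum(t2.data),
        },
        "stages": [],
    }

    if wm_mask is None:
        if not cfg.allow_wm_fallback:
            raise ConfigurationError(
                "no WM mask supplied and the intensity-clustering fallback is "
                "disabled; pass wm_mask or set allow_wm_fallback=True"
            )
        wm_mask = segment_wm_fallback(t1, seed=cfg.seed)
        provenance["stages"].append({"stage": "segment_wm_fallback"})
    else:
        provenance["inputs"]["wm_mask_checksum"] = _checksum(wm_mask.data)

    # registration: bring T2 onto the T1 grid
    if transform is not None:
        tfm, t2_reg = rigid_register(t2, t1, initial_transform=transform)
        provenance["stages"].append(
            {"stage": "rigid_register", "mode": "user-supplied", **tfm.to_dict()}
        )
    elif cfg.registration == "identity":
        tfm = RigidTransform()
        t2_reg = (
            t2
            if t2.shape == t1.shape and np.allclose(t2.affine, t1.affine)
            else resample_to(t2, t1, tfm)
        )
        provenance["stages"].append({"stage": "rigid_register", "mode": "identity"})
    else:
        tfm, t2_reg = rigid_register(t2, t1)
        provenance["stages"].append(
            {"stage": "rigid_register", "mode": "mutual-information", **tfm.to_dict()}
        )

    if cfg.denoise:
        t2_reg = denoise_adaptive(t2_reg)
        provenance["stages"].append({"stage": "denoise_adaptive"})

    t2_unif = uniformize_wm(t2_reg, wm_mask, target_level=cfg.uniformize_target)
    provenance["stages"].append(
        {"stage": "uniformize_wm", "target_level": cfg.uniformize_target}
    )

    eroded = erode_mask(wm_mask, iterations=cfg.erosion_iterations, mode=cfg.erosion_mode)
    provenance["stages"].append(
        {
            "stage": "erode_mask",
            "iterations": cfg.erosion_iterations,
            "mode": cfg.erosion_mode,
        }
    )

    nb = cfg.neighborhood()
    result, pvs, _diff = quantify_subject(
        t2_unif, eroded, threshold=cfg.threshold, neighborhood=nb
    )
    provenance["stages"].append(
        {
            "stage": "quantify",
            "threshold": cfg.threshold,
            "neighborhood": nb.describe(),
            "out_of_mask_neighbors_included": nb.include_outside_mask,
        }
    )

    report = {
        "subject_id": cfg.subject_id,
        "threshold": cfg.threshold,
        "neighborhood": nb.describe(),
        **result.to_dict(),
        "provenance": provenance,
    }
    return SubjectOutput(
        report=report,
        pvs_mask=pvs,
        eroded_wm=eroded,
        t2_uniformized=t2_unif,
        transform=tfm,
    )


def run_cohort(
    subject_reports: list[dict],
    cohort: pd.DataFrame,
    group_variable: str = "group",
) -> tuple[pd.DataFrame, dict]:
    """Merge per-subject PVS results into the covariate table and analyse.

    Matching is by ``subject_id``; unmatched or duplicated ids are errors.
    """
    ids = [r["subject_id"] for r in subject_reports]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids in reports: {dupes}")
    if cohort["subject_id"].duplicated().any():
        dupes = sorted(cohort.loc[cohort["subject_id"].duplicated(), "subject_id"])
        raise ValueError(f"duplicate subject ids in cohort table: {dupes}")
    missing = sorted(set(ids) - set(cohort["subject_id"]))
    if missing:
        raise ValueError(f"subject ids absent from cohort table: {missing}")
    metrics = pd.DataFrame(
        [
            {
                "subject_id": r["subject_id"],
                "pvs_volume_voxels": r["pvs_voxel_count"],
                "pvs_normalized_volume": r["normalized_volume"],
                "pvs_max_slice_count": r["max_slice_count"],
                "pvs_grade": r["grade"],
                "pvs_enlargement": r["enlargement_flag"],
            }
            for r in subject_reports
        ]
    )
    merged = cohort.drop(
        columns=[c for c in metrics.columns if c != "subject_id" and c in cohort.columns]
    ).merge(metrics, on="subject_id", how="left")
    report = build_report(merged, group_variable=group_variable)
    return merged, report
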