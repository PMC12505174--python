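"""Per-image measurement pipeline: GBM + FP + EDD in one record.

Glue layer combining :mod:`glomorph.gbm_morphometry` and
:mod:`glomorph.ultrastructure_scoring` into the flat per-image record that
feeds report serialization and the subtype classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gbm_morphometry import FilterCriteria, GbmInstance, measure_gbm
from .mask_io import MaskSet
from .ultrastructure_scoring import (
    DEFAULT_MIN_EDD_AREA_NM2,
    DEFAULT_REFERENCE_DENSITY,
    count_fp_near_gbm,
    edd_presence,
    fp_profile,
)


@dataclass
class MeasureConfig:
    """Tunable parameters of the whole measurement engine."""

    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    thickness_method: str = "skeleton"  # or "boundary"
    reference_density_per_um: float = DEFAULT_REFERENCE_DENSITY
    fp_max_dist_px: float = 20.0
    min_edd_area_nm2: float = DEFAULT_MIN_EDD_AREA_NM2


def instance_rows(image_id: str, insts: list[GbmInstance]) -> list[dict]:
    """Flat per-instance CSV rows for all GBM candidates."""
    rows = []
    for i in insts:
        d, sk, t = i.descriptors, i.skeleton, i.thickness
        rows.append(
            {
                "image_id": image_id,
                "instance_id": i.instance_id,
                "area_px2": i.area_px2,
                "perimeter_px": d.perimeter_px if d else np.nan,
                "compactness": d.compactness if d else np.nan,
                "fill_rate": d.fill_rate if d else np.nan,
                "skeleton_len_px": sk.length_px if sk else np.nan,
                "branch_points": sk.branch_point_count if sk else -1,
                "norm_curvature": sk.norm_curvature if sk else np.nan,
                "thickness_boundary_nm": t.mean_boundary_nm if t else np.nan,
                "thickness_skeleton_nm": t.mean_skeleton_nm if t else np.nan,
                "accepted": i.accepted,
                "reject_reason": ";".join(i.reject_reasons),
            }
        )
    return rows


def measure_mask_set(
    mask_set: MaskSet,
    config: MeasureConfig | None = None,
    *,
    return_instances: bool = False,
):
    """Measure one calibrated mask set; returns a nested per-image record.

    With ``return_instances=True`` also returns the list of GBM candidate
    instances (needed by feature assembly for shape statistics and the
    default embedding).
    """
    config = config or MeasureConfig()
    calib = mask_set.calibration
    gbm_rec, insts = measure_gbm(mask_set, config.criteria, method=config.thickness_method)
    accepted = [i for i in insts if i.accepted]

    gbm_union = np.zeros(calib.shape, dtype=bool)
    for i in accepted:
        gbm_union |= i.full_mask()
    gbm_len_nm = gbm_rec["total_skeleton_len_nm"]

    if gbm_len_nm > 0:
        n_fp = count_fp_near_gbm(mask_set, gbm_union, max_dist_px=config.fp_max_dist_px)
        fp = fp_profile(n_fp, gbm_len_nm, config.reference_density_per_um)
        fp_rec = {
            "fp_measured": True,
            "fp_count": fp.fp_count,
            "gbm_length_um": fp.gbm_length_um,
            "fp_density_per_um": fp.density_per_um,
            "effacement_fraction": fp.effacement_fraction,
            "fusion_grade": fp.grade.value,
            "diffuse_flag": fp.diffuse_flag,
        }
    else:
        fp_rec = {
            "fp_measured": False,
            "fp_count": 0,
            "gbm_length_um": 0.0,
            "fp_density_per_um": np.nan,
            "effacement_fraction": np.nan,
            "fusion_grade": None,
            "diffuse_flag": False,
        }

    edd = edd_presence(mask_set.by_class("EDD"), calib, config.min_edd_area_nm2)
    record = {
        "image_id": mask_set.image_id,
        **gbm_rec,
        **fp_rec,
        "edd_present": edd.edd_present,
        "edd_count": edd.edd_count,
        "edd_area_nm2": edd.total_area_nm2,
        "instances": instance_rows(mask_set.image_id, insts),
    }
    if return_instances:
        return record, insts
    return record


def featurize_mask_set(mask_set: MaskSet, config: MeasureConfig | None = None, *, use_embedding: bool = True):
    """Measure one mask set and assemble its classifier feature vector.

    Returns ``(record, features)`` where ``features`` is a named pandas
    Series following the fixed feature schema.
    """
    from .subtype_classifier import assemble_features

    record, insts = measure_mask_set(mask_set, config, return_instances=True)
    feats = assemble_features(record, instances=insts, use_embedding=use_embedding)
    return record, feats
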