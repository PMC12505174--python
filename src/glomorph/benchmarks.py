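"""Reusable phantom benchmarks for the measurement engine.

These routines generate seeded phantom datasets and run the measurement
pipeline on them; they back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom_generator import PhantomSpec, generate_phantom
from .pipeline import MeasureConfig, measure_mask_set


def run_thickness_sweep(seed: int = 0) -> pd.DataFrame:
    """Both thickness estimators on a 10 x 5 grid of widths and calibrations.

    Widths span 150–800 nm and pixel sizes 1–4 nm/px (50 ribbons in all,
    with mild waviness and boundary noise); returns one row per ribbon with
    the true width and both estimates in nm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for width_nm in np.linspace(150, 800, 10):
        for npp in (1.0, 1.75, 2.5, 3.25, 4.0):
            wpx = width_nm / npp
            spec = PhantomSpec(
                nm_per_pixel=npp,
                image_height=int(wpx + 80),
                image_width=int(max(6 * wpx, 400)),
                width_nm=float(width_nm),
                waviness_amplitude_px=float(0.1 * wpx),
                waviness_period_px=float(max(2 * wpx, 250)),
                boundary_noise_sd_px=0.5,
            )
            ms, _ = generate_phantom(spec, int(rng.integers(2**31)))
            rec = measure_mask_set(ms, MeasureConfig())
            r = rec["instances"][0]
            rows.append(
                {
                    "width_nm": width_nm,
                    "nm_per_px": npp,
                    "skel_nm": r["thickness_skeleton_nm"],
                    "bnd_nm": r["thickness_boundary_nm"],
                }
            )
    return pd.DataFrame(rows)


def run_filtering_phantom(seed: int = 5) -> tuple[int, int]:
    """10 true ribbons + 5 compact blob artifacts across 5 phantom images.

    Returns ``(accepted_ribbons, rejected_artifacts)`` under the default
    filter criteria.
    """
    accepted_ribbons = rejected_artifacts = 0
    for k in range(5):
        spec = PhantomSpec(
            nm_per_pixel=8.0, image_height=224, image_width=768, width_nm=350.0,
            waviness_amplitude_px=10, waviness_period_px=300, boundary_noise_sd_px=0.5,
            ribbon_count=2, artifact_count=1, artifact_radius_px=20.0,
        )
        ms, _ = generate_phantom(spec, seed + k)
        rec = measure_mask_set(ms, MeasureConfig())
        for row in rec["instances"]:
            is_artifact = row["instance_id"] >= 900
            if is_artifact and not row["accepted"]:
                rejected_artifacts += 1
            if not is_artifact and row["accepted"]:
                accepted_ribbons += 1
    return accepted_ribbons, rejected_artifacts
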