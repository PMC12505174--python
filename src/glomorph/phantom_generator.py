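"""Synthetic calibrated mask phantoms for the whole measurement pipeline.

Real TEM glomerular ultrastructure datasets are not redistributable, so
every downstream module is exercised on phantoms: GBM ribbons of controlled
true width, waviness and boundary noise; rows of foot-process (FP) blobs
along one ribbon side with a controlled contiguous effaced fraction
(effacement is modeled as FP *absence* over a fraction of membrane length,
matching the density-based detection route); elliptical electron-dense
deposit (EDD) blobs on the opposite side; and compact blob artifacts that
emulate false-positive GBM detections.

Every phantom carries its generative ground truth (true width, FP count,
effaced fraction, deposit areas, subtype label), and everything is
reproducible from a single integer seed.  Subtype-conditioned parameter
presets for the 7 glomerulopathy classes live in ``presets/subtypes.yaml``;
they encode textbook ultrastructure (thin membranes in TBMN, thickened in
MN/DN, diffuse effacement in MCD/MN, deposits in immune-mediated disease)
and are explicitly synthetic calibration values, not measurements from any
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .mask_io import Calibration, LabeledInstance, MaskSet

#: The 7 glomerulopathy subtypes, fixed order.
SUBTYPES = ("MCD", "MN", "IgA", "LN", "DN", "MsPGN", "TBMN")


@dataclass
class PhantomSpec:
    """Generative parameters for one phantom image."""

    nm_per_pixel: float = 2.0
    image_height: int = 256
    image_width: int = 512
    # ribbon
    width_nm: float = 350.0
    waviness_amplitude_px: float = 0.0
    waviness_period_px: float = 200.0
    boundary_noise_sd_px: float = 0.0
    ribbon_count: int = 1
    # foot processes
    reference_density_per_um: float = 5.0
    effaced_fraction: float = 0.0
    fp_enabled: bool = False
    # deposits
    edd_present: bool = False
    edd_count: int = 0
    edd_area_mean_nm2: float = 20000.0
    edd_area_sd_nm2: float = 4000.0
    # false-positive artifacts
    artifact_count: int = 0
    artifact_radius_px: float = 20.0
    subtype: str | None = None

    def calibration(self) -> Calibration:
        return Calibration(self.nm_per_pixel, self.image_width, self.image_height)


@dataclass
class PhantomTruth:
    """Ground truth recorded at generation time."""

    widths_nm: list[float] = field(default_factory=list)
    centerline_len_px: list[float] = field(default_factory=list)
    fp_count: int = 0
    fp_density_per_um: float = 0.0
    effaced_fraction: float = 0.0
    edd_present: bool = False
    edd_count: int = 0
    edd_total_area_nm2: float = 0.0
    subtype: str | None = None
    n_true_ribbons: int = 0
    n_artifacts: int = 0


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _centerline(spec: PhantomSpec, row0: float, rng: np.random.Generator, step: float = 0.25):
    """Dense sinusoidal centerline samples spanning the image width."""
    x = np.arange(-2.0, spec.image_width + 2.0, step)
    if spec.waviness_amplitude_px > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y = row0 + spec.waviness_amplitude_px * np.sin(2 * np.pi * x / spec.waviness_period_px + phase)
    else:
        y = np.full_like(x, row0)
    pts = np.column_stack([y, x])
    inside = (x >= -0.5) & (x <= spec.image_width - 0.5)
    seg = np.linalg.norm(np.diff(pts[inside], axis=0), axis=1)
    return pts, float(seg.sum())


def generate_gbm_ribbon(
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    row0: float | None = None,
    instance_id: int = 1,
) -> tuple[LabeledInstance, dict]:
    """One GBM ribbon: pixels within half the true width of a smooth centerline.

    Boundary noise perturbs the local half-width with a smoothed Gaussian
    field.  Returns the instance and a truth dict with the exact width and
    centerline length.
    """
    width_px = spec.width_nm / spec.nm_per_pixel
    if width_px < 3:
        raise ValueError(f"ribbon width {spec.width_nm} nm is < 3 px at {spec.nm_per_pixel} nm/px")
    if row0 is None:
        row0 = spec.image_height / 2.0
    pts, length_px = _centerline(spec, row0, rng)
    half = np.full(len(pts), width_px / 2.0)
    if spec.boundary_noise_sd_px > 0:
        noise = rng.normal(0.0, spec.boundary_noise_sd_px, len(pts))
        half = half + uniform_filter1d(noise, size=121, mode="nearest")
    tree = cKDTree(pts)
    margin = int(np.ceil(width_px / 2 + spec.waviness_amplitude_px + 4 * spec.boundary_noise_sd_px + 2))
    r_lo = max(int(row0 - spec.waviness_amplitude_px) - margin, 0)
    r_hi = min(int(row0 + spec.waviness_amplitude_px) + margin, spec.image_height - 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi + 1), np.arange(spec.image_width), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, idx = tree.query(pix)
    keep = d <= half[idx]
    mask = np.zeros((spec.image_height, spec.image_width), dtype=bool)
    mask[rr.ravel()[keep], cc.ravel()[keep]] = True
    inst = LabeledInstance(instance_id=instance_id, class_label="GBM", pixel_mask=mask)
    truth = {
        "width_nm": spec.width_nm,
        "width_px": width_px,
        "centerline_len_px": length_px,
        "centerline": pts,
        "row0": row0,
    }
    return inst, truth


def generate_fp_band(
    spec: PhantomSpec,
    rng: np.random.Generator,
    ribbon_truth: dict,
    *,
    first_id: int = 100,
) -> tuple[list[LabeledInstance], dict]:
    """FP blobs along the upper ribbon side at the reference spacing.

    A contiguous stretch covering ``effaced_fraction`` of the centerline
    carries no FPs; elsewhere blobs sit at spacing ``1/ρ_ref``.
    """
    f = float(np.clip(spec.effaced_fraction, 0.0, 1.0))
    pts = ribbon_truth["centerline"]
    width_px = ribbon_truth["width_px"]
    seg = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = seg[-1]
    spacing_px = (1000.0 / spec.reference_density_per_um) / spec.nm_per_pixel
    fp_radius = max(min(0.32 * spacing_px, 12.0), 2.0)
    # contiguous effaced window, random start
    s0 = rng.uniform(0.0, total)
    e_len = f * total
    positions = np.arange(spacing_px / 2.0, total, spacing_px)
    in_window = ((positions - s0) % total) < e_len
    keep = positions[~in_window]
    instances: list[LabeledInstance] = []
    h, w = spec.image_height, spec.image_width
    for j, s in enumerate(keep):
        i = int(np.searchsorted(seg, s))
        i = min(max(i, 1), len(pts) - 2)
        tang = pts[i + 1] - pts[i - 1]
        tang = tang / (np.linalg.norm(tang) + 1e-12)
        normal = np.array([-tang[1], tang[0]])
        if normal[0] > 0:  # keep the upward (negative-row) side
            normal = -normal
        normal = normal / (np.linalg.norm(normal) + 1e-12)
        center = pts[i] + normal * (width_px / 2.0 + fp_radius + 2.0)
        r0, c0 = center
        if not (fp_radius <= r0 < h - fp_radius and fp_radius <= c0 < w - fp_radius):
            continue
        m = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((r0, c0), fp_radius, shape=(h, w))
        m[rr, cc] = True
        instances.append(LabeledInstance(instance_id=first_id + j, class_label="FP", pixel_mask=m))
    length_um = total * spec.nm_per_pixel / 1000.0
    truth = {
        "fp_count": len(instances),
        "effaced_fraction": f,
        "density_per_um": len(instances) / length_um if length_um > 0 else 0.0,
        "reference_density_per_um": spec.reference_density_per_um,
    }
    return instances, truth


def generate_edd_blobs(
    spec: PhantomSpec,
    rng: np.random.Generator,
    ribbon_truth: dict,
    *,
    first_id: int = 500,
) -> tuple[list[LabeledInstance], dict]:
    """Elliptical deposits adjacent to the lower ribbon side."""
    if not spec.edd_present or spec.edd_count <= 0:
        return [], {"edd_present": False, "edd_count": 0, "edd_total_area_nm2": 0.0}
    pts = ribbon_truth["centerline"]
    width_px = ribbon_truth["width_px"]
    h, w = spec.image_height, spec.image_width
    instances: list[LabeledInstance] = []
    total_area_px2 = 0.0
    attempts = 0
    while len(instances) < spec.edd_count and attempts < spec.edd_count * 20:
        attempts += 1
        area_nm2 = max(rng.normal(spec.edd_area_mean_nm2, spec.edd_area_sd_nm2), 200.0)
        area_px2 = area_nm2 / spec.nm_per_pixel**2
        aspect = rng.uniform(1.2, 1.8)
        b = np.sqrt(area_px2 / (np.pi * aspect))
        a = aspect * b
        i = rng.integers(10, len(pts) - 10)
        center = pts[i] + np.array([1.0, 0.0]) * (width_px / 2.0 + a + 3.0)
        r0, c0 = center
        if not (a + 1 <= r0 < h - a - 1 and a + 1 <= c0 < w - a - 1):
            continue
        m = np.zeros((h, w), dtype=bool)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=rng.uniform(0, np.pi))
        m[rr, cc] = True
        if not m.any():
            continue
        instances.append(
            LabeledInstance(instance_id=first_id + len(instances), class_label="EDD", pixel_mask=m)
        )
        total_area_px2 += float(m.sum())
    truth = {
        "edd_present": len(instances) > 0,
        "edd_count": len(instances),
        "edd_total_area_nm2": total_area_px2 * spec.nm_per_pixel**2,
    }
    return instances, truth


def generate_artifacts(
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    first_id: int = 900,
) -> list[LabeledInstance]:
    """Compact blob artifacts labeled GBM, emulating false-positive detections."""
    h, w = spec.image_height, spec.image_width
    out: list[LabeledInstance] = []
    for k in range(spec.artifact_count):
        rad = spec.artifact_radius_px * rng.uniform(0.8, 1.2)
        r0 = rng.uniform(rad + 1, h - rad - 1)
        c0 = rng.uniform(rad + 1, w - rad - 1)
        m = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((r0, c0), rad, shape=(h, w))
        m[rr, cc] = True
        out.append(LabeledInstance(instance_id=first_id + k, class_label="GBM", pixel_mask=m))
    return out


# ---------------------------------------------------------------------------
# whole phantoms & cohorts
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | int) -> tuple[MaskSet, PhantomTruth]:
    """Assemble one full phantom image: ribbons, FPs, EDDs, artifacts."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    calib = spec.calibration()
    truth = PhantomTruth(subtype=spec.subtype)
    instances: list[LabeledInstance] = []
    ribbon_truths = []
    n_rib = max(spec.ribbon_count, 1)
    rows = (np.linspace(0.3, 0.7, n_rib) if n_rib > 1 else np.array([0.5])) * spec.image_height
    for k in range(spec.ribbon_count):
        inst, rt = generate_gbm_ribbon(spec, rng, row0=float(rows[k]), instance_id=k + 1)
        instances.append(inst)
        ribbon_truths.append(rt)
        truth.widths_nm.append(rt["width_nm"])
        truth.centerline_len_px.append(rt["centerline_len_px"])
    truth.n_true_ribbons = spec.ribbon_count
    if spec.fp_enabled and ribbon_truths:
        total_fp = 0
        total_len_um = 0.0
        for k, rt in enumerate(ribbon_truths):
            fps, ft = generate_fp_band(spec, rng, rt, first_id=100 + 1000 * k)
            instances.extend(fps)
            total_fp += ft["fp_count"]
            total_len_um += rt["centerline_len_px"] * spec.nm_per_pixel / 1000.0
        truth.fp_count = total_fp
        truth.effaced_fraction = float(np.clip(spec.effaced_fraction, 0, 1))
        truth.fp_density_per_um = total_fp / total_len_um if total_len_um else 0.0
    if spec.edd_present and ribbon_truths:
        edds, et = generate_edd_blobs(spec, rng, ribbon_truths[-1])
        instances.extend(edds)
        truth.edd_present = et["edd_present"]
        truth.edd_count = et["edd_count"]
        truth.edd_total_area_nm2 = et["edd_total_area_nm2"]
    arts = generate_artifacts(spec, rng)
    instances.extend(arts)
    truth.n_artifacts = len(arts)
    mask_set = MaskSet(calibration=calib, instances=instances, image_id=f"phantom-{spec.subtype or 'x'}")
    return mask_set, truth


def load_preset_table(path: str | Path | None = None) -> dict:
    """Load the subtype preset table (shipped YAML by default)."""
    if path is None:
        with resources.files("glomorph.presets").joinpath("subtypes.yaml").open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def spec_from_preset(preset: dict, common: dict, rng: np.random.Generator, subtype: str) -> PhantomSpec:
    """Draw one sample's generative parameters from a subtype preset."""
    width = float(np.clip(rng.normal(preset["thickness_nm"]["mean"], preset["thickness_nm"]["sd"]),
                          common["min_thickness_nm"], common["max_thickness_nm"]))
    f = float(np.clip(rng.normal(preset["effaced_fraction"]["mean"], preset["effaced_fraction"]["sd"]), 0.0, 1.0))
    edd_present = bool(rng.random() < preset["edd_prob"])
    edd_count = int(max(round(rng.normal(preset["edd_count"]["mean"], preset["edd_count"]["sd"])), 1)) if edd_present else 0
    return PhantomSpec(
        nm_per_pixel=common["nm_per_pixel"],
        image_height=common["image_height"],
        image_width=common["image_width"],
        width_nm=width,
        waviness_amplitude_px=float(rng.uniform(*common["waviness_amplitude_px"])),
        waviness_period_px=float(rng.uniform(*common["waviness_period_px"])),
        boundary_noise_sd_px=common["boundary_noise_sd_px"],
        reference_density_per_um=common["reference_density_per_um"],
        effaced_fraction=f,
        fp_enabled=True,
        edd_present=edd_present,
        edd_count=edd_count,
        edd_area_mean_nm2=preset["edd_area_nm2"]["mean"],
        edd_area_sd_nm2=preset["edd_area_nm2"]["sd"],
        subtype=subtype,
    )


def generate_cohort(
    n: int,
    class_mix: dict[str, float] | None = None,
    preset_table: dict | None = None,
    seed: int = 0,
) -> list[tuple[MaskSet, PhantomTruth]]:
    """Generate a subtype-labeled cohort of phantom mask sets.

    Class counts use deterministic largest-remainder allocation (a balanced
    mix over 7 classes with n=700 gives exactly 100 per class); per-sample
    parameters are drawn from the subtype's preset distributions.  Fully
    reproducible from ``seed``.
    """
    table = preset_table or load_preset_table()
    common = table["common"]
    presets = table["subtypes"]
    if class_mix is None:
        class_mix = {s: 1.0 / len(SUBTYPES) for s in SUBTYPES}
    unknown = set(class_mix) - set(presets)
    if unknown:
        raise ValueError(f"unknown subtype(s) in class mix: {sorted(unknown)}")
    labels = sorted(class_mix)
    raw = np.array([class_mix[s] * n for s in labels])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(rem):
        counts[order[i % len(labels)]] += 1
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n)
    out: list[tuple[MaskSet, PhantomTruth]] = []
    k = 0
    for lab, cnt in zip(labels, counts):
        for _ in range(cnt):
            rng = np.random.default_rng(children[k])
            spec = spec_from_preset(presets[lab], common, rng, lab)
            ms, truth = generate_phantom(spec, rng)
            ms.image_id = f"cohort-{k:04d}-{lab}"
            out.append((ms, truth))
            k += 1
    return out
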