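"""Synthetic abdominal CT phantoms with known L3 position and tissue labels.

The generator emulates the statistical structure an L3-detection /
body-composition pipeline relies on: a trunk with subcutaneous fat, an
abdominal-wall and paraspinal muscle compartment, visceral fat, a segmented
vertebral column with disc gaps, lungs in the cranial third, a pelvic girdle
caudally, and optional hard cases (arms in the field of view, a high-density
vertebral implant emulating cementoplasty).  Geometry is stylized —
ellipses and cylinders — because the downstream operators only need
contrast, topology and Hounsfield-unit statistics, not anatomical meshes.

Conventions: axis 0 is craniocaudal (caudal -> cranial), axis 1
anteroposterior (anterior -> posterior), axis 2 left -> right;
``z_mm = slice_index * spacing_z`` with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .ctio import CTVolume, TissueLabelMap, LABEL_BACKGROUND, LABEL_OTHER, LABEL_SM, LABEL_VAT, LABEL_SAT

__all__ = [
    "PhantomSpec",
    "CohortVariability",
    "GroundTruth",
    "generate_phantom",
    "generate_l3_slice",
    "generate_cohort",
    "iter_cohort",
    "trunk_mask",
]

# HU windows the phantom must respect (manual-threshold semantics).
MUSCLE_HU_WINDOW = (-29.0, 150.0)
ADIPOSE_HU_WINDOW = (-500.0, -30.0)

# internal construction codes (not the public label codes)
_AIR = 0
_LUNG = 1
_SAT = 2
_MUSCLE = 3
_VAT = 4
_SOFT = 5     # solid organ / bowel, HU overlaps muscle window on purpose
_DISC = 6     # intervertebral disc
_BONE = 7
_IMPLANT = 8
_ARM_SAT = 9
_ARM_MUSCLE = 10

_DEFAULT_TISSUE_HU = {
    "air": (-1000.0, 0.0),
    "lung": (-800.0, 50.0),
    "sat": (-105.0, 20.0),
    "vat": (-90.0, 20.0),
    "muscle": (45.0, 15.0),
    "soft": (50.0, 10.0),
    "disc": (70.0, 10.0),
    "bone": (400.0, 100.0),
    "implant": (1500.0, 100.0),
}

_CODE_TO_TISSUE = {
    _AIR: "air",
    _LUNG: "lung",
    _SAT: "sat",
    _MUSCLE: "muscle",
    _VAT: "vat",
    _SOFT: "soft",
    _DISC: "disc",
    _BONE: "bone",
    _IMPLANT: "implant",
    _ARM_SAT: "sat",
    _ARM_MUSCLE: "muscle",
}

_CODE_TO_LABEL = {
    _AIR: LABEL_BACKGROUND,
    _LUNG: LABEL_OTHER,
    _SAT: LABEL_SAT,
    _MUSCLE: LABEL_SM,
    _VAT: LABEL_VAT,
    _SOFT: LABEL_OTHER,
    _DISC: LABEL_OTHER,
    _BONE: LABEL_OTHER,
    _IMPLANT: LABEL_OTHER,
    # arms are non-pertinent structures the pipeline must learn to exclude
    _ARM_SAT: LABEL_BACKGROUND,
    _ARM_MUSCLE: LABEL_BACKGROUND,
}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic abdominal CT volume.

    ``tissue_hu`` maps tissue name to (mean HU, sd HU); per-voxel texture is
    drawn from a +-3 sd truncated normal so that, with ``noise_sd_hu = 0``,
    every muscle voxel is guaranteed inside [-29, 150] HU and every adipose
    voxel inside [-500, -30] HU.
    """

    shape_vox: tuple[int, int, int] = (200, 512, 512)
    spacing_mm: tuple[float, float, float] = (2.5, 0.98, 0.98)
    n_vertebrae: int = 8
    l3_index_from_caudal: int = 3
    body_halfaxes_mm: tuple[float, float] = (110.0, 160.0)  # (AP, LR) semi-axes
    tissue_hu: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUE_HU))
    arms_present: bool = False
    implant_present: bool = False
    noise_sd_hu: float = 10.0
    patient_height_m: float = 1.70
    seed: int = 0
    # stylized-geometry knobs (mm)
    vertebra_height_mm: float = 35.0
    disc_gap_mm: float = 8.0
    column_start_z_mm: float = 95.0
    vertebra_radius_mm: float = 16.0
    sat_thickness_mm: float = 18.0
    muscle_wall_mm: float = 10.0

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Reduced-scale preset: 96 x 96 in-plane at 2.25 mm, 432 mm extent."""
        base = dict(
            shape_vox=(144, 96, 96),
            spacing_mm=(3.0, 2.25, 2.25),
            n_vertebrae=6,
            body_halfaxes_mm=(72.0, 88.0),
        )
        base.update(overrides)
        return cls(**base)

    # ---- derived quantities -------------------------------------------------

    @property
    def extent_z_mm(self) -> float:
        return self.shape_vox[0] * self.spacing_mm[0]

    @property
    def vertebra_pitch_mm(self) -> float:
        return self.vertebra_height_mm + self.disc_gap_mm

    @property
    def l3_z_mm(self) -> float:
        """Craniocaudal position of the L3 vertebral-body center."""
        start = self.column_start_z_mm + (self.l3_index_from_caudal - 1) * self.vertebra_pitch_mm
        return start + self.vertebra_height_mm / 2.0

    @property
    def l3_extent_mm(self) -> tuple[float, float]:
        start = self.column_start_z_mm + (self.l3_index_from_caudal - 1) * self.vertebra_pitch_mm
        return (start, start + self.vertebra_height_mm)

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if any(n <= 0 for n in self.shape_vox):
            raise PhantomSpecError(f"shape must be positive, got {self.shape_vox}")
        if self.n_vertebrae < 5:
            raise PhantomSpecError("n_vertebrae must be >= 5")
        if not (1 <= self.l3_index_from_caudal <= self.n_vertebrae):
            raise PhantomSpecError("l3_index_from_caudal out of range")
        if self.noise_sd_hu < 0:
            raise PhantomSpecError("noise_sd_hu must be >= 0")
        if self.patient_height_m <= 0:
            raise PhantomSpecError("patient_height_m must be > 0")
        mu, sd = self.tissue_hu["muscle"]
        if not (MUSCLE_HU_WINDOW[0] <= mu - 3 * sd and mu + 3 * sd <= MUSCLE_HU_WINDOW[1]):
            raise PhantomSpecError("muscle mean +- 3 sd must lie inside [-29, 150] HU")
        for t in ("vat", "sat"):
            mu, sd = self.tissue_hu[t]
            if not (ADIPOSE_HU_WINDOW[0] <= mu - 3 * sd and mu + 3 * sd <= ADIPOSE_HU_WINDOW[1]):
                raise PhantomSpecError(f"{t} mean +- 3 sd must lie inside [-500, -30] HU")
        if self.tissue_hu["bone"][0] <= 150:
            raise PhantomSpecError("bone mean must exceed 150 HU")
        if self.tissue_hu["lung"][0] >= -500:
            raise PhantomSpecError("lung mean must be below -500 HU")
        top = self.column_start_z_mm + self.n_vertebrae * self.vertebra_pitch_mm
        if top > self.extent_z_mm:
            raise PhantomSpecError("vertebral column does not fit in the volume extent")


@dataclass
class GroundTruth:
    """Construction truth for one phantom: L3 position and L3-slice labels."""

    l3_z_mm: float
    l3_slice_index: int
    tissue_labels: TissueLabelMap
    vertebra_extent_mm: tuple[float, float]
    meta: dict = field(default_factory=dict)


# ---- geometry painting ------------------------------------------------------


def _plane_coords(spec: PhantomSpec):
    ny, nx = spec.shape_vox[1], spec.shape_vox[2]
    sy, sx = spec.spacing_mm[1], spec.spacing_mm[2]
    y = (np.arange(ny) + 0.5) * sy
    x = (np.arange(nx) + 0.5) * sx
    return np.meshgrid(y, x, indexing="ij")


def _ellipse(yy, xx, cy, cx, ay, ax):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def trunk_mask(spec: PhantomSpec) -> np.ndarray:
    """In-plane boolean mask of the trunk ellipse (same for every slice)."""
    yy, xx = _plane_coords(spec)
    cy = spec.shape_vox[1] * spec.spacing_mm[1] / 2.0
    cx = spec.shape_vox[2] * spec.spacing_mm[2] / 2.0
    by, bx = spec.body_halfaxes_mm
    return _ellipse(yy, xx, cy, cx, by, bx)


def _paint_plane_sets(spec: PhantomSpec):
    """Precompute the in-plane masks shared by all slices."""
    yy, xx = _plane_coords(spec)
    cy = spec.shape_vox[1] * spec.spacing_mm[1] / 2.0
    cx = spec.shape_vox[2] * spec.spacing_mm[2] / 2.0
    by, bx = spec.body_halfaxes_mm
    t_sat, t_mus = spec.sat_thickness_mm, spec.muscle_wall_mm

    body = _ellipse(yy, xx, cy, cx, by, bx)
    inner1 = _ellipse(yy, xx, cy, cx, by - t_sat, bx - t_sat)
    inner2 = _ellipse(yy, xx, cy, cx, by - t_sat - t_mus, bx - t_sat - t_mus)

    spine_cy = cy + 0.55 * by
    spine = _ellipse(yy, xx, spine_cy, cx, spec.vertebra_radius_mm, spec.vertebra_radius_mm)
    para_off = spec.vertebra_radius_mm + 14.0
    paraspinal = (
        _ellipse(yy, xx, spine_cy - 2.0, cx - para_off, 20.0, 16.0)
        | _ellipse(yy, xx, spine_cy - 2.0, cx + para_off, 20.0, 16.0)
    ) & inner2
    organ = _ellipse(yy, xx, cy - 0.4 * by, cx - 0.35 * bx, 0.38 * by, 0.40 * bx) & inner2
    lungs = (
        _ellipse(yy, xx, cy - 0.25 * by, cx - 0.43 * bx, 0.42 * by, 0.30 * bx)
        | _ellipse(yy, xx, cy - 0.25 * by, cx + 0.43 * bx, 0.42 * by, 0.30 * bx)
    ) & inner2
    wings = (
        _ellipse(yy, xx, cy + 0.30 * by, cx - 0.45 * bx, 25.0, 0.32 * bx)
        | _ellipse(yy, xx, cy + 0.30 * by, cx + 0.45 * bx, 25.0, 0.32 * bx)
    )
    sacrum = (np.abs(yy - spine_cy) <= 10.0) & (np.abs(xx - cx) <= 0.43 * bx)
    pelvis = (wings | sacrum) & body
    arm_l = _ellipse(yy, xx, cy, cx - bx - 10.0, 14.0, 7.0)
    arm_r = _ellipse(yy, xx, cy, cx + bx + 10.0, 14.0, 7.0)
    arm_core_l = _ellipse(yy, xx, cy, cx - bx - 10.0, 10.0, 4.0)
    arm_core_r = _ellipse(yy, xx, cy, cx + bx + 10.0, 10.0, 4.0)
    implant = _ellipse(yy, xx, spine_cy, cx, 8.0, 8.0)

    return {
        "body": body, "sat": body & ~inner1, "muscle": inner1 & ~inner2, "vat": inner2,
        "spine": spine, "paraspinal": paraspinal, "organ": organ, "lungs": lungs,
        "pelvis": pelvis, "arms": (arm_l | arm_r) & ~body,
        "arm_core": (arm_core_l | arm_core_r) & ~body, "implant": implant,
    }


def _vertebra_spans(spec: PhantomSpec) -> list[tuple[float, float]]:
    return [
        (spec.column_start_z_mm + k * spec.vertebra_pitch_mm,
         spec.column_start_z_mm + k * spec.vertebra_pitch_mm + spec.vertebra_height_mm)
        for k in range(spec.n_vertebrae)
    ]


def _paint_codes(spec: PhantomSpec, z_indices: np.ndarray, implant_vertebra: int | None) -> np.ndarray:
    """Tissue-code image stack for the requested slice indices."""
    sets = _paint_plane_sets(spec)
    dz = spec.spacing_mm[0]
    z_mm = z_indices * dz  # slice centers, z = index * spacing
    n = len(z_indices)
    codes = np.zeros((n,) + sets["body"].shape, dtype=np.uint8)

    codes[:, sets["sat"]] = _SAT
    codes[:, sets["muscle"]] = _MUSCLE
    codes[:, sets["vat"]] = _VAT
    codes[:, sets["organ"]] = _SOFT
    codes[:, sets["paraspinal"]] = _MUSCLE

    lung_lo, lung_hi = spec.extent_z_mm - 115.0, spec.extent_z_mm - 8.0
    in_lung = (z_mm >= lung_lo) & (z_mm <= lung_hi)
    for i in np.nonzero(in_lung)[0]:
        codes[i][sets["lungs"]] = _LUNG

    # vertebral column: bodies are bone, gaps are disc
    col_lo = spec.column_start_z_mm
    col_hi = col_lo + spec.n_vertebrae * spec.vertebra_pitch_mm - spec.disc_gap_mm
    spans = _vertebra_spans(spec)
    for i, z in enumerate(z_mm):
        if col_lo <= z <= col_hi:
            in_body = any(lo <= z <= hi for lo, hi in spans)
            codes[i][sets["spine"]] = _BONE if in_body else _DISC
            if implant_vertebra is not None:
                lo, hi = spans[implant_vertebra]
                if lo <= z <= hi:
                    codes[i][sets["implant"] & sets["spine"]] = _IMPLANT

    pel_lo, pel_hi = 10.0, 82.0
    in_pelvis = (z_mm >= pel_lo) & (z_mm <= pel_hi)
    for i in np.nonzero(in_pelvis)[0]:
        codes[i][sets["pelvis"]] = _BONE

    if spec.arms_present:
        codes[:, sets["arms"]] = _ARM_SAT
        codes[:, sets["arm_core"]] = _ARM_MUSCLE
    return codes


def _truncated_normal(rng: np.random.Generator, k: int, bound: float = 3.0,
                      max_rounds: int = 8) -> np.ndarray:
    """Standard normal draws truncated to [-bound, bound] by rejection."""
    vals = rng.standard_normal(k)
    for _ in range(max_rounds):
        bad = np.abs(vals) > bound
        m = int(bad.sum())
        if m == 0:
            break
        vals[bad] = rng.standard_normal(m)
    return np.clip(vals, -bound, bound)


def _sample_hu(codes: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    hu = np.full(codes.shape, spec.tissue_hu["air"][0], dtype=np.float32)
    for code, tissue in _CODE_TO_TISSUE.items():
        if tissue == "air":
            continue
        mask = codes == code
        k = int(mask.sum())
        if k == 0:
            continue
        mean, sd = spec.tissue_hu.get(tissue, _DEFAULT_TISSUE_HU[tissue])
        if sd > 0:
            vals = _truncated_normal(rng, k) * sd + mean
        else:
            vals = np.full(k, mean)
        hu[mask] = vals
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape).astype(np.float32)
    return np.clip(hu, -1024.0, 3071.0).astype(np.float32)


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Build one phantom volume and its construction ground truth.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    implant_vertebra = int(rng.integers(spec.n_vertebrae)) if spec.implant_present else None

    z_idx = np.arange(spec.shape_vox[0])
    codes = _paint_codes(spec, z_idx, implant_vertebra)
    hu = _sample_hu(codes, spec, rng)
    vol = CTVolume(voxels=hu, spacing_mm=spec.spacing_mm)

    l3_z = spec.l3_z_mm
    l3_idx = int(np.clip(_round_half_up(l3_z / spec.spacing_mm[0]), 0, spec.shape_vox[0] - 1))
    labels = np.vectorize(_CODE_TO_LABEL.get, otypes=[np.uint8])(codes[l3_idx])
    label_map = TissueLabelMap(labels=labels, spacing_mm=(spec.spacing_mm[1], spec.spacing_mm[2]))

    dz = spec.spacing_mm[0]
    lung_slices = np.nonzero((codes == _LUNG).any(axis=(1, 2)))[0]
    pelvis = _paint_plane_sets(spec)["pelvis"]
    pel_slices = np.nonzero([(codes[i] == _BONE)[pelvis].any() and i * dz <= 82.0 for i in z_idx])[0]
    meta = {
        "spec": spec,
        "implant_vertebra": implant_vertebra,
        "lung_centroid_z_mm": float(lung_slices.mean() * dz) if lung_slices.size else None,
        "pelvis_centroid_z_mm": float(pel_slices.mean() * dz) if pel_slices.size else None,
    }
    gt = GroundTruth(
        l3_z_mm=l3_z,
        l3_slice_index=l3_idx,
        tissue_labels=label_map,
        vertebra_extent_mm=spec.l3_extent_mm,
        meta=meta,
    )
    return vol, gt


def generate_l3_slice(spec: PhantomSpec) -> tuple[np.ndarray, TissueLabelMap]:
    """The L3 axial slice only: (HU image, tissue label map).

    Uses the same geometry and the same seed stream layout as
    :func:`generate_phantom` restricted to one slice, so it is cheap enough
    to build large slice cohorts for the body-composition task.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    implant_vertebra = int(rng.integers(spec.n_vertebrae)) if spec.implant_present else None
    l3_idx = int(np.clip(_round_half_up(spec.l3_z_mm / spec.spacing_mm[0]), 0, spec.shape_vox[0] - 1))
    codes = _paint_codes(spec, np.array([l3_idx]), implant_vertebra)
    hu = _sample_hu(codes, spec, rng)[0]
    labels = np.vectorize(_CODE_TO_LABEL.get, otypes=[np.uint8])(codes[0])
    return hu, TissueLabelMap(labels=labels, spacing_mm=(spec.spacing_mm[1], spec.spacing_mm[2]))


# ---- cohorts ----------------------------------------------------------------


@dataclass(frozen=True)
class CohortVariability:
    """Per-phantom jitter ranges emulating scanner and patient diversity."""

    spacing_z_choices: Sequence[float] = (1.0, 2.5, 5.0)
    body_scale: tuple[float, float] = (0.85, 1.15)
    vertebra_height_mm: tuple[float, float] = (28.0, 42.0)
    column_start_z_mm: tuple[float, float] = (85.0, 105.0)
    sat_thickness_mm: tuple[float, float] = (13.0, 23.0)
    muscle_wall_mm: tuple[float, float] = (8.0, 13.0)
    height_m: tuple[float, float] = (1.50, 1.90)
    arm_fraction: float = 0.2
    implant_fraction: float = 0.1


def sample_cohort_specs(n: int, base_spec: PhantomSpec, variability: CohortVariability,
                        seed: int) -> list[PhantomSpec]:
    """The seeded per-phantom spec sampler (re-runnable as its own oracle).

    Draw order per phantom is fixed: spacing, body scale, vertebra height,
    column start, SAT thickness, muscle wall, height, arm flag, implant flag,
    child seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    v = variability
    specs = []
    extent = base_spec.extent_z_mm
    for _ in range(n):
        dz = float(rng.choice(np.asarray(v.spacing_z_choices, dtype=float)))
        scale = float(rng.uniform(*v.body_scale))
        vb = float(rng.uniform(*v.vertebra_height_mm))
        z0 = float(rng.uniform(*v.column_start_z_mm))
        sat = float(rng.uniform(*v.sat_thickness_mm))
        wall = float(rng.uniform(*v.muscle_wall_mm))
        height = float(rng.uniform(*v.height_m))
        arms = bool(rng.random() < v.arm_fraction)
        implant = bool(rng.random() < v.implant_fraction)
        child_seed = int(rng.integers(2**31))
        by, bx = base_spec.body_halfaxes_mm
        specs.append(replace(
            base_spec,
            shape_vox=(int(round(extent / dz)),) + tuple(base_spec.shape_vox[1:]),
            spacing_mm=(dz,) + tuple(base_spec.spacing_mm[1:]),
            body_halfaxes_mm=(by * scale, bx * scale),
            vertebra_height_mm=vb,
            column_start_z_mm=z0,
            sat_thickness_mm=sat,
            muscle_wall_mm=wall,
            patient_height_m=height,
            arms_present=arms,
            implant_present=implant,
            seed=child_seed,
        ))
    return specs


def iter_cohort(n: int, base_spec: PhantomSpec | None = None,
                variability: CohortVariability | None = None,
                seed: int = 0) -> Iterator[tuple[CTVolume, GroundTruth]]:
    """Stream ``n`` jittered phantoms (memory-friendly form of the cohort)."""
    base_spec = base_spec or PhantomSpec()
    variability = variability or CohortVariability()
    for spec in sample_cohort_specs(n, base_spec, variability, seed):
        yield generate_phantom(spec)


def generate_cohort(n: int, base_spec: PhantomSpec | None = None,
                    variability: CohortVariability | None = None,
                    seed: int = 0) -> list[tuple[CTVolume, GroundTruth]]:
    """Materialized cohort; see :func:`iter_cohort` for the streaming form."""
    return list(iter_cohort(n, base_spec, variability, seed))
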