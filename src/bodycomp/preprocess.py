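"""Preprocessing: body mask, coronal max projection, pre-crop, 1 mm grid.

The L3-detection task is posed in 2-D on a coronal maximum-intensity
projection: voxels outside a whole-body mask are suppressed, the volume is
collapsed along the anteroposterior axis, rows are rescaled to a fixed
millimetre pitch and padded to a fixed grid, and the annotated L3 position
becomes a thin horizontal band (1 cm thick) for a segmentation network.
Every geometric step records provenance so a predicted row can be mapped
back to an original slice index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .ctio import CTVolume, z_mm_to_slice_index

__all__ = [
    "BACKGROUND_HU",
    "Provenance", "CoronalProjection",
    "BodyMaskConfig", "PrecropConfig", "StandardizeConfig", "AugmentConfig",
    "body_mask", "coronal_max_projection", "precrop", "PrecropResult",
    "standardize", "network_pad", "make_l3_target",
    "row_to_z_mm", "z_mm_to_row", "row_to_slice_index",
    "augment_batch", "hu_to_unit",
]

BACKGROUND_HU = -1000.0


class DegenerateInputError(ValueError):
    """Raised when an input has no usable content (e.g. an all-air volume)."""


def hu_to_unit(hu: np.ndarray, window: tuple[float, float] = (-200.0, 250.0)) -> np.ndarray:
    """Window-and-normalize HU to [0, 1] for network input.

    The default window (-200..250 HU) is a soft-tissue display window: it
    spreads the muscle/fat/organ contrast the networks must discriminate
    over most of the unit interval, while air saturates at 0 and bone,
    implants and contrast material saturate at 1.
    """
    lo, hi = window
    return np.clip((np.asarray(hu, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)


# ---- provenance and coordinate mapping --------------------------------------


@dataclass(frozen=True)
class Provenance:
    """Everything needed to invert a standardized row to a volume position.

    ``row_scale`` is source spacing_z / row_mm (rows per original slice);
    ``crop_offset_mm`` is the caudal cut of the pre-crop in original-volume
    millimetres.  Negative ``pad_top_rows`` records a center crop.
    """

    crop_offset_mm: float
    spacing_z_mm: float
    row_mm: float
    pad_top_rows: int
    pad_left_cols: int
    original_n_slices: int

    @property
    def row_scale(self) -> float:
        return self.spacing_z_mm / self.row_mm


@dataclass
class CoronalProjection:
    """2-D coronal max-intensity image on a fixed grid, with provenance."""

    image: np.ndarray  # rows = craniocaudal (caudal at row 0), cols = left-right
    provenance: Provenance


def row_to_z_mm(row, prov: Provenance):
    """Standardized row -> craniocaudal position in original-volume mm."""
    return (np.asarray(row, dtype=float) - prov.pad_top_rows) * prov.row_mm + prov.crop_offset_mm


def z_mm_to_row(z_mm, prov: Provenance):
    """Original-volume z in mm -> nearest standardized row (half-up)."""
    r = (np.asarray(z_mm, dtype=float) - prov.crop_offset_mm) / prov.row_mm
    return np.floor(r + 0.5).astype(int) + prov.pad_top_rows


def row_to_slice_index(row, prov: Provenance):
    """Standardized row -> original 0-based slice index (half-up rounding)."""
    return z_mm_to_slice_index(row_to_z_mm(row, prov), prov.spacing_z_mm)


# ---- body mask --------------------------------------------------------------


@dataclass(frozen=True)
class BodyMaskConfig:
    threshold_hu: float = -200.0
    closing_mm: float = 5.0
    dilation_mm: float = 5.0
    fill_holes: bool = True  # internal air (lungs, bowel) belongs to the body


def _radius_vox(mm: float, spacing: tuple[float, float, float]) -> tuple[int, ...]:
    return tuple(max(1, int(round(mm / s))) for s in spacing)


def _separable(op, mask: np.ndarray, radii: tuple[int, ...]) -> np.ndarray:
    # box structuring element applied as three 1-D passes (exact for boxes)
    out = mask
    for axis, r in enumerate(radii):
        shape = [1, 1, 1]
        shape[axis] = 2 * r + 1
        out = op(out, structure=np.ones(shape, bool))
    return out


def body_mask(volume: CTVolume, config: BodyMaskConfig | None = None) -> np.ndarray:
    """Whole-body mask: threshold, closing, largest component, dilation.

    Holes enclosed in-plane (lungs, bowel gas) are filled so that the mask
    is a superset of the trunk.  Detached objects (scanner table, arms) are
    removed by the largest-connected-component rule.
    """
    config = config or BodyMaskConfig()
    raw = volume.voxels > config.threshold_hu
    if not raw.any():
        raise DegenerateInputError("body mask is empty: no voxels above threshold")
    radii = _radius_vox(config.closing_mm, volume.spacing_mm)
    closed = _separable(ndimage.binary_erosion,
                        _separable(ndimage.binary_dilation, raw, radii), radii)
    labels, n = ndimage.label(closed)
    if n == 0:
        raise DegenerateInputError("body mask is empty after morphology")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if config.fill_holes:
        for i in range(mask.shape[0]):
            mask[i] = ndimage.binary_fill_holes(mask[i])
    mask = _separable(ndimage.binary_dilation, mask,
                      _radius_vox(config.dilation_mm, volume.spacing_mm))
    return mask


# ---- projection -------------------------------------------------------------


def coronal_max_projection(volume: CTVolume, mask: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along the anteroposterior axis.

    Out-of-mask voxels are set to the background value first, so each output
    pixel (row z, col x) is the maximum in-body HU along y.  Returns the raw
    (n_slices, n_cols) image; :func:`standardize` puts it on the fixed grid.
    """
    if mask.shape != volume.voxels.shape:
        raise ValueError("mask shape must match volume shape")
    vox = np.where(mask, volume.voxels, BACKGROUND_HU)
    return vox.max(axis=1)


# ---- pre-crop ---------------------------------------------------------------


@dataclass(frozen=True)
class PrecropConfig:
    lung_threshold_hu: float = -500.0
    bone_threshold_hu: float = 150.0
    min_centroid_distance_mm: float = 200.0  # crop only beyond 20 cm
    margin_mm: float = 20.0
    # undo the body-mask safety dilation before looking for enclosed air,
    # so the air rim around the body is not mistaken for lung
    mask_erosion_mm: float = 7.0


@dataclass
class PrecropResult:
    volume: CTVolume
    mask: np.ndarray | None
    crop_offset_mm: float
    lung_centroid_z_mm: float | None
    pelvis_centroid_z_mm: float | None
    cropped: bool


def _lung_centroid_z(volume: CTVolume, mask: np.ndarray, cfg: PrecropConfig) -> float | None:
    core = _separable(ndimage.binary_erosion, mask,
                      _radius_vox(cfg.mask_erosion_mm, volume.spacing_mm))
    lung = (volume.voxels < cfg.lung_threshold_hu) & core
    labels, n = ndimage.label(lung)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    return float(ndimage.center_of_mass(comp)[0] * volume.spacing_mm[0])


def _pelvis_centroid_z(volume: CTVolume, mask: np.ndarray, cfg: PrecropConfig) -> float | None:
    """Skeleton centroid of the largest caudal-half bone structure.

    Restricting to the largest caudal component isolates the pelvic girdle
    from the caudal portion of the vertebral column before skeletonization.
    """
    half = volume.n_slices // 2
    bone = (volume.voxels[:half] > cfg.bone_threshold_hu) & mask[:half]
    labels, n = ndimage.label(bone)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    sl = ndimage.find_objects(comp.astype(np.int8), max_label=1)[0]
    skel = skeletonize(comp[sl])
    if not skel.any():
        skel = comp[sl]
    z0 = sl[0].start
    return float((np.nonzero(skel)[0].mean() + z0) * volume.spacing_mm[0])


def precrop(volume: CTVolume, mask: np.ndarray | None = None,
            config: PrecropConfig | None = None) -> PrecropResult:
    """Craniocaudal pre-crop between the pelvic and lung centroids.

    Cropping happens only when the two centroids are more than 20 cm apart;
    a missing lung or pelvis falls back to no crop with a warning.
    """
    config = config or PrecropConfig()
    had_mask = mask is not None
    if mask is None:
        mask = body_mask(volume)
    lung_z = _lung_centroid_z(volume, mask, config)
    pelvis_z = _pelvis_centroid_z(volume, mask, config)
    if lung_z is None or pelvis_z is None:
        missing = "lung" if lung_z is None else "pelvis"
        warnings.warn(f"precrop: {missing} not found, skipping pre-crop")
        return PrecropResult(volume, mask if had_mask else mask, 0.0, lung_z, pelvis_z, False)
    if abs(lung_z - pelvis_z) <= config.min_centroid_distance_mm:
        return PrecropResult(volume, mask, 0.0, lung_z, pelvis_z, False)
    dz = volume.spacing_mm[0]
    lo = max(0, int(np.floor((min(pelvis_z, lung_z) - config.margin_mm) / dz)))
    hi = min(volume.n_slices, int(np.ceil((max(pelvis_z, lung_z) + config.margin_mm) / dz)) + 1)
    cropped = CTVolume(volume.voxels[lo:hi], volume.spacing_mm, volume.origin_mm)
    return PrecropResult(cropped, mask[lo:hi], lo * dz, lung_z, pelvis_z, True)


# ---- standardization --------------------------------------------------------


@dataclass(frozen=True)
class StandardizeConfig:
    """Fixed-grid parameters.

    The full-scale profile mirrors the clinical pipeline exactly: 1 mm per
    row, padding to 1064 x 512, then a network pad to 1088 rows.  The desk
    profile is the reduced-scale analog used for CPU experiments.
    """

    row_mm: float = 1.0
    target_shape: tuple[int, int] = (1064, 512)
    network_rows: int = 1088
    # optional column max-pooling (the L3 band is a per-row structure, so
    # the reduced-scale profile can afford coarse columns)
    col_pool: int = 1

    @classmethod
    def desk(cls) -> "StandardizeConfig":
        return cls(row_mm=3.0, target_shape=(144, 48), network_rows=144, col_pool=2)


def standardize(raw_projection: np.ndarray, spacing_z_mm: float,
                crop_offset_mm: float = 0.0,
                config: StandardizeConfig | None = None) -> CoronalProjection:
    """Rescale rows to ``row_mm`` per pixel and pad to the fixed grid.

    Padding is symmetric with the background value; an input larger than the
    grid is center-cropped with a warning (recorded as negative padding).
    """
    config = config or StandardizeConfig()
    n_slices, n_cols = raw_projection.shape
    n_rows = max(1, int(round(n_slices * spacing_z_mm / config.row_mm)))
    if abs(spacing_z_mm - config.row_mm) < 1e-12:
        scaled = raw_projection.astype(np.float32)
        n_rows = n_slices
    else:
        rr, cc = np.meshgrid(np.arange(n_rows) * config.row_mm / spacing_z_mm,
                             np.arange(n_cols), indexing="ij")
        scaled = ndimage.map_coordinates(
            raw_projection.astype(np.float32), [rr, cc],
            order=1, mode="constant", cval=BACKGROUND_HU)

    if config.col_pool > 1:
        k = config.col_pool
        pad_c = (-scaled.shape[1]) % k
        if pad_c:
            scaled = np.pad(scaled, ((0, 0), (0, pad_c)), constant_values=BACKGROUND_HU)
        # max over column groups: consistent with the maximum-intensity projection
        scaled = scaled.reshape(scaled.shape[0], -1, k).max(axis=2)
        n_cols = scaled.shape[1]

    th, tw = config.target_shape
    out = np.full((th, tw), BACKGROUND_HU, dtype=np.float32)
    if n_rows > th or n_cols > tw:
        warnings.warn(f"projection {n_rows}x{n_cols} exceeds {th}x{tw}; center-cropping")
    pad_top = (th - n_rows) // 2
    pad_left = (tw - n_cols) // 2
    src_r = slice(max(0, -pad_top), max(0, -pad_top) + min(th, n_rows))
    src_c = slice(max(0, -pad_left), max(0, -pad_left) + min(tw, n_cols))
    dst_r = slice(max(0, pad_top), max(0, pad_top) + min(th, n_rows))
    dst_c = slice(max(0, pad_left), max(0, pad_left) + min(tw, n_cols))
    out[dst_r, dst_c] = scaled[src_r, src_c]

    prov = Provenance(
        crop_offset_mm=float(crop_offset_mm),
        spacing_z_mm=float(spacing_z_mm),
        row_mm=float(config.row_mm),
        pad_top_rows=int(pad_top),
        pad_left_cols=int(pad_left),
        original_n_slices=int(n_slices),
    )
    return CoronalProjection(image=out, provenance=prov)


def network_pad(projection: CoronalProjection,
                config: StandardizeConfig | None = None) -> CoronalProjection:
    """Extra symmetric row padding at network entry (e.g. 1064 -> 1088)."""
    config = config or StandardizeConfig()
    h, w = projection.image.shape
    extra = config.network_rows - h
    if extra < 0:
        raise ValueError("network_rows smaller than standardized rows")
    top, bottom = extra // 2, extra - extra // 2
    image = np.pad(projection.image, ((top, bottom), (0, 0)),
                   constant_values=BACKGROUND_HU)
    prov = dc_replace(projection.provenance,
                      pad_top_rows=projection.provenance.pad_top_rows + top)
    return CoronalProjection(image=image, provenance=prov)


def make_l3_target(l3_z_mm: float, provenance: Provenance, shape: tuple[int, int],
                   band_mm: float = 10.0) -> np.ndarray:
    """Binary L3 band: the annotated row extended to 1 cm thickness."""
    row = int(z_mm_to_row(l3_z_mm, provenance))
    k = max(1, int(round(band_mm / provenance.row_mm)))
    start, stop = row - (k - 1) // 2, row - (k - 1) // 2 + k
    if start < 0 or stop > shape[0]:
        warnings.warn(f"L3 band rows [{start}, {stop}) clipped to image border")
    mask = np.zeros(shape, dtype=np.uint8)
    mask[max(0, start):min(shape[0], stop), :] = 1
    return mask


# ---- augmentation -----------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation ranges plus artificial-arm insertion.

    All ranges are half-widths of symmetric uniform draws; zero everywhere
    (and ``arm_probability = 0``) makes augmentation the identity.
    """

    rotate_deg: float = 10.0
    scale: float = 0.1
    translate_px: float = 10.0
    elastic_alpha_px: float = 0.0
    elastic_sigma_px: float = 4.0
    arm_probability: float = 0.0
    arm_halfaxes_px: tuple[float, float] = (10.0, 5.0)
    arm_hu: tuple[float, float] = (45.0, 15.0)
    body_threshold_hu: float = -200.0

    def validate(self) -> None:
        if self.scale < 0 or self.scale >= 1:
            raise ValueError("scale half-width must be in [0, 1)")
        if self.rotate_deg < 0 or self.translate_px < 0 or self.elastic_alpha_px < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.elastic_sigma_px <= 0:
            raise ValueError("elastic_sigma_px must be positive")
        if not (0 <= self.arm_probability <= 1):
            raise ValueError("arm_probability must be in [0, 1]")


def _affine_pair(image, target, angle_deg, scale, shift, cval_img):
    h, w = image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) / scale
    offset = c - rot @ c + np.asarray(shift)
    img = ndimage.affine_transform(image, rot, offset=offset, order=1,
                                   mode="constant", cval=cval_img)
    tgt = ndimage.affine_transform(target, rot, offset=offset, order=0,
                                   mode="constant", cval=0)
    return img, tgt


def _elastic_pair(image, target, alpha, sigma, rng, cval_img):
    h, w = image.shape
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [rr + dy, cc + dx]
    img = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=cval_img)
    tgt = ndimage.map_coordinates(target, coords, order=0, mode="constant", cval=0)
    return img, tgt


def _insert_arm(image, rng, cfg: AugmentConfig):
    """Paint a soft-tissue ellipse lateral to the thresholded body mask."""
    h, w = image.shape
    body = image > cfg.body_threshold_hu
    cols = np.nonzero(body.any(axis=0))[0]
    if cols.size == 0:
        return image
    side = rng.choice([-1, 1])
    edge = cols[0] if side < 0 else cols[-1]
    ay = cfg.arm_halfaxes_px[0] * rng.uniform(0.7, 1.3)
    ax = cfg.arm_halfaxes_px[1] * rng.uniform(0.7, 1.3)
    cx = edge + side * (ax + rng.uniform(2, 6))
    cy = rng.uniform(0.25 * h, 0.75 * h)
    ang = rng.uniform(0, np.pi)
    rr, cc = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    u = rr * np.cos(ang) + cc * np.sin(ang)
    v = -rr * np.sin(ang) + cc * np.cos(ang)
    ell = ((u / ay) ** 2 + (v / ax) ** 2 <= 1.0) & ~body
    k = int(ell.sum())
    if k:
        mu, sd = cfg.arm_hu
        vals = np.clip(rng.normal(mu, sd, k), -29.0, 150.0)
        image = image.copy()
        image[ell] = vals
    return image


def augment_batch(images: np.ndarray, targets: np.ndarray,
                  config: AugmentConfig | None = None,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform per (image, target) pair.

    Images are HU-valued 2-D arrays stacked along axis 0; targets are integer
    label maps of the same shape and receive the identical transform with
    nearest-neighbour interpolation.  Deterministic given ``seed``.
    """
    config = config or AugmentConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    out_i = np.empty_like(np.asarray(images, dtype=np.float32))
    out_t = np.empty_like(np.asarray(targets))
    for i, (img, tgt) in enumerate(zip(images, targets)):
        img = np.asarray(img, dtype=np.float32)
        if config.rotate_deg or config.scale or config.translate_px:
            ang = rng.uniform(-config.rotate_deg, config.rotate_deg)
            sc = 1.0 + rng.uniform(-config.scale, config.scale)
            shift = rng.uniform(-config.translate_px, config.translate_px, 2)
            img, tgt = _affine_pair(img, tgt, ang, sc, shift, BACKGROUND_HU)
        if config.elastic_alpha_px:
            img, tgt = _elastic_pair(img, tgt, config.elastic_alpha_px,
                                     config.elastic_sigma_px, rng, BACKGROUND_HU)
        if config.arm_probability and rng.random() < config.arm_probability:
            img = _insert_arm(img, rng, config)
        out_i[i], out_t[i] = img, tgt
    return out_i, out_t
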