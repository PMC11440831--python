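"""Test-time pipeline: probability maps -> L3 slice index -> tissue maps.

L3 detection: the 2-class probability map over the standardized coronal
grid is collapsed to a 1-D signal (mean L3 probability per craniocaudal
row), smoothed with a Gaussian filter, and the global maximum among local
maxima gives the L3 row, mapped back to an original slice index through the
projection provenance.  Body composition: per-pixel argmax over class
probabilities, then pixels with HU above 150 or below -500 are forced to
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ctio import (CTVolume, TissueLabelMap, LABEL_BACKGROUND, LABEL_SM,
                   LABEL_VAT, LABEL_SAT)
from .metrics import build_report
from .nn.unet import UNet
from .preprocess import (Provenance, StandardizeConfig,
                         body_mask, coronal_max_projection, hu_to_unit,
                         network_pad, precrop, row_to_slice_index, row_to_z_mm,
                         standardize)

__all__ = [
    "PostprocessConfig", "L3Prediction", "NoPeakError", "PipelineStageError",
    "project_probability_signal", "locate_l3", "hu_filter", "segment_slice",
    "detect_and_segment",
]


class NoPeakError(ValueError):
    """The smoothed probability signal has no peak (e.g. it is constant)."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PostprocessConfig:
    gaussian_sigma_rows: float = 5.0
    hu_window: tuple[float, float] = (-500.0, 150.0)
    strict_tissue_windows: bool = False  # muscle [-29,150], fat [-500,-30]

    def __post_init__(self):
        if self.gaussian_sigma_rows <= 0:
            raise ValueError("gaussian_sigma_rows must be > 0")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window low must be below high")


@dataclass
class L3Prediction:
    slice_index: int
    z_mm: float
    signal: np.ndarray       # smoothed per-row mean L3 probability
    peak_row: int
    confidence: float


def project_probability_signal(prob_map: np.ndarray) -> np.ndarray:
    """Mean L3-class probability per craniocaudal row.

    Accepts either the L3-class plane (H, W) or the full channels-last
    (H, W, C) softmax stack, in which case channel 1 is the L3 class.
    """
    p = np.asarray(prob_map)
    if p.ndim == 3:
        p = p[..., 1]
    if p.ndim != 2:
        raise ValueError(f"expected (H, W) or (H, W, C), got shape {p.shape}")
    return p.mean(axis=1)


def _local_maxima(signal: np.ndarray) -> np.ndarray:
    s = signal
    idx = [i for i in range(len(s))
           if (i == 0 or s[i] >= s[i - 1]) and (i == len(s) - 1 or s[i] >= s[i + 1])]
    return np.asarray(idx, dtype=int)


def locate_l3(signal: np.ndarray, config: PostprocessConfig | None = None,
              provenance: Provenance | None = None) -> L3Prediction:
    """Gaussian-smooth the signal and take the global maximum as L3.

    Ties break toward the lowest (most caudal) row.  The provenance converts
    the peak row to an original-volume position; without provenance the
    prediction stays in row coordinates.
    """
    config = config or PostprocessConfig()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("empty signal")
    smoothed = ndimage.gaussian_filter1d(signal, config.gaussian_sigma_rows)
    if np.ptp(smoothed) < 1e-12:
        raise NoPeakError("signal is constant after smoothing; no L3 peak")
    candidates = _local_maxima(smoothed)
    peak_row = int(candidates[np.argmax(smoothed[candidates])])
    confidence = float(smoothed[peak_row])
    if provenance is None:
        return L3Prediction(peak_row, float(peak_row), smoothed, peak_row, confidence)
    z = float(row_to_z_mm(peak_row, provenance))
    idx = int(row_to_slice_index(peak_row, provenance))
    # valid original-volume indices: the (possibly pre-cropped) z range
    lo = int(round(provenance.crop_offset_mm / provenance.spacing_z_mm))
    idx = int(np.clip(idx, lo, lo + provenance.original_n_slices - 1))
    return L3Prediction(idx, z, smoothed, peak_row, confidence)


def hu_filter(labels: np.ndarray, hu: np.ndarray,
              config: PostprocessConfig | None = None) -> np.ndarray:
    """Force out-of-window pixels (HU > 150 or < -500) to background.

    Idempotent.  With ``strict_tissue_windows`` the per-tissue manual
    thresholds are applied on top: muscle [-29, 150], fat [-500, -30].
    """
    config = config or PostprocessConfig()
    lo, hi = config.hu_window
    out = np.asarray(labels).copy()
    out[(hu < lo) | (hu > hi)] = LABEL_BACKGROUND
    if config.strict_tissue_windows:
        out[(out == LABEL_SM) & ((hu < -29) | (hu > 150))] = LABEL_BACKGROUND
        fat = (out == LABEL_VAT) | (out == LABEL_SAT)
        out[fat & ((hu < -500) | (hu > -30))] = LABEL_BACKGROUND
    return out


def _pad_to_multiple(img: np.ndarray, mult: int):
    h, w = img.shape
    ph, pw = (-h) % mult, (-w) % mult
    top, left = ph // 2, pw // 2
    padded = np.pad(img, ((top, ph - top), (left, pw - left)), mode="edge")
    return padded, (top, left, h, w)


def segment_slice(slice_hu: np.ndarray, model: UNet,
                  config: PostprocessConfig | None = None,
                  spacing_mm: tuple[float, float] = (1.0, 1.0)) -> TissueLabelMap:
    """Segment one axial HU slice into the five body-composition classes."""
    config = config or PostprocessConfig()
    slice_hu = np.asarray(slice_hu, dtype=np.float32)
    if slice_hu.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {slice_hu.shape}")
    padded, (top, left, h, w) = _pad_to_multiple(slice_hu, 2 ** model.config.depth)
    probs = model.predict_proba(hu_to_unit(padded)[None, ..., None])[0]
    labels = probs.argmax(axis=-1).astype(np.uint8)  # ties -> lowest class code
    labels = labels[top:top + h, left:left + w]
    labels = hu_filter(labels, slice_hu, config)
    return TissueLabelMap(labels=labels, spacing_mm=spacing_mm)


def detect_and_segment(volume: CTVolume, l3_model: UNet, body_model: UNet,
                       std_config: StandardizeConfig | None = None,
                       post_config: PostprocessConfig | None = None,
                       height_m: float | None = None,
                       debug: dict | None = None):
    """End-to-end: volume -> (L3Prediction, TissueLabelMap, SarcopeniaReport).

    Runs pre-crop, coronal projection, standardization, the L3 network, peak
    post-processing, axial-slice extraction, the body-composition network
    with HU filtering, and the sarcopenia report.  Pass a dict as ``debug``
    to receive every intermediate.  Stage failures raise
    :class:`PipelineStageError` naming the stage.
    """
    std_config = std_config or StandardizeConfig()
    post_config = post_config or PostprocessConfig()

    def run(stage, fn):
        try:
            out = fn()
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
        if debug is not None:
            debug[stage] = out
        return out

    mask = run("body_mask", lambda: body_mask(volume))
    pre = run("precrop", lambda: precrop(volume, mask))
    raw = run("projection", lambda: coronal_max_projection(pre.volume, pre.mask))
    proj = run("standardize", lambda: network_pad(
        standardize(raw, volume.spacing_mm[0], pre.crop_offset_mm, std_config), std_config))
    probs = run("l3_model", lambda: l3_model.predict_proba(
        hu_to_unit(proj.image)[None, ..., None])[0])
    signal = run("signal", lambda: project_probability_signal(probs))
    prediction = run("locate_l3", lambda: locate_l3(signal, post_config, proj.provenance))
    slice_hu = run("extract_slice", lambda: np.asarray(
        volume.voxels[prediction.slice_index], dtype=np.float32))
    labels = run("segment_slice", lambda: segment_slice(
        slice_hu, body_model, post_config,
        spacing_mm=(volume.spacing_mm[1], volume.spacing_mm[2])))
    report = run("report", lambda: build_report(slice_hu, labels, height_m=height_m))
    return prediction, labels, report
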