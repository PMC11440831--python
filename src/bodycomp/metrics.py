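"""Sarcopenia measurements and cohort evaluation metrics.

Measurements on the L3 axial slice: tissue cross-sectional areas (cm^2),
skeletal muscle density SMD (mean muscle HU within [-29, 150]), skeletal
muscle index SMI = area / height^2 (cm^2/m^2), skeletal muscle gauge
SMG = SMI x SMD (HU cm^2/m^2), and lean body mass
LBM (kg) = 0.3 x muscle area (cm^2) + 6.06.

Cohort evaluation mirrors the clinical reporting: L3 mean absolute error in
mm and correct-slice rate at a half-vertebral-height tolerance; per-class
DICE median and IQR; MAE, MAPE and R^2 for areas and sarcopenia metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .ctio import (TissueLabelMap, LABEL_NAMES, LABEL_SM, LABEL_VAT, LABEL_SAT)

__all__ = [
    "SarcopeniaReport", "EvaluationSummary", "AgreementStats", "UndefinedMetricError",
    "dice_coefficient", "agreement_stats", "area_cm2", "smd", "smi", "smg", "lbm",
    "correct_slice_rate", "build_report", "evaluate_cohort",
]

SMD_HU_WINDOW = (-29.0, 150.0)


class UndefinedMetricError(ValueError):
    pass


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


class AgreementStats(NamedTuple):
    mae: float
    mape: float
    r2: float


def agreement_stats(predicted: Sequence[float], truth: Sequence[float]) -> AgreementStats:
    """MAE, MAPE (%), and R^2 between matched prediction/truth vectors."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and truth must be matched 1-D vectors")
    if len(p) < 2:
        raise UndefinedMetricError("need at least 2 paired values")
    if np.any(t == 0):
        raise UndefinedMetricError("MAPE undefined: truth contains zeros")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 undefined: truth has zero variance")
    mae = float(np.abs(p - t).mean())
    mape = float(100.0 * (np.abs(p - t) / np.abs(t)).mean())
    r2 = float(1.0 - ((p - t) ** 2).sum() / ss_tot)
    return AgreementStats(mae=mae, mape=mape, r2=r2)


def area_cm2(label_map: TissueLabelMap, class_code: int) -> float:
    """Cross-sectional area of one class: pixel count x pixel area / 100."""
    mask = label_map.mask(class_code)  # validates the class code
    sy, sx = label_map.spacing_mm
    return float(mask.sum() * sy * sx / 100.0)


def smd(slice_hu: np.ndarray, sm_mask: np.ndarray) -> float:
    """Mean muscle attenuation (HU) over muscle pixels within [-29, 150]."""
    hu = np.asarray(slice_hu, dtype=float)
    mask = np.asarray(sm_mask, dtype=bool)
    if hu.shape != mask.shape:
        raise ValueError("slice and mask shapes differ")
    lo, hi = SMD_HU_WINDOW
    sel = mask & (hu >= lo) & (hu <= hi)
    if not sel.any():
        raise UndefinedMetricError("no muscle pixels inside the [-29, 150] HU window")
    return float(hu[sel].mean())


def smi(area_sm_cm2: float, height_m: float) -> float:
    """Skeletal muscle index: muscle area normalized by height squared."""
    if height_m is None or height_m <= 0:
        raise UndefinedMetricError("SMI requires a positive patient height")
    return float(area_sm_cm2 / height_m ** 2)


def smg(smi_value: float, smd_value: float) -> float:
    """Skeletal muscle gauge: SMI x SMD (HU cm^2/m^2)."""
    if smi_value is None or smd_value is None:
        raise UndefinedMetricError("SMG requires both SMI and SMD")
    return float(smi_value * smd_value)


def lbm(area_sm_cm2: float) -> float:
    """Lean body mass (kg) = 0.3 x L3 muscle area (cm^2) + 6.06."""
    if area_sm_cm2 < 0:
        raise ValueError("muscle area must be >= 0")
    return float(0.3 * area_sm_cm2 + 6.06)


def correct_slice_rate(pred_z_mm: Sequence[float], true_z_mm: Sequence[float],
                       tolerance_mm: float = 20.0) -> float:
    """Fraction of scans with |pred z - true z| within the tolerance.

    The 20 mm default is half a typical (~40 mm) vertebral-body height, i.e.
    the prediction still falls inside the L3 body.
    """
    p = np.asarray(pred_z_mm, dtype=float)
    t = np.asarray(true_z_mm, dtype=float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth vectors must be matched")
    return float(np.mean(np.abs(p - t) <= tolerance_mm))


@dataclass
class SarcopeniaReport:
    """Areas and sarcopenia metrics for one L3 slice, with units in names."""

    area_sm_cm2: float
    area_vat_cm2: float
    area_sat_cm2: float
    smd_hu: float | None
    lbm_kg: float
    height_m: float | None = None
    smi_cm2_m2: float | None = None
    smg_hu_cm2_m2: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def build_report(slice_hu: np.ndarray, label_map: TissueLabelMap,
                 height_m: float | None = None,
                 smg_mode: str = "smi") -> SarcopeniaReport:
    """Sarcopenia report from one segmented L3 slice.

    ``smg_mode`` selects the SMG operand: ``"smi"`` (default, matches the
    printed HU cm^2/m^2 unit) multiplies SMI by SMD; ``"area"`` multiplies
    the raw muscle area by SMD.
    """
    if smg_mode not in ("smi", "area"):
        raise ValueError("smg_mode must be 'smi' or 'area'")
    a_sm = area_cm2(label_map, LABEL_SM)
    a_vat = area_cm2(label_map, LABEL_VAT)
    a_sat = area_cm2(label_map, LABEL_SAT)
    try:
        smd_value = smd(slice_hu, label_map.mask(LABEL_SM))
    except UndefinedMetricError:
        smd_value = None
    smi_value = smi(a_sm, height_m) if height_m else None
    if smd_value is None:
        smg_value = None
    elif smg_mode == "area":
        smg_value = smg(a_sm, smd_value)
    else:
        smg_value = smg(smi_value, smd_value) if smi_value is not None else None
    return SarcopeniaReport(
        area_sm_cm2=a_sm, area_vat_cm2=a_vat, area_sat_cm2=a_sat,
        smd_hu=smd_value, lbm_kg=lbm(a_sm), height_m=height_m,
        smi_cm2_m2=smi_value, smg_hu_cm2_m2=smg_value)


@dataclass
class EvaluationSummary:
    """Cohort-level performance in the layout of the clinical result tables."""

    n: int
    l3_mae_mm: float | None = None
    l3_correct_rate: float | None = None
    dice_median: dict = field(default_factory=dict)   # class name -> median
    dice_iqr: dict = field(default_factory=dict)      # class name -> (q1, q3)
    quantity_stats: dict = field(default_factory=dict)  # name -> AgreementStats or None
    coverage: dict = field(default_factory=dict)      # quantity -> usable pairs

    def to_dict(self) -> dict:
        return {
            "n": self.n, "l3_mae_mm": self.l3_mae_mm,
            "l3_correct_rate": self.l3_correct_rate,
            "dice_median": self.dice_median,
            "dice_iqr": {k: list(v) for k, v in self.dice_iqr.items()},
            "quantity_stats": {k: (None if v is None else v._asdict())
                               for k, v in self.quantity_stats.items()},
            "coverage": self.coverage,
        }


def _report_quantities(report: SarcopeniaReport) -> dict:
    return {
        "area_sm_cm2": report.area_sm_cm2,
        "area_vat_cm2": report.area_vat_cm2,
        "area_sat_cm2": report.area_sat_cm2,
        "smd_hu": report.smd_hu,
        "smi_cm2_m2": report.smi_cm2_m2,
        "lbm_kg": report.lbm_kg,
        "smg_hu_cm2_m2": report.smg_hu_cm2_m2,
    }


def evaluate_cohort(pred_maps: Sequence[TissueLabelMap],
                    true_maps: Sequence[TissueLabelMap],
                    slices_hu: Sequence[np.ndarray],
                    heights_m: Sequence[float] | None = None,
                    pred_l3_z_mm: Sequence[float] | None = None,
                    true_l3_z_mm: Sequence[float] | None = None,
                    tolerance_mm: float = 20.0) -> EvaluationSummary:
    """Aggregate L3, segmentation and sarcopenia agreement over a cohort.

    SMD for predicted and true masks is computed on the same HU slice, so the
    comparison isolates segmentation disagreement.  Quantities undefined for
    the whole cohort (e.g. R^2 with one scan) are reported as ``None`` with
    their coverage count.
    """
    n = len(pred_maps)
    if n == 0 or len(true_maps) != n or len(slices_hu) != n:
        raise ValueError("cohort inputs must be nonempty and matched")
    heights = list(heights_m) if heights_m is not None else [None] * n

    summary = EvaluationSummary(n=n)
    if pred_l3_z_mm is not None and true_l3_z_mm is not None:
        p = np.asarray(pred_l3_z_mm, dtype=float)
        t = np.asarray(true_l3_z_mm, dtype=float)
        summary.l3_mae_mm = float(np.abs(p - t).mean())
        summary.l3_correct_rate = correct_slice_rate(p, t, tolerance_mm)

    per_class = {name: [] for name in LABEL_NAMES.values()}
    for pm, tm in zip(pred_maps, true_maps):
        for code, name in LABEL_NAMES.items():
            per_class[name].append(dice_coefficient(pm.mask(code), tm.mask(code)))
    for name, vals in per_class.items():
        v = np.asarray(vals)
        summary.dice_median[name] = float(np.median(v))
        summary.dice_iqr[name] = (float(np.percentile(v, 25)), float(np.percentile(v, 75)))

    pred_q = {k: [] for k in _report_quantities(build_report(slices_hu[0], pred_maps[0]))}
    true_q = {k: [] for k in pred_q}
    for pm, tm, hu, h in zip(pred_maps, true_maps, slices_hu, heights):
        rp = _report_quantities(build_report(hu, pm, height_m=h))
        rt = _report_quantities(build_report(hu, tm, height_m=h))
        for k in pred_q:
            if rp[k] is not None and rt[k] is not None:
                pred_q[k].append(rp[k])
                true_q[k].append(rt[k])
    for k in pred_q:
        summary.coverage[k] = len(pred_q[k])
        try:
            summary.quantity_stats[k] = agreement_stats(pred_q[k], true_q[k])
        except (UndefinedMetricError, ValueError):
            summary.quantity_stats[k] = None
    return summary
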