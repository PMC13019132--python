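"""Dose-distribution evaluation: DVHs, DVH parameters, isodose Dice
similarity, voxel-wise dose difference, MAE and pass-rate curves.

Conventions (all oracle-checkable against per-voxel enumeration):

* cumulative DVH: fraction of structure volume receiving at least each dose;
* D_x% is the largest voxel dose d with coverage(d) >= x/100, computed from
  the exact order statistics of the voxel doses (no interpolation);
* iDSC at threshold t% compares the sets {dose >= t% of prescription} of
  two plans over the full common grid;
* the voxel-wise dose difference DD(i) = (auto - reference)/prescription,
  in percent, is evaluated on Body voxels only, and a voxel "passes" a
  threshold t when |DD(i)| < t (strict).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grids import DoseGrid, FrameMismatchError, Prescription, StructureMask

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "DDGrid",
    "SimilarityReport",
    "compute_dvh",
    "dvh_metric",
    "dose_at_volume_fraction",
    "idsc",
    "idsc_curve",
    "dose_difference",
    "mae",
    "pass_rate_curve",
    "compare_doses",
]

IDSC_THRESHOLDS = np.arange(1, 96)  # % of prescription, 1..95
PASS_THRESHOLDS = np.arange(1, 21)  # % of prescription, 1..20


@dataclass
class DVHCurve:
    structure: str
    edges_gy: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.cumulative_fraction, dtype=float)
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def fraction_at(self, dose_gy: float) -> float:
        """Volume fraction receiving at least ``dose_gy`` (step lookup)."""
        idx = np.searchsorted(self.edges_gy, dose_gy, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.cumulative_fraction[min(idx, self.edges_gy.size - 1)])


@dataclass(frozen=True)
class MetricSpec:
    """One DVH parameter, e.g. D95% (% of Rx), D1cc (%), V20Gy, Dmean, Dmax."""

    kind: str  # D_percent | D_cc | V_Gy | Dmean | Dmax
    argument: float = 0.0
    unit: str = "Gy"  # Gy | % (of prescription) | %vol (volume metrics)

    def __post_init__(self):
        if self.kind not in ("D_percent", "D_cc", "V_Gy", "Dmean", "Dmax"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.argument < 0:
            raise ValueError("metric argument must be non-negative")
        if self.kind == "D_percent" and self.argument > 100:
            raise ValueError("D_x% needs x <= 100")

    @property
    def label(self) -> str:
        if self.kind == "D_percent":
            return f"D{self.argument:g}%"
        if self.kind == "D_cc":
            return f"D{self.argument:g}cc"
        if self.kind == "V_Gy":
            return f"V{self.argument:g}Gy"
        return self.kind

    @classmethod
    def parse(cls, label: str, unit: Optional[str] = None) -> "MetricSpec":
        """Parse the field's usual labels: D95%, D1cc, V20Gy, Dmean, Dmax."""
        label = label.strip()
        if label.lower() == "dmean":
            return cls("Dmean", unit=unit or "Gy")
        if label.lower() == "dmax":
            return cls("Dmax", unit=unit or "Gy")
        m = re.fullmatch(r"[Dd]([\d.]+)%", label)
        if m:
            return cls("D_percent", float(m.group(1)), unit or "%")
        m = re.fullmatch(r"[Dd]([\d.]+)cc", label)
        if m:
            return cls("D_cc", float(m.group(1)), unit or "%")
        m = re.fullmatch(r"[Vv]([\d.]+)Gy", label)
        if m:
            return cls("V_Gy", float(m.group(1)), unit or "%vol")
        raise ValueError(f"cannot parse metric label {label!r}")


@dataclass
class DDGrid:
    """Voxel-wise dose difference in % of prescription, on Body voxels."""

    values_percent: np.ndarray  # 1D, one entry per Body voxel
    prescription_gy: float
    frame_id: str

    def __post_init__(self):
        self.values_percent = np.asarray(self.values_percent, dtype=float).ravel()
        if not np.all(np.isfinite(self.values_percent)):
            raise ValueError("dose differences must be finite")


@dataclass
class SimilarityReport:
    """Similarity of one automated plan against a reference plan."""

    idsc_thresholds: np.ndarray
    idsc_values: np.ndarray
    mae_percent: float
    pass_thresholds: np.ndarray
    pass_rates: np.ndarray


# ---------------------------------------------------------------------------
# DVH


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.frame_id != mask.frame_id:
        raise FrameMismatchError(f"dose and mask {mask.name!r} frames differ")
    d = dose.values[mask.occupancy]
    if d.size == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    return d


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH of ``mask`` under ``dose``.

    The curve samples the fraction of structure volume receiving at least
    each bin edge, edges running from 0 past the structure maximum.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    d = np.sort(_structure_doses(dose, mask))
    edges = np.arange(0.0, d[-1] + 2 * bin_width_gy, bin_width_gy)
    # fraction receiving >= edge, via the sorted dose vector
    n_below = np.searchsorted(d, edges, side="left")
    frac = (d.size - n_below) / d.size
    return DVHCurve(mask.name, edges, frac)


def dose_at_volume_fraction(doses: np.ndarray, fraction: float) -> float:
    """Largest dose d with (volume receiving >= d) / volume >= ``fraction``.

    Exact order-statistic convention: with voxel doses sorted descending,
    this is the ceil(N * fraction)-th hottest voxel.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    a = np.sort(np.asarray(doses, dtype=float))[::-1]
    k = int(np.ceil(a.size * fraction - 1e-9))
    return float(a[max(k, 1) - 1])


def dvh_metric(
    dose: DoseGrid, mask: StructureMask, spec: MetricSpec, rx: Prescription
) -> float:
    """Evaluate one DVH parameter, converted to ``spec.unit``."""
    d = _structure_doses(dose, mask)
    if spec.kind == "D_percent":
        value_gy = dose_at_volume_fraction(d, spec.argument / 100.0)
    elif spec.kind == "D_cc":
        vox_cc = dose.voxel_volume_cc
        needed = spec.argument / vox_cc
        if d.size * vox_cc < spec.argument - 1e-9:
            raise ValueError(
                f"structure {mask.name!r} ({d.size * vox_cc:.2f} cc) smaller than "
                f"{spec.argument} cc"
            )
        k = int(np.ceil(needed - 1e-9))
        value_gy = float(np.sort(d)[::-1][max(k, 1) - 1])
    elif spec.kind == "V_Gy":
        return float(100.0 * np.mean(d >= spec.argument))
    elif spec.kind == "Dmean":
        value_gy = float(d.mean())
    else:  # Dmax
        value_gy = float(d.max())

    if spec.unit == "Gy":
        return value_gy
    if spec.unit == "%":
        return 100.0 * value_gy / rx.total_dose
    raise ValueError(f"unit {spec.unit!r} not applicable to {spec.kind}")


# ---------------------------------------------------------------------------
# isodose Dice similarity


def idsc(doseA: DoseGrid, doseB: DoseGrid, threshold_percent: float, rx: Prescription) -> float:
    """Dice overlap of the two plans' isodose volumes at a threshold.

    A and B are the sets of voxels at or above threshold% of prescription.
    Two empty sets count as perfect agreement (1.0); one empty set as 0.0.
    """
    if doseA.frame_id != doseB.frame_id:
        raise FrameMismatchError("iDSC needs both doses on a common grid; resample first")
    level = threshold_percent / 100.0 * rx.total_dose
    a = doseA.values >= level
    b = doseB.values >= level
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def idsc_curve(
    doseA: DoseGrid, doseB: DoseGrid, rx: Prescription
) -> Tuple[np.ndarray, np.ndarray]:
    """iDSC at 1..95% of prescription in 1% steps (95 values)."""
    values = np.array([idsc(doseA, doseB, float(t), rx) for t in IDSC_THRESHOLDS])
    return IDSC_THRESHOLDS.copy(), values


# ---------------------------------------------------------------------------
# voxel-wise dose difference


def dose_difference(
    dose_auto: DoseGrid, dose_ref: DoseGrid, body: StructureMask, rx: Prescription
) -> DDGrid:
    """DD(i) = (auto - reference)/prescription in %, over Body voxels."""
    if dose_auto.frame_id != dose_ref.frame_id or dose_auto.frame_id != body.frame_id:
        raise FrameMismatchError("dose difference needs doses and Body on one grid")
    if not body.occupancy.any():
        raise ValueError("Body mask is empty")
    diff = (dose_auto.values - dose_ref.values)[body.occupancy]
    return DDGrid(100.0 * diff / rx.total_dose, rx.total_dose, dose_auto.frame_id)


def mae(dd: DDGrid) -> float:
    """Mean absolute dose difference in % of prescription."""
    if dd.values_percent.size == 0:
        raise ValueError("empty dose-difference grid")
    return float(np.mean(np.abs(dd.values_percent)))


def pass_rate_curve(
    dds: Sequence[DDGrid], thresholds: Sequence[float] = PASS_THRESHOLDS
) -> Tuple[np.ndarray, np.ndarray]:
    """Aggregate pass rates over pooled voxels of one or more cases.

    A voxel passes threshold t when |DD| < t (strict).  Returns
    (thresholds, % passing), monotone non-decreasing in the threshold.
    """
    if len(dds) == 0:
        raise ValueError("need at least one dose-difference grid")
    pooled = np.abs(np.concatenate([dd.values_percent for dd in dds]))
    if pooled.size == 0:
        raise ValueError("pooled voxel set is empty")
    th = np.asarray(thresholds, dtype=float)
    rates = np.array([100.0 * np.mean(pooled < t) for t in th])
    return th, rates


def compare_doses(
    dose_auto: DoseGrid, dose_ref: DoseGrid, body: StructureMask, rx: Prescription
) -> SimilarityReport:
    """Full similarity report for one plan pair on a common grid."""
    th_i, v_i = idsc_curve(dose_auto, dose_ref, rx)
    dd = dose_difference(dose_auto, dose_ref, body, rx)
    th_p, rates = pass_rate_curve([dd])
    return SimilarityReport(th_i, v_i, mae(dd), th_p, rates)
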