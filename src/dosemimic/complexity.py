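"""Modulation Complexity Score for VMAT (MCSv).

MCSv condenses how strongly a VMAT arc is modulated into a single number in
[0, 1]: 1 means static, fully open, rectangular apertures; lower values mean
stronger inter-control-point variation of aperture area and leaf positions.
It combines, per control point,

* LSV (leaf-sequence variability): per MLC bank, how much adjacent in-field
  leaves differ relative to the bank's position range,
* AAV (aperture-area variability): the open area relative to the maximal
  per-leaf opening observed anywhere in the arc,

and weights adjacent-control-point averages of the two by the MU delivered
in each segment:

    MCSv = sum_i [(AAV_i + AAV_{i+1})/2] * [(LSV_i + LSV_{i+1})/2] * MU_i / MU_total

Leaves are considered in-field when their gap exceeds 0.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MachineSpec", "VMATPlan", "ComplexityResult", "lsv", "aav", "mcsv"]

#: leaf pairs with a gap larger than this (mm) count as in-field
IN_FIELD_GAP_MM = 0.5


@dataclass(frozen=True)
class MachineSpec:
    """MLC geometry of the delivery machine."""

    n_leaves: int = 40
    leaf_width_mm: float = 5.0
    max_extent_mm: float = 200.0  # full travel: leaves move within +/- max_extent/2

    def __post_init__(self):
        if self.n_leaves < 2 or self.leaf_width_mm <= 0 or self.max_extent_mm <= 0:
            raise ValueError("invalid machine description")

    @property
    def leaf_widths(self) -> np.ndarray:
        return np.full(self.n_leaves, self.leaf_width_mm)


@dataclass
class VMATPlan:
    """Ordered control-point sequence of one VMAT delivery.

    ``left``/``right`` are (n_cp, n_leaves) arrays of leaf-tip positions in
    mm (left <= right per pair); ``mu_weight`` is the per-control-point MU
    weight (>= 0).  Segment MU between adjacent control points is taken as
    the mean of the two bounding control-point weights.
    """

    gantry_deg: np.ndarray
    mu_weight: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_widths_mm: np.ndarray
    max_extent_mm: float = 200.0

    def __post_init__(self):
        self.gantry_deg = np.asarray(self.gantry_deg, dtype=float)
        self.mu_weight = np.asarray(self.mu_weight, dtype=float)
        self.left = np.atleast_2d(np.asarray(self.left, dtype=float))
        self.right = np.atleast_2d(np.asarray(self.right, dtype=float))
        self.leaf_widths_mm = np.asarray(self.leaf_widths_mm, dtype=float)
        n = self.n_control_points
        if n < 2:
            raise ValueError("a VMAT arc needs at least 2 control points")
        if self.left.shape != self.right.shape or self.left.shape[0] != n:
            raise ValueError("leaf bank arrays must be (n_cp, n_leaves)")
        if self.left.shape[1] != self.leaf_widths_mm.size:
            raise ValueError("leaf_widths length must match the number of leaf pairs")
        if np.any(self.mu_weight < 0):
            raise ValueError("MU weights must be non-negative")
        if np.any(self.right - self.left < -1e-9):
            raise ValueError("left leaf positions must not exceed right positions")

    @property
    def n_control_points(self) -> int:
        return int(self.gantry_deg.size)

    @property
    def n_leaves(self) -> int:
        return int(self.left.shape[1])

    @property
    def total_mu(self) -> float:
        return float(self.segment_mu().sum())

    def segment_mu(self) -> np.ndarray:
        """MU attributed to each of the n_cp - 1 segments."""
        return 0.5 * (self.mu_weight[:-1] + self.mu_weight[1:])

    def gaps(self) -> np.ndarray:
        return self.right - self.left

    def in_field(self) -> np.ndarray:
        """(n_cp, n_leaves) bool: leaf pairs contributing to the aperture."""
        return self.gaps() > IN_FIELD_GAP_MM


@dataclass
class ComplexityResult:
    mcsv: float
    lsv_per_cp: np.ndarray
    aav_per_cp: np.ndarray
    segment_mu_fraction: np.ndarray
    flags: List[str] = field(default_factory=list)


def _bank_lsv(positions: np.ndarray) -> float:
    """Variability of one bank's in-field leaf positions at one control point."""
    n = positions.size
    if n < 2:
        return 1.0  # a single in-field leaf has no sequence to vary
    pos_max = float(positions.max() - positions.min())
    if pos_max <= 0:
        return 1.0  # all leaves aligned: perfectly regular
    diffs = np.abs(np.diff(positions))
    return float(np.sum(pos_max - diffs) / ((n - 1) * pos_max))


def lsv(plan: VMATPlan, cp: int) -> float:
    """Leaf-sequence variability at control point ``cp`` (product of banks).

    Returns 0.0 when no leaf pair is open (degenerate closed aperture).
    """
    open_pairs = plan.in_field()[cp]
    if not open_pairs.any():
        return 0.0
    return _bank_lsv(plan.left[cp, open_pairs]) * _bank_lsv(plan.right[cp, open_pairs])


def aav(plan: VMATPlan, cp: int) -> float:
    """Aperture-area variability at control point ``cp``.

    Open area divided by the area of the arc-maximal aperture, where each
    leaf pair's maximal opening is (max over control points of right) minus
    (min over control points of left).  Returns 0.0 when the arc never
    opens.
    """
    widths = plan.leaf_widths_mm
    gaps = np.clip(plan.gaps()[cp], 0.0, None)
    max_open = np.clip(plan.right.max(axis=0) - plan.left.min(axis=0), 0.0, None)
    denom = float(np.sum(max_open * widths))
    if denom <= 0:
        return 0.0
    return float(np.sum(gaps * widths) / denom)


def mcsv(plan: VMATPlan) -> ComplexityResult:
    """Modulation Complexity Score of a VMAT arc.

    Raises on single-control-point plans and zero-MU plans; otherwise the
    score is guaranteed to lie in [0, 1].
    """
    n = plan.n_control_points
    if n < 2:
        raise ValueError("MCSv needs at least two control points")
    seg = plan.segment_mu()
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("MCSv is undefined for a zero-MU plan")

    flags: List[str] = []
    lsv_cp = np.empty(n)
    aav_cp = np.empty(n)
    any_open = plan.in_field().any(axis=1)
    for i in range(n):
        if not any_open[i]:
            flags.append(f"control point {i}: no open leaf pairs")
        lsv_cp[i] = lsv(plan, i)
        aav_cp[i] = aav(plan, i)

    frac = seg / total
    score = float(
        np.sum(0.5 * (aav_cp[:-1] + aav_cp[1:]) * 0.5 * (lsv_cp[:-1] + lsv_cp[1:]) * frac)
    )
    score = min(max(score, 0.0), 1.0)  # guard float round-off at the bounds
    return ComplexityResult(score, lsv_cp, aav_cp, frac, flags)
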