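"""Dose-mimicking pipeline: normalization, isodose-band optimization
structures, dose-volume objectives and the end-to-end plan mimicking run.

A predicted (ideal, non-deliverable) 3D dose distribution is turned into a
deliverable-style plan in three stages:

1. the prediction is normalized so that 50% of the PTV receives 100% of the
   prescription (the plan-normalization rule used throughout);
2. twelve optimization structures are derived from the normalized
   prediction: eight isodose bands in the Body, two in the Lungs, the part
   of the PTV falling outside 99–110% of prediction, and PTV minus CTV;
3. dose-volume objectives from a shipped template are attached to those
   structures and solved against a beamlet dose model
   (:mod:`dosemimic.beamlets`).

Band intervals are half-open, ``low% <= dose < high%`` of prescription, so
adjacent bands partition their dose range; deliberately overlapping bands
(60–80 / 70–90 / 80–95) are kept exactly as specified by the template.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .grids import (
    DoseGrid,
    Prescription,
    StructureMask,
    StructureSet,
    mask_subtract,
)
from .metrics import dose_at_volume_fraction

__all__ = [
    "BandSpec",
    "DoseObjective",
    "BODY_BANDS",
    "LUNG_BANDS",
    "PTV_BAND",
    "normalize_dose",
    "extract_band",
    "generate_optimization_structures",
    "load_template",
    "build_objectives",
    "objective_penalty",
    "merge_structure_sets",
    "decimate_grid",
    "decimate_structures",
    "mimic_plan",
    "MimicResult",
]


# ---------------------------------------------------------------------------
# normalization


def normalize_dose(dose: DoseGrid, ptv: StructureMask, rx: Prescription) -> DoseGrid:
    """Rescale ``dose`` so that PTV D50% equals the prescribed dose.

    The scale factor is rx.total_dose / D50%(PTV); idempotent for an
    already-normalized dose.  Raises when the PTV median dose is zero.
    """
    if dose.frame_id != ptv.frame_id:
        raise ValueError("dose and PTV mask live on different frames")
    ptv_doses = dose.values[ptv.occupancy]
    if ptv_doses.size == 0:
        raise ValueError("PTV mask is empty")
    d50 = dose_at_volume_fraction(ptv_doses, 0.5)
    if d50 <= 0:
        raise ValueError("PTV D50% is zero; cannot normalize")
    return dose.with_values(dose.values * (rx.total_dose / d50))


# ---------------------------------------------------------------------------
# optimization structures (isodose bands)


@dataclass(frozen=True)
class BandSpec:
    """One isodose band: ``low% <= dose < high%`` of prescription, within a
    domain (Body, Lungs, or the PTV-complement construction)."""

    name: str
    low: float
    high: float
    domain: str  # Body | Lungs | PTV-complement

    def __post_init__(self):
        if not (0 <= self.low < self.high):
            raise ValueError(f"band needs 0 <= low < high, got {self.low}..{self.high}")


def _band_name(prefix: str, lo: float, hi: float) -> str:
    return f"{prefix}{lo:.1f}-{hi:.1f}%"


BODY_BAND_EDGES: Tuple[Tuple[float, float], ...] = (
    (5.0, 8.3),
    (8.3, 33.0),
    (33.0, 40.0),
    (40.0, 60.0),
    (60.0, 80.0),
    (70.0, 90.0),
    (80.0, 95.0),
    (103.0, 110.0),
)
LUNG_BAND_EDGES: Tuple[Tuple[float, float], ...] = ((5.0, 8.3), (8.3, 33.0))

BODY_BANDS = tuple(
    BandSpec(_band_name("dose_", lo, hi), lo, hi, "Body") for lo, hi in BODY_BAND_EDGES
)
LUNG_BANDS = tuple(
    BandSpec(_band_name("Lungs/Dose", lo, hi), lo, hi, "Lungs") for lo, hi in LUNG_BAND_EDGES
)
PTV_BAND = BandSpec("PTV-Dose99.0-110.0%", 99.0, 110.0, "PTV-complement")


def extract_band(
    dose: DoseGrid, rx: Prescription, band: BandSpec, structures: StructureSet
) -> StructureMask:
    """Voxels of the band's domain whose normalized dose lies in the band.

    For the PTV-complement construction the result is the PTV *minus* the
    in-band voxels (the cold/hot part of the target the optimizer must fix).
    """
    pct = dose.values / rx.total_dose * 100.0
    in_band = (pct >= band.low) & (pct < band.high)
    if band.domain in ("Body", "Lungs"):
        if band.domain not in structures:
            raise ValueError(f"band domain structure {band.domain!r} missing")
        occ = structures[band.domain].occupancy & in_band
    elif band.domain == "PTV-complement":
        if "PTV" not in structures:
            raise ValueError("band domain structure 'PTV' missing")
        occ = structures["PTV"].occupancy & ~in_band
    else:
        raise ValueError(f"unknown band domain {band.domain!r}")
    return StructureMask(band.name, occ, dose.frame_id)


def generate_optimization_structures(
    predicted: DoseGrid, structures: StructureSet, rx: Prescription
) -> StructureSet:
    """Derive the 12 optimization structures from a normalized prediction.

    Eight Body bands, two Lungs bands, the PTV outside its 99–110% band and
    PTV minus CTV, with stable names matching the shipped objective
    templates.  ``predicted`` must already be normalized (PTV D50% = Rx).
    """
    for required in ("Body", "Lungs", "PTV", "CTV"):
        if required not in structures:
            raise ValueError(f"required structure {required!r} missing")
    out = StructureSet()
    for band in (*BODY_BANDS, *LUNG_BANDS, PTV_BAND):
        out.add(extract_band(predicted, rx, band, structures))
    out.add(mask_subtract(structures["PTV"], structures["CTV"], name="PTV-CTV"))
    return out


def merge_structure_sets(*sets: StructureSet) -> StructureSet:
    """Union of structure sets on one frame (later sets win on name clash)."""
    merged = StructureSet()
    for s in sets:
        for name in s.names:
            merged.add(s[name])
    return merged


# ---------------------------------------------------------------------------
# objectives


@dataclass(frozen=True)
class DoseObjective:
    """One dose-volume optimization goal.

    ``kind`` Upper with volume 0 bounds every voxel from above; ``kind``
    Lower with volume 100 bounds every voxel from below.  Only these two
    point-objective forms are supported.
    """

    structure: str
    kind: str  # Upper | Lower
    volume: float  # % of structure volume; 0 or 100
    dose: float  # Gy
    priority: float

    def __post_init__(self):
        if self.kind not in ("Upper", "Lower"):
            raise ValueError(f"objective kind must be Upper or Lower, got {self.kind!r}")
        if self.volume not in (0.0, 100.0):
            raise ValueError("only volume 0 (Upper) and 100 (Lower) objectives are supported")
        if self.dose < 0:
            raise ValueError("objective dose must be non-negative")
        if self.priority <= 0:
            raise ValueError("objective priority must be positive")


def load_template(name: str) -> dict:
    """Load a shipped objective template (``ratoguide`` / ``rapidplan_static``)
    or a user YAML file path."""
    shipped = {"ratoguide": "ratoguide.yaml", "rapidplan_static": "rapidplan.yaml"}
    if name in shipped:
        ref = importlib.resources.files("dosemimic.templates").joinpath(shipped[name])
        text = ref.read_text()
    else:
        from pathlib import Path

        p = Path(name)
        if not p.exists():
            raise ValueError(f"unknown template {name!r}")
        text = p.read_text()
    return yaml.safe_load(text)


def build_objectives(
    structures: StructureSet, template: Union[str, dict] = "ratoguide"
) -> List[DoseObjective]:
    """Instantiate the dose-volume objectives of a template.

    Raises when the template references structures that are absent, listing
    all missing names.  Template entries marked as model-generated (line
    objectives, normal-tissue objective) are carried in the template file
    but never instantiated here.
    """
    spec = load_template(template) if isinstance(template, str) else template
    objectives = [
        DoseObjective(
            structure=str(row["structure"]),
            kind=str(row["kind"]),
            volume=float(row["volume"]),
            dose=float(row["dose"]),
            priority=float(row["priority"]),
        )
        for row in spec.get("objectives", [])
    ]
    missing = sorted({o.structure for o in objectives} - set(structures.names))
    if missing:
        raise ValueError(f"template references missing structures: {missing}")
    return objectives


def objective_penalty(
    dose: DoseGrid,
    objectives: Sequence[DoseObjective],
    structures: StructureSet,
) -> Tuple[float, Dict[str, float]]:
    """Quadratic one-sided penalty of a dose against a set of objectives.

    Per objective with structure s of N voxels and dose bound D:
    ``priority / N * sum(max(0, d - D)^2)`` for Upper and
    ``priority / N * sum(max(0, D - d)^2)`` for Lower; the total is the sum.
    Empty structures contribute zero with a warning.
    """
    per: Dict[str, float] = {}
    total = 0.0
    for i, obj in enumerate(objectives):
        if obj.structure not in structures:
            raise ValueError(f"objective structure {obj.structure!r} not available")
        key = f"{obj.structure} {obj.kind} {obj.dose:g}Gy"
        if key in per:
            key = f"{key} #{i}"
        occ = structures[obj.structure].occupancy
        n = int(occ.sum())
        if n == 0:
            warnings.warn(f"objective structure {obj.structure!r} is empty; contributes 0")
            per[key] = 0.0
            continue
        d = dose.values[occ]
        if obj.kind == "Upper":
            viol = np.clip(d - obj.dose, 0.0, None)
        else:
            viol = np.clip(obj.dose - d, 0.0, None)
        val = float(obj.priority / n * np.sum(viol**2))
        per[key] = val
        total += val
    return total, per


# ---------------------------------------------------------------------------
# grid decimation (optimization runs on a coarser copy of the native grid)


def decimate_grid(grid: DoseGrid, factor: int) -> DoseGrid:
    """Every ``factor``-th voxel per axis; voxel centers are preserved."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    sl = (slice(None, None, factor),) * 3
    return DoseGrid(grid.origin.copy(), grid.spacing * factor, grid.values[sl])


def decimate_structures(structures: StructureSet, factor: int, frame_id: str) -> StructureSet:
    sl = (slice(None, None, factor),) * 3
    out = StructureSet()
    for name in structures.names:
        out.add(StructureMask(name, structures[name].occupancy[sl], frame_id))
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class MimicResult:
    """Everything the mimicking run produced."""

    predicted_normalized: DoseGrid
    optimization_structures: StructureSet
    objectives: List[DoseObjective]
    optimization: "OptimizationResult"  # noqa: F821 - forward ref to beamlets
    achieved_dose: DoseGrid  # on the native grid, plan-normalized
    plan: "VMATPlan"  # noqa: F821


def mimic_plan(
    predicted: DoseGrid,
    structures: StructureSet,
    rx: Prescription,
    template: Union[str, dict] = "ratoguide",
    side: str = "right",
    n_control_points: int = 16,
    iterations: int = 200,
    decimation: int = 2,
    seed: Optional[int] = None,
) -> MimicResult:
    """Run the full dose-mimicking pipeline on one case.

    Normalizes the prediction, derives the optimization structures, builds
    the template objectives and solves the dose-volume optimization on a
    beamlet model over a ``decimation``-fold coarsened copy of the native
    grid; the achieved dose is resampled back to the native grid and
    plan-normalized.  Deterministic for a fixed seed and inputs.
    """
    from .beamlets import ArcSpec, compute_beamlet_matrix, optimize_weights, weights_to_apertures
    from .grids import resample_to

    ptv = structures["PTV"]
    pred_n = normalize_dose(predicted, ptv, rx)
    opt_structs = generate_optimization_structures(pred_n, structures, rx)
    merged = merge_structure_sets(structures, opt_structs)
    objectives = build_objectives(merged, template)

    coarse_geom = decimate_grid(pred_n, decimation)
    coarse_structs = decimate_structures(merged, decimation, coarse_geom.frame_id)
    arc = ArcSpec(side=side, n_control_points=n_control_points)
    matrix = compute_beamlet_matrix(coarse_geom, coarse_structs, arc)
    opt = optimize_weights(
        matrix, objectives, coarse_structs, iterations=iterations, seed=seed, rx=rx
    )
    achieved_native = resample_to(opt.achieved_dose, predicted)
    achieved_native = normalize_dose(achieved_native, ptv, rx)
    plan = weights_to_apertures(opt, matrix)
    return MimicResult(pred_n, opt_structs, objectives, opt, achieved_native, plan)
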