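"""Seeded synthetic thorax phantoms, reference dose fields and VMAT plans.

Everything downstream of this module (band extraction, optimization, DVH
and similarity metrics, complexity scoring) is exercised on phantoms built
here, so every generator is a pure function of its spec and seed.

The anatomy is assembled from analytic solids rasterized by voxel-center
membership — an elliptical body, two lung ellipsoids, a spherical PTV with
its CTV a fixed margin inside, an esophagus tube, a heart ellipsoid and a
spinal-cord tube with a 3 mm planning margin (PRV).  The reference dose is
a closed-form field, not a physics simulation: a near-uniform plateau over
the PTV, an exponential falloff with a tunable length scale outside it, and
a laterally weighted low-dose bath that is heavier on the tumor side, as an
arc delivery through the ipsilateral hemithorax produces.  Closed forms
keep every metric test checkable against analytic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .complexity import MachineSpec, VMATPlan
from .grids import DoseGrid, Prescription, StructureMask, StructureSet, expand_margin
from .mimic import normalize_dose

__all__ = [
    "PhantomSpec",
    "DosePerturbation",
    "make_phantom",
    "make_reference_dose",
    "perturb_dose",
    "make_vmat_plan",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and anatomy parameters of one synthetic thorax.

    Lengths are mm.  The default grid is 2 mm isotropic, 128³ voxels
    (≈ 25.6 cm cube).  ``side`` selects the lung hosting the tumor; the
    CTV-to-PTV margin must lie in the clinically used 5–7 mm range and the
    cord PRV margin defaults to 3 mm.
    """

    shape: Tuple[int, int, int] = (128, 128, 128)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    side: str = "right"
    body_semiaxes: Tuple[float, float, float] = (120.0, 100.0, 125.0)
    lung_center_x: float = 55.0
    lung_semiaxes: Tuple[float, float, float] = (45.0, 60.0, 85.0)
    ptv_radius: float = 30.0
    ptv_center: Optional[Tuple[float, float, float]] = None
    ctv_margin: float = 6.0
    esophagus_radius: float = 8.0
    heart_semiaxes: Tuple[float, float, float] = (40.0, 35.0, 45.0)
    cord_radius: float = 5.0
    cord_y: float = 70.0
    prv_margin: float = 3.0
    ptv_volume_range_cc: Tuple[float, float] = (40.0, 990.0)
    jitter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not (5.0 <= self.ctv_margin <= 7.0):
            raise ValueError("CTV-to-PTV margin must be within 5–7 mm")
        if self.prv_margin < 0:
            raise ValueError("PRV margin must be non-negative")

    @property
    def side_sign(self) -> float:
        """World-x sign of the tumor side (patient right = negative x)."""
        return -1.0 if self.side == "right" else 1.0


@dataclass(frozen=True)
class DosePerturbation:
    """A controlled modification of a dose field with known statistics."""

    mode: str  # uniform_shift | multiplicative | smooth_noise | low_dose_bath
    magnitude: float  # % of prescription (multiplicative: % change)
    correlation_length_mm: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("uniform_shift", "multiplicative", "smooth_noise", "low_dose_bath"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


def _grid_axes(spec: PhantomSpec):
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = -spacing * (shape - 1) / 2.0  # centered grid
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return origin, spacing, axes


def _ellipsoid(axes, center, semi) -> np.ndarray:
    x, y, z = np.ix_(axes[0], axes[1], axes[2])
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _tube_z(axes, center_xy_of_z, radius, z_range) -> np.ndarray:
    """Tube of given radius around a (possibly curved) path along z."""
    x, y, z = np.ix_(axes[0], axes[1], axes[2])
    cx, cy = center_xy_of_z(axes[2])  # arrays over z
    inside_z = (z >= z_range[0]) & (z <= z_range[1])
    return (((x - cx[None, None, :]) ** 2 + (y - cy[None, None, :]) ** 2) <= radius**2) & inside_z


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Tuple[DoseGrid, StructureSet]:
    """Build the thorax anatomy; returns (grid geometry token, structures).

    Deterministic for a fixed spec (the seed drives small jitters of organ
    centers).  Raises when a structure cannot fit in the grid or the PTV
    volume falls outside the requested range.
    """
    origin, spacing, axes = _grid_axes(spec)
    rng = np.random.default_rng(spec.seed)
    jit = lambda: rng.uniform(-spec.jitter_mm, spec.jitter_mm)  # noqa: E731

    half_extent = spacing * (np.asarray(spec.shape) - 1) / 2.0
    if np.any(np.asarray(spec.body_semiaxes) > half_extent + 1e-9):
        raise ValueError("body does not fit inside the grid extent")

    geometry = DoseGrid(origin, spacing, np.zeros(spec.shape))
    fid = geometry.frame_id

    body = _ellipsoid(axes, (0.0, 0.0, 0.0), spec.body_semiaxes)

    s = spec.side_sign
    lung_dz = (jit(), jit())
    lung_ipsi = _ellipsoid(axes, (s * spec.lung_center_x + jit(), jit(), lung_dz[0]), spec.lung_semiaxes)
    lung_contra = _ellipsoid(axes, (-s * spec.lung_center_x + jit(), jit(), lung_dz[1]), spec.lung_semiaxes)
    lungs = (lung_ipsi | lung_contra) & body

    if spec.ptv_center is None:
        ptv_center = (s * spec.lung_center_x + jit(), -5.0 + jit(), jit())
    else:
        ptv_center = spec.ptv_center
    r = spec.ptv_radius
    ptv = _ellipsoid(axes, ptv_center, (r, r, r))
    r_ctv = r - spec.ctv_margin
    if r_ctv <= 0:
        raise ValueError("PTV radius too small for the CTV margin")
    ctv = _ellipsoid(axes, ptv_center, (r_ctv, r_ctv, r_ctv))

    if np.any(ptv & ~body):
        raise ValueError("PTV does not fit inside the body")

    esoph = _tube_z(
        axes,
        lambda z: (5.0 * np.sin(2 * np.pi * z / 400.0), np.full_like(z, 25.0)),
        spec.esophagus_radius,
        (-spec.body_semiaxes[2] * 0.9, spec.body_semiaxes[2] * 0.9),
    ) & body

    heart = _ellipsoid(axes, (15.0 + jit(), 15.0 + jit(), -30.0 + jit()), spec.heart_semiaxes) & body

    cord = _tube_z(
        axes,
        lambda z: (np.zeros_like(z), np.full_like(z, spec.cord_y)),
        spec.cord_radius,
        (-spec.body_semiaxes[2], spec.body_semiaxes[2]),
    ) & body

    sset = StructureSet()
    for name, occ in [
        ("Body", body),
        ("PTV", ptv),
        ("CTV", ctv),
        ("Lungs", lungs),
        ("Esophagus", esoph),
        ("Heart", heart),
        ("SpinalCord", cord),
    ]:
        sset.add(StructureMask(name, occ, fid))
    sset.add(expand_margin(sset["SpinalCord"], spec.prv_margin, spacing).renamed("SpinalCord_PRV"))

    problems = sset.validate()
    if problems:
        raise ValueError(f"generated anatomy violates invariants: {problems}")
    if np.any(lungs & cord):
        raise ValueError("lungs overlap the spinal cord")

    vol = sset["PTV"].volume_cc(spacing)
    lo, hi = spec.ptv_volume_range_cc
    if not (lo <= vol <= hi):
        raise ValueError(f"PTV volume {vol:.1f} cc outside requested range {lo}-{hi} cc")
    return geometry, sset


def make_reference_dose(
    geometry: DoseGrid,
    structures: StructureSet,
    rx: Prescription = Prescription(),
    falloff_mm: float = 12.0,
    bath_level_percent: float = 8.0,
    side: str = "right",
) -> DoseGrid:
    """Closed-form, clinically shaped dose field, plan-normalized.

    Inside the PTV: a near-uniform plateau between 98% and 104% of
    prescription (within the clinical 95–107% window) before normalization.
    Outside: 100% · exp(-d/falloff) with d the Euclidean distance to the
    PTV surface, plus a low-dose bath of ``bath_level_percent`` weighted
    toward the tumor side.  Zero outside the Body; the returned field is
    normalized so PTV D50% equals the prescription.
    """
    spacing = geometry.spacing
    ptv = structures["PTV"].occupancy
    body = structures["Body"].occupancy
    if not ptv.any():
        raise ValueError("PTV is empty")

    d_out = ndimage.distance_transform_edt(~ptv, sampling=spacing)
    d_in = ndimage.distance_transform_edt(ptv, sampling=spacing)

    pct = np.where(
        ptv,
        104.0 - 6.0 * np.exp(-d_in / 20.0),
        100.0 * np.exp(-d_out / falloff_mm),
    )
    if bath_level_percent > 0:
        sgn = -1.0 if side == "right" else 1.0
        xs = geometry.voxel_centers()[0]
        lateral_w = 0.625 + 0.375 * np.tanh(sgn * xs / 30.0)  # ipsi 1.0, contra 0.25
        bath = bath_level_percent * lateral_w[:, None, None] * np.exp(-d_out / (4.0 * falloff_mm))
        pct = pct + np.where(ptv, 0.0, bath)
    pct[~body] = 0.0

    dose = geometry.with_values(pct / 100.0 * rx.total_dose)
    return normalize_dose(dose, structures["PTV"], rx)


def perturb_dose(
    dose: DoseGrid, p: DosePerturbation, rx: Prescription = Prescription()
) -> DoseGrid:
    """Apply a calibrated perturbation; deterministic per seed.

    ``uniform_shift`` adds magnitude% of the prescription everywhere (so
    the body-restricted MAE against the original is exactly the magnitude);
    ``multiplicative`` scales by (1 + magnitude/100); ``smooth_noise`` adds
    a Gaussian-correlated field scaled so its mean absolute value is
    magnitude% of prescription, flipping the local sign where a negative
    shift would undershoot zero (the perturbation magnitude is preserved);
    ``low_dose_bath`` adds a one-sided smooth bath.  Results never go
    negative.
    """
    v = dose.values
    amp_gy = p.magnitude / 100.0 * rx.total_dose
    if p.mode == "uniform_shift":
        out = v + amp_gy
    elif p.mode == "multiplicative":
        out = v * (1.0 + p.magnitude / 100.0)
    elif p.mode == "smooth_noise":
        rng = np.random.default_rng(p.seed)
        noise = rng.standard_normal(v.shape)
        sigma_vox = np.maximum(p.correlation_length_mm / dose.spacing, 1e-6)
        # periodic smoothing keeps the field stationary, so the calibrated
        # mean |noise| holds on any interior sub-region (e.g. the Body)
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
        mean_abs = np.mean(np.abs(noise))
        if mean_abs > 0:
            noise = noise / mean_abs
        shift = amp_gy * noise
        # keep the perturbation magnitude where a negative shift would
        # undershoot zero: flip its sign there instead of clamping it away
        out = np.where(v + shift < 0, v - shift, v + shift)
    else:  # low_dose_bath
        xs = dose.voxel_centers()[0]
        w = 0.5 * (1.0 + np.tanh(xs / 40.0))
        out = v + amp_gy * w[:, None, None]
    return dose.with_values(np.clip(out, 0.0, None))


def make_vmat_plan(
    seed: int = 0,
    n_control_points: int = 16,
    modulation_level: float = 0.0,
    machine: MachineSpec = MachineSpec(),
    side: str = "right",
    total_mu: float = 500.0,
) -> VMATPlan:
    """Synthetic two-half-arc VMAT control-point sequence.

    ``modulation_level`` 0 produces identical, fully open apertures with
    uniform MU (MCSv = 1); larger values randomly shrink and shift the
    apertures and unbalance the MU weights, increasing inter-control-point
    variability.  Right-sided arcs run 181°→0°, left-sided 0°→179°.
    """
    if n_control_points < 2:
        raise ValueError("need at least 2 control points")
    if not 0.0 <= modulation_level <= 1.0:
        raise ValueError("modulation_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_control_points)
    gantry = (181.0 + 179.0 * t) % 360.0 if side == "right" else 179.0 * t

    n_leaves = machine.n_leaves
    half = machine.max_extent_mm / 2.0
    m = modulation_level
    halfwidth = half * (1.0 - m * rng.random((n_control_points, n_leaves)))
    center = m * (half / 2.0) * rng.uniform(-1.0, 1.0, (n_control_points, n_leaves))
    left = np.clip(center - halfwidth, -half, half)
    right = np.clip(center + halfwidth, -half, half)

    mu = 1.0 + m * rng.random(n_control_points)
    seg_total = float(0.5 * (mu[:-1] + mu[1:]).sum())
    mu *= total_mu / seg_total

    return VMATPlan(
        gantry_deg=gantry,
        mu_weight=mu,
        left=left,
        right=right,
        leaf_widths_mm=machine.leaf_widths,
        max_extent_mm=machine.max_extent_mm,
    )
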