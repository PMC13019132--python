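"""Dose grids, structure masks and geometric operations.

The package works on regular 3D voxel grids.  A :class:`DoseGrid` holds a
scalar dose field (Gy) together with its geometry; a :class:`StructureMask`
holds a boolean occupancy map on the same geometry.  The coordinate
convention is fixed throughout: voxel ``(i, j, k)`` has its *center* at
``origin + (i, j, k) * spacing`` (millimetres, 0-based indices, axis order
x/y/z).  Volumes in cc are voxel counts times the voxel volume.

Grids that share a geometry carry the same ``frame_id``; operations that
combine two grids require matching frames and refuse to guess.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "DoseGrid",
    "StructureMask",
    "StructureSet",
    "Prescription",
    "FrameMismatchError",
    "resample_to",
    "expand_margin",
    "mask_union",
    "mask_intersect",
    "mask_subtract",
]

#: Structure names every planning/evaluation pipeline in this package expects.
REQUIRED_STRUCTURES = (
    "Body",
    "PTV",
    "CTV",
    "Lungs",
    "Esophagus",
    "Heart",
    "SpinalCord",
    "SpinalCord_PRV",
)


class FrameMismatchError(ValueError):
    """Two grids/masks with different geometries were combined."""


def geometry_frame_id(origin: Sequence[float], spacing: Sequence[float], shape: Sequence[int]) -> str:
    """Deterministic frame identifier derived from the grid geometry.

    Grids constructed independently with identical geometry compare equal,
    which is the behaviour wanted for synthetic phantoms and round-trips.
    """
    h = hashlib.sha1()
    h.update(np.asarray(origin, dtype=np.float64).round(6).tobytes())
    h.update(np.asarray(spacing, dtype=np.float64).round(6).tobytes())
    h.update(np.asarray(shape, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _as_vec3(x, dtype=np.float64) -> np.ndarray:
    v = np.asarray(x, dtype=dtype).reshape(3)
    return v


@dataclass
class DoseGrid:
    """A 3D dose distribution on a regular grid.

    Parameters
    ----------
    origin : (3,) float
        World position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel size (mm) per axis; strictly positive.
    values : (nx, ny, nz) float array
        Dose per voxel in Gy; finite and non-negative.
    frame_id : str, optional
        Geometry identifier; derived from the geometry when omitted.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame_id: str = ""

    def __post_init__(self):
        self.origin = _as_vec3(self.origin)
        self.spacing = _as_vec3(self.spacing)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"dose values must be 3D, got shape {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if not self.frame_id:
            self.frame_id = geometry_frame_id(self.origin, self.spacing, self.values.shape)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_frame(self, other) -> bool:
        return self.frame_id == other.frame_id

    def voxel_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """New grid with identical geometry and replaced values."""
        return DoseGrid(self.origin.copy(), self.spacing.copy(), np.asarray(values), self.frame_id)

    def geometry_like(self) -> "DoseGrid":
        """Zero-valued grid with this geometry (convenient geometry token)."""
        return self.with_values(np.zeros(self.shape))


@dataclass
class StructureMask:
    """A named boolean occupancy mask sharing a DoseGrid geometry."""

    name: str
    occupancy: np.ndarray
    frame_id: str

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3D")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def volume_cc(self, spacing: Sequence[float]) -> float:
        return self.voxel_count * float(np.prod(np.asarray(spacing))) / 1000.0

    def renamed(self, name: str) -> "StructureMask":
        return StructureMask(name, self.occupancy, self.frame_id)


@dataclass
class StructureSet:
    """Collection of structure masks on one common grid geometry."""

    masks: Dict[str, StructureMask] = field(default_factory=dict)

    def __post_init__(self):
        frames = {m.frame_id for m in self.masks.values()}
        if len(frames) > 1:
            raise FrameMismatchError(f"masks span multiple frames: {sorted(frames)}")

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def names(self) -> List[str]:
        return list(self.masks)

    @property
    def frame_id(self) -> Optional[str]:
        for m in self.masks.values():
            return m.frame_id
        return None

    def add(self, mask: StructureMask) -> None:
        fid = self.frame_id
        if fid is not None and mask.frame_id != fid:
            raise FrameMismatchError(
                f"mask {mask.name!r} frame {mask.frame_id} != set frame {fid}"
            )
        self.masks[mask.name] = mask

    def missing_required(self) -> List[str]:
        return [n for n in REQUIRED_STRUCTURES if n not in self.masks]

    def validate(self, require_all: bool = True) -> List[str]:
        """Check containment invariants; returns a list of violation messages.

        CTV ⊆ PTV ⊆ Body and SpinalCord ⊆ SpinalCord_PRV must hold for a
        planning-ready anatomy.
        """
        problems: List[str] = []
        if require_all:
            missing = self.missing_required()
            if missing:
                problems.append(f"missing required structures: {missing}")
        pairs = [("CTV", "PTV"), ("PTV", "Body"), ("SpinalCord", "SpinalCord_PRV")]
        for inner, outer in pairs:
            if inner in self and outer in self:
                if np.any(self[inner].occupancy & ~self[outer].occupancy):
                    problems.append(f"{inner} not contained in {outer}")
        return problems


@dataclass(frozen=True)
class Prescription:
    """Prescribed dose and the fixed plan-normalization rule.

    The normalization rule is structural: every plan is rescaled so that
    50% of the PTV volume receives 100% of ``total_dose``.
    """

    total_dose: float = 60.0
    fractions: int = 30

    def __post_init__(self):
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.fractions


# ---------------------------------------------------------------------------
# geometric operations


def resample_to(grid: DoseGrid, reference: DoseGrid) -> DoseGrid:
    """Resample ``grid`` onto the geometry of ``reference``.

    Trilinear interpolation at the reference voxel centers; points outside
    the source extent evaluate to 0 Gy.  The result carries the reference
    frame.  Raises if the two extents are spatially disjoint.
    """
    if grid.frame_id == reference.frame_id:
        return reference.with_values(grid.values.copy())

    src_lo = grid.origin
    src_hi = grid.origin + grid.spacing * (np.asarray(grid.shape) - 1)
    ref_lo = reference.origin
    ref_hi = reference.origin + reference.spacing * (np.asarray(reference.shape) - 1)
    if np.any(src_hi < ref_lo) or np.any(src_lo > ref_hi):
        raise ValueError("source and reference grids do not overlap spatially")

    axes = reference.voxel_centers()
    xg, yg, zg = np.meshgrid(*axes, indexing="ij")
    coords = np.stack(
        [(xg - grid.origin[0]) / grid.spacing[0],
         (yg - grid.origin[1]) / grid.spacing[1],
         (zg - grid.origin[2]) / grid.spacing[2]]
    )
    out = ndimage.map_coordinates(grid.values, coords, order=1, mode="constant", cval=0.0)
    return reference.with_values(out)


def expand_margin(mask: StructureMask, margin_mm: float, spacing: Sequence[float]) -> StructureMask:
    """Isotropic Euclidean dilation of a mask by ``margin_mm``.

    A voxel is set in the output iff its center lies within ``margin_mm``
    of the center of some occupied input voxel, so the operation is exactly
    checkable against brute-force lattice enumeration.  Extensive
    (output ⊇ input) and monotone in the margin.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    occ = mask.occupancy
    if margin_mm == 0 or not occ.any():
        return StructureMask(mask.name, occ.copy(), mask.frame_id)
    dist = ndimage.distance_transform_edt(~occ, sampling=np.asarray(spacing, dtype=float))
    return StructureMask(mask.name, dist <= margin_mm + 1e-9, mask.frame_id)


def _check_frames(a: StructureMask, b: StructureMask) -> None:
    if a.frame_id != b.frame_id:
        raise FrameMismatchError(f"{a.name!r} and {b.name!r} live on different frames")


def mask_union(a: StructureMask, b: StructureMask, name: Optional[str] = None) -> StructureMask:
    _check_frames(a, b)
    return StructureMask(name or f"{a.name}|{b.name}", a.occupancy | b.occupancy, a.frame_id)


def mask_intersect(a: StructureMask, b: StructureMask, name: Optional[str] = None) -> StructureMask:
    _check_frames(a, b)
    return StructureMask(name or f"{a.name}&{b.name}", a.occupancy & b.occupancy, a.frame_id)


def mask_subtract(a: StructureMask, b: StructureMask, name: Optional[str] = None) -> StructureMask:
    _check_frames(a, b)
    return StructureMask(name or f"{a.name}-{b.name}", a.occupancy & ~b.occupancy, a.frame_id)
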