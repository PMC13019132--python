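"""Simplified beamlet dose engine and dose-volume optimizer.

The engine stands in for a clinical optimizer's dose model at desk scale.
Each arc control point contributes a rectangular grid of beamlets (leaf
rows stacked in z, lateral bins across the field).  A beamlet deposits

    dose(v) = exp(-mu * waterpath(v)) * exp(-r^2 / (2 sigma^2)),   r <= 3 sigma

per unit weight, where ``waterpath`` is the path length through the Body
upstream of the voxel along the beam direction and ``r`` the lateral
distance of the voxel from the beamlet central axis.  Beams are parallel
(no divergence) and the medium is water-equivalent.

The optimizer is projected first-order descent with backtracking on the
quadratic one-sided objective penalty; the recorded objective trace is
non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .complexity import VMATPlan
from .grids import DoseGrid, Prescription, StructureSet
from .mimic import DoseObjective

__all__ = [
    "ArcSpec",
    "BeamletMatrix",
    "OptimizationResult",
    "arc_gantry_angles",
    "compute_beamlet_matrix",
    "optimize_weights",
    "weights_to_apertures",
]


@dataclass(frozen=True)
class ArcSpec:
    """Two half-arc VMAT geometry: 181°→0° for right-sided targets and
    0°→179° for left-sided ones, sampled at ``n_control_points``."""

    side: str = "right"
    n_control_points: int = 16

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.n_control_points < 2:
            raise ValueError("need at least 2 control points")


def arc_gantry_angles(arc: ArcSpec) -> np.ndarray:
    """Gantry angles (deg) of the arc's control points."""
    t = np.linspace(0.0, 1.0, arc.n_control_points)
    if arc.side == "right":
        return (181.0 + 179.0 * t) % 360.0
    return 179.0 * t


def _beam_axes(gantry_deg: float) -> Tuple[np.ndarray, np.ndarray]:
    """(beam direction, lateral unit vector) in the axial plane.

    Gantry 0° has the source anterior of the patient (beam travels +y);
    gantry 270° (right-sided arcs) shoots from the patient's right (+x).
    """
    th = np.deg2rad(gantry_deg)
    direction = np.array([-np.sin(th), np.cos(th), 0.0])
    lateral = np.array([np.cos(th), np.sin(th), 0.0])
    return direction, lateral


@dataclass
class BeamletMatrix:
    """Sparse dose-per-unit-weight matrix over Body voxels.

    ``matrix`` has one row per Body voxel (flat grid index in
    ``voxel_index``) and one column per beamlet; beamlet ``b`` maps to
    (control point, leaf row, lateral bin) = unravel(b, (n_cp, n_rows,
    n_bins)).
    """

    matrix: sparse.csr_matrix
    voxel_index: np.ndarray  # flat indices into the grid, sorted
    geometry: DoseGrid  # geometry token (values ignored)
    gantry_deg: np.ndarray
    n_rows: int
    n_bins: int
    row_centers_z: np.ndarray  # mm, world z of leaf rows
    bin_offsets: np.ndarray  # mm, lateral offsets of bins from the field center
    row_width_mm: float
    bin_width_mm: float

    @property
    def n_control_points(self) -> int:
        return int(self.gantry_deg.size)

    @property
    def n_beamlets(self) -> int:
        return int(self.matrix.shape[1])

    def achieved_dose(self, weights: np.ndarray) -> DoseGrid:
        """Scatter ``matrix @ weights`` back onto the full grid."""
        flat = np.zeros(int(np.prod(self.geometry.shape)))
        flat[self.voxel_index] = self.matrix @ np.asarray(weights, dtype=float)
        return self.geometry.with_values(flat.reshape(self.geometry.shape))


def compute_beamlet_matrix(
    geometry: DoseGrid,
    structures: StructureSet,
    arc: ArcSpec,
    mu_per_mm: float = 0.005,
    sigma_mm: float = 4.0,
    row_width_mm: float = 5.0,
    bin_width_mm: float = 5.0,
    field_margin_mm: float = 15.0,
    depth_step_mm: Optional[float] = None,
) -> BeamletMatrix:
    """Build the beamlet dose matrix for one two-half-arc geometry.

    The beamlet field covers the PTV cross-section plus ``field_margin_mm``
    in the leaf-row (z) and lateral directions.  Water paths are ray-marched
    through the Body mask with step ``depth_step_mm`` (defaults to the mean
    voxel spacing).
    """
    if "Body" not in structures or not structures["Body"].occupancy.any():
        raise ValueError("a non-empty Body structure is required")
    body = structures["Body"].occupancy
    target = structures["PTV"] if "PTV" in structures else structures["Body"]
    if not target.occupancy.any():
        raise ValueError("target structure is empty")

    xs, ys, zs = geometry.voxel_centers()
    flat_idx = np.flatnonzero(body.ravel())
    ii, jj, kk = np.unravel_index(flat_idx, geometry.shape)
    vx, vy, vz = xs[ii], ys[jj], zs[kk]

    # field extent from the target
    ti, tj, tk = np.nonzero(target.occupancy)
    tx, ty, tz = xs[ti], ys[tj], zs[tk]
    cx, cy = float(tx.mean()), float(ty.mean())
    lat_half = float(np.max(np.hypot(tx - cx, ty - cy))) + field_margin_mm
    z_lo, z_hi = float(tz.min()) - field_margin_mm, float(tz.max()) + field_margin_mm

    n_rows = max(int(np.ceil((z_hi - z_lo) / row_width_mm)), 1)
    row_centers = z_lo + (np.arange(n_rows) + 0.5) * row_width_mm
    n_bins = max(int(np.ceil(2 * lat_half / bin_width_mm)), 1)
    bin_offsets = (np.arange(n_bins) + 0.5) * bin_width_mm - n_bins * bin_width_mm / 2.0

    step = depth_step_mm if depth_step_mm is not None else float(geometry.spacing.mean())
    extent = geometry.spacing * (np.asarray(geometry.shape) - 1)
    max_path = float(np.hypot(extent[0], extent[1]))
    n_steps = int(np.ceil(max_path / step))

    gantry = arc_gantry_angles(arc)
    cutoff = 3.0 * sigma_mm
    cutoff2 = cutoff * cutoff
    inv2s2 = 1.0 / (2.0 * sigma_mm * sigma_mm)

    rows_out: List[np.ndarray] = []
    cols_out: List[np.ndarray] = []
    vals_out: List[np.ndarray] = []
    n_rowvox = flat_idx.size

    for ci, ang in enumerate(gantry):
        direction, lateral = _beam_axes(float(ang))
        u = vx * lateral[0] + vy * lateral[1]
        u_center = cx * lateral[0] + cy * lateral[1]

        # water-equivalent depth: march upstream through the Body mask
        depth = np.zeros(n_rowvox)
        for s in range(1, n_steps + 1):
            px = vx - s * step * direction[0]
            py = vy - s * step * direction[1]
            gi = np.rint((px - geometry.origin[0]) / geometry.spacing[0]).astype(np.intp)
            gj = np.rint((py - geometry.origin[1]) / geometry.spacing[1]).astype(np.intp)
            inside = (gi >= 0) & (gi < body.shape[0]) & (gj >= 0) & (gj < body.shape[1])
            hit = np.zeros(n_rowvox, dtype=bool)
            hit[inside] = body[gi[inside], gj[inside], kk[inside]]
            depth += step * hit
        att = np.exp(-mu_per_mm * depth)

        order = np.argsort(u, kind="stable")
        u_sorted = u[order]
        for r in range(n_rows):
            dz_all = vz - row_centers[r]
            for b in range(n_bins):
                ub = u_center + bin_offsets[b]
                lo = np.searchsorted(u_sorted, ub - cutoff)
                hi = np.searchsorted(u_sorted, ub + cutoff)
                if hi <= lo:
                    continue
                sel = order[lo:hi]
                du = u[sel] - ub
                dz = dz_all[sel]
                r2 = du * du + dz * dz
                keep = r2 <= cutoff2
                if not keep.any():
                    continue
                sel = sel[keep]
                val = att[sel] * np.exp(-r2[keep] * inv2s2)
                col = (ci * n_rows + r) * n_bins + b
                rows_out.append(sel)
                cols_out.append(np.full(sel.size, col, dtype=np.intp))
                vals_out.append(val)

    n_beamlets = gantry.size * n_rows * n_bins
    if rows_out:
        coo = sparse.coo_matrix(
            (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
            shape=(n_rowvox, n_beamlets),
        )
        mat = coo.tocsr()
    else:
        mat = sparse.csr_matrix((n_rowvox, n_beamlets))

    return BeamletMatrix(
        matrix=mat,
        voxel_index=flat_idx,
        geometry=geometry.geometry_like(),
        gantry_deg=gantry,
        n_rows=n_rows,
        n_bins=n_bins,
        row_centers_z=row_centers,
        bin_offsets=bin_offsets,
        row_width_mm=row_width_mm,
        bin_width_mm=bin_width_mm,
    )


# ---------------------------------------------------------------------------
# optimization


@dataclass
class OptimizationResult:
    weights: np.ndarray
    achieved_dose: DoseGrid  # matrix @ weights on the optimization grid
    trace: np.ndarray  # total penalty per accepted iterate, non-increasing
    converged: bool
    per_objective: dict = field(default_factory=dict)


def _objective_rows(
    matrix: BeamletMatrix, objectives: Sequence[DoseObjective], structures: StructureSet
):
    """Per objective: (row positions in the matrix, N voxels, constant term)."""
    prepared = []
    for obj in objectives:
        if obj.structure not in structures:
            raise ValueError(f"objective structure {obj.structure!r} not available")
        occ = structures[obj.structure].occupancy
        n = int(occ.sum())
        if n == 0:
            warnings.warn(f"objective structure {obj.structure!r} is empty; contributes 0")
            prepared.append((obj, np.empty(0, dtype=np.intp), 1, 0.0))
            continue
        flat = np.flatnonzero(occ.ravel())
        pos = np.searchsorted(matrix.voxel_index, flat)
        clipped = np.clip(pos, 0, matrix.voxel_index.size - 1)
        valid = matrix.voxel_index[clipped] == flat
        pos = clipped[valid]
        # voxels of the structure outside the matrix rows always receive 0 Gy:
        # Lower objectives pick up a constant penalty for them
        n_off = n - pos.size
        const = obj.priority / n * n_off * obj.dose**2 if obj.kind == "Lower" else 0.0
        prepared.append((obj, pos.astype(np.intp), n, const))
    return prepared


def _penalty_and_residual(d: np.ndarray, prepared, want_grad: bool):
    total = 0.0
    per = {}
    c = np.zeros_like(d) if want_grad else None
    for i, (obj, pos, n, const) in enumerate(prepared):
        if pos.size == 0:
            val = const
        else:
            if obj.kind == "Upper":
                r = np.clip(d[pos] - obj.dose, 0.0, None)
                sgn = 1.0
            else:
                r = np.clip(obj.dose - d[pos], 0.0, None)
                sgn = -1.0
            val = obj.priority / n * float(np.sum(r * r)) + const
            if want_grad and r.size:
                np.add.at(c, pos, sgn * (2.0 * obj.priority / n) * r)
        key = f"{obj.structure} {obj.kind} {obj.dose:g}Gy"
        per[key if key not in per else f"{key} #{i}"] = val
        total += val
    return total, per, c


def optimize_weights(
    matrix: BeamletMatrix,
    objectives: Sequence[DoseObjective],
    structures: StructureSet,
    iterations: int = 200,
    tol: float = 1e-6,
    seed: Optional[int] = None,
    init: str = "uniform",
    rx: Optional[Prescription] = None,
) -> OptimizationResult:
    """Projected gradient descent with backtracking on the objective penalty.

    Weights stay non-negative; the objective trace is non-increasing (a
    failed line search terminates the run).  ``converged`` reports whether
    the relative decrease fell below ``tol`` within the iteration budget.
    Deterministic; ``seed`` only matters for ``init='random'``.
    """
    if matrix.n_beamlets == 0 or matrix.matrix.nnz == 0:
        raise ValueError("empty beamlet matrix")
    if not objectives:
        raise ValueError("no objectives to optimize")

    A = matrix.matrix
    prepared = _objective_rows(matrix, objectives, structures)

    target = rx.total_dose if rx is not None else 60.0
    if init == "random":
        rng = np.random.default_rng(seed)
        w = rng.random(matrix.n_beamlets)
    else:
        w = np.ones(matrix.n_beamlets)
    d1 = A @ w
    # scale the initial weights so target-level objectives start in range
    lower_rows = np.concatenate(
        [pos for (obj, pos, _, _) in prepared if obj.kind == "Lower" and pos.size]
        or [np.arange(d1.size)]
    )
    ref = float(np.mean(d1[lower_rows])) if lower_rows.size else float(d1.mean())
    if ref > 0:
        w *= target / ref

    d = A @ w
    f, per, _ = _penalty_and_residual(d, prepared, want_grad=False)
    trace = [f]
    step = 1.0
    converged = False
    for _ in range(iterations):
        _, _, c = _penalty_and_residual(d, prepared, want_grad=True)
        g = A.T @ c
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            converged = True
            break
        accepted = False
        t = step
        for _bt in range(40):
            w_new = np.clip(w - t * g, 0.0, None)
            d_new = A @ w_new
            f_new, per_new, _ = _penalty_and_residual(d_new, prepared, want_grad=False)
            if f_new <= f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True
            break
        step = t * 2.0
        rel = (f - f_new) / max(f, 1e-300)
        w, d, f, per = w_new, d_new, f_new, per_new
        trace.append(f)
        if rel < tol:
            converged = True
            break

    return OptimizationResult(
        weights=w,
        achieved_dose=matrix.achieved_dose(w),
        trace=np.asarray(trace),
        converged=converged,
        per_objective=per,
    )


# ---------------------------------------------------------------------------
# deliverability proxy: weights -> apertures


def weights_to_apertures(
    result: OptimizationResult,
    matrix: BeamletMatrix,
    open_fraction: float = 0.2,
) -> VMATPlan:
    """Convert beamlet weights into one MLC aperture per control point.

    Per control point and leaf row, the leaves open over the longest
    contiguous run of lateral bins whose weight exceeds ``open_fraction``
    of that control point's peak weight; the control point's MU weight is
    the mean retained beamlet weight.  An all-zero solution yields an
    all-closed, zero-MU plan (flagged with a warning).
    """
    n_cp, n_rows, n_bins = matrix.n_control_points, matrix.n_rows, matrix.n_bins
    w = np.asarray(result.weights, dtype=float).reshape(n_cp, n_rows, n_bins)
    half_bin = matrix.bin_width_mm / 2.0
    left = np.zeros((n_cp, n_rows))
    right = np.zeros((n_cp, n_rows))
    mu = np.zeros(n_cp)
    for ci in range(n_cp):
        peak = float(w[ci].max())
        if peak <= 0:
            continue
        thresh = open_fraction * peak
        retained: List[float] = []
        for r in range(n_rows):
            above = w[ci, r] >= thresh
            if not above.any():
                continue
            # longest contiguous run of open bins
            best_len, best_lo = 0, 0
            run_lo = None
            for b in range(n_bins + 1):
                on = b < n_bins and above[b]
                if on and run_lo is None:
                    run_lo = b
                elif not on and run_lo is not None:
                    if b - run_lo > best_len:
                        best_len, best_lo = b - run_lo, run_lo
                    run_lo = None
            lo, hi = best_lo, best_lo + best_len - 1
            left[ci, r] = matrix.bin_offsets[lo] - half_bin
            right[ci, r] = matrix.bin_offsets[hi] + half_bin
            retained.extend(w[ci, r, lo : hi + 1].tolist())
        mu[ci] = float(np.mean(retained)) if retained else 0.0
    if mu.sum() == 0:
        warnings.warn("all-zero beamlet weights: emitting an all-closed, zero-MU plan")
    return VMATPlan(
        gantry_deg=matrix.gantry_deg.copy(),
        mu_weight=mu,
        left=left,
        right=right,
        leaf_widths_mm=np.full(n_rows, matrix.row_width_mm),
        max_extent_mm=n_bins * matrix.bin_width_mm,
    )
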