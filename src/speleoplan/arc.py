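"""Arc and fixed-field planning: spot placement, energy segmentation,
beamlet-library assembly and non-negative least-squares weight optimisation.

An arc delivery scans one beam's-eye-view (BEV) column of spots at each
discrete gantry angle while the filter provides the depth modulation; a
greedy partition of the arc into contiguous angular segments assigns the
few energies needed to keep the filter's SOBP on the target's radiological
depth interval.  Fixed-field IMPT plans enumerate conventional energy
layers on a 2.5 MeV grid instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .engine import (Beamlet, BeamModel, beamlet_dose, bragg_curve,
                     effective_curve, proton_range,
                     radiological_depth_profile, _gantry_frame)
from .filters import SpeleoFilter, wet_histogram
from .grids import DoseGrid, Phantom

__all__ = [
    "ArcLayout", "EnergySegment", "Plan", "DoseInfluence", "WeightResult",
    "place_spots_arc", "place_spots_impt", "impt_energy_layers",
    "segment_energies", "assign_segment_energies",
    "build_dose_influence", "optimize_weights", "count_energy_changes",
    "target_depth_interval", "filter_sobp_interval",
]


@dataclass
class ArcLayout:
    span: tuple[float, float] = (0.0, 360.0)
    angle_step: float = 1.0
    mode: str = "arc"              # "arc" or "fixed_fields"
    field_angles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("arc stop angle must exceed start angle")
        if self.angle_step <= 0:
            raise ValueError("angle_step must be positive")
        if self.mode not in ("arc", "fixed_fields"):
            raise ValueError("mode must be 'arc' or 'fixed_fields'")

    @property
    def angles(self) -> np.ndarray:
        if self.mode == "fixed_fields":
            return np.asarray(self.field_angles, dtype=float)
        return np.arange(self.span[0], self.span[1], self.angle_step)


@dataclass
class EnergySegment:
    angle_start: float
    angle_stop: float
    energy: float
    max_violation_mm: float = 0.0


@dataclass
class Plan:
    spots: list[Beamlet]
    layout: ArcLayout
    energy_segments: list[EnergySegment] = field(default_factory=list)
    filter_id: str | None = None

    def __post_init__(self) -> None:
        if any(s.weight < 0 for s in self.spots):
            raise ValueError("spot weights must be >= 0")
        if self.layout.mode == "arc" and self.energy_segments:
            for s in self.spots:
                seg = self._segment_of(s.gantry_angle)
                if seg is not None and abs(s.energy - seg.energy) > 1e-6:
                    raise ValueError(
                        f"spot at {s.gantry_angle} deg has energy "
                        f"{s.energy}, segment demands {seg.energy}")

    def _segment_of(self, angle: float) -> EnergySegment | None:
        for seg in self.energy_segments:
            if seg.angle_start - 1e-9 <= angle <= seg.angle_stop + 1e-9:
                return seg
        return None

    def with_weights(self, weights: np.ndarray) -> "Plan":
        spots = [Beamlet(s.bev_x, s.bev_y, s.energy, s.gantry_angle,
                         float(w)) for s, w in zip(self.spots, weights)]
        return Plan(spots, self.layout, self.energy_segments, self.filter_id)


# ---------------------------------------------------------------------------
# Spot placement

def _target_bev_extent(phantom: Phantom, angle: float):
    """(min, max) of target voxel centres along BEV x and y at an angle."""
    t = phantom.roi_masks["target"]
    if not np.any(t):
        raise ValueError("target mask is empty")
    xs, ys, zs = phantom.axes
    ii, jj, kk = np.nonzero(t)
    _, ex, _ = _gantry_frame(angle)
    bx = xs[ii] * ex[0] + zs[kk] * ex[2]
    return (bx.min(), bx.max()), (ys[jj].min(), ys[jj].max())


SECONDARY_OFFSETS = (-5.0, -2.5, 0.0, 2.5, 5.0)


def place_spots_arc(phantom: Phantom, layout: ArcLayout, beam: BeamModel, *,
                    primary_spacing: float = 5.0, margin: float = 5.0,
                    mode: str = "bev_columns") -> list[Beamlet]:
    """Spot positions over an arc (energies assigned later by segment).

    ``mode="bev_columns"``: primary BEV columns at ``primary_spacing``
    cover the target's BEV x extent plus margin; each column is delivered
    at one discrete angle (columns spread evenly over the arc) together
    with secondary columns offset by +/-2.5 and +/-5 mm along the scan
    advance, so a 10 mm band is scanned per angle.  Rows cover the BEV y
    extent at ``primary_spacing``.

    ``mode="full_surface"``: the full filter surface is scanned at every
    discrete angle with ``beam.spot_spacing`` (the fixed-filter study
    layout); for planar (single-voxel-y) phantoms only the y = 0 row is
    used.
    """
    angles = layout.angles
    spots: list[Beamlet] = []
    planar = phantom.shape[1] == 1
    e0 = beam.nominal_energy
    if mode == "full_surface":
        half_x = beam.field_size[0] / 2
        xcols = np.arange(-half_x, half_x + 1e-9, beam.spot_spacing)
        if planar:
            yrows = np.array([0.0])
        else:
            half_y = beam.field_size[1] / 2
            yrows = np.arange(-half_y, half_y + 1e-9, beam.spot_spacing)
        for ang in angles:
            for x in xcols:
                for y in yrows:
                    spots.append(Beamlet(float(x), float(y), e0, float(ang)))
        return spots
    if mode != "bev_columns":
        raise ValueError(f"unknown spot placement mode {mode!r}")

    (bx0, bx1), (by0, by1) = _target_bev_extent(phantom, float(angles[0]))
    cols = np.arange(bx0 - margin, bx1 + margin + 1e-9, primary_spacing)
    if planar:
        rows = np.array([0.0])
    else:
        rows = np.arange(by0 - margin, by1 + margin + 1e-9, primary_spacing)
    half_x = beam.field_size[0] / 2
    half_y = beam.field_size[1] / 2
    # each primary column is delivered at one angle, spread over the arc
    col_angles = angles[np.linspace(0, len(angles) - 1,
                                    len(cols)).round().astype(int)]
    uncovered = [float(c) for c in cols if abs(c) > half_x + 5.0 + 1e-9]
    if uncovered:
        raise ValueError(
            f"target BEV columns outside the scanned field: {uncovered}")
    for c, ang in zip(cols, col_angles):
        for off in SECONDARY_OFFSETS:
            x = float(np.clip(c + off, -half_x, half_x))
            for y in rows:
                y = float(np.clip(y, -half_y, half_y))
                spots.append(Beamlet(x, y, e0, float(ang)))
    return spots


def impt_energy_layers(d_prox: float, d_dist: float, *,
                       energy_step: float = 2.5,
                       e_min: float = 60.0, e_max: float = 250.0) -> np.ndarray:
    """Energy-grid layers whose range falls in the target depth interval."""
    grid = np.arange(e_min, e_max + 1e-9, energy_step)
    r = proton_range(grid)
    sel = (r >= d_prox) & (r <= d_dist)
    if not np.any(sel):
        raise ValueError("no energy layer reaches the target interval")
    return grid[sel]


def place_spots_impt(phantom: Phantom, field_angles, beam: BeamModel, *,
                     margin: float = 5.0, energy_step: float = 2.5,
                     energies=None) -> list[Beamlet]:
    """Fixed-field IMPT spots: per field, all energy layers covering the
    target's radiological depth interval (or an explicit ``energies``
    list), each with a full lateral spot map at ``beam.spot_spacing``."""
    spots: list[Beamlet] = []
    planar = phantom.shape[1] == 1
    for ang in field_angles:
        if energies is not None:
            layers = np.asarray(energies, dtype=float)
        else:
            d_prox, d_dist = target_depth_interval(phantom, float(ang))
            layers = impt_energy_layers(d_prox, d_dist,
                                        energy_step=energy_step)
        (bx0, bx1), (by0, by1) = _target_bev_extent(phantom, float(ang))
        xs = np.arange(bx0 - margin, bx1 + margin + 1e-9, beam.spot_spacing)
        ys = np.array([0.0]) if planar else \
            np.arange(by0 - margin, by1 + margin + 1e-9, beam.spot_spacing)
        half_x, half_y = beam.field_size[0] / 2, beam.field_size[1] / 2
        for e in layers:
            for x in xs:
                for y in ys:
                    spots.append(Beamlet(
                        float(np.clip(x, -half_x, half_x)),
                        float(np.clip(y, -half_y, half_y)),
                        float(e), float(ang)))
    return spots


# ---------------------------------------------------------------------------
# Energy segmentation

def target_depth_interval(phantom: Phantom, angle: float):
    """Radiological depths of the target's proximal/distal surfaces along
    the central ray aimed at the target centre."""
    t = phantom.roi_masks["target"]
    xs, ys, zs = phantom.axes
    ii, jj, kk = np.nonzero(t)
    center = np.array([xs[ii].mean(), ys[jj].mean(), zs[kk].mean()])
    u, _, _ = _gantry_frame(angle)
    diag = float(np.linalg.norm(phantom.spacing * np.array(phantom.shape)))
    start = center - diag * u
    s, rd = radiological_depth_profile(phantom, start, u, step=0.5)
    pts = start[None, :] + s[:, None] * u[None, :]
    idx = np.array([(pts[:, k] - phantom.origin[k]) / phantom.spacing[k]
                    for k in range(3)])
    from scipy.ndimage import map_coordinates
    inside = map_coordinates(t.astype(float), idx, order=0) > 0.5
    if not np.any(inside):
        raise ValueError(f"central ray misses the target at {angle} deg")
    w = np.nonzero(inside)[0]
    return float(rd[w[0]]), float(rd[w[-1]])


def filter_sobp_interval(filt: SpeleoFilter, energy: float,
                         beam: BeamModel, *, level: float = 0.90):
    """(proximal, distal) interval where the filter's full-footprint SOBP
    stays above ``level`` of its plateau maximum, at the given energy."""
    from .sobp import superpose
    pristine = bragg_curve(energy, beam.energy_sigma, beam.depth_step)
    est = superpose(pristine, wet_histogram(filt, "full"))
    thresh = level * est.dose.max()
    above = np.nonzero(est.dose >= thresh)[0]
    return float(est.depths[above[0]]), float(est.depths[above[-1]])


def _coverage_violation(p_prox, p_dist, d_prox, d_dist) -> float:
    return max(0.0, d_dist - p_dist) + max(0.0, p_prox - d_prox)


def segment_energies(phantom: Phantom, layout: ArcLayout,
                     filt: SpeleoFilter, beam: BeamModel,
                     energy_grid, *, coverage_tol_mm: float = 5.0,
                     strict: bool = False) -> list[EnergySegment]:
    """Greedy minimal partition of the arc into single-energy segments.

    For each discrete angle the target's radiological depth interval is
    ray-traced and compared against the filter's SOBP interval shifted by
    the range difference of each candidate energy.  Angles whose coverage
    violation is within ``coverage_tol_mm`` accept that energy; a greedy
    sweep extends each segment while the feasible-energy set stays
    non-empty, which yields the minimal number of contiguous segments.
    If an angle has no feasible energy, ``strict=True`` raises; otherwise
    the angle takes its least-violating energy and the violation is
    reported on the segment.
    """
    energy_grid = np.asarray(energy_grid, dtype=float)
    if energy_grid.size == 0:
        raise ValueError("energy grid is empty")
    angles = layout.angles
    e0 = beam.nominal_energy
    p_prox0, p_dist0 = filter_sobp_interval(filt, e0, beam)
    r0 = proton_range(e0)
    shifts = proton_range(energy_grid) - r0

    viol = np.zeros((len(angles), len(energy_grid)))
    for a, ang in enumerate(angles):
        d_prox, d_dist = target_depth_interval(phantom, float(ang))
        for e in range(len(energy_grid)):
            viol[a, e] = _coverage_violation(
                p_prox0 + shifts[e], p_dist0 + shifts[e], d_prox, d_dist)
    feasible = viol <= coverage_tol_mm
    infeasible_angles = np.nonzero(~feasible.any(axis=1))[0]
    if infeasible_angles.size:
        if strict:
            bad = ", ".join(f"{angles[a]:g}" for a in infeasible_angles[:5])
            raise ValueError(
                f"no energy covers the target at angles: {bad} deg")
        # best-effort: relax the tolerance to the smallest value that
        # leaves every angle at least one admissible energy, so the
        # greedy partition stays minimal instead of fragmenting
        tol_eff = float(viol.min(axis=1).max()) + 1e-9
        feasible = viol <= max(coverage_tol_mm, tol_eff)

    segments: list[EnergySegment] = []
    a = 0
    while a < len(angles):
        current = feasible[a].copy()
        b = a
        while b + 1 < len(angles) and np.any(current & feasible[b + 1]):
            current &= feasible[b + 1]
            b += 1
        cand = np.nonzero(current)[0]
        # choose the feasible energy with the least worst-case violation
        worst = viol[a:b + 1, cand].max(axis=0)
        e_idx = int(cand[int(np.argmin(worst))])
        stop = angles[b + 1] if b + 1 < len(angles) else \
            (layout.span[1] if layout.mode == "arc" else angles[b])
        segments.append(EnergySegment(float(angles[a]), float(stop),
                                      float(energy_grid[e_idx]),
                                      float(viol[a:b + 1, e_idx].max())))
        a = b + 1
    return segments


def assign_segment_energies(spots: list[Beamlet],
                            segments: list[EnergySegment]) -> list[Beamlet]:
    """Return spots with each energy set from its angular segment."""
    out = []
    for s in spots:
        seg = next((g for g in segments
                    if g.angle_start - 1e-9 <= s.gantry_angle
                    <= g.angle_stop + 1e-9), None)
        if seg is None:
            raise ValueError(f"no segment covers angle {s.gantry_angle}")
        out.append(Beamlet(s.bev_x, s.bev_y, seg.energy, s.gantry_angle,
                           s.weight))
    return out


# ---------------------------------------------------------------------------
# Dose influence and weight optimisation

@dataclass
class DoseInfluence:
    """Sparse voxels-x-spots matrix of Gy per unit spot weight.

    Rows are restricted to ``voxel_idx`` (flat indices of dose-relevant
    voxels); ``shape3d`` remembers the full grid.
    """

    matrix: sparse.csr_matrix
    voxel_idx: np.ndarray
    shape3d: tuple[int, int, int]
    spots: list[Beamlet] = field(default_factory=list)
    voxel_volume_mm3: float = 1.0

    def dose_grid(self, weights: np.ndarray, origin, spacing) -> DoseGrid:
        flat = np.zeros(int(np.prod(self.shape3d)))
        flat[self.voxel_idx] = self.matrix @ weights
        return DoseGrid(flat.reshape(self.shape3d), origin, spacing)


def build_dose_influence(spots: list[Beamlet], phantom: Phantom,
                         filt: SpeleoFilter | None, beam: BeamModel, *,
                         cutoff: float = 1e-3,
                         voxel_mask: np.ndarray | None = None) -> DoseInfluence:
    """Column-by-column beamlet library with sparse storage.

    Entries below ``cutoff`` times the column maximum are dropped.  Rows
    cover ``voxel_mask`` (default: the body mask, else all voxels).
    """
    if len(spots) == 0:
        raise ValueError("no spots to simulate")
    if voxel_mask is None:
        voxel_mask = phantom.roi_masks.get(
            "body", np.ones(phantom.shape, dtype=bool))
    vidx = np.nonzero(voxel_mask.ravel())[0]
    pos = -np.ones(int(np.prod(phantom.shape)), dtype=np.int64)
    pos[vidx] = np.arange(len(vidx))

    cols, rows, vals = [], [], []
    cache: dict = {}
    for j, sp in enumerate(spots):
        key = (round(sp.energy, 4), round(sp.bev_x, 3), round(sp.bev_y, 3))
        if key not in cache:
            cache[key] = effective_curve(sp.energy, filt, beam,
                                         sp.bev_x, sp.bev_y)
        d = beamlet_dose(sp, phantom, filt, beam, curve=cache[key])
        flat = d.values.ravel()[vidx]
        mx = flat.max()
        if mx <= 0:
            continue
        keep = np.nonzero(flat > cutoff * mx)[0]
        rows.append(keep)
        vals.append(flat[keep])
        cols.append(np.full(len(keep), j, dtype=np.int64))
    if not rows:
        raise ValueError("all beamlet columns are empty")
    mat = sparse.csr_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(vidx), len(spots)))
    return DoseInfluence(mat, vidx, phantom.shape, list(spots),
                         phantom.voxel_volume_mm3)


@dataclass
class WeightResult:
    weights: np.ndarray
    objective_trace: list[float]
    scale: float = 1.0
    status: str = "ok"


def _goal_terms(di: DoseInfluence, goals: dict, roi_masks: dict):
    """Normalise the goal dict into per-ROI (rows, kind, dose, lam) terms."""
    terms = []
    for name, g in goals.items():
        mask = roi_masks.get(name)
        if mask is None:
            raise ValueError(f"goal references unknown ROI {name!r}")
        rows = np.nonzero(mask.ravel()[di.voxel_idx])[0]
        if rows.size == 0:
            raise ValueError(f"ROI {name!r} is empty on the influence rows")
        kind = g.get("type", "uniform")
        dose = g["dose"]
        if kind == "match":
            dose = np.asarray(dose).ravel()[di.voxel_idx][rows]
        lam = float(g.get("weight", 1.0))
        terms.append((name, rows, kind, dose, lam / rows.size))
    return terms


def optimize_weights(di: DoseInfluence, goals: dict, roi_masks: dict, *,
                     prescription: float | None = None,
                     max_iter: int = 2000, rel_tol: float = 1e-6,
                     renormalize_d95: bool = True) -> WeightResult:
    """Projected-gradient (FISTA) non-negative least squares for IMPT.

    Minimises ``sum_r lam_r/|r| * ||(D x - d_r)_r||^2`` with ``x >= 0``;
    one-sided for ``type="max"`` penalties (only overdose counts).  Goal
    types: ``uniform`` (two-sided at ``dose``), ``max`` (one-sided cap),
    ``match`` (two-sided against a voxelwise reference).  When a
    ``target`` uniform goal is present and ``renormalize_d95`` is set,
    the solution is scaled so the target D95 equals the prescription.
    """
    D = di.matrix
    if D.nnz == 0:
        raise ValueError("dose-influence matrix is empty")
    terms = _goal_terms(di, goals, roi_masks)
    if prescription is None:
        tgt = goals.get("target")
        prescription = float(tgt["dose"]) \
            if tgt and np.ndim(tgt["dose"]) == 0 else None

    n = D.shape[1]
    x = np.zeros(n)

    def obj_and_grad(x):
        d = D @ x
        f = 0.0
        resid = np.zeros_like(d)
        for _, rows, kind, dose, lam in terms:
            r = d[rows] - dose
            if kind == "max":
                r = np.clip(r, 0.0, None)
            f += lam * float(r @ r)
            resid[rows] += 2.0 * lam * r
        return f, D.T @ resid

    # Lipschitz estimate by power iteration on D^T W D
    lam_tot = sum(t[4] for t in terms)
    v = np.random.default_rng(0).standard_normal(n)
    v /= np.linalg.norm(v)
    for _ in range(20):
        w = D.T @ (D @ v)
        nv = np.linalg.norm(w)
        if nv == 0:
            break
        v = w / nv
    L = 2.0 * max(nv, 1e-12) * max(lam_tot, 1e-12)

    f, g = obj_and_grad(x)
    trace = [f]
    y, t = x.copy(), 1.0
    best = f
    for it in range(max_iter):
        fy, gy = obj_and_grad(y)
        x_new = np.clip(y - gy / L, 0.0, None)
        f_new, _ = obj_and_grad(x_new)
        if f_new > fy:   # FISTA restart on non-monotone step
            y, t = x.copy(), 1.0
            L *= 1.5
            continue
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        y = x_new + (t - 1) / t_new * (x_new - x)
        x, t = x_new, t_new
        trace.append(f_new)
        if best - f_new < rel_tol * max(best, 1e-30) and it > 10:
            best = min(best, f_new)
            break
        best = min(best, f_new)

    status = "ok"
    scale = 1.0
    if renormalize_d95 and prescription and "target" in goals:
        rows = np.nonzero(
            roi_masks["target"].ravel()[di.voxel_idx])[0]
        d95 = float(np.percentile(D[rows] @ x, 5))
        if d95 <= 0:
            status = "d95-renormalization-failed"
        else:
            scale = prescription / d95
            x = x * scale
    # keep the trace monotone non-increasing (best-so-far convention)
    trace = list(np.minimum.accumulate(trace))
    return WeightResult(x, trace, scale, status)


# ---------------------------------------------------------------------------

def count_energy_changes(plan: Plan) -> int:
    """Number of energy switches required to deliver a plan.

    Fixed fields: the sum over fields of (number of distinct energy
    layers - 1), layers delivered in descending-energy order within each
    field.  Arcs: the number of transitions between adjacent energy
    segments across the delivered span.
    """
    if not plan.spots:
        raise ValueError("plan has no spots")
    if plan.layout.mode == "fixed_fields":
        total = 0
        for ang in plan.layout.field_angles:
            energies = {s.energy for s in plan.spots
                        if abs(s.gantry_angle - ang) < 1e-9}
            if energies:
                total += len(energies) - 1
        return total
    if plan.energy_segments:
        return max(len(plan.energy_segments) - 1, 0)
    # fall back to counting changes along the angular delivery order
    order = sorted(plan.spots, key=lambda s: s.gantry_angle)
    changes = sum(1 for a, b in zip(order, order[1:])
                  if abs(a.energy - b.energy) > 1e-9)
    return changes
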