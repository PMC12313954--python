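"""Synthetic phantom geometries, ROI masks and ground-truth recovery cases.

All fixtures are generated programmatically and deterministically from a
spec (and a seed where randomness is involved).  The standard geometry is
a 25 cm diameter cylindrical water phantom (axis along y) with a 5 cm
cylindrical target, either centred or offset by 5 cm toward the 0-degree
beam entrance; ROI masks follow the planning-study conventions: ``skin``
is the inner 5 mm rind from the body perimeter and ``ring10`` the 10 mm
shell of healthy tissue around the target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Phantom

__all__ = ["PhantomSpec", "make_phantom", "make_ground_truth_case"]


@dataclass
class PhantomSpec:
    """Parametric water phantom description.

    ``kind`` is ``"cylinder"`` (diameter x length, axis along y) or
    ``"cube"``.  ``target_offset_mm`` displaces the target centre along -z
    (toward the 0-degree beam entrance).  ``slab_2d=True`` collapses y to
    a single voxel layer for fast planar studies.
    """

    kind: str = "cylinder"
    diameter_mm: float = 250.0
    length_mm: float = 250.0
    target_diameter_mm: float = 50.0
    target_length_mm: float = 50.0
    target_offset_mm: float = 0.0
    voxel_size: tuple[float, float, float] = (1.0, 5.0, 1.0)
    slab_2d: bool = False
    skin_rind_mm: float = 5.0
    ring_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "cube"):
            raise ValueError("kind must be 'cylinder' or 'cube'")
        if min(self.diameter_mm, self.length_mm,
               self.target_diameter_mm) <= 0:
            raise ValueError("dimensions must be positive")
        if np.any(np.asarray(self.voxel_size) <= 0):
            raise ValueError("voxel size must be positive")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Water phantom (rsp = 1 inside the body) with ROI masks.

    Masks: ``body``, ``target`` (cylinder, central or offset), ``skin``
    (inner rind from the body perimeter) and ``ring10`` (shell around the
    target, clipped to the body and excluding the target).
    """
    vx, vy, vz = spec.voxel_size
    half = spec.diameter_mm / 2.0

    def centered_axis(extent, v):
        n = max(int(np.ceil(extent / v)), 1)
        return (np.arange(n) - (n - 1) / 2.0) * v

    xs = centered_axis(spec.diameter_mm, vx)
    zs = centered_axis(spec.diameter_mm, vz)
    ys = np.array([0.0]) if spec.slab_2d else centered_axis(spec.length_mm, vy)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    if spec.kind == "cylinder":
        body = X ** 2 + Z ** 2 <= half ** 2
    else:
        body = (np.abs(X) <= half) & (np.abs(Z) <= half)
    body &= np.abs(Y) <= spec.length_mm / 2.0 + 1e-9

    tz = -spec.target_offset_mm
    tr = spec.target_diameter_mm / 2.0
    target = (X ** 2 + (Z - tz) ** 2 <= tr ** 2)
    if not spec.slab_2d:
        target &= np.abs(Y) <= spec.target_length_mm / 2.0
    target &= body
    if np.any((X ** 2 + (Z - tz) ** 2 <= tr ** 2) & ~body):
        raise ValueError("target breaches the body outline")

    sampling = (vx, vy, vz)
    # EDT measures centre-to-centre distance, which overestimates the
    # depth below the surface by about half a voxel
    half = 0.5 * min(vx, vz)
    depth_from_edge = ndimage.distance_transform_edt(
        body, sampling=sampling) - half
    skin = body & (depth_from_edge <= spec.skin_rind_mm)
    dist_to_target = ndimage.distance_transform_edt(~target, sampling=sampling)
    ring = body & ~target & (dist_to_target <= spec.ring_mm) \
        & (dist_to_target > 0)

    rsp = np.where(body, 1.0, 0.0)
    origin = np.array([xs[0], ys[0], zs[0]])
    return Phantom(rsp=rsp, origin=origin, spacing=np.array([vx, vy, vz]),
                   roi_masks={"body": body, "target": target,
                              "skin": skin, "ring10": ring})


@dataclass
class GroundTruthCase:
    phantom: Phantom
    filter_truth: "SpeleoFilter"
    spots: list
    weights_truth: np.ndarray
    beam: "BeamModel"
    dose_truth: "DoseGrid"
    goals: dict
    filter_init: "SpeleoFilter" = None
    seed: int = 0


def make_ground_truth_case(seed: int = 0,
                           complexity: str = "toy") -> GroundTruthCase:
    """Seeded synthetic case with a known optimal filter.

    A small planar cylinder phantom is irradiated from two angles through
    a coarse-pitch pillar strip with smoothly varying random heights and
    random positive weights; the resulting dose is taken as the planning
    goal, so the generating filter attains (near-)zero objective and
    parameter-recovery error is well defined.  ``filter_init`` is the
    truth distorted by a seeded random offset, the starting point for
    co-optimisation.
    """
    from .engine import BeamModel, Beamlet, field_dose
    from .filters import SpeleoFilter

    rng = np.random.default_rng(seed)
    if complexity == "toy":
        n_pillars, pitch = 11, 4.0
        diameter = 120.0
        angles = (0.0, 60.0, 120.0)
        voxel = (2.0, 5.0, 1.0)
    else:
        n_pillars, pitch = 21, 2.5
        diameter = 200.0
        angles = (0.0, 60.0, 120.0)
        voxel = (2.0, 5.0, 1.0)

    spec = PhantomSpec(diameter_mm=diameter, length_mm=voxel[1],
                       target_diameter_mm=diameter / 3,
                       voxel_size=voxel, slab_2d=True)
    phantom = make_phantom(spec)

    # smooth random truth heights a few mm around a mid plateau; the fine
    # (1 mm) dose sampling along the beam makes each pillar's distal
    # falloff visible to the objective, which is what identifies heights
    # against compensation by the free spot weights
    base_height = 12.0
    bumps = rng.normal(0.0, 3.0, size=n_pillars)
    kernel = np.array([0.25, 0.5, 0.25])
    bumps = np.convolve(bumps, kernel, mode="same")
    heights = np.clip(base_height + bumps, 2.0, 40.0)[:, None]
    filter_truth = SpeleoFilter(heights, pitch=pitch)

    beam = BeamModel(nominal_energy=110.0, spot_sigma_air=2.0,
                     field_size=(n_pillars * pitch, n_pillars * pitch),
                     spot_spacing=pitch)
    spots = []
    xs = filter_truth.x_centers
    for ang in angles:
        for x in xs:
            spots.append(Beamlet(bev_x=float(x), bev_y=0.0,
                                 energy=beam.nominal_energy,
                                 gantry_angle=ang))
    weights = rng.uniform(0.5, 1.5, size=len(spots))
    plan_spots = [Beamlet(s.bev_x, s.bev_y, s.energy, s.gantry_angle,
                          float(w)) for s, w in zip(spots, weights)]
    dose_truth = field_dose(plan_spots, phantom, filter_truth, beam)

    goals = {"body": {"type": "match", "dose": dose_truth.values,
                      "weight": 1.0}}
    init = np.clip(heights + rng.normal(0.0, 2.0, size=heights.shape),
                   0.5, 45.0)
    filter_init = filter_truth.with_heights(init)
    return GroundTruthCase(phantom=phantom, filter_truth=filter_truth,
                           spots=spots, weights_truth=weights, beam=beam,
                           dose_truth=dose_truth, goals=goals,
                           filter_init=filter_init, seed=seed)
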