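"""Format round-tripping: CSV profiles and height maps, JSON plans and
metrics, NRRD grids, binary STL meshes.

Coordinate conventions are documented in :mod:`speleoplan.grids`: mm
units, beam along +z at gantry 0, 0-based voxel indices, world
coordinates at voxel centres.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .arc import ArcLayout, EnergySegment, Plan
from .engine import Beamlet, DepthDoseCurve
from .filters import SpeleoFilter
from .grids import DoseGrid

__all__ = [
    "curve_to_csv", "curve_from_csv", "heights_to_csv", "heights_from_csv",
    "dose_to_nrrd", "dose_from_nrrd", "plan_to_json", "plan_from_json",
    "save_json", "export_stl",
]


def curve_to_csv(curve: DepthDoseCurve, path) -> None:
    arr = np.column_stack([curve.depths, curve.dose])
    np.savetxt(path, arr, delimiter=",", header="depth_mm,dose", comments="")


def curve_from_csv(path) -> DepthDoseCurve:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return DepthDoseCurve(arr[:, 0], arr[:, 1])


def heights_to_csv(filt: SpeleoFilter, path) -> None:
    np.savetxt(path, filt.heights, delimiter=",", fmt="%.17g")


def heights_from_csv(path, **kwargs) -> SpeleoFilter:
    return SpeleoFilter(np.atleast_2d(np.loadtxt(path, delimiter=",")),
                        **kwargs)


def dose_to_nrrd(dose: DoseGrid, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(dose.values.transpose(2, 1, 0), dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in dose.spacing))
    img.SetOrigin(tuple(float(o) for o in dose.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def dose_from_nrrd(path) -> DoseGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    vals = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return DoseGrid(vals, np.array(img.GetOrigin()),
                    np.array(img.GetSpacing()))


def plan_to_json(plan: Plan, path=None) -> str:
    doc = {
        "layout": {"span": list(plan.layout.span),
                   "angle_step": plan.layout.angle_step,
                   "mode": plan.layout.mode,
                   "field_angles": list(plan.layout.field_angles)},
        "filter_id": plan.filter_id,
        "energy_segments": [
            {"angle_start": s.angle_start, "angle_stop": s.angle_stop,
             "energy": s.energy, "max_violation_mm": s.max_violation_mm}
            for s in plan.energy_segments],
        "spots": [
            {"gantry_angle": s.gantry_angle, "bev_x": s.bev_x,
             "bev_y": s.bev_y, "energy": s.energy, "weight": s.weight}
            for s in plan.spots],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def plan_from_json(src) -> Plan:
    text = Path(src).read_text() if not str(src).lstrip().startswith("{") \
        else str(src)
    doc = json.loads(text)
    layout = ArcLayout(span=tuple(doc["layout"]["span"]),
                       angle_step=doc["layout"]["angle_step"],
                       mode=doc["layout"]["mode"],
                       field_angles=tuple(doc["layout"]["field_angles"]))
    segs = [EnergySegment(**s) for s in doc["energy_segments"]]
    spots = [Beamlet(s["bev_x"], s["bev_y"], s["energy"],
                     s["gantry_angle"], s["weight"]) for s in doc["spots"]]
    return Plan(spots, layout, segs, doc.get("filter_id"))


def save_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def export_stl(filt: SpeleoFilter, path) -> None:
    from .filters import export_mesh

    export_mesh(filt).export(str(path))
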