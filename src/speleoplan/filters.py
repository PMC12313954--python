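"""Pillar-array energy modulators ("SpeleoFilters").

A SpeleoFilter is a rectangular grid of square pillars of varying height
standing on a thin common base layer.  Each pillar's water-equivalent
thickness (WET) pulls the Bragg peak of protons crossing it upstream, so
the height *distribution* under a beam footprint turns one scanned energy
into a polyenergetic depth dose.

The filter lives in its own right-handed frame: pillar centres in the
(x, y) plane, the base slab occupying z in [0, base_thickness] and pillars
extruding toward the source, z in [-h_ij, 0].  The filter centre is at
(x, y) = (0, 0), which planning code aligns with the beam's-eye-view
origin.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

__all__ = [
    "Material",
    "SpeleoFilter",
    "WetHistogram",
    "trace_wet",
    "wet_histogram",
    "make_prototype",
    "export_mesh",
    "compare_surfaces",
]

#: Default pillar material: a clear 3D-printing photopolymer.  The relative
#: stopping power is derived once by Bragg additivity from the nominal
#: density of 1.19 g/cm^3 and an adipose-like elemental composition
#: (H 11.4%, C 58.9%, N 0.7%, O 28.7%, Na/S/Cl 0.1% each) and kept as a
#: configurable constant.
DEFAULT_DENSITY = 1.19  # g/cm^3
DEFAULT_RSP = 1.16
DEFAULT_COMPOSITION = {
    "H": 0.114, "C": 0.589, "N": 0.007, "O": 0.287,
    "Na": 0.001, "S": 0.001, "Cl": 0.001,
}
MAX_HEIGHT_MM = 120.0


@dataclass
class Material:
    density: float = DEFAULT_DENSITY
    rsp: float = DEFAULT_RSP
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))

    def __post_init__(self) -> None:
        if self.rsp <= 0 or self.density <= 0:
            raise ValueError("density and rsp must be positive")


@dataclass
class SpeleoFilter:
    """Pillar-height grid on a base layer.

    ``heights[i, j]`` is the height in mm of the pillar centred at
    ``(x_centers[i], y_centers[j])``.  Heights are continuous internally;
    mesh export rounds them to 0.01 mm.
    """

    heights: np.ndarray
    pitch: float = 1.0
    base_thickness: float = 1.0
    material: Material = field(default_factory=Material)
    max_height: float = MAX_HEIGHT_MM

    def __post_init__(self) -> None:
        self.heights = np.atleast_2d(np.asarray(self.heights, dtype=float))
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("pillar heights must be finite")
        if np.any(self.heights < 0):
            raise ValueError("pillar heights must be >= 0")
        if np.any(self.heights > self.max_height):
            raise ValueError(f"pillar heights exceed {self.max_height} mm")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.base_thickness < 0:
            raise ValueError("base thickness must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def x_centers(self) -> np.ndarray:
        n = self.heights.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def y_centers(self) -> np.ndarray:
        n = self.heights.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def extent(self) -> tuple[float, float]:
        """Full (x, y) side lengths in mm."""
        return (self.heights.shape[0] * self.pitch,
                self.heights.shape[1] * self.pitch)

    def pillar_wet(self) -> np.ndarray:
        """WET of a normally incident ray through each pillar (incl. base)."""
        return (self.heights + self.base_thickness) * self.material.rsp

    def with_heights(self, heights: np.ndarray) -> "SpeleoFilter":
        return SpeleoFilter(np.asarray(heights, dtype=float),
                            pitch=self.pitch,
                            base_thickness=self.base_thickness,
                            material=self.material,
                            max_height=self.max_height)

    def shifted(self, delta: float, clamp: bool = True) -> "SpeleoFilter":
        """Uniformly add ``delta`` mm to every pillar (clamped at 0)."""
        h = self.heights + delta
        if clamp:
            h = np.clip(h, 0.0, None)
        return self.with_heights(h)

    def analytic_volume_mm3(self) -> float:
        ex, ey = self.extent
        base = ex * ey * self.base_thickness
        return float(base + self.pitch ** 2 * self.heights.sum())


@dataclass
class WetHistogram:
    """Areal-fraction distribution of WET under a beam footprint."""

    wet_bins: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.wet_bins = np.asarray(self.wet_bins, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.wet_bins.shape != self.mass.shape:
            raise ValueError("wet_bins and mass must match")
        if np.any(self.mass < -1e-12):
            raise ValueError("histogram mass must be >= 0")
        tot = self.mass.sum()
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")


# ---------------------------------------------------------------------------
# WET ray tracing

def _box_path_length(origin, direction, lo, hi) -> float:
    """Exact chord length of a ray (infinite line, t >= 0) through an AABB."""
    t0, t1 = 0.0, np.inf
    for k in range(3):
        if abs(direction[k]) < 1e-12:
            if origin[k] < lo[k] or origin[k] > hi[k]:
                return 0.0
            continue
        a = (lo[k] - origin[k]) / direction[k]
        b = (hi[k] - origin[k]) / direction[k]
        if a > b:
            a, b = b, a
        t0, t1 = max(t0, a), min(t1, b)
    return max(0.0, t1 - t0)


def trace_wet(filt: SpeleoFilter, ray: dict) -> float:
    """Water-equivalent thickness of ``filt`` along a ray.

    ``ray`` is ``{"origin": (x, y, z), "direction": (dx, dy, dz)}`` in the
    filter frame; the origin should lie upstream of the filter.  The result
    is RSP times the exact geometric path length through the base slab and
    every intersected pillar box (no voxel sampling).
    """
    o = np.asarray(ray["origin"], dtype=float)
    d = np.asarray(ray["direction"], dtype=float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise ValueError("degenerate ray direction")
    d = d / nrm

    ex, ey = filt.extent
    length = 0.0
    # base slab
    length += _box_path_length(
        o, d,
        (-ex / 2, -ey / 2, 0.0),
        (ex / 2, ey / 2, filt.base_thickness),
    )
    # pillars: restrict to cells whose (x, y) footprint the ray can touch
    # while inside the pillar layer z in [-h_max, 0]
    hmax = float(filt.heights.max(initial=0.0))
    if hmax > 0:
        xc, yc = filt.x_centers, filt.y_centers
        half = filt.pitch / 2
        # parameter interval where the ray is inside the pillar layer
        if abs(d[2]) > 1e-12:
            ta = (-hmax - o[2]) / d[2]
            tb = (0.0 - o[2]) / d[2]
            tlo, thi = min(ta, tb), max(ta, tb)
        else:
            tlo, thi = 0.0, np.inf
            if o[2] < -hmax or o[2] > 0:
                tlo, thi = 0.0, -1.0
        if thi >= max(tlo, 0.0):
            tlo = max(tlo, 0.0)
            xs = o[0] + np.array([tlo, thi]) * d[0]
            ys = o[1] + np.array([tlo, thi]) * d[1]
            pad = filt.pitch
            i0 = np.searchsorted(xc, xs.min() - half - pad)
            i1 = np.searchsorted(xc, xs.max() + half + pad)
            j0 = np.searchsorted(yc, ys.min() - half - pad)
            j1 = np.searchsorted(yc, ys.max() + half + pad)
            for i in range(max(i0 - 1, 0), min(i1 + 1, len(xc))):
                for j in range(max(j0 - 1, 0), min(j1 + 1, len(yc))):
                    h = filt.heights[i, j]
                    if h <= 0:
                        continue
                    length += _box_path_length(
                        o, d,
                        (xc[i] - half, yc[j] - half, -h),
                        (xc[i] + half, yc[j] + half, 0.0),
                    )
    return float(length * filt.material.rsp)


# ---------------------------------------------------------------------------
# Footprint WET histograms

def _footprint_weights(filt: SpeleoFilter, footprint) -> np.ndarray:
    """Per-pillar areal weights of a footprint over the filter grid.

    ``footprint`` may be:

    * ``"full"`` — uniform coverage of the whole filter;
    * ``{"center": (x, y), "sigma": s}`` — 2-D Gaussian fluence, the
      weight of each pillar cell is the separable Gaussian mass over it;
    * ``{"center": (x, y), "halfwidth": (wx, wy)}`` — uniform rectangle,
      weights are exact cell-overlap areas.
    """
    nx, ny = filt.shape
    if isinstance(footprint, str) and footprint == "full":
        return np.full((nx, ny), 1.0)
    cx, cy = footprint["center"]
    half = filt.pitch / 2
    xe = np.concatenate([filt.x_centers - half, [filt.x_centers[-1] + half]])
    ye = np.concatenate([filt.y_centers - half, [filt.y_centers[-1] + half]])
    if "sigma" in footprint and footprint["sigma"] is not None:
        s = float(footprint["sigma"])
        if s <= 0:
            raise ValueError("footprint sigma must be positive")
        wx = np.diff(norm.cdf(xe, loc=cx, scale=s))
        wy = np.diff(norm.cdf(ye, loc=cy, scale=s))
    else:
        hx, hy = footprint["halfwidth"]
        wx = np.clip(np.minimum(xe[1:], cx + hx) - np.maximum(xe[:-1], cx - hx),
                     0.0, None)
        wy = np.clip(np.minimum(ye[1:], cy + hy) - np.maximum(ye[:-1], cy - hy),
                     0.0, None)
    return np.outer(wx, wy)


def wet_histogram(filt: SpeleoFilter, footprint="full",
                  decimals: int = 6) -> WetHistogram:
    """Bin the per-pillar WETs under a footprint into a normalised histogram.

    Pillars are weighted by the areal (or Gaussian) coverage of the
    footprint; pillars with equal WET (after rounding to ``decimals``)
    share a bin.
    """
    w = _footprint_weights(filt, footprint)
    tot = w.sum()
    if tot <= 1e-12:
        raise ValueError("footprint does not overlap the filter")
    wet = np.round(filt.pillar_wet(), decimals)
    bins, inv = np.unique(wet.ravel(), return_inverse=True)
    mass = np.bincount(inv, weights=w.ravel(), minlength=len(bins))
    mass = mass / mass.sum()
    keep = mass > 0
    return WetHistogram(bins[keep], mass[keep] / mass[keep].sum())


# ---------------------------------------------------------------------------
# Prototype fixtures

def make_prototype(kind: str, *, n: int = 50, pitch: float = 1.0,
                   base_thickness: float = 1.0, material: Material | None = None,
                   height: float = 30.0, high: float = 50.0, low: float = 3.0,
                   layout: str = "checkerboard",
                   heights: np.ndarray | None = None) -> SpeleoFilter:
    """Named filter fixtures on a 5 x 5 cm grid by default.

    ``kind``:

    * ``"solid"`` — uniform block, every pillar at ``height`` mm;
    * ``"alternating"`` — repeating pattern of ``high``/``low`` pillars
      (50 mm / 3 mm default) as a ``"checkerboard"`` or ``"stripes"``
      layout;
    * ``"from_heights"`` — explicit ``heights`` matrix.
    """
    material = material or Material()
    if kind == "solid":
        h = np.full((n, n), float(height))
    elif kind == "alternating":
        i, j = np.indices((n, n))
        if layout == "checkerboard":
            sel = (i + j) % 2 == 0
        elif layout == "stripes":
            sel = i % 2 == 0
        else:
            raise ValueError(f"unknown layout {layout!r}")
        h = np.where(sel, float(high), float(low))
    elif kind == "from_heights":
        if heights is None:
            raise ValueError("from_heights requires a heights matrix")
        h = np.asarray(heights, dtype=float)
    else:
        raise ValueError(f"unknown prototype kind {kind!r}")
    return SpeleoFilter(h, pitch=pitch, base_thickness=base_thickness,
                        material=material)


# ---------------------------------------------------------------------------
# Mesh export

def export_mesh(filt: SpeleoFilter):
    """Triangle mesh (one watertight box per pillar plus the base slab).

    Heights are rounded to 0.01 mm on export (well below the 0.127 mm
    manufacturing tolerance of the printing process this targets).
    Mesh volume equals the analytic volume exactly up to rounding.
    """
    import trimesh

    ex, ey = filt.extent
    boxes = []
    base = trimesh.creation.box(extents=(ex, ey, max(filt.base_thickness, 1e-6)))
    base.apply_translation((0, 0, filt.base_thickness / 2))
    boxes.append(base)
    xc, yc = filt.x_centers, filt.y_centers
    h = np.round(filt.heights, 2)
    for i in range(h.shape[0]):
        for j in range(h.shape[1]):
            if h[i, j] <= 0:
                continue
            b = trimesh.creation.box(extents=(filt.pitch, filt.pitch, h[i, j]))
            b.apply_translation((xc[i], yc[j], -h[i, j] / 2))
            boxes.append(b)
    mesh = trimesh.util.concatenate(boxes)
    return mesh


# ---------------------------------------------------------------------------
# Design-vs-scan QC

def voxelize_solid(filt: SpeleoFilter, voxel: float = 0.5,
                   bounds=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Solid occupancy mask of the filter on a regular grid.

    Returns ``(mask, origin, voxel)``; ``bounds`` may fix the common grid
    for two filters being compared.
    """
    ex, ey = filt.extent
    hmax = float(filt.heights.max(initial=0.0))
    if bounds is None:
        lo = np.array([-ex / 2, -ey / 2, -hmax])
        hi = np.array([ex / 2, ey / 2, filt.base_thickness])
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    xs = lo[0] + (np.arange(shape[0]) + 0.5) * voxel
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * voxel
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * voxel
    ix = np.clip(np.round(xs / filt.pitch + (filt.shape[0] - 1) / 2).astype(int),
                 0, filt.shape[0] - 1)
    iy = np.clip(np.round(ys / filt.pitch + (filt.shape[1] - 1) / 2).astype(int),
                 0, filt.shape[1] - 1)
    inx = (np.abs(xs) <= ex / 2)
    iny = (np.abs(ys) <= ey / 2)
    hmap = filt.heights[np.ix_(ix, iy)]
    z = zs[None, None, :]
    occ = (z >= -hmap[:, :, None]) & (z <= filt.base_thickness)
    # outside the base slab in z but above a shorter pillar -> only base band
    occ &= inx[:, None, None] & iny[None, :, None]
    return occ, lo, voxel


def _surface_distances(a: np.ndarray, b: np.ndarray, voxel: float):
    """Symmetric surface-to-surface distances of two solid masks."""
    def surface(m):
        er = ndimage.binary_erosion(m)
        return m & ~er

    sa, sb = surface(a), surface(b)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=voxel)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=voxel)
    d_ab = dt_b[sa]
    d_ba = dt_a[sb]
    return np.concatenate([d_ab, d_ba])


def compare_surfaces(design: SpeleoFilter, scanned, voxel: float = 0.5,
                     bounds=None) -> dict:
    """DICE and surface-distance QC between a design and a scanned shape.

    ``scanned`` is another :class:`SpeleoFilter` (e.g. reconstructed from a
    CT surface) or a boolean occupancy mask on the grid defined by
    ``voxel`` (and ``bounds``, when given).
    Returns ``{"dice", "mean_hausdorff", "hd95"}`` with distances in mm.
    """
    if isinstance(scanned, SpeleoFilter):
        if bounds is None:
            ex = max(design.extent[0], scanned.extent[0])
            ey = max(design.extent[1], scanned.extent[1])
            hmax = max(design.heights.max(initial=0.0),
                       scanned.heights.max(initial=0.0))
            base = max(design.base_thickness, scanned.base_thickness)
            bounds = (
                np.array([-ex / 2 - voxel, -ey / 2 - voxel, -hmax - voxel]),
                np.array([ex / 2 + voxel, ey / 2 + voxel, base + voxel]))
        a, _, _ = voxelize_solid(design, voxel, bounds)
        b, _, _ = voxelize_solid(scanned, voxel, bounds)
    else:
        a, _, _ = voxelize_solid(design, voxel, bounds)
        b = np.asarray(scanned, dtype=bool)
        if b.shape != a.shape:
            raise ValueError("scanned mask must share the design grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("empty volume in surface comparison")
    inter = int((a & b).sum())
    dice = 2.0 * inter / (na + nb)
    if inter == 0:
        return {"dice": 0.0, "mean_hausdorff": float("inf"), "hd95": float("inf")}
    d = _surface_distances(a, b, voxel)
    return {"dice": float(dice),
            "mean_hausdorff": float(d.mean()),
            "hd95": float(np.percentile(d, 95))}


# ---------------------------------------------------------------------------
# CSV round-trip

def heights_to_csv(filt: SpeleoFilter) -> str:
    buf = _io.StringIO()
    np.savetxt(buf, filt.heights, delimiter=",", fmt="%.17g")
    return buf.getvalue()


def heights_from_csv(text_or_path, **kwargs) -> SpeleoFilter:
    h = np.atleast_2d(np.loadtxt(
        _io.StringIO(text_or_path) if "\n" in str(text_or_path) or "," in str(text_or_path)
        else text_or_path, delimiter=","))
    return SpeleoFilter(h, **kwargs)
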