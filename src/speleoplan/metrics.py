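"""Plan-quality metrics: DVHs, conformity, integral/skin dose, PDD
extraction, gamma-index comparison and the pillar-error sensitivity study.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import BeamModel, DepthDoseCurve, field_dose
from .filters import SpeleoFilter
from .grids import DoseGrid, Phantom

__all__ = [
    "DVH", "dvh", "dose_at_volume", "conformity", "integral_dose",
    "dmax_1cc", "extract_pdd", "plateau_uniformity", "gamma_index",
    "sensitivity_study",
]


@dataclass
class DVH:
    """Cumulative dose-volume histogram: V(d) = fraction of the ROI
    receiving at least d Gy.  Monotone non-increasing, V(0) = 1."""

    dose_bins: np.ndarray
    volume_fraction: np.ndarray

    def v_at(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose``."""
        i = np.searchsorted(self.dose_bins, dose, side="right") - 1
        return float(self.volume_fraction[max(i, 0)])

    def d_at(self, volume_fraction: float) -> float:
        """Minimum dose received by the hottest ``volume_fraction``."""
        idx = np.nonzero(self.volume_fraction >= volume_fraction)[0]
        return float(self.dose_bins[idx[-1]]) if idx.size else 0.0


def dvh(dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.1) -> DVH:
    if not np.any(mask):
        raise ValueError("ROI mask is empty")
    d = dose.values[mask]
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    # V(edge) = fraction with dose >= edge
    ge = (d.size - np.concatenate([[0], np.cumsum(counts)])) / d.size
    return DVH(edges, ge)


def dose_at_volume(dose: DoseGrid, mask: np.ndarray, volume_pct: float) -> float:
    """D_x: dose received by at least x% of the ROI (exact percentile)."""
    if not np.any(mask):
        raise ValueError("ROI mask is empty")
    return float(np.percentile(dose.values[mask], 100.0 - volume_pct))


def conformity(dose: DoseGrid, target: np.ndarray, level: float,
               prescription: float) -> dict:
    """Isodose-to-target volume ratio and target encapsulation.

    ``ci = V(dose >= level * Rx) / V(target)`` over the whole grid;
    ``encapsulation`` is the fraction of the target at or above the same
    isodose level, so the "completely encapsulated" premise is checkable.
    """
    nt = int(target.sum())
    if nt == 0:
        raise ValueError("target volume is zero")
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    iso = dose.values >= level * prescription
    return {"ci": float(iso.sum() / nt),
            "encapsulation": float((iso & target).sum() / nt)}


def integral_dose(dose: DoseGrid, body: np.ndarray) -> float:
    """Body-integrated dose in units of 1e-3 Gy m^3 (= 1000 Gy cm^3)."""
    gy_mm3 = float(dose.values[body].sum() * dose.voxel_volume_mm3)
    return gy_mm3 / 1e6   # mm^3 -> 1000 cm^3


def dmax_1cc(dose: DoseGrid, mask: np.ndarray) -> float:
    """Minimum dose of the hottest 1 cm^3 of the ROI."""
    d = np.sort(dose.values[mask])[::-1]
    n = max(int(round(1000.0 / dose.voxel_volume_mm3)), 1)
    n = min(n, d.size)
    return float(d[n - 1])


def extract_pdd(dose: DoseGrid, phantom: Phantom | None = None, *,
                at: tuple[float, float] = (0.0, 0.0),
                normalization_depth: float | None = 40.0) -> DepthDoseCurve:
    """Central-axis percent depth dose along +z.

    The profile is read from the voxel column nearest to world
    ``(x, y) = at``; depth 0 is the upstream phantom surface (first voxel
    with rsp > 0) when a phantom is given, else the grid start.  The
    curve is normalised to 100 at ``normalization_depth`` (default the
    4 cm plateau reference) or to the maximum if ``None``.
    """
    xs, ys, zs = dose.axes
    i = int(np.argmin(np.abs(xs - at[0])))
    j = int(np.argmin(np.abs(ys - at[1])))
    prof = dose.values[i, j, :].astype(float)
    k0 = 0
    if phantom is not None:
        inside = np.nonzero(phantom.rsp[i, j, :] > 0)[0]
        if inside.size:
            k0 = int(inside[0])
    # depth of a voxel centre below the upstream face of the first
    # material voxel
    depths = zs[k0:] - zs[k0] + dose.spacing[2] / 2.0
    curve = DepthDoseCurve(depths, prof[k0:])
    if normalization_depth is None:
        ref = curve.peak_dose
    else:
        if normalization_depth > depths[-1] or normalization_depth < 0:
            raise ValueError("normalization depth outside the profile")
        ref = float(curve.at(np.array([normalization_depth]))[0])
    if ref <= 0:
        raise ValueError("zero dose at the normalisation depth")
    return DepthDoseCurve(depths, 100.0 * curve.dose / ref)


def plateau_uniformity(curve: DepthDoseCurve,
                       interval: tuple[float, float]) -> dict:
    """max |D - mean| / mean over an interval, plus the fraction of
    points within 2.5% of the mean."""
    m = (curve.depths >= interval[0]) & (curve.depths <= interval[1])
    if not np.any(m):
        raise ValueError("interval contains no samples")
    d = curve.dose[m]
    mean = d.mean()
    dev = np.abs(d - mean) / mean
    return {"max_deviation_pct": float(100.0 * dev.max()),
            "mean": float(mean),
            "within_2p5_pct": float(100.0 * np.mean(dev <= 0.025))}


# ---------------------------------------------------------------------------
# Gamma analysis

def gamma_index(eval_dist, reference, dose_crit_pct: float,
                dist_crit_mm: float, *, search_factor: float = 3.0,
                interp_fraction: float = 0.1) -> dict:
    """Global-normalisation gamma comparison of two distributions.

    ``gamma(r) = min_{r'} sqrt(|r - r'|^2 / dist_crit^2
    + (D_e(r) - D_r(r'))^2 / (dose_crit% of global ref max)^2)``, searched
    within ``search_factor * dist_crit`` of each evaluation point on a
    reference grid resampled to ``interp_fraction * dist_crit``.  Inputs
    are :class:`DepthDoseCurve` objects or ``(values, spacing_mm)`` pairs
    (1-D profiles or N-D grids on uniform spacing).  Returns the per-point
    gamma values and the pass fraction (gamma <= 1).
    """
    def unpack(obj):
        if isinstance(obj, DepthDoseCurve):
            return obj.dose, np.array([obj.step]), np.array([obj.depths[0]])
        vals, spacing = obj
        vals = np.asarray(vals, dtype=float)
        spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
        return vals, spacing, np.zeros(vals.ndim)

    ev, ev_sp, ev_o = unpack(eval_dist)
    rf, rf_sp, rf_o = unpack(reference)
    if rf.max() <= 0:
        raise ValueError("reference maximum is zero")
    dose_tol = dose_crit_pct / 100.0 * rf.max()

    # integer upsampling factors keep every original reference node on
    # the fine grid, so identical distributions give gamma exactly 0
    fine_step = interp_fraction * dist_crit_mm
    factors = tuple(max(int(np.ceil(s / fine_step)), 1) for s in rf_sp)
    if any(f > 1 for f in factors):
        from scipy.ndimage import map_coordinates
        axes = [np.arange((n - 1) * f + 1) / f
                for n, f in zip(rf.shape, factors)]
        mesh = np.meshgrid(*axes, indexing="ij")
        rf_fine = map_coordinates(rf, np.array(mesh), order=1)
    else:
        rf_fine = rf
    fine_sp = np.array([s / f for s, f in zip(rf_sp, factors)])

    radius = search_factor * dist_crit_mm
    win = np.maximum(np.round(radius / fine_sp).astype(int), 0)

    # squared distance kernel over the search window
    offs = np.meshgrid(*[np.arange(-w, w + 1) * s
                         for w, s in zip(win, fine_sp)], indexing="ij")
    dist2 = sum(o ** 2 for o in offs)
    inside = dist2 <= radius ** 2 + 1e-9

    gamma = np.empty(ev.shape)
    it = np.ndindex(*ev.shape)
    scale = np.array([es / fs for es, fs in zip(ev_sp, fine_sp)])
    off0 = (ev_o - rf_o) / fine_sp
    for idx in it:
        center = np.round(np.array(idx) * scale + off0).astype(int)
        sl, ksl = [], []
        ok = True
        for k in range(rf_fine.ndim):
            lo = center[k] - win[k]
            hi = center[k] + win[k] + 1
            clo, chi = max(lo, 0), min(hi, rf_fine.shape[k])
            if clo >= chi:
                ok = False
                break
            sl.append(slice(clo, chi))
            ksl.append(slice(clo - lo, (clo - lo) + (chi - clo)))
        if not ok:
            gamma[idx] = np.inf
            continue
        block = rf_fine[tuple(sl)]
        d2 = dist2[tuple(ksl)]
        msk = inside[tuple(ksl)]
        diff2 = (ev[idx] - block) ** 2 / dose_tol ** 2
        g2 = d2 / dist_crit_mm ** 2 + diff2
        gamma[idx] = np.sqrt(g2[msk].min()) if np.any(msk) else np.inf
    return {"gamma": gamma,
            "pass_fraction": float(np.mean(gamma <= 1.0 + 1e-9))}


# ---------------------------------------------------------------------------
# Sensitivity study

def sensitivity_study(spots, filt: SpeleoFilter, phantom: Phantom,
                      beam: BeamModel, prescription: float, *,
                      deltas=(-1.0, -0.5, 0.5, 1.0),
                      pdd_at: tuple[float, float] = (0.0, 0.0)) -> dict:
    """Re-evaluate a delivered plan with uniformly mis-printed pillars.

    With beamlet weights fixed, every pillar height is shifted by each
    delta (clamped at zero, flagged when clamping occurs) and the dose is
    recomputed.  Reports, per delta, the change in target V_Rx, in the
    target's hottest-1cc dose, in the ring-10mm hottest-1cc dose, and the
    shift of the central-axis distal 80% falloff depth.
    """
    target = phantom.roi_masks["target"]
    ring = phantom.roi_masks.get("ring10")
    base_dose = field_dose(spots, phantom, filt, beam)
    base_pdd = extract_pdd(base_dose, phantom, at=pdd_at,
                           normalization_depth=None)
    base = {
        "v_rx": float(np.mean(base_dose.values[target] >= prescription)),
        "dmax_1cc": dmax_1cc(base_dose, target),
        "ring_dmax_1cc": dmax_1cc(base_dose, ring) if ring is not None
        and np.any(ring) else float("nan"),
        "falloff80_mm": base_pdd.distal_falloff(0.8),
    }
    results = {0.0: {k: 0.0 for k in
                     ("d_v_rx", "d_dmax_1cc", "d_ring_dmax_1cc",
                      "d_falloff80_mm")} | {"clamped": False}}
    for delta in deltas:
        clamped = bool(np.any(filt.heights + delta < 0))
        f2 = filt.shifted(delta)
        d2 = field_dose(spots, phantom, f2, beam)
        pdd2 = extract_pdd(d2, phantom, at=pdd_at, normalization_depth=None)
        results[float(delta)] = {
            "d_v_rx": float(np.mean(d2.values[target] >= prescription)
                            - base["v_rx"]),
            "d_dmax_1cc": dmax_1cc(d2, target) - base["dmax_1cc"],
            "d_ring_dmax_1cc": (dmax_1cc(d2, ring) - base["ring_dmax_1cc"])
            if ring is not None and np.any(ring) else float("nan"),
            "d_falloff80_mm": pdd2.distal_falloff(0.8)
            - base["falloff80_mm"],
            "clamped": clamped,
        }
    return {"baseline": base, "deltas": results,
            "rsp": filt.material.rsp}
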