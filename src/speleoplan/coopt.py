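"""Joint refinement of pillar heights and beamlet weights.

Each outer iteration simulates three delivery scenarios — the nominal
filter, and the same filter with a seeded random subset of pillars
systematically raised/lowered by ``delta`` — re-optimises beamlet weights
on the nominal scenario, applies those weights to all three, and builds a
per-voxel objective-function map for each.  A central finite difference of
the scenario objectives, restricted to the voxels influenced by the
beamlets crossing each perturbed pillar, gives a per-pillar sensitivity
used to update heights.  The loop stops when the best objective no longer
improves.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arc import Beamlet, BeamModel, DoseInfluence, build_dose_influence, \
    optimize_weights
from .filters import SpeleoFilter, _footprint_weights
from .grids import DoseGrid, Phantom

__all__ = [
    "ScenarioSet", "ObjectiveMap", "CooptConfig", "CooptResult",
    "perturb_scenarios", "objective_map", "update_pillars", "coopt",
]


@dataclass
class ScenarioSet:
    nominal: SpeleoFilter
    increased: SpeleoFilter
    decreased: SpeleoFilter
    subset: np.ndarray          # flat pillar indices
    delta: float

    def __post_init__(self) -> None:
        up = self.increased.heights - self.nominal.heights
        dn = self.nominal.heights - self.decreased.heights
        flat_up = up.ravel()
        sub = np.zeros(flat_up.size, dtype=bool)
        sub[self.subset] = True
        if np.any(np.abs(flat_up[~sub]) > 1e-9) or \
                np.any(np.abs(dn.ravel()[~sub]) > 1e-9):
            raise ValueError("scenario perturbs pillars outside the subset")
        if np.any(np.abs(flat_up[sub] - self.delta) > 1e-9):
            raise ValueError("increase scenario must add delta on the subset")


@dataclass
class ObjectiveMap:
    """Per-voxel objective contributions on the influence-row voxels."""

    values: np.ndarray          # aligned with DoseInfluence.voxel_idx
    total: float

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-12):
            raise ValueError("objective map must be >= 0")


@dataclass
class CooptConfig:
    delta: float = 1.0
    subset_fraction: float = 0.25
    eta: float | None = None     # None -> auto (max step = delta) + backtracking
    seed: int = 0
    max_outer: int = 10
    rel_tol: float = 1e-4
    reoptimize_scenarios: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.subset_fraction <= 1):
            raise ValueError("subset_fraction must be in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class CooptResult:
    plan_weights: np.ndarray
    filter: SpeleoFilter
    trace: list[float] = field(default_factory=list)
    status: str = "ok"


def perturb_scenarios(filt: SpeleoFilter, subset_fraction: float,
                      delta: float, seed: int) -> ScenarioSet:
    """Three filter scenarios with a seeded random pillar subset moved
    up/down by ``delta`` (down-clamped at zero height)."""
    if not (0 < subset_fraction <= 1):
        raise ValueError("subset_fraction must be in (0, 1]")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    n = filt.heights.size
    k = max(1, int(round(subset_fraction * n)))
    subset = np.sort(rng.choice(n, size=k, replace=False))
    up = filt.heights.ravel().copy()
    dn = filt.heights.ravel().copy()
    up[subset] += delta
    dn[subset] = np.clip(dn[subset] - delta, 0.0, None)
    return ScenarioSet(filt,
                       filt.with_heights(up.reshape(filt.heights.shape)),
                       filt.with_heights(dn.reshape(filt.heights.shape)),
                       subset, delta)


def objective_map(dose, di: DoseInfluence, goals: dict,
                  roi_masks: dict) -> ObjectiveMap:
    """Voxelwise weighted squared deviations from the planning goals.

    ``dose`` is a DoseGrid or a flat vector aligned with
    ``di.voxel_idx``.  The map sums exactly to the scalar objective used
    by :func:`speleoplan.arc.optimize_weights` at those doses.
    """
    from .arc import _goal_terms
    if isinstance(dose, DoseGrid):
        d = dose.values.ravel()[di.voxel_idx]
    else:
        d = np.asarray(dose, dtype=float)
    vals = np.zeros_like(d)
    for _, rows, kind, goal_dose, lam in _goal_terms(di, goals, roi_masks):
        r = d[rows] - goal_dose
        if kind == "max":
            r = np.clip(r, 0.0, None)
        vals[rows] += lam * r ** 2
    return ObjectiveMap(vals, float(vals.sum()))


def _pillar_spot_map(filt: SpeleoFilter, spots: list[Beamlet],
                     beam: BeamModel, thresh: float = 1e-3):
    """For each pillar (flat index), the spot indices whose Gaussian
    footprint puts more than ``thresh`` of its mass on that pillar."""
    n = filt.heights.size
    hits: list[list[int]] = [[] for _ in range(n)]
    for j, sp in enumerate(spots):
        w = _footprint_weights(filt, {"center": (sp.bev_x, sp.bev_y),
                                      "sigma": beam.spot_sigma_air})
        for idx in np.nonzero(w.ravel() > thresh)[0]:
            hits[idx].append(j)
    return hits


def update_pillars(scenarios: ScenarioSet, maps: dict,
                   di: DoseInfluence, *, beam: BeamModel,
                   eta: float | None = None,
                   eta_scale: float = 1.0) -> SpeleoFilter:
    """Gradient-style height update from the three scenario maps.

    For each perturbed pillar, the finite-difference sensitivity
    ``g = (f+ - f-) / (2 delta)`` is formed from the increased/decreased
    objective maps restricted to the voxels influenced by beamlets
    crossing that pillar; the height moves by ``-eta * g``, clipped to
    ``|step| <= delta``.  Unperturbed pillars are unchanged.
    """
    filt = scenarios.nominal
    delta = scenarios.delta
    if delta == 0:
        return filt
    hits = _pillar_spot_map(filt, di.spots, beam)
    Dc = di.matrix.tocsc()
    grads = np.zeros(filt.heights.size)
    for k in np.asarray(scenarios.subset):
        js = hits[k]
        if not js:
            continue
        rows = np.unique(Dc[:, js].nonzero()[0])
        if rows.size == 0:
            continue
        f_up = float(maps["increased"].values[rows].sum())
        f_dn = float(maps["decreased"].values[rows].sum())
        grads[k] = (f_up - f_dn) / (2.0 * delta)
    gmax = np.abs(grads).max()
    if gmax == 0:
        return filt
    if eta is None:
        eta = delta / gmax
    step = np.clip(-eta * eta_scale * grads, -delta, delta)
    new = np.clip(filt.heights.ravel() + step, 0.0, filt.max_height)
    return filt.with_heights(new.reshape(filt.heights.shape))


def coopt(spots: list[Beamlet], filter0: SpeleoFilter, phantom: Phantom,
          goals: dict, beam: BeamModel,
          cfg: CooptConfig | None = None) -> CooptResult:
    """Outer loop of the joint filter/weight optimisation.

    Per iteration: rebuild the beamlet library for the three scenarios,
    re-optimise nominal weights, evaluate the three objective maps with
    the nominal weights applied, update pillar heights from the map
    gradient (with backtracking on the step scale so the accepted filter
    does not worsen the nominal objective), and iterate until the best
    objective stops improving for two consecutive iterations or
    ``max_outer`` is reached.  Returns the best-seen (weights, filter)
    pair and the monotone best-objective trace.
    """
    cfg = cfg or CooptConfig()
    roi_masks = phantom.roi_masks
    status = "ok"

    def nominal_objective(f: SpeleoFilter):
        di = build_dose_influence(spots, phantom, f, beam)
        res = optimize_weights(di, goals, roi_masks, renormalize_d95=False)
        m = objective_map(di.matrix @ res.weights, di, goals, roi_masks)
        return di, res, m

    filt = filter0
    di, res, m_nom = nominal_objective(filt)
    best = (res.weights, filt)
    best_obj = m_nom.total
    trace = [best_obj]
    stall = 0

    for it in range(cfg.max_outer):
        if cfg.delta == 0:
            break
        scen = perturb_scenarios(filt, cfg.subset_fraction, cfg.delta,
                                 cfg.seed + it)
        maps = {}
        for name, f_s in (("increased", scen.increased),
                          ("decreased", scen.decreased)):
            di_s = build_dose_influence(spots, phantom, f_s, beam)
            if cfg.reoptimize_scenarios:
                w_s = optimize_weights(di_s, goals, roi_masks,
                                       renormalize_d95=False).weights
            else:
                w_s = res.weights
            maps[name] = objective_map(di_s.matrix @ w_s, di_s, goals,
                                       roi_masks)
        maps["nominal"] = m_nom
        proposal = update_pillars(scen, maps, di, beam=beam, eta=cfg.eta)
        step = proposal.heights - filt.heights

        # backtracking on the step scale; every trial is judged with its
        # own re-optimised weights
        accepted = False
        for scale in (1.0, 0.5, 0.25, 0.125):
            trial = filt.with_heights(
                np.clip(filt.heights + scale * step, 0.0, filt.max_height))
            di_t, res_t, m_t = nominal_objective(trial)
            if m_t.total < best_obj - cfg.rel_tol * max(best_obj, 1e-30):
                filt, di, res, m_nom = trial, di_t, res_t, m_t
                best = (res.weights, filt)
                best_obj = m_t.total
                accepted = True
                break
        if accepted:
            stall = 0
        else:
            stall += 1
            if it == 0:
                status = "no-improvement-at-start"
        trace.append(best_obj)
        if stall >= 2:
            break
    return CooptResult(best[0], best[1], trace, status)
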