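"""Pillar-height optimisation for spread-out Bragg peak (SOBP) goals.

The designer treats the depth dose under a uniformly scanned field as the
superposition of WET-shifted pristine curves, one shift per pillar.  A
coordinate-descent sweep proposes a +/- step change to each pillar in
turn, keeps only changes that reduce the weighted squared deviation from
the goal profile, and repeats over a decreasing step schedule.  Because
the superposition model ignores changes in lateral scattering inside the
filter, the goal can be iteratively "augmented" against a full engine
recomputation (a damped fixed-point correction on the plateau).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DepthDoseCurve, shift_curve
from .filters import SpeleoFilter, WetHistogram

__all__ = [
    "GoalProfile", "DesignerConfig", "DesignResult",
    "make_sobp_goal", "superpose", "objective",
    "optimize_pillars", "augment_goal",
]


@dataclass
class GoalProfile:
    """Desired depth-dose profile with per-point importance weights.

    ``plateau`` is the (proximal, distal) interval in mm that should carry
    uniform dose; points there default to weight 1, the distal falloff to
    0.5 and the entrance region to 0.25.
    """

    depths: np.ndarray
    goal_dose: np.ndarray
    plateau: tuple[float, float]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.goal_dose = np.asarray(self.goal_dose, dtype=float)
        if self.depths.shape != self.goal_dose.shape:
            raise ValueError("depths and goal_dose must match")
        if np.any(self.goal_dose < 0):
            raise ValueError("goal dose must be >= 0")
        lo, hi = self.plateau
        if not (self.depths[0] <= lo < hi <= self.depths[-1]):
            raise ValueError("plateau must lie within the depth grid")
        if self.weights is None:
            w = np.full_like(self.depths, 0.25)
            w[(self.depths >= lo) & (self.depths <= hi)] = 1.0
            w[(self.depths > hi) & (self.depths <= hi + 10.0)] = 0.5
            self.weights = w
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.depths.shape:
                raise ValueError("weights must match the depth grid")

    @property
    def plateau_mask(self) -> np.ndarray:
        lo, hi = self.plateau
        return (self.depths >= lo) & (self.depths <= hi)


@dataclass
class DesignerConfig:
    """Sweep schedule for :func:`optimize_pillars`.

    ``iterations`` full-filter sweeps are run at each entry of the
    (strictly decreasing) ``step_schedule``.
    """

    iterations: int = 15
    step_schedule: tuple[float, ...] = (5.0, 1.0, 0.25, 0.1)
    sweep_order: str = "raster"   # or "shuffled"
    seed: int = 0
    goal_correction_rounds: int = 3
    damping: float = 1.0

    def __post_init__(self) -> None:
        steps = np.asarray(self.step_schedule, dtype=float)
        if np.any(steps <= 0) or np.any(np.diff(steps) >= 0):
            raise ValueError("step_schedule must be positive and decreasing")
        if self.sweep_order not in ("raster", "shuffled"):
            raise ValueError("sweep_order must be 'raster' or 'shuffled'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class DesignResult:
    filter: SpeleoFilter
    objective_trace: list[float] = field(default_factory=list)
    accepted_per_sweep: list[int] = field(default_factory=list)


def make_sobp_goal(pristine: DepthDoseCurve, width_mm: float, *,
                   distal_mm: float | None = None, rsp: float = 1.16,
                   base_thickness: float = 1.0, level: float | None = None,
                   falloff_mm: float = 3.0) -> GoalProfile:
    """Flat-plateau goal of the given width for a pristine beam.

    The distal plateau edge defaults to the pristine 90% range pulled back
    by the WET of the base layer plus 2 mm of pillar headroom, so a filter
    with small but nonzero minimum pillar height can reach it.  The
    plateau ``level`` defaults to the mean plateau dose of an ideal SOBP
    built from a uniform WET spread over the plateau width, so the goal
    is on the scale unit-fluence superposition can actually deliver.
    """
    if distal_mm is None:
        distal_mm = pristine.range_d90 - rsp * (base_thickness + 2.0)
    proximal = distal_mm - width_mm
    if proximal <= 0:
        raise ValueError("SOBP width exceeds the available range")
    # ideal-SOBP template: non-negative least-squares weights over a 1 mm
    # WET spread so the superposed curve is flat on the plateau; this
    # fixes both the achievable plateau level and the natural entrance
    # dose for the goal.
    from scipy.optimize import nnls

    wet0 = max(pristine.range_d90 - distal_mm, 0.0)
    wets = wet0 + np.arange(0.0, width_mm + 2.0 + 1e-9, 1.0)
    A = np.stack([
        np.interp(pristine.depths + w, pristine.depths, pristine.dose,
                  left=0.0, right=0.0) for w in wets], axis=1)
    m = (pristine.depths >= proximal) & (pristine.depths <= distal_mm)
    sol, _ = nnls(A[m], np.ones(int(m.sum())))
    tot = sol.sum()
    if tot <= 0:
        raise ValueError("SOBP template infeasible for this width")
    est = A @ (sol / tot)
    if level is None:
        level = float(est[m].mean())
    entrance = est * (level / max(float(est[m].mean()), 1e-12))
    # flat plateau at `level`, template entrance upstream, linear falloff
    # downstream.  The ramp starts one pristine 90->20% falloff width
    # beyond the plateau so range straggling can round the shoulder
    # without eating into the plateau.
    shoulder = max(pristine.distal_falloff(0.2) - pristine.range_d90, 0.0)
    ramp_start = distal_mm + shoulder
    goal = np.where(
        pristine.depths < proximal,
        entrance,
        np.where(
            pristine.depths <= ramp_start,
            level,
            np.clip(1.0 - (pristine.depths - ramp_start) / falloff_mm,
                    0.0, None) * level,
        ),
    )
    return GoalProfile(pristine.depths.copy(), goal, (proximal, distal_mm))


def superpose(pristine: DepthDoseCurve, hist: WetHistogram) -> DepthDoseCurve:
    """Histogram-weighted superposition of WET-shifted pristine curves."""
    dose = np.zeros_like(pristine.dose)
    for wet, mass in zip(hist.wet_bins, hist.mass):
        dose += mass * shift_curve(pristine, float(wet)).dose
    return DepthDoseCurve(pristine.depths.copy(), dose, pristine.energy)


def objective(est: DepthDoseCurve, goal: GoalProfile) -> float:
    """Weighted sum of squared deviations on the goal grid."""
    if est.depths[-1] < goal.plateau[1]:
        raise ValueError("estimate grid does not cover the goal plateau")
    e = est.at(goal.depths)
    return float(np.sum(goal.weights * (e - goal.goal_dose) ** 2))


class _SweepState:
    """Incremental objective bookkeeping for the coordinate-descent sweep.

    Keeps the running sum of per-pillar shifted curves on the goal grid so
    a candidate height change costs one cached-curve lookup and one vector
    update instead of a full re-superposition.
    """

    def __init__(self, pristine: DepthDoseCurve, goal: GoalProfile,
                 filt: SpeleoFilter):
        self.goal = goal
        self.pristine = pristine
        self.rsp = filt.material.rsp
        self.base = filt.base_thickness
        self.n = filt.heights.size
        self._cache: dict[int, np.ndarray] = {}
        self.heights = filt.heights.ravel().copy()
        self.total = np.zeros_like(goal.depths)
        for h in self.heights:
            self.total += self._shifted(h)

    def _shifted(self, height: float) -> np.ndarray:
        key = int(round(height * 1000))
        arr = self._cache.get(key)
        if arr is None:
            wet = (key / 1000.0 + self.base) * self.rsp
            arr = np.interp(self.goal.depths + wet, self.pristine.depths,
                            self.pristine.dose, left=0.0, right=0.0) / self.n
            self._cache[key] = arr
        return arr

    def objective_of(self, total: np.ndarray) -> float:
        return float(np.sum(self.goal.weights *
                            (total - self.goal.goal_dose) ** 2))

    def try_move(self, idx: int, new_height: float,
                 current_obj: float) -> float | None:
        """Apply the move if it improves the objective; return new value."""
        cand = self.total - self._shifted(self.heights[idx]) \
            + self._shifted(new_height)
        obj = self.objective_of(cand)
        if obj < current_obj:
            self.total = cand
            self.heights[idx] = new_height
            return obj
        return None


def optimize_pillars(goal: GoalProfile, pristine: DepthDoseCurve,
                     filter0: SpeleoFilter,
                     cfg: DesignerConfig | None = None) -> DesignResult:
    """Coordinate-descent pillar-height optimisation against a goal SOBP.

    Each sweep visits every pillar once (raster or seeded-shuffle order),
    evaluates +/- the current step, and accepts only objective-improving
    changes, which take effect immediately and are compiled into the new
    reference filter at the end of the sweep.  The objective trace over
    sweeps is therefore non-increasing by construction.
    """
    cfg = cfg or DesignerConfig()
    if goal.plateau[1] > pristine.range_d90 + pristine.step:
        raise ValueError(
            f"goal plateau distal edge {goal.plateau[1]:.1f} mm is beyond the "
            f"pristine range {pristine.range_d90:.1f} mm")
    st = _SweepState(pristine, goal, filter0)
    rng = np.random.default_rng(cfg.seed)
    hmax = filter0.max_height
    obj = st.objective_of(st.total)
    trace = [obj]
    accepted_counts = []
    for step in cfg.step_schedule:
        for _ in range(cfg.iterations):
            order = np.arange(st.n)
            if cfg.sweep_order == "shuffled":
                rng.shuffle(order)
            accepted = 0
            for idx in order:
                best = None
                for cand in (st.heights[idx] + step, st.heights[idx] - step):
                    if cand < 0 or cand > hmax:
                        continue
                    res = st.try_move(idx, cand, obj)
                    if res is not None:
                        obj = res
                        best = cand
                        break  # greedy: first improving direction wins
                if best is not None:
                    accepted += 1
            trace.append(obj)
            accepted_counts.append(accepted)
            if accepted == 0:
                break
    new_heights = st.heights.reshape(filter0.heights.shape)
    return DesignResult(filter0.with_heights(new_heights), trace,
                        accepted_counts)


def augment_goal(goal: GoalProfile, engine_check: DepthDoseCurve, *,
                 damping: float = 0.7,
                 reference: GoalProfile | None = None,
                 extend_mm: float = 0.0) -> GoalProfile:
    """Damped fixed-point goal correction restricted to the plateau.

    Where the full engine over/under-shoots the intended profile, the goal
    handed to the superposition-model designer is moved the opposite way:
    ``goal' = goal + damping * (ref - engine_check)`` on plateau points
    (optionally extended ``extend_mm`` past the distal edge, into the
    shoulder band), where ``ref`` is the original (un-augmented) goal when
    iterating over several correction rounds, or ``goal`` itself by
    default.  The engine check must be normalised to the goal's plateau
    mean by the caller.
    """
    ref = reference if reference is not None else goal
    est = engine_check.at(goal.depths)
    new = goal.goal_dose.copy()
    lo, hi = goal.plateau
    m = (goal.depths >= lo) & (goal.depths <= hi + extend_mm)
    new[m] = goal.goal_dose[m] + damping * (ref.goal_dose[m] - est[m])
    new = np.clip(new, 0.0, None)
    return GoalProfile(goal.depths.copy(), new, goal.plateau,
                       goal.weights.copy())


def distribute_heights(filt: SpeleoFilter, method: str = "stratified",
                       seed: int = 0) -> SpeleoFilter:
    """Spatially redistribute a filter's height multiset.

    The superposition model constrains only the *distribution* of pillar
    heights, but a scanned beamlet samples the pillars under its own
    footprint: spatially correlated heights (as a raster sweep tends to
    leave behind) make the local WET histogram differ from the designed
    one and produce hot/cold streaks.  ``"stratified"`` places the sorted
    heights along a 2-D low-discrepancy (R2 lattice) ordering so every
    neighbourhood samples the full distribution; ``"shuffled"`` uses a
    seeded random permutation; ``"none"`` returns the filter unchanged.
    The height multiset (and hence the full-footprint histogram) is
    preserved exactly.
    """
    if method == "none":
        return filt
    h = filt.heights
    flat = h.ravel()
    if method == "shuffled":
        rng = np.random.default_rng(seed)
        out = flat.copy()
        rng.shuffle(out)
    elif method == "stratified":
        g = 1.32471795724474602596   # plastic number: R2 sequence
        a1, a2 = 1.0 / g, 1.0 / g ** 2
        i, j = np.indices(h.shape)
        key = (a1 * i + a2 * j) % 1.0
        order = np.argsort(key.ravel(), kind="stable")
        out = np.empty_like(flat)
        out[order] = np.sort(flat)
    else:
        raise ValueError(f"unknown placement method {method!r}")
    return filt.with_heights(out.reshape(h.shape))
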