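"""Spot placement and robust spot-weight optimization.

Setup/range uncertainty enters the target objective as an expectation over
the 21-scenario grid (nominal + 6 axis-aligned shifts, each at range scales
0.95/1.00/1.05); organ-at-risk and functional-lung penalties are one-sided
quadratics on the nominal dose. Plans failing the worst-case coverage gate
(V95 of the CTV >= 95% in every scenario) are re-optimized with the target
weight escalated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ventavoid.core import ImageGrid
from ventavoid.dose_engine import (
    Beam,
    InfluenceMatrix,
    MachineModel,
    Scenario,
    SpotPlan,
    beam_wepl_volume,
    build_influence,
    compute_dose_volume,
)
from ventavoid.metrics_stats import dvh_metric


# --------------------------------------------------------------------------
# objectives
# --------------------------------------------------------------------------

TERM_KINDS = ("uniform_target", "max_dose", "mean_dose", "dose_volume")


@dataclass(frozen=True)
class ObjectiveTerm:
    structure: str
    kind: str
    dose_gy: float
    weight: float
    volume_fraction: float | None = None    # for dose_volume terms
    robust: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("objective weights must be >= 0")


@dataclass(frozen=True)
class ObjectiveSet:
    terms: tuple[ObjectiveTerm, ...]

    def __post_init__(self) -> None:
        if not any(t.kind == "uniform_target" for t in self.terms):
            raise ValueError("objective set must contain a uniform_target term")

    @property
    def target(self) -> ObjectiveTerm:
        return next(t for t in self.terms if t.kind == "uniform_target")

    def with_target_weight(self, weight: float) -> "ObjectiveSet":
        new = tuple(
            replace(t, weight=weight) if t.kind == "uniform_target" else t
            for t in self.terms
        )
        return ObjectiveSet(terms=new)


def standard_objectives(rx_gy: float, target_weight: float = 100.0) -> ObjectiveSet:
    """Coverage plus generic OAR sparing (RTOG-style placeholder limits)."""
    return ObjectiveSet(terms=(
        ObjectiveTerm("ctv", "uniform_target", rx_gy, target_weight, robust=True),
        ObjectiveTerm("lungs", "mean_dose", 0.0, 0.4),
        ObjectiveTerm("esophagus", "mean_dose", 0.0, 0.3),
        ObjectiveTerm("heart", "mean_dose", 0.0, 0.3),
        ObjectiveTerm("cord", "max_dose", 0.75 * rx_gy, 5.0),
        ObjectiveTerm("hotspot_region", "max_dose", 1.10 * rx_gy, 5.0),
    ))


def functional_objectives(rx_gy: float, target_weight: float = 100.0,
                          functional_weight: float = 2.0) -> ObjectiveSet:
    """Standard objectives plus avoidance of the functional-lung structures."""
    base = standard_objectives(rx_gy, target_weight).terms
    extra = (
        ObjectiveTerm("functional_minus_ptv", "mean_dose", 0.0, functional_weight),
        ObjectiveTerm("functional_minus_ptv", "dose_volume", 20.0, functional_weight,
                      volume_fraction=0.0),
    )
    return ObjectiveSet(terms=base + extra)


# --------------------------------------------------------------------------
# spot placement
# --------------------------------------------------------------------------


def place_spots(ct: ImageGrid, ctv_mask: np.ndarray, machine: MachineModel,
                beams: list[Beam], rx_gy: float,
                lateral_spacing_mm: float = 6.0, layer_spacing_mm: float = 6.0,
                depth_margin_mm: float = 4.0, lateral_margin_sigma: float = 1.0,
                setup_margin_mm: float = 5.0, range_margin_pct: float = 5.0
                ) -> SpotPlan:
    """Hexagonal lateral grid and depth layers covering the CTV per beam.

    Margins cover the robustness scenarios: the lateral grid extends by
    ``setup_margin_mm`` plus ``lateral_margin_sigma`` in-air sigma beyond
    the CTV projection, and the layer span absorbs setup shifts along the
    beam axis plus the range-uncertainty fraction.
    """
    ctv_mask = np.asarray(ctv_mask, dtype=bool)
    if not np.any(ctv_mask):
        raise ValueError("CTV mask is empty")

    spot_beam, spot_energy, spot_lat = [], [], []
    for b, beam in enumerate(beams):
        wepl = beam_wepl_volume(ct, beam)
        w_ctv = wepl[ctv_mask]
        pad = depth_margin_mm + setup_margin_mm
        w_lo = (float(np.min(w_ctv)) - pad) * (1.0 - range_margin_pct / 100.0)
        w_hi = (float(np.max(w_ctv)) + pad) * (1.0 + range_margin_pct / 100.0)
        ranges = np.asarray(machine.range_mm(machine.energies_mev))
        if w_hi > ranges[-1]:
            raise ValueError(
                f"CTV extends to WEPL {w_hi:.0f} mm, beyond the maximum machine "
                f"range {ranges[-1]:.0f} mm"
            )
        targets = np.arange(max(w_lo, ranges[0]), w_hi + layer_spacing_mm / 2,
                            layer_spacing_mm)
        layer_idx = sorted(set(int(np.argmin(np.abs(ranges - t))) for t in targets))
        energies = machine.energies_mev[layer_idx]

        # lateral hexagonal grid over the CTV projection + sigma margin
        la, lb = beam.lateral_axes
        proj = np.any(ctv_mask, axis=beam.axis)
        margin = (lateral_margin_sigma * float(machine.sigma_air_mm(energies[0]))
                  + setup_margin_mm)
        sp = (ct.spacing[la], ct.spacing[lb])
        dist = ndimage.distance_transform_edt(~proj, sampling=sp)
        o = (ct.origin[la], ct.origin[lb])
        ext = (o[0] + sp[0] * (proj.shape[0] - 1), o[1] + sp[1] * (proj.shape[1] - 1))
        row_step = lateral_spacing_mm * np.sqrt(3.0) / 2.0
        lat_points = []
        for r, a in enumerate(np.arange(o[0], ext[0] + 1e-9, row_step)):
            offset = (r % 2) * lateral_spacing_mm / 2.0
            for bcoord in np.arange(o[1] + offset, ext[1] + 1e-9, lateral_spacing_mm):
                ia = (a - o[0]) / sp[0]
                ib = (bcoord - o[1]) / sp[1]
                d = ndimage.map_coordinates(dist, [[ia], [ib]], order=1)[0]
                if d <= margin:
                    lat_points.append((a, bcoord))
        for e in energies:
            for lat in lat_points:
                spot_beam.append(b)
                spot_energy.append(float(e))
                spot_lat.append(lat)

    return SpotPlan(
        beams=beams,
        spot_beam=np.asarray(spot_beam, dtype=np.int64),
        spot_energy=np.asarray(spot_energy),
        spot_lat=np.asarray(spot_lat),
        weights=np.ones(len(spot_beam)),
        prescription_gy=rx_gy,
    )


def robust_scenarios(setup_mm: float = 5.0, range_pct: float = 5.0
                     ) -> list[Scenario]:
    """Nominal plus axis-aligned setup shifts crossed with range scales."""
    shifts = {(0.0, 0.0, 0.0)}
    if setup_mm > 0:
        for ax, sign in itertools.product(range(3), (+1, -1)):
            v = [0.0, 0.0, 0.0]
            v[ax] = sign * setup_mm
            shifts.add(tuple(v))
    scales = {1.0}
    if range_pct > 0:
        scales |= {1.0 - range_pct / 100.0, 1.0 + range_pct / 100.0}
    return [Scenario(shift_mm=s, range_scale=r)
            for r in sorted(scales) for s in sorted(shifts)]


# --------------------------------------------------------------------------
# optimization problem
# --------------------------------------------------------------------------


@dataclass
class PlannerProblem:
    """Pre-computed influence restricted to the structures the objectives touch."""

    ct: ImageGrid
    plan: SpotPlan
    machine: MachineModel
    structure_masks: dict[str, np.ndarray]
    scenarios: list[Scenario]
    target_ops: dict[int, InfluenceMatrix] = field(default_factory=dict)
    term_ops: dict[str, InfluenceMatrix] = field(default_factory=dict)

    @classmethod
    def build(cls, ct: ImageGrid, plan: SpotPlan, machine: MachineModel,
              structure_masks: dict[str, np.ndarray], objectives: ObjectiveSet,
              scenarios: list[Scenario]) -> "PlannerProblem":
        problem = cls(ct=ct, plan=plan, machine=machine,
                      structure_masks=structure_masks, scenarios=scenarios)
        target_mask = structure_masks[objectives.target.structure]
        for i, sc in enumerate(scenarios):
            problem.target_ops[i] = build_influence(ct, plan, machine, sc,
                                                    voxel_subset=target_mask)
        nominal = next(sc for sc in scenarios if sc.is_nominal)
        for term in objectives.terms:
            if term.kind == "uniform_target" or term.structure in problem.term_ops:
                continue
            problem.term_ops[term.structure] = build_influence(
                ct, plan, machine, nominal, voxel_subset=structure_masks[term.structure]
            )
        return problem

    @property
    def nominal_index(self) -> int:
        return next(i for i, sc in enumerate(self.scenarios) if sc.is_nominal)


def _term_value_grad(term: ObjectiveTerm, op: InfluenceMatrix, w: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    d = op.compose(w)
    n = max(d.size, 1)
    if term.kind == "max_dose":
        over = np.maximum(d - term.dose_gy, 0.0)
        return float(np.sum(over**2) / n), (2.0 / n) * (op.matrix.T @ over)
    if term.kind == "mean_dose":
        excess = max(float(np.mean(d)) - term.dose_gy, 0.0)
        if excess == 0.0:
            return 0.0, np.zeros_like(w)
        ones = np.full(d.size, 1.0 / n)
        return excess**2, 2.0 * excess * (op.matrix.T @ ones)
    if term.kind == "dose_volume":
        over_idx = np.where(d > term.dose_gy)[0]
        allowed = int(np.floor((term.volume_fraction or 0.0) * n))
        if over_idx.size <= allowed:
            return 0.0, np.zeros_like(w)
        # penalize the coldest offenders beyond the allowed volume
        order = over_idx[np.argsort(d[over_idx])]
        culprits = order[: over_idx.size - allowed]
        over = d[culprits] - term.dose_gy
        grad = np.zeros(d.size)
        grad[culprits] = 2.0 * over / n
        return float(np.sum(over**2) / n), op.matrix.T @ grad
    raise ValueError(f"unsupported term kind {term.kind!r}")


@dataclass
class OptimizationResult:
    weights: np.ndarray
    objective_trace: list[float]
    converged: bool


def optimize_weights(problem: PlannerProblem, objectives: ObjectiveSet,
                     max_iterations: int = 150, tolerance: float = 1e-5,
                     warm_start: np.ndarray | None = None,
                     seed: int = 0) -> OptimizationResult:
    """Projected (non-negative) gradient descent with a monotone line search.

    Deterministic given inputs; ``seed`` only breaks ties in the initial
    guess perturbation (disabled by default scale 0).
    """
    target = objectives.target
    rx = target.dose_gy
    ops = problem.target_ops
    n_sc = len(ops)

    if warm_start is not None:
        w = np.asarray(warm_start, dtype=np.float64).copy()
    else:
        d1 = ops[problem.nominal_index].compose(np.ones(problem.plan.n_spots))
        mean1 = float(np.mean(d1)) if d1.size else 0.0
        if mean1 <= 0:
            raise ValueError("influence is all zero on the target")
        w = np.full(problem.plan.n_spots, rx / mean1)

    def objective_and_grad(wv: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros_like(wv)
        if target.weight > 0:
            for op in ops.values():
                d = op.compose(wv)
                res = d - rx
                n = max(d.size, 1)
                total += target.weight * float(np.sum(res**2)) / (n * n_sc)
                grad += target.weight * (2.0 / (n * n_sc)) * (op.matrix.T @ res)
        for term in objectives.terms:
            if term.kind == "uniform_target" or term.weight == 0:
                continue
            val, g = _term_value_grad(term, problem.term_ops[term.structure], wv)
            total += term.weight * val
            grad += term.weight * g
        return total, grad

    obj, grad = objective_and_grad(w)
    trace = [obj]
    gmax = float(np.max(np.abs(grad))) or 1.0
    step = 0.1 * float(np.max(w) + 1.0) / gmax
    converged = False
    for _ in range(max_iterations):
        accepted = False
        for _ in range(30):
            cand = np.maximum(w - step * grad, 0.0)
            c_obj, c_grad = objective_and_grad(cand)
            if c_obj < trace[-1]:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        w, obj, grad = cand, c_obj, c_grad
        trace.append(obj)
        step *= 1.5
        if abs(trace[-2] - trace[-1]) <= tolerance * max(trace[-2], 1e-12):
            converged = True
            break
    return OptimizationResult(weights=w, objective_trace=trace, converged=converged)


# --------------------------------------------------------------------------
# robustness evaluation and the re-weighting loop
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RobustnessReport:
    v95_pct: list[float]
    worst_case_pct: float
    passes: bool


def evaluate_robustness(problem: PlannerProblem, weights: np.ndarray,
                        rx_gy: float, coverage_pct: float = 95.0,
                        dose_pct: float = 95.0) -> RobustnessReport:
    """V95 of the target per scenario; pass when the worst case covers
    ``coverage_pct`` of the volume at ``dose_pct`` of prescription."""
    threshold = dose_pct / 100.0 * rx_gy
    v95 = []
    for i in sorted(problem.target_ops):
        d = problem.target_ops[i].compose(weights)
        v95.append(100.0 * float(np.mean(d >= threshold)))
    worst = min(v95)
    return RobustnessReport(v95_pct=v95, worst_case_pct=worst,
                            passes=worst >= coverage_pct)


@dataclass
class PlanResult:
    plan: SpotPlan
    objectives: ObjectiveSet
    optimization: OptimizationResult
    robustness: RobustnessReport
    rounds: int
    robust_pass: bool


def _normalized_weights(problem: PlannerProblem, weights: np.ndarray,
                        rx_gy: float) -> tuple[np.ndarray, float]:
    d_nom = problem.target_ops[problem.nominal_index].compose(weights)
    d99 = dvh_metric(d_nom, ("D", 99.0))
    if d99 <= 0:
        raise ValueError("nominal target D99 is zero")
    s = 0.99 * rx_gy / d99
    return weights * s, s


def reweight_until_robust(problem: PlannerProblem, objectives: ObjectiveSet,
                          max_rounds: int = 3, escalation: float = 2.0,
                          max_iterations: int = 150) -> PlanResult:
    """Escalate the target weight until the worst-case coverage gate passes.

    Every candidate is first normalized to nominal CTV D99 = 99% of
    prescription (the same global rescale applied to all compared plans)
    before the worst-case evaluation. Failure after ``max_rounds`` is
    reported in the result, not raised.
    """
    rx = objectives.target.dose_gy
    result = optimize_weights(problem, objectives, max_iterations=max_iterations)
    weights, _ = _normalized_weights(problem, result.weights, rx)
    report = evaluate_robustness(problem, weights, rx)
    rounds = 0
    while not report.passes and rounds < max_rounds:
        rounds += 1
        if escalation <= 1.0:
            continue
        objectives = objectives.with_target_weight(
            objectives.target.weight * escalation
        )
        result = optimize_weights(problem, objectives,
                                  max_iterations=max_iterations,
                                  warm_start=result.weights)
        weights, _ = _normalized_weights(problem, result.weights, rx)
        report = evaluate_robustness(problem, weights, rx)
    plan = problem.plan.with_weights(weights)
    return PlanResult(plan=plan, objectives=objectives, optimization=result,
                      robustness=report, rounds=rounds, robust_pass=report.passes)


def normalize_plan(plan: SpotPlan, dose: ImageGrid, ctv_mask: np.ndarray,
                   rx_gy: float) -> tuple[SpotPlan, ImageGrid, float]:
    """Globally rescale so D99 of the target equals 99% of prescription."""
    d99 = dvh_metric(dose.data[np.asarray(ctv_mask, dtype=bool)], ("D", 99.0))
    if d99 <= 0:
        raise ValueError("target D99 is zero; cannot normalize")
    s = 0.99 * rx_gy / d99
    return plan.with_weights(plan.weights * s), dose.with_data(dose.data * s), s
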