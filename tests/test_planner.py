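import numpy as np
import pytest
from scipy import sparse

from ventavoid import dose_engine as de
from ventavoid import planner as pl
from ventavoid.core import ImageGrid


@pytest.fixture(scope="module")
def machine() -> de.MachineModel:
    return de.default_machine_model()


@pytest.fixture(scope="module")
def water() -> ImageGrid:
    return ImageGrid(np.zeros((64, 64, 64)), (2.5, 2.5, 2.5))


def sphere_mask(shape, center, radius_vox):
    zz, yy, xx = np.indices(shape)
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius_vox**2


class TestRobustScenarios:
    def test_default_21(self):
        scens = pl.robust_scenarios()
        assert len(scens) == 21
        assert sum(s.is_nominal for s in scens) == 1

    def test_shift_norms(self):
        for s in pl.robust_scenarios():
            norm = float(np.linalg.norm(s.shift_mm))
            assert norm in (0.0, 5.0)
            assert s.range_scale in (0.95, 1.0, 1.05)

    def test_no_uncertainty_single_nominal(self):
        scens = pl.robust_scenarios(setup_mm=0.0, range_pct=0.0)
        assert len(scens) == 1
        assert scens[0].is_nominal

    def test_enumeration_oracle(self):
        # 7 shifts x 3 scales, constructed independently
        expected = {((0.0, 0.0, 0.0)), }
        for ax in range(3):
            for sign in (1, -1):
                v = [0.0, 0.0, 0.0]
                v[ax] = 5.0 * sign
                expected.add(tuple(v))
        got = {(s.shift_mm, s.range_scale) for s in pl.robust_scenarios()}
        assert got == {(sh, sc) for sh in expected for sc in (0.95, 1.0, 1.05)}


class TestPlaceSpots:
    def test_deeper_target_more_layers(self, water, machine):
        shallow = sphere_mask(water.shape, (32, 12, 32), 4)
        deep = sphere_mask(water.shape, (32, 44, 32), 4)
        beams = [de.Beam(0.0)]
        p_sh = pl.place_spots(water, shallow, machine, beams, 60.0)
        p_dp = pl.place_spots(water, deep, machine, beams, 60.0)
        assert len(set(p_dp.spot_energy)) >= len(set(p_sh.spot_energy))
        assert p_dp.spot_energy.max() > p_sh.spot_energy.max()

    def test_spot_count_matches_enumeration(self, water, machine):
        ctv = sphere_mask(water.shape, (32, 32, 32), 5)
        plan = pl.place_spots(water, ctv, machine, [de.Beam(0.0)], 60.0,
                              lateral_spacing_mm=6.0)
        n_layers = len(set(plan.spot_energy))
        # oracle: hex points within margin of the projection, enumerated
        from scipy import ndimage
        proj = np.any(ctv, axis=1)
        dist = ndimage.distance_transform_edt(~proj, sampling=(2.5, 2.5))
        e_low = min(set(plan.spot_energy))
        margin = float(machine.sigma_air_mm(e_low)) + 5.0
        count = 0
        row_step = 6.0 * np.sqrt(3) / 2
        for r, a in enumerate(np.arange(0.0, 63 * 2.5 + 1e-9, row_step)):
            for b in np.arange((r % 2) * 3.0, 63 * 2.5 + 1e-9, 6.0):
                d = ndimage.map_coordinates(dist, [[a / 2.5], [b / 2.5]], order=1)[0]
                if d <= margin:
                    count += 1
        assert plan.n_spots == count * n_layers

    def test_identical_beams_identical_geometry(self, water, machine):
        ctv = sphere_mask(water.shape, (32, 32, 32), 5)
        plan = pl.place_spots(water, ctv, machine,
                              [de.Beam(0.0), de.Beam(0.0)], 60.0)
        b0 = plan.spot_beam == 0
        b1 = plan.spot_beam == 1
        assert np.array_equal(plan.spot_lat[b0], plan.spot_lat[b1])
        assert np.array_equal(plan.spot_energy[b0], plan.spot_energy[b1])

    def test_target_beyond_range_rejected(self, machine):
        big = ImageGrid(np.zeros((64, 160, 64)), (2.5, 2.5, 2.5))
        ctv = np.zeros(big.shape, dtype=bool)
        ctv[30:34, 150:156, 30:34] = True  # ~380 mm deep in water
        with pytest.raises(ValueError, match="range"):
            pl.place_spots(big, ctv, machine, [de.Beam(0.0)], 60.0)

    def test_empty_target_rejected(self, water, machine):
        with pytest.raises(ValueError, match="empty"):
            pl.place_spots(water, np.zeros(water.shape, bool), machine,
                           [de.Beam(0.0)], 60.0)


def synthetic_problem(columns: np.ndarray, scenarios=None) -> pl.PlannerProblem:
    """PlannerProblem with hand-built target influence (voxels x spots)."""
    scenarios = scenarios or [de.Scenario()]
    n_vox, _ = columns.shape
    ops = {}
    for i, sc in enumerate(scenarios):
        ops[i] = de.InfluenceMatrix(
            matrix=sparse.csc_matrix(columns), shape3d=(n_vox, 1, 1),
            voxel_indices=np.arange(n_vox), scenario=sc,
        )
    plan = de.SpotPlan(
        beams=[de.Beam(0.0)],
        spot_beam=np.zeros(columns.shape[1], dtype=np.int64),
        spot_energy=np.full(columns.shape[1], 120.0),
        spot_lat=np.zeros((columns.shape[1], 2)),
        weights=np.ones(columns.shape[1]),
        prescription_gy=60.0,
    )
    ct = ImageGrid(np.zeros((n_vox, 1, 1)), (1.0, 1.0, 1.0))
    return pl.PlannerProblem(ct=ct, plan=plan, machine=de.default_machine_model(),
                             structure_masks={}, scenarios=scenarios,
                             target_ops=ops)


class TestOptimizeWeights:
    def test_single_spot_closed_form(self):
        # one spot, one voxel, dose 0.02 Gy/MU: optimum = Rx / 0.02
        problem = synthetic_problem(np.array([[0.02]]))
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 1.0),
        ))
        res = pl.optimize_weights(problem, objectives, max_iterations=300,
                                  tolerance=1e-14)
        assert res.weights[0] == pytest.approx(60.0 / 0.02, rel=1e-3)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(5)
        problem = synthetic_problem(rng.uniform(0.001, 0.02, size=(30, 8)))
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 1.0),
        ))
        res = pl.optimize_weights(problem, objectives, max_iterations=100)
        assert np.all(np.diff(res.objective_trace) < 0)

    def test_zero_weight_objective_keeps_warm_start(self):
        problem = synthetic_problem(np.array([[0.02]]))
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 0.0),
        ))
        w0 = np.array([123.0])
        res = pl.optimize_weights(problem, objectives, warm_start=w0)
        assert res.weights[0] == pytest.approx(123.0)

    def test_weights_nonnegative(self):
        rng = np.random.default_rng(9)
        problem = synthetic_problem(rng.uniform(0, 0.02, size=(40, 12)))
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 1.0),
        ))
        res = pl.optimize_weights(problem, objectives, max_iterations=80)
        assert np.all(res.weights >= 0)

    def test_matches_two_spot_grid_search(self):
        # brute-force oracle on a 2-spot least-squares problem
        cols = np.array([[0.010, 0.002],
                         [0.004, 0.012],
                         [0.008, 0.008]])
        problem = synthetic_problem(cols)
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 1.0),
        ))
        res = pl.optimize_weights(problem, objectives, max_iterations=500,
                                  tolerance=1e-14)
        w_grid = np.linspace(0, 8000, 401)
        best, best_val = None, np.inf
        for w1 in w_grid:
            d = cols @ np.array([w1, 0.0])
            resid = cols[:, 1] @ (60.0 - d) / np.sum(cols[:, 1] ** 2)
            w2 = max(resid, 0.0)
            val = np.mean((cols @ np.array([w1, w2]) - 60.0) ** 2)
            if val < best_val:
                best, best_val = (w1, w2), val
        ours = float(np.mean((cols @ res.weights - 60.0) ** 2))
        assert ours <= best_val * (1 + 1e-3)


class TestEvaluateRobustness:
    def test_nominal_only_worst_is_nominal(self):
        problem = synthetic_problem(np.array([[0.02], [0.018], [0.01]]))
        rep = pl.evaluate_robustness(problem, np.array([3000.0]), 60.0)
        assert len(rep.v95_pct) == 1
        assert rep.worst_case_pct == rep.v95_pct[0]

    def test_uniform_rx_everywhere_is_100(self):
        problem = synthetic_problem(np.full((5, 1), 0.02),
                                    scenarios=[de.Scenario(),
                                               de.Scenario(range_scale=1.05)])
        rep = pl.evaluate_robustness(problem, np.array([3000.0]), 60.0)
        assert rep.v95_pct == [100.0, 100.0]
        assert rep.passes

    def test_three_voxel_counting(self):
        # doses 60, 58, 50 at rx 60: threshold 57 -> 2/3 covered
        problem = synthetic_problem(np.array([[0.02], [0.0193333], [0.0166667]]))
        rep = pl.evaluate_robustness(problem, np.array([3000.0]), 60.0)
        assert rep.worst_case_pct == pytest.approx(100.0 * 2 / 3)
        assert not rep.passes


class TestReweightUntilRobust:
    def test_passing_problem_zero_rounds(self):
        problem = synthetic_problem(np.full((4, 2), 0.01))
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 10.0),
        ))
        res = pl.reweight_until_robust(problem, objectives, max_iterations=200)
        assert res.robust_pass
        assert res.rounds == 0

    def test_unreachable_coverage_reports_failure(self):
        # second voxel receives no dose in the off scenario: V95 can't pass
        cols = np.array([[0.02], [0.02]])
        problem = synthetic_problem(cols, scenarios=[de.Scenario()])
        off = de.InfluenceMatrix(
            matrix=sparse.csc_matrix(np.array([[0.02], [0.0]])),
            shape3d=(2, 1, 1), voxel_indices=np.arange(2),
            scenario=de.Scenario(shift_mm=(5.0, 0.0, 0.0)),
        )
        problem.target_ops[1] = off
        problem.scenarios.append(off.scenario)
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 10.0),
        ))
        res = pl.reweight_until_robust(problem, objectives, max_rounds=2)
        assert not res.robust_pass
        assert res.rounds == 2

    def test_unity_escalation_terminates(self):
        problem = synthetic_problem(np.array([[0.02], [0.02]]))
        off = de.InfluenceMatrix(
            matrix=sparse.csc_matrix(np.array([[0.02], [0.0]])),
            shape3d=(2, 1, 1), voxel_indices=np.arange(2),
            scenario=de.Scenario(shift_mm=(5.0, 0.0, 0.0)),
        )
        problem.target_ops[1] = off
        problem.scenarios.append(off.scenario)
        objectives = pl.ObjectiveSet(terms=(
            pl.ObjectiveTerm("ctv", "uniform_target", 60.0, 10.0),
        ))
        res = pl.reweight_until_robust(problem, objectives, max_rounds=3,
                                       escalation=1.0)
        assert not res.robust_pass
        assert res.rounds == 3


class TestNormalizePlan:
    def test_d99_exact_after_normalization(self, water, machine):
        ctv = sphere_mask(water.shape, (32, 32, 32), 4)
        plan = pl.place_spots(water, ctv, machine, [de.Beam(0.0)], 60.0)
        plan = plan.with_weights(np.full(plan.n_spots, 2.0))
        dose = de.compute_dose_volume(water, plan, machine)
        from ventavoid.metrics_stats import dvh_metric
        plan2, dose2, s = pl.normalize_plan(plan, dose, ctv, 60.0)
        assert dvh_metric(dose2, ("D", 99.0), mask=ctv) == pytest.approx(
            0.99 * 60.0, rel=1e-12)

    def test_already_normalized_scale_one(self, water, machine):
        ctv = sphere_mask(water.shape, (32, 32, 32), 4)
        plan = pl.place_spots(water, ctv, machine, [de.Beam(0.0)], 60.0)
        plan = plan.with_weights(np.full(plan.n_spots, 2.0))
        dose = de.compute_dose_volume(water, plan, machine)
        _, dose1, s1 = pl.normalize_plan(plan, dose, ctv, 60.0)
        _, _, s2 = pl.normalize_plan(plan, dose1, ctv, 60.0)
        assert s2 == pytest.approx(1.0, rel=1e-12)

    def test_metrics_scale_linearly(self, water, machine):
        from ventavoid.metrics_stats import dvh_metric
        ctv = sphere_mask(water.shape, (32, 32, 32), 4)
        plan = pl.place_spots(water, ctv, machine, [de.Beam(0.0)], 60.0)
        plan = plan.with_weights(np.full(plan.n_spots, 2.0))
        dose = de.compute_dose_volume(water, plan, machine)
        _, dose2, s = pl.normalize_plan(plan, dose, ctv, 60.0)
        for spec in ("mean", "max", ("D", 50.0)):
            assert dvh_metric(dose2, spec, mask=ctv) == pytest.approx(
                s * dvh_metric(dose, spec, mask=ctv), rel=1e-12)

    def test_zero_dose_rejected(self, water):
        from ventavoid.dose_engine import SpotPlan
        ctv = sphere_mask(water.shape, (32, 32, 32), 4)
        plan = SpotPlan(beams=[de.Beam(0.0)], spot_beam=np.zeros(1, np.int64),
                        spot_energy=np.array([120.0]),
                        spot_lat=np.zeros((1, 2)), weights=np.array([0.0]),
                        prescription_gy=60.0)
        dose = water.with_data(np.zeros(water.shape))
        with pytest.raises(ValueError, match="D99"):
            pl.normalize_plan(plan, dose, ctv, 60.0)


class TestObjectiveSets:
    def test_target_required(self):
        with pytest.raises(ValueError, match="uniform_target"):
            pl.ObjectiveSet(terms=(
                pl.ObjectiveTerm("lungs", "mean_dose", 0.0, 1.0),
            ))

    def test_functional_extends_standard(self):
        std = pl.standard_objectives(60.0)
        fun = pl.functional_objectives(60.0)
        assert {t.structure for t in std.terms} < {t.structure for t in fun.terms}
        assert any(t.structure.startswith("functional") for t in fun.terms)

    def test_with_target_weight(self):
        std = pl.standard_objectives(60.0)
        esc = std.with_target_weight(400.0)
        assert esc.target.weight == 400.0
        assert std.target.weight == 100.0
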