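"""Static recruitment: toy-problem oracles, KKT structure, force extraction."""

import numpy as np
import pytest
from scipy.linalg import null_space

from lumbarload import (
    InfeasibleProblemError,
    ValidationError,
    assemble_problem,
    build_chain,
    build_muscle_set,
    build_posture,
    intersegmental_force,
    load_constants,
    make_params,
    simulate_configuration,
    solve_recruitment,
)
from lumbarload.body import superincumbent_load
from lumbarload.config import LUMBAR_JOINTS
from lumbarload.muscles import line_of_action
from lumbarload.solver import RecruitmentProblem, _crossing


def _problem(arms, strengths, moments, p=3.0):
    arms = np.atleast_2d(np.asarray(arms, dtype=float))
    return RecruitmentProblem(
        joints=tuple(f"j{i}" for i in range(arms.shape[0])),
        gravity_moments=np.asarray(moments, dtype=float),
        moment_arm_matrix=arms,
        strengths=np.asarray(strengths, dtype=float),
        fascicle_names=tuple(f"m{i}" for i in range(arms.shape[1])),
        criterion_power=p,
    )


def _grid_oracle(problem, n=200, box=6000.0, refinements=4):
    """Exhaustive search over the feasible affine slice (for tiny problems).

    Coarse scan of the nullspace coordinates followed by successive local
    refinements around the incumbent, so vertex optima on the nonnegativity
    boundary are resolved as well.
    """
    A = problem.moment_arm_matrix
    b = problem.gravity_moments
    f_p, *_ = np.linalg.lstsq(A, b, rcond=None)
    N = null_space(A)
    if N.shape[1] == 0:
        return f_p, float(np.sum((f_p / problem.strengths)
                                 ** problem.criterion_power))

    def scan(center, half_width):
        axes = [np.linspace(c - half_width, c + half_width, n)
                for c in center]
        grids = np.meshgrid(*axes)
        ts = np.stack([g.ravel() for g in grids], axis=1)
        candidates = f_p[None, :] + ts @ N.T
        ok = np.all(candidates >= -1e-12, axis=1)
        ts, candidates = ts[ok], np.maximum(candidates[ok], 0.0)
        obj = np.sum((candidates / problem.strengths)
                     ** problem.criterion_power, axis=1)
        k = int(np.argmin(obj))
        return ts[k], candidates[k], float(obj[k])

    center = np.zeros(N.shape[1])
    width = box
    t, best_f, best = scan(center, width)
    for _ in range(refinements):
        width = width * 4.0 / n
        t, best_f, best = scan(t, width)
    return best_f, best


class TestSolveRecruitment:
    def test_single_extensor_equilibrium(self):
        """One joint, one muscle: f = M / r."""
        sol = solve_recruitment(_problem([[0.05]], [1000.0], [20.0]))
        assert sol.muscle_forces[0] == pytest.approx(400.0, rel=1e-9)
        assert sol.equilibrium_residual <= 1e-6

    def test_identical_synergists_share_equally(self):
        sol = solve_recruitment(_problem([[0.05, 0.05]], [1000.0, 1000.0],
                                         [20.0]))
        assert sol.muscle_forces == pytest.approx([200.0, 200.0], rel=1e-6)

    def test_cubic_split_ratio_for_unequal_strengths(self):
        """Equal arms, S1/S2 = 2: the split is (S1/S2)^{p/(p-1)} = 2^1.5."""
        problem = _problem([[0.05, 0.05]], [1000.0, 500.0], [20.0])
        sol = solve_recruitment(problem)
        ratio = sol.muscle_forces[0] / sol.muscle_forces[1]
        assert ratio == pytest.approx(2.0 ** 1.5, rel=1e-3)
        _, best = _grid_oracle(problem)
        assert sol.objective_value <= best * (1 + 1e-3)

    def test_flexor_silent_under_net_flexion_demand(self):
        """With a flexion-positive gravity moment the flexor stays at zero."""
        problem = _problem([[0.05, -0.09]], [1000.0, 900.0], [15.0])
        sol = solve_recruitment(problem)
        assert sol.muscle_forces[1] == pytest.approx(0.0, abs=1e-8)
        _, best = _grid_oracle(problem)
        assert sol.objective_value <= best * (1 + 1e-3)

    def test_extensor_silent_under_net_extension_demand(self):
        problem = _problem([[0.05, -0.09]], [1000.0, 900.0], [-12.0])
        sol = solve_recruitment(problem)
        assert sol.muscle_forces[0] == pytest.approx(0.0, abs=1e-8)
        assert sol.muscle_forces[1] == pytest.approx(12.0 / 0.09, rel=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_grid_search_on_random_small_problems(self, seed):
        """<= 3 muscles, <= 2 joints: objective within 0.1% of brute force."""
        rng = np.random.default_rng(seed)
        nj = int(rng.integers(1, 3))
        nf = int(rng.integers(nj, 4))
        arms = rng.uniform(-0.1, 0.1, size=(nj, nf))
        strengths = rng.uniform(300.0, 2000.0, size=nf)
        f_true = rng.uniform(0.0, 500.0, size=nf)
        moments = arms @ f_true  # guarantees feasibility
        problem = _problem(arms, strengths, moments)
        sol = solve_recruitment(problem)
        assert sol.equilibrium_residual <= 1e-6
        _, best = _grid_oracle(problem, n=200 if nf - nj == 1 else 60)
        # two-sided agreement: neither side beats the other by > 0.1%
        assert sol.objective_value <= best * (1 + 1e-3)
        assert best <= sol.objective_value * (1 + 1e-3)

    def test_infeasible_problem_raises(self):
        with pytest.raises(InfeasibleProblemError):
            solve_recruitment(_problem([[0.05]], [1000.0], [-5.0]))

    def test_over_strength_activation_warns(self):
        with pytest.warns(RuntimeWarning, match="activation above 1"):
            sol = solve_recruitment(_problem([[0.05]], [100.0], [20.0]))
        assert sol.activations[0] > 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            _problem([[0.05, 0.04]], [1000.0], [20.0])
        with pytest.raises(ValidationError, match="power"):
            _problem([[0.05]], [1000.0], [20.0], p=1.0)


class TestAssembleProblem:
    def test_gravity_moments_match_free_body_oracle(self, reference_posture,
                                                    constants):
        chain = build_chain(reference_posture, constants)
        muscles = build_muscle_set(constants)
        problem = assemble_problem(chain, muscles, reference_posture, constants)
        for k, joint in enumerate(problem.joints):
            _, moment = superincumbent_load(chain, joint)
            assert problem.gravity_moments[k] == pytest.approx(moment)

    def test_zero_gravity_posture_has_zero_moments(self, reference_posture):
        zero_g = load_constants(overrides={
            "anthropometry": {"gravity_m_s2": 0.0}})
        chain = build_chain(reference_posture, zero_g)
        muscles = build_muscle_set(zero_g)
        problem = assemble_problem(chain, muscles, reference_posture, zero_g)
        assert np.allclose(problem.gravity_moments, 0.0)

    def test_constraint_matrix_shape(self, reference_posture, constants):
        chain = build_chain(reference_posture, constants)
        muscles = build_muscle_set(constants)
        problem = assemble_problem(chain, muscles, reference_posture, constants)
        assert problem.joints == LUMBAR_JOINTS
        assert problem.moment_arm_matrix.shape == (5, len(muscles.fascicles))


class TestIntersegmentalForce:
    def test_reaction_without_muscles_is_gravity_load(self, reference_posture,
                                                      constants):
        chain = build_chain(reference_posture, constants)
        muscles = build_muscle_set(constants)
        # fabricate an all-zero solution over the real muscle set
        from lumbarload.solver import RecruitmentSolution
        zeros = RecruitmentSolution(
            muscle_forces=np.zeros(len(muscles.fascicles)),
            activations=np.zeros(len(muscles.fascicles)),
            objective_value=0.0, equilibrium_residual=0.0,
            fascicle_names=tuple(f.name for f in muscles.fascicles))
        force = intersegmental_force(chain, muscles, zeros, "l4l5")
        gravity, _ = superincumbent_load(chain, "l4l5")
        assert np.allclose(force, gravity)

    def test_conservation_across_levels(self, constants):
        """Reactions at L4L5 and L5S1 differ by L5's weight plus the tensions
        of fascicles crossing exactly one of the two levels."""
        params = make_params("RT3", 40, 50, "front", constants)
        posture = build_posture(params, constants)
        chain = build_chain(posture, constants)
        muscles = build_muscle_set(constants)
        problem = assemble_problem(chain, muscles, posture, constants)
        sol = solve_recruitment(problem)
        f45 = intersegmental_force(chain, muscles, sol, "l4l5")
        f51 = intersegmental_force(chain, muscles, sol, "l5s1")
        l5_weight = np.array([0.0, -chain.segment("l5").mass * chain.gravity])
        extra = np.zeros(2)
        for fascicle, force in zip(muscles.fascicles, sol.muscle_forces):
            if force > 0 and (_crossing(fascicle, "l5s1")
                              != _crossing(fascicle, "l4l5")):
                u, *_ = line_of_action(fascicle, posture)
                sign = 1.0 if _crossing(fascicle, "l5s1") else -1.0
                extra += sign * force * u
        assert np.allclose(f51, f45 + l5_weight + extra, atol=1e-9)

    def test_unknown_level_rejected(self, reference_posture, constants):
        chain = build_chain(reference_posture, constants)
        muscles = build_muscle_set(constants)
        sol = solve_recruitment(
            assemble_problem(chain, muscles, reference_posture, constants))
        with pytest.raises(ValidationError):
            intersegmental_force(chain, muscles, sol, "c7t1")


class TestSimulateConfiguration:
    def test_reference_configuration_is_compressive(self, constants):
        result = simulate_configuration(
            make_params("RT1", 25, 40, "med", constants), constants)
        assert result.fl4l5c > 0
        assert result.fl5s1c > 0
        assert result.f_l4l5[1] < 0  # transmitted load points downward

    def test_deterministic(self, constants):
        params = make_params("RT2", 30, 45, "front", constants)
        a = simulate_configuration(params, constants)
        b = simulate_configuration(params, constants)
        assert a.to_row() == b.to_row()  # bit-identical scalar outputs
        assert np.array_equal(a.f_l4l5, b.f_l4l5)
        assert np.array_equal(a.f_l5s1, b.f_l5s1)

    def test_zero_gravity_yields_zero_forces(self):
        zero_g = load_constants(overrides={
            "anthropometry": {"gravity_m_s2": 0.0}})
        result = simulate_configuration(
            make_params("RT2", 30, 40, "med", zero_g), zero_g)
        assert np.allclose(result.f_l4l5, 0.0)
        assert np.allclose(result.f_l5s1, 0.0)
        assert result.f_mf == result.f_es == result.f_ra == 0.0

    def test_longissimus_alias(self, constants):
        result = simulate_configuration(
            make_params("RT1", 30, 40, "front", constants), constants)
        assert result.f_ls == result.f_es
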