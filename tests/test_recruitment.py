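import itertools

import numpy as np
import pytest

from kneesim.errors import AlignmentError, DomainError, GeometryError, InfeasibleError
from kneesim.recruitment import (
    MuscleUnit,
    RecruitmentProblem,
    intersegmental_load,
    max_isometric_force,
    moment_arm_matrix,
    resample_to,
    solve_recruitment,
)


def single_eq_problem(c, r, N, V=None):
    c = np.asarray(c, float)
    n = len(c)
    return RecruitmentProblem(
        C=c[None, :],
        r=np.array([float(r)]),
        is_muscle=np.ones(n, bool),
        N=np.asarray(N, float),
        V=np.ones(n) if V is None else np.asarray(V, float),
    )


def grid_search_objective(problem, resolution=400):
    """Brute-force oracle: dense grid over the feasible polytope (<=3 muscles,
    1-2 equations) returning the best feasible objective."""
    n = problem.C.shape[1]
    # Upper bound per muscle from the constraint scale.
    bound = 3.0 * max(1.0, np.abs(problem.r).max()) / max(
        np.abs(problem.C).min() if np.abs(problem.C).min() > 0 else 1.0, 1e-3
    )
    axes = [np.linspace(0.0, bound, resolution)] * (n - 1)
    best = np.inf
    tol = np.abs(problem.C).max() * bound / resolution * 2.0
    for combo in itertools.product(*axes):
        f = np.array(combo + (0.0,))
        # Solve the last muscle from the first equation when possible.
        c_last = problem.C[0, -1]
        rem = problem.r[0] - problem.C[0, :-1] @ f[:-1]
        if abs(c_last) < 1e-12:
            continue
        f[-1] = rem / c_last
        if f[-1] < 0:
            continue
        if problem.C.shape[0] > 1:
            if np.abs(problem.C[1:] @ f - problem.r[1:]).max() > tol:
                continue
        best = min(best, problem.objective(f))
    return best


class TestMaxIsometricForce:
    def test_formula(self):
        assert max_isometric_force(100.0, 10.0, 27.0) == pytest.approx(270.0)

    def test_default_mu(self):
        assert max_isometric_force(100.0, 10.0) == pytest.approx(270.0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            max_isometric_force(0.0, 10.0)

    def test_muscle_unit_f0(self):
        m = MuscleUnit("m", vol0=100.0, lf0=10.0, path=[("femur", (0, 0, 0)),
                                                        ("tibia", (0, 0, -10))])
        assert m.f0 == pytest.approx(270.0)
        assert m.n_i == pytest.approx(270.0)


class TestSolveRecruitment:
    def test_symmetric_split(self):
        p = single_eq_problem([1.0, 1.0], 100.0, [500.0, 500.0])
        sol = solve_recruitment(p)
        np.testing.assert_allclose(sol.x, [50.0, 50.0], atol=1e-9)
        assert sol.kkt_residual < 1e-6

    def test_strength_ratio_closed_form(self):
        """N1 = 2 N2: KKT gives f1 = 2 sqrt(2) f2, so f1 ~ 73.88 N."""
        p = single_eq_problem([1.0, 1.0], 100.0, [1000.0, 500.0])
        sol = solve_recruitment(p)
        f1 = 200.0 * np.sqrt(2.0) / (1.0 + 2.0 * np.sqrt(2.0))
        np.testing.assert_allclose(sol.x, [f1, 100.0 - f1], atol=1e-6)

    def test_zero_demand(self):
        p = single_eq_problem([1.0, -1.0], 0.0, [500.0, 500.0])
        sol = solve_recruitment(p)
        np.testing.assert_allclose(sol.x, 0.0, atol=1e-12)

    def test_infeasible_opposing_arms(self):
        p = single_eq_problem([-1.0, -2.0], 100.0, [500.0, 500.0])
        with pytest.raises(InfeasibleError):
            solve_recruitment(p)

    def test_general_solver_matches_analytic(self):
        """Dual route: SLSQP path vs the single-equation closed form."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = rng.integers(2, 6)
            c = rng.uniform(0.5, 3.0, n) * rng.choice([-1.0, 1.0], n)
            N = rng.uniform(200.0, 2000.0, n)
            V = rng.uniform(0.5, 2.0, n)
            r = rng.uniform(-200.0, 200.0)
            p = single_eq_problem(c, r, N, V)
            if not np.any(np.sign(c) == np.sign(r)) and r != 0:
                continue
            a = solve_recruitment(p, method="analytic")
            s = solve_recruitment(p, method="slsqp")
            assert s.objective == pytest.approx(a.objective, rel=1e-5, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_grid_search_oracle_three_muscles(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.5, 2.0, 3)
        N = rng.uniform(300.0, 1500.0, 3)
        V = rng.uniform(0.5, 2.0, 3)
        r = rng.uniform(50.0, 300.0)
        p = single_eq_problem(c, r, N, V)
        sol = solve_recruitment(p)
        best_grid = grid_search_objective(p, resolution=200)
        assert sol.objective <= best_grid + 1e-9
        # the grid comes close to the optimum at its own resolution
        assert best_grid == pytest.approx(sol.objective, rel=0.05)

    def test_v_scaling_leaves_argmin(self):
        p1 = single_eq_problem([1.0, 1.5], 120.0, [400.0, 800.0], [1.0, 2.0])
        p2 = single_eq_problem([1.0, 1.5], 120.0, [400.0, 800.0], [5.0, 10.0])
        s1, s2 = solve_recruitment(p1), solve_recruitment(p2)
        np.testing.assert_allclose(s1.x, s2.x, atol=1e-8)
        assert s2.objective == pytest.approx(5.0 * s1.objective, rel=1e-9)

    def test_strength_monotonicity(self):
        shares = []
        for n1 in (300.0, 500.0, 900.0, 1500.0):
            sol = solve_recruitment(
                single_eq_problem([1.0, 1.0], 100.0, [n1, 500.0])
            )
            shares.append(sol.x[0])
        assert all(a <= b + 1e-9 for a, b in zip(shares, shares[1:]))

    def test_reactions_excluded_from_objective(self):
        C = np.array([[1.0, 1.0, 0.0], [0.3, -0.2, 1.0]])
        p = RecruitmentProblem(
            C=C,
            r=np.array([100.0, 20.0]),
            is_muscle=np.array([True, True, False]),
            N=np.array([500.0, 500.0, 1.0]),
            V=np.array([1.0, 1.0, 1.0]),
        )
        sol = solve_recruitment(p)
        assert sol.constraint_residual < 1e-6
        x = sol.x.copy()
        g0 = p.objective(x)
        x[2] += 123.0  # perturb the reaction only
        assert p.objective(x) == g0
        # muscles still split evenly (reaction absorbs equation 2)
        np.testing.assert_allclose(sol.x[:2], [50.0, 50.0], atol=1e-5)

    def test_kkt_residual_reported(self):
        p = single_eq_problem([1.0, 2.0], 150.0, [500.0, 700.0])
        sol = solve_recruitment(p)
        assert sol.kkt_residual < 1e-6
        assert np.all(sol.x >= -1e-9)

    def test_zero_muscle_column_raises(self):
        from kneesim.errors import RankError

        with pytest.raises(RankError):
            RecruitmentProblem(
                C=np.array([[1.0, 0.0]]),
                r=np.array([10.0]),
                is_muscle=np.array([True, True]),
                N=np.array([500.0, 500.0]),
                V=np.ones(2),
            )


class TestMomentArms:
    def test_line_through_center_zero(self):
        C = moment_arm_matrix(
            [np.array([[0.0, 0.0, 50.0], [0.0, 0.0, -50.0]])],
            joint_center=(0, 0, 0),
            axes=np.eye(3),
        )
        assert np.abs(C).max() < 1e-12

    def test_perpendicular_distance_40(self):
        path = np.array([[0.0, 40.0, 50.0], [0.0, 40.0, -50.0]])
        C = moment_arm_matrix([path], joint_center=(0, 0, 0), axes=[[1, 0, 0]])
        assert abs(abs(C[0, 0]) - 40.0) < 1e-9

    def test_zero_length_segment_raises(self):
        with pytest.raises(GeometryError):
            moment_arm_matrix(
                [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])],
                joint_center=(0, 0, 0),
                axes=[[1, 0, 0]],
            )

    def test_tendon_excursion_matches_geometric(self, model):
        """dL/dtheta equals the geometric arm for straight femur-tibia
        muscles (hamstrings, gastrocnemii) within 1e-3 mm."""
        from kneesim.kinematics import KneeDofState

        state = KneeDofState(tf_flexion=20.0)
        model._zeta_guess = 0.0
        tp, pp, zeta = model.poses(state)
        arms = model.flexion_moment_arms(state, zeta)
        flex_axis = -np.array([1.0, 0.0, 0.0])
        for i, m in enumerate(model.muscles):
            if m.path[-1][0] != "tibia":
                continue
            origin = m.path[0][1]
            insertion = tp.apply(m.path[-1][1])
            u = (origin - insertion) / np.linalg.norm(origin - insertion)
            geometric = flex_axis @ np.cross(insertion - model.joint.center, u)
            assert arms[i] == pytest.approx(geometric, abs=1e-3)


class TestIntersegmentalLoad:
    def test_static_stance(self):
        bw = 73.4 * 9.81
        n = 5
        t = np.linspace(0, 1, n)
        force, moment = intersegmental_load(
            t,
            knee_center=np.zeros((n, 3)),
            segment_com=np.tile([0.0, 0.0, -250.0], (n, 1)),
            segment_mass=4.4,
            grf_force=np.tile([0.0, 0.0, 0.5 * bw], (n, 1)),
            grf_cop=np.tile([0.0, 0.0, -430.0], (n, 1)),
        )
        expected = 0.5 * bw - 4.4 * 9.81
        assert abs(force[0, 2]) == pytest.approx(expected, rel=1e-9)

    def test_zero_grf_zero_gravity(self):
        n = 4
        t = np.linspace(0, 1, n)
        force, moment = intersegmental_load(
            t,
            np.zeros((n, 3)),
            np.zeros((n, 3)),
            4.4,
            np.zeros((n, 3)),
            np.zeros((n, 3)),
            gravity=0.0,
        )
        assert np.abs(force).max() == 0.0
        assert np.abs(moment).max() == 0.0

    def test_anterior_cop_moment(self):
        n = 3
        t = np.linspace(0, 1, n)
        _, moment = intersegmental_load(
            t,
            np.zeros((n, 3)),
            np.zeros((n, 3)),
            0.0,
            np.tile([0.0, 0.0, 100.0], (n, 1)),
            np.tile([0.0, 50.0, 0.0], (n, 1)),
            gravity=0.0,
        )
        assert abs(moment[0, 0]) == pytest.approx(5000.0)  # 5 N*m in N*mm

    def test_alignment_error(self):
        with pytest.raises(AlignmentError):
            intersegmental_load(
                np.linspace(0, 1, 5),
                np.zeros((5, 3)),
                np.zeros((5, 3)),
                4.0,
                np.zeros((7, 3)),
                np.zeros((5, 3)),
            )

    def test_dynamic_mode_inertial_force(self):
        """Constant upward COM acceleration adds m*a to the knee force."""
        n = 21
        t = np.linspace(0.0, 1.0, n)
        a = 2000.0  # mm/s^2
        com = np.zeros((n, 3))
        com[:, 2] = 0.5 * a * t**2
        force, _ = intersegmental_load(
            t,
            np.zeros((n, 3)),
            com,
            4.0,
            np.zeros((n, 3)),
            np.zeros((n, 3)),
            quasi_static=False,
            gravity=0.0,
        )
        assert force[n // 2, 2] == pytest.approx(4.0 * a / 1000.0, rel=1e-6)

    def test_resample_linear(self):
        t_src = np.linspace(0, 1, 11)
        vals = np.column_stack([t_src * 2, -t_src])
        t_dst = np.linspace(0, 1, 101)
        out = resample_to(t_src, vals, t_dst)
        np.testing.assert_allclose(out[:, 0], t_dst * 2, atol=1e-12)
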