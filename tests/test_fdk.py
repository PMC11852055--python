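import numpy as np
import pytest

from kneesim import fdk
from kneesim.contact import ContactPair, Material, contact_forces
from kneesim.fdk import Trial, run_trial, solve_fdk_frame
from kneesim.kinematics import Pose, SECONDARY_IS_ROTATION
from kneesim.ligaments import bundle_force
from kneesim.model import FrameInputs
from tests.conftest import make_plate, make_sphere_surface


class TestToySystems:
    def test_spring_at_natural_length(self):
        res = lambda a: np.array([-100.0 * a[0]])  # noqa: E731
        assert res(np.zeros(1))[0] == 0.0
        state = solve_fdk_frame(res, np.zeros(1), is_rotation=np.array([False]))
        assert state.converged
        assert abs(state.alpha[0]) < 1e-6

    def test_spring_displaced_residual(self):
        res = lambda a: np.array([-100.0 * a[0]])  # noqa: E731
        assert res(np.array([0.2]))[0] == pytest.approx(-20.0)

    def test_spring_with_load_equilibrium(self):
        """k = 100 N/mm, external 50 N -> equilibrium at 0.5 mm."""
        res = lambda a: np.array([50.0 - 100.0 * a[0]])  # noqa: E731
        state = solve_fdk_frame(res, np.zeros(1), is_rotation=np.array([False]))
        assert state.converged
        assert state.alpha[0] == pytest.approx(0.5, abs=0.01)
        assert abs(state.residual[0]) < 1.0

    def test_start_at_equilibrium(self):
        res = lambda a: np.array([50.0 - 100.0 * a[0]])  # noqa: E731
        state = solve_fdk_frame(res, np.array([0.5]), is_rotation=np.array([False]))
        assert state.converged
        assert state.iterations == 0
        assert state.alpha[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_dof_coupled(self):
        K = np.array([[120.0, 30.0], [30.0, 80.0]])
        load = np.array([40.0, -25.0])
        res = lambda a: load - K @ a  # noqa: E731
        state = solve_fdk_frame(res, np.zeros(2), is_rotation=np.zeros(2, bool))
        assert state.converged
        np.testing.assert_allclose(state.alpha, np.linalg.solve(K, load), atol=0.02)

    def test_iteration_cap_reports_best(self):
        res = lambda a: np.array([1000.0])  # unsolvable constant residual
        state = solve_fdk_frame(
            res, np.zeros(1), is_rotation=np.array([False]), max_iter=5
        )
        assert not state.converged
        assert state.residual[0] == pytest.approx(1000.0)


class TestSphereOnPlane:
    def test_elastic_foundation_load_penetration(self):
        """FDK equilibrium penetration matches F = PM pi R delta^2 within 2%."""
        R = 20.0
        load = 500.0
        m = Material(E=5.0, v=0.46, h=2.2)
        plane = make_plate(18.0, 41, z=0.0, normal_up=True)
        sphere = make_sphere_surface(R, center=(0, 0, R), n_theta=48, n_phi=96)
        pair = ContactPair("sp", plane, m, sphere, m)

        def residual(a):
            # 1 DOF: plane raised by a[0] against the fixed sphere
            res = contact_forces(pair, Pose(np.eye(3), [0.0, 0.0, a[0]]))
            return np.array([load + res.resultant_on_slave()[2]])

        state = solve_fdk_frame(residual, np.zeros(1), is_rotation=np.array([False]))
        assert state.converged
        delta = state.alpha[0]
        analytic_delta = np.sqrt(load / (pair.pm * np.pi * R))
        assert delta == pytest.approx(analytic_delta, rel=0.02)


class TestEnergyGradientOracle:
    def test_contact_energy_gradient_plate(self):
        """Normal-incidence contact: residual = -d(1/2 PM A d^2)/dx exactly."""
        m = Material(E=5.0, v=0.46, h=2.2)
        slave = make_plate(10.0, 11, z=0.0, normal_up=True)
        master = make_plate(12.0, 11, z=-0.05, normal_up=False)
        pair = ContactPair("pp", slave, m, master, m)

        def force(x):
            res = contact_forces(pair, Pose(np.eye(3), [0.0, 0.0, x]))
            return res.resultant_on_slave()[2]

        def energy(x):
            res = contact_forces(pair, Pose(np.eye(3), [0.0, 0.0, x]))
            return 0.5 * pair.pm * np.sum(res.areas * res.depths**2)

        h = 1e-6
        for x in (-0.1, -0.2, -0.3):
            grad = (energy(x + h) - energy(x - h)) / (2 * h)
            assert force(x) == pytest.approx(-grad, rel=1e-4)

    def test_elastic_residual_matches_energy_gradient(self, model):
        """Ligament-elastic configuration (muscles off, no external load, no
        contact engaged): the generalized residual equals -dE/dalpha by
        central finite differences within 1e-4 relative, including the
        patellar tendon constraint elimination."""
        fi = FrameInputs(time=0.0, flexion_deg=10.0)
        # Tibia distracted and patella lifted radially: all pairs separated.
        alpha = np.array([0.3, -0.4, 0.2, -0.3, -1.0, 0.5, -0.3, 0.2, 0.15, 2.0])
        ff0 = model.evaluate(alpha, fi, with_muscles=False)
        assert all(r.n_contacting == 0 for r in ff0.contact_results)

        def energy(a):
            ff = model.evaluate(np.asarray(a, float), fi, with_muscles=False)
            e = 0.0
            # ligament strain energy (piecewise closed form)
            for j, b in enumerate(model.ligaments):
                L0 = model._lig_L0[j]
                # recover strain from the stored force via the pose
                o = ff.tibia_pose if b.origin_body == "tibia" else (
                    ff.patella_pose if b.origin_body == "patella" else None
                )
                i = ff.tibia_pose if b.insertion_body == "tibia" else (
                    ff.patella_pose if b.insertion_body == "patella" else None
                )
                ow = b.origin_point if o is None else o.apply(b.origin_point)
                iw = b.insertion_point if i is None else i.apply(b.insertion_point)
                eps = (np.linalg.norm(ow - iw) - L0) / L0
                el = b.eps_l
                if eps <= 0:
                    continue
                if eps <= 2 * el:
                    e += b.k * L0 * eps**3 / (12.0 * el)
                else:
                    e_toe = b.k * L0 * (2 * el) ** 3 / (12.0 * el)
                    e += e_toe + b.k * L0 * (
                        (eps - el) ** 2 / 2.0 - el**2 / 2.0
                    )
            # contact energy: PM A d^2 / 2 per vertex
            for res, pair in zip(ff.contact_results, model.pairs):
                e += 0.5 * pair.pm * np.sum(res.areas * res.depths**2)
            return e

        res = model.evaluate(alpha, fi, with_muscles=False).residual
        h = 1e-4
        for j in range(10):
            ap, am = alpha.copy(), alpha.copy()
            ap[j] += h
            am[j] -= h
            grad = (energy(ap) - energy(am)) / (2 * h)
            expected = -grad
            if SECONDARY_IS_ROTATION[j]:
                expected /= np.deg2rad(1.0)  # coordinates are in degrees
            assert res[j] == pytest.approx(expected, rel=1e-4), f"component {j}"


class TestKneeFrames:
    def test_unloaded_reference_converges(self, model):
        fi = FrameInputs(time=0.0, flexion_deg=4.0)
        state = solve_fdk_frame(model, np.zeros(10), frame_inputs=fi)
        assert state.converged
        scaled = np.abs(state.residual) / np.where(SECONDARY_IS_ROTATION, 10.0, 1.0)
        assert scaled.max() <= 1.0

    def test_warm_start_path_independence(self, model):
        fi = FrameInputs(
            time=0.0,
            flexion_deg=15.0,
            external_force=(0.0, 0.0, 720.0),
            external_moment=(30000.0, -19000.0, 0.0),
        )
        bw = model.body_weight_n

        def tfcf_from(start):
            st = solve_fdk_frame(model, start, frame_inputs=fi)
            assert st.converged
            vec = model.evaluate(st.alpha, fi).tfcf_vectors()["total"]
            return np.linalg.norm(vec) / bw

        a = tfcf_from(np.zeros(10))
        b = tfcf_from(np.array([0.2, -0.3, 0.1, -0.2, 0.3, 0.4, -0.2, 0.1, 0.1, -0.1]))
        assert abs(a - b) / a < 0.005

    def test_monotone_axial_load_response(self, model):
        """TFCF_Total is non-decreasing under a ramp of axial knee load."""
        alpha = np.zeros(10)
        values = []
        for load_bw in (0.0, 0.5, 1.0, 1.5, 2.0):
            fi = FrameInputs(
                time=0.0,
                flexion_deg=15.0,
                external_force=(0.0, 0.0, load_bw * model.body_weight_n),
            )
            st = solve_fdk_frame(model, alpha, frame_inputs=fi)
            assert st.converged
            alpha = st.alpha
            vec = model.evaluate(alpha, fi).tfcf_vectors()["total"]
            values.append(np.linalg.norm(vec))
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))

    def test_tendon_constraint_maintained(self, model):
        from kneesim.kinematics import KneeDofState, patellar_tendon_residual

        fi = FrameInputs(time=0.0, flexion_deg=25.0, external_force=(0, 0, 500.0))
        st = solve_fdk_frame(model, np.zeros(10), frame_inputs=fi)
        assert st.converged
        ff = model.evaluate(st.alpha, fi)
        assert abs(
            patellar_tendon_residual(ff.tibia_pose, ff.patella_pose, model.joint)
        ) < 1e-3


@pytest.fixture(scope="module")
def short_trial_result(model):
    times = np.linspace(0.0, 0.05, 6)
    flexion = np.linspace(5.0, 12.0, 6)
    force = np.tile([0.0, 0.0, 500.0], (6, 1))
    moment = np.tile([15000.0, -10000.0, 0.0], (6, 1))
    trial = Trial("walk", times, flexion, force, moment)
    return run_trial(model, trial), trial


class TestRunTrial:

    def test_converged_and_curves(self, short_trial_result):
        result, _ = short_trial_result
        assert result.all_converged
        assert len(result.curves["total"].values) == 101
        assert result.max_converged_residual() <= 1.0

    def test_compartment_vector_identity(self, short_trial_result):
        result, _ = short_trial_result
        for f in result.frames:
            v = f.tfcf_vectors_n
            np.testing.assert_allclose(
                v["medial"] + v["lateral"], v["total"], atol=1e-9
            )

    def test_determinism(self, model, short_trial_result):
        result, trial = short_trial_result
        again = run_trial(model, trial)
        for key in ("total", "medial", "lateral"):
            assert np.array_equal(
                result.curves[key].values, again.curves[key].values
            )

    def test_write_outputs(self, short_trial_result, tmp_path):
        result, _ = short_trial_result
        fdk.write_curves(result, tmp_path / "curves.csv")
        fdk.write_frames(result, tmp_path / "frames.csv")
        fdk.write_contact_summary(result, tmp_path / "contacts.csv")
        lines = (tmp_path / "curves.csv").read_text().strip().splitlines()
        assert len(lines) == 102
        assert lines[0].startswith("activity,percent_cycle")
        contacts = (tmp_path / "contacts.csv").read_text().strip().splitlines()
        assert contacts[0].startswith("frame,pair,compartment")
        assert len(contacts) == 1 + 5 * len(result.frames)
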