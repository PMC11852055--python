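import numpy as np
import pytest

from kneesim import fixtures, metrics
from kneesim.contact import vertex_penetrations
from kneesim.errors import DomainError
from kneesim.fixtures import (
    ActivityParams,
    KneeFixtureParams,
    flexion_from_markers,
    flexion_waveform,
    grf_waveform,
    make_activity_trial,
    make_knee_geometry,
    make_pseudo_reference,
)
from kneesim.mesh import write_stl
from kneesim.metrics import Curve, N_CYCLE_POINTS


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit (independent oracle)."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = np.sqrt(sol[3] + center @ center)
    return center, radius


class TestKneeGeometry:
    def test_schema(self, geometry):
        assert set(geometry.surfaces) == {
            "femoral_cartilage",
            "medial_tibial_cartilage",
            "lateral_tibial_cartilage",
            "medial_meniscus",
            "lateral_meniscus",
            "patellar_cartilage",
        }
        assert set(geometry.bones) == {"femur", "tibia", "patella"}
        assert len(geometry.ligament_bundles) == 22
        assert all(
            b.origin_point is not None and b.insertion_point is not None
            for b in geometry.ligament_bundles
        )

    def test_bones_watertight(self, geometry):
        for mesh in geometry.bones.values():
            assert mesh.is_closed()

    def test_deterministic_stl_bytes(self, geometry, tmp_path):
        for i in (1, 2):
            write_stl(
                geometry.surfaces["femoral_cartilage"], tmp_path / f"f{i}.stl"
            )
        assert (tmp_path / "f1.stl").read_bytes() == (tmp_path / "f2.stl").read_bytes()

        regen = make_knee_geometry(KneeFixtureParams())
        write_stl(regen.surfaces["femoral_cartilage"], tmp_path / "f3.stl")
        assert (tmp_path / "f1.stl").read_bytes() == (tmp_path / "f3.stl").read_bytes()

    def test_condyle_sphere_fit(self):
        params = KneeFixtureParams(medial_condyle_radius=22.0)
        geom = make_knee_geometry(params)
        fc = geom.surfaces["femoral_cartilage"]
        medial_faces = fc.faces[fc.compartment == "medial"]
        pts = fc.vertices[np.unique(medial_faces)]
        center, radius = fit_sphere(pts)
        assert radius == pytest.approx(22.0, abs=0.1)
        assert center[0] == pytest.approx(params.condyle_offset, abs=0.1)

    def test_no_initial_penetration(self, geometry, model):
        from kneesim.kinematics import Pose

        for pair, engine in zip(model.pairs, model.engines):
            depths, _ = vertex_penetrations(pair, engine=engine)
            assert np.all(depths == 0.0), pair.name

    def test_reference_clearance(self, geometry):
        p = geometry.params
        dish = geometry.surfaces["medial_tibial_cartilage"]
        d = np.linalg.norm(
            dish.vertices - np.array([p.condyle_offset, 0.0, 0.0]), axis=1
        )
        assert (d - p.medial_condyle_radius).min() >= 0.05

    def test_invalid_params(self):
        with pytest.raises(DomainError):
            KneeFixtureParams(medial_condyle_radius=-1.0)
        with pytest.raises(DomainError):
            KneeFixtureParams(medial_dish_radius=10.0)


class TestWaveforms:
    def test_walking_flexion_shape(self):
        p = np.linspace(0, 100, 201)
        f = flexion_waveform("walk", p)
        swing = f[(p > 55) & (p < 90)]
        assert 50.0 < swing.max() < 70.0  # swing flexion wave
        stance = f[(p > 5) & (p < 30)]
        assert 10.0 < stance.max() < 25.0  # stance flexion wave

    def test_stair_flexion_peaks(self):
        p = np.linspace(0, 100, 201)
        assert 85.0 < flexion_waveform("stair_ascent", p).max() < 105.0
        assert 85.0 < flexion_waveform("stair_descent", p).max() < 105.0

    def test_transfer_monotone_sweep(self):
        p = np.linspace(0, 100, 201)
        sts = flexion_waveform("sit_to_stand", p)
        assert sts[0] > 80.0 and sts[-1] < 10.0
        assert np.all(np.diff(sts) <= 1e-9)
        stsit = flexion_waveform("stand_to_sit", p)
        assert stsit[0] < 10.0 and stsit[-1] > 80.0
        assert np.all(np.diff(stsit) >= -1e-9)

    def test_gait_periodic_consistency(self):
        p = np.array([0.0, 100.0])
        for act in ("walk", "stair_ascent", "stair_descent"):
            f = flexion_waveform(act, p)
            assert f[0] == pytest.approx(f[1], abs=1e-6)

    def test_grf_nonnegative_vertical(self):
        p = np.linspace(0, 100, 500)
        for act in metrics.ACTIVITIES:
            grf = grf_waveform(act, p, bw=720.0)
            assert grf[:, 2].min() >= -1e-9

    def test_walking_impulse_balance(self):
        """Two-feet vertical impulse over the cycle equals BW x duration
        within 2% (built into the generator)."""
        bw = 720.0
        p = np.linspace(0, 100, 2000)
        fz = grf_waveform("walk", p, bw)[:, 2]
        other = np.interp((p + 50.0) % 100.0, p, fz)
        assert np.mean(fz + other) == pytest.approx(bw, rel=0.02)

    def test_unknown_activity(self):
        with pytest.raises(ValueError):
            flexion_waveform("hopping", np.array([0.0]))
        with pytest.raises(ValueError):
            grf_waveform("hopping", np.array([0.0]), 700.0)


class TestActivityTrials:
    def test_noiseless_marker_closed_loop(self, geometry):
        """With sigma = 0 the MT stage recovers the ground-truth flexion
        profile within 1e-6 degrees."""
        fx = make_activity_trial(
            "walk", geometry, ActivityParams(noise_sigma_mm=0.0), seed=1
        )
        recovered = flexion_from_markers(
            geometry, fx.marker_names, fx.marker_positions
        )
        assert np.abs(recovered - fx.flexion_truth_deg).max() < 1e-6

    def test_noisy_marker_recovery_reasonable(self, geometry):
        fx = make_activity_trial(
            "walk", geometry, ActivityParams(noise_sigma_mm=1.0), seed=2
        )
        recovered = flexion_from_markers(
            geometry, fx.marker_names, fx.marker_positions
        )
        assert np.abs(recovered - fx.flexion_truth_deg).max() < 3.0

    def test_same_seed_identical_files(self, geometry, tmp_path):
        for sub in ("a", "b"):
            fx = make_activity_trial("walk", geometry, seed=7)
            fx.write(tmp_path / sub)
        for name in ("walk_markers.txt", "walk_grf.txt", "walk_flexion.txt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seed_differs(self, geometry):
        a = make_activity_trial("walk", geometry, seed=1)
        b = make_activity_trial("walk", geometry, seed=2)
        assert not np.array_equal(a.marker_positions, b.marker_positions)

    def test_drive_signals_shape(self, geometry):
        fx = make_activity_trial("walk", geometry, seed=0)
        n = len(fx.marker_times)
        assert n == 101  # 1.0 s at 100 Hz inclusive
        assert fx.trial.external_force.shape == (n, 3)
        assert len(fx.grf_times) == 1001

    def test_moment_targets_realized(self, geometry):
        """COP inverse design reproduces the knee moment targets during
        foot contact (quasi-static, mass terms are the only deviation)."""
        from kneesim.fixtures import knee_moment_targets

        fx = make_activity_trial(
            "sit_to_stand",
            geometry,
            ActivityParams(noise_sigma_mm=0.0, shank_foot_mass_fraction=1e-9),
            seed=0,
        )
        p = 100.0 * fx.marker_times / fx.marker_times[-1]
        bw = fx.params.subject_mass_kg * 9.81
        targets = knee_moment_targets("sit_to_stand", p, bw)
        applied = fx.trial.external_moment
        sel = np.abs(targets[:, 0]) > 0.05 * np.abs(targets[:, 0]).max()
        assert np.allclose(applied[sel, 0], targets[sel, 0], rtol=0.02, atol=50.0)

    def test_unknown_label(self, geometry):
        with pytest.raises(ValueError):
            make_activity_trial("jumping", geometry)


class TestPseudoReference:
    @pytest.fixture
    def curve(self):
        pct = np.linspace(0, 100, N_CYCLE_POINTS)
        return Curve(
            1.5 + np.sin(2 * np.pi * pct / 100.0) ** 2, "walk"
        )

    def test_no_distortion_identity(self, curve):
        ref = make_pseudo_reference(curve)
        M, P, CE = metrics.sprague_geers(ref, curve)
        assert (M, P, CE) == (0.0, 0.0, 0.0)
        assert metrics.r_squared(ref, curve) == 1.0

    def test_amplitude_distortion_recovered(self, curve):
        ref = make_pseudo_reference(curve, amplitude=0.1)
        M, P, _ = metrics.sprague_geers(ref, curve)
        assert M == pytest.approx(0.1, abs=1e-9)
        assert P == pytest.approx(0.0, abs=1e-6)

    def test_noise_rmse_scale(self, curve):
        sigma = 0.2
        ref = make_pseudo_reference(curve, noise_sigma=sigma, seed=3)
        r = metrics.rmse(ref, curve)
        assert 0.5 * sigma < r < 1.5 * sigma

    def test_seeded_determinism(self, curve):
        a = make_pseudo_reference(curve, noise_sigma=0.1, seed=9)
        b = make_pseudo_reference(curve, noise_sigma=0.1, seed=9)
        assert np.array_equal(a.values, b.values)
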