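"""Rigid fits, ICP, displacement fields and the marker-noise Monte Carlo."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from implantkinetics import (
    DegeneracyError,
    MarkerSet,
    PatientSeries,
    Point3,
    RigidTransform,
    best_fit_rigid,
    catheter_displacements,
    generate_patient,
    icp_register,
    marker_based_displacements,
    marker_noise_uncertainty,
    paired_dwells,
)
from implantkinetics.implant_model import DwellPosition, ImplantSnapshot
from tests.conftest import make_config, noiseless_overrides


def random_rigid(rng, trans_scale=10.0) -> RigidTransform:
    return RigidTransform(
        Rotation.random(rng=rng).as_matrix(), rng.normal(0, trans_scale, 3)
    )


def transform_gap(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """(translation distance mm, rotation angle deg) between two transforms."""
    rel = a.compose(b.inverse())
    return float(np.linalg.norm(a.translation - b.translation)), rel.rotation_angle_deg()


class TestRigidTransform:
    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(0)
        T = random_rigid(rng)
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0, atol=1e-12)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestBestFitRigid:
    def test_identity_on_equal_clouds(self):
        P = np.random.default_rng(1).normal(0, 10, (20, 3))
        T = best_fit_rigid(P, P)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-10)

    def test_pure_translation(self):
        P = np.random.default_rng(2).normal(0, 10, (15, 3))
        T = best_fit_rigid(P, P + [1.0, 2.0, 3.0])
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, [1, 2, 3], atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_transforms_exactly(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 15, (30, 3))
        T_true = random_rigid(rng)
        T_fit = best_fit_rigid(P, T_true.apply(P))
        assert np.abs(T_fit.rotation - T_true.rotation).max() < 1e-9
        assert np.abs(T_fit.translation - T_true.translation).max() < 1e-9
        assert np.allclose(T_fit.apply(P), T_true.apply(P), atol=1e-9)

    def test_matches_svd_oracle_on_noisy_correspondences(self):
        # independent oracle: Kabsch via scipy align_vectors on centred clouds
        rng = np.random.default_rng(5)
        P = rng.normal(0, 15, (40, 3))
        Q = random_rigid(rng).apply(P) + rng.normal(0, 1.0, P.shape)
        T = best_fit_rigid(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        R_oracle = rot.as_matrix()
        t_oracle = Q.mean(0) - R_oracle @ P.mean(0)
        assert np.allclose(T.rotation, R_oracle, atol=1e-8)
        assert np.allclose(T.translation, t_oracle, atol=1e-8)

    def test_residuals_never_beat_identity(self):
        rng = np.random.default_rng(6)
        P = rng.normal(0, 15, (25, 3))
        Q = P + rng.normal(0, 2, P.shape)
        T = best_fit_rigid(P, Q)
        sse_fit = np.sum((Q - T.apply(P)) ** 2)
        assert sse_fit <= np.sum((Q - P) ** 2) + 1e-9

    def test_collinear_input_raises(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(DegeneracyError, match="collinear"):
            best_fit_rigid(line, line)

    def test_too_few_points_raise(self):
        P = np.random.default_rng(0).normal(0, 1, (2, 3))
        with pytest.raises(DegeneracyError):
            best_fit_rigid(P, P)


def _implant_cloud(seed=13):
    series, _ = generate_patient(make_config(**noiseless_overrides()), seed)
    return series.snapshot("CT1").in_target_points()


class TestICP:
    def test_identical_clouds_converge_immediately(self):
        Q = _implant_cloud()
        res = icp_register(Q, Q)
        assert res.converged and res.rms_residual < 1e-9
        assert res.n_iterations <= 2
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_small_rigid_perturbation(self):
        Q = _implant_cloud()
        rng = np.random.default_rng(3)
        T_true = RigidTransform(
            Rotation.from_rotvec(np.deg2rad(2.0) * np.array([0, 0, 1.0])).as_matrix(),
            np.array([1.2, -1.0, 0.8]),
        )
        res = icp_register(T_true.inverse().apply(Q), Q)
        assert res.converged and res.rms_residual < 1e-6
        dt, dr = transform_gap(res.transform, T_true)
        assert dt < 1e-6 and dr < 1e-6

    def test_rms_history_monotone_under_noise(self):
        Q = _implant_cloud()
        rng = np.random.default_rng(4)
        P = Q + rng.normal(0, 1.0, Q.shape)
        res = icp_register(P, Q)
        hist = np.array(res.rms_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_known_correspondence_mode_is_the_closed_form_fit(self):
        Q = _implant_cloud()
        rng = np.random.default_rng(5)
        P = Q + rng.normal(0, 1.0, Q.shape)
        res = icp_register(P, Q, matching="known")
        T = best_fit_rigid(P, Q)
        assert np.allclose(res.transform.rotation, T.rotation)
        assert np.allclose(res.transform.translation, T.translation)

    def test_nonconvergence_flagged_not_raised(self):
        Q = _implant_cloud()
        P = Q + np.random.default_rng(6).normal(0, 1.0, Q.shape)
        res = icp_register(P, Q, max_iter=1)
        assert not res.converged and res.n_iterations == 1


def _manual_series(points_a, points_b, markers_a, markers_b):
    def snap(scan, pts, mk):
        dwells = tuple(
            DwellPosition(f"C{i % 4}", i // 4, Point3.from_array(p), True)
            for i, p in enumerate(pts)
        )
        return ImplantSnapshot(scan, dwells, mk)

    return PatientSeries("P01", (snap("CT1", points_a, markers_a),
                                 snap("CT2", points_b, markers_b)))


class TestDisplacementFields:
    def test_identical_snapshots_zero_fields(self, null_cohort):
        cohort, _ = null_cohort
        for fn in (catheter_displacements, marker_based_displacements):
            fld = fn(cohort[0], ("CT1", "CT2"))
            assert np.allclose(fld.vectors, 0, atol=1e-9)

    def test_whole_implant_translation_absorbed_by_icp_only(self):
        cfg = make_config(
            true_dv_percent_ct2=0.0, true_dv_percent_ct3=0.0, **noiseless_overrides()
        )
        series, _ = generate_patient(cfg, 17)
        shift = np.array([1.0, 2.0, -1.0])
        snap_a = series.snapshot("CT1")
        pts = snap_a.in_target_points()
        markers = snap_a.markers.as_array()
        moved = _manual_series_from(snap_a, pts + shift, markers)  # markers fixed
        cath = catheter_displacements(moved, ("CT1", "CT2"))
        mark = marker_based_displacements(moved, ("CT1", "CT2"))
        assert np.allclose(cath.vectors, 0, atol=1e-6)  # absorbed
        assert np.allclose(mark.vectors, shift, atol=1e-9)  # revealed

    def test_shared_rigid_motion_of_markers_and_dwells_is_invisible(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 15, (16, 3))
        mk = MarkerSet.from_array(np.array([[-8.0, -12, 1], [8.0, -12, 1], [0.5, 13, -2]]))
        T = RigidTransform(
            Rotation.from_rotvec([0.01, -0.02, 0.015]).as_matrix(), np.array([1.0, -2, 0.5])
        )
        s = _manual_series(pts, T.apply(pts), mk, MarkerSet.from_array(T.apply(mk.as_array())))
        fld = marker_based_displacements(s, ("CT1", "CT2"))
        assert np.allclose(fld.vectors, 0, atol=1e-9)

    def test_single_catheter_slip_shows_in_that_catheter(self):
        cfg = make_config(
            true_dv_percent_ct2=0.0, true_dv_percent_ct3=0.0,
            bow_sagitta_max_mm=0.0, **noiseless_overrides()
        )
        series, _ = generate_patient(cfg, 19)
        snap_a = series.snapshot("CT1")
        pairs = paired_dwells(snap_a, snap_a)
        pts_b = pairs.points_b.copy()
        slipped = np.array([k[0] == "C01" for k in pairs.keys])
        pts_b[slipped, 1] += 2.0  # 2 mm caudal slip, below NN confusion range
        moved = _manual_series_from(snap_a, pts_b, snap_a.markers.as_array())
        fld = catheter_displacements(moved, ("CT1", "CT2"))
        # oracle: closed-form fit with the true correspondences
        T = best_fit_rigid(pts_b, pairs.points_a)
        expected = T.apply(pts_b) - pairs.points_a
        assert np.allclose(fld.vectors, expected, atol=1e-6)
        dy = fld.vectors[:, 1]
        assert dy[slipped].mean() > 1.5  # slip minus the fitted compensation
        assert np.abs(dy[~slipped]).mean() < 0.5


def _manual_series_from(snap_a, new_points, new_markers):
    """Clone snapshot a as CT2 with replaced in-target coordinates."""
    keys = sorted(snap_a.in_target_map())
    lookup = {k: p for k, p in zip(keys, new_points)}
    dwells = tuple(
        DwellPosition(
            d.catheter_id,
            d.dwell_index,
            Point3.from_array(lookup.get((d.catheter_id, d.dwell_index),
                                         d.position.as_array())),
            d.in_target,
        )
        for d in snap_a.dwells
    )
    snap_b = ImplantSnapshot("CT2", dwells, MarkerSet.from_array(new_markers))
    return PatientSeries("P01", (snap_a, snap_b))


class TestMarkerNoiseUncertainty:
    def test_zero_noise_is_exactly_zero(self, null_cohort):
        cohort, _ = null_cohort
        res = marker_noise_uncertainty(cohort, noise_sd_mm=(0, 0, 0), n_reps=3, seed=1)
        assert np.all(res.mean_mm == 0) and np.all(res.sd_mm == 0)

    def test_doubling_noise_doubles_spread(self, small_cohort):
        cohort, _ = small_cohort
        r1 = marker_noise_uncertainty(cohort, (0.25, 0.5, 0.25), n_reps=60, seed=2)
        r2 = marker_noise_uncertainty(cohort, (0.5, 1.0, 0.5), n_reps=60, seed=2)
        ratio = r2.sd_mm / r1.sd_mm
        assert np.all(ratio > 1.6) and np.all(ratio < 2.4)

    def test_determinism_under_seed(self, small_cohort):
        cohort, _ = small_cohort
        r1 = marker_noise_uncertainty(cohort, n_reps=5, seed=9)
        r2 = marker_noise_uncertainty(cohort, n_reps=5, seed=9)
        assert np.array_equal(r1.mean_mm, r2.mean_mm)
        assert np.array_equal(r1.sd_mm, r2.sd_mm)
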