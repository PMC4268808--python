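"""MRD estimator, cube-law volume change and uncertainty propagation."""

import math

import numpy as np
import pytest

from implantkinetics import (
    apply_relative_change,
    centre_of_mass_xz,
    diameter_change,
    mean_radial_distance,
    relative_volume_change,
    series_volume_changes,
)
from tests.conftest import make_config, noiseless_overrides
from implantkinetics import generate_patient


def _random_points(seed, n=80):
    return np.random.default_rng(seed).normal(0, 15, size=(n, 3))


class TestCentreOfMass:
    def test_symmetric_pair_centres_at_origin(self):
        pts = np.array([[1, 5, 1], [-1, 9, -1]], dtype=float)
        assert centre_of_mass_xz(pts) == (0.0, 0.0)

    def test_single_point_is_its_own_centre(self):
        assert centre_of_mass_xz(np.array([[3.2, 9.9, -1.5]])) == (3.2, -1.5)

    def test_matches_independent_summation_order(self):
        pts = _random_points(4)
        cx, cz = centre_of_mass_xz(pts)
        # brute-force: python-level accumulation in reversed order
        sx = sz = 0.0
        for p in reversed(pts):
            sx += p[0]
            sz += p[2]
        assert cx == pytest.approx(sx / len(pts), rel=1e-12)
        assert cz == pytest.approx(sz / len(pts), rel=1e-12)


class TestMeanRadialDistance:
    def test_symmetric_cross_has_mrd_a(self):
        a = 7.5
        pts = np.array([[a, 1, 0], [-a, 2, 0], [0, 3, a], [0, 4, -a]])
        assert mean_radial_distance(pts).mrd == pytest.approx(a, rel=1e-14)

    def test_sigma_mrd_is_sigma_over_sqrt_n(self):
        pts = _random_points(1, n=80)
        res = mean_radial_distance(pts, point_sigma_mm=1.0)
        assert res.sigma_mrd == pytest.approx(1.0 / math.sqrt(80), rel=1e-14)
        assert round(res.sigma_mrd, 1) == 0.1

    def test_matches_per_point_loop_oracle(self):
        pts = _random_points(2, n=100)
        res = mean_radial_distance(pts)
        cx, cz = centre_of_mass_xz(pts)
        acc = 0.0
        for p in pts:
            acc += math.sqrt((p[0] - cx) ** 2 + (p[2] - cz) ** 2)
        assert res.mrd == pytest.approx(acc / 100, rel=1e-12)

    def test_coincident_cloud_warns_and_returns_zero(self):
        pts = np.tile([[1.0, 0.0, 2.0]], (5, 1))
        pts[:, 1] = np.arange(5)  # distinct y, coincident in x-z
        with pytest.warns(UserWarning, match="coincident"):
            assert mean_radial_distance(pts).mrd == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariances(self, seed):
        pts = _random_points(seed)
        base = mean_radial_distance(pts).mrd
        # translation invariance
        assert mean_radial_distance(pts + [3.0, -7.0, 11.0]).mrd == pytest.approx(
            base, rel=1e-12
        )
        # C-C insensitivity is bit-identical
        perturbed = pts.copy()
        perturbed[:, 1] += np.random.default_rng(seed + 10).normal(0, 5, len(pts))
        assert mean_radial_distance(perturbed).mrd == base
        # planar rotation about the COM
        cx, cz = centre_of_mass_xz(pts)
        th = 0.83
        rot = pts.copy()
        dx, dz = pts[:, 0] - cx, pts[:, 2] - cz
        rot[:, 0] = cx + math.cos(th) * dx - math.sin(th) * dz
        rot[:, 2] = cz + math.sin(th) * dx + math.cos(th) * dz
        assert mean_radial_distance(rot).mrd == pytest.approx(base, rel=1e-12)

    def test_scale_equivariance_and_cube_law(self):
        pts = _random_points(3)
        s = 1.07
        cx, cz = centre_of_mass_xz(pts)
        scaled = pts.copy()
        scaled[:, 0] = cx + s * (pts[:, 0] - cx)
        scaled[:, 2] = cz + s * (pts[:, 2] - cz)
        m1 = mean_radial_distance(pts).mrd
        m2 = mean_radial_distance(scaled).mrd
        assert m2 == pytest.approx(s * m1, rel=1e-12)
        dv = relative_volume_change(m1, m2).dv_percent
        assert dv == pytest.approx(100 * (s**3 - 1), rel=1e-9)


class TestVolumeChange:
    def test_equal_mrds_give_zero(self):
        assert relative_volume_change(12.0, 12.0).dv_percent == 0.0

    def test_doubling_mrd_is_plus_700_percent(self):
        assert relative_volume_change(10.0, 20.0).dv_percent == pytest.approx(700.0)

    def test_worked_example_value(self):
        dv = relative_volume_change(15.0, 15.7).dv_percent
        assert dv == pytest.approx(100 * (15.7**3 - 15**3) / 15**3, rel=1e-14)
        assert round(dv, 1) == 14.7

    def test_nonpositive_mrd_rejected(self):
        with pytest.raises(ValueError):
            relative_volume_change(0.0, 10.0)

    def test_printed_vs_delta_method_propagation(self):
        s = 0.1118
        printed = relative_volume_change(15.0, 15.0, s, s).sigma_dv_percent
        delta = relative_volume_change(
            15.0, 15.0, s, s, propagation="delta_method"
        ).sigma_dv_percent
        assert printed == pytest.approx(100 * math.sqrt(3 * 2 * (s / 15) ** 2))
        assert delta == pytest.approx(300 * math.sqrt(2) * s / 15)
        assert delta / printed == pytest.approx(math.sqrt(3), rel=1e-12)

    def test_apply_relative_change(self):
        assert apply_relative_change(10.0, -50.0) == pytest.approx(5.0)
        assert apply_relative_change(77.0, 0.0) == 77.0
        dv = relative_volume_change(15.0, 15.7).dv_percent
        assert round(apply_relative_change(42.0, dv), 1) == 48.2

    def test_diameter_change_doubles_mrd_change(self):
        assert diameter_change(15.0, 15.8) == pytest.approx(1.6)


class TestSeriesVolumeChanges:
    def test_null_patient_has_zero_change_everywhere(self, null_cohort):
        cohort, _ = null_cohort
        results = series_volume_changes(cohort[0])
        assert len(results) == 3
        assert all(r.dv_percent == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_generator_closed_loop_recovers_truth(self):
        cfg = make_config(
            true_dv_percent_ct2=10.0, true_dv_percent_ct3=10.0,
            **noiseless_overrides(),
        )
        series, _ = generate_patient(cfg, 21)
        for r in series_volume_changes(series):
            expected = 0.0 if r.interval == ("CT2", "CT3") else 10.0
            assert r.dv_percent == pytest.approx(expected, abs=1e-9)

    def test_missing_scan_skips_interval_with_notice(self, null_cohort):
        cohort, _ = null_cohort
        from implantkinetics import PatientSeries

        short = PatientSeries(
            "PX", tuple(s for s in cohort[0].snapshots if s.scan_id != "CT3")
        )
        with pytest.warns(UserWarning, match="skipped"):
            results = series_volume_changes(short)
        assert [r.interval for r in results] == [("CT1", "CT2")]
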