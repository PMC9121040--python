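"""Simulator unit and property tests: leaf shift, fluence closed forms,
measurement model, sweeping-gap DLG estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlcopt import (
    DlgEstimate,
    GeometryError,
    MeasurementModel,
    MLCModel,
    ValidationError,
    apply_leaf_shift,
    as_trajectories,
    chair,
    default_toy_patterns,
    estimate_dlg_sweeping_gap,
    measure_plane,
    open_field,
    simulate_plane,
    static_blocked,
    sweeping_gap,
)


def central_dose(plane):
    i = np.argmin(np.abs(plane.y))
    j = np.argmin(np.abs(plane.x))
    return plane.values[i, j]


class TestLeafShift:
    def test_each_leaf_moves_half_the_dlg(self):
        # a DLG of 1.25 mm moves every leaf tip by 0.625 mm
        traj = as_trajectories(sweeping_gap(5.0))
        shifted = apply_leaf_shift(traj, 1.25)
        assert np.allclose(np.abs(shifted.bank_a - traj.bank_a), 0.625)
        assert np.allclose(np.abs(shifted.bank_b - traj.bank_b), 0.625)

    def test_zero_dlg_is_identity(self):
        pat = sweeping_gap(5.0)
        out = apply_leaf_shift(pat, 0.0)
        assert out.kind == pat.kind and out.gap == pat.gap

    def test_gap_widens_by_dlg_at_every_control_point(self):
        shifted = apply_leaf_shift(sweeping_gap(5.0), 1.0)
        gaps = shifted.bank_b - shifted.bank_a
        assert np.allclose(gaps, 6.0)

    def test_negative_dlg_rejected(self):
        with pytest.raises(ValidationError):
            apply_leaf_shift(sweeping_gap(5.0), -0.1)


class TestSimulatePlane:
    def test_open_field_central_dose_is_mu_independent_of_transmission(self):
        for t in (0.0, 0.02, 0.05):
            plane = simulate_plane(open_field(mu=150.0), MLCModel(0.0, t, 0.0),
                                   spacing=2.0, extent=80.0)
            assert central_dose(plane) == pytest.approx(150.0)

    def test_static_blocked_central_dose_is_transmission_fraction(self):
        machine = MLCModel(0.0, 0.018, 0.0)
        blocked = simulate_plane(static_blocked(mu=100.0), machine,
                                 spacing=2.0, extent=80.0)
        opened = simulate_plane(open_field(mu=100.0), machine,
                                spacing=2.0, extent=80.0)
        assert central_dose(blocked) == pytest.approx(
            0.018 * central_dose(opened), rel=1e-12)

    @pytest.mark.parametrize("gap", [2.0, 5.0, 10.0, 20.0])
    def test_sweeping_gap_matches_closed_form(self, gap):
        # time-integrated fluence: mu * [(g+dlg)/L + T*(1-(g+dlg)/L)]
        dlg, trans, mu, L = 1.25, 0.015, 100.0, 60.0
        plane = simulate_plane(sweeping_gap(gap, sweep_extent=L, mu=mu),
                               MLCModel(dlg, trans, penumbra_sigma=0.0),
                               spacing=1.0, extent=60.0)
        phi = (gap + dlg) / L
        expected = mu * (phi + trans * (1 - phi))
        assert central_dose(plane) == pytest.approx(expected, rel=1e-3)

    def test_dose_linear_in_mu(self):
        machine = MLCModel(1.0, 0.015, 2.0)
        a = simulate_plane(sweeping_gap(5.0, mu=100.0), machine, 2.0, 60.0)
        b = simulate_plane(sweeping_gap(5.0, mu=250.0), machine, 2.0, 60.0)
        assert np.allclose(b.values, 2.5 * a.values, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("name", ["sweep5", "sweep10", "chair"])
    def test_dose_monotone_in_dlg_and_transmission(self, name):
        pat = default_toy_patterns()[name]
        lo = simulate_plane(pat, MLCModel(0.5, 0.005, 2.0), 2.0, 60.0)
        hi_d = simulate_plane(pat, MLCModel(1.5, 0.005, 2.0), 2.0, 60.0)
        hi_t = simulate_plane(pat, MLCModel(0.5, 0.02, 2.0), 2.0, 60.0)
        assert np.all(hi_d.values >= lo.values - 1e-9)
        assert np.all(hi_t.values >= lo.values - 1e-9)

    def test_extent_smaller_than_field_raises(self):
        with pytest.raises(GeometryError):
            simulate_plane(open_field(field_size=(80.0, 80.0)),
                           MLCModel(), spacing=1.0, extent=60.0)

    def test_chair_has_three_informative_regions(self):
        # transmission-dominated, gap-dominated and open regions; the
        # transmission region must sit above the usual 10% threshold
        machine = MLCModel(1.0, 0.015, 2.0)
        plane = simulate_plane(chair(), machine, 1.0, 60.0)
        mid = plane.values[30]
        d_trans, d_gap, d_open = mid[10], mid[30], mid[52]
        assert d_trans > 0.10 * plane.values.max()
        assert d_trans < 0.3 * d_gap
        base = simulate_plane(chair(), MLCModel(1.0, 0.0145, 2.0), 1.0, 60.0)
        # transmission region responds to T, not to DLG
        up_t = simulate_plane(chair(), MLCModel(1.0, 0.0155, 2.0), 1.0, 60.0)
        up_d = simulate_plane(chair(), MLCModel(1.2, 0.0145, 2.0), 1.0, 60.0)
        assert up_t.values[30, 10] - base.values[30, 10] > 5 * abs(
            up_d.values[30, 10] - base.values[30, 10])
        assert up_d.values[30, 30] > base.values[30, 30]

    def test_identifiability_of_parameter_map_on_toy_set(self):
        # central doses of the two sweeping gaps separate every pair of
        # grid-box parameters
        pats = default_toy_patterns()
        points = [(d, t) for d in np.linspace(0, 2.5, 6)
                  for t in np.linspace(0.0001, 0.025, 6)]
        doses = []
        for d, t in points:
            machine = MLCModel(d, t, 0.0)
            doses.append([
                central_dose(simulate_plane(pats["sweep5"], machine, 2.0, 60.0)),
                central_dose(simulate_plane(pats["sweep10"], machine, 2.0, 60.0)),
            ])
        doses = np.asarray(doses)
        dist = np.linalg.norm(doses[:, None, :] - doses[None, :, :], axis=-1)
        iu = np.triu_indices(len(points), k=1)
        assert dist[iu].min() > 1e-3


class TestMeasurePlane:
    def test_identity_when_pitch_matches_and_no_noise(self):
        plane = simulate_plane(sweeping_gap(5.0), MLCModel(1.0, 0.015), 2.0, 60.0)
        out = measure_plane(plane, MeasurementModel(2.0, 0.0, seed=1))
        assert np.array_equal(out.values, plane.values)

    def test_seeded_noise_is_reproducible(self):
        plane = simulate_plane(sweeping_gap(5.0), MLCModel(1.0, 0.015), 2.0, 60.0)
        a = measure_plane(plane, MeasurementModel(2.0, 0.01, seed=42))
        b = measure_plane(plane, MeasurementModel(2.0, 0.01, seed=42))
        c = measure_plane(plane, MeasurementModel(2.0, 0.01, seed=43))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_block_average_downsampling(self):
        from mlcopt import DosePlane
        values = np.arange(36, dtype=float).reshape(6, 6) + 10.0
        plane = DosePlane(values, 1.0, 1.0, origin_x=-2.5, origin_y=2.5)
        out = measure_plane(plane, MeasurementModel(2.0, 0.0, seed=0))
        assert out.spacing_x == 2.0
        assert out.values.shape[0] >= 2 and out.values.shape[1] >= 2
        assert out.values.min() >= values.min()
        assert out.values.max() <= values.max()

    def test_noise_mean_converges_to_truth(self):
        # law of large numbers on a uniform 100 cGy plane
        from mlcopt import DosePlane
        plane = DosePlane(np.full((5, 5), 100.0), 5.0, 5.0)
        n = 1000
        means = [
            measure_plane(plane, MeasurementModel(5.0, 0.01, seed=s)).values.mean()
            for s in range(n)
        ]
        se = np.std(means, ddof=1) / np.sqrt(n)
        assert abs(np.mean(means) - 100.0) < 3 * se + 1e-9

    def test_pitch_coarser_than_extent_raises(self):
        from mlcopt import DosePlane
        plane = DosePlane(np.full((4, 4), 10.0), 1.0, 1.0)
        with pytest.raises(GeometryError):
            measure_plane(plane, MeasurementModel(50.0, 0.0, seed=0))


class TestEstimateDlg:
    def readings_for(self, dlg, trans, gaps, L=60.0, mu=100.0):
        out = []
        for g in gaps:
            plane = simulate_plane(sweeping_gap(g, sweep_extent=L, mu=mu),
                                   MLCModel(dlg, trans, 0.0), 1.0, 60.0)
            out.append((g, central_dose(plane)))
        opened = simulate_plane(open_field(mu=mu), MLCModel(dlg, trans, 0.0),
                                1.0, 60.0)
        return out, central_dose(opened)

    def test_exact_inversion_noise_free(self):
        readings, open_r = self.readings_for(1.5, 0.015,
                                             [2, 4, 6, 10, 14, 16, 20])
        est = estimate_dlg_sweeping_gap(readings, 0.015, open_r,
                                        sweep_extent=60.0)
        assert est.dlg_mm == pytest.approx(1.5, abs=1e-9)
        assert not est.suspect

    def test_zero_offset_line_gives_zero(self):
        readings = [(g, 2.0 * g) for g in (2.0, 5.0, 10.0)]
        est = estimate_dlg_sweeping_gap(readings, 0.0, 100.0, sweep_extent=60.0)
        assert est.dlg_mm == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(dlg=st.floats(0.0, 2.5), trans=st.floats(0.0, 0.025))
    def test_round_trip_recovers_any_dlg(self, dlg, trans):
        readings, open_r = self.readings_for(dlg, trans, [2, 6, 10, 16, 20])
        est = estimate_dlg_sweeping_gap(readings, trans, open_r,
                                        sweep_extent=60.0)
        assert est.dlg_mm == pytest.approx(dlg, abs=1e-8)

    def test_noisy_estimate_within_measurement_uncertainty(self):
        # 0.5% multiplicative noise on the readings: the estimate scatters
        # by roughly a tenth of a millimetre
        readings, open_r = self.readings_for(1.5, 0.015,
                                             [2, 4, 6, 10, 14, 16, 20])
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(50):
            noisy = [(g, r * (1 + 0.005 * rng.standard_normal()))
                     for g, r in readings]
            est = estimate_dlg_sweeping_gap(noisy, 0.015, open_r,
                                            sweep_extent=60.0)
            errs.append(est.dlg_mm - 1.5)
        assert np.max(np.abs(errs)) < 0.2

    def test_negative_estimate_flagged_not_rejected(self):
        readings = [(g, 2.0 * (g - 0.3)) for g in (2.0, 5.0, 10.0)]
        est = estimate_dlg_sweeping_gap(readings, 0.0, 100.0, sweep_extent=60.0)
        assert isinstance(est, DlgEstimate)
        assert est.dlg_mm == pytest.approx(-0.3, abs=1e-9)
        assert est.suspect

    def test_singular_and_invalid_inputs(self):
        with pytest.raises(ValidationError):
            estimate_dlg_sweeping_gap([(5.0, 10.0)], 0.01, 100.0)
        with pytest.raises(ValidationError):
            estimate_dlg_sweeping_gap([(5.0, 10.0), (5.0, 11.0)], 0.01, 100.0)
        with pytest.raises(ValidationError):
            estimate_dlg_sweeping_gap([(5.0, -1.0), (10.0, 2.0)], 0.01, 100.0)
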