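"""Gamma-engine unit and property tests."""

import numpy as np
import pytest

from mlcopt import (
    DegenerateInputError,
    DosePlane,
    GammaCriteria,
    GeometryError,
    MLCModel,
    ValidationError,
    compute_gamma,
    summarize,
    sweeping_gap,
    simulate_plane,
    threshold_mask,
)
from conftest import gamma_bruteforce, random_plane


def make_uniform(value=100.0, n=10, spacing=2.0):
    return DosePlane(np.full((n, n), value), spacing, spacing)


class TestThresholdMask:
    def test_uniform_plane_all_above(self):
        mask = threshold_mask(make_uniform(100.0), GammaCriteria(threshold=0.10))
        assert mask.all()

    def test_half_plane_masked(self):
        values = np.full((10, 10), 5.0)
        values[:5] = 100.0
        plane = DosePlane(values, 1.0, 1.0)
        mask = threshold_mask(plane, GammaCriteria(threshold=0.10))
        assert mask[:5].all() and not mask[5:].any()

    def test_zero_threshold_masks_everything(self):
        values = np.zeros((5, 5))
        values[2, 2] = 50.0
        mask = threshold_mask(DosePlane(values, 1.0, 1.0),
                              GammaCriteria(threshold=0.0))
        assert mask.all()

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            threshold_mask(make_uniform(5.0),
                           GammaCriteria(threshold=0.10, norm_dose=100.0))


class TestSummarize:
    @pytest.mark.parametrize(
        "values, pass_rate, mean_gamma",
        [
            ([0.0, 0.0, 0.0, 0.0], 1.0, 0.0),
            ([0.5, 0.5, 2.0, 2.0], 0.5, 1.25),
            ([1.0], 1.0, 1.0),  # gamma exactly 1 passes
        ],
    )
    def test_direct_arithmetic(self, values, pass_rate, mean_gamma):
        g = np.full((2, max(2, len(values))), np.nan)
        mask = np.zeros_like(g, dtype=bool)
        g[0, : len(values)] = values
        mask[0, : len(values)] = True
        pr, mg = summarize(g, mask)
        assert pr == pytest.approx(pass_rate)
        assert mg == pytest.approx(mean_gamma)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            summarize(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))


class TestComputeGamma:
    def test_identity_is_zero(self, rng):
        plane = simulate_plane(sweeping_gap(5.0), MLCModel(1.0, 0.015),
                               spacing=2.0, extent=60.0)
        res = compute_gamma(plane, plane)
        assert res.pass_rate == 1.0
        assert res.mean_gamma == 0.0
        assert np.all(res.gamma_map[res.mask] == 0.0)

    def test_two_percent_scaling_saturates_at_norm_plateau(self):
        # plateau holding the normalization dose plus a low-dose half: a
        # uniform 2% scaling with dd = 2% puts gamma exactly at 1 on plateau
        # pixels far from the step (no dose relief there) and below 1 on the
        # low half; gamma = 1 still passes
        values = np.full((12, 24), 50.0)
        values[:, :12] = 100.0
        ref = DosePlane(values, 1.0, 1.0)
        ev = DosePlane(values * 1.02, 1.0, 1.0)
        res = compute_gamma(ref, ev, GammaCriteria(dta=2.0, dd=0.02,
                                                   threshold=0.10))
        plateau_interior = res.gamma_map[:, :4]
        assert np.allclose(plateau_interior, 1.0, atol=1e-9)
        assert (res.gamma_map[:, 14:] < 1.0).all()
        assert res.pass_rate == 1.0

    def test_ramp_translated_by_dta_matches_closed_form(self):
        # linear ramp of slope s translated by the DTA: minimizing the gamma
        # integrand along the gradient gives gamma = k/sqrt(1+k^2) with
        # k = s*dta/(dd*Dnorm); steep ramps approach 1 from below
        slope, dta, dd = 20.0, 2.0, 0.02
        values = np.tile(100.0 + slope * np.arange(16.0), (10, 1))
        ref = DosePlane(values, 1.0, 1.0)
        shifted = DosePlane(values - slope * dta, 1.0, 1.0)
        res = compute_gamma(ref, shifted, GammaCriteria(dta=dta, dd=dd))
        k = slope * dta / (dd * values.max())
        expected = k / np.sqrt(1 + k**2)
        interior = res.gamma_map[4:6, 6:10]
        assert np.allclose(interior, expected, atol=2e-3)

    def test_matches_bruteforce_oracle(self, rng):
        crit = GammaCriteria(dta=2.0, dd=0.02, threshold=0.10)
        for _ in range(10):
            ref = random_plane(rng, 20, 20)
            ev = DosePlane(
                ref.values * (1 + 0.02 * rng.standard_normal(ref.values.shape)),
                ref.spacing_x, ref.spacing_y, ref.origin_x, ref.origin_y)
            res = compute_gamma(ref, ev, crit, search_factor=3.0,
                                upsample_factor=10)
            oracle, mask = gamma_bruteforce(ref, ev, crit, upsample_factor=10)
            valid = mask & (oracle <= 3.0)  # exhaustive min within radius
            assert valid.any()
            assert np.nanmax(np.abs(res.gamma_map[valid] - oracle[valid])) <= 1e-6

    def test_monotone_in_criteria(self, rng):
        ref = random_plane(rng, 15, 15)
        ev = DosePlane(ref.values * (1 + 0.03 * np.sin(np.arange(225).reshape(15, 15))),
                       ref.spacing_x, ref.spacing_y, ref.origin_x, ref.origin_y)
        base = compute_gamma(ref, ev, GammaCriteria(dta=2.0, dd=0.02))
        for crit in (GammaCriteria(dta=3.0, dd=0.02), GammaCriteria(dta=2.0, dd=0.03)):
            loose = compute_gamma(ref, ev, crit)
            assert loose.pass_rate >= base.pass_rate
            assert loose.mean_gamma <= base.mean_gamma + 1e-12

    def test_statistics_invariant_to_below_threshold_pixels(self):
        core = np.full((6, 6), 100.0)
        core[2, 2] = 103.0
        small_ref = DosePlane(core, 2.0, 2.0, origin_x=0.0, origin_y=0.0)
        small_ev = DosePlane(core * 1.01, 2.0, 2.0, origin_x=0.0, origin_y=0.0)
        pad = np.zeros((10, 10))
        pad[2:8, 2:8] = core
        big_ref = DosePlane(pad, 2.0, 2.0, origin_x=-4.0, origin_y=4.0)
        pad_ev = np.zeros((10, 10))
        pad_ev[2:8, 2:8] = core * 1.01
        big_ev = DosePlane(pad_ev, 2.0, 2.0, origin_x=-4.0, origin_y=4.0)
        a = compute_gamma(small_ref, small_ev)
        b = compute_gamma(big_ref, big_ev)
        assert b.mask.sum() == a.mask.sum()
        assert b.pass_rate == pytest.approx(a.pass_rate)
        assert b.mean_gamma == pytest.approx(a.mean_gamma, abs=1e-12)

    def test_local_normalization_uniform_offset(self):
        ref = make_uniform(100.0)
        ev = make_uniform(101.0)
        res = compute_gamma(ref, ev, GammaCriteria(dd=0.02, normalization="local"))
        assert np.allclose(res.gamma_map[res.mask], 0.5)

    def test_translation_within_dta_bounded(self):
        plane = simulate_plane(sweeping_gap(10.0), MLCModel(1.0, 0.015),
                               spacing=1.0, extent=60.0)
        shifted = DosePlane(plane.values, 1.0, 1.0,
                            origin_x=plane.origin_x + 1.5,
                            origin_y=plane.origin_y)
        res = compute_gamma(plane, shifted, GammaCriteria(dta=2.0, dd=0.02))
        interior = res.gamma_map[10:-10, 10:-10]
        vals = interior[~np.isnan(interior)]
        assert (vals <= 1.0 + 0.05).all()

    def test_non_overlapping_planes_raise(self):
        a = make_uniform()
        b = DosePlane(np.full((5, 5), 50.0), 1.0, 1.0, origin_x=1000.0)
        with pytest.raises(GeometryError):
            compute_gamma(a, b)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValidationError):
            GammaCriteria(dta=-1.0)
        with pytest.raises(ValidationError):
            GammaCriteria(threshold=1.0)
        with pytest.raises(ValidationError):
            GammaCriteria(normalization="max")

    def test_all_below_threshold_degenerate(self):
        ref = make_uniform(5.0)
        with pytest.raises(DegenerateInputError):
            compute_gamma(ref, ref, GammaCriteria(threshold=0.10, norm_dose=100.0))
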