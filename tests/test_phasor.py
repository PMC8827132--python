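"""Phasor computation, calibration, lifetimes, mixtures, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatedphasor.phasor import (
    Phasor,
    analyze_mixture,
    bin_rois,
    calibrate,
    calibrate_image,
    compute_phasor,
    compute_phasor_image,
    fit_mu_chi,
    lifetime_map,
    phase_lifetime,
    phasor_histogram2d,
    phasor_ratio,
    phasor_ratio_from_volume_fraction,
    single_exp_phasor,
    volume_fraction,
)

F20 = 20e6
T = 50.0


class TestComputePhasor:
    def test_single_gate_at_origin(self):
        assert compute_phasor([5.0], [0.0], F20) == Phasor(1.0, 0.0)

    def test_antiphase_cancellation(self):
        p = compute_phasor([1.0, 1.0], [0.0, T / 2], F20)
        assert p.g == pytest.approx(0.0, abs=1e-12)
        assert p.s == pytest.approx(0.0, abs=1e-12)

    def test_four_gate_hand_example(self):
        # z = (4 + 3i - 2 - 1i) / 10 = 0.2 + 0.2i
        p = compute_phasor([4, 3, 2, 1], [0, T / 4, T / 2, 3 * T / 4], F20)
        assert p.g == pytest.approx(0.2, abs=1e-12)
        assert p.s == pytest.approx(0.2, abs=1e-12)

    def test_zero_intensity_raises_for_scalar_call(self):
        with pytest.raises(ValueError):
            compute_phasor([0.0, 0.0], [0.0, 1.0], F20)

    @settings(derandomize=True, max_examples=40)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.01, 10.0), st.floats(0.01, 10.0)),
            min_size=3,
            max_size=12,
        )
    )
    def test_linearity_of_profile_mixing(self, data):
        """Phasor of summed profiles = intensity-weighted phasor combination."""
        a = np.array([x for x, _ in data])
        b = np.array([y for _, y in data])
        t = np.linspace(0, T, len(data), endpoint=False)
        za = compute_phasor(a, t, F20).z
        zb = compute_phasor(b, t, F20).z
        zab = compute_phasor(a + b, t, F20).z
        wa, wb = a.sum(), b.sum()
        assert zab == pytest.approx((wa * za + wb * zb) / (wa + wb), abs=1e-12)


class TestPhasorImage:
    def test_zero_pixels_flagged_not_nan(self):
        values = np.zeros((4, 2, 2))
        values[:, 0, 0] = [4, 3, 2, 1]
        img = compute_phasor_image(values, np.array([0, T / 4, T / 2, 3 * T / 4]), F20)
        assert img.valid[0, 0] and not img.valid[1, 1]
        assert np.isfinite(img.g).all()  # invalid pixels carry zeros, not NaN
        assert img.g[0, 0] == pytest.approx(0.2)

    def test_matches_scalar_phasor_per_pixel(self):
        rng = np.random.default_rng(0)
        values = rng.random((6, 3, 3)) + 0.1
        t = np.linspace(0, T, 6, endpoint=False)
        img = compute_phasor_image(values, t, F20)
        p = compute_phasor(values[:, 1, 2], t, F20)
        assert img.g[1, 2] == pytest.approx(p.g, abs=1e-12)
        assert img.s[1, 2] == pytest.approx(p.s, abs=1e-12)


class TestPhaseLifetime:
    def test_zero_s_gives_zero_lifetime(self):
        assert phase_lifetime(Phasor(0.7, 0.0), F20) == 0.0

    def test_unit_slope_at_20mhz(self):
        tau = phase_lifetime(Phasor(0.5, 0.5), F20)
        assert tau == pytest.approx(1 / (2 * np.pi * 0.02), abs=1e-9)  # 7.9577 ns

    def test_roundtrip_through_theoretical_phasor(self):
        assert phase_lifetime(single_exp_phasor(2.8, F20), F20) == pytest.approx(2.8)

    def test_second_quadrant_flagged_nan(self):
        assert np.isnan(phase_lifetime(Phasor(-0.1, 0.5), F20))


class TestSingleExpPhasor:
    def test_limits(self):
        assert single_exp_phasor(0.0, F20) == Phasor(1.0, 0.0)
        far = single_exp_phasor(1e9, F20)
        assert abs(far.z) < 1e-3

    def test_cy3b_at_20mhz(self):
        # u = 2*pi*0.02*2.8 = 0.3518584
        p = single_exp_phasor(2.8, F20)
        assert p.g == pytest.approx(0.8898346, abs=1e-6)
        assert p.s == pytest.approx(0.3130958, abs=1e-6)
        assert p.semicircle_residual() == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(tau=st.floats(0.0, 1000.0))
    def test_always_on_universal_semicircle(self, tau):
        p = single_exp_phasor(tau, F20)
        assert p.semicircle_residual() == pytest.approx(0.0, abs=1e-12)


class TestCalibration:
    def test_self_calibration_recovers_reference(self):
        z_exp = Phasor(0.3, 0.2)
        out = calibrate(z_exp, z_exp, 2.8, F20)
        theo = single_exp_phasor(2.8, F20)
        assert out.g == pytest.approx(theo.g, abs=1e-12)
        assert out.s == pytest.approx(theo.s, abs=1e-12)

    def test_ideal_instrument_is_identity(self):
        z_exp = Phasor(0.6, 0.25)
        out = calibrate(z_exp, single_exp_phasor(2.8, F20), 2.8, F20)
        assert out.g == pytest.approx(z_exp.g, abs=1e-12)
        assert out.s == pytest.approx(z_exp.s, abs=1e-12)

    def test_zero_calibration_phasor_rejected(self):
        with pytest.raises(ValueError):
            calibrate(Phasor(0.5, 0.2), Phasor(0.0, 0.0), 2.8, F20)

    def test_simulated_stack_roundtrip(self, stack_factory):
        """4.08 ns sample calibrated with a 2.8 ns stack recovers its lifetime."""
        s_i = stack_factory(4.08, seed=50, shape=(16, 16))
        s_c = stack_factory(2.8, seed=51, shape=(16, 16))
        from gatedphasor.corrections import correct_stack

        img = compute_phasor_image(
            correct_stack(s_i).values, s_i.timestamps_ns, F20
        )
        cal = compute_phasor_image(
            correct_stack(s_c).values, s_c.timestamps_ns, F20
        )
        taus = calibrate_image(img, cal, 2.8, "per_pixel").phase_lifetimes_ns()
        se = np.nanstd(taus) / np.sqrt(np.isfinite(taus).sum())
        assert np.nanmean(taus) == pytest.approx(4.08, abs=3 * se)

    def test_global_granularity_matches_weighted_mean(self):
        rng = np.random.default_rng(1)
        values = rng.random((8, 4, 4)) + 0.5
        t = np.linspace(0, T, 8, endpoint=False)
        img = compute_phasor_image(values, t, F20)
        cal = compute_phasor_image(values, t, F20)
        out = calibrate_image(img, cal, 2.8, "global")
        w = cal.intensity
        z_cal = (cal.z * w).sum() / w.sum()
        expected = img.z * single_exp_phasor(2.8, F20).z / z_cal
        assert out.z == pytest.approx(expected, abs=1e-12)


class TestBinRois:
    def test_identity_at_n1(self):
        img = np.random.default_rng(2).random((5, 7))
        assert bin_rois(img, 1) == pytest.approx(img)

    def test_constant_tiles_sum(self):
        out = bin_rois(np.full((8, 8), 3.0), 4)
        assert out.shape == (2, 2)
        assert out == pytest.approx(np.full((2, 2), 48.0))

    def test_sensor_geometry_118x64(self):
        out = bin_rois(np.zeros((472, 256)), 4)
        assert out.shape == (118, 64)

    def test_partial_tiles_dropped(self):
        out = bin_rois(np.ones((7, 9)), 4)
        assert out.shape == (1, 2)

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            bin_rois(np.ones((3, 3)), 4)


class TestPhasorRatio:
    z1 = Phasor(0.3, 0.4)
    z2 = Phasor(0.8, 0.1)

    def test_pure_species_one(self):
        r1, proj = phasor_ratio(self.z1, self.z1, self.z2)
        assert r1 == 1.0
        assert proj == self.z1

    def test_midpoint(self):
        mid = Phasor(0.55, 0.25)
        r1, _ = phasor_ratio(mid, self.z1, self.z2)
        assert r1 == pytest.approx(0.5)

    def test_off_segment_projection_clamps(self):
        beyond = Phasor(1.5, -0.3)  # projects past z2
        r1, proj = phasor_ratio(beyond, self.z1, self.z2)
        assert r1 == 0.0
        assert proj.z == pytest.approx(self.z2.z, abs=1e-12)

    def test_orthogonal_offset_projects_onto_segment(self):
        mid = 0.5 * (self.z1.z + self.z2.z)
        seg = self.z2.z - self.z1.z
        off = mid + 0.1j * seg / abs(seg)  # perpendicular push
        r1, proj = phasor_ratio(Phasor.from_complex(off), self.z1, self.z2)
        assert r1 == pytest.approx(0.5)
        assert proj.z == pytest.approx(mid, abs=1e-12)

    def test_coincident_references_rejected(self):
        with pytest.raises(ValueError):
            phasor_ratio(self.z1, self.z1, self.z1)

    def test_mixture_result_distances(self):
        res = analyze_mixture(Phasor(0.55, 0.25), self.z1, self.z2, mu_chi=1.0)
        assert res.r1 == pytest.approx(res.d2 / (res.d1 + res.d2))
        assert res.v1 == pytest.approx(res.r1)


class TestMixtureRelation:
    def test_identity_when_mu_chi_one(self):
        v = np.linspace(0.05, 0.95, 11)
        assert phasor_ratio_from_volume_fraction(v, 1.0) == pytest.approx(v)
        assert volume_fraction(v, 1.0) == pytest.approx(v)

    def test_known_point(self):
        assert phasor_ratio_from_volume_fraction(0.5, 5.51) == pytest.approx(
            5.51 / 6.51, abs=1e-9
        )

    def test_inversion_roundtrip(self):
        v = np.linspace(0.01, 0.99, 25)
        r = phasor_ratio_from_volume_fraction(v, 5.51)
        assert volume_fraction(r, 5.51) == pytest.approx(v, abs=1e-12)

    def test_extremes_returned_exactly(self):
        assert volume_fraction(0.0, 5.51) == 0.0
        assert volume_fraction(1.0, 5.51) == 1.0

    def test_fit_recovers_mu_chi_from_noiseless_pairs(self):
        v = np.linspace(0.1, 0.9, 5)
        r = phasor_ratio_from_volume_fraction(v, 5.51)
        est, se = fit_mu_chi(v, r)
        assert est == pytest.approx(5.51, abs=1e-6)
        assert se < 1e-5

    def test_degenerate_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_mu_chi([0.5], [0.8])
        with pytest.raises(ValueError):
            fit_mu_chi([0.0, 1.0], [0.0, 1.0])


class TestLifetimeMap:
    def _img(self, g, s, intensity=None, valid=None):
        g = np.asarray(g, float)
        from gatedphasor.phasor import PhasorImage

        return PhasorImage(
            g=g,
            s=np.asarray(s, float),
            intensity=np.ones_like(g) if intensity is None else np.asarray(intensity, float),
            valid=np.ones_like(g, bool) if valid is None else np.asarray(valid, bool),
            freq_hz=F20,
        )

    ref_red = Phasor(0.6, 0.3)
    ref_blue = Phasor(0.2, 0.35)

    def test_all_at_red_reference_is_uniform(self):
        img = self._img(np.full((3, 3), 0.6), np.full((3, 3), 0.3))
        rgb = lifetime_map(img, self.ref_red, self.ref_blue, "flat")
        assert rgb.shape == (3, 3, 3)
        assert (rgb == rgb[0, 0]).all()
        assert rgb[0, 0, 0] > rgb[0, 0, 2]  # red dominates blue at ratio 0

    def test_blue_end_renders_blue(self):
        img = self._img([[0.2]], [[0.35]])
        rgb = lifetime_map(img, self.ref_red, self.ref_blue, "flat")
        assert rgb[0, 0, 2] > rgb[0, 0, 0]

    def test_scaled_mode_zero_intensity_is_black(self):
        img = self._img([[0.6, 0.2]], [[0.3, 0.35]], intensity=[[0.0, 5.0]])
        rgb = lifetime_map(img, self.ref_red, self.ref_blue, "scaled")
        assert rgb[0, 0] == pytest.approx([0, 0, 0])
        assert rgb[0, 1].sum() > 0

    def test_invalid_pixels_get_null_color(self):
        img = self._img([[0.6, 0.6]], [[0.3, 0.3]], valid=[[True, False]])
        rgb = lifetime_map(img, self.ref_red, self.ref_blue, "flat",
                           null_color=(1.0, 1.0, 1.0))
        assert rgb[0, 1] == pytest.approx([1, 1, 1])


class TestPhasorHistogram:
    def test_single_pixel_single_bin(self):
        img = TestLifetimeMap()._img([[0.4]], [[0.2]])
        counts, _, _ = phasor_histogram2d(img, bins=10)
        assert counts.sum() == 1
        assert (counts == 1).sum() == 1

    def test_total_mass_equals_valid_pixels(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.1, 0.9, (8, 8))
        s = rng.uniform(0.05, 0.5, (8, 8))
        valid = rng.random((8, 8)) > 0.3
        img = TestLifetimeMap()._img(g, s, valid=valid)
        counts, _, _ = phasor_histogram2d(img, bins=20)
        assert counts.sum() == valid.sum()

    def test_mode_near_theoretical_phasor_for_simulated_decay(self, stack_factory):
        from gatedphasor.corrections import correct_stack

        stack = stack_factory(2.8, seed=60, shape=(24, 24), brightness=1.5)
        img = compute_phasor_image(
            correct_stack(stack).values, stack.timestamps_ns, F20
        )
        # uncalibrated phasors are rotated by the gate factor (s < 0 here),
        # so histogram over the full lower half-plane as well
        counts, g_edges, s_edges = phasor_histogram2d(
            img, bins=40, range_gs=((0.0, 1.0), (-0.6, 0.6))
        )
        gi, si = np.unravel_index(np.argmax(counts), counts.shape)
        # uncalibrated phasors carry the gate factor; compare against the
        # expected (gated) phasor computed from the noiseless profile
        from gatedphasor.gate_model import DecayModel, expected_gate_fraction

        frac = expected_gate_fraction(
            DecayModel.single(2.8), stack.timestamps_ns, 13.1, T
        )
        z_exp = compute_phasor(frac, stack.timestamps_ns, F20)
        bin_w = g_edges[1] - g_edges[0]
        bin_h = s_edges[1] - s_edges[0]
        assert abs(g_edges[gi] + bin_w / 2 - z_exp.g) <= 1.5 * bin_w
        assert abs(s_edges[si] + bin_h / 2 - z_exp.s) <= 1.5 * bin_h
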