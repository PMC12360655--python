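"""Phase maps, plane fitting, circular correlation, null, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corticowave.eeg import EEGRecord, EEG_SFREQ
from corticowave.fixtures import PlanarWaveSpec, make_planar_scalp_wave
from corticowave.wavefit import (
    FW_AXIS_ANGLE,
    NullDistribution,
    PlaneFitGrid,
    build_null,
    circ_corr,
    circular_median,
    classify,
    compute_phase,
    fit_waves,
    get_roi,
    lateral_reference_axis,
    plane_fit,
    predicted_phases,
    wrap_angle,
)


@pytest.fixture(scope="module")
def midline():
    return get_roi("midline")


def _sine_eeg(phases_per_channel, montage, n=400, f=10.0):
    t = np.arange(n) / EEG_SFREQ
    data = np.sin(2 * np.pi * f * t[None, :] + phases_per_channel[:, None])
    return EEGRecord(data, EEG_SFREQ, montage.ch_names, montage)


class TestComputePhase:
    def test_identical_channels_have_zero_relative_phase(self, montage, midline):
        eeg = _sine_eeg(np.zeros(64), montage)
        pm = compute_phase(eeg, midline)
        assert np.all(np.abs(pm.phases) < 1e-8)

    def test_planar_ramp_recovered(self, montage, midline):
        spec = PlanarWaveSpec(direction=np.pi / 2, spatial_freq=0.8)
        eeg = make_planar_scalp_wave(spec, 4.0)
        pm = compute_phase(eeg, midline)
        a, b = spec.gradient
        expected = predicted_phases(midline.positions, np.pi / 2, 0.8)
        expected = wrap_angle(expected - np.angle(np.mean(np.exp(1j * expected))))
        err = np.abs(wrap_angle(pm.phases[50:-50] - expected[None, :]))
        assert err.max() < 0.05

    def test_common_offset_invariance(self, montage, midline):
        # away from filter edge transients, referencing to the ROI mean
        # phase makes the map invariant to a common phase offset
        base = np.linspace(0.0, 1.0, 64)
        pm1 = compute_phase(_sine_eeg(base, montage), midline)
        pm2 = compute_phase(_sine_eeg(base + 1.3, montage), midline)
        interior = slice(80, -80)
        diff = wrap_angle(pm1.phases[interior] - pm2.phases[interior])
        # residual is DFT-Hilbert leakage on the finite record, not referencing
        assert np.abs(diff).max() < 1e-3

    def test_band_above_nyquist_rejected(self, montage, midline):
        eeg = _sine_eeg(np.zeros(64), montage)
        with pytest.raises(ValueError):
            compute_phase(eeg, midline, band=(40.0, 60.0))


class TestPlaneFit:
    def test_grid_points_recovered_within_one_step(self, midline):
        grid = PlaneFitGrid()
        AB, alpha_g, xi_g = grid.vectors(midline.positions)
        rng = np.random.default_rng(0)
        d_alpha = 2 * np.pi / grid.n_directions
        for idx in rng.choice(np.arange(1, len(AB)), 12, replace=False):
            phases = midline.positions @ AB[idx]
            alpha, xi, rbar = plane_fit(phases[None, :], midline.positions, grid)
            assert rbar[0] > 0.999
            assert abs(wrap_angle(alpha[0] - alpha_g[idx])) <= d_alpha + 1e-9
            assert abs(xi[0] - xi_g[idx]) <= xi_g[1:].min() + 1e-9

    def test_uniform_phases_degenerate_to_zero_frequency(self, midline):
        alpha, xi, rbar = plane_fit(np.zeros((1, 38)), midline.positions)
        assert xi[0] == 0.0
        assert np.isnan(alpha[0])
        assert rbar[0] == pytest.approx(1.0)

    def test_global_phase_shift_invariance(self, midline):
        grid = PlaneFitGrid()
        AB, _, _ = grid.vectors(midline.positions)
        phases = midline.positions @ AB[500]
        r1 = plane_fit(phases[None, :], midline.positions, grid)
        r2 = plane_fit(phases[None, :] + np.pi, midline.positions, grid)
        assert r1[0][0] == r2[0][0] and r1[1][0] == r2[1][0]
        assert r1[2][0] == pytest.approx(r2[2][0])

    def test_collinear_layout_rejected(self):
        pos = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            plane_fit(np.zeros((1, 5)), pos)

    def test_resultant_is_one_for_constant_residuals(self, midline):
        # phases = plane + constant: residuals identical => rbar exactly 1
        grid = PlaneFitGrid()
        AB, _, _ = grid.vectors(midline.positions)
        phases = midline.positions @ AB[200] + 0.4
        _, _, rbar = plane_fit(phases[None, :], midline.positions, grid)
        assert rbar[0] == pytest.approx(1.0, abs=1e-12)

    def test_grid_argmax_matches_dense_bruteforce_small_layout(self):
        # 5-electrode instance: coarse grid vs a 600x denser evaluation
        rng = np.random.default_rng(3)
        pos = rng.uniform(-1, 1, (5, 2))
        phases = rng.uniform(-np.pi, np.pi, (3, 5))
        coarse = PlaneFitGrid(n_directions=60, n_frequencies=30)
        dense = PlaneFitGrid(n_directions=1200, n_frequencies=900)
        a_c, x_c, _ = plane_fit(phases, pos, coarse)
        a_d, x_d, _ = plane_fit(phases, pos, dense)
        diff = pos[:, None, :] - pos[None, :, :]
        ximax = 2 * np.pi / np.sqrt((diff**2).sum(-1)).max()
        for ac, xc, ad, xd in zip(a_c, x_c, a_d, x_d):
            if np.isnan(ac) or np.isnan(ad):
                continue
            assert abs(wrap_angle(ac - ad)) <= 2 * np.pi / 60 + 1e-9
            assert abs(xc - xd) <= ximax / 29 + 1e-9


class TestCircCorr:
    def test_perfect_agreement(self, rng):
        theta = rng.uniform(-1.0, 1.0, 38)
        assert circ_corr(theta, theta) == pytest.approx(1.0)

    def test_sign_flip_about_mean(self, rng):
        theta = rng.uniform(-1.0, 1.0, 38)
        m = np.angle(np.mean(np.exp(1j * theta)))
        flipped = wrap_angle(2 * m - theta)
        assert circ_corr(theta, flipped) == pytest.approx(-1.0, abs=1e-6)

    def test_independent_phases_uncorrelated_on_average(self, rng):
        vals = [
            circ_corr(rng.uniform(-np.pi, np.pi, 38), rng.uniform(-np.pi, np.pi, 38))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            circ_corr(np.zeros(5), np.zeros(6))


class TestNullAndClassification:
    def test_planar_wave_beats_null(self, rng):
        spec = PlanarWaveSpec(direction=np.pi / 2, spatial_freq=1.0, noise_sd=0.05)
        eeg = make_planar_scalp_wave(spec, 3.0, rng)
        res = fit_waves(eeg, "midline", rng=rng)
        null = build_null([compute_phase(eeg, get_roi("midline"))], rng)
        assert np.mean(res.rho > null.threshold) > 0.95

    def test_white_noise_false_positive_rate(self, montage, rng):
        data = rng.standard_normal((64, 1200))
        eeg = EEGRecord(data, EEG_SFREQ, montage.ch_names, montage)
        roi = get_roi("midline")
        pm = compute_phase(eeg, roi)
        null = build_null([pm], rng)
        alpha, xi, _ = plane_fit(pm.phases, roi.positions)
        from corticowave.wavefit import _rho_per_window

        rho = _rho_per_window(pm.phases, roi.positions, alpha, xi)
        # 95% one-sided cut: ~5% of windows exceed by construction
        assert np.mean(rho > null.threshold) < 0.2

    def test_classification_rules(self):
        null = NullDistribution(np.linspace(0, 0.5, 100))
        thr = null.threshold
        # on-axis and significant
        assert classify([FW_AXIS_ANGLE], [thr + 0.1], null)[0] == "FW"
        assert classify([FW_AXIS_ANGLE + np.pi], [thr + 0.1], null)[0] == "BW"
        # below threshold -> Null regardless of angle
        assert classify([FW_AXIS_ANGLE], [thr - 0.1], null)[0] == "Null"
        # orthogonal to the axis -> Null even when significant
        assert classify([FW_AXIS_ANGLE + np.pi / 2], [thr + 0.1], null)[0] == "Null"
        # 0.5 rad is inclusive
        assert classify([FW_AXIS_ANGLE + 0.49], [thr + 0.1], null)[0] == "FW"


class TestLateralAxis:
    def test_pure_axis(self):
        alphas = np.full(20, -np.pi / 2)
        states = np.array(["FW"] * 20)
        assert lateral_reference_axis(alphas, states) == pytest.approx(-np.pi / 2)

    def test_symmetric_spread_gives_midline(self):
        alphas = np.array([-np.pi / 2 + 0.3, -np.pi / 2 - 0.3] * 10 + [-np.pi / 2])
        states = np.array(["FW"] * 21)
        assert lateral_reference_axis(alphas, states) == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_bw_fits_fold_onto_fw_axis(self):
        alphas = np.array([-np.pi / 2, np.pi / 2, np.pi / 2])
        states = np.array(["FW", "BW", "BW"])
        assert lateral_reference_axis(alphas, states) == pytest.approx(-np.pi / 2)

    def test_single_fit(self):
        assert lateral_reference_axis(np.array([0.3]), np.array(["FW"])) == pytest.approx(0.3)

    def test_no_classified_windows_rejected(self):
        with pytest.raises(ValueError):
            lateral_reference_axis(np.array([0.1]), np.array(["Null"]))


@settings(max_examples=100, deadline=None)
@given(st.floats(-50.0, 50.0))
def test_wrap_angle_range(a):
    w = wrap_angle(a)
    assert -np.pi <= w <= np.pi
    assert np.isclose(np.exp(1j * w), np.exp(1j * a))


def test_circular_median_is_a_sample_minimizing_distance():
    angles = np.array([0.1, 0.2, 0.25, 3.0])
    m = circular_median(angles)
    assert m in angles
    d_m = np.abs(wrap_angle(angles - m)).sum()
    for other in angles:
        assert d_m <= np.abs(wrap_angle(angles - other)).sum() + 1e-12
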