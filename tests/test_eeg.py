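"""EEG forward chain: preprocessing, pink noise, lead field, projection."""

import numpy as np
import pytest

from corticowave.eeg import (
    EEG_SFREQ,
    area_source_positions,
    area_source_signal,
    lead_field,
    make_pink_noise,
    preprocess_traces,
    project,
    roi_channel_lists,
    standard_montage,
    traces_to_eeg,
)


class TestMontage:
    def test_biosemi64_layout(self, montage):
        assert len(montage.ch_names) == 64
        assert {"Oz", "Fz", "Iz", "C3", "C4"} <= set(montage.ch_names)
        # 2D projection: anterior electrodes have larger y than posterior
        names = list(montage.ch_names)
        assert montage.pos2d[names.index("Fpz"), 1] > montage.pos2d[names.index("Oz"), 1]

    def test_frozen_roi_sizes(self):
        lists = roi_channel_lists()
        assert len(lists["midline"]) == 38
        assert len(lists["left"]) == 20
        assert len(lists["right"]) == 20
        assert not set(lists["left"]) & set(lists["right"])


class TestPreprocess:
    def test_dc_passes_unchanged(self):
        x = np.full(2000, 3.7)
        y = preprocess_traces(x)
        assert y == pytest.approx(3.7, abs=1e-9)

    def test_40hz_attenuation_matches_order3_response(self):
        # |H(2*fc)| for a 3rd-order Butterworth: 1/sqrt(1+2^6) ~ -18 dB
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 40.0 * t)
        y = preprocess_traces(x)
        gain = y[200:-200].std() / x[::10][200:-200].std()
        expected = 1.0 / np.sqrt(1.0 + (40.0 / 20.0) ** 6)
        # filtfilt applies the filter twice
        assert gain == pytest.approx(expected**2, rel=0.1)

    def test_output_rate(self):
        y = preprocess_traces(np.zeros(5000))
        assert len(y) == 500  # 1 kHz -> 100 Hz

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_traces(np.zeros(500))


class TestAreaSource:
    def test_zero_and_constant_traces_give_zero_source(self, rest_traces):
        import copy

        tr = copy.copy(rest_traces)
        tr.rates = np.zeros_like(rest_traces.rates)
        assert np.all(area_source_signal(tr, 1) == 0.0)
        tr.rates = np.full_like(rest_traces.rates, 7.0)
        assert area_source_signal(tr, 2) == pytest.approx(0.0)

    def test_source_inherits_pure_oscillation_spectrum(self, rest_traces):
        # constant rates everywhere except a pure 10 Hz pacemaker rhythm:
        # the area average must peak at exactly that frequency
        import copy

        from scipy.signal import welch

        tr = copy.copy(rest_traces)
        tr.rates = np.full_like(rest_traces.rates, 5.0)
        t = np.arange(tr.n_steps) * tr.dt
        tr.rates[:, :, tr.node_names.index("Cx1.IGIB")] = 20.0 + 10.0 * np.sin(
            2 * np.pi * 10.0 * t
        )
        src = area_source_signal(tr, 1)[0]
        f, p = welch(src, fs=1000, nperseg=2048)
        band = (f >= 2) & (f <= 30)
        assert f[band][np.argmax(p[band])] == pytest.approx(10.0, abs=0.5)


class TestPinkNoise:
    def test_spectral_slope(self, rng):
        x = make_pink_noise(2**15, rng)
        f = np.fft.rfftfreq(len(x), d=0.01)
        p = np.abs(np.fft.rfft(x)) ** 2
        sel = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_independent_realizations(self, rng):
        a = make_pink_noise(10_000, rng)
        b = make_pink_noise(10_000, rng)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.05

    def test_zero_mean_unit_sd(self, rng):
        x = make_pink_noise(4096, rng)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0)


class TestProjection:
    def test_linearity_without_noise(self, rng):
        t = np.arange(300) / EEG_SFREQ
        sig = np.sin(2 * np.pi * 10 * t)[None, :].repeat(3, axis=0)
        sig *= np.array([[1.0], [0.5], [2.0]])
        e1 = project(sig, rng, noise_sources=0)
        e2 = project(3.0 * sig, rng, noise_sources=0)
        # signals are z-scored before projection, so scaling is invariant
        np.testing.assert_allclose(e1.data, e2.data, atol=1e-12)

    def test_single_source_common_frequency(self, rng):
        t = np.arange(500) / EEG_SFREQ
        src = np.sin(2 * np.pi * 11 * t)[None, :]
        eeg = project(src, rng, noise_sources=0)
        spec = np.abs(np.fft.rfft(eeg.data, axis=1))
        f = np.fft.rfftfreq(eeg.data.shape[1], 1 / EEG_SFREQ)
        # amplitudes proportional to the lead-field column (single-stream
        # projections use the sphere-dipole kernel)
        pos, (mapping, scale) = area_source_positions(1)
        g = (lead_field(pos, kernel="sphere_dipole") * scale).sum(axis=1)
        amp = eeg.data.std(axis=1)
        ratio = amp / np.abs(g)
        assert ratio.std() / ratio.mean() < 1e-6
        # every electrode with non-negligible gain oscillates at 11 Hz
        strong = np.abs(g) > 0.05 * np.abs(g).max()
        assert np.all(f[np.argmax(spec[strong], axis=1)] == pytest.approx(11.0, abs=0.5))

    def test_left_sources_lateralize_rms(self, rng):
        # left-hemisphere-only activity: more RMS over left electrodes
        t = np.arange(400) / EEG_SFREQ
        sig = np.zeros((6, 400))
        sig[:3] = np.sin(2 * np.pi * 10 * t)  # left-stream areas only
        eeg = project(sig, rng, hemispheres=2, noise_sources=0)
        names = list(eeg.ch_names)
        left = [i for i, n in enumerate(names) if n.endswith(("1", "3", "5", "7", "9")) and n[0] != "I"]
        right = [i for i, n in enumerate(names) if n.endswith(("2", "4", "6", "8", "0"))]
        rms = eeg.data.std(axis=1)
        assert rms[left].mean() > 1.5 * rms[right].mean()

    def test_noise_only_output(self, rng):
        src = np.zeros((3, 300))
        eeg = project(src, rng, noise_sources=5)
        assert eeg.data.std() > 0.0

    def test_full_chain_shapes(self, rest_traces, rng):
        eeg = traces_to_eeg(rest_traces, 0, rng)
        assert eeg.data.shape[0] == 64
        assert eeg.sfreq == EEG_SFREQ
        assert eeg.data.shape[1] == rest_traces.n_steps // 10


class TestLeadFieldIO:
    def test_round_trip(self, tmp_path, montage):
        from corticowave.eeg import load_lead_field, save_lead_field

        pos, (mapping, scale) = area_source_positions()
        G = lead_field(pos, kernel="sphere_dipole")
        path = str(tmp_path / "leadfield.json")
        save_lead_field(path, G, list(montage.ch_names), [f"s{i}" for i in range(6)])
        G2, chs, labels = load_lead_field(path)
        np.testing.assert_allclose(G, G2)
        assert chs == list(montage.ch_names)
        assert labels == [f"s{i}" for i in range(6)]
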