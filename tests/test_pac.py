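"""Phase/amplitude extraction and Tort modulation-index machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacstim import pac, spectral
from pacstim.simulate import inject_pac

FS = 1024.0


def mi_oracle(phase, amp, n_bins=18):
    """Brute-force reference: explicit per-bin loops over histogram edges."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        if j < n_bins - 1:
            sel = (phase >= edges[j]) & (phase < edges[j + 1])
        else:
            sel = (phase >= edges[j]) & (phase <= edges[j + 1])
        means.append(amp[sel].mean() if sel.any() else 0.0)
    p = np.array(means) / np.sum(means)
    h = -sum(pj * np.log(pj) for pj in p if pj > 0)
    return (np.log(n_bins) - h) / np.log(n_bins)


@pytest.fixture(scope="module")
def tone_scalogram():
    t = np.arange(0, 12, 1 / FS)
    x = np.sin(2 * np.pi * 4 * t)
    params = spectral.WaveletParams(frequency_grid=spectral.log_grid(1, 64, 8))
    return t, x, spectral.morlet_cwt(x, FS, params)


class TestPhaseExtraction:
    def test_unwrapped_slope_is_2pi_f(self, tone_scalogram):
        t, _, scal = tone_scalogram
        ph = np.unwrap(pac.extract_phase(scal, 4.0))
        valid = scal.coi_valid()[:, scal.freq_index(4.0)]
        slope = np.polyfit(t[valid], ph[valid], 1)[0]
        assert slope / (2 * np.pi) == pytest.approx(4.0, rel=1e-3)

    def test_cosine_reference_convention(self):
        """A pure cosine has phase ~0 at its maxima (angle of the analytic
        coefficient); a sine lags it by pi/2."""
        t = np.arange(0, 12, 1 / FS)
        x = np.cos(2 * np.pi * 4 * t)
        scal = spectral.morlet_cwt(x, FS, spectral.WaveletParams(frequency_grid=np.array([4.0])))
        ph = pac.extract_phase(scal, 4.0)
        maxima = np.nonzero(np.isclose(np.mod(t, 0.25), 0.0, atol=1e-9))[0]
        maxima = maxima[scal.coi_valid()[maxima, 0]]
        assert np.allclose(ph[maxima], 0.0, atol=0.02)

    def test_conjugation_negates_phase(self, tone_scalogram):
        _, _, scal = tone_scalogram
        ph = pac.extract_phase(scal, 4.0)
        conj = scal.coefficients[:, scal.freq_index(4.0)].conj()
        assert np.allclose(np.angle(conj), -ph, atol=1e-12)

    def test_frequency_not_on_grid_raises(self, tone_scalogram):
        _, _, scal = tone_scalogram
        with pytest.raises(ValueError, match="grid"):
            pac.extract_phase(scal, 5.37)


class TestAmplitudeExtraction:
    def test_zero_signal(self):
        scal = spectral.morlet_cwt(np.zeros(4096), FS, spectral.WaveletParams(frequency_grid=np.array([10.0])))
        assert np.allclose(pac.extract_amplitude(scal, 10.0), 0.0)

    def test_initial_phase_invariance_and_scaling(self):
        t = np.arange(0, 8, 1 / FS)
        params = spectral.WaveletParams(frequency_grid=np.array([10.0]))
        a0 = pac.extract_amplitude(spectral.morlet_cwt(np.sin(2 * np.pi * 10 * t), FS, params), 10.0)
        a1 = pac.extract_amplitude(spectral.morlet_cwt(np.sin(2 * np.pi * 10 * t + 1.3), FS, params), 10.0)
        a2 = pac.extract_amplitude(spectral.morlet_cwt(2 * np.sin(2 * np.pi * 10 * t), FS, params), 10.0)
        valid = slice(int(2 * FS), int(6 * FS))
        assert np.allclose(a0[valid], a1[valid], rtol=1e-3)
        assert np.allclose(a2[valid], 2 * a0[valid], rtol=1e-9)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 10_000)
        assert pac.modulation_index(phase, np.ones_like(phase)) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_concentration_gives_one(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 10_000)
        amp = np.where((phase > -np.pi) & (phase <= -np.pi + np.pi / 9), 1.0, 0.0)
        assert pac.modulation_index(phase, amp) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 50_000)
        amp = 1.0 + 0.8 * np.sin(phase)
        mi = pac.modulation_index(phase, amp)
        assert mi == pytest.approx(mi_oracle(phase, amp), abs=1e-12)
        assert 0.0 < mi < 1.0

    def test_monotone_in_modulation_depth(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        mis = [pac.modulation_index(phase, 1.0 + chi * np.sin(phase)) for chi in np.linspace(0, 1, 11)]
        assert np.all(np.diff(mis) >= 0)

    @given(c=st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=30)
    def test_amplitude_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1.0 + 0.5 * np.sin(phase)
        assert pac.modulation_index(phase, c * amp) == pytest.approx(
            pac.modulation_index(phase, amp), abs=1e-12
        )

    def test_bin_aligned_rotation_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        amp = 1.0 + 0.7 * np.cos(phase)
        rotated = np.angle(np.exp(1j * (phase + 2 * np.pi / 18)))
        assert pac.modulation_index(rotated, amp) == pytest.approx(
            pac.modulation_index(phase, amp), abs=1e-12
        )

    def test_all_zero_amplitude_raises(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 1000)
        with pytest.raises(ValueError, match="zero"):
            pac.modulation_index(phase, np.zeros_like(phase))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="n_bins"):
            pac.modulation_index(np.zeros(5), np.ones(5), n_bins=18)


class TestComodulogram:
    @pytest.fixture(scope="class")
    def pac_signal(self):
        fs = 2048.0
        rng = np.random.default_rng(7)
        n = int(30 * fs)
        x = inject_pac(np.zeros(n), fs, (0, 30), 1.0, 100.0, 0.9, 5.0)
        x += 0.5 * rng.standard_normal(n)
        params = pac.ComodulogramParams()
        grid = np.unique(np.concatenate([params.phase_freqs, params.amp_freqs]))
        scal = spectral.morlet_cwt(x, fs, spectral.WaveletParams(frequency_grid=grid))
        return scal, params

    def test_argmax_at_injected_cell(self, pac_signal):
        scal, params = pac_signal
        com = pac.comodulogram(scal, params)
        fp, fa = com.argmax_cell()
        # nearest grid cells (log distance) to the injected (1, 100) Hz
        assert fp == pytest.approx(min(params.phase_freqs, key=lambda f: abs(np.log(f / 1.0))))
        assert fa == pytest.approx(min(params.amp_freqs, key=lambda f: abs(np.log(f / 100.0))))

    def test_default_grid_and_bins(self, pac_signal):
        _, params = pac_signal
        assert params.n_phase_bins == 18  # 20-degree bins
        assert params.phase_freqs[0] == 1.0 and params.phase_freqs[-1] == 32.0
        assert params.amp_freqs[0] == 32.0 and params.amp_freqs[-1] == 512.0
        assert params.window * params.phase_freqs.min() >= 4.0  # >= 4 cycles at the floor

    def test_windowed_matches_per_window_recompute(self, pac_signal):
        """Streaming implementation equals naive MI on every window slice."""
        scal, params = pac_signal
        com = pac.comodulogram(scal, params)
        fs = scal.sample_rate
        win = int(round(params.window * fs))
        coi = scal.coi_valid()
        for w_idx in [0, len(com.window_starts) // 2, -1]:
            i0 = int(round(com.window_starts[w_idx] * fs))
            for ip in [0, 10]:
                for ia in [3, 12]:
                    jp = scal.freq_index(params.phase_freqs[ip])
                    ja = scal.freq_index(params.amp_freqs[ia])
                    sl = slice(i0, i0 + win)
                    vv = coi[sl, jp] & coi[sl, ja]
                    expected = pac.modulation_index(
                        np.angle(scal.coefficients[sl, jp])[vv],
                        np.abs(scal.coefficients[sl, ja])[vv],
                        params.n_phase_bins,
                    )
                    assert com.mi[w_idx, ip, ia] == pytest.approx(expected, abs=1e-12)

    def test_white_noise_below_surrogate_null(self, rng):
        fs = 512.0
        n = int(30 * fs)
        x = rng.standard_normal(n)
        grid = np.array([2.0, 80.0])
        scal = spectral.morlet_cwt(x, fs, spectral.WaveletParams(frequency_grid=grid))
        valid = scal.coi_valid().all(axis=1)
        ph = pac.extract_phase(scal, 2.0)[valid]
        am = pac.extract_amplitude(scal, 80.0)[valid]
        mi = pac.modulation_index(ph, am)
        thr = pac.surrogate_threshold(ph, am, fs, n_surrogates=100, seed=0)
        assert mi < thr

    def test_fully_masked_window_omitted(self, pac_signal):
        scal, params = pac_signal
        mask = spectral.EpochMask.from_intervals(len(scal.times), scal.sample_rate, [(10.0, 16.0)])
        com = pac.comodulogram(scal, params, mask)
        # windows fully inside the masked span are absent, not NaN rows
        for t0 in com.window_starts:
            assert not (10.0 <= t0 and t0 + params.window <= 16.0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="cycles"):
            pac.ComodulogramParams(window=2.0)


class TestSurrogateThreshold:
    def test_coupled_pair_exceeds_threshold(self, rng):
        fs = 256.0
        t = np.arange(0, 30, 1 / fs)
        # drifting instantaneous frequency so circular shifts cannot realign
        inst_f = 1.0 + 0.2 * np.sin(2 * np.pi * 0.07 * t)
        phase = np.angle(np.exp(1j * 2 * np.pi * np.cumsum(inst_f) / fs))
        amp = 1.0 + 0.9 * np.sin(phase) + 0.05 * rng.standard_normal(t.size)
        amp = np.clip(amp, 0, None)
        mi = pac.modulation_index(phase, amp)
        thr = pac.surrogate_threshold(phase, amp, fs, n_surrogates=100, seed=1)
        assert mi > thr

    def test_deterministic_given_seed(self, rng):
        fs = 256.0
        phase = rng.uniform(-np.pi, np.pi, int(10 * fs))
        amp = rng.random(phase.size) + 0.1
        t1 = pac.surrogate_threshold(phase, amp, fs, n_surrogates=50, seed=9)
        t2 = pac.surrogate_threshold(phase, amp, fs, n_surrogates=50, seed=9)
        assert t1 == t2

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(ValueError, match="19"):
            pac.surrogate_threshold(np.zeros(1000), np.ones(1000), 256.0, n_surrogates=5)
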