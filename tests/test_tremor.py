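"""Spectral band finding, Hilbert amplitude/phase, correlation matrices."""

import numpy as np
import pytest

from oracles import circular_corr_pairwise, moving_average_bruteforce
from mocapkit.tremor import (
    band_hilbert,
    circular_correlation,
    find_tremor_band,
    power_spectrum,
    smooth_spectrum,
    tremor_correlations,
    tremor_profiles,
    tremor_summary,
    windowed_amplitude,
    TremorProfile,
)

FS = 300.0


def _sine(f, amp=1.0, duration=20.0, phase=0.0):
    t = np.arange(int(duration * FS)) / FS
    return amp * np.sin(2 * np.pi * f * t + phase)


class TestPowerSpectrum:
    def test_sinusoid_peak_and_parseval(self):
        a = 0.5
        freqs, pxx = power_spectrum(_sine(10.0, a), FS)
        assert freqs[np.argmax(pxx)] == pytest.approx(10.0, abs=0.5)
        band_power = np.trapezoid(pxx, freqs)
        assert band_power == pytest.approx(a**2 / 2, rel=0.1)

    def test_out_of_band_sinusoid_rejected(self):
        freqs, pxx = power_spectrum(_sine(5.0, 1.0), FS)
        assert np.trapezoid(pxx, freqs) < 1e-3 * 0.5

    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(5):
            _, pxx = power_spectrum(rng.normal(0, 1, int(60 * FS)), FS)
            ratios.append(pxx.max() / pxx.mean())
        assert np.mean(ratios) < 3.0  # no dominant line

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="short"):
            power_spectrum(np.zeros(100), FS)

    def test_gap_rejected(self):
        sig = _sine(10.0)
        sig[10] = np.nan
        with pytest.raises(ValueError, match="gap-free"):
            power_spectrum(sig, FS)


class TestSmoothSpectrum:
    FREQS = np.linspace(6, 18, 97)

    def test_smooth_unimodal_near_identity(self):
        p = np.exp(-0.5 * ((self.FREQS - 10) / 1.5) ** 2)
        sm = smooth_spectrum(self.FREQS, p)
        assert np.max(np.abs(sm - p)) < 0.01 * p.max()

    def test_noisy_peak_argmax_within_one_bin(self):
        rng = np.random.default_rng(1)
        clean = np.exp(-0.5 * ((self.FREQS - 11) / 1.0) ** 2)
        noisy = clean + rng.normal(0, 0.04, clean.shape)
        sm = smooth_spectrum(self.FREQS, noisy)
        df = self.FREQS[1] - self.FREQS[0]
        assert abs(self.FREQS[np.argmax(sm)] - 11.0) <= 1.5 * df

    def test_flat_stays_flat_and_nonnegative(self):
        sm = smooth_spectrum(self.FREQS, np.full_like(self.FREQS, 2.0))
        np.testing.assert_allclose(sm, 2.0, atol=1e-6)
        assert (smooth_spectrum(self.FREQS, np.zeros_like(self.FREQS)) >= 0).all()


class TestFindTremorBand:
    FREQS = np.linspace(6, 18, 97)

    def test_gaussian_peak_symmetric_band(self):
        p = np.exp(-0.5 * ((self.FREQS - 10) / 1.0) ** 2)
        (lo, hi), peak = find_tremor_band(self.FREQS, p)
        assert peak == pytest.approx(10.0, abs=0.13)
        df = self.FREQS[1] - self.FREQS[0]
        assert (10 - lo) == pytest.approx(hi - 10, abs=1.5 * df)
        assert lo < 10 < hi

    def test_bimodal_band_bounded_by_interpeak_minimum(self):
        p = (
            np.exp(-0.5 * ((self.FREQS - 12) / 0.8) ** 2)
            + 0.6 * np.exp(-0.5 * ((self.FREQS - 7.5) / 0.8) ** 2)
        )
        (lo, hi), peak = find_tremor_band(self.FREQS, p)
        assert peak == pytest.approx(12.0, abs=0.13)
        assert lo > 7.5  # second peak excluded
        assert hi > 12.0

    def test_flat_psd_no_band(self):
        assert find_tremor_band(self.FREQS, np.ones_like(self.FREQS)) is None

    def test_monotone_psd_no_band(self):
        assert find_tremor_band(self.FREQS, np.linspace(0, 1, len(self.FREQS))) is None

    def test_fallback_triggers_on_shoulder_without_derivative_dip(self):
        # a peak riding a steep ramp keeps |dP/df| above threshold on one
        # side, so the derivative walk fails and flanking minima take over
        p = np.exp(-0.5 * ((self.FREQS - 10) / 0.6) ** 2) + 0.3 * np.sin(
            (self.FREQS - 6) * 2.0
        ) ** 2
        got = find_tremor_band(self.FREQS, p)
        assert got is not None
        (lo, hi), peak = got
        assert lo < peak < hi


class TestBandHilbert:
    def test_in_band_sinusoid_amplitude_and_phase_rate(self):
        f, a = 10.0, 0.7
        amp, phase, valid = band_hilbert(_sine(f, a), (8, 12), FS)
        assert np.abs(amp[valid] - a).max() < 0.02 * a
        rate = np.diff(np.unwrap(phase))[valid[1:]] * FS / (2 * np.pi)
        assert np.median(rate) == pytest.approx(f, rel=0.01)

    def test_am_envelope_tracked(self):
        t = np.arange(int(30 * FS)) / FS
        env = 1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * t)
        sig = env * np.sin(2 * np.pi * 10.0 * t)
        amp, _, valid = band_hilbert(sig, (8, 12), FS)
        assert np.abs(amp[valid] - env[valid]).max() < 0.05 * env.max()

    def test_out_of_band_rejected(self):
        amp, _, valid = band_hilbert(_sine(3.0, 1.0), (8, 12), FS)
        assert np.abs(amp[valid]).max() < 0.01

    def test_band_outside_nyquist_errors(self):
        with pytest.raises(ValueError):
            band_hilbert(_sine(10.0), (8, 200), FS)

    def test_edge_margin_flagged(self):
        _, _, valid = band_hilbert(_sine(10.0, duration=4.0), (8, 12), FS)
        assert not valid[: int(1.0 * FS)].any()
        assert not valid[-int(1.0 * FS):].any()
        assert valid[int(1.0 * FS): -int(1.0 * FS)].all()


class TestWindowedAmplitude:
    def test_constant(self):
        out = windowed_amplitude(np.full(1000, 0.3), 150)
        np.testing.assert_allclose(out, 0.3)

    def test_step_ramp_width(self):
        a = np.concatenate([np.ones(500), 2 * np.ones(500)])
        out = windowed_amplitude(a, 150)
        in_ramp = (out > 1.001) & (out < 1.999)
        assert in_ramp.sum() == pytest.approx(150, abs=2)

    def test_matches_bruteforce(self, rng):
        a = rng.gamma(2.0, 0.2, size=777)
        for w in (10, 150, 151):
            np.testing.assert_allclose(
                windowed_amplitude(a, w), moving_average_bruteforce(a, w), atol=1e-10
            )


class TestCorrelations:
    @staticmethod
    def _profile(marker, axis, amp, phase):
        valid = np.ones(len(amp), bool)
        return TremorProfile(marker, axis, (8.0, 12.0), 10.0, amp, phase, valid,
                             float(amp.mean()))

    def test_identical_oscillators_fully_correlated(self, rng):
        t = np.arange(3000) / FS
        amp = 1 + 0.3 * np.sin(2 * np.pi * 0.2 * t)
        phase = np.angle(np.exp(1j * 2 * np.pi * 10 * t))
        a = self._profile("a", "z", amp, phase)
        b = self._profile("b", "z", amp.copy(), phase.copy())
        cm = tremor_correlations([a, b])
        assert cm.amplitude_corr[0, 1] == pytest.approx(1.0)
        assert cm.phase_corr[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_envelopes_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 9000
        t = np.arange(n) / FS

        def env(seed):
            r = np.random.default_rng(seed)
            return 1 + 0.3 * np.convolve(
                r.normal(0, 1, n), np.ones(10) / 10, mode="same"
            )

        phase = np.angle(np.exp(1j * 2 * np.pi * 10 * t))
        rs = []
        for sa, sb in ((1, 2), (3, 4), (5, 6)):
            a = self._profile("a", "z", env(sa), phase)
            b = self._profile("b", "z", env(sb), phase.copy())
            rs.append(tremor_correlations([a, b]).amplitude_corr[0, 1])
        assert max(abs(r) for r in rs) < 0.1

    def test_antiphase_plus_one_by_convention(self):
        # a fixed phase offset (including pi) is perfect circular association
        t = np.arange(3000) / FS
        pa = np.angle(np.exp(1j * 2 * np.pi * 10 * t))
        pb = np.angle(np.exp(1j * (2 * np.pi * 10 * t + np.pi)))
        amp = np.ones(3000)
        cm = tremor_correlations(
            [self._profile("a", "z", amp, pa), self._profile("b", "z", amp.copy(), pb)]
        )
        assert cm.phase_corr[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_reflected_phases_minus_one(self):
        t = np.arange(3000) / FS
        pa = np.angle(np.exp(1j * (2 * np.pi * 10 * t + 0.3 * np.sin(t))))
        assert circular_correlation(pa, -pa) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_pairwise_definition(self, rng):
        a = rng.uniform(-np.pi, np.pi, 120)
        b = 0.7 * a + rng.normal(0, 0.5, 120)
        b = np.angle(np.exp(1j * b))
        assert circular_correlation(a, b) == pytest.approx(
            circular_corr_pairwise(a, b), abs=1e-9
        )

    def test_matrix_structure(self, tremor_trial):
        trial, _ = tremor_trial
        profiles = tremor_profiles(trial, markers=["hip_l", "knee_l"])
        cm = tremor_correlations(profiles)
        for m in (cm.amplitude_corr, cm.phase_corr):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(m), 1.0)
            finite = np.isfinite(m)
            assert (np.abs(m[finite]) <= 1 + 1e-9).all()

    def test_constant_series_flagged_nan(self):
        amp = np.ones(3000)
        phase = np.zeros(3000)
        varying = 1 + 0.2 * np.sin(np.arange(3000) / 40)
        cm = tremor_correlations(
            [self._profile("a", "z", amp, phase),
             self._profile("b", "z", varying, phase.copy())]
        )
        assert np.isnan(cm.amplitude_corr[0, 1])


class TestTremorSummary:
    def test_whole_body_frequency_and_amplitude_recovered(self, tremor_trial):
        trial, truth = tremor_trial
        summary = tremor_summary(trial)
        for lab, d in summary["per_marker"].items():
            assert d["peak_frequency_hz"] == pytest.approx(
                truth.tremor["frequency_hz"], abs=0.5
            )
            assert d["mean_amplitude_mm"] == pytest.approx(
                truth.tremor["amplitude_mm"][lab], rel=0.05
            )

    def test_no_tremor_injected_no_band(self):
        from mocapkit.fixtures import tremor_trial_config
        from mocapkit.synthetic import generate_trial

        cfg = tremor_trial_config(seed=9, duration_s=10.0, noise_sd_mm=0.0)
        cfg.tremor_model.enabled = False
        trial, _ = generate_trial(cfg)
        profiles = tremor_profiles(trial, markers=["hip_l", "shoulder_r"])
        assert all(p.band is None for p in profiles)

    def test_amplitude_scaling_between_markers(self):
        # double the oscillation on one marker and its mean amplitude doubles
        from mocapkit.fixtures import tremor_trial_config
        from mocapkit.synthetic import generate_trial

        cfg = tremor_trial_config(seed=10, duration_s=20.0)
        trial, _ = generate_trial(cfg)
        boosted = trial.markers["hip_l"]
        base = boosted.positions - boosted.positions.mean(axis=0)
        boosted.positions = boosted.positions.mean(axis=0) + 2 * base
        summary = tremor_summary(trial, markers=["hip_l", "hip_r"])
        ratio = (
            summary["per_marker"]["hip_l"]["mean_amplitude_mm"]
            / summary["per_marker"]["hip_r"]["mean_amplitude_mm"]
        )
        assert ratio == pytest.approx(2.0, rel=0.05)
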