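"""Unit and property tests for the broadband spectral pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seegtag.spectral import (
    EpochedTrials,
    SpectralError,
    TrialSpectra,
    ZSpectrum,
    compute_itpc,
    epoch_trials,
    extract_band,
    rayleigh_p,
    rayleigh_z,
    remove_baseline,
    trial_spectra,
    trim_transient,
    value_at_frequency,
    zspectrum_from_epochs,
)

SFREQ = 512.0


def _epochs(data, window=(-0.5, 10.0), sfreq=SFREQ):
    return EpochedTrials(np.atleast_2d(data), sfreq, window)


def naive_itpc(data: np.ndarray) -> np.ndarray:
    """Brute-force oracle: per-trial DFT coefficients by direct summation,
    then the magnitude of the mean unit phasor per bin."""
    n_trials, n = data.shape
    t = np.arange(n)
    n_bins = n // 2 + 1
    out = np.empty(n_bins)
    for k in range(n_bins):
        coeff = data @ np.exp(-2j * np.pi * k * t / n)
        phasors = coeff / np.abs(coeff)
        out[k] = np.abs(phasors.mean())
    return out


class TestEpoching:
    def test_epoch_count_and_length(self):
        sig = np.zeros(int(600 * SFREQ))
        onsets = 5.0 + np.arange(40) * 12.0
        ep = epoch_trials(sig, SFREQ, onsets)
        assert ep.n_trials == 40
        assert ep.data.shape[1] == int(10.5 * SFREQ)

    def test_trial_near_edge_dropped(self):
        sig = np.zeros(int(60 * SFREQ))
        onsets = [0.2, 15.0, 30.0]  # first needs samples before t=0
        ep = epoch_trials(sig, SFREQ, onsets)
        assert ep.n_trials == 2

    def test_empty_window_rejected(self):
        with pytest.raises(SpectralError, match="window"):
            epoch_trials(np.zeros(1000), SFREQ, [1.0], window=(0.0, 0.0))

    def test_all_trials_outside_is_error(self):
        with pytest.raises(SpectralError, match="no usable trials"):
            epoch_trials(np.zeros(100), SFREQ, [50.0])

    def test_trial_order_preserved(self):
        sig = np.arange(int(100 * SFREQ), dtype=float)
        onsets = [40.0, 20.0]  # deliberately out of time order
        ep = epoch_trials(sig, SFREQ, onsets, window=(0.0, 1.0))
        assert ep.data[0, 0] > ep.data[1, 0]


class TestBaselineAndTrim:
    def test_constant_trial_becomes_zero(self):
        ep = _epochs(np.full((3, int(10.5 * SFREQ)), 7.5))
        out = remove_baseline(ep)
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_baseline_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, int(10.5 * SFREQ)))
        ep = _epochs(data)
        t = ep.times
        data[:, (t >= -0.5) & (t < 0)] -= data[:, (t >= -0.5) & (t < 0)].mean(
            axis=1, keepdims=True)
        out = remove_baseline(_epochs(data))
        assert np.allclose(out.data, data)

    def test_offset_removed_sinusoid_preserved(self):
        t = np.arange(int(10.5 * SFREQ)) / SFREQ - 0.5
        sine = np.sin(2 * np.pi * 4 * t)
        # sinusoid has (near) zero mean over the half-integer baseline span
        ep = _epochs(2.0 + sine)
        out = remove_baseline(ep)
        assert np.allclose(out.data[0], sine, atol=1e-2)
        assert abs(out.data[0].mean() - sine.mean()) < 1e-2

    def test_missing_baseline_window_is_error(self):
        ep = _epochs(np.zeros((2, int(10 * SFREQ))), window=(0.0, 10.0))
        with pytest.raises(SpectralError, match="baseline"):
            remove_baseline(ep)

    @pytest.mark.parametrize("sfreq,n_expected", [(512.0, 4608), (2048.0, 18432)])
    def test_segment_sample_counts(self, sfreq, n_expected):
        ep = _epochs(np.zeros((2, int(10.5 * sfreq))), sfreq=sfreq)
        out = trim_transient(ep)
        assert out.data.shape[1] == n_expected
        assert out.data.shape[1] / sfreq == 9.0

    def test_short_segment_is_error(self):
        ep = _epochs(np.zeros((2, 100)), window=(-0.5, 10.0), sfreq=8.0)
        with pytest.raises(SpectralError):
            trim_transient(ep, (1.0, 20.0))


class TestTrialSpectra:
    def test_bin_spacing_prints_as_0_11(self):
        ep = _epochs(np.zeros((2, 4608)), window=(1.0, 10.0))
        sp = trial_spectra(ep)
        spacing = sp.freqs[1] - sp.freqs[0]
        assert spacing == pytest.approx(1.0 / 9.0)
        assert round(spacing, 2) == 0.11

    def test_pure_4hz_lands_in_bin_36(self):
        t = np.arange(4608) / SFREQ
        ep = _epochs(np.sin(2 * np.pi * 4 * t), window=(1.0, 10.0))
        sp = trial_spectra(ep)
        mags = np.abs(sp.coeffs[0])
        assert np.argmax(mags) == 36
        assert sp.freqs[36] == pytest.approx(4.0)
        others = np.delete(mags, 36)
        assert others.max() < 1e-6 * mags[36]

    def test_zero_trials_give_zero_coefficients(self):
        ep = _epochs(np.zeros((2, 4608)), window=(1.0, 10.0))
        assert np.all(trial_spectra(ep).coeffs == 0)


class TestITPC:
    def _spectra_from_phases(self, phases):
        coeffs = np.exp(1j * np.asarray(phases))[:, None]
        return TrialSpectra(coeffs, np.array([4.0]))

    @pytest.mark.parametrize("phases,expected", [
        ([0, 0, 0, 0], 1.0),
        ([0, np.pi / 2, np.pi, 3 * np.pi / 2], 0.0),
        ([0, 0, np.pi], 1.0 / 3.0),
    ])
    def test_hand_cases(self, phases, expected):
        itpc = compute_itpc(self._spectra_from_phases(phases))
        assert itpc[0] == pytest.approx(expected, abs=1e-12)

    def test_fft_path_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            data = rng.standard_normal((8, 64))
            ep = EpochedTrials(data, 64.0, (0.0, 1.0))
            itpc = compute_itpc(trial_spectra(ep))
            expected = naive_itpc(data)
            np.testing.assert_allclose(itpc, expected, atol=1e-10)

    def test_zero_coefficient_bin_flagged_undefined(self):
        coeffs = np.array([[1 + 0j, 0 + 0j], [1j, 1 + 1j]])
        itpc = compute_itpc(TrialSpectra(coeffs, np.array([1.0, 2.0])))
        assert not np.isnan(itpc[0])
        assert np.isnan(itpc[1])

    def test_identical_trials_give_unit_itpc(self, rng):
        trial = rng.standard_normal(128)
        data = np.tile(trial, (6, 1))
        itpc = compute_itpc(trial_spectra(EpochedTrials(data, 64.0, (0.0, 2.0))))
        nonzero = np.abs(np.fft.rfft(trial)) > 1e-9
        assert np.allclose(itpc[nonzero], 1.0)

    def test_needs_two_trials(self):
        with pytest.raises(SpectralError):
            compute_itpc(TrialSpectra(np.ones((1, 4), complex), np.arange(4.0)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariances(self, seed):
        """ITPC is invariant under common phase rotation of all trials and
        under positive per-trial amplitude scaling, and lies in [0, 1]."""
        r = np.random.default_rng(seed)
        data = r.standard_normal((6, 32))
        base = compute_itpc(trial_spectra(EpochedTrials(data, 32.0, (0.0, 1.0))))
        assert np.nanmin(base) >= 0.0 and np.nanmax(base) <= 1.0
        # positive per-trial scaling
        scaled = data * r.uniform(0.1, 10.0, size=(6, 1))
        s = compute_itpc(trial_spectra(EpochedTrials(scaled, 32.0, (0.0, 1.0))))
        np.testing.assert_allclose(s, base, atol=1e-9)
        # common phase rotation, applied in the spectral domain
        sp = trial_spectra(EpochedTrials(data, 32.0, (0.0, 1.0)))
        rot = TrialSpectra(sp.coeffs * np.exp(1j * r.uniform(0, 2 * np.pi)),
                           sp.freqs)
        np.testing.assert_allclose(compute_itpc(rot), base, atol=1e-9)


class TestRayleighZ:
    @pytest.mark.parametrize("itpc,n,expected", [
        (0.0, 40, 0.0),
        (1.0, 40, 40.0),
        (1.0 / 3.0, 3, 1.0 / 3.0),
    ])
    def test_examples(self, itpc, n, expected):
        assert rayleigh_z(itpc, n) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(SpectralError):
            rayleigh_z(1.5, 10)
        with pytest.raises(SpectralError):
            rayleigh_z(0.5, 1)

    def test_null_mean_is_one(self, rng):
        """Uniform random phases: E[n R^2] = 1."""
        zs = []
        for _ in range(2000):
            phases = rng.uniform(0, 2 * np.pi, size=40)
            r = np.abs(np.exp(1j * phases).mean())
            zs.append(rayleigh_z(r, 40))
        assert np.mean(zs) == pytest.approx(1.0, abs=0.05)

    def test_p_value_matches_null_simulation(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(20000, 40))
        z = 40 * np.abs(np.exp(1j * phases).mean(axis=1)) ** 2
        for z0 in (2.0, 3.0, 4.0):
            emp = (z >= z0).mean()
            assert rayleigh_p(z0, 40) == pytest.approx(emp, abs=3e-3)


class TestBandAndLookup:
    def _zspec(self):
        freqs = np.arange(42) / 9.0
        z = np.arange(42, dtype=float)
        return ZSpectrum(freqs, z / 42, z, 40)

    def test_band_bin_count_and_keeps_tags(self):
        # integers k with 0.5 <= k/9 <= 4.5 are k = 5..40: 36 bins
        out = extract_band(self._zspec(), 0.5, 4.5)
        assert len(out.freqs) == 36
        for tag in (1.0, 2.0, 4.0):
            assert np.any(np.isclose(out.freqs, tag))

    def test_point_band(self):
        out = extract_band(self._zspec(), 4.0, 4.0)
        assert len(out.freqs) == 1
        assert out.freqs[0] == pytest.approx(4.0)

    def test_empty_band_is_error(self):
        with pytest.raises(SpectralError):
            extract_band(self._zspec(), 4.05, 4.06)

    @pytest.mark.parametrize("tag,bin_index", [(4.0, 36), (1.0, 9), (2.0, 18)])
    def test_tag_bins_exact(self, tag, bin_index):
        zs = self._zspec()
        assert value_at_frequency(zs, tag) == zs.z[bin_index]
        assert zs.freqs[bin_index] == pytest.approx(tag)

    def test_out_of_axis_tag_is_error(self):
        with pytest.raises(SpectralError, match="outside"):
            value_at_frequency(self._zspec(), 100.0)


class TestFullPath:
    def test_locked_sinusoid_detected_noise_floor_flat(self, rng):
        """End-to-end: phase-locked 4 Hz across 20 trials gives itpc ~= 1
        at the 4 Hz bin and near-null z elsewhere."""
        n = int(10.5 * SFREQ)
        t = np.arange(n) / SFREQ - 0.5
        stim = (t >= 0) & (t < 10)
        trials = []
        for _ in range(20):
            x = rng.standard_normal(n) * 0.5
            x[stim] += np.sin(2 * np.pi * 4 * t[stim] + 1.0)
            trials.append(x)
        ep = EpochedTrials(np.stack(trials), SFREQ, (-0.5, 10.0))
        zs = zspectrum_from_epochs(ep)
        assert value_at_frequency(zs, 4.0) > 15.0
        band = extract_band(zs, 0.5, 4.5)
        off = band.z[~np.isclose(band.freqs, 4.0)]
        assert np.median(off) < 3.0
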