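"""The 37-feature extractor against closed forms and independent oracles."""

import numpy as np
import pytest

from sleepmem import (
    FEATURE_NAMES,
    FeatureSpec,
    band_powers,
    extract_features,
    higuchi_fd,
    hjorth_features,
    power_ratios,
    spectral_shape,
    time_domain_features,
    wavelet_features,
    zscore_activity_within_subject,
)
from sleepmem.errors import DegenerateSignalError, InsufficientDataError
from sleepmem.features import DEFAULT_BANDS

from conftest import FS, N, make_epoch, noise_epoch, sine_epoch

# ---------------------------------------------------------------- oracles


def higuchi_oracle(x, kmax):
    """Literal transcription of the curve-length algorithm, kept naive."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    log_lk, log_inv_k = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(1, k + 1):  # 1-based offsets as in the original
            n_max = int(np.floor((n - m) / k))
            if n_max < 1:
                continue
            total = 0.0
            for i in range(1, n_max + 1):
                total += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
            lm.append(total * (n - 1) / (n_max * k) / k)
        log_lk.append(np.log(np.mean(lm)))
        log_inv_k.append(np.log(1.0 / k))
    return np.polyfit(log_inv_k, log_lk, 1)[0]


def band_power_oracle(x, fs, low, high):
    """Sum of squared one-sided DFT magnitudes via the full FFT."""
    n = len(x)
    X = np.fft.fft(x)
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * fs / n
        if low <= f < high:
            total += abs(X[k]) ** 2
    return total


# db4 analysis filters, hard-coded from the standard tables (independent
# of the wavelet library's own coefficient source).
DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
DB4_HI = np.array([
    -0.23037781330885523, 0.7148465705525415, -0.6308807679295904,
    -0.02798376941698385, 0.18703481171888114, 0.030841381835986965,
    -0.032883011666982945, -0.010597401784997278,
])


def filter_bank_detail_energies(x, levels):
    """Periodized two-channel filter bank; returns [E(D1)..E(Dlevels)].

    Exact for dyadic-friendly lengths (even at every level); circular
    correlation with the analysis filters, downsampled by two.
    """

    def analysis(sig, filt):
        n = len(sig)
        idx = (np.arange(n)[:, None] + np.arange(len(filt))[None, :] - 3) % n
        return (sig[idx] @ filt[::-1])[::2]

    energies = []
    approx = x
    for _ in range(levels):
        detail = analysis(approx, DB4_HI)
        approx = analysis(approx, DB4_LO)
        energies.append(float((detail**2).sum()))
    return energies  # index 0 = D1 (finest)


# ------------------------------------------------------------ time domain


class TestTimeDomain:
    def test_pure_sine_is_unskewed(self):
        skew, _, _ = time_domain_features(sine_epoch(5.0))
        assert abs(skew) < 1e-8

    def test_sine_kurtosis_is_three_halves(self):
        # Pearson (non-excess) kurtosis of a sinusoid is 1.5.
        _, kurt, _ = time_domain_features(sine_epoch(5.0))
        assert kurt == pytest.approx(1.5, abs=1e-6)

    def test_straight_line_has_dimension_one(self):
        ramp = make_epoch(np.linspace(0.0, 1.0, N))
        _, _, hfd = time_domain_features(ramp)
        assert hfd == pytest.approx(1.0, abs=0.05)

    def test_white_noise_matches_independent_higuchi(self):
        x = noise_epoch(seed=5).samples
        _, _, hfd = time_domain_features(make_epoch(x), hfd_kmax=10)
        assert hfd == pytest.approx(higuchi_oracle(x, 10), abs=0.05)
        assert 1.8 < hfd <= 2.1  # noise-like

    def test_constant_epoch_rejected(self):
        with pytest.raises(DegenerateSignalError):
            time_domain_features(make_epoch(np.ones(N)))

    def test_short_epoch_rejected_for_hfd(self):
        with pytest.raises(InsufficientDataError):
            higuchi_fd(np.arange(5.0), kmax=10)


class TestHjorth:
    def test_sine_activity_is_half_amplitude_squared(self):
        act, _, _ = hjorth_features(sine_epoch(5.0, amplitude=3.0))
        assert act == pytest.approx(9.0 / 2, rel=0.02)

    def test_sine_mobility_and_complexity_closed_form(self):
        freq = 5.0
        omega = 2 * np.pi * freq / FS  # rad/sample
        _, mob, comp = hjorth_features(sine_epoch(freq))
        assert mob == pytest.approx(2 * np.sin(omega / 2), rel=0.02)
        assert comp == pytest.approx(1.0, rel=0.02)

    def test_scaling_moves_only_activity(self):
        x = noise_epoch(seed=1).samples
        a1, m1, c1 = hjorth_features(make_epoch(x))
        a2, m2, c2 = hjorth_features(make_epoch(3.0 * x))
        assert a2 == pytest.approx(9 * a1, rel=1e-12)
        assert m2 == pytest.approx(m1, abs=1e-9)
        assert c2 == pytest.approx(c1, abs=1e-9)


class TestActivityZScore:
    def test_two_point_population_convention(self):
        assert zscore_activity_within_subject(np.array([1.0, 3.0])).tolist() == [-1, 1]

    def test_affine_invariance(self):
        x = np.random.default_rng(2).random(40)
        z1 = zscore_activity_within_subject(x)
        z2 = zscore_activity_within_subject(5.0 * x - 7.0)
        assert np.allclose(z1, z2)

    def test_matches_formula_oracle(self):
        x = np.random.default_rng(3).random(25)
        assert np.allclose(zscore_activity_within_subject(x),
                           (x - x.mean()) / x.std())

    def test_zero_dispersion_gives_zeros(self):
        assert np.all(zscore_activity_within_subject(np.full(10, 2.0)) == 0)


# ------------------------------------------------------- frequency domain


class TestBandPowers:
    def test_in_band_tone_concentrates_power(self):
        powers = band_powers(sine_epoch(2.0))
        assert powers["delta"] / powers["full"] > 0.99

    def test_alpha_tone_maximizes_alpha(self):
        powers = band_powers(sine_epoch(10.0))
        named = {b: powers[b] for b in ("delta", "theta", "alpha", "sigma", "beta")}
        assert max(named, key=named.get) == "alpha"

    def test_noise_matches_dft_bin_sum_oracle(self):
        epoch = noise_epoch(seed=9)
        powers = band_powers(epoch)
        for band, (low, high) in DEFAULT_BANDS.items():
            oracle = band_power_oracle(epoch.samples, FS, low, high)
            assert powers[band] == pytest.approx(oracle, rel=1e-9)


class TestPowerRatios:
    def test_unit_powers_force_known_vector(self):
        powers = dict.fromkeys(("delta", "theta", "alpha", "sigma", "beta"), 1.0)
        assert power_ratios(powers).tolist() == [1, 1, 1, 1, 1, 1, 0.5, 1]

    def test_hand_arithmetic_example(self):
        powers = {"delta": 4.0, "theta": 2.0, "alpha": 1.0, "beta": 1.0,
                  "sigma": 2.0}
        assert power_ratios(powers).tolist() == [4, 4, 2, 2, 2, 0.5, 2, 3]

    def test_homogeneity_of_degree_zero(self):
        rng = np.random.default_rng(4)
        powers = {b: float(v) for b, v in
                  zip(("delta", "theta", "alpha", "sigma", "beta"),
                      rng.random(5) + 0.1)}
        doubled = {b: 2 * v for b, v in powers.items()}
        assert np.allclose(power_ratios(powers), power_ratios(doubled))

    def test_zero_denominator_guarded_not_fatal(self):
        powers = {"delta": 1.0, "theta": 1.0, "alpha": 0.0, "sigma": 1.0,
                  "beta": 0.0}
        ratios = power_ratios(powers)
        assert np.all(np.isfinite(ratios))


class TestSpectralShape:
    def test_single_tone_line_spectrum(self):
        ent, cen, roll = spectral_shape(sine_epoch(10.0))
        bin_hz = FS / N
        assert abs(cen - 10.0) <= bin_hz
        assert abs(roll - 10.0) <= bin_hz
        assert ent < 0.2

    def test_flat_spectrum_maximizes_entropy(self):
        # The unit impulse has unit DFT magnitude in every bin.
        impulse = np.zeros(N)
        impulse[0] = 1.0
        ent, _, _ = spectral_shape(make_epoch(impulse))
        assert ent == pytest.approx(1.0, abs=1e-6)

    def test_two_equal_tones_centroid_midpoint(self):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        _, cen, _ = spectral_shape(make_epoch(x))
        assert abs(cen - 10.0) <= FS / N


# ----------------------------------------------------------------- wavelet


class TestWaveletFeatures:
    def test_relative_energies_sum_to_one(self):
        wav = wavelet_features(noise_epoch(seed=6))
        rels = wav[0::4]
        assert rels.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((rels >= 0) & (rels <= 1))

    def test_delta_tone_lands_in_d5(self):
        wav = wavelet_features(sine_epoch(2.0))
        assert int(np.argmax(wav[0::4])) == 4  # D5

    def test_beta_tone_lands_in_d2(self):
        wav = wavelet_features(sine_epoch(25.0))
        assert int(np.argmax(wav[0::4])) == 1  # D2

    def test_energies_match_filter_bank_oracle(self):
        # fs = 128 Hz gives a 3840-sample epoch, even at all 5 levels,
        # where the periodized transform equals the plain filter bank.
        epoch = noise_epoch(seed=8, fs=128.0)
        wav = wavelet_features(epoch)
        oracle = np.array(filter_bank_detail_energies(epoch.samples, 5))
        assert np.allclose(wav[0::4], oracle / oracle.sum(), rtol=1e-8)


# ------------------------------------------------------------ full vector


class TestFeatureVector:
    def test_exactly_37_named_features(self):
        assert len(FEATURE_NAMES) == 37
        vec = extract_features(noise_epoch(seed=10))
        assert vec.shape == (37,)
        assert np.all(np.isfinite(vec))

    def test_deterministic_for_identical_epochs(self):
        assert np.array_equal(extract_features(noise_epoch(seed=11)),
                              extract_features(noise_epoch(seed=11)))

    def test_amplitude_scaling_moves_only_activity(self):
        x = noise_epoch(seed=12).samples
        v1 = extract_features(make_epoch(x))
        v2 = extract_features(make_epoch(2.0 * x))
        act = FEATURE_NAMES.index("hjorth_activity")
        assert v2[act] == pytest.approx(4 * v1[act], rel=1e-9)
        others = np.delete(np.arange(37), act)
        assert np.allclose(v2[others], v1[others], rtol=1e-6)

    def test_block_structure_of_names(self):
        assert FEATURE_NAMES[:6] == ("skewness", "kurtosis", "hfd",
                                     "hjorth_activity", "hjorth_mobility",
                                     "hjorth_complexity")
        assert FEATURE_NAMES[6:14] == tuple(f"ratio_{i}" for i in range(1, 9))
        assert FEATURE_NAMES[14:17] == ("spectral_entropy", "spectral_centroid",
                                        "spectral_rolloff")
        assert len([n for n in FEATURE_NAMES if n.startswith("D")]) == 20
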