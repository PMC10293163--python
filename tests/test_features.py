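"""Spectral estimation, relative band power, imaginary coherence, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyeeg.features import (
    BandScheme,
    DEFAULT_BANDS,
    SpectralEstimate,
    assemble_features,
    cross_spectra,
    estimate_spectra,
    feature_names,
    imaginary_coherence,
    relative_band_power,
)
from amyeeg.preprocess import EpochSet


def _epochset(data):
    return EpochSet("s", data, data.shape[2] / 250.0, 250.0)


# ---------------------------------------------------------------------------
# Spectral estimation


def test_white_noise_psd_is_flat():
    rng = np.random.default_rng(0)
    es = _epochset(rng.standard_normal((45, 19, 1000)))
    se = estimate_spectra(es)
    assert se.freqs[1] - se.freqs[0] == pytest.approx(0.25)
    masks = DEFAULT_BANDS.masks(se.freqs)
    means = np.array([se.psd[0, m].mean() for m in masks])
    ses = np.array([se.psd[0, m].mean() / np.sqrt(45 * m.sum()) for m in masks])
    grand = means.mean()
    assert np.all(np.abs(means - grand) < 5 * ses)


def test_sinusoid_power_and_peak_bin():
    fs, L, a = 250.0, 1000, 3.0
    t = np.arange(6 * L) / fs
    x = a * np.sin(2 * np.pi * 10.0 * t)
    data = np.tile(x.reshape(6, 1, L), (1, 19, 1))
    se = estimate_spectra(_epochset(data))
    peak = se.freqs[np.argmax(se.psd[0])]
    assert peak == pytest.approx(10.0)
    total = se.psd[0].sum() * 0.25
    assert total == pytest.approx(a ** 2 / 2, rel=0.01)


def test_parseval_within_one_percent():
    rng = np.random.default_rng(1)
    data = 4.0 * rng.standard_normal((100, 19, 1000))
    se = estimate_spectra(_epochset(data))
    for ch in range(3):
        integral = se.psd[ch].sum() * 0.25
        variance = np.mean([np.var(data[e, ch]) for e in range(100)])
        assert integral == pytest.approx(variance, rel=0.01)


def test_self_cross_spectrum_is_the_real_psd():
    rng = np.random.default_rng(2)
    se = estimate_spectra(_epochset(rng.standard_normal((5, 19, 1000))))
    diag = np.einsum("iif->if", se.cross)
    assert np.max(np.abs(np.imag(diag))) < 1e-9
    assert np.allclose(np.real(diag), se.psd)
    # Hermitian pair symmetry
    assert np.allclose(se.cross[2, 7], np.conj(se.cross[7, 2]))


def test_too_few_epochs_rejected():
    with pytest.raises(ValueError, match="epochs"):
        cross_spectra(np.zeros((1, 19, 1000)), 250.0)


def test_wrong_resolution_rejected():
    es = EpochSet("s", np.zeros((3, 19, 500)), 2.0, 250.0)
    with pytest.raises(ValueError, match="resolution"):
        estimate_spectra(es)


# ---------------------------------------------------------------------------
# Direct-DFT oracle on a small toy input


def _naive_cross_spectra(epochs, fs, window):
    """Reference: explicit DFT sums, no FFT, no vectorized tricks."""
    n_ep, C, L = epochs.shape
    if window == "boxcar":
        w = np.ones(L)
    else:
        raise ValueError(window)
    U = np.sum(w ** 2)
    n_freq = L // 2 + 1
    S = np.zeros((C, C, n_freq), dtype=complex)
    for e in range(n_ep):
        X = np.zeros((C, n_freq), dtype=complex)
        for c in range(C):
            for k in range(n_freq):
                X[c, k] = np.sum(
                    epochs[e, c] * w * np.exp(-2j * np.pi * k * np.arange(L) / L)
                )
        for i in range(C):
            for j in range(C):
                S[i, j] += X[i] * np.conj(X[j])
    S /= n_ep
    S *= 2.0 / (fs * U)
    S[..., 0] /= 2.0
    if L % 2 == 0:
        S[..., -1] /= 2.0
    return np.fft.rfftfreq(L, 1.0 / fs), S


def test_cross_spectra_match_direct_dft_reference():
    rng = np.random.default_rng(3)
    epochs = rng.standard_normal((5, 3, 40))
    fs = 10.0
    freqs, S_ref = _naive_cross_spectra(epochs, fs, "boxcar")
    freqs2, S = cross_spectra(epochs, fs, window="boxcar")
    assert np.allclose(freqs, freqs2)
    assert np.max(np.abs(S - S_ref)) < 1e-9


def test_imaginary_coherence_matches_per_bin_reference():
    rng = np.random.default_rng(4)
    epochs = rng.standard_normal((5, 3, 40))
    fs = 10.0
    freqs, S = cross_spectra(epochs, fs, window="boxcar")
    toy_bands = BandScheme(bands=(("lo", 1.0, 2.0), ("mid", 2.0, 3.0), ("hi", 3.0, 5.0)))
    se = SpectralEstimate(freqs=freqs, psd=np.real(np.einsum("iif->if", S)),
                          cross=S, n_epochs=5, channels=("A", "B", "C"))
    got = imaginary_coherence(se, toy_bands)
    # reference: direct per-bin computation for each pair
    pairs = [(0, 1), (0, 2), (1, 2)]
    for p, (i, j) in enumerate(pairs):
        for b, m in enumerate(toy_bands.masks(freqs)):
            c = S[i, j, m] / np.sqrt(S[i, i, m].real * S[j, j, m].real)
            assert got[p, b] == pytest.approx(np.mean(np.abs(np.imag(c))), abs=1e-9)


# ---------------------------------------------------------------------------
# Relative band power


def test_single_band_sinusoid_dominates_theta():
    fs, L = 250.0, 1000
    t = np.arange(4 * L) / fs
    data = 0.001 * np.random.default_rng(5).standard_normal((4, 19, L))
    data[:, 2, :] += (10 * np.sin(2 * np.pi * 6.0 * t)).reshape(4, L)
    rp = relative_band_power(estimate_spectra(_epochset(data)))
    assert rp[2, DEFAULT_BANDS.names.index("theta")] >= 0.99


def test_equal_power_sinusoids_split_evenly():
    fs, L = 250.0, 1000
    t = np.arange(4 * L) / fs
    x = 5 * np.sin(2 * np.pi * 2.0 * t) + 5 * np.sin(2 * np.pi * 25.0 * t)
    data = np.tile(x.reshape(4, 1, L), (1, 19, 1))
    rp = relative_band_power(estimate_spectra(_epochset(data)))
    assert rp[0, DEFAULT_BANDS.names.index("delta")] == pytest.approx(0.5, abs=0.01)
    assert rp[0, DEFAULT_BANDS.names.index("beta3")] == pytest.approx(0.5, abs=0.01)


def test_zero_channel_rejected():
    rng = np.random.default_rng(6)
    data = rng.standard_normal((3, 19, 1000))
    data[:, 4, :] = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        relative_band_power(estimate_spectra(_epochset(data)))


# ---------------------------------------------------------------------------
# Imaginary coherence behavior


def test_duplicated_channel_has_zero_imaginary_coherence():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((10, 19, 1000))
    data[:, 1, :] = data[:, 0, :]  # Fp2 := copy of Fp1
    ic = imaginary_coherence(estimate_spectra(_epochset(data)))
    assert np.all(ic[0] < 1e-9)  # pair (Fp1, Fp2) is the first pair


def test_lagged_shared_source_vs_independent_noise():
    """Two channels sharing a quarter-cycle-lagged narrowband alpha source
    show near-unit imaginary coherence in that band; pure-noise pairs stay
    near the finite-sample floor."""
    from scipy.signal import butter, hilbert, sosfiltfilt

    rng = np.random.default_rng(8)
    fs, L, n_ep = 250.0, 1000, 20
    n = n_ep * L
    sos = butter(4, [8.0, 10.0], btype="bandpass", fs=fs, output="sos")
    src = sosfiltfilt(sos, rng.standard_normal(n))
    src /= src.std()
    lagged = np.real(hilbert(src) * np.exp(-1j * np.pi / 2))
    data = 0.3 * rng.standard_normal((n_ep, 19, L))
    data[:, 0, :] += 3 * src.reshape(n_ep, L)
    data[:, 1, :] += 3 * lagged.reshape(n_ep, L)
    ic = imaginary_coherence(estimate_spectra(_epochset(data)))
    a1 = DEFAULT_BANDS.names.index("alpha1")
    assert ic[0, a1] > 0.8  # (Fp1, Fp2) share the lagged source
    pair_names = feature_names()
    idx_f7t6 = pair_names.index("ic_F7-T6_alpha1")
    flat = assemble_features(np.full((19, 8), 1.0 / 8), ic)
    assert flat.iloc[idx_f7t6] < 0.25


def test_independent_channels_stay_below_bias_bound():
    rng = np.random.default_rng(9)
    ic = imaginary_coherence(
        estimate_spectra(_epochset(rng.standard_normal((45, 19, 1000))))
    )
    assert np.all(ic < 0.2)
    assert np.all((0.0 <= ic) & (ic <= 1.0))


# ---------------------------------------------------------------------------
# Assembly and naming


def test_feature_vector_layout_and_naming():
    names = feature_names()
    assert len(names) == 1520
    assert names[0] == "rp_Fp1_delta"
    assert "ic_C3-C4_beta2" in names
    rng = np.random.default_rng(10)
    rp = rng.random((19, 8))
    rp /= rp.sum(axis=1, keepdims=True)
    ic = rng.random((171, 8))
    fv = assemble_features(rp, ic, subject_id="s1")
    assert len(fv) == 1520
    assert fv["rp_Fp1_delta"] == rp[0, 0]
    assert fv["ic_C3-C4_beta2"] == ic[
        [(i, j) for i in range(19) for j in range(i + 1, 19)].index((8, 10)),
        DEFAULT_BANDS.names.index("beta2"),
    ]
    with pytest.raises(ValueError, match="relative-power"):
        assemble_features(rp[:5], ic)


def test_feature_table_round_trip(tmp_path):
    from amyeeg.io import read_feature_table, write_feature_table

    rng = np.random.default_rng(11)
    feats = pd.DataFrame(
        rng.random((4, 1520)), columns=feature_names(),
        index=[f"s{i}" for i in range(4)],
    )
    profiles = pd.DataFrame(
        {"age": [65, 70, 75, 80], "sex": list("MFMF"),
         "diagnosis": ["SCD"] * 4, "amyloid": ["POS", "NEG", "POS", "NEG"]},
        index=feats.index,
    )
    path = tmp_path / "features.csv"
    write_feature_table(feats, profiles, path)
    back, meta = read_feature_table(path)
    assert np.allclose(back.to_numpy(), feats.to_numpy(), rtol=1e-11, atol=1e-14)
    assert list(meta["sex"]) == list("MFMF")


# ---------------------------------------------------------------------------
# Property tests


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1))
def test_conservation_properties_hold_for_random_epochs(seed):
    """Relative powers sum to 1 per channel; iCoh stays in [0, 1]."""
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.5, 20.0)
    data = scale * rng.standard_normal((4, 19, 1000))
    se = estimate_spectra(_epochset(data))
    rp = relative_band_power(se)
    assert np.allclose(rp.sum(axis=1), 1.0, atol=1e-9)
    ic = imaginary_coherence(se)
    assert np.all((ic >= 0.0) & (ic <= 1.0))


def test_features_survive_common_average_reference(clean_recording):
    from amyeeg.preprocess import epoch, rereference_car

    es = epoch(rereference_car(clean_recording), 4.0)
    se = estimate_spectra(es)
    rp = relative_band_power(se)
    ic = imaginary_coherence(se)
    assert np.all(np.isfinite(rp)) and np.all(np.isfinite(ic))
    assert np.allclose(rp.sum(axis=1), 1.0, atol=1e-9)
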