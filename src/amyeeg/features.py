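"""QEEG feature extraction: relative band power and imaginary coherence.

Spectra are estimated per 4-s epoch by tapered FFT at 0.25 Hz resolution and
averaged across epochs; the cross-spectrum between channels i and j is
``S_ij(f) = <x_i(f) x_j*(f)>``.  Relative band power is a channel's power
within one band divided by its summed power over the eight analysis bands.
Imaginary coherence is ``|Im(S_ij / sqrt(S_ii S_jj))|`` averaged over a
band's frequency bins — the imaginary part of the normalized cross-spectrum,
insensitive to zero-lag volume conduction.

The full feature vector holds 1,520 named values: 19 channels x 8 bands of
relative power plus 171 channel pairs x 8 bands of imaginary coherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from amyeeg.montage import CHANNELS, N_CHANNELS
from amyeeg.preprocess import EpochSet, PreprocessConfig, preprocess_recording
from amyeeg.recording import Recording

logger = logging.getLogger(__name__)

FREQ_RESOLUTION = 0.25  # Hz


@dataclass(frozen=True)
class BandScheme:
    """Ordered analysis bands covering 1-45 Hz.

    Each band is ``[low, high)`` except the last, which is closed at its
    upper edge so the 45 Hz bin belongs to gamma.
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = None
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValueError(f"band {name}: high {hi} <= low {lo}")
            if prev_high is not None and abs(lo - prev_high) > 1e-9:
                raise ValueError(f"bands must be contiguous; gap/overlap before {name}")
            prev_high = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def masks(self, freqs: np.ndarray) -> list[np.ndarray]:
        """Boolean bin masks per band: [low, high), last band [low, high]."""
        out = []
        last = len(self.bands) - 1
        for k, (_, lo, hi) in enumerate(self.bands):
            if k == last:
                out.append((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
            else:
                out.append((freqs >= lo - 1e-9) & (freqs < hi - 1e-9))
        return out


DEFAULT_BANDS = BandScheme(
    bands=(
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha1", 8.0, 10.0),
        ("alpha2", 10.0, 12.0),
        ("beta1", 12.0, 15.0),
        ("beta2", 15.0, 20.0),
        ("beta3", 20.0, 30.0),
        ("gamma", 30.0, 45.0),
    )
)


@dataclass
class SpectralEstimate:
    """Epoch-averaged PSD and full cross-spectral matrix on a 0.25 Hz grid."""

    freqs: np.ndarray  # (F,)
    psd: np.ndarray  # (C, F), uV^2/Hz
    cross: np.ndarray  # (C, C, F), complex
    n_epochs: int
    channels: tuple[str, ...] = field(default=CHANNELS)

    @property
    def n_channels(self) -> int:
        return self.psd.shape[0]


def cross_spectra(
    epochs: np.ndarray, fs: float, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged one-sided cross-spectral matrix of an (E, C, L) array.

    Returns ``(freqs, S)`` with ``S`` of shape (C, C, F).  Scaling is
    density-style (uV^2/Hz): summing the diagonal over frequency times the
    bin width recovers the mean signal variance (Parseval within 1% for the
    default Hann taper).
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3:
        raise ValueError(f"epochs must be (n_epochs, channels, samples); got {epochs.shape}")
    n_ep, _, L = epochs.shape
    if n_ep < 2:
        raise ValueError(
            "cross-spectral averaging needs >= 2 epochs "
            f"(got {n_ep}); the expectation is estimated across epochs"
        )
    w = sp_signal.get_window(window, L, fftbins=True)
    U = float(np.sum(w ** 2))
    X = np.fft.rfft(epochs * w, axis=2)  # (E, C, F)
    S = np.einsum("ecf,edf->cdf", X, np.conj(X)) / n_ep
    S *= 2.0 / (fs * U)
    S[..., 0] /= 2.0
    if L % 2 == 0:
        S[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(L, 1.0 / fs)
    return freqs, S


def estimate_spectra(es: EpochSet, window: str = "hann") -> SpectralEstimate:
    """Estimate PSD and cross-spectra from an epoch set at 0.25 Hz resolution."""
    L = es.epochs.shape[2]
    df = es.fs / L
    if abs(df - FREQ_RESOLUTION) > 1e-9:
        raise ValueError(
            f"epoch length {L} samples at {es.fs} Hz gives {df:.4f} Hz resolution; "
            f"need {FREQ_RESOLUTION} Hz (4 s epochs)"
        )
    freqs, S = cross_spectra(es.epochs, es.fs, window=window)
    psd = np.real(np.einsum("iif->if", S)).copy()
    return SpectralEstimate(
        freqs=freqs, psd=psd, cross=S, n_epochs=es.n_epochs, channels=CHANNELS
    )


def relative_band_power(
    se: SpectralEstimate, bands: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Per-channel relative band powers, rows summing to 1.  Shape (C, n_bands)."""
    df = float(se.freqs[1] - se.freqs[0])
    masks = bands.masks(se.freqs)
    absolute = np.stack([se.psd[:, m].sum(axis=1) * df for m in masks], axis=1)
    totals = absolute.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = [se.channels[i] for i in np.where(totals[:, 0] <= 0)[0]]
        raise ValueError(f"degenerate recording: zero total band power on channels {bad}")
    return absolute / totals


def imaginary_coherence(
    se: SpectralEstimate, bands: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Band-averaged imaginary coherence for all channel pairs (i < j).

    Per frequency bin, coherency ``C_ij = S_ij / sqrt(S_ii S_jj)``; the band
    value is the unweighted mean of ``|Im(C_ij)|`` over the band's bins.
    Bins with a zero auto-spectrum are excluded from the mean (logged).
    Shape (C*(C-1)/2, n_bands), values in [0, 1].
    """
    C = se.n_channels
    auto = np.real(np.einsum("iif->if", se.cross))  # (C, F)
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    valid = denom > 0.0
    n_zero = int((~valid).sum())
    if n_zero:
        logger.warning("imaginary_coherence: %d zero auto-spectrum bins excluded", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        im = np.abs(np.imag(se.cross) / np.where(valid, denom, 1.0))
    masks = bands.masks(se.freqs)
    n_pairs = C * (C - 1) // 2
    out = np.zeros((n_pairs, len(bands)))
    iu, ju = np.triu_indices(C, k=1)
    for b, m in enumerate(masks):
        vals = im[iu, ju][:, m]
        ok = valid[iu, ju][:, m]
        counts = ok.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("a band has no valid frequency bins for some pair")
        out[:, b] = np.where(ok, vals, 0.0).sum(axis=1) / counts
    return np.clip(out, 0.0, 1.0)


def feature_names(bands: BandScheme = DEFAULT_BANDS) -> list[str]:
    """Canonical ordered names of the 1,520 features.

    All relative powers first (channel-major, band-minor:
    ``rp_<CH>_<BAND>``), then all coherences (pair-major:
    ``ic_<CH1>-<CH2>_<BAND>`` with CH1 before CH2 in montage order).
    """
    names = [f"rp_{ch}_{b}" for ch in CHANNELS for b in bands.names]
    for i in range(N_CHANNELS):
        for j in range(i + 1, N_CHANNELS):
            names.extend(
                f"ic_{CHANNELS[i]}-{CHANNELS[j]}_{b}" for b in bands.names
            )
    return names


def assemble_features(
    rp: np.ndarray,
    ic: np.ndarray,
    subject_id: str | None = None,
    bands: BandScheme = DEFAULT_BANDS,
) -> pd.Series:
    """Assemble the named 1,520-entry feature vector in canonical order."""
    rp = np.asarray(rp)
    ic = np.asarray(ic)
    n_pairs = N_CHANNELS * (N_CHANNELS - 1) // 2
    if rp.shape != (N_CHANNELS, len(bands)):
        raise ValueError(f"relative-power matrix must be ({N_CHANNELS}, {len(bands)}); got {rp.shape}")
    if ic.shape != (n_pairs, len(bands)):
        raise ValueError(f"coherence matrix must be ({n_pairs}, {len(bands)}); got {ic.shape}")
    values = np.concatenate([rp.ravel(), ic.ravel()])
    return pd.Series(values, index=feature_names(bands), name=subject_id)


def extract_features(
    rec: Recording,
    prep: PreprocessConfig = PreprocessConfig(),
    bands: BandScheme = DEFAULT_BANDS,
    window: str = "hann",
) -> pd.Series:
    """Preprocess one recording and compute its full QEEG feature vector."""
    es = preprocess_recording(rec, prep)
    se = estimate_spectra(es, window=window)
    rp = relative_band_power(se, bands)
    ic = imaginary_coherence(se, bands)
    return assemble_features(rp, ic, subject_id=rec.subject_id, bands=bands)
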