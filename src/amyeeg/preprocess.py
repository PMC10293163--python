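"""Denoising and harmonization of raw recordings.

The pipeline order is fixed: resample -> bandpass/notch -> common-average
reference -> epoch -> bad-epoch rejection -> ocular/EMG removal.  Every step
appends to the epoch set's provenance log.

The bad-epoch rejector (amplitude + variance rule) and the ocular/EMG
cleaner (regression or ICA) are deliberately simple, documented stand-ins
for heavier published artifact-removal algorithms; the downstream analysis
does not depend on their internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from amyeeg.montage import CHANNELS, N_CHANNELS, channel_index
from amyeeg.recording import Recording, VALID_SAMPLING_RATES

logger = logging.getLogger(__name__)

_NOTCH_WARNED: set[tuple[float, float, float]] = set()  # warn once per combo


@dataclass
class EpochSet:
    """Fixed-length epochs from one subject plus kept/rejected bookkeeping."""

    subject_id: str
    epochs: np.ndarray  # (n_kept, 19, samples_per_epoch), microvolts
    epoch_length: float  # seconds
    fs: float
    kept: list[bool] = field(default_factory=list)  # per original epoch
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != N_CHANNELS:
            raise ValueError(
                f"epochs must be (n, {N_CHANNELS}, samples); got {self.epochs.shape}"
            )
        if self.epochs.shape[0] == 0:
            raise ValueError(f"no epochs left for subject {self.subject_id}")
        if not self.kept:
            self.kept = [True] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling to ``target_fs`` (200 or 250 Hz).

    Returns the input unchanged when already at the target rate.
    """
    if float(target_fs) not in VALID_SAMPLING_RATES:
        raise ValueError(f"target_fs must be one of {VALID_SAMPLING_RATES}, got {target_fs}")
    if abs(rec.fs - target_fs) < 1e-9:
        return rec
    from math import gcd

    up, down = int(target_fs), int(rec.fs)
    g = gcd(up, down)
    up, down = up // g, down // g
    data = signal.resample_poly(rec.data, up, down, axis=1)
    return rec.copy_with(fs=float(target_fs), data=data)


def bandpass_and_notch(
    rec: Recording,
    low: float = 1.0,
    high: float = 45.5,
    line_freq: float = 60.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass plus mains notch.

    ``low``/``high`` name the nominal passband; the Butterworth cutoffs are
    designed with a margin outside it (low/2 and high*1.1) because the -3 dB
    point sits *at* the cutoff and zero-phase application squares the
    magnitude response — cutoffs placed exactly at the band edges would
    halve the power of the outermost analysis bins twice over.

    The notch is skipped with a logged warning when ``line_freq`` falls
    outside the passband (it is then already suppressed by the bandpass).
    """
    nyq = rec.fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < fs/2; got low={low}, high={high}, fs={rec.fs}")
    cut_lo = low / 2.0
    cut_hi = min(high * 1.1, 0.98 * nyq)
    sos = signal.butter(4, [cut_lo, cut_hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if low < line_freq < high:
        b, a = signal.iirnotch(line_freq, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    elif (line_freq, low, high) not in _NOTCH_WARNED:
        _NOTCH_WARNED.add((line_freq, low, high))
        logger.warning(
            "notch at %.1f Hz outside passband (%.1f-%.1f Hz); skipped "
            "(already suppressed by the bandpass)", line_freq, low, high
        )
    return rec.copy_with(data=data)


def rereference_car(rec: Recording) -> Recording:
    """Re-reference to the common average; idempotent."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="common-average")


def epoch(rec: Recording, length: float = 4.0, overlap: float = 0.0) -> EpochSet:
    """Cut the recording into fixed-length epochs (non-overlapping default)."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    samples = length * rec.fs
    if abs(samples - round(samples)) > 1e-9:
        raise ValueError(f"epoch length {length} s x fs {rec.fs} is not an integer sample count")
    L = int(round(samples))
    step = int(round(L * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: epoch step below one sample")
    if rec.n_samples < L:
        raise ValueError(
            f"recording {rec.subject_id} shorter ({rec.duration:.1f} s) than one epoch ({length} s)"
        )
    n = (rec.n_samples - L) // step + 1
    idx = np.arange(n)[:, None] * step + np.arange(L)[None, :]
    epochs = rec.data[:, idx].transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        epochs=epochs,
        epoch_length=length,
        fs=rec.fs,
        log=[f"epoch(length={length}, overlap={overlap}) -> {n} epochs"],
    )


def reject_bad_epochs(
    es: EpochSet, amp_thresh: float = 100.0, var_mult: float = 5.0
) -> EpochSet:
    """Amplitude/variance bad-epoch rejection.

    An epoch is rejected when any channel's peak absolute amplitude exceeds
    ``amp_thresh`` (microvolts) or any channel's variance exceeds
    ``var_mult`` times that channel's median epoch variance.
    """
    if amp_thresh <= 0 or var_mult <= 0:
        raise ValueError("amp_thresh and var_mult must be > 0")
    peak = np.abs(es.epochs).max(axis=2)  # (n, 19)
    var = es.epochs.var(axis=2)
    med = np.median(var, axis=0, keepdims=True)
    bad = (peak > amp_thresh).any(axis=1) | (var > var_mult * med).any(axis=1)
    if bad.all():
        raise RuntimeError(f"all epochs rejected for subject {es.subject_id}")
    keep = ~bad
    return EpochSet(
        subject_id=es.subject_id,
        epochs=es.epochs[keep],
        epoch_length=es.epoch_length,
        fs=es.fs,
        kept=[bool(k) for k in keep],
        log=es.log + [
            f"reject_bad_epochs(amp_thresh={amp_thresh}, var_mult={var_mult}) "
            f"rejected {int(bad.sum())}/{bad.size}"
        ],
    )


_FRONTAL_POLAR = ("Fp1", "Fp2")


def _ocular_proxy(epochs: np.ndarray, fs: float) -> np.ndarray:
    """Low-pass (<4 Hz) mean of the frontopolar channels, per epoch."""
    idx = [channel_index(c) for c in _FRONTAL_POLAR]
    proxy = epochs[:, idx, :].mean(axis=1)
    sos = signal.butter(4, 4.0, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, proxy, axis=1)


def remove_ocular_emg(es: EpochSet, mode: str = "regression",
                      seed: int = 0) -> EpochSet:
    """Remove ocular (and, in ICA mode, myogenic) artifact from kept epochs.

    regression
        For every non-frontopolar channel, the least-squares projection onto
        a low-pass (<4 Hz) Fp1/Fp2 ocular proxy is subtracted, epoch by
        epoch.  Output variance never exceeds input variance per channel.
    ica
        FastICA across concatenated epochs; components correlating with the
        ocular proxy (|r| > 0.7) or dominated by >20 Hz power (fraction
        > 0.7) are zeroed before back-projection.  Requires >= 8 kept epochs.
    """
    if mode not in ("regression", "ica"):
        raise ValueError(f"mode must be 'regression' or 'ica', got {mode!r}")
    proxy = _ocular_proxy(es.epochs, es.fs)

    if mode == "regression":
        cleaned = es.epochs.copy()
        denom = np.einsum("et,et->e", proxy, proxy)
        if np.all(denom < 1e-12):
            logger.warning("zero-variance ocular proxy for %s; regression skipped", es.subject_id)
            return EpochSet(es.subject_id, es.epochs, es.epoch_length, es.fs,
                            list(es.kept), es.log + ["remove_ocular_emg(regression): skipped"])
        safe = np.where(denom < 1e-12, 1.0, denom)
        skip = {channel_index(c) for c in _FRONTAL_POLAR}
        for ch in range(N_CHANNELS):
            if ch in skip:
                continue
            beta = np.einsum("et,et->e", cleaned[:, ch, :], proxy) / safe
            beta = np.where(denom < 1e-12, 0.0, beta)
            cleaned[:, ch, :] -= beta[:, None] * proxy
        log_line = "remove_ocular_emg(regression)"
    else:
        if es.n_epochs < 8:
            raise ValueError(f"ica mode needs >= 8 kept epochs, got {es.n_epochs}")
        from sklearn.decomposition import FastICA

        n_ep, _, L = es.epochs.shape
        X = es.epochs.transpose(1, 0, 2).reshape(N_CHANNELS, n_ep * L)
        ica = FastICA(n_components=N_CHANNELS, random_state=seed, max_iter=500,
                      whiten="unit-variance", tol=1e-3)
        sources = ica.fit_transform(X.T).T  # (components, time)
        proxy_flat = proxy.reshape(-1)
        f, pxx = signal.periodogram(sources, fs=es.fs, axis=1)
        hf_frac = pxx[:, f > 20.0].sum(axis=1) / np.maximum(pxx.sum(axis=1), 1e-30)
        removed = []
        for k in range(sources.shape[0]):
            s = sources[k]
            r = 0.0
            if s.std() > 0 and proxy_flat.std() > 0:
                r = float(np.corrcoef(s, proxy_flat)[0, 1])
            if abs(r) > 0.7 or hf_frac[k] > 0.7:
                removed.append(k)
        sources[removed, :] = 0.0
        X_clean = (ica.mixing_ @ sources) + ica.mean_[:, None]
        cleaned = X_clean.reshape(N_CHANNELS, n_ep, L).transpose(1, 0, 2)
        log_line = f"remove_ocular_emg(ica): zeroed components {removed}"

    return EpochSet(
        subject_id=es.subject_id,
        epochs=cleaned,
        epoch_length=es.epoch_length,
        fs=es.fs,
        kept=list(es.kept),
        log=es.log + [log_line],
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the fixed preprocessing chain.

    ``max_epochs`` caps the number of kept epochs entering spectral
    estimation (the earliest surviving ones are used).  A fixed epoch budget
    keeps the epoch-averaged spectral estimators — whose finite-sample bias
    depends on the number of epochs averaged, most visibly for imaginary
    coherence — comparable across recordings of different length, e.g.
    between whole recordings and the half-recordings created by
    positive-class augmentation.
    """

    target_fs: float = 250.0
    low: float = 1.0
    high: float = 45.5
    line_freq: float = 60.0
    epoch_length: float = 4.0
    overlap: float = 0.0
    amp_thresh: float = 100.0
    var_mult: float = 5.0
    ocular_mode: str = "regression"  # regression | ica | none
    max_epochs: int | None = None


def preprocess_recording(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Run the full fixed-order preprocessing chain on one recording."""
    r = resample(rec, cfg.target_fs)
    r = bandpass_and_notch(r, cfg.low, cfg.high, cfg.line_freq)
    r = rereference_car(r)
    es = epoch(r, cfg.epoch_length, cfg.overlap)
    es.log.insert(0, f"resample(target_fs={cfg.target_fs}); bandpass({cfg.low}-{cfg.high}); "
                     f"notch({cfg.line_freq}); car")
    es = reject_bad_epochs(es, cfg.amp_thresh, cfg.var_mult)
    if cfg.max_epochs is not None and es.n_epochs > cfg.max_epochs:
        es = EpochSet(
            subject_id=es.subject_id,
            epochs=es.epochs[: cfg.max_epochs],
            epoch_length=es.epoch_length, fs=es.fs, kept=list(es.kept),
            log=es.log + [f"capped at the first {cfg.max_epochs} kept epochs"],
        )
    if cfg.ocular_mode != "none":
        es = remove_ocular_emg(es, mode=cfg.ocular_mode)
    return es
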