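"""Synthetic EEG cohort generator.

Generates normative and study cohorts with the statistical structure the
downstream analysis assumes, so every stage of the pipeline is testable
without clinical data.  Each channel of a synthetic recording is the sum of

* a ``1/f^chi`` Gaussian background,
* per-band narrowband oscillators (band-filtered Gaussian noise) scaled by a
  per-channel per-band gain,
* lagged shared sources injecting nonzero imaginary coherence at chosen
  channel pairs, and
* scheduled artifacts: ocular blinks (frontal biphasic transients), EMG
  bursts (high-frequency noise on temporal channels) and mains interference.

Amyloid-positive study subjects receive a frontal/frontotemporal theta gain
increment and a centroparietal beta2 gain decrement; both are amplified in
MCI relative to SCD.  Normative subjects carry a linear age drift (theta
gain up, alpha peak frequency down with age) and a small sex offset, giving
the normative z-scoring a real physiological effect to remove.

Every generator is a pure function of its specification and seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from amyeeg.montage import (
    CHANNELS,
    CENTROPARIETAL,
    FRONTOTEMPORAL,
    N_CHANNELS,
    POSTERIOR,
    TEMPORAL,
    channel_index,
)
from amyeeg.recording import Recording, SubjectProfile, VALID_SAMPLING_RATES

BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2", "beta3", "gamma")
_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 12.0),
    "beta1": (12.0, 15.0),
    "beta2": (15.0, 20.0),
    "beta3": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}

# Amplitude scales, microvolts (std of the corresponding component at gain 1).
BACKGROUND_SCALE_UV = 5.0
OSCILLATOR_SCALE_UV = 2.0


@dataclass(frozen=True)
class Coupling:
    """A lagged shared narrowband source between two channels.

    ``lag`` is the phase lag in radians applied to the second channel's copy
    of the source; any nonzero lag other than 0/pi yields nonzero imaginary
    coherence for the pair in that band.
    """

    ch_i: str
    ch_j: str
    band: str
    strength: float
    lag: float

    def __post_init__(self) -> None:
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"coupling strength must be in [0, 1], got {self.strength}")
        if not -math.pi < self.lag <= math.pi:
            raise ValueError(f"phase lag must be in (-pi, pi], got {self.lag}")


@dataclass
class SpectralProfile:
    """Per-subject spectral ground truth: oscillator gains and couplings."""

    gains: np.ndarray  # (19, 8) dimensionless amplitude multipliers
    chi: float = 1.0  # 1/f^chi background exponent
    alpha_peak_hz: float = 10.5
    couplings: list[Coupling] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=np.float64)
        if self.gains.shape != (N_CHANNELS, len(BAND_NAMES)):
            raise ValueError(
                f"gains must be ({N_CHANNELS}, {len(BAND_NAMES)}); got {self.gains.shape}"
            )
        if np.any(self.gains < 0):
            raise ValueError("all oscillator gains must be >= 0")


@dataclass
class CohortSpec:
    """Study-cohort composition, injected effect sizes and recording settings.

    Defaults mirror the four-stratum SCD/MCI amyloid cohort (36 SCD+, 160
    SCD-, 54 MCI+, 61 MCI-; 311 subjects) with ~3 min recordings at 250 Hz.
    Per-stratum age distributions follow the reported group means/SDs; the
    male fractions are approximate.
    """

    n_scd_pos: int = 36
    n_scd_neg: int = 160
    n_mci_pos: int = 54
    n_mci_neg: int = 61
    # Injected amyloid signature (gain units; see module docstring).
    delta_theta: float = 0.35
    delta_beta2: float = 0.20
    mci_multiplier: float = 1.5
    # Per-stratum (SCD+, SCD-, MCI+, MCI-) age normal(mean, sd), clipped 60-90.
    age_means: tuple[float, float, float, float] = (72.0, 71.3, 74.5, 71.5)
    age_sds: tuple[float, float, float, float] = (5.9, 6.9, 6.1, 6.8)
    male_fractions: tuple[float, float, float, float] = (0.53, 0.59, 0.62, 0.44)
    # Artifact schedule.
    blink_rate_per_min: float = 2.0
    emg_rate_per_min: float = 1.0
    line_noise_uv: float = 1.0
    line_freq: float = 60.0
    duration: float = 180.0
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_scd_pos", "n_scd_neg", "n_mci_pos", "n_mci_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mci_multiplier < 1.0:
            raise ValueError("mci_multiplier must be >= 1")
        _check_duration_fs(self.duration, self.fs)

    @property
    def strata(self) -> list[tuple[str, str, int]]:
        return [
            ("SCD", "POS", self.n_scd_pos),
            ("SCD", "NEG", self.n_scd_neg),
            ("MCI", "POS", self.n_mci_pos),
            ("MCI", "NEG", self.n_mci_neg),
        ]

    @property
    def n_total(self) -> int:
        return self.n_scd_pos + self.n_scd_neg + self.n_mci_pos + self.n_mci_neg


def _check_duration_fs(duration: float, fs: float) -> None:
    if duration < 60.0:
        raise ValueError(f"duration must be >= 60 s, got {duration}")
    if float(fs) not in VALID_SAMPLING_RATES:
        raise ValueError(f"fs must be one of {VALID_SAMPLING_RATES}, got {fs}")


# ---------------------------------------------------------------------------
# Spectral profiles

# Base per-band gains; alpha is boosted posteriorly, slow bands frontally.
_BASE_GAINS = {
    "delta": 0.9,
    "theta": 1.0,
    "alpha1": 1.2,
    "alpha2": 0.9,
    "beta1": 0.7,
    "beta2": 0.7,
    "beta3": 0.5,
    "gamma": 0.3,
}

THETA_AGE_SLOPE = 0.010  # gain units per year, referenced to age 65
ALPHA_PEAK_AGE_SLOPE = -0.030  # Hz per year
FEMALE_ALPHA_FACTOR = 1.05
GAIN_JITTER_SIGMA = 0.20  # lognormal sigma of inter-subject gain variability

_DEFAULT_COUPLINGS = [
    Coupling("O1", "O2", "alpha1", 0.5, 1.2),
    Coupling("P3", "P4", "alpha1", 0.4, 1.0),
    Coupling("C3", "C4", "beta1", 0.4, 1.2),
    Coupling("F3", "F4", "theta", 0.4, 1.0),
]


def default_spectral_profile(
    age: int,
    sex: str,
    rng: np.random.Generator,
    jitter_sigma: float = GAIN_JITTER_SIGMA,
) -> SpectralProfile:
    """Build a subject's spectral ground truth with age/sex drift and jitter.

    Theta gain increases and the alpha peak frequency decreases linearly with
    age; females get a mild alpha boost.  A lognormal jitter on every gain
    models inter-subject variability.
    """
    gains = np.empty((N_CHANNELS, len(BAND_NAMES)))
    for b, band in enumerate(BAND_NAMES):
        gains[:, b] = _BASE_GAINS[band]
    post = [channel_index(c) for c in POSTERIOR]
    front = [channel_index(c) for c in ("Fp1", "Fp2", "F3", "Fz", "F4")]
    for b in (BAND_NAMES.index("alpha1"), BAND_NAMES.index("alpha2")):
        gains[post, b] *= 1.8
    for b in (BAND_NAMES.index("delta"), BAND_NAMES.index("theta")):
        gains[front, b] *= 1.2

    gains[:, BAND_NAMES.index("theta")] += THETA_AGE_SLOPE * (age - 65)

    alpha_peak = float(np.clip(10.5 + ALPHA_PEAK_AGE_SLOPE * (age - 65), 8.5, 11.5))
    # A lower peak shifts oscillatory mass from alpha2 into alpha1.
    t = float(np.clip((alpha_peak - 9.0) / 2.0, 0.1, 0.9))
    gains[:, BAND_NAMES.index("alpha1")] *= 2.0 * (1.0 - t)
    gains[:, BAND_NAMES.index("alpha2")] *= 2.0 * t

    if sex == "F":
        for b in (BAND_NAMES.index("alpha1"), BAND_NAMES.index("alpha2")):
            gains[:, b] *= FEMALE_ALPHA_FACTOR

    if jitter_sigma > 0:
        gains *= rng.lognormal(0.0, jitter_sigma, size=gains.shape)
    gains = np.clip(gains, 0.0, None)

    return SpectralProfile(
        gains=gains,
        chi=1.0,
        alpha_peak_hz=alpha_peak,
        couplings=list(_DEFAULT_COUPLINGS),
    )


def apply_amyloid_signature(
    spectral: SpectralProfile,
    delta_theta: float,
    delta_beta2: float,
    multiplier: float = 1.0,
) -> SpectralProfile:
    """Inject the amyloid-positive signature into a spectral profile.

    Adds ``delta_theta * multiplier`` to the theta gain of the nine frontal/
    frontotemporal channels and subtracts ``delta_beta2 * multiplier`` from
    the beta2 gain of the six centroparietal channels (floored at 0.05).
    """
    gains = spectral.gains.copy()
    ft = [channel_index(c) for c in FRONTOTEMPORAL]
    cp = [channel_index(c) for c in CENTROPARIETAL]
    gains[ft, BAND_NAMES.index("theta")] += delta_theta * multiplier
    b2 = BAND_NAMES.index("beta2")
    gains[cp, b2] = np.clip(gains[cp, b2] - delta_beta2 * multiplier, 0.05, None)
    return dataclasses.replace(spectral, gains=gains)


# ---------------------------------------------------------------------------
# Signal synthesis
#
# Background and oscillators are built in a single frequency-domain pass: a
# white Gaussian spectrum is shaped by the square root of the summed target
# power response (1/f^chi background plus one rectangular band response per
# oscillator).  This is the same Gaussian signal family as time-domain
# band-filtering, at a fraction of the cost.


def _band_mask(band: str, freqs: np.ndarray) -> np.ndarray:
    lo, hi = _BAND_EDGES[band]
    if band == BAND_NAMES[-1]:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def _power_response(gains: np.ndarray, chi: float, n: int, fs: float) -> np.ndarray:
    """Per-channel squared amplitude response on the rfft grid.

    Scaled so a unit-variance white input yields a signal whose background
    component has std BACKGROUND_SCALE_UV and whose band-b oscillator has
    std ``gains[:, b] * OSCILLATOR_SCALE_UV`` (in expectation).
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-chi) if chi != 0 else 1.0
    total = np.sum(shape)
    resp = np.zeros((gains.shape[0], freqs.size))
    if total > 0:
        resp += BACKGROUND_SCALE_UV ** 2 * shape[None, :] * n / (2.0 * total)
    for b, band in enumerate(BAND_NAMES):
        m = _band_mask(band, freqs)
        cnt = int(m.sum())
        if cnt == 0:
            continue
        band_var = (gains[:, b] * OSCILLATOR_SCALE_UV) ** 2
        resp[:, m] += band_var[:, None] * n / (2.0 * cnt)
    return resp


def _narrowband_source(band: str, n: int, fs: float, rng: np.random.Generator,
                       lag: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """A unit-variance band-limited source and its phase-lagged copy."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    m = _band_mask(band, freqs)
    amp = np.zeros_like(freqs)
    cnt = max(int(m.sum()), 1)
    amp[m] = np.sqrt(n / (2.0 * cnt))
    Y = np.fft.rfft(rng.standard_normal(n)) * amp
    src = np.fft.irfft(Y, n=n)
    lagged = np.fft.irfft(Y * np.exp(-1j * lag), n=n)
    return src, lagged


def _blink_template(fs: float, width_s: float) -> np.ndarray:
    """Smooth biphasic ocular transient of the given width."""
    n = max(int(round(width_s * fs)), 4)
    t = np.arange(n) / n
    return np.sin(2.0 * np.pi * t) * np.hanning(n)


_BLINK_WEIGHTS = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.35, "F3": 0.35, "Fz": 0.35,
                  "F4": 0.35, "F8": 0.35, "T3": 0.1, "C3": 0.1, "Cz": 0.1,
                  "C4": 0.1, "T4": 0.1}
BLINK_AMPLITUDE_UV = 160.0
EMG_AMPLITUDE_UV = 25.0


def _add_blinks(data: np.ndarray, fs: float, rate_per_min: float,
                rng: np.random.Generator) -> None:
    n = data.shape[1]
    count = rng.poisson(rate_per_min * n / fs / 60.0)
    weights = np.array([_BLINK_WEIGHTS.get(c, 0.02) for c in CHANNELS])
    for _ in range(count):
        width = rng.uniform(0.3, 0.5)
        tpl = _blink_template(fs, width) * BLINK_AMPLITUDE_UV
        start = rng.integers(0, max(n - tpl.size, 1))
        data[:, start:start + tpl.size] += np.outer(weights, tpl)


def _add_emg_bursts(data: np.ndarray, fs: float, rate_per_min: float,
                    rng: np.random.Generator) -> None:
    n = data.shape[1]
    count = rng.poisson(rate_per_min * n / fs / 60.0)
    if count == 0:
        return
    sos = signal.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
    temporal_idx = [channel_index(c) for c in TEMPORAL]
    for _ in range(count):
        dur = rng.uniform(0.5, 2.0)
        m = int(round(dur * fs))
        ch = temporal_idx[rng.integers(0, len(temporal_idx))]
        burst = signal.sosfiltfilt(sos, rng.standard_normal(m))
        sd = burst.std() or 1.0
        burst = burst / sd * EMG_AMPLITUDE_UV * np.hanning(m)
        start = rng.integers(0, max(n - m, 1))
        data[ch, start:start + m] += burst[: data.shape[1] - start]


def synthesize_recording(
    profile: SubjectProfile,
    spectral: SpectralProfile,
    duration: float = 180.0,
    fs: float = 250.0,
    seed: int | None = None,
    blink_rate_per_min: float = 2.0,
    emg_rate_per_min: float = 1.0,
    line_noise_uv: float = 1.0,
    line_freq: float = 60.0,
) -> Recording:
    """Synthesize one subject's recording from its spectral ground truth.

    Deterministic: identical ``(profile, spectral, seed)`` give bit-identical
    output.  ``seed=None`` falls back to ``profile.seed``.
    """
    _check_duration_fs(duration, fs)
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))

    white = np.fft.rfft(rng.standard_normal((N_CHANNELS, n)), axis=1)
    resp = _power_response(spectral.gains, spectral.chi, n, fs)
    data = np.fft.irfft(white * np.sqrt(resp), n=n, axis=1)

    for c in spectral.couplings:
        src, lagged = _narrowband_source(c.band, n, fs, rng, lag=c.lag)
        amp = c.strength * OSCILLATOR_SCALE_UV * 2.0
        data[channel_index(c.ch_i)] += amp * src
        data[channel_index(c.ch_j)] += amp * lagged

    if blink_rate_per_min > 0:
        _add_blinks(data, fs, blink_rate_per_min, rng)
    if emg_rate_per_min > 0:
        _add_emg_bursts(data, fs, emg_rate_per_min, rng)
    if line_noise_uv > 0:
        t = np.arange(n) / fs
        data += line_noise_uv * np.sin(2.0 * np.pi * line_freq * t)

    return Recording(
        subject_id=profile.subject_id,
        fs=float(fs),
        data=data,
        reference="linked-ear",
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Cohorts


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds fanned out from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def iter_study_cohort(spec: CohortSpec):
    """Yield the study cohort one recording at a time (memory-friendly).

    Amyloid-positive subjects carry the injected frontotemporal-theta /
    centroparietal-beta2 signature; the increments are multiplied by
    ``spec.mci_multiplier`` for MCI subjects.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    seeds = iter(_subject_seeds(spec.seed, spec.n_total))
    for stratum_idx, (diagnosis, amyloid, count) in enumerate(spec.strata):
        mu = spec.age_means[stratum_idx]
        sd = spec.age_sds[stratum_idx]
        male_frac = spec.male_fractions[stratum_idx]
        for k in range(count):
            age = int(np.clip(round(rng.normal(mu, sd)), 60, 90))
            sex = "M" if rng.random() < male_frac else "F"
            subject_id = f"{diagnosis}{amyloid}-{k:03d}"
            subj_seed = next(seeds)
            profile = SubjectProfile(
                subject_id=subject_id, age=age, sex=sex,
                diagnosis=diagnosis, amyloid=amyloid, seed=subj_seed,
            )
            spectral = default_spectral_profile(age, sex, rng)
            if amyloid == "POS":
                mult = spec.mci_multiplier if diagnosis == "MCI" else 1.0
                spectral = apply_amyloid_signature(
                    spectral, spec.delta_theta, spec.delta_beta2, mult
                )
            yield synthesize_recording(
                profile, spectral, spec.duration, spec.fs, subj_seed,
                blink_rate_per_min=spec.blink_rate_per_min,
                emg_rate_per_min=spec.emg_rate_per_min,
                line_noise_uv=spec.line_noise_uv,
                line_freq=spec.line_freq,
            )


def generate_study_cohort(spec: CohortSpec) -> list[Recording]:
    """The study cohort as a list; see :func:`iter_study_cohort`."""
    return list(iter_study_cohort(spec))


DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (40, 50), (50, 60), (60, 70), (70, 80), (80, 90),
)


def iter_normative_cohort(
    n_per_stratum: int,
    age_bins: list[tuple[int, int]] | tuple = DEFAULT_AGE_BINS,
    seed: int = 0,
    duration: float = 180.0,
    fs: float = 250.0,
    blink_rate_per_min: float = 2.0,
    emg_rate_per_min: float = 1.0,
    line_noise_uv: float = 1.0,
    line_freq: float = 60.0,
):
    """Yield the age/sex-stratified normative cohort one recording at a time.

    Every (sex x age-bin) cell receives ``n_per_stratum`` healthy (NORM)
    subjects with ages uniform within the bin, carrying the built-in age
    drift (theta up, alpha peak down) so normative z-scoring has a real
    physiological effect to remove.
    """
    if n_per_stratum < 2:
        raise ValueError("n_per_stratum must be >= 2")
    if not age_bins:
        raise ValueError("age_bins must be non-empty")
    _check_duration_fs(duration, fs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_total = 2 * len(age_bins) * n_per_stratum
    seeds = iter(_subject_seeds(seed + 10_000, n_total))
    for sex in ("M", "F"):
        for lo, hi in age_bins:
            for k in range(n_per_stratum):
                age = int(rng.integers(lo, hi))
                subj_seed = next(seeds)
                subject_id = f"NORM-{sex}-{lo}_{hi}-{k:03d}"
                profile = SubjectProfile(
                    subject_id=subject_id, age=age, sex=sex,
                    diagnosis="NORM", amyloid="NA", seed=subj_seed,
                )
                spectral = default_spectral_profile(age, sex, rng)
                yield synthesize_recording(
                    profile, spectral, duration, fs, subj_seed,
                    blink_rate_per_min=blink_rate_per_min,
                    emg_rate_per_min=emg_rate_per_min,
                    line_noise_uv=line_noise_uv,
                    line_freq=line_freq,
                )


def generate_normative_cohort(*args, **kwargs) -> list[Recording]:
    """The normative cohort as a list; see :func:`iter_normative_cohort`."""
    return list(iter_normative_cohort(*args, **kwargs))


def split_ids(
    profiles: list[SubjectProfile],
    held_out_counts: dict[tuple[str, str], int],
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified held-out split over subject ids; see split_train_validation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    by_stratum: dict[tuple[str, str], list[str]] = {}
    for p in profiles:
        by_stratum.setdefault((p.diagnosis, p.amyloid), []).append(p.subject_id)
    val_ids: set[str] = set()
    for key, want in held_out_counts.items():
        members = sorted(by_stratum.get(key, []))
        if want > len(members):
            raise ValueError(
                f"requested {want} held-out subjects from stratum {key} "
                f"but only {len(members)} available"
            )
        chosen = rng.choice(len(members), size=want, replace=False)
        val_ids.update(members[i] for i in chosen)
    all_ids = [p.subject_id for p in profiles]
    return (
        [s for s in all_ids if s not in val_ids],
        [s for s in all_ids if s in val_ids],
    )


def split_train_validation(
    cohort: list[Recording],
    held_out_counts: dict[tuple[str, str], int],
    seed: int = 0,
) -> tuple[list[Recording], list[Recording]]:
    """Stratified held-out split by (diagnosis, amyloid), without replacement.

    ``held_out_counts`` maps (diagnosis, amyloid) to the number of subjects
    to hold out for validation.  The default study split holds out
    ``{("SCD","POS"): 13, ("SCD","NEG"): 24, ("MCI","POS"): 20,
    ("MCI","NEG"): 19}`` — 76 subjects of 311.  Deterministic under ``seed``.
    """
    for rec in cohort:
        if rec.profile is None:
            raise ValueError(f"recording {rec.subject_id} has no subject profile")
    train_ids, val_ids = split_ids(
        [r.profile for r in cohort], held_out_counts, seed=seed
    )
    val = set(val_ids)
    return (
        [r for r in cohort if r.subject_id not in val],
        [r for r in cohort if r.subject_id in val],
    )


DEFAULT_HELD_OUT_COUNTS = {
    ("SCD", "POS"): 13,
    ("SCD", "NEG"): 24,
    ("MCI", "POS"): 20,
    ("MCI", "NEG"): 19,
}
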