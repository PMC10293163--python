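"""Subject metadata and the in-memory EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from amyeeg.montage import CHANNELS, N_CHANNELS

DIAGNOSES = ("NORM", "SCD", "MCI")
AMYLOID_LABELS = ("POS", "NEG", "NA")
SEXES = ("M", "F")

VALID_SAMPLING_RATES = (200.0, 250.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics, diagnosis and amyloid-PET label for one subject.

    Normative (``NORM``) subjects span ages 40-90 and carry no amyloid label;
    study subjects (``SCD``/``MCI``) span 60-90 with a POS/NEG PET read.
    """

    subject_id: str
    age: int
    sex: str
    diagnosis: str
    amyloid: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}"
            )
        if self.amyloid not in AMYLOID_LABELS:
            raise ValueError(
                f"amyloid must be one of {AMYLOID_LABELS}, got {self.amyloid!r}"
            )
        if self.diagnosis == "NORM":
            if self.amyloid != "NA":
                raise ValueError("NORM subjects must have amyloid = NA")
            lo, hi = 40, 90
        else:
            lo, hi = 60, 90
        if not lo <= self.age <= hi:
            raise ValueError(
                f"age {self.age} outside [{lo}, {hi}] for diagnosis {self.diagnosis}"
            )


@dataclass
class Recording:
    """One subject's multichannel EEG: 19 channels x samples, microvolts.

    Channels are always the full 10-20 montage in canonical order.
    """

    subject_id: str
    fs: float
    data: np.ndarray  # (19, n_samples), microvolts
    reference: str = "linked-ear"  # linked-ear | common-average | other
    profile: SubjectProfile | None = None
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if tuple(self.channels) != CHANNELS:
            raise ValueError(
                "recording must carry the 19 standard 10-20 channels in "
                f"montage order; got {self.channels}"
            )
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"data must be ({N_CHANNELS}, n_samples); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite samples in recording {self.subject_id}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        params = dict(
            subject_id=self.subject_id,
            fs=self.fs,
            data=self.data,
            reference=self.reference,
            profile=self.profile,
        )
        params.update(kwargs)
        return Recording(**params)
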