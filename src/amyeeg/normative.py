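"""Age/sex-stratified normative database and z-scoring.

Aging and sex shift the resting EEG spectrum (slow-wave power rises and the
alpha peak slows with age); z-scoring each feature against the mean/SD of an
age- and sex-matched healthy stratum removes those physiological effects
before any group contrast is computed.  Strata are (sex x age-bin) cells;
lookup is nearest-bin only (no cross-bin smoothing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-6


@dataclass
class NormativeDB:
    """Per-(sex, age-bin) per-feature mean/SD from a healthy cohort.

    ``age_bins`` are ``[low, high)`` year intervals, except the last which
    includes its upper edge.  ``means``/``sds`` map ``(sex, bin_index)`` to a
    Series over the canonical feature names; ``counts`` holds stratum sizes.
    """

    age_bins: list[tuple[int, int]]
    means: dict[tuple[str, int], pd.Series]
    sds: dict[tuple[str, int], pd.Series]
    counts: dict[tuple[str, int], int]

    def bin_index(self, age: float) -> int:
        for k, (lo, hi) in enumerate(self.age_bins):
            last = k == len(self.age_bins) - 1
            if lo <= age < hi or (last and age == hi):
                return k
        lo, hi = self.age_bins[0][0], self.age_bins[-1][1]
        raise ValueError(f"age {age} outside the normative range [{lo}, {hi}]")

    # -- persistence ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "age_bins": [list(b) for b in self.age_bins],
            "feature_names": list(next(iter(self.means.values())).index),
            "strata": [
                {
                    "sex": sex,
                    "bin": k,
                    "n": self.counts[(sex, k)],
                    "mean": self.means[(sex, k)].tolist(),
                    "sd": self.sds[(sex, k)].tolist(),
                }
                for (sex, k) in sorted(self.means)
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeDB":
        payload = json.loads(Path(path).read_text())
        names = payload["feature_names"]
        means, sds, counts = {}, {}, {}
        for s in payload["strata"]:
            key = (s["sex"], int(s["bin"]))
            means[key] = pd.Series(s["mean"], index=names)
            sds[key] = pd.Series(s["sd"], index=names)
            counts[key] = int(s["n"])
        return cls(
            age_bins=[tuple(b) for b in payload["age_bins"]],
            means=means, sds=sds, counts=counts,
        )


def build_normative_db(
    features: pd.DataFrame,
    profiles: pd.DataFrame,
    age_bins: list[tuple[int, int]],
) -> NormativeDB:
    """Build the normative DB from a healthy cohort's feature table.

    ``features``: rows = subjects (index = subject_id), columns = the 1,520
    canonical features.  ``profiles``: same index, columns ``age`` and
    ``sex``.  Every (sex x age-bin) cell must hold >= 2 subjects.  Features
    with zero stratum SD are floored at 1e-6 (logged) so the vector length
    stays fixed.
    """
    if not len(age_bins):
        raise ValueError("age_bins must be non-empty")
    db = NormativeDB(age_bins=[tuple(b) for b in age_bins], means={}, sds={}, counts={})
    bin_idx = profiles["age"].map(db.bin_index)
    for sex in ("M", "F"):
        for k in range(len(age_bins)):
            members = profiles.index[(profiles["sex"] == sex) & (bin_idx == k)]
            if len(members) < 2:
                raise ValueError(
                    f"normative stratum (sex={sex}, age bin {age_bins[k]}) has "
                    f"{len(members)} member(s); need >= 2"
                )
            sub = features.loc[members]
            mean = sub.mean(axis=0)
            sd = sub.std(axis=0, ddof=1)
            n_floored = int((sd < SD_FLOOR).sum())
            if n_floored:
                logger.warning(
                    "stratum (%s, %s): %d feature(s) with near-zero SD floored at %g",
                    sex, age_bins[k], n_floored, SD_FLOOR,
                )
            sd = sd.clip(lower=SD_FLOOR)
            key = (sex, k)
            db.means[key] = mean
            db.sds[key] = sd
            db.counts[key] = len(members)
    return db


def standardize(
    values: pd.Series, age: float, sex: str, db: NormativeDB
) -> pd.Series:
    """Z-score one subject's features against its (sex, age-bin) stratum."""
    k = db.bin_index(age)
    key = (sex, k)
    if key not in db.means:
        raise ValueError(f"no normative stratum for sex={sex}, age bin index {k}")
    z = (values - db.means[key]) / db.sds[key]
    if not np.all(np.isfinite(z.to_numpy())):
        raise ValueError("non-finite z-scores produced during standardization")
    return z


def standardize_table(
    features: pd.DataFrame, profiles: pd.DataFrame, db: NormativeDB
) -> pd.DataFrame:
    """Z-score a whole feature table subject by subject."""
    rows = [
        standardize(features.loc[sid], profiles.loc[sid, "age"],
                    profiles.loc[sid, "sex"], db).rename(sid)
        for sid in features.index
    ]
    return pd.DataFrame(rows)
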