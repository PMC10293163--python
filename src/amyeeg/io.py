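"""Readers and writers for recordings, feature tables and cohort manifests.

Two on-disk recording formats are supported for reading: EDF (via mne, with
vendor channel-label normalization) and a plain numeric matrix (CSV,
samples x channels, microvolts) with a JSON metadata sidecar.  Writing uses
the matrix + sidecar format.  Feature tables are CSV with 12 significant
digits, one row per subject, metadata columns first.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from amyeeg.montage import CHANNELS, normalize_label
from amyeeg.recording import Recording, SubjectProfile

META_COLUMNS = ("age", "sex", "diagnosis", "amyloid")
FLOAT_FORMAT = "%.12g"


def _profile_to_dict(p: SubjectProfile | None) -> dict | None:
    if p is None:
        return None
    return {
        "subject_id": p.subject_id, "age": p.age, "sex": p.sex,
        "diagnosis": p.diagnosis, "amyloid": p.amyloid, "seed": p.seed,
    }


def write_recording(rec: Recording, directory: str | Path) -> Path:
    """Write a recording as ``<id>.csv`` (samples x channels) + ``<id>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_path = directory / f"{rec.subject_id}.csv"
    sidecar_path = directory / f"{rec.subject_id}.json"
    frame = pd.DataFrame(rec.data.T, columns=list(CHANNELS))
    frame.to_csv(data_path, index=False, float_format=FLOAT_FORMAT)
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "reference": rec.reference,
        "unit": "uV",
        "profile": _profile_to_dict(rec.profile),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return data_path


def _read_matrix_recording(path: Path) -> Recording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(path)
    matched = {}
    unmatched = []
    for col in frame.columns:
        canon = normalize_label(col)
        if canon is None:
            unmatched.append(col)
        else:
            matched[canon] = col
    missing = [c for c in CHANNELS if c not in matched]
    if missing or unmatched:
        raise ValueError(
            f"{path.name}: cannot map columns onto the 10-20 montage; "
            f"missing {missing}, unmatched {unmatched}"
        )
    data = frame[[matched[c] for c in CHANNELS]].to_numpy().T
    prof = sidecar.get("profile")
    profile = SubjectProfile(**prof) if prof else None
    return Recording(
        subject_id=sidecar["subject_id"],
        fs=float(sidecar["fs"]),
        data=data,
        reference=sidecar.get("reference", "other"),
        profile=profile,
    )


def _read_edf_recording(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    matched = {}
    unmatched = []
    for name in raw.ch_names:
        canon = normalize_label(name)
        if canon is None:
            unmatched.append(name)
        else:
            matched[canon] = name
    missing = [c for c in CHANNELS if c not in matched]
    if missing:
        raise ValueError(
            f"{path.name}: EDF channels do not cover the 10-20 montage; "
            f"missing {missing}, unmatched labels {unmatched}"
        )
    picks = [raw.ch_names.index(matched[c]) for c in CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return Recording(
        subject_id=path.stem,
        fs=float(raw.info["sfreq"]),
        data=data,
        reference="other",
        profile=None,
    )


def read_recording(path: str | Path) -> Recording:
    """Read one recording: ``.edf`` or matrix-CSV + JSON sidecar.

    Channels are matched case-insensitively (ignoring ``EEG ``/``-REF``
    decorations) and reordered into canonical montage order; values are in
    microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf_recording(path)
    return _read_matrix_recording(path)


def write_cohort(
    recordings: list[Recording],
    directory: str | Path,
    split: dict[str, str] | None = None,
) -> Path:
    """Write every recording plus a cohort manifest CSV.

    ``split`` optionally maps subject_id to 'train'/'validation'.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        data_path = write_recording(rec, directory)
        p = rec.profile
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age": p.age if p else "",
                "sex": p.sex if p else "",
                "diagnosis": p.diagnosis if p else "",
                "amyloid": p.amyloid if p else "",
                "path": data_path.name,
                "split": (split or {}).get(rec.subject_id, ""),
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def profiles_frame(recordings: list[Recording]) -> pd.DataFrame:
    """Subject metadata table (index = subject_id) from recordings."""
    rows = {}
    for rec in recordings:
        p = rec.profile
        if p is None:
            raise ValueError(f"recording {rec.subject_id} has no profile")
        rows[rec.subject_id] = {
            "age": p.age, "sex": p.sex, "diagnosis": p.diagnosis, "amyloid": p.amyloid,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def write_feature_table(
    features: pd.DataFrame, profiles: pd.DataFrame, path: str | Path,
    split: dict[str, str] | None = None,
) -> None:
    """Write a feature table CSV: metadata columns then the 1,520 features."""
    meta = profiles.loc[features.index, list(META_COLUMNS)].copy()
    if split is not None:
        meta["split"] = [split.get(s, "") for s in features.index]
    table = pd.concat([meta, features], axis=1)
    table.index.name = "subject_id"
    table.to_csv(path, float_format=FLOAT_FORMAT)


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a feature table CSV back into (features, metadata)."""
    table = pd.read_csv(path, index_col="subject_id")
    meta_cols = [c for c in list(META_COLUMNS) + ["split"] if c in table.columns]
    meta = table[meta_cols]
    features = table.drop(columns=meta_cols)
    return features, meta
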