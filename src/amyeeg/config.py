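"""Run configuration: one schema-validated structure for the whole pipeline.

A single master seed fans out to per-stage seeds through a counter scheme
(``stage_seed``), so any stage can be rerun in isolation and the full run is
deterministic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

#: Stage indices of the seed fan-out; stable across versions.
STAGES = {
    "cohort": 0,
    "normative": 1,
    "split": 2,
    "selection": 3,
    "grid": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Block):
    n_scd_pos: int = 36
    n_scd_neg: int = 160
    n_mci_pos: int = 54
    n_mci_neg: int = 61
    delta_theta: float = 0.35
    delta_beta2: float = 0.20
    mci_multiplier: float = 1.5
    blink_rate_per_min: float = 2.0
    emg_rate_per_min: float = 1.0
    line_noise_uv: float = 1.0
    line_freq: float = 60.0
    duration: float = 180.0
    fs: float = 250.0


class NormativeBlock(_Block):
    n_per_stratum: int = 20
    age_bins: list[tuple[int, int]] = Field(
        default_factory=lambda: [(40, 50), (50, 60), (60, 70), (70, 80), (80, 90)]
    )


class PreprocessBlock(_Block):
    target_fs: float = 250.0
    low: float = 1.0
    high: float = 45.5
    line_freq: float = 60.0
    epoch_length: float = 4.0
    overlap: float = 0.0
    amp_thresh: float = 100.0
    var_mult: float = 5.0
    ocular_mode: str = "regression"
    # Epoch budget per sample; None = derive from the half-recording length
    # so whole recordings and augmented halves average the same number of
    # epochs (see preprocess.PreprocessConfig.max_epochs).
    max_epochs: int | None = None


class SplitBlock(_Block):
    scd_pos: int = 13
    scd_neg: int = 24
    mci_pos: int = 20
    mci_neg: int = 19

    def as_counts(self) -> dict[tuple[str, str], int]:
        return {
            ("SCD", "POS"): self.scd_pos,
            ("SCD", "NEG"): self.scd_neg,
            ("MCI", "POS"): self.mci_pos,
            ("MCI", "NEG"): self.mci_neg,
        }


class SelectionBlock(_Block):
    alpha: float = 0.05
    k: int = 50
    exclude_confounds: bool = True


class GridBlock(_Block):
    folds: int = 5
    gate_threshold: float = 0.75
    target_sensitivity: float | None = None


class RunConfig(_Block):
    """Everything a full pipeline run needs; unknown keys are rejected."""

    schema_version: int = 1
    master_seed: int = 0
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    normative: NormativeBlock = Field(default_factory=NormativeBlock)
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    split: SplitBlock = Field(default_factory=SplitBlock)
    selection: SelectionBlock = Field(default_factory=SelectionBlock)
    grid: GridBlock = Field(default_factory=GridBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
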