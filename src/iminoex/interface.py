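"""I/O and configuration binding the analysis stages into a pipeline.

All tabular data travel as TSV (tab-delimited, UTF-8, '.' decimal,
header row) written at 17 significant digits so that writer/reader round
trips are lossless.  Structured metadata (buffer specs, noise sds,
seeds) travel as JSON sidecars validated through pydantic models.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .fitting import IntensitySeries
from .titration import OpeningComparison

__all__ = [
    "StudyConfig",
    "ConditionSpec",
    "write_intensity_table",
    "read_intensity_table",
    "write_comparison_report",
    "read_config",
]

_FLOAT_FMT = "%.17g"
INTENSITY_COLUMNS = ["residue", "condition", "delay_s", "intensity", "acq_order"]


class ConditionSpec(BaseModel):
    """Metadata of one experimental condition label."""

    total_mM: float | None = None
    pH: float | None = None
    pKa: float | None = None
    temperature_c: float | None = None
    noise_sd: float = 0.0

    @field_validator("noise_sd")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
        return v


class StudyConfig(BaseModel):
    """Resolved configuration of a full study run."""

    conditions: dict[str, ConditionSpec] = Field(default_factory=dict)
    seed: int = 0
    n_mc: int = 50
    leakage_fraction: float = 0.0
    sd_multiplier: float = 1.0
    output_dir: str = "results"

    @field_validator("n_mc")
    @classmethod
    def _mc_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_mc must be >= 1")
        return v

    @field_validator("leakage_fraction")
    @classmethod
    def _leak_range(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("leakage_fraction must be in [0, 1)")
        return v


def read_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.model_validate(json.load(fh))


def write_intensity_table(path: str | Path, series_list: list[IntensitySeries]) -> None:
    """Write intensity series as a single TSV table.

    Columns: residue, condition, delay_s, intensity, acq_order.  Noise
    sds live in the sidecar config keyed by condition label.
    """
    rows = []
    for s in series_list:
        order = (
            s.acquisition_order
            if s.acquisition_order is not None
            else np.arange(len(s))
        )
        for d, i, a in zip(s.delays, s.intensities, order):
            rows.append((s.residue, s.condition, d, i, int(a)))
    df = pd.DataFrame(rows, columns=INTENSITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_intensity_table(
    path: str | Path, config: StudyConfig | None = None
) -> list[IntensitySeries]:
    """Read a TSV intensity table back into IntensitySeries objects.

    If a config is given, each series' noise_sd is taken from the
    condition entry matching its condition label (exact match, or the
    label's prefix before ':').
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    out: list[IntensitySeries] = []
    for (residue, condition), grp in df.groupby(["residue", "condition"], sort=False):
        noise_sd = 0.0
        if config is not None:
            key = condition if condition in config.conditions else condition.split(":")[0]
            if key in config.conditions:
                noise_sd = config.conditions[key].noise_sd
        out.append(
            IntensitySeries(
                residue=str(residue),
                condition=str(condition),
                delays=grp["delay_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                acquisition_order=grp["acq_order"].to_numpy(int),
                noise_sd=noise_sd,
            )
        )
    return out


def write_comparison_report(path: str | Path, comparisons: list[OpeningComparison]) -> None:
    """Write the in-cell vs in-vitro comparison as a TSV report."""
    df = pd.DataFrame(
        [
            (
                c.residue,
                c.k_open_invitro,
                c.k_open_invitro_sd,
                c.k_ex_incell,
                c.k_ex_incell_sd,
                c.verdict,
            )
            for c in comparisons
        ],
        columns=[
            "residue",
            "k_open_invitro",
            "k_open_invitro_sd",
            "k_ex_incell",
            "k_ex_incell_sd",
            "verdict",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
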