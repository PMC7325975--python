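"""Replicate-table IO, run configuration, and validation.

The canonical on-disk format for measurements is a long-format CSV with
header ``isolate,treatment,replicate,biomass_g,cu_mg_per_g``: one row per
experimental unit, treatments restricted to control/gradual/abrupt,
biomass in g dry weight and copper accumulation in mg Cu per g dry
biomass. Numeric output is written at full precision (shortest
round-tripping decimal representation), so write-then-read is lossless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import TableValidationError
from .schedules import TREATMENT_LABELS

__all__ = [
    "RunConfig",
    "read_replicate_table",
    "write_replicate_table",
    "read_panel",
    "write_panel",
]

REQUIRED_COLUMNS = ("isolate", "treatment", "replicate", "biomass_g", "cu_mg_per_g")


@dataclass
class RunConfig:
    """Settings for one simulate-analyze-classify-report run.

    Defaults mirror the canonical study settings: a 17 x 3 x 5 design
    (255 units), 5 pre-incubation days, a 9-day treatment phase ending at
    1 mM with the abrupt step on day 5, 9999 bootstrap iterations at the
    95% confidence level, and 999 tip permutations for the signal test.
    """

    n_isolates: int = 17
    n_replicates: int = 5
    pre_incubation_days: int = 5
    treatment_days: int = 9
    final_conc: float = 1.0
    step_day: int = 5
    n_boot: int = 9999
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 1
    noise_sigma: float = 0.05
    preset_mix: dict[str, float] | None = None
    trait_mode: str = "independent"
    outdir: str = "custress_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a replicate table as CSV at full float precision."""
    table.to_csv(path, index=False)


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format replicate CSV.

    Rejects missing columns, unknown treatment labels, non-numeric or
    non-positive biomass, negative copper values and duplicate
    (isolate, treatment, replicate) keys; raises
    :class:`TableValidationError` listing every offending row. Incomplete
    design cells (unequal replicate counts) are tolerated but reported in
    the error message only when a cell is empty.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TableValidationError(f"{path}: empty replicate table") from exc
    if table.empty:
        raise TableValidationError(f"{path}: empty replicate table")

    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required columns {missing}")

    bad_treat = table.loc[~table["treatment"].isin(TREATMENT_LABELS)]
    for idx, row in bad_treat.iterrows():
        problems.append(
            f"row {idx}: unknown treatment {row['treatment']!r} "
            f"(isolate {row['isolate']!r})"
        )

    for col in ("replicate", "biomass_g", "cu_mg_per_g"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[coerced.isna()]:
            problems.append(f"row {idx}: non-numeric {col} = {table.loc[idx, col]!r}")
        table[col] = coerced

    numeric_ok = table[["biomass_g", "cu_mg_per_g"]].notna().all(axis=1)
    bad_bio = table.loc[numeric_ok & (table["biomass_g"] <= 0)]
    problems += [f"row {i}: biomass_g must be > 0" for i in bad_bio.index]
    bad_cu = table.loc[numeric_ok & (table["cu_mg_per_g"] < 0)]
    problems += [f"row {i}: cu_mg_per_g must be >= 0" for i in bad_cu.index]

    dup = table.duplicated(subset=["isolate", "treatment", "replicate"], keep=False)
    if dup.any():
        keys = table.loc[dup, ["isolate", "treatment", "replicate"]]
        problems.append(
            "duplicate (isolate, treatment, replicate) keys: "
            + "; ".join(map(str, keys.drop_duplicates().itertuples(index=False, name=None)))
        )

    # Every isolate must appear in every arm for the contrasts to exist.
    if not problems:
        cells = table.groupby(["isolate", "treatment"]).size()
        for iso in table["isolate"].unique():
            present = set(cells.loc[iso].index) if iso in cells.index else set()
            absent = set(TREATMENT_LABELS) - present
            if absent:
                problems.append(f"isolate {iso!r}: no replicates for {sorted(absent)}")

    if problems:
        raise TableValidationError(
            f"{path}: invalid replicate table:\n  " + "\n  ".join(problems)
        )
    return table


def write_panel(panel, path: str | Path) -> None:
    """Write a list of isolate parameter sets as one CSV row per isolate."""
    df = pd.DataFrame([dataclasses.asdict(p) for p in panel])
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_panel(path: str | Path) -> list:
    """Read a panel CSV written by :func:`write_panel`."""
    from .simulate import IsolateParams

    table = pd.read_csv(path, float_precision="round_trip")
    records = table.to_dict(orient="records")
    panel = []
    for rec in records:
        if "preset" in rec and pd.isna(rec["preset"]):
            rec["preset"] = None
        panel.append(IsolateParams(**rec))
    return panel
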