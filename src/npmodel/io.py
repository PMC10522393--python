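"""CSV/JSON readers and writers for schedules and incidence tables.

The schedule dialect is a plain comma-separated file with a mandatory
header ``label,age_start,age_end,generation,turnover_per_year`` and an
optional ``observed_5yr_pct`` column; scientific notation is accepted and
numeric columns round-trip at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import pandas as pd

from .model import AgeGroupRow, IncidenceTable, Schedule

REQUIRED_COLUMNS = (
    "label",
    "age_start",
    "age_end",
    "generation",
    "turnover_per_year",
)
OPTIONAL_COLUMNS = ("observed_5yr_pct",)


class ScheduleValidationError(ValueError):
    """Raised when a schedule file is malformed, naming the offending cell."""


def read_schedule(path: Union[str, Path]) -> Schedule:
    """Read a 5-year-bracket schedule from CSV.

    Raises :class:`ScheduleValidationError` naming the missing column or the
    offending row for non-numeric cells, non-contiguous brackets, and other
    structural problems.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleValidationError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    numeric = [c for c in df.columns if c != "label"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise ScheduleValidationError(
                f"{path.name}: non-numeric value {df.loc[bad[0], col]!r} in "
                f"column {col!r}, row {bad[0] + 2}"  # +2: header + 1-based
            )
        df[col] = parsed
    has_observed = "observed_5yr_pct" in df.columns
    rows = []
    for i, rec in df.iterrows():
        obs = rec["observed_5yr_pct"] if has_observed else None
        obs = None if obs is None or pd.isna(obs) else float(obs)
        try:
            rows.append(
                AgeGroupRow(
                    label=str(rec["label"]),
                    age_start=float(rec["age_start"]),
                    age_end=float(rec["age_end"]),
                    generation=float(rec["generation"]),
                    turnover_per_year=float(rec["turnover_per_year"]),
                    observed_5yr_pct=obs,
                )
            )
        except ValueError as exc:
            raise ScheduleValidationError(f"{path.name}: row {i + 2}: {exc}") from exc
    try:
        return Schedule(tuple(rows))
    except ValueError as exc:
        raise ScheduleValidationError(f"{path.name}: {exc}") from exc


def write_schedule(schedule: Schedule, path: Union[str, Path]) -> None:
    """Write a schedule to CSV at full double precision.

    The default pandas float formatting is the shortest representation that
    round-trips, so numeric columns are lossless.
    """
    schedule.to_frame().to_csv(path, index=False)


def write_incidence(table: IncidenceTable, path: Union[str, Path]) -> None:
    """Write an incidence table (schedule + computed columns) to CSV."""
    table.to_frame().to_csv(path, index=False)


def write_json(summary: dict[str, Any], path: Union[str, Path]) -> None:
    """Write a scalar summary as indented JSON."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
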