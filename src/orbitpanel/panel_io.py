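"""Binary panel container and delimited-text I/O.

A panel holds complete 0/1 answers of n subjects to p variables over
T+1 observation times.  Two text layouts are supported, both
comma-delimited with a header row:

* wide — one row per (subject, time): ``subject_id, time, <var>, ...``
* long — one row per cell: ``subject_id, time, variable, value``

Inputs are assumed to be pre-coded 0 = unfavourable / 1 = favourable;
:class:`CodingRule` carries the human-readable favourable condition of
each variable as metadata for labeling outputs, not as a transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SubjectSeries
from .errors import CodingError, CompletenessError, DimensionError

__all__ = [
    "BinaryPanel",
    "CodingRule",
    "read_panel",
    "write_panel",
    "panel_from_frame",
    "completeness_filter",
    "code_mean_constant",
    "read_strata",
]


@dataclass(frozen=True)
class CodingRule:
    """Favourable-condition descriptions, one per variable (metadata only)."""

    rules: Mapping[str, str]

    def describe(self, variable: str) -> str:
        return self.rules.get(variable, "favourable = 1")


@dataclass(frozen=True)
class BinaryPanel:
    """Complete binary longitudinal data: ``values[l, i, t]`` for subject
    l, variable i, time t."""

    values: np.ndarray = field(repr=False)
    subject_ids: tuple[str, ...]
    variables: tuple[str, ...]
    times: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise DimensionError(f"values must be (n, p, T+1), got shape {v.shape}")
        if np.isnan(v.astype(float)).any():
            raise CompletenessError("panel contains missing cells")
        if not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))][0]
            raise CodingError(f"panel contains non-binary value {bad!r}")
        n, p, nt = v.shape
        if len(self.subject_ids) != n or len(self.variables) != p or len(self.times) != nt:
            raise DimensionError("label lengths do not match value dimensions")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "variables", tuple(str(c) for c in self.variables))
        object.__setattr__(self, "times", tuple(self.times))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def T(self) -> int:
        return self.values.shape[2] - 1

    def subject(self, subject_id: str) -> SubjectSeries:
        """Extract one subject's complete series."""
        try:
            idx = self.subject_ids.index(str(subject_id))
        except ValueError:
            raise KeyError(f"unknown subject {subject_id!r}") from None
        return SubjectSeries(str(subject_id), self.values[idx])

    def subset(self, subject_ids: Sequence[str]) -> "BinaryPanel":
        """Sub-panel restricted to the given subjects (order preserved)."""
        wanted = [str(s) for s in subject_ids]
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"unknown subjects {missing}")
        sel = [pos[s] for s in wanted]
        return BinaryPanel(self.values[sel], wanted, self.variables, self.times)

    def to_wide(self) -> pd.DataFrame:
        rows = []
        for l, sid in enumerate(self.subject_ids):
            for t, time in enumerate(self.times):
                row = {"subject_id": sid, "time": time}
                row.update(
                    {v: int(self.values[l, i, t]) for i, v in enumerate(self.variables)}
                )
                rows.append(row)
        return pd.DataFrame(rows, columns=["subject_id", "time", *self.variables])

    def to_long(self) -> pd.DataFrame:
        wide = self.to_wide()
        return wide.melt(
            id_vars=["subject_id", "time"], var_name="variable", value_name="value"
        ).sort_values(["subject_id", "time", "variable"], kind="stable").reset_index(drop=True)


def _panel_from_wide(df: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    variables = [c for c in df.columns if c not in ("subject_id", "time")]
    if not variables:
        raise DimensionError("wide layout has no variable columns")
    subjects = list(dict.fromkeys(df["subject_id"].astype(str)))
    times = sorted(df["time"].unique())
    cube = np.full((len(subjects), len(variables), len(times)), np.nan)
    srow = {s: i for i, s in enumerate(subjects)}
    trow = {t: i for i, t in enumerate(times)}
    for _, row in df.iterrows():
        l, t = srow[str(row["subject_id"])], trow[row["time"]]
        for i, v in enumerate(variables):
            cube[l, i, t] = row[v]
    return cube, subjects, variables, times


def _panel_from_long(df: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    required = {"subject_id", "time", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DimensionError(f"long layout missing columns {sorted(missing)}")
    subjects = list(dict.fromkeys(df["subject_id"].astype(str)))
    variables = list(dict.fromkeys(df["variable"].astype(str)))
    times = sorted(df["time"].unique())
    cube = np.full((len(subjects), len(variables), len(times)), np.nan)
    srow = {s: i for i, s in enumerate(subjects)}
    vrow = {v: i for i, v in enumerate(variables)}
    trow = {t: i for i, t in enumerate(times)}
    for sid, time, var, val in zip(
        df["subject_id"].astype(str), df["time"], df["variable"].astype(str), df["value"]
    ):
        cube[srow[sid], vrow[var], trow[time]] = val
    return cube, subjects, variables, times


def panel_from_frame(df: pd.DataFrame, layout: str = "wide") -> BinaryPanel:
    """Validate a dataframe in wide or long layout into a complete panel.

    Raises :class:`CompletenessError` naming the first missing
    subject/variable/time cell, and :class:`CodingError` on non-binary
    values.
    """
    if df.empty:
        raise CompletenessError("empty input: no observations")
    if layout == "wide":
        cube, subjects, variables, times = _panel_from_wide(df)
    elif layout == "long":
        cube, subjects, variables, times = _panel_from_long(df)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    gaps = np.argwhere(np.isnan(cube))
    if len(gaps):
        l, i, t = gaps[0]
        raise CompletenessError(
            f"missing cell: subject {subjects[l]!r}, variable {variables[i]!r}, "
            f"time {times[t]!r} ({len(gaps)} missing cells in total)"
        )
    return BinaryPanel(cube, subjects, variables, times)


def completeness_filter(
    df: pd.DataFrame, layout: str = "wide"
) -> tuple[BinaryPanel, list[str]]:
    """Drop subjects not observed at every time with every variable.

    Returns the complete sub-panel and the list of dropped subject ids.
    Only completeness is forgiven; non-binary values still raise.
    """
    if df.empty:
        raise CompletenessError("empty input: no observations")
    if layout == "wide":
        cube, subjects, variables, times = _panel_from_wide(df)
    elif layout == "long":
        cube, subjects, variables, times = _panel_from_long(df)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    complete = ~np.isnan(cube).any(axis=(1, 2))
    kept = [s for s, ok in zip(subjects, complete) if ok]
    dropped = [s for s, ok in zip(subjects, complete) if not ok]
    if not kept:
        raise CompletenessError("no subject has complete data")
    return BinaryPanel(cube[complete], kept, variables, times), dropped


def read_panel(path: str | Path, layout: str = "wide") -> BinaryPanel:
    """Read a complete binary panel from a delimited text file."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CompletenessError(f"empty input file: {path}") from None
    return panel_from_frame(df, layout=layout)


def write_panel(panel: BinaryPanel, path: str | Path, layout: str = "wide") -> Path:
    """Write a panel as delimited text (inverse of :func:`read_panel`)."""
    path = Path(path)
    if layout == "wide":
        panel.to_wide().to_csv(path, index=False)
    elif layout == "long":
        panel.to_long().to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    return path


def code_mean_constant(values: Sequence[float]) -> tuple[int, bool]:
    """Code a per-subject binary series by its mean over observed times.

    Returns ``(code, constant)`` where code is 0 if the mean lies in
    [0, 0.5] (the boundary 0.5 codes 0) and 1 otherwise, and
    ``constant`` flags whether the series never changes.  Used for
    stratification attributes observed at a subset of times, e.g. a
    poverty indicator gathered in 4 of 7 survey years.
    """
    values = list(values)
    if not values:
        raise CompletenessError("cannot code an empty series")
    if any(v not in (0, 1) for v in values):
        raise CodingError(f"series must be binary, got {values!r}")
    mean = sum(values) / len(values)
    return (0 if mean <= 0.5 else 1), len(set(values)) == 1


def read_strata(path: str | Path) -> pd.DataFrame:
    """Read a per-subject attribute table: ``subject_id, <attr1>, ...``."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise DimensionError("strata file must have a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.set_index("subject_id")
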