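"""Reading, validating and writing fixation tables and derived artifacts.

Fixation tables are plain CSV/TSV files with one row per fixation. Column
names are configurable because eye-tracker exports vary; the defaults are
``participant, stimulus, x, y, start_ms, duration_ms``. Coordinates are
screen pixels (origin top-left, y downward), times are milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("gazegroup")

DEFAULT_COLUMNS: dict[str, str] = {
    "participant": "participant",
    "stimulus": "stimulus",
    "x": "x",
    "y": "y",
    "start": "start_ms",
    "duration": "duration_ms",
}


class FormatError(ValueError):
    """A structural problem with an input table (missing column, bad cell)."""


class ValidationError(ValueError):
    """Data violates a scanpath invariant (e.g. overlapping fixations)."""


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: where the gaze rested, when, and for how long."""

    participant_id: str
    stimulus_id: str
    x: float
    y: float
    start: float  # ms, >= 0
    duration: float  # ms, > 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates in {self}")
        if not self.duration > 0:
            raise ValidationError(f"fixation duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise ValidationError(f"fixation start must be >= 0, got {self.start}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class Scanpath:
    """Ordered fixation sequence of one participant on one stimulus."""

    participant_id: str
    stimulus_id: str
    fixations: list[FixationRecord]

    def __post_init__(self) -> None:
        if len(self.fixations) < 1:
            raise ValidationError("a scanpath needs at least one fixation")

    def __len__(self) -> int:
        return len(self.fixations)

    def xy(self) -> np.ndarray:
        """Fixation centers as an (n, 2) array."""
        return np.array([[f.x, f.y] for f in self.fixations], dtype=float)

    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)

    def starts(self) -> np.ndarray:
        return np.array([f.start for f in self.fixations], dtype=float)

    def validate(self) -> None:
        """Check temporal ordering and non-overlap of consecutive fixations."""
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.start < a.start:
                raise ValidationError(
                    f"fixations out of order in ({self.participant_id}, {self.stimulus_id})"
                )
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping fixations in ({self.participant_id}, "
                    f"{self.stimulus_id}): start {b.start} < previous end {a.end}"
                )


@dataclass
class Dataset:
    """All scanpaths of a study, keyed by (participant, stimulus)."""

    scanpaths: dict[tuple[str, str], Scanpath] = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.scanpaths:
            seen.setdefault(pid, None)
        return sorted(seen)

    @property
    def stimuli(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sid in self.scanpaths:
            seen.setdefault(sid, None)
        return sorted(seen)

    def add(self, sp: Scanpath) -> None:
        key = (sp.participant_id, sp.stimulus_id)
        if key in self.scanpaths:
            raise ValidationError(f"duplicate scanpath for {key}")
        self.scanpaths[key] = sp

    def of_participant(self, pid: str) -> list[Scanpath]:
        return [sp for (p, _), sp in sorted(self.scanpaths.items()) if p == pid]

    def drop_participants(self, pids: Iterable[str]) -> "Dataset":
        drop = set(pids)
        keep = {k: v for k, v in self.scanpaths.items() if k[0] not in drop}
        if not keep:
            raise ValidationError("cannot drop every participant")
        return Dataset(scanpaths=keep)

    def __len__(self) -> int:
        return len(self.scanpaths)


def read_fixation_table(
    path,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    repair_overlaps: bool = False,
) -> Dataset:
    """Read a CSV/TSV fixation table into a :class:`Dataset`.

    Parameters
    ----------
    path : str or Path
        Table with one row per fixation.
    columns : mapping, optional
        Overrides for the logical→physical column names
        (keys: participant, stimulus, x, y, start, duration).
    delimiter : str, optional
        Field delimiter; sniffed from the file when omitted.
    repair_overlaps : bool
        When two consecutive fixations overlap in time, keep the later
        fixation's start and truncate the earlier one instead of raising.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    sep = delimiter
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            head = fh.readline()
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","

    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    for logical in ("x", "y", "start", "duration"):
        col = colmap[logical]
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = parsed

    n_read = len(df)
    n_dropped = int(df[list(colmap.values())].isna().any(axis=1).sum())
    if n_dropped:
        df = df.dropna(subset=list(colmap.values()))
        logger.warning("dropped %d incomplete rows", n_dropped)

    ds = Dataset()
    grouped = df.groupby([colmap["participant"], colmap["stimulus"]], sort=True)
    for (pid, sid), g in grouped:
        g = g.sort_values(colmap["start"], kind="mergesort")
        fixes: list[FixationRecord] = []
        for _, row in g.iterrows():
            fixes.append(
                FixationRecord(
                    participant_id=str(pid),
                    stimulus_id=str(sid),
                    x=float(row[colmap["x"]]),
                    y=float(row[colmap["y"]]),
                    start=float(row[colmap["start"]]),
                    duration=float(row[colmap["duration"]]),
                )
            )
        if repair_overlaps:
            fixes = _repair_overlaps(fixes, pid, sid)
        sp = Scanpath(str(pid), str(sid), fixes)
        sp.validate()
        ds.add(sp)
    logger.info("read %d rows (%d dropped), %d scanpaths", n_read, n_dropped, len(ds))
    return ds


def _repair_overlaps(
    fixes: list[FixationRecord], pid: str, sid: str
) -> list[FixationRecord]:
    """Truncate fixations that run into their successor's start time."""
    out: list[FixationRecord] = []
    for a, b in zip(fixes, fixes[1:]):
        if b.start < a.start + a.duration:
            logger.warning(
                "repaired overlap in (%s, %s): truncating fixation at %s", pid, sid, a.start
            )
            new_dur = b.start - a.start
            if new_dur <= 0:
                continue  # fully swallowed by its successor
            a = FixationRecord(a.participant_id, a.stimulus_id, a.x, a.y, a.start, new_dur)
        out.append(a)
    out.append(fixes[-1])
    return out


def write_fixation_table(dataset: Dataset, path, columns: Mapping[str, str] | None = None) -> None:
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    rows = []
    for (pid, sid), sp in sorted(dataset.scanpaths.items()):
        for f in sp.fixations:
            rows.append(
                {
                    colmap["participant"]: pid,
                    colmap["stimulus"]: sid,
                    colmap["x"]: f.x,
                    colmap["y"]: f.y,
                    colmap["start"]: f.start,
                    colmap["duration"]: f.duration,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metric_table(table: pd.DataFrame, path) -> None:
    """Write a participants × metrics table as CSV (index column = participant)."""
    if table.empty:
        raise ValueError("refusing to write an empty metric table")
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("metric table contains non-finite values")
    table.to_csv(path, index=True, index_label="participant")


def read_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant")


def write_matrix(matrix: pd.DataFrame | np.ndarray, path, labels=None) -> None:
    """Write a square matrix (e.g. combined similarity) as labeled CSV."""
    if isinstance(matrix, np.ndarray):
        if labels is None:
            labels = [str(i) for i in range(matrix.shape[0])]
        matrix = pd.DataFrame(matrix, index=labels, columns=labels)
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix contains non-finite values")
    matrix.to_csv(path, index=True, index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


def write_groups(assignment: Mapping[str, int], path) -> None:
    df = pd.DataFrame(sorted(assignment.items()), columns=["id", "group"])
    df.to_csv(path, index=False)


def read_groups(path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"id": str, "group": int})
    return dict(zip(df["id"], df["group"]))


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
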