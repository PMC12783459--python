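"""Session-log data model, CSV i/o, and preprocessing filters.

Log dialect
-----------
One UTF-8 CSV file per participant session, header required, one row per
play segment plus optional typed summary rows::

    participant_id,row_type,game_id,start_s,end_s,tickets
    p01,play,maze_runner,0,70,4.2
    p01,play,n_back,75,135,2.0
    p01,summary,end_time,,,1800
    p01,summary,total_tickets,,,6.2

* ``row_type`` is ``play`` or ``summary``; a missing ``row_type`` column is
  treated as all-play for convenience.
* times are seconds from session start, 0-based, half-open ``[start_s, end_s)``.
* summary rows carry a label in ``game_id`` and a value in ``tickets``.

The reader is deliberately non-lossy: rows past the session limit, duplicated
summary rows, and legacy game labels are all preserved as read and corrected
only by :func:`clean_session_log`, mirroring the preprocessing applied to the
raw study files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

#: Session length in seconds (30 minutes).
SESSION_DURATION_S = 1800.0

#: Legacy trial-row labels known to be emitted with inconsistent spellings.
#: Maps raw label -> canonical game_id.
DEFAULT_LABEL_FIXES: dict[str, str] = {
    "Tower of Hanoi - Intermediate": "hanoi_intermediate",
    "Tower of Hanoi—Intermediate": "hanoi_intermediate",
    "tower_of_hanoi_intermediate": "hanoi_intermediate",
    "Tower of Hanoi - Expert": "hanoi_expert",
    "Tower of Hanoi—Expert": "hanoi_expert",
    "tower_of_hanoi_expert": "hanoi_expert",
}


class LogSchemaError(ValueError):
    """A required column is missing from a session-log file."""


class LogParseError(ValueError):
    """A row contains a malformed value; the message carries the row number."""


@dataclass(frozen=True)
class LogDialect:
    """Column naming for the session-log CSV schema."""

    participant_col: str = "participant_id"
    row_type_col: str = "row_type"
    game_col: str = "game_id"
    start_col: str = "start_s"
    end_col: str = "end_s"
    tickets_col: str = "tickets"
    play_row_type: str = "play"
    summary_row_type: str = "summary"

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.participant_col, self.game_col, self.start_col, self.end_col, self.tickets_col)


DEFAULT_DIALECT = LogDialect()


@dataclass(frozen=True)
class PlaySegment:
    """A contiguous interval spent at one machine, with tickets earned."""

    game_id: str
    start_s: float
    end_s: float
    tickets: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.start_s) or not math.isfinite(self.end_s):
            raise ValueError("segment times must be finite")
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})")
        if not (math.isfinite(self.tickets) and self.tickets >= 0):
            raise ValueError(f"tickets must be finite and >= 0, got {self.tickets}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionLog:
    """One participant's ordered play segments over a 30-minute session.

    Gaps between consecutive segments represent travel/idle time. Raw logs
    may contain rows past ``duration_s`` (a known logging bug); such rows are
    allowed here and removed by :func:`clean_session_log`.
    """

    participant_id: str
    segments: tuple[PlaySegment, ...]
    summary_rows: tuple[tuple[str, float], ...] = ()
    duration_s: float = SESSION_DURATION_S

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "summary_rows", tuple(self.summary_rows))
        for prev, cur in zip(segments, segments[1:]):
            if cur.start_s < prev.end_s:
                raise ValueError(
                    "segments must be chronological and non-overlapping: "
                    f"[{prev.start_s}, {prev.end_s}) then [{cur.start_s}, {cur.end_s})"
                )

    @property
    def total_tickets(self) -> float:
        return float(sum(seg.tickets for seg in self.segments))

    @property
    def is_within_limit(self) -> bool:
        """True when no segment extends past ``duration_s``."""
        return all(seg.end_s <= self.duration_s for seg in self.segments)


@dataclass(frozen=True)
class CleaningReport:
    """Tally of corrections applied by :func:`clean_session_log`."""

    rows_removed_after_limit: int = 0
    duplicate_rows_removed: int = 0
    labels_corrected: int = 0

    def __post_init__(self) -> None:
        if min(self.rows_removed_after_limit, self.duplicate_rows_removed, self.labels_corrected) < 0:
            raise ValueError("cleaning counts must be >= 0")

    @property
    def is_clean(self) -> bool:
        return (
            self.rows_removed_after_limit == 0
            and self.duplicate_rows_removed == 0
            and self.labels_corrected == 0
        )


def _parse_float(raw: str, column: str, row_number: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise LogParseError(
            f"row {row_number}: non-numeric value {raw!r} in column {column!r}"
        ) from None


def read_session_log(
    path: str | Path,
    dialect: LogDialect = DEFAULT_DIALECT,
    duration_s: float = SESSION_DURATION_S,
) -> SessionLog:
    """Read one session-log CSV, preserving row order and all raw rows.

    Raises :class:`LogSchemaError` when a required column is absent and
    :class:`LogParseError` (with the offending row number) for malformed
    numeric fields. Cleaning is a separate, explicit step.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LogSchemaError(f"{path}: empty file, header required")
        for col in dialect.required_columns:
            if col not in reader.fieldnames:
                raise LogSchemaError(f"{path}: missing required column {col!r}")
        has_row_type = dialect.row_type_col in reader.fieldnames

        participant_id = ""
        segments: list[PlaySegment] = []
        summary_rows: list[tuple[str, float]] = []
        for row_number, row in enumerate(reader, start=2):  # row 1 is the header
            participant_id = row[dialect.participant_col] or participant_id
            row_type = row[dialect.row_type_col] if has_row_type else dialect.play_row_type
            if row_type == dialect.summary_row_type:
                label = row[dialect.game_col]
                value = _parse_float(row[dialect.tickets_col], dialect.tickets_col, row_number)
                summary_rows.append((label, value))
                continue
            segments.append(
                PlaySegment(
                    game_id=row[dialect.game_col],
                    start_s=_parse_float(row[dialect.start_col], dialect.start_col, row_number),
                    end_s=_parse_float(row[dialect.end_col], dialect.end_col, row_number),
                    tickets=_parse_float(row[dialect.tickets_col], dialect.tickets_col, row_number),
                )
            )
    return SessionLog(
        participant_id=participant_id,
        segments=tuple(segments),
        summary_rows=tuple(summary_rows),
        duration_s=duration_s,
    )


def write_session_log(
    log: SessionLog, path: str | Path, dialect: LogDialect = DEFAULT_DIALECT
) -> None:
    """Write a session log in the documented CSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                dialect.participant_col,
                dialect.row_type_col,
                dialect.game_col,
                dialect.start_col,
                dialect.end_col,
                dialect.tickets_col,
            ]
        )
        for seg in log.segments:
            writer.writerow(
                [log.participant_id, dialect.play_row_type, seg.game_id,
                 _fmt(seg.start_s), _fmt(seg.end_s), _fmt(seg.tickets)]
            )
        for label, value in log.summary_rows:
            writer.writerow([log.participant_id, dialect.summary_row_type, label, "", "", _fmt(value)])


def _fmt(x: float) -> str:
    return format(x, ".10g")


def clean_session_log(
    log: SessionLog,
    label_fixes: Mapping[str, str] | None = None,
) -> tuple[SessionLog, CleaningReport]:
    """Apply the session-log preprocessing filters.

    In order:

    1. correct legacy game labels via ``label_fixes``
       (default :data:`DEFAULT_LABEL_FIXES`);
    2. drop any play segment starting at or after the session limit;
    3. truncate a segment crossing the limit at ``duration_s``, prorating its
       tickets linearly by the retained fraction (proration is the
       least-assumption way to keep the in-limit part of a partial row);
    4. remove exact consecutive duplicates of the final two summary rows.

    Cleaning is total (never raises on valid logs) and idempotent.
    """
    if label_fixes is None:
        label_fixes = DEFAULT_LABEL_FIXES

    labels_corrected = 0
    relabelled: list[PlaySegment] = []
    for seg in log.segments:
        fixed = label_fixes.get(seg.game_id)
        if fixed is not None and fixed != seg.game_id:
            relabelled.append(replace(seg, game_id=fixed))
            labels_corrected += 1
        else:
            relabelled.append(seg)

    rows_removed = 0
    kept: list[PlaySegment] = []
    for seg in relabelled:
        if seg.start_s >= log.duration_s:
            rows_removed += 1
            continue
        if seg.end_s > log.duration_s:
            fraction = (log.duration_s - seg.start_s) / seg.duration_s
            seg = replace(seg, end_s=log.duration_s, tickets=seg.tickets * fraction)
        kept.append(seg)

    summary = list(log.summary_rows)
    duplicates_removed = 0
    # The known bug duplicates the final two summary rows (end time + final
    # total); detection is exact-match on the trailing pair only.
    while len(summary) >= 4 and summary[-2:] == summary[-4:-2]:
        del summary[-2:]
        duplicates_removed += 2

    cleaned = SessionLog(
        participant_id=log.participant_id,
        segments=tuple(kept),
        summary_rows=tuple(summary),
        duration_s=log.duration_s,
    )
    report = CleaningReport(
        rows_removed_after_limit=rows_removed,
        duplicate_rows_removed=duplicates_removed,
        labels_corrected=labels_corrected,
    )
    return cleaned, report


def read_and_clean(
    path: str | Path,
    dialect: LogDialect = DEFAULT_DIALECT,
    label_fixes: Mapping[str, str] | None = None,
) -> tuple[SessionLog, CleaningReport]:
    """Convenience wrapper: read a log file then clean it."""
    return clean_session_log(read_session_log(path, dialect=dialect), label_fixes=label_fixes)
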