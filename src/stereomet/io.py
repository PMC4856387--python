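"""Readers and writers for the package's plain-text interchange formats.

All tables are tab-separated with a header row, UTF-8, times in seconds,
proportions unscaled in ``[0, 1]``. Schemas:

- trials:  ``subject_id  trial  choice  baited  rewarded``
- visits:  ``subject_id  session_id  arm_id  entry_s  exit_s``
- events:  ``subject_id  behaviour  start_s  end_s  repeat_index``
- roles JSON: ``{"1": "positive", ..., "8": "negative"}``
- scheme JSON: keys of :class:`~stereomet.ethogram.ObservationScheme`

Validation failures raise :class:`SchemaError` (malformed data, exit code 2
in the CLI) or :class:`ConfigError` (inconsistent configuration, exit code
3), naming the offending row where possible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .bias import ArmRoleMap, ArmVisit, ArmVisitLog
from .ethogram import BehaviourEvent, ObservationScheme
from .guessing import ChoiceSequence, SIDES, Trial

__all__ = [
    "SchemaError",
    "ConfigError",
    "read_trials",
    "write_trials",
    "read_visits",
    "write_visits",
    "read_events",
    "write_events",
    "read_roles",
    "read_scheme",
]

PathLike = Union[str, Path]

TRIALS_COLUMNS = ["subject_id", "trial", "choice", "baited", "rewarded"]
VISITS_COLUMNS = ["subject_id", "session_id", "arm_id", "entry_s", "exit_s"]
EVENTS_COLUMNS = ["subject_id", "behaviour", "start_s", "end_s", "repeat_index"]


class SchemaError(ValueError):
    """A file does not conform to its schema."""


class ConfigError(ValueError):
    """A configuration value is missing or inconsistent."""


def _read_tsv(path: PathLike, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface as schema failure
        raise SchemaError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_trials(path: PathLike) -> list[ChoiceSequence]:
    """Read a trials TSV into one :class:`ChoiceSequence` per subject.

    Subject order follows first appearance; trial order follows the
    ``trial`` column, which must be contiguous 1..n per subject. Side codes
    are case-sensitive single characters.
    """
    df = _read_tsv(path, TRIALS_COLUMNS)
    sequences: dict[str, list[Trial]] = {}
    seen: set[tuple[str, int]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.subject_id
        try:
            idx = int(row.trial)
            rewarded = int(row.rewarded)
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: non-integer field ({exc})") from exc
        if row.choice not in SIDES or row.baited not in SIDES:
            raise SchemaError(
                f"{path}: row {row_no}: choice/baited must be 'L' or 'R' "
                f"(case-sensitive), got {row.choice!r}/{row.baited!r}"
            )
        if rewarded not in (0, 1):
            raise SchemaError(f"{path}: row {row_no}: rewarded must be 0 or 1")
        if (sid, idx) in seen:
            raise SchemaError(f"{path}: row {row_no}: duplicate trial {idx} for {sid!r}")
        seen.add((sid, idx))
        try:
            trial = Trial(index=idx, choice=row.choice, baited=row.baited,
                          rewarded=bool(rewarded))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: {exc}") from exc
        sequences.setdefault(sid, []).append(trial)
    out = []
    for sid, trials in sequences.items():
        trials.sort(key=lambda t: t.index)
        try:
            out.append(ChoiceSequence(subject_id=sid, trials=trials))
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return out


def write_trials(sequences: list[ChoiceSequence], path: PathLike) -> None:
    rows = [
        {"subject_id": s.subject_id, "trial": t.index, "choice": t.choice,
         "baited": t.baited, "rewarded": int(t.rewarded)}
        for s in sequences
        for t in s.trials
    ]
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_visits(
    path: PathLike,
    roles: ArmRoleMap,
    duration_s: float = 600.0,
) -> list[ArmVisitLog]:
    """Read a visits TSV into one log per (subject, session).

    A missing/empty ``exit_s`` means the session ended inside the arm and
    is truncated at ``duration_s``. Overlapping visits and arms absent from
    the role map are rejected with their row number.
    """
    df = _read_tsv(path, VISITS_COLUMNS)
    grouped: dict[tuple[str, str], list[ArmVisit]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            arm = int(row.arm_id)
            entry = float(row.entry_s)
            exit_ = float(row.exit_s) if row.exit_s != "" else duration_s
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: bad numeric field ({exc})") from exc
        if arm not in roles:
            raise ConfigError(f"{path}: row {row_no}: arm {arm} has no role assigned")
        try:
            visit = ArmVisit(arm_id=arm, entry_s=entry, exit_s=min(exit_, duration_s))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: {exc}") from exc
        grouped.setdefault((row.subject_id, row.session_id), []).append(visit)
    logs = []
    for (sid, sess), visits in grouped.items():
        visits.sort(key=lambda v: v.entry_s)
        try:
            logs.append(ArmVisitLog(subject_id=sid, session_id=sess,
                                    duration_s=duration_s, visits=visits))
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return logs


def write_visits(logs: list[ArmVisitLog], path: PathLike) -> None:
    rows = [
        {"subject_id": log.subject_id, "session_id": log.session_id,
         "arm_id": v.arm_id, "entry_s": v.entry_s, "exit_s": v.exit_s}
        for log in logs
        for v in log.visits
    ]
    pd.DataFrame(rows, columns=VISITS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path: PathLike) -> dict[str, list[BehaviourEvent]]:
    """Read an events TSV into per-subject time-ordered event lists."""
    df = _read_tsv(path, EVENTS_COLUMNS)
    out: dict[str, list[BehaviourEvent]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = float(row.start_s)
            end = float(row.end_s)
            rep = int(row.repeat_index) if row.repeat_index != "" else None
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: bad numeric field ({exc})") from exc
        try:
            ev = BehaviourEvent(behaviour=row.behaviour, start_s=start,
                                end_s=end, repeat_index=rep)
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row_no}: {exc}") from exc
        out.setdefault(row.subject_id, []).append(ev)
    for evs in out.values():
        evs.sort(key=lambda e: (e.start_s, e.end_s))
    return out


def write_events(events: dict[str, list[BehaviourEvent]], path: PathLike) -> None:
    rows = [
        {"subject_id": sid, "behaviour": e.behaviour, "start_s": e.start_s,
         "end_s": e.end_s,
         "repeat_index": "" if e.repeat_index is None else e.repeat_index}
        for sid, evs in events.items()
        for e in evs
    ]
    pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_roles(path: PathLike) -> ArmRoleMap:
    """Read an arm-role JSON map, e.g. ``{"1": "positive", ...}``."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot read roles JSON ({exc})") from exc
    try:
        return ArmRoleMap({int(k): v for k, v in raw.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def read_scheme(path: PathLike) -> ObservationScheme:
    """Read an observation-scheme JSON (missing keys take the defaults)."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot read scheme JSON ({exc})") from exc
    if "block_starts_s" in raw:
        raw["block_starts_s"] = tuple(float(x) for x in raw["block_starts_s"])
    try:
        return ObservationScheme(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
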