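"""Per-subject summary tables and the multi-stage pipeline runner.

The table builders turn validated in-memory objects into tidy pandas
DataFrames (one row per subject or subject x session); ``run_pipeline``
chains file reading, the analyses and output writing from a single
:class:`RunConfig`, and writes a machine-readable manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .bias import ArmRoleMap, ArmVisitLog, bias_scores
from .ethogram import (
    BehaviourEvent,
    ObservationScheme,
    STEREOTYPY_FORMS,
    one_zero_sample,
    stereotypy_level,
)
from .guessing import ChoiceSequence
from .io import ConfigError, read_events, read_roles, read_scheme, read_trials, read_visits
from .perseveration import (
    markov_perseveration,
    pure_alternations,
    pure_repetitions,
    side_bias,
    tetragram_counts,
    correct_choice_proportion,
)

__all__ = [
    "RunConfig",
    "perseveration_table",
    "bias_table",
    "ethogram_table",
    "run_pipeline",
]

log = logging.getLogger("stereomet")


def perseveration_table(
    sequences: Sequence[ChoiceSequence], order: int = 3, null: str = "marginal"
) -> pd.DataFrame:
    """One row per subject: perseveration test plus secondary measures."""
    rows = []
    for seq in sequences:
        res = markov_perseveration(seq, order=order, null=null)
        table = tetragram_counts(seq)
        rows.append(
            {
                "subject_id": seq.subject_id,
                "n_trials": seq.n,
                "chi_sq": res.chi_sq,
                "df": res.df,
                "p": res.p,
                "P": res.P,
                "logitP": res.logitP,
                "clamped": int(res.clamped),
                "repetitions": pure_repetitions(table),
                "alternations": pure_alternations(table),
                "side_bias": side_bias(seq),
                "correct_prop": correct_choice_proportion(seq),
            }
        )
    return pd.DataFrame(rows)


def bias_table(logs: Sequence[ArmVisitLog], roles: ArmRoleMap) -> pd.DataFrame:
    """One row per subject x session: arm scores and occupancy summaries."""
    rows = []
    for log_ in logs:
        s = bias_scores(log_, roles)
        row = {
            "subject_id": log_.subject_id,
            "session_id": log_.session_id,
            "positive_arm_score": s.positive_arm_score,
            "reference_arm_score": s.reference_arm_score,
            "ambiguous_arm_score": s.ambiguous_arm_score,
            "total_entries": s.total_entries,
            "rel_time_centre": s.centre_time_s / log_.duration_s,
        }
        for role, v in s.rel_time.items():
            row[f"rel_time_{role}"] = v
        for role, v in s.rel_entries.items():
            row[f"rel_entries_{role}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def ethogram_table(
    events_by_subject: dict[str, list[BehaviourEvent]],
    scheme: ObservationScheme,
) -> pd.DataFrame:
    """One row per subject: stereotypy levels and activity.

    ``sqrt_level_<form>`` columns carry the square-root transform commonly
    applied before model fitting; the inference itself is out of scope.
    """
    rows = []
    for sid, events in events_by_subject.items():
        matrix = one_zero_sample(events, scheme, subject_id=sid)
        active_prop = float(matrix.data["active"].mean())
        row = {
            "subject_id": sid,
            "n_intervals": matrix.n_intervals,
            "active_prop": active_prop,
        }
        for form in STEREOTYPY_FORMS + ("all",):
            lvl = stereotypy_level(matrix, form)
            row[f"level_{form}"] = lvl
            row[f"sqrt_level_{form}"] = math.sqrt(lvl) if not math.isnan(lvl) else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stages`` is a list of dicts, each with a ``stage`` key in
    ``{'perseveration', 'bias_scores', 'ethogram'}`` plus that stage's input
    paths and parameters (see the TSV/JSON schemas in :mod:`stereomet.io`).
    """

    out_dir: Path
    seed: Optional[int] = None
    stages: list[dict] = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"{path}: cannot read run config ({exc})") from exc
        try:
            return cls(
                out_dir=Path(raw["out_dir"]),
                seed=raw.get("seed"),
                stages=list(raw.get("stages", [])),
                log_level=raw.get("log_level", "INFO"),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from exc


def _melt_long(df: pd.DataFrame, id_cols: list[str]) -> pd.DataFrame:
    value_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(id_vars=id_cols, value_vars=value_cols,
                   var_name="metric", value_name="value")
    for col in ("session_id",):
        if col not in long.columns:
            long[col] = ""
    return long[["subject_id", "session_id", "metric", "value"]]


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the configured stages and write results plus a manifest.

    Writes, under ``config.out_dir``: one TSV per stage, a combined
    long-format ``results.tsv`` (subject, session, metric, value) and
    ``manifest.json`` recording the seed, package version, stage parameters
    and record counts. Returns the long-format table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_parts: list[pd.DataFrame] = []
    manifest: dict = {
        "package": "stereomet",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    for spec in config.stages:
        if "stage" not in spec:
            raise ConfigError(f"stage entry without 'stage' key: {spec}")
        stage = spec["stage"]
        entry = {"stage": stage, "params": {k: v for k, v in spec.items() if k != "stage"}}
        if stage == "perseveration":
            seqs = read_trials(spec["trials"])
            df = perseveration_table(
                seqs, order=int(spec.get("order", 3)), null=spec.get("null", "marginal")
            )
            df.to_csv(out_dir / "perseveration.tsv", sep="\t", index=False)
            long_parts.append(_melt_long(df, ["subject_id"]))
            entry["n_subjects"] = len(seqs)
        elif stage == "bias_scores":
            roles = read_roles(spec["roles"])
            logs = read_visits(spec["visits"], roles,
                               duration_s=float(spec.get("duration_s", 600.0)))
            df = bias_table(logs, roles)
            df.to_csv(out_dir / "bias.tsv", sep="\t", index=False)
            long_parts.append(_melt_long(df, ["subject_id", "session_id"]))
            entry["n_sessions"] = len(logs)
        elif stage == "ethogram":
            scheme = read_scheme(spec["scheme"]) if "scheme" in spec else ObservationScheme()
            events = read_events(spec["events"])
            df = ethogram_table(events, scheme)
            df.to_csv(out_dir / "ethogram.tsv", sep="\t", index=False)
            long_parts.append(_melt_long(df, ["subject_id"]))
            entry["n_subjects"] = len(events)
        else:
            raise ConfigError(f"unknown stage {stage!r}")
        manifest["stages"].append(entry)
        log.info("stage %s done", stage)

    if long_parts:
        results = pd.concat(long_parts, ignore_index=True)
    else:
        results = pd.DataFrame(columns=["subject_id", "session_id", "metric", "value"])
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
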