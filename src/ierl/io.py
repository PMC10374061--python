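"""Readers and writers for the package's file formats.

The canonical interchange format is a long-format trial CSV, one row
per trial:

``subject_id, phase, trial_index, context_ids, option_ids, choice,
outcomes, revealed_mask, feedback_regime``

``context_ids``, ``option_ids``, ``outcomes`` and ``revealed_mask`` are
';'-joined and aligned by position; ``context_ids`` holds each
available option's learning context of origin.  Outcomes are stored in
raw (unrescaled) units.  Fit and comparison reports are JSON with a
``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import TaskDesign, Trial, TrialRecord

__all__ = [
    "write_trials",
    "read_trials",
    "records_to_frame",
    "records_from_frame",
    "cohort_from_frame",
    "write_params",
    "read_params",
    "write_json_report",
]

SCHEMA_VERSION = 1

_COLUMNS = [
    "subject_id",
    "phase",
    "trial_index",
    "context_ids",
    "option_ids",
    "choice",
    "outcomes",
    "revealed_mask",
    "feedback_regime",
]


class TrialFileError(ValueError):
    """Raised when a trial CSV violates the schema."""


def records_to_frame(per_subject: dict[str, list[TrialRecord]], design: TaskDesign) -> pd.DataFrame:
    """Flatten per-subject records into the long trial-CSV frame."""
    rows = []
    for subject_id, records in per_subject.items():
        for t, rec in enumerate(records):
            trial = rec.trial
            opts = trial.options
            ctxs = [design.home_context(o).context_id for o in opts]
            rows.append(
                {
                    "subject_id": subject_id,
                    "phase": trial.phase,
                    "trial_index": t,
                    "context_ids": ";".join(ctxs),
                    "option_ids": ";".join(opts),
                    "choice": rec.choice,
                    "outcomes": ";".join(repr(float(rec.outcomes[o])) for o in opts),
                    "revealed_mask": ";".join(
                        str(int(rec.revealed.get(o, False))) for o in opts
                    ),
                    "feedback_regime": trial.feedback,
                }
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_trials(path, per_subject: dict[str, list[TrialRecord]], design: TaskDesign) -> None:
    records_to_frame(per_subject, design).to_csv(path, index=False)


def _trial_context_id(phase, option_ids, context_ids, design: TaskDesign, row) -> str:
    if phase in ("learning", "rating"):
        unique = set(context_ids)
        if len(unique) != 1:
            raise TrialFileError(
                f"row {row}: learning trial spans contexts {sorted(unique)}"
            )
        return context_ids[0]
    target = frozenset(option_ids)
    for c in design.test_contexts:
        if frozenset(c.option_ids) == target:
            return c.context_id
    raise TrialFileError(
        f"row {row} (column option_ids): no test pairing matches {sorted(target)}"
    )


def records_from_frame(df: pd.DataFrame, design: TaskDesign) -> list[TrialRecord]:
    """Parse one subject's rows (already sorted by trial_index)."""
    records = []
    last_index = -1
    for row_label, row in df.iterrows():
        idx = int(row["trial_index"])
        if idx <= last_index:
            raise TrialFileError(
                f"row {row_label} (column trial_index): indices must increase"
            )
        last_index = idx
        opts = tuple(str(row["option_ids"]).split(";"))
        ctxs = str(row["context_ids"]).split(";")
        if len(ctxs) != len(opts):
            raise TrialFileError(
                f"row {row_label} (column context_ids): {len(ctxs)} entries "
                f"for {len(opts)} options"
            )
        outs = str(row["outcomes"]).split(";")
        mask = str(row["revealed_mask"]).split(";")
        if len(outs) != len(opts):
            raise TrialFileError(
                f"row {row_label} (column outcomes): {len(outs)} entries "
                f"for {len(opts)} options"
            )
        if len(mask) != len(opts):
            raise TrialFileError(
                f"row {row_label} (column revealed_mask): {len(mask)} entries "
                f"for {len(opts)} options"
            )
        choice = str(row["choice"])
        if choice not in opts:
            raise TrialFileError(
                f"row {row_label} (column choice): {choice!r} not among {opts}"
            )
        phase = str(row["phase"])
        ctx_id = _trial_context_id(phase, opts, ctxs, design, row_label)
        trial = Trial(phase, ctx_id, opts, str(row["feedback_regime"]))
        records.append(
            TrialRecord(
                trial,
                choice,
                {o: float(v) for o, v in zip(opts, outs)},
                {o: bool(int(m)) for o, m in zip(opts, mask)},
            )
        )
    return records


def cohort_from_frame(df: pd.DataFrame, design: TaskDesign) -> dict[str, list[TrialRecord]]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrialFileError(f"missing column(s): {', '.join(missing)}")
    out = {}
    df = df.assign(trial_index=df["trial_index"].astype(int))
    for subject_id, sub in df.groupby("subject_id", sort=False):
        out[str(subject_id)] = records_from_frame(
            sub.sort_values("trial_index"), design
        )
    return out


def read_trials(path, design: TaskDesign) -> dict[str, list[TrialRecord]]:
    """Read a trial CSV into per-subject record lists (round-trips with
    :func:`write_trials` bit-exactly)."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise TrialFileError(f"missing column(s): {', '.join(missing)}")
        return {}
    return cohort_from_frame(df, design)


# ---------------------------------------------------------------------------
# JSON sidecars and reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_params(path, params_per_subject: dict[str, dict[str, float]], meta=None) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "params": _jsonable(params_per_subject)}
    if meta:
        payload.update(_jsonable(meta))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_params(path) -> dict[str, dict[str, float]]:
    return json.loads(Path(path).read_text())["params"]


def write_json_report(path, payload: dict) -> None:
    body = {"schema_version": SCHEMA_VERSION}
    body.update(_jsonable(payload))
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True))
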