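"""Domain types, validation, and delimited-text I/O for trial and SPQ tables.

A trial table has one row per behavioral trial: participant id, group
(DOP / NOP), feedback condition, emotion, actor id (1-10), trial index
(1-10, the ordinal presentation of that emotion within its block),
reaction time in seconds on (0, 10], and correctness (0/1).  Column
names follow the canonical schema below; a remapping dialect covers
other layouts.

SPQ tables come in two dialects: 74 dichotomous item columns
(item_1 .. item_74) or precomputed factor columns (raw_cp, raw_in,
raw_di, raw_total, optionally z_cp / z_in / z_di).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import EMOTIONS, FEEDBACK_LEVELS, GROUPS

__all__ = [
    "TrialRecord", "SPQProfile", "Dataset",
    "SchemaError", "ValidationError",
    "read_trial_table", "write_trial_table",
    "read_spq_table", "write_spq_table",
    "write_summary", "validate_trials",
]

TRIAL_COLUMNS = ("participant_id", "group", "feedback", "emotion",
                 "actor_id", "trial_index", "rt_seconds", "correct")

#: below this RT the log-RT covariate becomes an extreme negative value
RT_WARN_THRESHOLD = 0.05


class SchemaError(ValueError):
    """A required column is missing or the file layout is unrecognised."""


class ValidationError(ValueError):
    """One or more rows violate a dataset invariant.

    Carries the full list of violations in ``errors``, not only the
    first one found.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} validation error(s): {preview}{more}")


@dataclass
class TrialRecord:
    """One behavioral trial with its covariates and outcome."""

    participant_id: str
    group: str
    feedback: str
    emotion: str
    actor_id: int
    trial_index: int
    rt_seconds: float
    correct: int


@dataclass
class SPQProfile:
    """Raw and (optionally) standardized SPQ three-factor scores.

    CP (Cognitive-Perceptual) and IN (Interpersonal) range 0-33, DI
    (Disorganized) 0-16, the total 0-74.  The Suspiciousness subscale
    contributes to both CP and IN but only once to the total.
    """

    raw_cp: int
    raw_in: int
    raw_di: int
    raw_total: int
    z_cp: Optional[float] = None
    z_in: Optional[float] = None
    z_di: Optional[float] = None


@dataclass
class Dataset:
    """Trial table plus an optional participant -> SPQProfile mapping."""

    trials: pd.DataFrame
    spq: dict = field(default_factory=dict)
    meta: Optional[pd.DataFrame] = None  # unknown input columns, row-aligned

    def to_records(self) -> list[TrialRecord]:
        return [TrialRecord(**{c: row[c] for c in TRIAL_COLUMNS})
                for row in self.trials.to_dict("records")]

    @classmethod
    def from_records(cls, records, spq=None) -> "Dataset":
        df = pd.DataFrame([vars(r) for r in records], columns=TRIAL_COLUMNS)
        return cls(trials=df, spq=dict(spq or {}))

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.trials["participant_id"]))


# ---------------------------------------------------------------------------
# validation

def validate_trials(df: pd.DataFrame, emotions=EMOTIONS) -> list[str]:
    """Return the full list of invariant violations (empty if valid)."""
    errors: list[str] = []
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column '{col}'")
    if errors:
        return errors
    emoset, grpset, fbset = set(emotions), set(GROUPS), set(FEEDBACK_LEVELS)
    rts = pd.to_numeric(df["rt_seconds"], errors="coerce")
    for i, (grp, fb, emo, actor, tidx, rt, corr) in enumerate(zip(
            df["group"], df["feedback"], df["emotion"], df["actor_id"],
            df["trial_index"], rts, df["correct"])):
        row = f"row {i}"
        if grp not in grpset:
            errors.append(f"{row}: unknown group label '{grp}'")
        if fb not in fbset:
            errors.append(f"{row}: unknown feedback label '{fb}'")
        if emo not in emoset:
            errors.append(f"{row}: unknown emotion label '{emo}'")
        try:
            if not (1 <= int(actor) <= 10):
                errors.append(f"{row}: actor_id {actor} outside 1..10")
        except (TypeError, ValueError):
            errors.append(f"{row}: non-integer actor_id '{actor}'")
        try:
            if not (1 <= int(tidx) <= 10):
                errors.append(f"{row}: trial_index {tidx} outside 1..10")
        except (TypeError, ValueError):
            errors.append(f"{row}: non-integer trial_index '{tidx}'")
        if not np.isfinite(rt) or rt <= 0 or rt > 10:
            errors.append(f"{row}: rt_seconds {rt} outside (0, 10]")
        if corr not in (0, 1):
            errors.append(f"{row}: correct must be 0 or 1, got '{corr}'")
    # one group per participant
    bygroup = df.groupby("participant_id")["group"].nunique()
    for pid in bygroup.index[bygroup > 1]:
        errors.append(f"participant '{pid}' appears in more than one group")
    # each (participant, feedback, emotion, trial_index) at most once
    dup = df.duplicated(
        subset=["participant_id", "feedback", "emotion", "trial_index"])
    for i in np.flatnonzero(dup.to_numpy()):
        errors.append(
            f"row {i}: duplicate (feedback, emotion, trial_index) triple "
            f"for participant '{df['participant_id'].iat[i]}'")
    if not errors:
        small = rts[(rts > 0) & (rts < RT_WARN_THRESHOLD)]
        if len(small):
            warnings.warn(
                f"{len(small)} trial(s) with rt_seconds < {RT_WARN_THRESHOLD}s: "
                "the log-RT covariate will be an extreme negative value",
                stacklevel=2)
    return errors


# ---------------------------------------------------------------------------
# trial-table I/O

def read_trial_table(path, dialect: Optional[dict] = None,
                     emotions=EMOTIONS) -> Dataset:
    """Read a delimited trial table into a validated Dataset (trials only).

    ``dialect`` may carry ``delimiter`` (default ',') and ``columns``, a
    mapping from canonical names to the file's column names.  Unknown
    columns are preserved, row-aligned, on ``Dataset.meta``; row order
    is retained.
    """
    dialect = dialect or {}
    df = pd.read_csv(path, sep=dialect.get("delimiter", ","))
    rename = {v: k for k, v in dialect.get("columns", {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    trials = df[list(TRIAL_COLUMNS)].copy()
    errors = validate_trials(trials, emotions=emotions)
    if errors:
        raise ValidationError(errors)
    trials["participant_id"] = trials["participant_id"].astype(str)
    trials["actor_id"] = trials["actor_id"].astype(int)
    trials["trial_index"] = trials["trial_index"].astype(int)
    trials["rt_seconds"] = trials["rt_seconds"].astype(float)
    trials["correct"] = trials["correct"].astype(int)
    meta = df[extra].copy() if extra else None
    return Dataset(trials=trials, meta=meta)


def write_trial_table(dataset: Dataset, path) -> None:
    dataset.trials.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SPQ-table I/O

_ITEM_COLS = [f"item_{i}" for i in range(1, 75)]
_FACTOR_RANGES = {"raw_cp": 33, "raw_in": 33, "raw_di": 16, "raw_total": 74}


def read_spq_table(path) -> dict:
    """Read an SPQ table (items or factor scores) into pid -> SPQProfile.

    Item files are scored with the default subscale key; factor files
    are range-checked.  Standardization is deferred to the spq module.
    """
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise SchemaError("missing required column 'participant_id'")
    if all(c in df.columns for c in _ITEM_COLS):
        return _profiles_from_items(df)
    if all(c in df.columns for c in ("raw_cp", "raw_in", "raw_di", "raw_total")):
        return _profiles_from_factors(df)
    raise SchemaError(
        "SPQ table must contain either item_1..item_74 or "
        "raw_cp/raw_in/raw_di/raw_total columns")


def _profiles_from_items(df: pd.DataFrame) -> dict:
    from . import spq as spqmod
    items = df[_ITEM_COLS].to_numpy()
    errors = [f"row {i}: item value outside {{0,1}}"
              for i in range(len(df))
              if not np.isin(items[i], (0, 1)).all()]
    if errors:
        raise ValidationError(errors)
    matrix = spqmod.SPQItemMatrix(responses=items.astype(int))
    sums = spqmod.score_subscales(matrix)
    profiles = spqmod.factor_scores(sums)
    return {str(pid): prof for pid, prof in zip(df["participant_id"], profiles)}


def _profiles_from_factors(df: pd.DataFrame) -> dict:
    errors = []
    for i, row in df.iterrows():
        for col, hi in _FACTOR_RANGES.items():
            v = row[col]
            if not (0 <= v <= hi):
                errors.append(f"row {i}: {col}={v} outside 0..{hi}")
        cp, in_, di, tot = (row["raw_cp"], row["raw_in"], row["raw_di"],
                            row["raw_total"])
        if all(0 <= v for v in (cp, in_, di)):
            shared_max = min(8, cp, in_)  # Suspiciousness capacity
            if not (cp + in_ + di - shared_max <= tot <= cp + in_ + di):
                errors.append(
                    f"row {i}: raw_total={tot} inconsistent with factor "
                    f"scores ({cp}, {in_}, {di})")
    if errors:
        raise ValidationError(errors)
    out = {}
    has_z = all(c in df.columns for c in ("z_cp", "z_in", "z_di"))
    for _, row in df.iterrows():
        prof = SPQProfile(int(row["raw_cp"]), int(row["raw_in"]),
                          int(row["raw_di"]), int(row["raw_total"]))
        if has_z:
            prof.z_cp = float(row["z_cp"])
            prof.z_in = float(row["z_in"])
            prof.z_di = float(row["z_di"])
        out[str(row["participant_id"])] = prof
    return out


def write_spq_table(spq: dict, path) -> None:
    rows = []
    for pid, p in spq.items():
        row = {"participant_id": pid, "raw_cp": p.raw_cp, "raw_in": p.raw_in,
               "raw_di": p.raw_di, "raw_total": p.raw_total}
        if p.z_cp is not None:
            row.update(z_cp=p.z_cp, z_in=p.z_in, z_di=p.z_di)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result artifacts

def write_summary(results: dict, outdir, decisions: Optional[dict] = None):
    """Write analysis tables as CSV plus one JSON report of decisions.

    ``results`` maps table names to DataFrames.  Floats are printed in
    shortest round-trip representation, so reading back with
    ``pd.read_csv(..., float_precision="round_trip")`` reproduces every
    value bit-exactly.  Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = outdir / "decisions.json"
    with open(p, "w") as fh:
        json.dump(decisions or {}, fh, indent=2, sort_keys=True)
    written.append(p)
    return written
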