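"""Canonical data model for the virtual-hand agency experiment.

One row per trial. A participant performs a finger movement while watching a
virtual hand; on 75% of trials the displayed movement is altered in one of two
aspects — a temporal delay (100/200/300 ms) or a spatial angular deviation
(6/10/14 degrees) — at one of three magnitudes, and on 25% it is unaltered.
The participant judges whether the displayed movement was identical to their
own (the agency judgment) and rates confidence on a continuous slider in
[-3, 3].

Trials carry exclusion flags for the pre-registered removal reasons (no
movement made, camera malfunction, no response). Magnitude is coded as an
ordinal level 0-3 shared by both aspects; unaltered trials have aspect
``none`` and are shared by both aspects in all per-aspect analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "psychosis")
ASPECTS = ("temporal", "spatial", "none")
EXCLUSION_REASONS = ("none", "no_movement", "camera_malfunction", "no_response")

#: physical magnitude per ordinal level, by aspect (ms / degrees)
MAGNITUDE_VALUES = {
    "temporal": {1: 100.0, 2: 200.0, 3: 300.0},
    "spatial": {1: 6.0, 2: 10.0, 3: 14.0},
}

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "block",
    "trial_index",
    "aspect",
    "magnitude_level",
    "magnitude_value",
    "response_identical",
    "confidence",
    "excluded",
    "exclusion_reason",
]

CLINICAL_COLUMNS = [
    "panss_positive",
    "panss_negative",
    "panss_general",
    "panss_total",
    "spqb_cogper",
    "spqb_inter",
    "spqb_disorg",
    "spqb_total",
]

PARTICIPANT_COLUMNS = ["participant_id", "group"] + CLINICAL_COLUMNS


class SchemaError(ValueError):
    """Input table does not have the documented columns."""


class ValidationError(ValueError):
    """Rows violate trial-record invariants; carries row-level diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        preview = "\n".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n... and {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} invalid row(s):\n{preview}{more}")


@dataclass
class StudyDataset:
    """Trial table + participant table + provenance metadata.

    ``trials`` follows the documented trial schema (plus a derived boolean
    ``altered`` column); ``participants`` has one row per participant with
    group membership and clinical scores (PANSS subscales for patients,
    SPQ-B subscales for controls; the other scale's columns are NaN).
    """

    trials: pd.DataFrame
    participants: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.trials.copy(), self.participants.copy(), dict(self.provenance))

    def retained(self) -> pd.DataFrame:
        """Trials surviving the pre-registered exclusions."""
        return self.trials[~self.trials["excluded"]]


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw trial table against the record invariants.

    Returns a normalized copy (dtypes coerced, ``altered`` derived).  Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    listing the offending rows for invariant violations.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    out = df[TRIAL_COLUMNS].copy()
    problems: list[str] = []

    def bad(mask: pd.Series, msg: str) -> None:
        for idx in out.index[np.asarray(mask, dtype=bool)]:
            problems.append(f"row {idx}: {msg}")

    bad(~out["group"].isin(GROUPS), f"group not in {GROUPS}")
    bad(~out["aspect"].isin(ASPECTS), f"aspect not in {ASPECTS}")
    bad(~out["exclusion_reason"].isin(EXCLUSION_REASONS), "unknown exclusion_reason")

    block = pd.to_numeric(out["block"], errors="coerce")
    bad(block.isna() | (block < 1) | (block > 5) | (block != block.round()), "block must be integer 1-5")
    tidx = pd.to_numeric(out["trial_index"], errors="coerce")
    bad(tidx.isna() | (tidx < 1) | (tidx != tidx.round()), "trial_index must be integer >= 1")
    level = pd.to_numeric(out["magnitude_level"], errors="coerce")
    bad(level.isna() | ~level.isin([0, 1, 2, 3]), "magnitude_level must be 0-3")
    value = pd.to_numeric(out["magnitude_value"], errors="coerce")

    # aspect/level/value consistency
    is_none = out["aspect"] == "none"
    bad(is_none & ((level != 0) | (value != 0)), "aspect 'none' requires magnitude_level 0 and value 0")
    bad(~is_none & (level == 0), "altered aspect requires magnitude_level in {1,2,3}")
    for aspect, table in MAGNITUDE_VALUES.items():
        sel = out["aspect"] == aspect
        for lvl, val in table.items():
            m = sel & (level == lvl) & (value != val)
            bad(m, f"{aspect} level {lvl} must have magnitude_value {val}")

    conf = pd.to_numeric(out["confidence"], errors="coerce")
    bad(out["confidence"].notna() & conf.isna(), "confidence not numeric")
    bad(conf.notna() & ((conf < -3) | (conf > 3)), "confidence outside [-3, 3]")

    excluded = _to_bool(out["excluded"], problems, "excluded")
    bad(excluded & (out["exclusion_reason"] == "none"), "excluded=true requires a reason")
    bad(~excluded & (out["exclusion_reason"] != "none"), "exclusion_reason set but excluded=false")

    # duplicate trial indices within a participant
    dup = out.duplicated(subset=["participant_id", "trial_index"], keep=False)
    bad(dup & ~out.duplicated(subset=["participant_id", "trial_index"]), "duplicate trial_index within participant")

    if problems:
        raise ValidationError(problems)

    out["block"] = block.astype(int)
    out["trial_index"] = tidx.astype(int)
    out["magnitude_level"] = level.astype(int)
    out["magnitude_value"] = value.astype(float)
    out["confidence"] = conf
    out["excluded"] = excluded
    out["response_identical"] = _to_bool_or_na(out["response_identical"])
    out["altered"] = out["magnitude_level"] > 0
    return out


def _to_bool(col: pd.Series, problems: list[str], name: str) -> pd.Series:
    mapped = col.map({True: True, False: False, "true": True, "false": False, "True": True, "False": False})
    for idx in col.index[mapped.isna()]:
        problems.append(f"row {idx}: {name} must be true/false")
    return mapped.fillna(False).astype(bool)


def _to_bool_or_na(col: pd.Series) -> pd.Series:
    return col.map(
        {True: True, False: False, "true": True, "false": False, "True": True, "False": False}
    ).astype(object)


def read_trials(trials_path, participants_path=None) -> StudyDataset:
    """Read and validate a trial CSV (and optional participant CSV)."""
    raw = pd.read_csv(trials_path, dtype={"participant_id": str}, float_precision="round_trip")
    trials = validate_trials(raw)
    if participants_path is not None:
        participants = pd.read_csv(participants_path, dtype={"participant_id": str})
        missing = [c for c in ("participant_id", "group") if c not in participants.columns]
        if missing:
            raise SchemaError(f"participant table missing column(s): {missing}")
        for c in CLINICAL_COLUMNS:
            if c not in participants.columns:
                participants[c] = np.nan
        participants = participants[PARTICIPANT_COLUMNS]
    else:
        participants = (
            trials[["participant_id", "group"]].drop_duplicates().reset_index(drop=True)
        )
        for c in CLINICAL_COLUMNS:
            participants[c] = np.nan
    unknown = set(trials["participant_id"]) - set(participants["participant_id"])
    if unknown:
        raise ValidationError([f"trial participant_id {p!r} missing from participant table" for p in sorted(unknown)])
    return StudyDataset(trials=trials, participants=participants, provenance={"source": str(trials_path)})


def write_trials(dataset: StudyDataset, trials_path, participants_path=None) -> None:
    """Write the dataset back to the documented CSV schema.

    Booleans are serialized as ``true``/``false``, missing values as empty
    cells, so a read/write round-trip preserves every field.
    """
    out = dataset.trials[TRIAL_COLUMNS].copy()
    for col in ("response_identical", "excluded"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(trials_path, index=False)
    if participants_path is not None:
        dataset.participants.to_csv(participants_path, index=False)


def trials_to_csv_text(dataset: StudyDataset) -> str:
    buf = io.StringIO()
    write_trials(dataset, buf)
    return buf.getvalue()


def apply_exclusions(dataset: StudyDataset) -> tuple[StudyDataset, dict]:
    """Drop trials flagged by the pre-registered exclusion rules.

    Removes every trial whose ``exclusion_reason`` is not ``none`` (no
    movement made, camera malfunction, or no response).  The participant set
    is unchanged.  Returns the filtered dataset and a per-group report::

        {group: {"n_total": int, "n_excluded": int, "fraction": float,
                 "by_reason": {reason: int}}}

    Idempotent: applying it twice yields the same dataset and a 0% report
    the second time.
    """
    trials = dataset.trials
    report: dict = {}
    for group in GROUPS:
        sub = trials[trials["group"] == group]
        if len(sub) == 0:
            continue
        excl = sub[sub["excluded"]]
        by_reason = excl["exclusion_reason"].value_counts().to_dict()
        report[group] = {
            "n_total": int(len(sub)),
            "n_excluded": int(len(excl)),
            "fraction": float(len(excl) / len(sub)),
            "by_reason": {str(k): int(v) for k, v in sorted(by_reason.items())},
        }
    kept = trials[~trials["excluded"]].reset_index(drop=True)
    return StudyDataset(kept, dataset.participants.copy(), dict(dataset.provenance)), report


def exclude_participants(dataset: StudyDataset, participant_ids) -> StudyDataset:
    """Drop whole participants by explicit ID list.

    Participant-level exclusion criteria live in pre-registrations rather
    than in a trial table, so the package takes an explicit list (e.g. from
    the pipeline config) instead of guessing criteria.  Unknown IDs raise.
    """
    ids = set(participant_ids)
    known = set(dataset.participants["participant_id"])
    unknown = ids - known
    if unknown:
        raise ValueError(f"unknown participant_id(s): {sorted(unknown)}")
    trials = dataset.trials[~dataset.trials["participant_id"].isin(ids)].reset_index(drop=True)
    participants = dataset.participants[
        ~dataset.participants["participant_id"].isin(ids)
    ].reset_index(drop=True)
    prov = dict(dataset.provenance)
    prov["excluded_participants"] = sorted(ids)
    return StudyDataset(trials, participants, prov)


def label_accuracy(trials: pd.DataFrame) -> pd.Series:
    """Correctness of each agency judgment.

    A judgment is correct when the participant answered "identical" on an
    unaltered trial or "not identical" on an altered trial, i.e.
    ``response_identical != altered``.  Raises for missing responses —
    those trials should have been excluded upstream.
    """
    resp = trials["response_identical"]
    if resp.isna().any():
        rows = list(trials.index[resp.isna()])
        raise ValueError(f"missing response_identical on rows {rows[:10]}; exclude these trials first")
    return resp.astype(bool) != trials["altered"].astype(bool)
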