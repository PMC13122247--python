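"""Trial-level data model for the two gaze-perception tasks.

Data are tabular, one row per behavioral trial.  Two tasks are represented:

``implicit``
    Object-detection under a naturalistic gaze cue.  The cued object is
    present on half the trials; on present trials the actor's gaze is
    either directed at the object (*valid*) or opposite (*invalid*), and
    the actor's body is either aligned with the turned head (*congruent*)
    or facing forward (*incongruent*).  Object-absent filler trials carry
    ``gaze_validity = not_applicable``.

``explicit``
    Deliberate forced-choice judgment of the actor's gaze target.  All
    trials are gaze-valid and "object present" by construction; the only
    manipulated factor is body-head congruency.

Every trial records binary correctness and a confidence rating on an
11-point grid (0, 10, ..., 100).  Subjects additionally carry an
Autism-Spectrum Quotient (AQ) total score (0-50 instrument range).

The canonical in-memory containers are validated :class:`pandas.DataFrame`
objects using the column schemas below; loaders normalize factor labels
case-insensitively and reject malformed rows with row-indexed errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "GAZE_LEVELS",
    "CONGRUENCY_LEVELS",
    "CONFIDENCE_GRID",
    "TRIAL_COLUMNS",
    "SUBJECT_COLUMNS",
    "SchemaError",
    "TrialValidationError",
    "DesignReport",
    "load_trials",
    "load_subjects",
    "write_trials",
    "write_subjects",
    "validate_trials",
    "validate_subjects",
    "validate_design",
    "filter_present_trials",
    "summarize_accuracy",
    "assign_aq_group",
]

TASKS = ("implicit", "explicit")
GAZE_LEVELS = ("valid", "invalid", "not_applicable")
CONGRUENCY_LEVELS = ("congruent", "incongruent")
CONFIDENCE_GRID = tuple(range(0, 101, 10))

TRIAL_COLUMNS = (
    "subject_id",
    "task",
    "trial_index",
    "gaze_validity",
    "body_head_congruency",
    "object_present",
    "correct",
    "confidence",
)
SUBJECT_COLUMNS = ("subject_id", "aq_score")

_GAZE_ALIASES = {
    "valid": "valid",
    "invalid": "invalid",
    "not_applicable": "not_applicable",
    "na": "not_applicable",
    "n/a": "not_applicable",
    "none": "not_applicable",
}
_BOOL_ALIASES = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable header."""


class TrialValidationError(ValueError):
    """One or more rows violate the trial-table invariants.

    The message lists each offending row by its 0-based position."""


# ---------------------------------------------------------------------------
# loading / writing

def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def load_trials(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited trial table and validate it.

    Factor labels are normalized case-insensitively ("Valid", "N/A", "TRUE"
    are all accepted).  Raises :class:`SchemaError` for missing columns and
    :class:`TrialValidationError` naming rows for value-level problems.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str},
                     keep_default_na=False, na_values=[""])
    df.columns = [str(c).strip().lower() for c in df.columns]
    _require_columns(df, TRIAL_COLUMNS, "trial")
    df = df.loc[:, list(TRIAL_COLUMNS)].copy()
    for col in ("task", "gaze_validity", "body_head_congruency"):
        df[col] = df[col].astype(str).str.strip().str.lower()
    df["gaze_validity"] = df["gaze_validity"].map(
        lambda s: _GAZE_ALIASES.get(s, s)
    )
    if df["object_present"].dtype == object:
        df["object_present"] = (
            df["object_present"].astype(str).str.strip().str.lower()
            .map(_BOOL_ALIASES)
        )
    df["object_present"] = df["object_present"].astype(bool)
    validate_trials(df)
    df["trial_index"] = df["trial_index"].astype(int)
    df["correct"] = df["correct"].astype(int)
    df["confidence"] = df["confidence"].astype(int)
    return df.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a trial table; output round-trips through :func:`load_trials`."""
    validate_trials(trials)
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def load_subjects(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a subject table (subject_id, aq_score, optional age/gender)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    _require_columns(df, SUBJECT_COLUMNS, "subject")
    validate_subjects(df)
    df["aq_score"] = df["aq_score"].astype(int)
    return df.reset_index(drop=True)


def write_subjects(subjects: pd.DataFrame, path, delimiter: str = ",") -> None:
    validate_subjects(subjects)
    cols = [c for c in subjects.columns if c == "subject_id" or c in
            ("aq_score", "aq_group", "age", "gender")]
    subjects.loc[:, cols].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# validation

def validate_trials(trials: pd.DataFrame) -> None:
    """Raise :class:`TrialValidationError` if any row breaks an invariant.

    Checked invariants:

    * task in {implicit, explicit}; factor labels in their level sets
    * correctness is binary
    * confidence lies on the 11-point grid {0, 10, ..., 100}
    * explicit rows are gaze-valid and object-present
    * implicit object-absent rows have gaze_validity = not_applicable,
      implicit object-present rows have a real validity level
    """
    _require_columns(trials, TRIAL_COLUMNS, "trial")
    problems: list[str] = []

    def flag(mask: pd.Series, msg: str) -> None:
        idx = np.flatnonzero(np.asarray(mask))
        for i in idx[:20]:
            problems.append(f"row {i}: {msg}")
        if len(idx) > 20:
            problems.append(f"... {len(idx) - 20} more rows: {msg}")

    flag(~trials["task"].isin(TASKS), "unknown task")
    flag(~trials["gaze_validity"].isin(GAZE_LEVELS), "unknown gaze_validity")
    flag(~trials["body_head_congruency"].isin(CONGRUENCY_LEVELS),
         "unknown body_head_congruency")
    flag(~trials["correct"].isin((0, 1)), "correct must be 0 or 1")
    flag(~trials["confidence"].isin(CONFIDENCE_GRID),
         "confidence not on the 11-point grid (0,10,...,100)")

    expl = trials["task"] == "explicit"
    flag(expl & (trials["gaze_validity"] != "valid"),
         "explicit trials must be gaze-valid")
    flag(expl & ~trials["object_present"].astype(bool),
         "explicit trials must be object-present")
    impl = trials["task"] == "implicit"
    present = trials["object_present"].astype(bool)
    flag(impl & ~present & (trials["gaze_validity"] != "not_applicable"),
         "implicit object-absent trials must have gaze_validity=not_applicable")
    flag(impl & present & ~trials["gaze_validity"].isin(("valid", "invalid")),
         "implicit object-present trials need gaze_validity valid/invalid")

    if problems:
        raise TrialValidationError(
            "invalid trial table:\n  " + "\n  ".join(problems)
        )


def validate_subjects(subjects: pd.DataFrame) -> None:
    _require_columns(subjects, SUBJECT_COLUMNS, "subject")
    aq = subjects["aq_score"]
    bad = ~((aq >= 0) & (aq <= 50))
    if bad.any():
        rows = list(np.flatnonzero(np.asarray(bad))[:20])
        raise TrialValidationError(
            f"aq_score outside instrument range [0, 50] at rows {rows}"
        )
    if subjects["subject_id"].duplicated().any():
        raise TrialValidationError("duplicate subject_id in subject table")


# ---------------------------------------------------------------------------
# design balance

@dataclass
class DesignReport:
    """Per-task trial counts, per-condition cell counts and balance violations.

    ``violations`` is empty iff every subject matches the target design:
    implicit, 96 trials with the 48 object-present trials split 12/12/12/12
    over validity x congruency; explicit, 96 trials split 48/48 over
    congruency.
    """

    n_trials: dict = field(default_factory=dict)
    cell_counts: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self, **kw) -> str:
        return json.dumps(
            {"n_trials": self.n_trials, "cell_counts": self.cell_counts,
             "violations": self.violations, "ok": self.ok},
            **{"indent": 2, **kw},
        )


def validate_design(
    trials: pd.DataFrame,
    trials_per_implicit_cell: int = 12,
    trials_per_explicit_condition: int = 48,
) -> DesignReport:
    """Check every subject's trial counts against the factorial design.

    Violations are data, not exceptions: the report lists them as strings
    naming the subject and the offending cell.
    """
    report = DesignReport()
    if len(trials) == 0:
        report.violations.append("no trials")
        return report
    validate_trials(trials)

    k = trials_per_implicit_cell
    n_impl = 8 * k            # 4 present cells + matched absent fillers
    n_expl = 2 * trials_per_explicit_condition

    for task, sub in trials.groupby("task", sort=True):
        report.n_trials[task] = int(len(sub))
        counts: dict[str, int] = {}
        for sid, s in sub.groupby("subject_id", sort=True):
            if task == "implicit":
                if len(s) != n_impl:
                    report.violations.append(
                        f"subject {sid}: implicit has {len(s)} trials "
                        f"(expected {n_impl})")
                pres = s[s["object_present"]]
                if len(pres) != 4 * k:
                    report.violations.append(
                        f"subject {sid}: implicit has {len(pres)} "
                        f"object-present trials (expected {4 * k})")
                for gv in ("valid", "invalid"):
                    for bc in CONGRUENCY_LEVELS:
                        n = int(((pres["gaze_validity"] == gv)
                                 & (pres["body_head_congruency"] == bc)).sum())
                        counts[f"{gv}/{bc}"] = counts.get(f"{gv}/{bc}", 0) + n
                        if n != k:
                            report.violations.append(
                                f"subject {sid}: implicit cell {gv}/{bc} has "
                                f"{n} trials (expected {k})")
            else:
                if len(s) != n_expl:
                    report.violations.append(
                        f"subject {sid}: explicit has {len(s)} trials "
                        f"(expected {n_expl})")
                for bc in CONGRUENCY_LEVELS:
                    n = int((s["body_head_congruency"] == bc).sum())
                    counts[bc] = counts.get(bc, 0) + n
                    if n != trials_per_explicit_condition:
                        report.violations.append(
                            f"subject {sid}: explicit condition {bc} has "
                            f"{n} trials (expected "
                            f"{trials_per_explicit_condition})")
        report.cell_counts[task] = counts
    return report


# ---------------------------------------------------------------------------
# analysis helpers

def filter_present_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Restrict implicit-task trials to those where the cued object was shown.

    Accuracy and confidence analyses of the implicit task use only
    object-present trials (half of all trials under the balanced design);
    object-absent fillers are dropped here, never at load time, so overall
    accuracy summaries remain computable upstream.  Order is preserved and
    the operation is idempotent.

    Raises ``ValueError`` if any explicit-task rows are passed: the filter
    is an implicit-task contract.
    """
    if (trials["task"] == "explicit").any():
        raise ValueError(
            "filter_present_trials applies to implicit-task trials only")
    return trials[trials["object_present"].astype(bool)]


def summarize_accuracy(
    trials: pd.DataFrame,
    by: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Mean accuracy per condition, aggregated subject-first.

    For each grouping cell, each subject's mean accuracy is computed and the
    cell mean/SE are taken across subjects (SE = sd of subject means / sqrt
    of number of subjects), matching how condition means are reported for
    this design.  Accuracy is returned in percent.  If ``subject_id`` is
    itself a grouping factor the SE column is NaN (a single mean per cell).
    Empty groups (possible with categorical inputs) are dropped with a
    warning.
    """
    by = [c for c in by if c != "subject_id"]
    per_subject = by and "subject_id" not in by
    keys = list(by) + ["subject_id"] if per_subject else (list(by) or ["subject_id"])
    missing = [c for c in keys if c not in trials.columns]
    if missing:
        raise KeyError(f"grouping factors not in trial table: {missing}")

    subj = (trials.groupby(keys, observed=False)["correct"]
            .agg(n="size", acc="mean").reset_index())
    empty = subj["n"] == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty groups")
        subj = subj[~empty]
    subj["acc"] *= 100.0

    if not by:
        out = subj.rename(columns={"acc": "mean_accuracy"})
        out["se"] = np.nan
        return out.reset_index(drop=True)
    agg = (subj.groupby(list(by), observed=False)
           .agg(n_subjects=("subject_id", "nunique"),
                n_trials=("n", "sum"),
                mean_accuracy=("acc", "mean"),
                sd=("acc", lambda a: a.std(ddof=1)))
           .reset_index())
    agg = agg[agg["n_trials"] > 0]
    agg["se"] = agg["sd"] / np.sqrt(agg["n_subjects"])
    return agg.drop(columns="sd").reset_index(drop=True)


def assign_aq_group(subjects: pd.DataFrame) -> pd.DataFrame:
    """Median-split AQ scores into low/high groups.

    The split point is the sample median; subjects exactly at the median go
    to the *low* group (deterministic tie rule).  Returns a copy with an
    ``aq_group`` column and records the median in ``DataFrame.attrs``.
    """
    out = subjects.copy()
    med = float(out["aq_score"].median())
    out["aq_group"] = np.where(out["aq_score"] <= med, "low", "high")
    out.attrs["aq_median"] = med
    return out
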