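"""Scoring of trial-level self-paced-reading (SPR) data.

Each trial presents a sentence region by region (subject, relative clause,
main clause, modifier) in one of two closely matched structures:
subject-relative (SR, canonical) or object-relative (OR, noncanonical),
followed by a comprehension question.  Per participant we compute:

* accuracy per condition and pooled over all trials (``acc_overall``),
* mean relative-clause reading time per condition and pooled
  (``rt_overall``) — the relative clause is the region of interest, the
  other region RTs are carried but unused,
* structural disadvantage scores: ``rt_sds = rt_sr - rt_or`` and
  ``acc_sds = acc_or - acc_sr``.  More negative SDS means relatively worse
  performance on the harder OR structure.

Participant-level outlier exclusion flags anyone whose raw summary is more
than k (default 3) SDs from the cohort mean *in both conditions of the same
measure family* (both RTs, or both accuracies); means and SDs are computed
once on the full sample, and z-transformation for modeling happens after
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "QUESTION_TYPES",
    "TRIAL_COLUMNS",
    "BehavioralSummary",
    "score_participant",
    "score_trials",
    "apply_outlier_exclusion",
    "standardize",
    "read_trials",
]

CONDITIONS = ("SR", "OR")
QUESTION_TYPES = ("relative-clause-probe", "main-clause-probe")

#: Column schema of a trial table (RTs in seconds, floats).
TRIAL_COLUMNS = (
    "participant_id",
    "condition",
    "rt_subject",
    "rt_relative_clause",
    "rt_main_clause",
    "rt_modifier",
    "question_type",
    "question_correct",
)

SUMMARY_COLUMNS = (
    "participant_id",
    "acc_sr",
    "acc_or",
    "acc_overall",
    "rt_sr",
    "rt_or",
    "rt_overall",
    "acc_sds",
    "rt_sds",
    "excluded",
)


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-participant SPR summary (RTs in seconds, accuracies in [0, 1])."""

    participant_id: str
    acc_sr: float
    acc_or: float
    acc_overall: float
    rt_sr: float
    rt_or: float
    rt_overall: float
    acc_sds: float
    rt_sds: float
    excluded: bool = False


def _validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table is missing columns: {missing}")
    bad_cond = set(trials["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    rt_cols = ["rt_subject", "rt_relative_clause", "rt_main_clause", "rt_modifier"]
    if (trials[rt_cols].to_numpy(dtype=float) <= 0).any():
        raise ValueError("all region RTs must be positive (seconds)")


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Score a trial table into one summary row per participant.

    Requires at least one trial in each condition per participant; raises a
    diagnostic naming any participant with a missing condition.  ``rt_*``
    uses the relative-clause region only; ``acc_overall`` and ``rt_overall``
    pool trials over conditions.
    """
    _validate_trials(trials)
    counts = trials.groupby(["participant_id", "condition"]).size().unstack(fill_value=0)
    for cond in CONDITIONS:
        if cond not in counts.columns:
            counts[cond] = 0
    lacking = counts.index[(counts[list(CONDITIONS)] == 0).any(axis=1)]
    if len(lacking):
        raise ValueError(
            "participants missing trials in a condition: " + ", ".join(map(str, lacking))
        )
    g = trials.groupby(["participant_id", "condition"])
    acc = g["question_correct"].mean().unstack()
    rt = g["rt_relative_clause"].mean().unstack()
    pooled = trials.groupby("participant_id")
    out = pd.DataFrame(
        {
            "participant_id": acc.index,
            "acc_sr": acc["SR"].to_numpy(dtype=float),
            "acc_or": acc["OR"].to_numpy(dtype=float),
            "acc_overall": pooled["question_correct"].mean().reindex(acc.index).to_numpy(dtype=float),
            "rt_sr": rt["SR"].to_numpy(dtype=float),
            "rt_or": rt["OR"].to_numpy(dtype=float),
            "rt_overall": pooled["rt_relative_clause"].mean().reindex(acc.index).to_numpy(dtype=float),
        }
    )
    out["acc_sds"] = out["acc_or"] - out["acc_sr"]
    out["rt_sds"] = out["rt_sr"] - out["rt_or"]
    out["excluded"] = False
    return out.reset_index(drop=True)


def score_participant(trials: pd.DataFrame) -> BehavioralSummary:
    """Score the trials of a single participant into a BehavioralSummary."""
    ids = trials["participant_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected trials of one participant, got ids {list(ids)}")
    row = score_trials(trials).iloc[0]
    return BehavioralSummary(
        participant_id=str(row["participant_id"]),
        acc_sr=float(row["acc_sr"]),
        acc_or=float(row["acc_or"]),
        acc_overall=float(row["acc_overall"]),
        rt_sr=float(row["rt_sr"]),
        rt_or=float(row["rt_or"]),
        rt_overall=float(row["rt_overall"]),
        acc_sds=float(row["acc_sds"]),
        rt_sds=float(row["rt_sds"]),
    )


def _extreme_both(df: pd.DataFrame, col1: str, col2: str, k: float) -> np.ndarray:
    """Participants beyond k SDs from the full-sample mean in *both* columns."""
    flags = np.ones(len(df), dtype=bool)
    for col in (col1, col2):
        v = df[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return np.zeros(len(df), dtype=bool)  # SD=0: nobody excluded
        flags &= np.abs(v - v.mean()) > k * sd
    return flags


def apply_outlier_exclusion(summaries: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Mark participants extreme in both conditions of a measure family.

    A participant is excluded iff |value - cohort mean| > k*SD in *both* the
    SR and OR conditions for the same family (RT pair, or accuracy pair).
    Means/SDs are computed once on the full sample (no iterative
    re-exclusion); raw (not z-scored) summaries are used.  Returns a copy
    with the ``excluded`` flag set.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 participants for outlier exclusion")
    if k < 0:
        raise ValueError("k must be >= 0")
    out = summaries.copy()
    excl = _extreme_both(out, "rt_sr", "rt_or", k) | _extreme_both(out, "acc_sr", "acc_or", k)
    out["excluded"] = excl
    return out


def standardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Z-transform to mean 0, sample SD 1 (n-1 denominator).

    Rejects constant vectors.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1D vector")
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct values to standardize")
    return (v - v.mean()) / v.std(ddof=1)


def read_trials(path: str) -> pd.DataFrame:
    """Read a trial CSV with the documented column schema."""
    df = pd.read_csv(path)
    _validate_trials(df)
    df["question_correct"] = df["question_correct"].astype(bool)
    return df
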