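"""Binary fall-risk labels from clinical test scores.

Three screening instruments are supported, each with its published
cut-off:

* TUG (Timed Up and Go): completion time strictly over 12.47 s flags a
  mobility problem.
* SFBBS (Short-Form Berg Balance Scale, 0-28 points): a score strictly
  below 23 flags a balance problem.
* SPMSQ (Short Portable Mental Status Questionnaire, 0-10 errors):
  three or more errors flag impaired cognition.

Multifactor labels (TUG+BBS, TUG+SPMSQ, BBS+SPMSQ) use the intersection
rule: a subject is at fall risk only if flagged by both constituent
tests.  The rule is isolated in :func:`label_combined` so an OR variant
is a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TUG_CUTOFF_SECONDS = 12.47
SFBBS_CUTOFF_POINTS = 23
SPMSQ_CUTOFF_ERRORS = 3

HEALTHY = "healthy"
FALL_RISK = "fall_risk"

SINGLE_TESTS = ("BBS", "TUG", "SPMSQ")
COMBINED_TESTS = ("TUG+BBS", "TUG+SPMSQ", "BBS+SPMSQ")
ALL_TESTS = ("BBS", "TUG", "TUG+BBS", "SPMSQ", "TUG+SPMSQ", "BBS+SPMSQ")


class InvalidScoreError(ValueError):
    """Raised when a clinical score is outside its valid range."""


@dataclass(frozen=True)
class ClinicalScores:
    """Raw scores for one subject on the three clinical tests."""

    tug_seconds: float
    sfbbs_points: int
    spmsq_errors: int

    def __post_init__(self) -> None:
        if self.tug_seconds <= 0:
            raise InvalidScoreError(
                f"TUG time must be positive, got {self.tug_seconds}")
        if not 0 <= self.sfbbs_points <= 28:
            raise InvalidScoreError(
                f"SFBBS score must be in 0..28, got {self.sfbbs_points}")
        if not 0 <= self.spmsq_errors <= 10:
            raise InvalidScoreError(
                f"SPMSQ errors must be in 0..10, got {self.spmsq_errors}")


def label_tug(tug_seconds: float) -> str:
    """Fall risk iff the TUG time is strictly over 12.47 s."""
    if tug_seconds <= 0:
        raise InvalidScoreError(f"TUG time must be positive, got {tug_seconds}")
    return FALL_RISK if tug_seconds > TUG_CUTOFF_SECONDS else HEALTHY


def label_bbs(sfbbs_points: int) -> str:
    """Fall risk iff the SFBBS score is strictly below 23 points."""
    if not 0 <= sfbbs_points <= 28:
        raise InvalidScoreError(
            f"SFBBS score must be in 0..28, got {sfbbs_points}")
    return FALL_RISK if sfbbs_points < SFBBS_CUTOFF_POINTS else HEALTHY


def label_spmsq(spmsq_errors: int) -> str:
    """Fall risk iff three or more SPMSQ questions were answered wrong."""
    if not 0 <= spmsq_errors <= 10:
        raise InvalidScoreError(
            f"SPMSQ errors must be in 0..10, got {spmsq_errors}")
    return FALL_RISK if spmsq_errors >= SPMSQ_CUTOFF_ERRORS else HEALTHY


def label_combined(label_a: str, label_b: str) -> str:
    """Intersection rule: fall risk only when both tests flag the subject."""
    return FALL_RISK if label_a == FALL_RISK and label_b == FALL_RISK else HEALTHY


def label_set(scores: ClinicalScores) -> dict[str, str]:
    """Labels for all six clinical-test conditions of one subject."""
    bbs = label_bbs(scores.sfbbs_points)
    tug = label_tug(scores.tug_seconds)
    spmsq = label_spmsq(scores.spmsq_errors)
    return {
        "BBS": bbs,
        "TUG": tug,
        "TUG+BBS": label_combined(tug, bbs),
        "SPMSQ": spmsq,
        "TUG+SPMSQ": label_combined(tug, spmsq),
        "BBS+SPMSQ": label_combined(bbs, spmsq),
    }


def label_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-subject 0/1 label columns for all six conditions.

    `scores` must have columns tug_seconds, sfbbs_points, spmsq_errors;
    the index (subject id) is preserved.  1 encodes fall risk.
    """
    rows = {}
    for subject_id, row in scores.iterrows():
        labels = label_set(ClinicalScores(
            tug_seconds=float(row["tug_seconds"]),
            sfbbs_points=int(row["sfbbs_points"]),
            spmsq_errors=int(row["spmsq_errors"]),
        ))
        rows[subject_id] = {t: int(labels[t] == FALL_RISK) for t in ALL_TESTS}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(ALL_TESTS))
    table.index.name = scores.index.name or "subject_id"
    return table
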