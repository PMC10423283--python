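"""Attentiveness promotion (AP): control-image selection and session vetting.

Each annotator-day is a *session*: 57 presentations covering 56 distinct
images, of which 6 are control images (whose expected dyad was fixed in a
pilot study) and exactly one image appears twice.  A session is valid iff
the two presentations of the repeated image carry the same dyad AND at
least 5 of the 6 controls were answered with their expected dyad; invalid
sessions are discarded wholesale.  Control images are ordinary subset
images — their votes (from valid sessions) feed the public tallies.

Control selection mirrors the pilot rule: an image becomes a control when
some dyad gathers at least ``min_coincidence`` of the pilot votes (4 of 5
in the study), and that dyad is its expected answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CONTROLS_PER_SESSION",
    "MIN_CONTROLS_CORRECT",
    "ControlImage",
    "SessionOutcome",
    "MalformedSessionError",
    "select_controls",
    "validate_session",
    "apply_ap",
]

CONTROLS_PER_SESSION = 6
MIN_CONTROLS_CORRECT = 5


class MalformedSessionError(ValueError):
    """Session violates the 57-presentation / 6-control / 1-duplicate shape."""


@dataclass(frozen=True)
class ControlImage:
    image_id: object
    expected_dyad: int


@dataclass(frozen=True)
class SessionOutcome:
    """Validation verdict for one annotator-day."""

    annotator_id: object
    day: int
    n_controls_correct: int
    repeat_consistent: bool
    valid: bool


def select_controls(
    pilot_votes: pd.DataFrame, min_coincidence: int = 4
) -> list[ControlImage]:
    """Pick control images from pilot annotations.

    Parameters
    ----------
    pilot_votes
        Long table with columns ``image_id`` and ``dyad_id``, one row per
        pilot vote.
    min_coincidence
        Minimum number of coinciding pilot votes on one dyad for the image
        to qualify (study rule: 4 of 5 pilots).

    Returns
    -------
    Controls sorted by image id; empty when no image qualifies.  Ties in the
    (rare) case of two dyads both reaching the threshold resolve to the
    dyad with more votes, then the lower id.
    """
    if min_coincidence < 1:
        raise ValueError("min_coincidence must be >= 1")
    if pilot_votes.empty:
        return []
    tally = pd.crosstab(pilot_votes["image_id"], pilot_votes["dyad_id"])
    best = tally.idxmax(axis=1)  # first (lowest-id) maximum on ties
    best_count = tally.max(axis=1)
    qualified = best_count >= min_coincidence
    return [
        ControlImage(image_id, int(best[image_id]))
        for image_id in sorted(tally.index[qualified])
    ]


def _controls_mapping(controls) -> dict:
    if isinstance(controls, Mapping):
        return dict(controls)
    return {c.image_id: c.expected_dyad for c in controls}


def validate_session(
    session: pd.DataFrame,
    controls: Iterable[ControlImage] | Mapping,
    min_correct: int = MIN_CONTROLS_CORRECT,
    n_controls: int = CONTROLS_PER_SESSION,
) -> SessionOutcome:
    """Apply the AP discard rules to one session.

    ``session`` holds one annotator-day's presentations in order, with
    columns ``image_id, annotator_id, day, dyad_id``.  Structural
    requirements — exactly one image presented twice, no image more than
    twice, exactly ``n_controls`` distinct control images — raise
    :class:`MalformedSessionError`.  Control correctness is judged on each
    control's first presentation; should the duplicated image be a control,
    both rules still apply independently.
    """
    expected = _controls_mapping(controls)
    counts = session["image_id"].value_counts()
    if (counts > 2).any():
        raise MalformedSessionError("an image appears more than twice")
    duplicated = counts.index[counts == 2]
    if len(duplicated) != 1:
        raise MalformedSessionError(
            f"expected exactly one duplicated image, found {len(duplicated)}"
        )
    control_ids = [i for i in counts.index if i in expected]
    if len(control_ids) != n_controls:
        raise MalformedSessionError(
            f"expected {n_controls} control images, found {len(control_ids)}"
        )

    first_vote = session.drop_duplicates("image_id").set_index("image_id")["dyad_id"]
    n_correct = sum(int(first_vote[i]) == expected[i] for i in control_ids)
    dup_votes = session.loc[session["image_id"] == duplicated[0], "dyad_id"]
    repeat_consistent = bool(dup_votes.iloc[0] == dup_votes.iloc[1])
    row = session.iloc[0]
    return SessionOutcome(
        annotator_id=row["annotator_id"],
        day=int(row["day"]),
        n_controls_correct=int(n_correct),
        repeat_consistent=repeat_consistent,
        valid=repeat_consistent and n_correct >= min_correct,
    )


def apply_ap(
    records: pd.DataFrame,
    controls: Iterable[ControlImage] | Mapping,
    min_correct: int = MIN_CONTROLS_CORRECT,
    n_controls: int = CONTROLS_PER_SESSION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard invalid sessions and collapse the duplicated presentation.

    Parameters
    ----------
    records
        Annotation table (``image_id, annotator_id, day, dyad_id``) whose
        row order preserves presentation order within each session.
    controls
        Control images with expected dyads.

    Returns
    -------
    retained : DataFrame
        Records of valid sessions only, one row per distinct image (the
        first presentation of the duplicated image is kept — by validity the
        two presentations agree, so the choice is inert).
    audit : DataFrame
        One row per session: ``annotator_id, day, n_controls_correct,
        repeat_consistent, valid``.
    """
    columns = ["image_id", "annotator_id", "day", "dyad_id"]
    if records.empty:
        return records.head(0)[columns].copy(), pd.DataFrame(
            columns=["annotator_id", "day", "n_controls_correct",
                     "repeat_consistent", "valid"]
        )
    outcomes = []
    kept = []
    for _, session in records.groupby(["annotator_id", "day"], sort=True):
        outcome = validate_session(session, controls, min_correct, n_controls)
        outcomes.append(outcome)
        if outcome.valid:
            kept.append(session.drop_duplicates("image_id"))
    retained = (
        pd.concat(kept, ignore_index=True)[columns]
        if kept
        else records.head(0)[columns].copy()
    )
    audit = pd.DataFrame([vars(o) for o in outcomes])
    return retained, audit
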