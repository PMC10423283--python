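"""Synthetic annotators: a generative model of the dyad-relabeling study.

The simulator emits the exact table dialects the pipeline consumes, so every
stage is testable without the deposited human annotations.  Its generative
assumptions:

* Each image has one *true* dyad (ground truth, balanced across the 8
  categories).
* An attentive rater perceives, per image, a dyad drawn from a wheel-distance
  mixture around the truth: probability ``p_true`` on the true dyad,
  ``p_adjacent`` split over the two wheel-adjacent dyads, ``p_opposite`` on
  the wheel-opposite dyad (the projection effect), and the residual mass
  spread uniformly over the remaining four.  The perceived dyad is drawn
  once per (rater, image), so the repeated image of a session is answered
  consistently; controls are answered correctly with probability
  ``p_control_correct`` (otherwise uniformly among the other 7 dyads).
* A fraction ``inattentive_rate`` of rater-sessions instead votes uniformly
  at random *per presentation* — so an inattentive session passes the AP
  checks only with probability
  ``(1/8) * [6 (7/8) (1/8)^5 + (1/8)^6] ~= 2.1e-5``.

Sessions follow the study design: per day a disjoint block of
``images_per_session`` images (6 of them controls picked by a simulated
5-rater pilot with the 4-coincidence rule) shown to every rater of the day,
plus one repeated non-control image, in shuffled presentation order.  All
randomness flows from a single :class:`numpy.random.Generator` seeded by the
config, making every output table byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attentiveness import (
    CONTROLS_PER_SESSION,
    MIN_CONTROLS_CORRECT,
    ControlImage,
    select_controls,
)
from .taxonomy import N_DYADS, DyadCatalog, default_catalog

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "InfeasibleConfigError",
    "mixture_matrix",
    "simulate",
    "simulate_vote_counts",
    "simulate_original_annotations",
    "simulate_session_validity",
    "uniform_session_pass_probability",
    "recovery_report",
]


class InfeasibleConfigError(ValueError):
    """The simulation configuration cannot produce well-formed sessions."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 1,120 images, 20 days, 28 raters/day, 56
    images per session, 6 controls (4-of-5 pilot rule), 5-of-6 pass rule."""

    n_images: int = 1120
    n_days: int = 20
    raters_per_day: int = 28
    images_per_session: int = 56
    p_true: float = 0.65
    p_adjacent: float = 0.20
    p_opposite: float = 0.05
    inattentive_rate: float = 0.10
    p_control_correct: float = 0.95
    n_pilot_raters: int = 5
    control_coincidence: int = 4
    controls_per_session: int = CONTROLS_PER_SESSION
    min_controls_correct: int = MIN_CONTROLS_CORRECT
    seed: int = 0

    def __post_init__(self):
        probs = {
            "p_true": self.p_true,
            "p_adjacent": self.p_adjacent,
            "p_opposite": self.p_opposite,
            "inattentive_rate": self.inattentive_rate,
            "p_control_correct": self.p_control_correct,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InfeasibleConfigError(f"{name}={p} outside [0, 1]")
        if self.p_true + self.p_adjacent + self.p_opposite > 1.0 + 1e-12:
            raise InfeasibleConfigError(
                "p_true + p_adjacent + p_opposite exceeds 1"
            )
        if self.images_per_session <= self.controls_per_session:
            raise InfeasibleConfigError(
                "images_per_session must exceed controls_per_session"
            )
        if self.n_days * self.images_per_session > self.n_images:
            raise InfeasibleConfigError(
                f"{self.n_days} days x {self.images_per_session} images/session "
                f"needs more than the {self.n_images} available images"
            )


@dataclass(frozen=True)
class SimulatedStudy:
    """Bundle returned by :func:`simulate`."""

    records: pd.DataFrame  # image_id, annotator_id, day, dyad_id (presentation order)
    controls: list[ControlImage]
    truth: pd.DataFrame  # image_id, true_dyad
    pilot_votes: pd.DataFrame  # image_id, annotator_id, dyad_id

    @property
    def truth_map(self) -> dict:
        return dict(zip(self.truth["image_id"], self.truth["true_dyad"]))


def mixture_matrix(
    p_true: float,
    p_adjacent: float,
    p_opposite: float,
    catalog: DyadCatalog | None = None,
) -> np.ndarray:
    """Row-stochastic (8, 8) matrix: P[vote | true dyad], wheel-distance mixture.

    Row t-1 places ``p_true`` on dyad t, ``p_adjacent/2`` on each
    wheel-adjacent dyad, ``p_opposite`` on the wheel-opposite dyad, and the
    residual uniformly on the remaining four.
    """
    catalog = catalog or default_catalog()
    residual = 1.0 - p_true - p_adjacent - p_opposite
    if residual < -1e-12:
        raise InfeasibleConfigError("mixture masses exceed 1")
    residual = max(residual, 0.0)
    P = np.zeros((N_DYADS, N_DYADS))
    for t in range(1, N_DYADS + 1):
        P[t - 1, t - 1] = p_true
        for a in catalog.dyads_at_distance(t, 1):
            P[t - 1, a - 1] = p_adjacent / 2.0
        P[t - 1, catalog.opposite(t) - 1] = p_opposite
        for far in catalog.dyads_at_distance(t, 2) + catalog.dyads_at_distance(t, 3):
            P[t - 1, far - 1] = residual / 4.0
    return P


def _draw(rng: np.random.Generator, cum_rows: np.ndarray) -> np.ndarray:
    """Draw one category id (1-based) per row of cumulative probabilities."""
    u = rng.random(cum_rows.shape[0])
    return (u[:, None] > cum_rows).sum(axis=1) + 1


def _balanced_truth(rng: np.random.Generator, n_images: int) -> np.ndarray:
    base = np.resize(np.arange(1, N_DYADS + 1), n_images)
    return rng.permutation(base)


def simulate(
    config: SimulationConfig,
    catalog: DyadCatalog | None = None,
    image_ids: Sequence | None = None,
    truth: Mapping | None = None,
) -> SimulatedStudy:
    """Run the full generative model of the annotation study.

    Parameters
    ----------
    config
        Simulation parameters; all randomness derives from ``config.seed``.
    image_ids, truth
        Optionally annotate a caller-supplied image set (e.g. the output of
        subset selection) with known true dyads; by default ids are
        ``1..n_images`` with a balanced random truth assignment.

    Returns
    -------
    :class:`SimulatedStudy` with the annotation records (in presentation
    order), the control images actually deployed (6 per day, disjoint
    across days), the ground truth, and the pilot votes.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)

    if image_ids is None:
        image_ids = np.arange(1, config.n_images + 1)
    else:
        image_ids = np.asarray(image_ids)
        if len(image_ids) != config.n_images:
            config = replace(config, n_images=len(image_ids))
    if truth is None:
        true_dyads = _balanced_truth(rng, config.n_images)
    else:
        true_dyads = np.array([truth[i] for i in image_ids], dtype=int)
    pos = {img: k for k, img in enumerate(image_ids)}

    P = mixture_matrix(config.p_true, config.p_adjacent, config.p_opposite, catalog)
    cum = P.cumsum(axis=1)

    # --- pilot study: n_pilot_raters vote on every image ------------------
    pilot_votes = np.column_stack(
        [_draw(rng, cum[true_dyads - 1]) for _ in range(config.n_pilot_raters)]
    )
    pilot_df = pd.DataFrame(
        {
            "image_id": np.repeat(image_ids, config.n_pilot_raters),
            "annotator_id": np.tile(
                [f"pilot_{k + 1}" for k in range(config.n_pilot_raters)],
                config.n_images,
            ),
            "dyad_id": pilot_votes.ravel(),
        }
    )
    candidates = select_controls(pilot_df, config.control_coincidence)
    need = config.controls_per_session * config.n_days
    if len(candidates) < need:
        raise InfeasibleConfigError(
            f"pilot produced {len(candidates)} control candidates; "
            f"{need} are needed ({config.controls_per_session}/day x "
            f"{config.n_days} days)"
        )
    expected = {c.image_id: c.expected_dyad for c in candidates}
    chosen = rng.choice(len(candidates), size=need, replace=False)
    used_ids = np.array([candidates[k].image_id for k in chosen])
    day_controls = used_ids.reshape(config.n_days, config.controls_per_session)
    controls_used = [
        ControlImage(i, expected[i]) for i in sorted(used_ids.tolist())
    ]

    # --- partition non-control images into disjoint day blocks ------------
    pool = rng.permutation(np.setdiff1d(image_ids, used_ids))
    per_day = config.images_per_session - config.controls_per_session

    img_col, ann_col, day_col, vote_col = [], [], [], []
    annotator = 0
    for day in range(1, config.n_days + 1):
        ctrl_ids = day_controls[day - 1]
        non_ids = pool[(day - 1) * per_day : day * per_day]
        images_day = np.concatenate([ctrl_ids, non_ids])
        truth_day = true_dyads[[pos[i] for i in images_day]]
        expected_day = np.array([expected[i] for i in ctrl_ids])
        n_ctrl = len(ctrl_ids)
        for _ in range(config.raters_per_day):
            annotator += 1
            dup = non_ids[rng.integers(len(non_ids))]
            order = rng.permutation(config.images_per_session + 1)
            presented = np.append(images_day, dup)[order]
            if rng.random() >= config.inattentive_rate:
                votes = _draw(rng, cum[truth_day - 1])
                # control answers: correct w.p. p_control_correct, else one
                # of the other 7 dyads uniformly
                correct = rng.random(n_ctrl) < config.p_control_correct
                slips = (
                    expected_day + 1 + rng.integers(0, N_DYADS - 1, size=n_ctrl)
                )
                votes[:n_ctrl] = np.where(
                    correct, expected_day, (slips - 1) % N_DYADS + 1
                )
                vote_map = dict(zip(images_day, votes))
                session_votes = np.array([vote_map[i] for i in presented])
            else:
                session_votes = rng.integers(1, N_DYADS + 1, size=len(presented))
            img_col.append(presented)
            ann_col.append(np.full(len(presented), annotator))
            day_col.append(np.full(len(presented), day))
            vote_col.append(session_votes)

    records = pd.DataFrame(
        {
            "image_id": np.concatenate(img_col),
            "annotator_id": np.concatenate(ann_col),
            "day": np.concatenate(day_col),
            "dyad_id": np.concatenate(vote_col).astype(int),
        }
    )
    truth_df = pd.DataFrame({"image_id": image_ids, "true_dyad": true_dyads})
    return SimulatedStudy(records, controls_used, truth_df, pilot_df)


def simulate_vote_counts(
    n_images: int,
    raters_per_image: int,
    p_true: float,
    p_adjacent: float = 0.05,
    p_opposite: float = 0.02,
    seed: int | np.random.Generator = 0,
    catalog: DyadCatalog | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct per-image vote tallies, bypassing the session machinery.

    Every image receives ``raters_per_image`` attentive votes from the
    wheel-distance mixture.  Intended for parameter sweeps (agreement vs
    ``p_true``) and filter-recovery experiments where session structure is
    irrelevant.

    Returns ``(counts, truth)``: an ``(n_images, 8)`` integer matrix and the
    true dyad per image.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_images < 1:
        raise InfeasibleConfigError("need at least one image")
    cum = mixture_matrix(p_true, p_adjacent, p_opposite, catalog).cumsum(axis=1)
    truth = _balanced_truth(rng, n_images)
    u = rng.random((n_images, raters_per_image))
    votes = (u[:, :, None] > cum[truth - 1][:, None, :]).sum(axis=2)  # 0-based
    counts = np.zeros((n_images, N_DYADS), dtype=int)
    np.add.at(counts, (np.repeat(np.arange(n_images), raters_per_image), votes.ravel()), 1)
    return counts, truth


def simulate_original_annotations(
    n_images: int,
    raters_per_image: int,
    p_true: float = 0.65,
    p_adjacent: float = 0.20,
    p_opposite: float = 0.05,
    seed: int | np.random.Generator = 0,
    catalog: DyadCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMOTIC-style 26-word original annotations for the selection stage.

    Each rater perceives a dyad from the wheel-distance mixture and then
    reports a uniformly chosen word from that dyad's vocabulary group.

    Returns ``(records, truth)``: a long table with columns ``image_id,
    annotator_id, emotion_word`` and the ground-truth table.
    """
    catalog = catalog or default_catalog()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = mixture_matrix(p_true, p_adjacent, p_opposite, catalog).cumsum(axis=1)
    truth = _balanced_truth(rng, n_images)
    groups = catalog.word_groups()
    image_ids = np.arange(1, n_images + 1)
    rows_img, rows_ann, rows_word = [], [], []
    for img, t in zip(image_ids, truth):
        dyads = _draw(rng, np.tile(cum[t - 1], (raters_per_image, 1)))
        words = [groups[d][rng.integers(len(groups[d]))] for d in dyads]
        rows_img.extend([img] * raters_per_image)
        rows_ann.extend(range(1, raters_per_image + 1))
        rows_word.extend(words)
    records = pd.DataFrame(
        {"image_id": rows_img, "annotator_id": rows_ann, "emotion_word": rows_word}
    )
    truth_df = pd.DataFrame({"image_id": image_ids, "true_dyad": truth})
    return records, truth_df


def simulate_session_validity(
    config: SimulationConfig, n_sessions: int, seed: int | None = None
) -> np.ndarray:
    """Monte Carlo of the AP verdict for ``n_sessions`` rater-sessions.

    Draws only the validation-relevant quantities of the generative model
    (control correctness and duplicate consistency), which makes simulating
    millions of sessions cheap.  Returns a boolean validity array.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    attentive = rng.random(n_sessions) >= config.inattentive_rate
    p_ctrl = np.where(attentive, config.p_control_correct, 1.0 / N_DYADS)
    n_correct = rng.binomial(config.controls_per_session, p_ctrl)
    repeat_ok = np.where(
        attentive, True, rng.random(n_sessions) < 1.0 / N_DYADS
    )
    return repeat_ok & (n_correct >= config.min_controls_correct)


def uniform_session_pass_probability(
    n_controls: int = CONTROLS_PER_SESSION,
    min_correct: int = MIN_CONTROLS_CORRECT,
    n_categories: int = N_DYADS,
) -> float:
    """Exact pass probability for a uniformly-guessing session.

    The duplicate matches with probability 1/K and, independently, at least
    ``min_correct`` of ``n_controls`` controls are hit, each with
    probability 1/K.  For the study constants (K=8, 5 of 6) this is
    ``(1/8) [6 (7/8) (1/8)^5 + (1/8)^6] ~= 2.05e-5``.
    """
    p = 1.0 / n_categories
    return float(p * stats.binom.sf(min_correct - 1, n_controls, p))


def recovery_report(re_results: pd.DataFrame, truth: Mapping | pd.DataFrame) -> dict:
    """Score the reliability filter against simulation ground truth.

    Parameters
    ----------
    re_results
        Per-image filter table from :func:`emoagree.reliability.run_re_stage`.
    truth
        ``image_id -> true_dyad`` mapping or a ``truth.csv``-schema frame.

    Returns
    -------
    dict with ``n_images``, ``frac_true_kept`` (true dyad among the kept
    labels), ``frac_true_unique`` (true dyad is the only kept label) and
    ``mean_kappa_pre`` / ``mean_kappa_post``.
    """
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["image_id"], truth["true_dyad"]))
    if re_results.empty:
        raise ValueError("no filtered images to score")
    missing = [i for i in re_results["image_id"] if i not in truth]
    if missing:
        raise ValueError(f"truth missing for image(s) {missing[:5]}")
    kept_sets = [
        {int(j) for j in kept.split(";")} for kept in re_results["kept_dyads"]
    ]
    true_arr = [int(truth[i]) for i in re_results["image_id"]]
    contained = [t in k for t, k in zip(true_arr, kept_sets)]
    unique = [k == {t} for t, k in zip(true_arr, kept_sets)]
    return {
        "n_images": int(len(re_results)),
        "frac_true_kept": float(np.mean(contained)),
        "frac_true_unique": float(np.mean(unique)),
        "mean_kappa_pre": float(re_results["kappa_pre"].mean()),
        "mean_kappa_post": float(re_results["kappa_post"].mean()),
    }
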