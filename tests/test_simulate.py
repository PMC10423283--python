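import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emoagree.attentiveness import apply_ap
from emoagree.model import AnnotationAgreement
from emoagree.reliability import run_re_stage
from emoagree.simulate import (
    InfeasibleConfigError,
    SimulationConfig,
    mixture_matrix,
    recovery_report,
    simulate,
    simulate_original_annotations,
    simulate_session_validity,
    simulate_vote_counts,
    uniform_session_pass_probability,
)

SMALL = dict(
    n_images=48,
    n_days=2,
    raters_per_day=5,
    images_per_session=16,
    p_true=0.9,
    p_adjacent=0.05,
    p_opposite=0.02,
    seed=3,
)


def test_mixture_matrix_is_row_stochastic_with_wheel_structure(catalog):
    P = mixture_matrix(0.65, 0.20, 0.05, catalog)
    assert P.shape == (8, 8)
    assert np.allclose(P.sum(axis=1), 1.0)
    for t in range(1, 9):
        assert P[t - 1, t - 1] == pytest.approx(0.65)
        assert P[t - 1, catalog.opposite(t) - 1] == pytest.approx(0.05)
        for a in catalog.dyads_at_distance(t, 1):
            assert P[t - 1, a - 1] == pytest.approx(0.10)


def test_infeasible_configs_rejected():
    with pytest.raises(InfeasibleConfigError):
        SimulationConfig(n_images=10, images_per_session=56)  # more than available
    with pytest.raises(InfeasibleConfigError):
        SimulationConfig(p_true=0.9, p_adjacent=0.2, p_opposite=0.05)  # mass > 1
    with pytest.raises(InfeasibleConfigError):
        SimulationConfig(images_per_session=6)  # no room beside the controls
    with pytest.raises(InfeasibleConfigError):
        SimulationConfig(inattentive_rate=1.5)


def test_simulation_is_deterministic_given_seed():
    a = simulate(SimulationConfig(**SMALL))
    b = simulate(SimulationConfig(**SMALL))
    pd.testing.assert_frame_equal(a.records, b.records)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    assert a.controls == b.controls
    assert a.records.to_csv(index=False) == b.records.to_csv(index=False)


def test_sessions_are_structurally_well_formed():
    study = simulate(SimulationConfig(**SMALL))
    control_ids = {c.image_id for c in study.controls}
    for (_, _), session in study.records.groupby(["annotator_id", "day"]):
        assert len(session) == 17  # images_per_session + 1 duplicate
        counts = session["image_id"].value_counts()
        assert (counts == 2).sum() == 1
        assert counts.max() == 2
        assert len(set(session["image_id"]) & control_ids) == 6
        # the duplicated image is never a control
        assert counts.idxmax() not in control_ids


def test_degenerate_limit_every_session_valid_and_unanimous():
    cfg = SimulationConfig(
        **{**SMALL, "p_true": 1.0, "p_adjacent": 0.0, "p_opposite": 0.0},
        inattentive_rate=0.0,
        p_control_correct=1.0,
    )
    study = simulate(cfg)
    retained, audit = apply_ap(study.records, study.controls)
    assert audit["valid"].all()
    results = AnnotationAgreement.from_records(retained).fit()
    assert results.mean_kappa == pytest.approx(1.0)
    # every vote equals the image's true dyad
    truth = study.truth_map
    assert all(
        truth[i] == d for i, d in zip(retained["image_id"], retained["dyad_id"])
    )


def test_control_candidates_respect_pilot_rule():
    study = simulate(SimulationConfig(**SMALL))
    tally = pd.crosstab(study.pilot_votes["image_id"], study.pilot_votes["dyad_id"])
    for control in study.controls:
        assert tally.loc[control.image_id].max() >= 4
        assert tally.loc[control.image_id].idxmax() == control.expected_dyad


def test_uniform_pass_probability_closed_form():
    p = uniform_session_pass_probability()
    expected = (1 / 8) * (6 * (7 / 8) * (1 / 8) ** 5 + (1 / 8) ** 6)
    assert p == pytest.approx(expected, rel=1e-12)
    assert p == pytest.approx(2.05e-5, rel=0.01)


def test_attentive_pass_rate_matches_binomial_model():
    cfg = SimulationConfig(inattentive_rate=0.0, p_control_correct=0.9)
    valid = simulate_session_validity(cfg, 200_000, seed=5)
    expected = stats.binom.sf(4, 6, 0.9)
    assert stats.binomtest(int(valid.sum()), valid.size, expected).pvalue > 1e-3


def test_simulate_vote_counts_shapes_and_totals(rng):
    counts, truth = simulate_vote_counts(50, 28, p_true=0.7, seed=rng)
    assert counts.shape == (50, 8)
    assert (counts.sum(axis=1) == 28).all()
    assert set(truth) <= set(range(1, 9))
    # the true dyad is the modal vote for most images at p_true 0.7
    assert (counts.argmax(axis=1) + 1 == truth).mean() > 0.9


def test_mean_agreement_rises_with_rater_fidelity():
    means = []
    for p_true in (0.3, 0.5, 0.7, 0.9):
        counts, _ = simulate_vote_counts(150, 28, p_true, 0.05, 0.02, seed=11)
        table = AnnotationAgreement(counts).fit()
        means.append(table.mean_kappa)
    assert all(a < b for a, b in zip(means, means[1:]))


def test_recovery_report_perfect_raters():
    counts, truth = simulate_vote_counts(40, 20, p_true=1.0, p_adjacent=0.0,
                                         p_opposite=0.0, seed=2)
    results, _ = run_re_stage(counts)
    report = recovery_report(
        results, dict(zip(range(40), truth))
    )
    assert report["frac_true_kept"] == 1.0
    assert report["frac_true_unique"] == 1.0
    assert report["mean_kappa_post"] == pytest.approx(1.0)


def test_recovery_report_matches_bruteforce_recount(rng):
    counts, truth = simulate_vote_counts(80, 28, p_true=0.8, p_adjacent=0.12,
                                         p_opposite=0.03, seed=rng)
    results, _ = run_re_stage(counts)
    report = recovery_report(results, dict(enumerate(truth)))
    # independent recount straight from the count matrix
    mu = counts.mean(axis=1)
    kept = counts >= mu[:, None]
    contained = kept[np.arange(80), truth - 1]
    unique = contained & (kept.sum(axis=1) == 1)
    assert report["frac_true_kept"] == pytest.approx(contained.mean())
    assert report["frac_true_unique"] == pytest.approx(unique.mean())


def test_recovery_report_errors():
    counts, truth = simulate_vote_counts(5, 10, p_true=0.9, seed=0)
    results, _ = run_re_stage(counts)
    with pytest.raises(ValueError, match="truth missing"):
        recovery_report(results, {0: 1})
    with pytest.raises(ValueError, match="no filtered images"):
        recovery_report(results.iloc[0:0], dict(enumerate(truth)))


def test_projection_votes_are_suppressed_by_the_filter():
    counts, truth = simulate_vote_counts(300, 28, p_true=0.65, p_adjacent=0.20,
                                         p_opposite=0.05, seed=6)
    opp_idx = np.array(
        [_OPPOSITE[t] - 1 for t in truth]
    )
    frac_pre = (counts[np.arange(300), opp_idx] > 0).mean()
    post, _ = run_re_stage(counts)
    post_counts = post[[f"counts_post_{j}" for j in range(1, 9)]].to_numpy()
    frac_post = (post_counts[np.arange(300), opp_idx] > 0).mean()
    assert frac_post < frac_pre


def test_original_annotations_use_vocabulary_words(catalog):
    records, truth = simulate_original_annotations(30, 6, seed=4)
    assert len(records) == 180
    mapped = records["emotion_word"].map(catalog.map_emotic_label)
    # words are drawn within the perceived dyad's vocabulary group
    assert mapped.isin(range(1, 9)).all()
    by_image = records.groupby("image_id").size()
    assert (by_image == 6).all()
    assert len(truth) == 30


_OPPOSITE = {1: 4, 4: 1, 2: 7, 7: 2, 3: 8, 8: 3, 5: 6, 6: 5}
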