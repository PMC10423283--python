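import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emoagree.agreement import (
    BANDS,
    KAPPA_MIN,
    UndefinedAgreementError,
    VoteVector,
    kappa_band,
    kappa_table,
    mean_kappa,
    per_image_kappa,
    summarize,
)

from .conftest import pair_counting_p_obs

counts_strategy = st.lists(st.integers(0, 30), min_size=8, max_size=8).filter(
    lambda c: sum(c) >= 2
)


def test_published_vote_vector_reproduces_headline_kappa(crowd_votes_joy):
    result = per_image_kappa(crowd_votes_joy)
    assert round(result.kappa, 2) == 0.53
    assert result.n == 30
    assert result.n_labels == 6
    assert result.category == "Moderate"


def test_split_vote_vector_kappa(crowd_votes_split):
    # oracle: 220 agreeing pairs of 756, rescaled against uniform chance 1/8
    result = per_image_kappa(crowd_votes_split)
    assert result.p_obs == pytest.approx(220 / 756)
    assert result.kappa == pytest.approx((220 / 756 - 1 / 8) / (7 / 8))
    assert round(result.kappa, 4) == 0.1897


def test_unanimity_gives_kappa_one():
    result = per_image_kappa(VoteVector("u", (0, 0, 28, 0, 0, 0, 0, 0)))
    assert result.kappa == pytest.approx(1.0)
    assert result.category == "Almost Perfect"
    assert result.n_labels == 1


def test_fewer_than_two_raters_is_undefined():
    with pytest.raises(UndefinedAgreementError):
        per_image_kappa(VoteVector("x", (1, 0, 0, 0, 0, 0, 0, 0)))


def test_vote_vector_validation():
    with pytest.raises(ValueError):
        VoteVector("x", (1, 2, 3))
    with pytest.raises(ValueError):
        VoteVector("x", (1, -1, 0, 0, 0, 0, 0, 0))


@given(counts_strategy)
def test_kappa_matches_pair_counting_oracle(counts):
    result = per_image_kappa(VoteVector("h", tuple(counts)))
    p_obs = pair_counting_p_obs(counts)
    assert result.p_obs == pytest.approx(p_obs, abs=1e-12)
    assert result.kappa == pytest.approx((p_obs - 1 / 8) / (7 / 8), abs=1e-12)


@given(counts_strategy, st.permutations(list(range(8))))
def test_kappa_invariant_under_category_permutation(counts, perm):
    base = per_image_kappa(VoteVector("h", tuple(counts)))
    shuffled = per_image_kappa(VoteVector("h", tuple(counts[j] for j in perm)))
    assert shuffled.kappa == pytest.approx(base.kappa)


@given(counts_strategy)
def test_kappa_one_iff_single_voted_category(counts):
    result = per_image_kappa(VoteVector("h", tuple(counts)))
    assert (result.kappa == pytest.approx(1.0)) == (result.n_labels == 1)
    assert KAPPA_MIN - 1e-12 <= result.kappa <= 1 + 1e-12


def test_minimum_kappa_at_one_vote_per_category():
    result = per_image_kappa(VoteVector("m", (1,) * 8))
    assert result.kappa == pytest.approx(KAPPA_MIN)
    assert result.kappa == pytest.approx(-1 / 7)


def test_mean_kappa_trivial_cases():
    one = per_image_kappa(VoteVector("a", (0, 0, 5, 0, 0, 0, 0, 0)))
    assert mean_kappa([one]) == pytest.approx(one.kappa)
    flat = per_image_kappa(VoteVector("b", (1,) * 8))
    assert mean_kappa([one, flat]) == pytest.approx((1 + (-1 / 7)) / 2)
    with pytest.raises(ValueError):
        mean_kappa([])


def test_mean_kappa_matches_independent_resummation(rng):
    counts = rng.multinomial(25, np.full(8, 1 / 8), size=10)
    table = kappa_table(counts)
    expected = sum(
        per_image_kappa(VoteVector(i, tuple(row))).kappa
        for i, row in enumerate(counts)
    ) / len(counts)
    assert mean_kappa(table) == pytest.approx(expected)


def test_kappa_table_matches_scalar_path(rng):
    counts = rng.multinomial(30, np.full(8, 1 / 8), size=25)
    table = kappa_table(counts, image_ids=[f"img{i}" for i in range(25)])
    for _, row in table.iterrows():
        scalar = per_image_kappa(
            VoteVector(row["image_id"], tuple(row[f"counts_{j}"] for j in range(1, 9)))
        )
        assert row["kappa"] == pytest.approx(scalar.kappa)
        assert row["band"] == scalar.category
        assert row["n_labels"] == scalar.n_labels


def test_summarize_unanimous_fixture_single_band():
    counts = np.zeros((5, 8), dtype=int)
    counts[np.arange(5), np.arange(5)] = 20
    table = kappa_table(counts)
    by_band = summarize(table, "band")
    assert list(by_band.index) == ["Almost Perfect"]
    assert by_band.loc["Almost Perfect", "n_images"] == 5
    assert (table["n_labels"] == 1).all()


def test_summarize_band_fixture_spans_all_bands():
    # constructed so the six kappas land one per Landis-Koch band
    counts = np.array(
        [
            (1, 1, 1, 1, 1, 1, 1, 1),  # kappa -1/7   -> Poor
            (1, 13, 7, 0, 0, 0, 5, 2),  # 0.1897      -> Slight
            (10, 5, 5, 0, 0, 0, 0, 0),  # 0.2481      -> Fair
            (1, 1, 1, 0, 23, 0, 3, 1),  # 0.5297      -> Moderate
            (18, 2, 0, 0, 0, 0, 0, 0),  # 0.7835      -> Substantial
            (0, 0, 28, 0, 0, 0, 0, 0),  # 1.0         -> Almost Perfect
        ]
    )
    table = kappa_table(counts)
    by_band = summarize(table, "band")
    assert by_band["n_images"].sum() == 6
    assert (by_band["n_images"] == 1).all()
    assert set(by_band.index) == set(BANDS)


def test_summarize_by_modal_dyad_groups_match_construction():
    counts = np.array(
        [
            (9, 1, 0, 0, 0, 0, 0, 0),
            (8, 0, 2, 0, 0, 0, 0, 0),
            (0, 0, 0, 0, 10, 0, 0, 0),
            (5, 0, 0, 0, 5, 0, 0, 0),  # tie -> lowest dyad id (1)
        ]
    )
    by_mode = summarize(kappa_table(counts), "modal_dyad")
    assert by_mode.loc[1, "n_images"] == 3
    assert by_mode.loc[5, "n_images"] == 1


def test_summarize_unknown_key_and_empty_table():
    table = kappa_table(np.array([(2, 0, 0, 0, 0, 0, 0, 0)]))
    with pytest.raises(ValueError, match="unknown grouping key"):
        summarize(table, "color")
    with pytest.raises(ValueError):
        summarize(table.iloc[0:0], "band")
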