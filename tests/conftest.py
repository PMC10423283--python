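import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emoagree import VoteVector, default_catalog

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(20230812)


# The two published per-image vote listings, indexed by dyad id 1..8
# (Anger, Engagement, Disgust, Fear, Joy, Sadness, Surprise, Trust).
@pytest.fixture
def crowd_votes_joy():
    """30 raters: 23 on Joy, scattered remainder including wheel-opposites."""
    return VoteVector("left", (1, 1, 1, 0, 23, 0, 3, 1))


@pytest.fixture
def crowd_votes_split():
    """28 raters split over five dyads, modal dyad Engagement."""
    return VoteVector("right", (1, 13, 7, 0, 0, 0, 5, 2))


def pair_counting_p_obs(counts) -> float:
    """Independent oracle: observed agreement by explicit rater-pair counting."""
    labels = np.repeat(np.arange(len(counts)), counts)
    n = labels.size
    assert n >= 2
    agree = int((labels[:, None] == labels[None, :]).sum()) - n
    return agree / (n * (n - 1))


def make_session(
    annotator_id,
    day,
    control_ids,
    control_votes,
    filler_ids,
    dup_id,
    dup_votes,
    filler_vote=5,
):
    """Build one well-formed 57-presentation session as a records frame.

    Presentation order: controls, fillers, then the duplicate's second
    presentation last (``dup_id`` must be one of the fillers).
    """
    assert dup_id in filler_ids
    images = list(control_ids) + list(filler_ids)
    votes = list(control_votes) + [
        dup_votes[0] if i == dup_id else filler_vote for i in filler_ids
    ]
    images.append(dup_id)
    votes.append(dup_votes[1])
    return pd.DataFrame(
        {
            "image_id": images,
            "annotator_id": annotator_id,
            "day": day,
            "dyad_id": votes,
        }
    )
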