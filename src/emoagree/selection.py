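"""Category-balanced image subset selection from original EMOTIC-style labels.

EMOTIC's native annotations are heavily imbalanced across emotions, so the
relabeling subset is built by (1) collapsing each image's original 26-word
votes into the 8 dyads, (2) scoring each image by the *vote percentage* of
its best dyad,

    Pct = votes for the dyad / total votes for the image,

and (3) taking, per dyad, the ``quota`` images with that dyad as their
representative (highest percentage first).  Percentage, not an agreement
coefficient, is the selection statistic because the original per-image rater
counts vary wildly.  Ties break deterministically: the lowest dyad id wins
the argmax, and equal percentages rank by ascending image id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomy import N_DYADS, DyadCatalog, default_catalog

__all__ = [
    "RepresentativeScore",
    "SubsetShortfallError",
    "score_image",
    "score_table",
    "select_balanced_subset",
]


class SubsetShortfallError(ValueError):
    """A dyad has fewer eligible images than the requested quota."""

    def __init__(self, dyad_id: int, available: int, quota: int):
        self.dyad_id = dyad_id
        self.available = available
        self.quota = quota
        super().__init__(
            f"dyad {dyad_id}: only {available} eligible images for quota {quota}"
        )


@dataclass(frozen=True)
class RepresentativeScore:
    """Per-dyad vote fractions and the representative dyad for one image."""

    image_id: object
    pct_per_dyad: tuple[float, ...]
    representative_dyad: int
    pct: float


def score_image(
    words: Sequence[str], image_id=None, catalog: DyadCatalog | None = None
) -> RepresentativeScore:
    """Score one image from its original emotion-word votes.

    Every word is mapped into its dyad; the per-dyad fraction of the total
    votes is computed and the dyad with the maximum fraction (ties to the
    lowest id) is the image's representative emotion.
    """
    catalog = catalog or default_catalog()
    if len(words) == 0:
        raise ValueError(f"image {image_id!r}: empty vote set")
    counts = np.zeros(N_DYADS)
    for word in words:
        counts[catalog.map_emotic_label(word) - 1] += 1
    pct = counts / counts.sum()
    best = int(pct.argmax())  # argmax takes the first maximum: lowest dyad id
    return RepresentativeScore(image_id, tuple(pct), best + 1, float(pct[best]))


def score_table(
    table: pd.DataFrame, catalog: DyadCatalog | None = None
) -> pd.DataFrame:
    """Score every image of an original-annotation table.

    Parameters
    ----------
    table
        Long table with columns ``image_id`` and ``emotion_word`` (the
        ``original_annotations.csv`` dialect; extra columns such as
        ``annotator_id`` are ignored).

    Returns
    -------
    DataFrame with columns ``image_id, representative_dyad, pct`` plus the
    eight per-dyad fractions ``pct_1..8``, one row per image.
    """
    catalog = catalog or default_catalog()
    if table.empty:
        raise ValueError("empty annotation table")
    dyad = table["emotion_word"].map(catalog.map_emotic_label)
    tally = (
        pd.crosstab(table["image_id"], dyad)
        .reindex(columns=range(1, N_DYADS + 1), fill_value=0)
        .sort_index()
    )
    frac = tally.div(tally.sum(axis=1), axis=0)
    out = pd.DataFrame(
        {
            "image_id": tally.index,
            "representative_dyad": frac.to_numpy().argmax(axis=1) + 1,
            "pct": frac.to_numpy().max(axis=1),
        }
    ).reset_index(drop=True)
    out[[f"pct_{j}" for j in range(1, N_DYADS + 1)]] = frac.to_numpy()
    return out


def select_balanced_subset(
    table: pd.DataFrame, quota: int, catalog: DyadCatalog | None = None
) -> pd.DataFrame:
    """Select ``quota`` images per dyad, most representative first.

    Within each dyad's pool (images whose representative emotion is that
    dyad) images are ranked by descending vote percentage, then ascending
    image id, and the top ``quota`` are taken.  The result is grouped by
    dyad id, so its length is exactly ``8 * quota``.

    Raises
    ------
    SubsetShortfallError
        If some dyad has fewer eligible images than ``quota``; the error
        names the dyad and its available count.
    """
    if quota < 0:
        raise ValueError("quota must be nonnegative")
    scores = score_table(table, catalog)
    picked = []
    for dyad_id in range(1, N_DYADS + 1):
        pool = scores[scores["representative_dyad"] == dyad_id]
        if len(pool) < quota:
            raise SubsetShortfallError(dyad_id, len(pool), quota)
        pool = pool.sort_values(
            ["pct", "image_id"], ascending=[False, True], kind="mergesort"
        )
        picked.append(pool.head(quota))
    subset = pd.concat(picked, ignore_index=True) if picked else scores.head(0)
    return subset[["image_id", "representative_dyad", "pct"]].reset_index(drop=True)
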