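"""Reliability enhancement (RE): Z-score filtering of per-image vote vectors.

Even among attentive annotators, an image's votes typically scatter over
several dyads — occasionally including wheel-opposite ones, the signature of
annotators projecting their own emotions rather than reading the depicted
subject's.  The RE stage standardizes each image's 8 counts,

    z_j = (n_j - mu) / sigma,      mu, sigma over all 8 counts (zeros included),

keeps the dyads with z_j >= 0 (equivalently n_j >= mu, since sigma only
rescales), discards the votes of the remaining dyads, and recomputes the
agreement coefficient on the surviving counts with the category space still
of size 8.  Because the most-voted dyad always sits at or above the mean, the
kept set is never empty; when all counts are equal (sigma = 0) every z is
defined as 0 and the filter is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import (
    BANDS,
    COUNT_COLUMNS,
    KappaResult,
    UndefinedAgreementError,
    VoteVector,
    kappa_table,
    per_image_kappa,
)

__all__ = [
    "ZScoreResult",
    "FilterResult",
    "z_scores",
    "apply_re",
    "filter_counts",
    "run_re_stage",
]

POST_COUNT_COLUMNS = [f"counts_post_{j}" for j in range(1, 9)]


@dataclass(frozen=True)
class ZScoreResult:
    """Standardized vote counts for one image."""

    image_id: object
    mu: float
    sigma: float
    z: tuple[float, ...]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the Z-score filter on one image."""

    image_id: object
    kept_dyads: tuple[int, ...]
    filtered_counts: tuple[int, ...]
    kappa_pre: KappaResult
    kappa_post: KappaResult


def z_scores(votes: VoteVector) -> ZScoreResult:
    """Standardize an image's 8 vote counts (population sigma, zeros included).

    With sigma = 0 (all counts equal) every z is defined as 0, so the
    subsequent ``z >= 0`` selection keeps all dyads.
    """
    c = np.asarray(votes.counts, dtype=float)
    mu = float(c.mean())
    sigma = float(c.std())  # population form: divide by 8
    if sigma > 0.0:
        z = (c - mu) / sigma
    else:
        z = np.zeros_like(c)
    return ZScoreResult(votes.image_id, mu, sigma, tuple(float(v) for v in z))


def filter_counts(counts, z_threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Z-score filter over a stack of vote-count vectors.

    Returns ``(post_counts, kept_mask)`` where discarded dyads are zeroed.
    At the default threshold 0 the kept set is ``{j : n_j >= mean}``; a
    nonzero threshold keeps ``{j : z_j >= z_threshold}`` and is exposed only
    as an exploration knob.
    """
    m = np.asarray(counts, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[None, :]
    mu = m.mean(axis=1, keepdims=True)
    if z_threshold == 0.0:
        kept = m >= mu
    else:
        sigma = m.std(axis=1, keepdims=True)
        z = np.divide(m - mu, sigma, out=np.zeros_like(m), where=sigma > 0)
        kept = z >= z_threshold
    post = np.where(kept, m, 0.0)
    if squeeze:
        return post[0], kept[0]
    return post, kept


def apply_re(votes: VoteVector, z_threshold: float = 0.0) -> FilterResult:
    """Filter one image's votes and recompute its agreement coefficient.

    Raises
    ------
    UndefinedAgreementError
        If fewer than two votes survive the filter (impossible at the
        default threshold for n >= 2, possible for stricter thresholds).
    """
    kappa_pre = per_image_kappa(votes)
    post, kept = filter_counts(votes.counts, z_threshold)
    post_counts = tuple(int(v) for v in post)
    if sum(post_counts) < 2:
        raise UndefinedAgreementError(
            f"image {votes.image_id!r}: fewer than 2 votes survive the filter"
        )
    kappa_post = per_image_kappa(VoteVector(votes.image_id, post_counts))
    kept_dyads = tuple(int(j) + 1 for j in np.flatnonzero(kept))
    return FilterResult(votes.image_id, kept_dyads, post_counts, kappa_pre, kappa_post)


def run_re_stage(
    counts, image_ids=None, z_threshold: float = 0.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the RE filter to every image and summarize before vs after.

    Parameters
    ----------
    counts
        ``(m, 8)`` array of per-image vote counts (the AP-retained tallies),
        or a ``kappa_table``-schema DataFrame from which counts and ids are
        taken.
    image_ids
        Optional identifiers when ``counts`` is an array.

    Returns
    -------
    results : DataFrame
        Schema of ``re_results.csv``: ``image_id, kept_dyads,
        counts_post_1..8, kappa_pre, kappa_post, band_pre, band_post,
        n_labels_pre, n_labels_post``.
    summary : dict
        ``band_counts`` and ``label_counts`` DataFrames (images per band /
        per number of labels, before and after) and ``mean_kappa``
        (``{"pre": ..., "post": ...}``).  Empty input yields empty outputs.
    """
    if isinstance(counts, pd.DataFrame):
        image_ids = counts["image_id"].to_numpy()
        counts = counts[COUNT_COLUMNS].to_numpy()
    m = np.asarray(counts, dtype=float)
    if m.size == 0:
        empty = pd.DataFrame(
            columns=["image_id", "kept_dyads", *POST_COUNT_COLUMNS, "kappa_pre",
                     "kappa_post", "band_pre", "band_post", "n_labels_pre",
                     "n_labels_post"]
        )
        return empty, {
            "band_counts": pd.DataFrame(),
            "label_counts": pd.DataFrame(),
            "mean_kappa": {"pre": np.nan, "post": np.nan},
        }

    pre = kappa_table(m, image_ids)
    post_counts, kept = filter_counts(m, z_threshold)
    if (post_counts.sum(axis=1) < 2).any():
        bad = int(np.argmax(post_counts.sum(axis=1) < 2))
        raise UndefinedAgreementError(
            f"image {pre['image_id'].iloc[bad]!r}: fewer than 2 votes survive"
        )
    post = kappa_table(post_counts, pre["image_id"].to_numpy())

    results = pd.DataFrame({"image_id": pre["image_id"]})
    results["kept_dyads"] = [
        ";".join(str(j + 1) for j in np.flatnonzero(row)) for row in kept
    ]
    results[POST_COUNT_COLUMNS] = post_counts.astype(int)
    results["kappa_pre"] = pre["kappa"]
    results["kappa_post"] = post["kappa"]
    results["band_pre"] = pre["band"]
    results["band_post"] = post["band"]
    results["n_labels_pre"] = pre["n_labels"]
    results["n_labels_post"] = post["n_labels"]

    band_counts = pd.DataFrame(
        {
            "n_images_pre": pre["band"].value_counts().reindex(BANDS, fill_value=0),
            "n_images_post": post["band"].value_counts().reindex(BANDS, fill_value=0),
        }
    ).rename_axis("band")
    labels_idx = pd.RangeIndex(1, 9, name="n_labels")
    label_counts = pd.DataFrame(
        {
            "n_images_pre": pre["n_labels"].value_counts().reindex(
                labels_idx, fill_value=0
            ),
            "n_images_post": post["n_labels"].value_counts().reindex(
                labels_idx, fill_value=0
            ),
        }
    )
    summary = {
        "band_counts": band_counts,
        "label_counts": label_counts,
        "mean_kappa": {
            "pre": float(pre["kappa"].mean()),
            "post": float(post["kappa"].mean()),
        },
    }
    return results, summary
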