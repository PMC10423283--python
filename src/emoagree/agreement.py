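"""Per-image chance-corrected agreement over the eight emotion dyads.

Each image is scored independently from its vote-count vector
``(n_1, ..., n_8)`` over the 8 dyads.  Observed agreement is the fraction of
concordant rater pairs,

    P_obs = (sum_j n_j^2 - n) / (n (n - 1)),

and the agreement coefficient rescales it against *uniform* chance agreement
P_e = 1/8:

    kappa = (P_obs - 1/8) / (1 - 1/8).

Uniform chance — rather than the marginal-based expected agreement of the
classic pooled Fleiss statistic — is the deliberate convention here: each
image is a standalone experiment whose rater count varies, so per-image
marginals are degenerate, and the uniform form is the one under which the
worked vote vector (1,1,1,23,3,1,0,0) reproduces its published value 0.53.
Kappa therefore lives in [-1/7, 1]: the minimum is attained when every dyad
receives exactly one vote, the maximum under unanimity.

Qualitative interpretation follows the Landis-Koch bands (Poor below 0,
Slight to 0.2, Fair to 0.4, Moderate to 0.6, Substantial below 0.8, Almost
Perfect at 0.8 and above).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_CATEGORIES",
    "CHANCE_AGREEMENT",
    "KAPPA_MIN",
    "BANDS",
    "UndefinedAgreementError",
    "VoteVector",
    "KappaResult",
    "observed_agreement",
    "per_image_kappa",
    "kappa_band",
    "kappa_table",
    "mean_kappa",
    "summarize",
]

N_CATEGORIES = 8
CHANCE_AGREEMENT = 1.0 / N_CATEGORIES
#: lower bound of the coefficient: (0 - 1/8) / (7/8)
KAPPA_MIN = -CHANCE_AGREEMENT / (1.0 - CHANCE_AGREEMENT)

#: Landis-Koch qualitative labels, in ascending order of agreement.
BANDS = ("Poor", "Slight", "Fair", "Moderate", "Substantial", "Almost Perfect")


class UndefinedAgreementError(ValueError):
    """Agreement is undefined for fewer than two raters."""


@dataclass(frozen=True)
class VoteVector:
    """Vote counts for one image over the 8 dyads (index j = dyad id j+1)."""

    image_id: object
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != N_CATEGORIES:
            raise ValueError(f"expected {N_CATEGORIES} counts, got {len(self.counts)}")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n(self) -> int:
        """Total number of raters."""
        return sum(self.counts)

    @property
    def n_labels(self) -> int:
        """Number of dyads that received at least one vote."""
        return sum(c > 0 for c in self.counts)


@dataclass(frozen=True)
class KappaResult:
    """Agreement diagnostics for one image."""

    image_id: object
    n: int
    p_obs: float
    kappa: float
    category: str
    n_labels: int


def observed_agreement(counts: Sequence[int]) -> float:
    """Fraction of rater pairs that chose the same dyad.

    Equals ``(sum n_j^2 - n) / (n (n-1))`` — the closed form of exhaustive
    pair counting.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise UndefinedAgreementError(f"need at least 2 raters, got {int(n)}")
    return float((np.square(c).sum() - n) / (n * (n - 1.0)))


def kappa_band(kappa: float) -> str:
    """Landis-Koch qualitative label for a kappa value.

    Poor: kappa < 0; Slight: 0 <= kappa <= 0.2; Fair: 0.2 < kappa <= 0.4;
    Moderate: 0.4 < kappa <= 0.6; Substantial: 0.6 < kappa < 0.8;
    Almost Perfect: kappa >= 0.8.
    """
    if kappa < 0.0:
        return "Poor"
    if kappa <= 0.2:
        return "Slight"
    if kappa <= 0.4:
        return "Fair"
    if kappa <= 0.6:
        return "Moderate"
    if kappa < 0.8:
        return "Substantial"
    return "Almost Perfect"


def per_image_kappa(votes: VoteVector) -> KappaResult:
    """Uniform-chance agreement coefficient for one image's vote vector."""
    p_obs = observed_agreement(votes.counts)
    kappa = (p_obs - CHANCE_AGREEMENT) / (1.0 - CHANCE_AGREEMENT)
    return KappaResult(
        image_id=votes.image_id,
        n=votes.n,
        p_obs=p_obs,
        kappa=kappa,
        category=kappa_band(kappa),
        n_labels=votes.n_labels,
    )


def _counts_matrix(counts) -> np.ndarray:
    m = np.asarray(counts, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] != N_CATEGORIES:
        raise ValueError(f"counts must have {N_CATEGORIES} columns")
    return m


COUNT_COLUMNS = [f"counts_{j}" for j in range(1, N_CATEGORIES + 1)]


def kappa_table(counts, image_ids: Sequence | None = None) -> pd.DataFrame:
    """Vectorized per-image kappa over a stack of vote-count vectors.

    Parameters
    ----------
    counts
        Array-like of shape ``(m, 8)``; row j holds image j's counts per dyad.
    image_ids
        Optional identifiers (defaults to 0..m-1).

    Returns
    -------
    DataFrame with columns ``image_id, n, counts_1..8, p_obs, kappa, band,
    n_labels`` — the schema of ``per_image_kappa.csv``.
    """
    m = _counts_matrix(counts)
    n = m.sum(axis=1)
    if (n < 2).any():
        bad = int(np.argmax(n < 2))
        raise UndefinedAgreementError(
            f"image at row {bad} has {int(n[bad])} raters; need at least 2"
        )
    p_obs = (np.square(m).sum(axis=1) - n) / (n * (n - 1.0))
    kappa = (p_obs - CHANCE_AGREEMENT) / (1.0 - CHANCE_AGREEMENT)
    if image_ids is None:
        image_ids = np.arange(m.shape[0])
    table = pd.DataFrame({"image_id": np.asarray(image_ids), "n": n.astype(int)})
    table[COUNT_COLUMNS] = m.astype(int)
    table["p_obs"] = p_obs
    table["kappa"] = kappa
    table["band"] = pd.Categorical(
        [kappa_band(k) for k in kappa], categories=BANDS, ordered=True
    )
    table["n_labels"] = (m > 0).sum(axis=1)
    return table


def mean_kappa(results) -> float:
    """Unweighted arithmetic mean of per-image kappas.

    Accepts a ``kappa_table`` DataFrame or an iterable of
    :class:`KappaResult`.
    """
    if isinstance(results, pd.DataFrame):
        values = results["kappa"].to_numpy(dtype=float)
    else:
        values = np.array([r.kappa for r in results], dtype=float)
    if values.size == 0:
        raise ValueError("mean_kappa of an empty collection is undefined")
    return float(values.mean())


def _modal_dyad(table: pd.DataFrame) -> np.ndarray:
    counts = table[COUNT_COLUMNS].to_numpy()
    return counts.argmax(axis=1) + 1  # ties -> lowest dyad id


def summarize(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Aggregate a per-image kappa table by a grouping key.

    Parameters
    ----------
    table
        Output of :func:`kappa_table`.
    by
        ``"band"`` (Landis-Koch category), ``"n_labels"`` (number of voted
        dyads), ``"n_raters"`` (raters per image) or ``"modal_dyad"``
        (most-voted dyad, ties to the lowest id).

    Returns
    -------
    DataFrame indexed by the grouping key with ``n_images``,
    ``mean_n_raters`` and ``mean_kappa`` columns.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    if by == "band":
        key = table["band"]
    elif by == "n_labels":
        key = table["n_labels"]
    elif by == "n_raters":
        key = table["n"].rename("n_raters")
    elif by == "modal_dyad":
        key = pd.Series(_modal_dyad(table), index=table.index, name="modal_dyad")
    else:
        raise ValueError(f"unknown grouping key: {by!r}")
    grouped = table.groupby(key, observed=True)
    out = grouped.agg(
        n_images=("image_id", "size"),
        mean_n_raters=("n", "mean"),
        mean_kappa=("kappa", "mean"),
    )
    return out
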