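"""Model/Results interface over the agreement and reliability analytics.

:class:`AnnotationAgreement` is built from per-image vote counts (or a long
annotation table); ``fit()`` yields :class:`AgreementResults` carrying the
per-image coefficients, band labels and summary tables, from which
``filter_reliability()`` produces a :class:`ReliabilityResults` comparing
the stage before and after the Z-score filter.  Plotting (agreement vs
number of raters, the study's diagnostic scatter) hangs off the results
objects.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement, reliability
from .agreement import COUNT_COLUMNS, N_CATEGORIES
from .simulate import recovery_report

__all__ = ["AnnotationAgreement", "AgreementResults", "ReliabilityResults"]


class AnnotationAgreement:
    """Per-image multi-rater agreement model over the 8 emotion dyads.

    Parameters
    ----------
    counts
        ``(n_images, 8)`` vote-count matrix, one row per image.
    image_ids
        Optional image identifiers aligned with the rows.
    """

    def __init__(self, counts, image_ids: Sequence | None = None):
        self.counts = np.asarray(counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CATEGORIES:
            raise ValueError(f"counts must be (n_images, {N_CATEGORIES})")
        self.image_ids = (
            np.asarray(image_ids)
            if image_ids is not None
            else np.arange(self.counts.shape[0])
        )

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "AnnotationAgreement":
        """Build the model from a long annotation table.

        ``records`` needs columns ``image_id`` and ``dyad_id`` (the
        ``annotations.csv`` dialect, typically after AP retention).
        """
        tally = (
            pd.crosstab(records["image_id"], records["dyad_id"])
            .reindex(columns=range(1, N_CATEGORIES + 1), fill_value=0)
            .sort_index()
        )
        return cls(tally.to_numpy(), tally.index.to_numpy())

    def fit(self) -> "AgreementResults":
        """Compute per-image observed agreement, kappa and band labels."""
        table = agreement.kappa_table(self.counts, self.image_ids)
        return AgreementResults(self, table)


class AgreementResults:
    """Fitted per-image agreement coefficients with summary utilities."""

    def __init__(self, model: AnnotationAgreement, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def mean_kappa(self) -> float:
        """Unweighted mean of the per-image kappas."""
        return agreement.mean_kappa(self.table)

    def summarize(self, by: str) -> pd.DataFrame:
        """Group the per-image table by band / n_labels / n_raters / modal_dyad."""
        return agreement.summarize(self.table, by)

    def filter_reliability(self, z_threshold: float = 0.0) -> "ReliabilityResults":
        """Apply the Z-score vote filter and re-fit on the surviving counts."""
        results, summary = reliability.run_re_stage(
            self.model.counts, self.model.image_ids, z_threshold
        )
        post_model = AnnotationAgreement(
            results[reliability.POST_COUNT_COLUMNS].to_numpy(),
            self.model.image_ids,
        )
        return ReliabilityResults(self, post_model.fit(), results, summary)

    def summary(self) -> str:
        """Human-readable digest: headline kappa and the band table."""
        bands = self.summarize("band")
        lines = [
            "Per-image agreement over 8 emotion dyads",
            f"  images: {len(self.table)}   "
            f"mean raters/image: {self.table['n'].mean():.1f}",
            f"  mean kappa: {self.mean_kappa:.2f} "
            f"({agreement.kappa_band(self.mean_kappa)})",
            "",
            bands.round({"mean_n_raters": 1, "mean_kappa": 4}).to_string(),
        ]
        return "\n".join(lines)

    def plot_kappa_vs_raters(self, ax=None, **scatter_kw):
        """Scatter of per-image kappa against the number of raters."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.table["kappa"], self.table["n"], marker="+", **scatter_kw)
        ax.set_xlabel("kappa")
        ax.set_ylabel("number of annotators")
        return ax


class ReliabilityResults:
    """Before/after comparison across the Z-score reliability filter."""

    def __init__(
        self,
        pre: AgreementResults,
        post: AgreementResults,
        table: pd.DataFrame,
        stage_summary: dict,
    ):
        self.pre = pre
        self.post = post
        #: per-image filter table (``re_results.csv`` schema)
        self.table = table
        self.band_counts = stage_summary["band_counts"]
        self.label_counts = stage_summary["label_counts"]
        self.mean_kappa_pre = stage_summary["mean_kappa"]["pre"]
        self.mean_kappa_post = stage_summary["mean_kappa"]["post"]

    def recovery(self, truth: Mapping | pd.DataFrame) -> dict:
        """Retention metrics against simulation ground truth."""
        return recovery_report(self.table, truth)

    def summary(self) -> str:
        lines = [
            "Z-score reliability filter (kept dyads: vote count >= image mean)",
            f"  images: {len(self.table)}",
            f"  mean kappa: {self.mean_kappa_pre:.2f} -> {self.mean_kappa_post:.2f}",
            f"  max labels/image: {int(self.table['n_labels_pre'].max())} -> "
            f"{int(self.table['n_labels_post'].max())}",
            "",
            "images per band (before -> after):",
            self.band_counts.to_string(),
            "",
            "images per number of labels (before -> after):",
            self.label_counts.to_string(),
        ]
        return "\n".join(lines)

    def plot_kappa_vs_raters(self, axes=None):
        """Side-by-side diagnostic scatter, before and after the filter."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, sharey=True, figsize=(9, 4))
        self.pre.plot_kappa_vs_raters(ax=axes[0])
        axes[0].set_title("attentiveness control only")
        self.post.plot_kappa_vs_raters(ax=axes[1])
        axes[1].set_title("after reliability filter")
        return axes
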