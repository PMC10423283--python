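"""CSV dialects of the pipeline (UTF-8, comma-separated, mandatory header).

Schemas
-------
``original_annotations.csv``  image_id,annotator_id,emotion_word
``annotations.csv``           image_id,annotator_id,day,dyad_id
``controls.csv``              image_id,expected_dyad_id
``truth.csv``                 image_id,true_dyad
``subset.csv``                image_id,representative_dyad,pct
``per_image_kappa.csv``       image_id,n,counts_1..8,p_obs,kappa,band,n_labels
``re_results.csv``            image_id,kept_dyads,counts_post_1..8,kappa_pre,
                              kappa_post,band_pre,band_post,n_labels_pre,
                              n_labels_post
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .attentiveness import ControlImage
from .taxonomy import N_DYADS

__all__ = [
    "MalformedTableError",
    "read_table",
    "read_annotations",
    "read_original_annotations",
    "read_controls",
    "write_controls",
    "read_truth",
]


class MalformedTableError(ValueError):
    """An input CSV does not match its declared schema."""


def read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # parser errors carry their own line info
        raise MalformedTableError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing column(s) {missing}")
    return table


def _check_dyad_column(table: pd.DataFrame, column: str, path) -> None:
    bad = ~table[column].isin(range(1, N_DYADS + 1))
    if bad.any():
        line = int(table.index[bad][0]) + 2  # +1 header, +1 one-based
        raise MalformedTableError(
            f"{path}: line {line}: {column}={table.loc[bad, column].iloc[0]!r} "
            f"not a dyad id 1..{N_DYADS}"
        )


def read_annotations(path) -> pd.DataFrame:
    table = read_table(path, ["image_id", "annotator_id", "day", "dyad_id"])
    _check_dyad_column(table, "dyad_id", path)
    return table


def read_original_annotations(path) -> pd.DataFrame:
    return read_table(path, ["image_id", "annotator_id", "emotion_word"])


def read_controls(path) -> list[ControlImage]:
    table = read_table(path, ["image_id", "expected_dyad_id"])
    _check_dyad_column(table, "expected_dyad_id", path)
    return [
        ControlImage(row.image_id, int(row.expected_dyad_id))
        for row in table.itertuples()
    ]


def write_controls(controls, path) -> None:
    pd.DataFrame(
        {
            "image_id": [c.image_id for c in controls],
            "expected_dyad_id": [c.expected_dyad for c in controls],
        }
    ).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    table = read_table(path, ["image_id", "true_dyad"])
    _check_dyad_column(table, "true_dyad", path)
    return table
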