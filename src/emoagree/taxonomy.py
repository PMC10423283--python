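"""Plutchik dyad taxonomy: eight emotion categories, wheel geometry, and the
26-word EMOTIC vocabulary mapping.

Annotators choose one *dyad* per image — a pair of near-synonymous emotion
words standing for one of Plutchik's eight basic emotions (Anger/Rage,
Engagement/Anticipation, Disgust/Disconnection, Fear/Worry, Joy/Affection,
Sadness/Discouragement, Surprise/Amazement, Trust/Peace).  Dyad ids 1-8 are
the fixed I/O convention used throughout the package; wheel positions 0-7
encode the circular Plutchik layout in which each basic emotion sits 180
degrees from its antagonist (joy-sadness, trust-disgust, fear-anger,
surprise-anticipation).  The wheel geometry drives the synthetic annotators'
projection noise (votes leaking to adjacent and to opposite categories).

EMOTIC's original 26 discrete emotion words are regrouped into the eight
dyads; the mapping ships as a JSON resource alongside this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "N_DYADS",
    "Dyad",
    "DyadCatalog",
    "UnknownEmotionLabelError",
    "default_catalog",
]

N_DYADS = 8


class UnknownEmotionLabelError(KeyError):
    """Raised when an emotion word is not in the 26-word EMOTIC vocabulary."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return f"unknown EMOTIC emotion label: {self.word!r}"


@dataclass(frozen=True, order=True)
class Dyad:
    """One of the eight emotion categories offered to annotators."""

    id: int
    name_pair: tuple[str, str]
    wheel_position: int

    @property
    def name(self) -> str:
        return "/".join(self.name_pair)


def _normalize(word: str) -> str:
    return word.strip().lower()


class DyadCatalog:
    """The fixed 8-dyad category system plus the EMOTIC word mapping.

    Parameters
    ----------
    dyads
        Exactly eight :class:`Dyad` entries whose ids are 1-8 and whose wheel
        positions are a permutation of 0-7.
    emotic_map
        Mapping from each of the 26 EMOTIC emotion words to a dyad id.
    aliases
        Optional alternative spellings, mapped to canonical vocabulary words.

    Word lookup is case-insensitive and whitespace-trimmed.
    """

    def __init__(
        self,
        dyads: Iterable[Dyad],
        emotic_map: Mapping[str, int],
        aliases: Mapping[str, str] | None = None,
    ):
        dyads = tuple(sorted(dyads))
        if [d.id for d in dyads] != list(range(1, N_DYADS + 1)):
            raise ValueError("dyad ids must be exactly 1..8")
        if sorted(d.wheel_position for d in dyads) != list(range(N_DYADS)):
            raise ValueError("wheel positions must be a permutation of 0..7")
        self.dyads = dyads
        self._by_id = {d.id: d for d in dyads}
        self._by_position = {d.wheel_position: d for d in dyads}

        self._canonical_words = tuple(emotic_map)
        for dyad_id in emotic_map.values():
            if dyad_id not in self._by_id:
                raise ValueError(f"emotic_map points at invalid dyad id {dyad_id}")
        self._word_to_dyad = {_normalize(w): d for w, d in emotic_map.items()}
        if len(self._word_to_dyad) != len(emotic_map):
            raise ValueError("emotic_map words collide after normalization")
        for alias, target in (aliases or {}).items():
            key = _normalize(target)
            if key not in self._word_to_dyad:
                raise ValueError(f"alias {alias!r} targets unknown word {target!r}")
            self._word_to_dyad[_normalize(alias)] = self._word_to_dyad[key]

    # -- basic access -----------------------------------------------------

    def dyad(self, dyad_id: int) -> Dyad:
        try:
            return self._by_id[dyad_id]
        except KeyError:
            raise ValueError(f"invalid dyad id: {dyad_id!r}") from None

    @property
    def dyad_ids(self) -> tuple[int, ...]:
        return tuple(d.id for d in self.dyads)

    @property
    def emotic_words(self) -> tuple[str, ...]:
        """The 26 canonical vocabulary words, in catalog order."""
        return self._canonical_words

    def word_groups(self) -> dict[int, tuple[str, ...]]:
        """Canonical vocabulary words housed by each dyad id."""
        groups: dict[int, list[str]] = {d.id: [] for d in self.dyads}
        for word in self._canonical_words:
            groups[self._word_to_dyad[_normalize(word)]].append(word)
        return {k: tuple(v) for k, v in groups.items()}

    # -- vocabulary mapping ----------------------------------------------

    def map_emotic_label(self, word: str) -> int:
        """Return the dyad id housing an EMOTIC emotion word."""
        try:
            return self._word_to_dyad[_normalize(word)]
        except KeyError:
            raise UnknownEmotionLabelError(word) from None

    # -- wheel geometry ---------------------------------------------------

    def wheel_distance(self, a: int, b: int) -> int:
        """Minimal circular distance (0-4) between two dyads on the wheel."""
        pa = self.dyad(a).wheel_position
        pb = self.dyad(b).wheel_position
        delta = abs(pa - pb)
        return min(delta, N_DYADS - delta)

    def opposite(self, dyad_id: int) -> int:
        """The dyad sitting 180 degrees across the wheel."""
        pos = self.dyad(dyad_id).wheel_position
        return self._by_position[(pos + N_DYADS // 2) % N_DYADS].id

    def dyads_at_distance(self, dyad_id: int, distance: int) -> tuple[int, ...]:
        """Dyad ids at a given wheel distance, in ascending id order."""
        return tuple(
            d.id
            for d in self.dyads
            if d.id != dyad_id or distance == 0
            if self.wheel_distance(dyad_id, d.id) == distance
        )


@lru_cache(maxsize=1)
def default_catalog() -> DyadCatalog:
    """Load the packaged Plutchik catalog (dyads, wheel, EMOTIC mapping)."""
    raw = json.loads(
        resources.files("emoagree.data").joinpath("plutchik_dyads.json").read_text()
    )
    dyads = [
        Dyad(d["id"], tuple(d["name_pair"]), d["wheel_position"]) for d in raw["dyads"]
    ]
    return DyadCatalog(dyads, raw["emotic_map"], raw.get("aliases"))
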