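"""Concept labels and vocalization logs.

Viewing side: per-second multi-hot annotations of which concepts are on
screen are expanded to 250-ms rows and concept gaps caused by camera
cuts are filled within scene boundaries. Recall side: a timestamped
word transcript is mapped onto concepts through a synonym ontology and
same-concept mentions within 5 s are deduplicated to the first one.

The shipped default ontology encodes eight concepts (persons, places
and abstract concepts from a single televised episode) and the ten
on-screen characters used by the selectivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

N_CONCEPTS = 8
DEDUP_GAP_S = 5.0


@dataclass
class ConceptOntology:
    """concept id -> synonym set (lower-cased), plus character -> concept."""

    concepts: dict
    characters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concepts = {c: {s.lower() for s in syns}
                         for c, syns in self.concepts.items()}
        seen: dict[str, str] = {}
        for c, syns in self.concepts.items():
            for s in syns:
                if s in seen:
                    raise ValueError(
                        f"synonym {s!r} maps to both {seen[s]!r} and {c!r}")
                seen[s] = c
        self._lookup = seen

    @property
    def names(self) -> list:
        return list(self.concepts)

    def match(self, word: str):
        """Concept id for a word/phrase, or None."""
        return self._lookup.get(word.strip().lower())

    def concept_for_character(self, character: str):
        return self.characters.get(character)

    @classmethod
    def default(cls) -> "ConceptOntology":
        with resources.files("memdecode.data").joinpath("ontology.json").open() as f:
            raw = json.load(f)
        return cls(concepts=raw["concepts"], characters=raw["characters"])


@dataclass
class VocalizationEvent:
    time_s: float
    word: str
    concept: str | None  # None = non-concept word (surrogate pool)


@dataclass
class VocalizationLog:
    events: list  # of VocalizationEvent, time-sorted

    def concept_onsets(self, concept: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.concept == concept])

    def other_onsets(self, concept: str) -> np.ndarray:
        """Surrogate pool for a concept: every vocalization onset that is
        not a vocalization of that concept (onsets of *other* concepts
        included)."""
        return np.array([e.time_s for e in self.events if e.concept != concept])

    def eligible_concepts(self, min_vocalizations: int = 3) -> list:
        names: dict[str, int] = {}
        for e in self.events:
            if e.concept is not None:
                names[e.concept] = names.get(e.concept, 0) + 1
        return [c for c, n in names.items() if n >= min_vocalizations]


def expand_labels(per_second: np.ndarray) -> np.ndarray:
    """Copy each second's multi-hot vector to its four 250-ms rows."""
    per_second = np.asarray(per_second)
    if per_second.size == 0:
        return np.zeros((0, N_CONCEPTS), dtype=np.int8)
    if per_second.ndim != 2 or per_second.shape[1] != N_CONCEPTS:
        raise ValueError(f"expected per-second vectors of length {N_CONCEPTS}")
    return np.repeat(per_second.astype(np.int8), 4, axis=0)


def fill_gaps(matrix: np.ndarray, scene_bounds_s: list, max_gap_s: float = 10.0,
              row_s: float = 0.25) -> np.ndarray:
    """Fill, per concept, any zero run shorter than ``max_gap_s`` that is
    flanked by ones on both sides *within a single scene* (concepts are
    treated as continuously present across brief camera cuts). Never
    clears a one; leading/trailing gaps are never filled.

    ``scene_bounds_s``: list of (start_s, end_s) partitioning the
    timeline.
    """
    out = np.array(matrix, dtype=np.int8, copy=True)
    max_rows = int(round(max_gap_s / row_s))
    for start_s, end_s in scene_bounds_s:
        a, b = int(round(start_s / row_s)), int(round(end_s / row_s))
        a, b = max(a, 0), min(b, out.shape[0])
        for c in range(out.shape[1]):
            col = out[a:b, c]
            ones = np.flatnonzero(col)
            if len(ones) < 2:
                continue
            for i, j in zip(ones[:-1], ones[1:]):
                if 1 < j - i <= max_rows:
                    col[i:j] = 1
    return out


def tokenize(text: str) -> list:
    return [w for w in text.lower().split() if w]


def map_vocalizations(transcript, ontology: ConceptOntology) -> VocalizationLog:
    """Map timestamped transcript entries onto concepts.

    ``transcript``: iterable of (time_s, word[, concept_override]).
    Matching is token-level and case-insensitive; multi-word synonyms
    match when the entry's full text equals the synonym. Unmatched words
    are retained with concept None (they form the surrogate pool).
    An explicit override (e.g. a pronoun resolved by the annotator)
    takes precedence.
    """
    events = []
    for entry in transcript:
        time_s, word = entry[0], entry[1]
        override = entry[2] if len(entry) > 2 else None
        if override:
            concept = override
            if concept not in ontology.concepts:
                raise ValueError(f"unknown concept override {concept!r}")
        else:
            concept = ontology.match(word)
        events.append(VocalizationEvent(float(time_s), word, concept))
    events.sort(key=lambda e: e.time_s)
    return VocalizationLog(events)


def dedup_concept_onsets(log: VocalizationLog,
                         gap_s: float = DEDUP_GAP_S) -> VocalizationLog:
    """Drop any concept mention less than ``gap_s`` after the last *kept*
    mention of the same concept, so retained onsets of one concept are
    always >= ``gap_s`` apart. Non-concept words pass through."""
    last_kept: dict[str, float] = {}
    kept = []
    for e in log.events:
        if e.concept is None:
            kept.append(e)
            continue
        prev = last_kept.get(e.concept)
        if prev is not None and e.time_s - prev < gap_s:
            continue
        last_kept[e.concept] = e.time_s
        kept.append(e)
    return VocalizationLog(kept)


def labels_from_schedule(schedule, duration_s: float, concept_names: list,
                         row_s: float = 0.25) -> np.ndarray:
    """Multi-hot 250-ms label matrix from (concept, onset_s, offset_s)
    intervals; a row is on when its midpoint lies inside an interval."""
    n_rows = int(np.floor(duration_s / row_s))
    mat = np.zeros((n_rows, len(concept_names)), dtype=np.int8)
    index = {c: i for i, c in enumerate(concept_names)}
    mids = (np.arange(n_rows) + 0.5) * row_s
    for concept, on, off in schedule:
        mat[(mids >= on) & (mids < off), index[concept]] = 1
    return mat
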