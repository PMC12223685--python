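"""Narrative text cleaning, abbreviation expansion and input composition.

The cleaning pipeline mirrors standard practice for abstractor-written
surveillance narratives: lowercase, strip digits, strip punctuation and
special characters, collapse whitespace.  Digits are removed before
punctuation so enumerated references like ``V1`` reduce to the bare
abbreviation token ``v``, which the (editable) abbreviation map can then
expand to ``victim``.  Replacement is exact-token, single-pass: expansion
text is never re-scanned, so ``s -> suspect`` cannot cascade.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .synthetic import NarrativeRecord

__all__ = [
    "AbbreviationMap",
    "PreprocessConfig",
    "default_abbreviation_map",
    "clean_text",
    "replace_abbreviations",
    "compose_input",
    "preprocess_corpus",
]

_DIGITS = re.compile(r"\d")
_NON_LETTER = re.compile(r"[^a-z\s]")


@dataclass(frozen=True)
class AbbreviationMap:
    """Ordered (abbreviation, expansion) pairs, all lowercase."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for abbrev, expansion in self.pairs:
            if not abbrev or any(ch.isspace() for ch in abbrev):
                raise ValueError(f"invalid abbreviation token: {abbrev!r}")
            if not expansion:
                raise ValueError(f"empty expansion for {abbrev!r}")
            if abbrev in seen:
                raise ValueError(f"duplicate abbreviation token: {abbrev!r}")
            seen.add(abbrev)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    @classmethod
    def from_csv(cls, path) -> "AbbreviationMap":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.reader(fh))

    @classmethod
    def _from_reader(cls, reader) -> "AbbreviationMap":
        rows = [row for row in reader if row]
        if rows and rows[0][:2] == ["abbrev", "expansion"]:
            rows = rows[1:]
        return cls(tuple((r[0].strip().lower(), r[1].strip().lower()) for r in rows))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["abbrev", "expansion"])
            writer.writerows(self.pairs)


def default_abbreviation_map() -> AbbreviationMap:
    """Packaged default map covering victim/suspect/police/gunshot-wound jargon.

    The canonical abbreviation inventory of the surveillance system is not
    public; this reconstruction ships as an editable CSV fixture
    (``narrsim/data/abbreviations.csv``).
    """
    with resources.files("narrsim.data").joinpath("abbreviations.csv").open(
        newline="", encoding="utf-8"
    ) as fh:
        return AbbreviationMap._from_reader(csv.reader(fh))


@dataclass
class PreprocessConfig:
    """How a record's narratives become one classifier input string."""

    source_mode: str = "combined"  # or "le_only"
    replace_abbreviations: bool = False
    abbreviation_map: AbbreviationMap = field(default_factory=default_abbreviation_map)
    max_tokens: int = 512

    def __post_init__(self) -> None:
        if self.source_mode not in ("combined", "le_only"):
            raise ValueError(f"unknown source_mode: {self.source_mode!r}")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")


def clean_text(text: str) -> str:
    """Lowercase; remove digits, then punctuation/special characters;
    collapse whitespace.  Total and idempotent."""
    t = text.lower()
    t = _DIGITS.sub("", t)
    t = _NON_LETTER.sub(" ", t)
    return " ".join(t.split())


def replace_abbreviations(text: str, abbrev_map: AbbreviationMap) -> str:
    """Expand whitespace-delimited tokens exactly matching a map entry.

    Single pass over the input tokens; expansions are emitted verbatim and
    never re-scanned.  Token order is preserved.
    """
    mapping = abbrev_map.as_dict()
    return " ".join(mapping.get(tok, tok) for tok in text.split())


def compose_input(record: NarrativeRecord, config: PreprocessConfig) -> str:
    """Build the model input text for one record.

    Combined mode concatenates the cleaned LE and CME narratives (LE first);
    ``le_only`` drops the CME text.  Optional abbreviation replacement is
    applied after cleaning; the result is truncated to the first
    ``max_tokens`` whitespace tokens.  Both narratives empty yields "".
    """
    parts = [clean_text(record.le_narrative)]
    if config.source_mode == "combined":
        parts.append(clean_text(record.cme_narrative))
    text = " ".join(p for p in parts if p)
    if config.replace_abbreviations:
        text = replace_abbreviations(text, config.abbreviation_map)
    tokens = text.split()
    if len(tokens) > config.max_tokens:
        tokens = tokens[: config.max_tokens]
    return " ".join(tokens)


def preprocess_corpus(
    records: Sequence[NarrativeRecord], config: PreprocessConfig
) -> list[tuple[str, str]]:
    """Order-preserving (record_id, input text) rows for a cohort."""
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record_ids in corpus")
    return [(r.record_id, compose_input(r, config)) for r in records]
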