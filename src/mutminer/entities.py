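"""Dictionary-based recognition of genes, strains, alleles and curation terms.

Plain whole-token dictionary lookup, no fuzzy matching: gene/strain/allele
surfaces match case-insensitively (papers freely write mec-5 or MEC-5) but
are reported with the dictionary's casing; variation types and generation
methods match case-sensitively when the surface is an all-caps acronym (EMS,
ENU) and case-insensitively otherwise.  Word boundaries are required on both
sides, so "EMS" never fires inside "EMSA".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover - import only for annotations
    from .corpus_io import Sentence

__all__ = [
    "ENTITY_CLASSES",
    "DictionaryError",
    "DictionaryEntry",
    "EntityDictionary",
    "EntityMatch",
    "load_dictionaries",
    "match_entities",
]

ENTITY_CLASSES = ("gene", "strain", "allele", "variation_type", "generation_method")

#: Classes whose surfaces always match case-insensitively.
_CASE_INSENSITIVE_CLASSES = frozenset({"gene", "strain", "allele"})

DICTIONARY_HEADER = ("surface_form", "canonical_id", "entity_class")


class DictionaryError(ValueError):
    """Raised for malformed or conflicting dictionary rows."""


@dataclass(frozen=True)
class DictionaryEntry:
    surface_form: str
    canonical_id: str
    entity_class: str


@dataclass(frozen=True)
class EntityMatch:
    doc_id: str
    sentence_id: int
    start: int
    end: int
    surface_form: str  # dictionary casing, not the literal slice
    canonical_id: str
    entity_class: str


class EntityDictionary:
    """Merged, validated entity dictionary with precompiled surface patterns."""

    def __init__(self, entries: Sequence[DictionaryEntry]):
        seen: dict[tuple[str, str], DictionaryEntry] = {}
        for entry in entries:
            if not entry.surface_form:
                raise DictionaryError("empty surface_form")
            if entry.entity_class not in ENTITY_CLASSES:
                raise DictionaryError(
                    f"unknown entity_class {entry.entity_class!r} "
                    f"for surface {entry.surface_form!r}"
                )
            key = (entry.surface_form.lower(), entry.entity_class)
            prior = seen.get(key)
            if prior is not None:
                if prior.canonical_id != entry.canonical_id:
                    raise DictionaryError(
                        f"conflicting ids for ({entry.surface_form!r}, "
                        f"{entry.entity_class}): {prior.canonical_id!r} vs "
                        f"{entry.canonical_id!r}"
                    )
                continue
            seen[key] = entry
        # canonical internal order: independent of input row order
        self.entries = tuple(
            sorted(seen.values(), key=lambda e: (e.entity_class, e.surface_form.lower()))
        )
        self._compiled = [(entry, self._compile(entry)) for entry in self.entries]

    @staticmethod
    def _compile(entry: DictionaryEntry) -> re.Pattern:
        pattern = rf"(?<![A-Za-z0-9]){re.escape(entry.surface_form)}(?![A-Za-z0-9])"
        flags = 0
        if entry.entity_class in _CASE_INSENSITIVE_CLASSES:
            flags = re.IGNORECASE
        elif not (entry.surface_form.isupper() and len(entry.surface_form) > 1):
            flags = re.IGNORECASE
        return re.compile(pattern, flags)

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionaries(paths: Iterable[str | Path]) -> EntityDictionary:
    """Read and merge one or more dictionary TSVs.

    Each file needs the header ``surface_form\tcanonical_id\tentity_class``.
    Duplicate (surface, class) rows with conflicting canonical ids raise a
    :class:`DictionaryError` naming both ids.
    """
    entries: list[DictionaryEntry] = []
    for path in paths:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != DICTIONARY_HEADER:
            raise DictionaryError(
                f"{path}: expected header {DICTIONARY_HEADER!r}"
            )
        for row_number, line in enumerate(lines[1:], start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise DictionaryError(f"{path}: row {row_number}: expected 3 fields")
            entries.append(DictionaryEntry(*(f.strip() for f in fields)))
    return EntityDictionary(entries)


def match_entities(
    sentence: "Sentence",
    dictionary: EntityDictionary,
    doc_id: str = "",
) -> list[EntityMatch]:
    """Find whole-token dictionary hits in one sentence.

    Overlapping hits are resolved longest-first (ties: leftmost, then
    entity class and surface alphabetically), making the result independent
    of dictionary row order.
    """
    candidates = []
    for entry, pattern in dictionary._compiled:
        for m in pattern.finditer(sentence.text):
            candidates.append((m.start(), m.end(), entry))
    candidates.sort(
        key=lambda c: (-(c[1] - c[0]), c[0], c[2].entity_class, c[2].surface_form)
    )
    chosen: list[tuple[int, int, DictionaryEntry]] = []
    for cand in candidates:
        if all(cand[1] <= s or cand[0] >= e for s, e, _ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return [
        EntityMatch(
            doc_id=doc_id,
            sentence_id=sentence.sentence_id,
            start=start,
            end=end,
            surface_form=entry.surface_form,
            canonical_id=entry.canonical_id,
            entity_class=entry.entity_class,
        )
        for start, end, entry in chosen
    ]
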