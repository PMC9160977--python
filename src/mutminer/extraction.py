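"""Mutation mention extraction: regex block, natural-language block, plugin seam.

Each sentence is processed by the regex block first.  Only when the regex
block finds nothing is the sentence handed to the natural-language block (or
to a registered plugin tagger) — structured mentions are easier to normalize
downstream, so they gate the noisier natural-language route.

The regex pattern set covers the structured surface forms that occur in the
variant-curation literature: one-letter substitutions (G109E, Q115P, with
"→"/"->" connectors accepted), three-letter hyphenated and concatenated
forms (Arg-107-Cys, Gly109Glu), full-name hyphen forms, nucleotide
substitutions (c.123A>G), nonsense changes (Q361*, W58amber), and simple
del/ins tokens attached to positions.  A token like G359A whose letters are
valid both as amino acids and as nucleotides is emitted once, as a protein
substitution: the pipeline targets protein-coding variants and downstream
sequence validation arbitrates truth.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from .corpus_io import Document, Sentence
from .normalize import NAME_TO_ONE, ONE_TO_THREE

__all__ = [
    "Components",
    "MutationMention",
    "MutationPattern",
    "PatternSet",
    "Lexicon",
    "default_pattern_set",
    "default_lexicon",
    "extract_regex",
    "extract_natural_language",
    "extract_all",
]

SOURCE_REGEX = "regex"
SOURCE_NATURAL_LANGUAGE = "natural_language"
SOURCE_PLUGIN = "plugin"

MENTION_KINDS = frozenset(
    {
        "protein_substitution",
        "dna_substitution",
        "nonsense",
        "deletion",
        "insertion",
        "indel",
        "natural_language_substitution",
        "other",
    }
)

#: Kinds whose mentions must carry a parsed (ref, position, alt) triple.
COMPONENT_KINDS = frozenset(
    {"protein_substitution", "dna_substitution", "nonsense", "natural_language_substitution"}
)


@dataclass(frozen=True)
class Components:
    """Parsed (reference, position, alternate) triple, tokens as matched."""

    ref: str
    position: int
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class MutationMention:
    """One raw mention located in a sentence (offsets sentence-relative)."""

    doc_id: str
    sentence_id: int
    start: int
    end: int
    raw_text: str
    source_block: str
    mention_kind: str
    components: Components | None = None
    pattern_id: str | None = None

    def __post_init__(self) -> None:
        if self.mention_kind not in MENTION_KINDS:
            raise ValueError(f"unknown mention_kind {self.mention_kind!r}")
        if self.mention_kind in COMPONENT_KINDS and self.components is None:
            raise ValueError(f"{self.mention_kind} mentions require parsed components")


@dataclass(frozen=True)
class MutationPattern:
    pattern_id: str
    mention_kind: str
    regex: re.Pattern


def _aa3_alternation() -> str:
    return "|".join(sorted(set(ONE_TO_THREE.values())))


def _escape_multiword(term: str) -> str:
    # re.escape turns " " into "\ "; allow any whitespace run between words
    return r"\s+".join(re.escape(part) for part in term.split())


def _name_alternation() -> str:
    names = sorted(NAME_TO_ONE, key=lambda n: (-len(n), n))
    return "|".join(_escape_multiword(n) for n in names)


class PatternSet:
    """Ordered, validated collection of compiled mention patterns."""

    def __init__(self, patterns: Sequence[MutationPattern]):
        ids = [p.pattern_id for p in patterns]
        if len(ids) != len(set(ids)):
            raise ValueError("pattern_ids must be unique")
        for p in patterns:
            if p.mention_kind not in MENTION_KINDS:
                raise ValueError(
                    f"pattern {p.pattern_id}: unknown mention_kind {p.mention_kind!r}"
                )
            if p.mention_kind in COMPONENT_KINDS:
                missing = {"ref", "pos", "alt"} - set(p.regex.groupindex)
                if missing:
                    raise ValueError(
                        f"pattern {p.pattern_id}: capture map missing groups {sorted(missing)}"
                    )
        self._patterns = tuple(patterns)

    def __iter__(self) -> Iterator[MutationPattern]:
        return iter(self._patterns)

    def __len__(self) -> int:
        return len(self._patterns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternSet":
        """Load patterns from a TSV resource (pattern_id, mention_kind, regex).

        ``{AA3}`` and ``{AANAME}`` placeholders in the regex column expand to
        the three-letter-code and full-name alternations of the shipped
        amino-acid table.
        """
        aa3, aaname = _aa3_alternation(), _name_alternation()
        patterns = []
        with open(path, encoding="utf-8", newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                raw = row["regex"].replace("{AA3}", aa3).replace("{AANAME}", aaname)
                patterns.append(
                    MutationPattern(
                        pattern_id=row["pattern_id"].strip(),
                        mention_kind=row["mention_kind"].strip(),
                        regex=re.compile(raw),
                    )
                )
        return cls(patterns)


@lru_cache(maxsize=1)
def default_pattern_set() -> PatternSet:
    with resources.as_file(
        resources.files("mutminer").joinpath("resources/patterns.tsv")
    ) as path:
        return PatternSet.from_tsv(path)


class Lexicon:
    """Bag-of-words lexicon feeding the natural-language block.

    Holds amino-acid names, substitution verbs/nouns, position nouns and
    nonsense keywords; template grammars for natural-language substitutions
    are composed from these alternations at load time.
    """

    def __init__(
        self,
        amino_acid_names: dict[str, str],
        substitution_verbs: Sequence[str],
        substitution_nouns: Sequence[str],
        position_nouns: Sequence[str],
        nonsense_keywords: Sequence[str] = (),
    ):
        self.amino_acid_names = dict(amino_acid_names)
        self.substitution_verbs = tuple(substitution_verbs)
        self.substitution_nouns = tuple(substitution_nouns)
        self.position_nouns = tuple(position_nouns)
        self.nonsense_keywords = tuple(nonsense_keywords)
        self._templates: tuple[tuple[str, str, re.Pattern], ...] | None = None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        buckets: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        with open(path, encoding="utf-8", newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                term = " ".join(row["term"].lower().split())
                category = row["category"].strip()
                if category == "amino_acid":
                    names[term] = (row.get("maps_to") or "").strip()
                else:
                    buckets.setdefault(category, []).append(term)
        return cls(
            amino_acid_names=names,
            substitution_verbs=buckets.get("substitution_verb", ()),
            substitution_nouns=buckets.get("substitution_noun", ()),
            position_nouns=buckets.get("position_noun", ()),
            nonsense_keywords=buckets.get("nonsense_keyword", ()),
        )

    @staticmethod
    def _alternation(terms: Iterable[str]) -> str:
        ordered = sorted(terms, key=lambda t: (-len(t), t))
        return "|".join(_escape_multiword(t) for t in ordered)

    @property
    def templates(self) -> tuple[tuple[str, str, re.Pattern], ...]:
        """Compiled (template_id, mention_kind, pattern) grammars.

        Covered orders: "<ref> to <alt> substitution at codon N",
        "<ref> was substituted by/with <alt> at residue N" (subject is the
        reference), "<alt> was substituted for <ref> at residue N" (subject
        is the replacement), "substitution of <ref> by <alt> at position N",
        plus a flag-only grammar for residue-level deletions/insertions.
        """
        if self._templates is None:
            name = f"(?:{self._alternation(self.amino_acid_names)})"
            verb = f"(?:{self._alternation(self.substitution_verbs)})"
            noun = f"(?:{self._alternation(self.substitution_nouns)})"
            posn = f"(?:{self._alternation(self.position_nouns)})"
            aux = r"(?:\s+(?:was|were|is|are|had\s+been|has\s+been|have\s+been))?"
            at = rf"\s+at\s+{posn}\s+(?P<pos>[1-9][0-9]*)"
            raw = [
                (
                    "nl_ref_to_alt",
                    "natural_language_substitution",
                    rf"(?P<ref>{name})\s+(?:to|into)\s+(?P<alt>{name})\s+{noun}{at}",
                ),
                (
                    "nl_passive_by",
                    "natural_language_substitution",
                    rf"(?P<ref>{name}){aux}\s+{verb}\s+(?:by|with|to|into)\s+(?P<alt>{name}){at}",
                ),
                (
                    "nl_passive_for",
                    "natural_language_substitution",
                    rf"(?P<alt>{name}){aux}\s+{verb}\s+for\s+(?P<ref>{name}){at}",
                ),
                (
                    "nl_noun_of",
                    "natural_language_substitution",
                    rf"{noun}\s+of\s+(?P<ref>{name})\s+(?:to|by|with|into|for)\s+(?P<alt>{name}){at}",
                ),
                (
                    "nl_indel_flag",
                    "",  # kind taken from the matched keyword
                    r"(?P<kind>deletion|insertion)s?\s+of\b[^.;]*?\bresidues?\b",
                ),
            ]
            self._templates = tuple(
                (tid, kind, re.compile(rx, re.IGNORECASE)) for tid, kind, rx in raw
            )
        return self._templates


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    with resources.as_file(
        resources.files("mutminer").joinpath("resources/lexicon.tsv")
    ) as path:
        return Lexicon.from_tsv(path)


def _resolve_overlaps(candidates):
    """Keep non-overlapping matches: longest first, then leftmost, then
    pattern order.  Returns survivors sorted by start offset."""
    ranked = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list = []
    for cand in ranked:
        if all(cand[1] <= s or cand[0] >= e for s, e, *_ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return chosen


def extract_regex(
    sentence: Sentence,
    patterns: PatternSet | None = None,
    doc_id: str = "",
) -> list[MutationMention]:
    """Run the regex block over one sentence.

    Overlapping matches are resolved longest-match-first (ties: leftmost,
    then pattern order), so e.g. the three-letter pattern wins over any
    partial interpretation of the same span.
    """
    patterns = patterns if patterns is not None else default_pattern_set()
    candidates = []
    for index, pattern in enumerate(patterns):
        for m in pattern.regex.finditer(sentence.text):
            candidates.append((m.start(), m.end(), index, pattern, m))
    mentions = []
    for start, end, _index, pattern, m in _resolve_overlaps(candidates):
        components = None
        if pattern.mention_kind in COMPONENT_KINDS:
            components = Components(
                ref=m.group("ref"), position=int(m.group("pos")), alt=m.group("alt")
            )
        mentions.append(
            MutationMention(
                doc_id=doc_id,
                sentence_id=sentence.sentence_id,
                start=start,
                end=end,
                raw_text=sentence.text[start:end],
                source_block=SOURCE_REGEX,
                mention_kind=pattern.mention_kind,
                components=components,
                pattern_id=pattern.pattern_id,
            )
        )
    return mentions


def extract_natural_language(
    sentence: Sentence,
    lexicon: Lexicon | None = None,
    doc_id: str = "",
) -> list[MutationMention]:
    """Run the rule-based natural-language block over one sentence.

    Substitution templates yield ``natural_language_substitution`` mentions
    with full-name components; residue-level deletion/insertion phrases are
    flagged without components (they are discarded downstream, but the flag
    keeps the accounting honest).
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    candidates = []
    for index, (tid, kind, pattern) in enumerate(lexicon.templates):
        for m in pattern.finditer(sentence.text):
            candidates.append((m.start(), m.end(), index, (tid, kind), m))
    mentions = []
    for start, end, _index, (tid, kind), m in _resolve_overlaps(candidates):
        if kind == "natural_language_substitution":
            components = Components(
                ref=m.group("ref"), position=int(m.group("pos")), alt=m.group("alt")
            )
        else:
            kind = m.group("kind").lower()
            components = None
        mentions.append(
            MutationMention(
                doc_id=doc_id,
                sentence_id=sentence.sentence_id,
                start=start,
                end=end,
                raw_text=sentence.text[start:end],
                source_block=SOURCE_NATURAL_LANGUAGE,
                mention_kind=kind,
                components=components,
                pattern_id=tid,
            )
        )
    return mentions


NerPlugin = Callable[[Sentence], Sequence[MutationMention]]


def extract_all(
    document: Document,
    patterns: PatternSet | None = None,
    lexicon: Lexicon | None = None,
    plugin: NerPlugin | None = None,
    enable_natural_language: bool = True,
) -> list[MutationMention]:
    """Extract mentions from a whole document with per-sentence gating.

    Each sentence goes to the regex block; if and only if that returns no
    mention, the sentence goes to the registered plugin tagger or, absent a
    plugin, to the rule-based natural-language block.  Plugin output is
    re-stamped with ``source_block="plugin"`` and document/sentence ids.
    """
    mentions: list[MutationMention] = []
    for sentence in document.sentences:
        found = extract_regex(sentence, patterns, doc_id=document.doc_id)
        if not found:
            if plugin is not None:
                for m in plugin(sentence):
                    m.doc_id = document.doc_id
                    m.sentence_id = sentence.sentence_id
                    m.source_block = SOURCE_PLUGIN
                    found.append(m)
            elif enable_natural_language:
                found = extract_natural_language(
                    sentence, lexicon, doc_id=document.doc_id
                )
        mentions.extend(found)
    mentions.sort(key=lambda m: (m.sentence_id, m.start))
    return mentions
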