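"""Canonical normalization of mutation mentions.

Mentions arriving from the extraction blocks carry heterogeneous residue
tokens: one-letter codes (``V600E``), three-letter codes (``Arg-107-Cys``),
full amino-acid names ("glycine to arginine substitution at codon 20"),
nonsense-codon keywords (amber/ochre/opal), and non-substitution events
(indels, nucleotide-level changes).  Every mention is mapped either to the
canonical one-letter substitution form ``<REF><POS><ALT>`` or to an explicit
discard code with a human-readable reason — nothing is dropped silently.

The module also produces the per-source-block discard accounting used in
run summaries, so a pipeline run can report what fraction of raw mentions
survived normalization.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover - import only for annotations
    from .extraction import MutationMention

__all__ = [
    "CANONICAL_RE",
    "ONE_LETTER",
    "NORMALIZED",
    "DISCARDED_INCOMPLETE",
    "DISCARDED_UNSUPPORTED",
    "NAME_TO_ONE",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "NormalizedMutation",
    "BlockCounts",
    "DiscardSummary",
    "residue_to_one",
    "parse_canonical",
    "normalize",
    "discard_accounting",
]

#: Grammar of a canonical substitution: REF/ALT are one-letter residues or "*".
CANONICAL_RE = re.compile(r"^([ACDEFGHIKLMNPQRSTVWY*])([1-9][0-9]*)([ACDEFGHIKLMNPQRSTVWY*])$")

ONE_LETTER = frozenset("ACDEFGHIKLMNPQRSTVWY")

NORMALIZED = "normalized"
DISCARDED_INCOMPLETE = "discarded_incomplete"
DISCARDED_UNSUPPORTED = "discarded_unsupported"

#: Mention kinds that can be canonicalized to protein-level one-letter form.
SUBSTITUTION_KINDS = frozenset(
    {"protein_substitution", "nonsense", "natural_language_substitution"}
)

#: Keywords describing a premature stop; all map to "*".
STOP_KEYWORDS = frozenset({"amber", "ochre", "opal", "stop", "ter"})


def _load_amino_acid_table():
    text = (
        resources.files("mutminer")
        .joinpath("resources/amino_acids.tsv")
        .read_text(encoding="utf-8")
    )
    name_to_one: dict[str, str] = {}
    three_to_one: dict[str, str] = {}
    one_to_three: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        name = " ".join(row["name"].lower().split())
        three = row["three_letter"].strip()
        one = row["one_letter"].strip()
        name_to_one[name] = one
        three_to_one.setdefault(three.lower(), one)
        # canonical names come first in the resource; synonym rows do not win
        one_to_three.setdefault(one, three)
    return name_to_one, three_to_one, one_to_three


NAME_TO_ONE, THREE_TO_ONE, ONE_TO_THREE = _load_amino_acid_table()


def residue_to_one(token: str) -> str | None:
    """Map a residue token of any supported style to its one-letter code.

    Accepts uppercase one-letter codes (case-sensitive by design: lowercase
    shapes are overwhelmingly false positives), ``*``/``X`` for stop,
    three-letter codes and full names (case-insensitive), and nonsense-codon
    keywords.  Returns ``None`` for unrecognized tokens, including
    selenocysteine/pyrrolysine which lie outside the 20+stop universe.
    """
    token = token.strip()
    if not token:
        return None
    if token in ("*", "X"):
        return "*"
    if len(token) == 1:
        return token if token in ONE_LETTER else None
    low = " ".join(token.lower().split())
    if low in STOP_KEYWORDS:
        return "*"
    if low in THREE_TO_ONE:
        return THREE_TO_ONE[low]
    return NAME_TO_ONE.get(low)


def parse_canonical(canonical: str) -> tuple[str, int, str]:
    """Split a canonical string like ``G109E`` into (ref, position, alt)."""
    m = CANONICAL_RE.match(canonical)
    if m is None:
        raise ValueError(f"{canonical!r} is not a canonical substitution")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass
class NormalizedMutation:
    """Outcome of normalizing one mention: canonical form or a discard code."""

    status: str
    canonical: str | None = None
    position: int | None = None
    reason: str | None = None
    mention: "MutationMention | None" = None

    def __post_init__(self) -> None:
        if self.status == NORMALIZED:
            if self.canonical is None or CANONICAL_RE.match(self.canonical) is None:
                raise ValueError(
                    f"normalized record requires a canonical form, got {self.canonical!r}"
                )
        else:
            if self.canonical is not None:
                raise ValueError("discarded records must not carry a canonical form")
            if not self.reason:
                raise ValueError("discarded records require a discard reason")


def normalize(mention: "MutationMention") -> NormalizedMutation:
    """Canonicalize one mention, or discard it with an explicit reason.

    Protein substitutions, nonsense changes and complete natural-language
    substitutions are mapped through the standard name/three-letter →
    one-letter table.  Nucleotide-level mentions and indel events are carried
    as ``discarded_unsupported``; mentions with a missing or unrecognizable
    (ref, position, alt) triple as ``discarded_incomplete``.  Positions are
    kept exactly as authors wrote them (no initiator-methionine renumbering):
    downstream validation against every isoform absorbs numbering ambiguity.
    """
    kind = mention.mention_kind
    if kind == "dna_substitution":
        return NormalizedMutation(
            DISCARDED_UNSUPPORTED,
            reason="nucleotide-level mention; only protein-level substitutions are normalized",
            mention=mention,
        )
    if kind not in SUBSTITUTION_KINDS:
        return NormalizedMutation(
            DISCARDED_UNSUPPORTED,
            reason=f"{kind} mentions are not normalized",
            mention=mention,
        )
    comp = mention.components
    if comp is None:
        return NormalizedMutation(
            DISCARDED_INCOMPLETE,
            reason="mention lacks a (ref, position, alt) triple",
            mention=mention,
        )
    if comp.position < 1:
        return NormalizedMutation(
            DISCARDED_INCOMPLETE,
            reason=f"non-positive position {comp.position}",
            mention=mention,
        )
    ref = residue_to_one(comp.ref)
    if ref is None:
        return NormalizedMutation(
            DISCARDED_INCOMPLETE,
            reason=f"unrecognized reference residue token {comp.ref!r}",
            mention=mention,
        )
    alt = residue_to_one(comp.alt)
    if alt is None:
        return NormalizedMutation(
            DISCARDED_INCOMPLETE,
            reason=f"unrecognized alternate residue token {comp.alt!r}",
            mention=mention,
        )
    return NormalizedMutation(
        NORMALIZED,
        canonical=f"{ref}{comp.position}{alt}",
        position=comp.position,
        mention=mention,
    )


@dataclass(frozen=True)
class BlockCounts:
    """Normalization outcome tallies for one source block."""

    total: int
    normalized: int
    discarded: int
    #: 100 x discarded-in-this-block / all mentions (None when no mentions).
    discard_percent_of_all: float | None


@dataclass(frozen=True)
class DiscardSummary:
    total_mentions: int
    total_normalized: int
    total_discarded: int
    overall_discard_percent: float | None
    per_block: Mapping[str, BlockCounts]


def discard_accounting(
    mentions: Sequence["MutationMention"],
    normalized: Sequence[NormalizedMutation],
) -> DiscardSummary:
    """Tally normalization outcomes per source block.

    ``normalized[i]`` must be the record for ``mentions[i]``.  Block
    percentages are expressed relative to the total mention count (all
    blocks), so a run summary can state e.g. what share of *all* mentions
    were natural-language mentions that had to be dropped.
    """
    if len(mentions) != len(normalized):
        raise ValueError(
            f"one normalized record per mention required "
            f"(got {len(mentions)} mentions, {len(normalized)} records)"
        )
    total = len(mentions)
    tallies: dict[str, list[int]] = {}
    for mention, record in zip(mentions, normalized):
        bucket = tallies.setdefault(mention.source_block, [0, 0])
        if record.status == NORMALIZED:
            bucket[0] += 1
        else:
            bucket[1] += 1
    per_block = {
        block: BlockCounts(
            total=ok + bad,
            normalized=ok,
            discarded=bad,
            discard_percent_of_all=(100.0 * bad / total) if total else None,
        )
        for block, (ok, bad) in sorted(tallies.items())
    }
    total_ok = sum(c.normalized for c in per_block.values())
    total_bad = sum(c.discarded for c in per_block.values())
    return DiscardSummary(
        total_mentions=total,
        total_normalized=total_ok,
        total_discarded=total_bad,
        overall_discard_percent=(100.0 * total_bad / total) if total else None,
        per_block=per_block,
    )
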