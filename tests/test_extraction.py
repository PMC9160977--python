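"""Regex block, natural-language block, gating and span invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from mutminer import Document, extract_all, extract_natural_language, extract_regex
from mutminer.extraction import (
    Components,
    MutationMention,
    PatternSet,
    MutationPattern,
    SOURCE_NATURAL_LANGUAGE,
    SOURCE_PLUGIN,
    SOURCE_REGEX,
)

from conftest import make_sentence


# --------------------------------------------------------------------------
# regex block
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,kind,triple",
    [
        ("We found mutations (e.g. Q115P) from publications.",
         "protein_substitution", ("Q", 115, "P")),
        ("the relative location eg. Arg-107-Cys.", "protein_substitution",
         ("Arg", 107, "Cys")),
        ("the same mutation G359A was studied", "protein_substitution",
         ("G", 359, "A")),
        ("a Gly109Glu substitution", "protein_substitution", ("Gly", 109, "Glu")),
        ("the Glycine-20-Arginine change", "protein_substitution",
         ("Glycine", 20, "Arginine")),
        ("carrying G12→V in one isoform", "protein_substitution", ("G", 12, "V")),
        ("carrying G12->V in one isoform", "protein_substitution", ("G", 12, "V")),
        ("the c.123A>G transition", "dna_substitution", ("A", 123, "G")),
        ("the 123A>G transition", "dna_substitution", ("A", 123, "G")),
        ("a premature Q361* codon", "nonsense", ("Q", 361, "*")),
        ("the W58amber allele", "nonsense", ("W", 58, "amber")),
    ],
)
def test_regex_block_structured_forms(text, kind, triple):
    mentions = extract_regex(make_sentence(text))
    assert len(mentions) == 1
    m = mentions[0]
    assert m.mention_kind == kind
    assert m.source_block == SOURCE_REGEX
    assert (m.components.ref, m.components.position, m.components.alt) == triple


@pytest.mark.parametrize(
    "text",
    [
        "The worms were grown at 20 degrees.",
        "the g109e lowercase shape is ignored",
        "strain CB502 and allele e1234",
        "GGN in the template",
    ],
)
def test_regex_block_ignores_non_mutation_text(text):
    assert extract_regex(make_sentence(text)) == []


def test_regex_block_del_ins_tokens_have_no_components():
    mentions = extract_regex(make_sentence("alleles with 508del and ins12 events"))
    assert [(m.mention_kind, m.components) for m in mentions] == [
        ("deletion", None), ("insertion", None)
    ]


def test_regex_block_overlaps_resolved_longest_first():
    # "Arg-107-Cys" must come out whole, not as fragments
    mentions = extract_regex(make_sentence("site Arg-107-Cys here"))
    assert [m.raw_text for m in mentions] == ["Arg-107-Cys"]
    spans = [(m.start, m.end) for m in mentions]
    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))


def test_pattern_set_rejects_duplicate_ids_and_missing_captures():
    import re

    p = MutationPattern("x", "protein_substitution", re.compile("foo"))
    with pytest.raises(ValueError, match="capture map"):
        PatternSet([p])
    q = MutationPattern("y", "deletion", re.compile("bar"))
    with pytest.raises(ValueError, match="unique"):
        PatternSet([q, q])


# --------------------------------------------------------------------------
# natural-language block
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,triple",
    [
        ("glycine to arginine substitution at codon 20", ("glycine", 20, "arginine")),
        ("glutamic acid was substituted by valine at residue 6",
         ("glutamic acid", 6, "valine")),
        # subject of "substituted for" is the replacement, not the reference
        ("arginine was substituted for glycine at codon 20", ("glycine", 20, "arginine")),
        ("replacement of proline by serine at position 12", ("proline", 12, "serine")),
    ],
)
def test_natural_language_substitution_templates(text, triple):
    mentions = extract_natural_language(make_sentence(text))
    assert len(mentions) == 1
    m = mentions[0]
    assert m.mention_kind == "natural_language_substitution"
    assert m.source_block == SOURCE_NATURAL_LANGUAGE
    got = (m.components.ref.lower(), m.components.position, m.components.alt.lower())
    assert got == triple


def test_natural_language_indel_phrase_is_flagged_without_components():
    text = "deletion of 10 and 8 residues from the N- and C-terminals"
    mentions = extract_natural_language(make_sentence(text))
    assert len(mentions) == 1
    assert mentions[0].mention_kind == "deletion"
    assert mentions[0].components is None


def test_natural_language_block_empty_on_plain_text():
    assert extract_natural_language(make_sentence("The worms were fed OP50.")) == []


# --------------------------------------------------------------------------
# gating and plugin seam
# --------------------------------------------------------------------------

def test_gating_regex_hit_suppresses_natural_language():
    text = "Here Q115P and a glycine to arginine substitution at codon 20 occur."
    document = Document.from_text("p", text)
    mentions = extract_all(document)
    assert [m.source_block for m in mentions] == [SOURCE_REGEX]
    assert mentions[0].raw_text == "Q115P"


def test_gating_is_per_sentence():
    text = ("Here Q115P occurs. Separately, a glycine to arginine substitution "
            "at codon 20 was reported.")
    document = Document.from_text("p", text)
    blocks = {m.sentence_id: m.source_block for m in extract_all(document)}
    assert blocks == {0: SOURCE_REGEX, 1: SOURCE_NATURAL_LANGUAGE}


def test_empty_document_yields_no_mentions():
    assert extract_all(Document.from_text("p", "")) == []


def test_plugin_replaces_natural_language_block():
    def tagger(sentence):
        return [
            MutationMention(
                doc_id="", sentence_id=0, start=0, end=4,
                raw_text=sentence.text[0:4], source_block="plugin",
                mention_kind="other",
            )
        ]

    document = Document.from_text("p", "Some untaggable phrasing. Also Q115P here.")
    mentions = extract_all(document, plugin=tagger)
    assert [(m.sentence_id, m.source_block) for m in mentions] == [
        (0, SOURCE_PLUGIN), (1, SOURCE_REGEX)
    ]
    assert mentions[0].doc_id == "p"


# --------------------------------------------------------------------------
# properties
# --------------------------------------------------------------------------

TOKENS = [
    "Q115P", "Arg-107-Cys", "G359A", "T47D", "c.123A>G", "508del", "Gly109Glu",
    "the", "worms", "were", "grown", "at", "20", "degrees", "mec-5", "e1234",
    "glycine", "to", "arginine", "substitution", "codon", "Q361*",
]


@given(st.lists(st.sampled_from(TOKENS), min_size=1, max_size=12))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_span_fidelity_and_disjointness(tokens):
    """Every emitted mention's raw_text is the literal sentence slice at its
    offsets, and regex mentions never overlap within a sentence."""
    sentence = make_sentence(" ".join(tokens))
    mentions = extract_regex(sentence)
    for m in mentions:
        assert sentence.text[m.start : m.end] == m.raw_text
    spans = sorted((m.start, m.end) for m in mentions)
    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))


@pytest.mark.parametrize(
    "surface", ["G109E", "Gly-109-Glu", "Gly109Glu"],
)
def test_coverage_floor_on_planted_surface_forms(surface):
    """All structured surface styles the fixture generator plants are
    recovered by the regex block."""
    mentions = extract_regex(make_sentence(f"The mutant carried the {surface} change."))
    assert len(mentions) == 1
    assert mentions[0].raw_text == surface
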