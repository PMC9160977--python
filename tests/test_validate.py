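"""Reference checks, degenerate-codon validation, and document-level pairing."""

import random

import pytest

from mutminer import (
    Document,
    Proteome,
    check_reference,
    check_reference_codon,
    degenerate_codons,
    extract_all,
    load_dictionaries,
    match_entities,
    normalize,
    pair_and_validate,
)
from mutminer.validate import Isoform, ProteomeError

from oracles import CODON_TO_AA, translate


PROTEIN = "M" + "A" * 107 + "G" + "A" * 40  # Gly at position 109


@pytest.mark.parametrize(
    "position,ref,expected",
    [(109, "G", True), (109, "A", False), (1, "M", True), (1000, "G", False), (0, "M", False)],
)
def test_check_reference(position, ref, expected):
    assert check_reference(PROTEIN, position, ref) is expected


def test_check_reference_out_of_range_on_short_protein():
    assert check_reference("M" + "A" * 49, 109, "G") is False


@pytest.mark.parametrize(
    "codon,ref,expected",
    [("GGA", "G", True), ("GGT", "G", True), ("GCA", "G", False), ("TGA", "*", True)],
)
def test_check_reference_codon(codon, ref, expected):
    cds = "ATG" * 108 + codon + "ATG" * 5
    assert check_reference_codon(cds, 109, ref) is expected


def test_check_reference_codon_past_end_is_false():
    assert check_reference_codon("ATGGGA", 3, "G") is False


def test_degenerate_sets_match_hand_written_code_table():
    for residue in set(CODON_TO_AA.values()):
        expected = {c for c, aa in CODON_TO_AA.items() if aa == residue}
        assert degenerate_codons(residue) == expected


def test_codon_check_agrees_with_translate_then_compare():
    """Protein-level and codon-level reference checks are equivalent routes,
    verified against the independent brute-force translator."""
    rng = random.Random(42)
    codons = sorted(CODON_TO_AA)
    residues = sorted(set(CODON_TO_AA.values()))
    for _ in range(300):
        n = rng.randint(1, 40)
        cds = "".join(rng.choice(codons) for _ in range(n))
        protein = translate(cds)
        for _ in range(10):
            position = rng.randint(1, n + 2)
            ref = rng.choice(residues)
            expected = position <= len(protein) and protein[position - 1] == ref
            assert check_reference_codon(cds, position, ref) == expected


# --------------------------------------------------------------------------
# proteome IO
# --------------------------------------------------------------------------

def test_proteome_fasta_round_trip(tmp_path):
    (tmp_path / "p.fasta").write_text(">gA|a\nMGV\n>gA|b\nMG\n>gB|a\nMVVG\n")
    (tmp_path / "c.fasta").write_text(">gA|a\nATGGGAGTTTAA\n>gB|a\nATGGTAGTGGGT\n")
    proteome = Proteome.from_fasta(tmp_path / "p.fasta", tmp_path / "c.fasta")
    assert sorted(proteome.genes) == ["gA", "gB"]
    isoforms = {i.isoform_id: i for i in proteome.genes["gA"]}
    assert isoforms["a"].cds == "ATGGGAGTTTAA"  # trailing stop tolerated
    assert isoforms["b"].cds is None


def test_proteome_rejects_inconsistent_cds(tmp_path):
    (tmp_path / "p.fasta").write_text(">gA|a\nMGV\n")
    (tmp_path / "c.fasta").write_text(">gA|a\nATGGCAGTT\n")  # translates MAV
    with pytest.raises(ProteomeError, match="translate"):
        Proteome.from_fasta(tmp_path / "p.fasta", tmp_path / "c.fasta")


def test_proteome_rejects_bad_header(tmp_path):
    (tmp_path / "p.fasta").write_text(">justonename\nMGV\n")
    with pytest.raises(ProteomeError, match="gene_id"):
        Proteome.from_fasta(tmp_path / "p.fasta")


# --------------------------------------------------------------------------
# pairing and metadata
# --------------------------------------------------------------------------

def run_pairing(text, proteome, gene_rows, doc_id="doc1"):
    document = Document.from_text(doc_id, text)
    mentions = extract_all(document)
    records = [normalize(m) for m in mentions]
    entities = [
        e for s in document.sentences for e in match_entities(s, gene_rows, doc_id)
    ]
    return pair_and_validate(doc_id, records, entities, proteome)


@pytest.fixture
def two_gene_setup(tmp_path):
    # gA: Gly at 109, 218 and 359; gB: Gly at 359 only
    protein_a = "M" + "A" * 107 + "G" + "A" * 108 + "G" + "A" * 140 + "G" + "A" * 10
    protein_b = "M" + "A" * 357 + "G" + "A" * 20
    (tmp_path / "p.fasta").write_text(f">gA|a\n{protein_a}\n>gB|a\n{protein_b}\n")
    proteome = Proteome.from_fasta(tmp_path / "p.fasta")
    dict_path = tmp_path / "dict.tsv"
    dict_path.write_text(
        "surface_form\tcanonical_id\tentity_class\n"
        "mec-5\tgA\tgene\nunc-54\tgB\tgene\nEMS\tGM:EMS\tgeneration_method\n"
    )
    return proteome, load_dictionaries([dict_path])


def test_single_verified_match(two_gene_setup):
    proteome, dictionary = two_gene_setup
    matches = run_pairing("In mec-5 we observed G109E after EMS treatment.",
                          proteome, dictionary)
    assert len(matches) == 1
    m = matches[0]
    assert (m.gene_symbol, m.canonical, m.valid_isoforms) == ("mec-5", "G109E", ["a"])
    assert m.mention_count == 1 and m.candidate_gene_count == 1
    assert any(e.entity_class == "generation_method" for e in m.supporting_entities)


def test_wrong_reference_is_rejected(two_gene_setup):
    proteome, dictionary = two_gene_setup
    assert run_pairing("In mec-5 we observed A109E.", proteome, dictionary) == []


def test_mutation_validating_in_two_genes_flags_ambiguity(two_gene_setup):
    proteome, dictionary = two_gene_setup
    matches = run_pairing(
        "Both mec-5 and unc-54 were sequenced. The mutation G359A was found.",
        proteome, dictionary,
    )
    assert [(m.gene_id, m.canonical) for m in matches] == [("gA", "G359A"), ("gB", "G359A")]
    assert all(m.candidate_gene_count == 2 for m in matches)


def test_similar_mutations_same_position_different_alt(two_gene_setup):
    proteome, dictionary = two_gene_setup
    matches = run_pairing(
        "In mec-5 both G218D and G218L were recovered.", proteome, dictionary
    )
    by_canonical = {m.canonical: m for m in matches}
    assert by_canonical["G218D"].similar_mutations == ["G218L"]
    assert by_canonical["G218L"].similar_mutations == ["G218D"]


def test_mention_count_counts_repeated_mentions(two_gene_setup):
    proteome, dictionary = two_gene_setup
    matches = run_pairing(
        "The G109E change in mec-5 was striking. Indeed G109E recurred.",
        proteome, dictionary,
    )
    assert len(matches) == 1
    assert matches[0].mention_count == 2
    assert matches[0].sentence_ids == [0, 1]


def test_gene_without_proteome_record_is_skipped(two_gene_setup, tmp_path, caplog):
    proteome, _ = two_gene_setup
    dict_path = tmp_path / "extra.tsv"
    dict_path.write_text(
        "surface_form\tcanonical_id\tentity_class\nzzz-9\tgZ\tgene\n"
    )
    dictionary = load_dictionaries([dict_path])
    import logging

    with caplog.at_level(logging.INFO, logger="mutminer.validate"):
        matches = run_pairing("In zzz-9 we observed G109E.", proteome, dictionary)
    assert matches == []
    assert any("no proteome record" in r.message for r in caplog.records)


def test_adding_isoforms_never_invalidates(two_gene_setup):
    """Monotonicity: a valid match stays valid when the gene gains isoforms."""
    proteome, dictionary = two_gene_setup
    text = "In mec-5 we observed G109E."
    before = run_pairing(text, proteome, dictionary)
    proteome.genes["gA"].append(Isoform("c", "MVV"))
    after = run_pairing(text, proteome, dictionary)
    assert {(m.gene_id, m.canonical) for m in before} <= {
        (m.gene_id, m.canonical) for m in after
    }


def test_fixture_planted_pairs_all_validate_and_decoys_fail(small_corpus):
    from mutminer import run_pipeline

    result = run_pipeline(
        small_corpus.document_paths,
        protein_fasta=small_corpus.protein_fasta,
        dict_paths=small_corpus.dictionary_paths,
        cds_fasta=small_corpus.cds_fasta,
        gold_path=small_corpus.gold_path,
    )
    assert result.report.fn == 0
    validated = {(m.doc_id, m.canonical) for m in result.matches}
    assert all(d not in validated for d in small_corpus.decoys)
    # CDS corroboration agrees with the authoritative protein check
    for m in result.matches:
        assert set(m.cds_corroborated_isoforms) <= set(m.valid_isoforms)
        assert m.cds_corroborated_isoforms
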