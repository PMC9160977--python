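"""Document loading, sentence segmentation, gold-annotation IO and synthetic fixtures.

Sentences are segmented with a deterministic rule-based splitter (terminal
punctuation plus an abbreviation stop-list), keeping exact character offsets
into the source text: every downstream mention and entity span is reported
relative to a sentence whose slice is verifiable against the document.

The fixture generator builds a miniature annotated corpus with known ground
truth: documents that plant structured mutation mentions whose reference
residues truly occur in the generated proteome (so sequence validation
succeeds by construction), decoy sentences carrying mutation-shaped strings
whose reference residue is deliberately wrong for every gene in the document
(so validation must reject them), entity dictionaries, a protein+CDS FASTA
pair, and a gold TSV listing exactly the planted gene-mutation pairs.
"""

from __future__ import annotations

import random
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .normalize import CANONICAL_RE, ONE_TO_THREE

__all__ = [
    "Sentence",
    "Document",
    "GoldAnnotation",
    "GoldFormatError",
    "FixtureSpec",
    "FixtureCorpus",
    "segment_sentences",
    "load_document",
    "read_gold",
    "write_gold",
    "generate_fixtures",
]

GOLD_HEADER = ("doc_id", "gene_symbol", "mutation")

# Terminal-period tokens that never end a sentence.
_ABBREVIATIONS = frozenset(
    {
        "fig", "figs", "eq", "eqs", "e.g", "i.e", "eg", "ie", "cf", "ca",
        "vs", "al", "etc", "approx", "sp", "spp", "st", "no", "dr", "ref",
        "refs",
    }
)

_TERMINATOR = re.compile(r"[.!?]+")
_FINAL_WORD = re.compile(r"[A-Za-z][A-Za-z.]*$")


@dataclass(frozen=True)
class Sentence:
    """One sentence with its 0-based, half-open span in the document text."""

    sentence_id: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sentence span must be non-empty")
        if len(self.text) != self.end - self.start:
            raise ValueError("sentence text length disagrees with its span")


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence]

    @classmethod
    def from_text(cls, doc_id: str, text: str) -> "Document":
        return cls(doc_id=doc_id, text=text, sentences=segment_sentences(text))


def _is_boundary(text: str, match: re.Match) -> bool:
    end = match.end()
    if end < len(text) and not text[end].isspace():
        return False  # mid-token punctuation, e.g. "20.5" or "e.g."
    k = end
    while k < len(text) and text[k].isspace():
        k += 1
    if k < len(text) and not (text[k].isupper() or text[k].isdigit() or text[k] in "\"'(["):
        return False  # lowercase continuation
    if "." in match.group():
        word = _FINAL_WORD.search(text, 0, match.start())
        if word and word.end() == match.start():
            if word.group().rstrip(".").lower() in _ABBREVIATIONS:
                return False
    return True


def segment_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with stable character offsets.

    Splits on runs of terminal punctuation followed by whitespace and an
    upper-case/digit/opening-quote continuation, unless the preceding token
    is a known abbreviation ("Fig.", "et al.", "e.g.", ...).  Deterministic
    by construction; whitespace between sentences is skipped, everything
    else is covered by exactly one sentence span.
    """
    sentences: list[Sentence] = []
    cursor = 0

    def emit(start: int, end: int) -> None:
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            sentences.append(
                Sentence(
                    sentence_id=len(sentences),
                    start=start,
                    end=end,
                    text=text[start:end],
                )
            )

    for match in _TERMINATOR.finditer(text):
        if match.start() < cursor:
            continue
        if _is_boundary(text, match):
            emit(cursor, match.end())
            cursor = match.end()
    emit(cursor, len(text))
    return sentences


def load_document(path: str | Path) -> Document:
    """Load a UTF-8 plain-text document; doc_id is the file stem."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return Document.from_text(doc_id=path.stem, text=text)


@dataclass(frozen=True)
class GoldAnnotation:
    """One manually curated gene-mutation match for a document."""

    doc_id: str
    gene_symbol: str
    normalized_mutation: str

    def __post_init__(self) -> None:
        if CANONICAL_RE.match(self.normalized_mutation) is None:
            raise ValueError(
                f"{self.normalized_mutation!r} does not parse as a canonical substitution"
            )


class GoldFormatError(ValueError):
    """Raised when a gold/prediction TSV row violates the expected format."""


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    """Read gene-mutation annotations from a TSV.

    The header must contain the columns ``doc_id``, ``gene_symbol`` and
    ``mutation`` (extra columns, e.g. from a curation report, are ignored).
    Rows whose mutation fails the canonical grammar are rejected with their
    row number.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise GoldFormatError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    try:
        idx = [header.index(col) for col in GOLD_HEADER]
    except ValueError as exc:
        raise GoldFormatError(
            f"{path}: header must contain columns {GOLD_HEADER}, got {header}"
        ) from exc
    annotations = []
    for row_number, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise GoldFormatError(f"{path}: row {row_number}: expected {len(header)} fields")
        doc_id, gene_symbol, mutation = (fields[i].strip() for i in idx)
        if CANONICAL_RE.match(mutation) is None:
            raise GoldFormatError(
                f"{path}: row {row_number}: {mutation!r} is not a canonical substitution"
            )
        annotations.append(GoldAnnotation(doc_id, gene_symbol, mutation))
    return annotations


def write_gold(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    rows = ["\t".join(GOLD_HEADER)]
    rows += [
        f"{a.doc_id}\t{a.gene_symbol}\t{a.normalized_mutation}" for a in annotations
    ]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Synthetic fixture generation
# --------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_STANDARD_TABLE.stop_codons)

_AA = "ACDEFGHIKLMNPQRSTVWY"

_FILLER_SENTENCES = (
    "The worms were grown at 20 degrees.",
    "Strains were maintained on NGM plates seeded with OP50.",
    "Behavioral assays were performed in triplicate.",
    "Animals were synchronized by hypochlorite treatment.",
    "Imaging was carried out on an inverted confocal microscope.",
    "Statistical comparisons used a two-tailed test.",
)

_PLANT_TEMPLATES = (
    "The {gene} mutant animals carried the {surface} substitution.",
    "Sequencing of {gene} revealed a {surface} change in the coding region.",
    "A {surface} lesion in {gene} was generated by EMS mutagenesis.",
)

_DECOY_TEMPLATES = (
    "Results were compared with the {surface} cell line data.",
    "The {surface} variant reported elsewhere was not observed here.",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a generated corpus: 20 documents of 3 planted
    structured mutations each, one decoy-bearing sentence per five, over a
    10-gene proteome of realistically sized proteins."""

    n_documents: int = 20
    n_genes: int = 10
    protein_length_range: tuple[int, int] = (120, 400)
    mutations_per_document: int = 3
    decoy_rate: float = 0.2
    random_seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_documents, self.n_genes, self.mutations_per_document) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must lie in [0, 1]")
        lo, hi = self.protein_length_range
        if not 2 <= lo <= hi:
            raise ValueError("protein_length_range must satisfy 2 <= lo <= hi")
        if self.mutations_per_document and self.n_genes == 0:
            raise ValueError("cannot plant mutations without genes")


@dataclass
class FixtureCorpus:
    """Paths and ground truth of one generated corpus."""

    spec: FixtureSpec
    root: Path
    document_paths: list[Path]
    dictionary_paths: list[Path]
    protein_fasta: Path
    cds_fasta: Path
    gold_path: Path
    planted: list[GoldAnnotation]
    #: (doc_id, canonical-form string) of every planted wrong-reference decoy
    decoys: list[tuple[str, str]]


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _write_fasta(records: Sequence[tuple[str, str]], path: Path) -> None:
    path.write_text(
        "".join(f">{header}\n{_wrap(seq)}\n" for header, seq in records),
        encoding="utf-8",
    )


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> FixtureCorpus:
    """Generate a synthetic corpus with known ground truth.

    Planted mentions cycle through one-letter, three-letter hyphenated and
    three-letter concatenated surface forms; the named gene's protein truly
    carries the stated reference residue at the stated position.  Decoy
    sentences carry mutation-shaped strings whose reference residue matches
    no isoform of any gene mentioned in the document.  Identical specs
    produce byte-identical outputs.
    """
    rng = random.Random(spec.random_seed)
    root = Path(out_dir)
    (root / "documents").mkdir(parents=True, exist_ok=True)
    (root / "dictionaries").mkdir(parents=True, exist_ok=True)

    # --- proteome -----------------------------------------------------
    symbols: list[str] = []
    seen = set()
    while len(symbols) < spec.n_genes:
        sym = "".join(rng.choices(string.ascii_lowercase, k=3)) + f"-{rng.randint(1, 99)}"
        if sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    gene_ids = [f"SGENE{i:05d}" for i in range(spec.n_genes)]
    lo, hi = spec.protein_length_range
    isoforms: dict[str, list[tuple[str, str, str]]] = {}  # gene_id -> (iso, protein, cds)
    for gene_id in gene_ids:
        length = rng.randint(lo, hi)
        protein = "M" + "".join(rng.choices(_AA, k=length - 1))
        gene_isoforms = [("a", protein)]
        if rng.random() < 0.4:
            gene_isoforms.append(("b", protein[: rng.randint(length // 2, length - 1)]))
        records = []
        for iso, seq in gene_isoforms:
            cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in seq)
            cds += rng.choice(_STOP_CODONS)
            records.append((iso, seq, cds))
        isoforms[gene_id] = records

    protein_fasta = root / "proteome.protein.fasta"
    cds_fasta = root / "proteome.cds.fasta"
    _write_fasta(
        [(f"{g}|{iso}", seq) for g in gene_ids for iso, seq, _ in isoforms[g]],
        protein_fasta,
    )
    _write_fasta(
        [(f"{g}|{iso}", cds) for g in gene_ids for iso, _, cds in isoforms[g]],
        cds_fasta,
    )

    genes_per_doc = min(3, spec.n_genes)
    if spec.mutations_per_document > genes_per_doc * (lo - 1):
        raise ValueError(
            f"mutations_per_document={spec.mutations_per_document} exceeds the "
            f"{genes_per_doc * (lo - 1)} positions achievable per document"
        )

    # --- documents ----------------------------------------------------
    def surface_for(ref: str, pos: int, alt: str, style: int) -> str:
        if style == 0:
            return f"{ref}{pos}{alt}"
        if style == 1:
            return f"{ONE_TO_THREE[ref]}-{pos}-{ONE_TO_THREE[alt]}"
        return f"{ONE_TO_THREE[ref]}{pos}{ONE_TO_THREE[alt]}"

    document_paths: list[Path] = []
    planted: list[GoldAnnotation] = []
    decoys: list[tuple[str, str]] = []
    alleles: list[str] = []
    strains: list[str] = []

    for d in range(spec.n_documents):
        doc_id = f"doc{d:03d}"
        doc_gene_idx = rng.sample(range(spec.n_genes), k=genes_per_doc) if spec.n_genes else []
        used_positions: set[tuple[str, int]] = set()
        sentences: list[str] = []

        for m in range(spec.mutations_per_document):
            gi = rng.choice(doc_gene_idx)
            gene_id, sym = gene_ids[gi], symbols[gi]
            protein = isoforms[gene_id][0][1]
            while True:
                pos = rng.randint(2, len(protein))
                if (gene_id, pos) not in used_positions:
                    used_positions.add((gene_id, pos))
                    break
            ref = protein[pos - 1]
            alt = rng.choice([a for a in _AA if a != ref])
            surface = surface_for(ref, pos, alt, style=m % 3)
            template = _PLANT_TEMPLATES[m % len(_PLANT_TEMPLATES)]
            sentences.append(template.format(gene=sym, surface=surface))
            planted.append(GoldAnnotation(doc_id, sym, f"{ref}{pos}{alt}"))

        allele, strain = f"e{1000 + d}", f"CB{500 + d}"
        alleles.append(allele)
        strains.append(strain)
        sentences.append(
            f"The allele {allele} was isolated from strain {strain} after mutagenesis."
        )
        n_filler = rng.randint(3, 5)
        sentences.extend(rng.choice(_FILLER_SENTENCES) for _ in range(n_filler))

        if spec.decoy_rate > 0 and doc_gene_idx:
            base = len(sentences)
            n_decoys = max(1, round(spec.decoy_rate / (1.0 - spec.decoy_rate + 1e-9) * base))
            doc_isoforms = [
                seq for gi in doc_gene_idx for _, seq, _ in isoforms[gene_ids[gi]]
            ]
            min_len = min(len(seq) for seq in doc_isoforms)
            for k in range(n_decoys):
                pos = rng.randint(2, min_len)
                forbidden = {seq[pos - 1] for seq in doc_isoforms if pos <= len(seq)}
                ref = rng.choice([a for a in _AA if a not in forbidden])
                alt = rng.choice([a for a in _AA if a != ref])
                surface = surface_for(ref, pos, alt, style=k % 2 * 2)
                sentences.append(rng.choice(_DECOY_TEMPLATES).format(surface=surface))
                decoys.append((doc_id, f"{ref}{pos}{alt}"))

        rng.shuffle(sentences)
        path = root / "documents" / f"{doc_id}.txt"
        path.write_text(" ".join(sentences) + "\n", encoding="utf-8")
        document_paths.append(path)

    # --- dictionaries and gold ---------------------------------------
    def write_dict(name: str, rows: Iterable[tuple[str, str, str]]) -> Path:
        path = root / "dictionaries" / name
        lines = ["surface_form\tcanonical_id\tentity_class"]
        lines += [f"{s}\t{c}\t{k}" for s, c, k in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    dictionary_paths = [
        write_dict("genes.tsv", [(s, g, "gene") for s, g in zip(symbols, gene_ids)]),
        write_dict(
            "strains_alleles.tsv",
            [(s, s, "strain") for s in strains] + [(a, a, "allele") for a in alleles],
        ),
        write_dict(
            "terms.tsv",
            [
                ("deletion", "VT:deletion", "variation_type"),
                ("insertion", "VT:insertion", "variation_type"),
                ("substitution", "VT:substitution", "variation_type"),
                ("point mutation", "VT:point_mutation", "variation_type"),
                ("EMS", "GM:EMS", "generation_method"),
                ("ENU", "GM:ENU", "generation_method"),
                ("CRISPR-Cas9", "GM:CRISPR-Cas9", "generation_method"),
                ("UV irradiation", "GM:UV", "generation_method"),
            ],
        ),
    ]
    gold_path = root / "gold.tsv"
    write_gold(planted, gold_path)

    return FixtureCorpus(
        spec=spec,
        root=root,
        document_paths=document_paths,
        dictionary_paths=dictionary_paths,
        protein_fasta=protein_fasta,
        cds_fasta=cds_fasta,
        gold_path=gold_path,
        planted=planted,
        decoys=decoys,
    )
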