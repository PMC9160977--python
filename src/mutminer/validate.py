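"""Gene-mutation pairing and proteome-backed reference validation.

The curation unit is the whole paper: every gene entity found anywhere in a
document is a candidate partner for every normalized mutation in that
document.  A pair survives only if at least one isoform of the gene carries
the claimed reference residue at the claimed (1-based) position — or, when a
CDS is available, a codon from the reference residue's degenerate set (e.g.
GGN for glycine).  Only verified pairs are materialized; the alternate
residue is never checked, because only the pre-edit state is verifiable
against the reference proteome.

Kept matches carry curator metadata: how often the mutation was mentioned,
how many genes in the document it validated against (the same G359A
validating in two genes is a red flag worth surfacing), and very similar
mutations (same gene, same position, different alternate, e.g. G218D next
to G218L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .entities import EntityMatch
from .normalize import NORMALIZED, NormalizedMutation, parse_canonical

__all__ = [
    "ProteomeError",
    "Isoform",
    "Proteome",
    "GeneMutationMatch",
    "degenerate_codons",
    "check_reference",
    "check_reference_codon",
    "pair_and_validate",
]

logger = logging.getLogger("mutminer.validate")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class ProteomeError(ValueError):
    """Raised for malformed proteome FASTA input."""


@lru_cache(maxsize=None)
def degenerate_codons(residue: str) -> frozenset[str]:
    """All DNA codons encoding ``residue`` under the standard genetic code;
    ``"*"`` yields the stop codons."""
    if residue == "*":
        return frozenset(_STANDARD_TABLE.stop_codons)
    return frozenset(
        codon for codon, aa in _STANDARD_TABLE.forward_table.items() if aa == residue
    )


def check_reference(protein: str, position: int, ref: str) -> bool:
    """True iff the protein carries ``ref`` at 1-based ``position``.

    Out-of-range positions are simply False — an author may count from a
    different isoform, which is why the caller tries every isoform.
    """
    if position < 1 or position > len(protein):
        return False
    return protein[position - 1] == ref


def check_reference_codon(cds: str, position: int, ref: str) -> bool:
    """True iff codon ``position`` of the CDS lies in ``ref``'s degenerate set.

    Codon ``position`` occupies nucleotides ``3*(position-1)+1 .. 3*position``
    (1-based).  RNA input is tolerated (U is read as T); out-of-range
    positions are False.
    """
    if position < 1:
        return False
    codon = cds[3 * (position - 1) : 3 * position].upper().replace("U", "T")
    if len(codon) != 3:
        return False
    return codon in degenerate_codons(ref)


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    protein: str
    cds: str | None = None


@dataclass
class Proteome:
    """gene_id -> isoform list, loaded from protein (and optional CDS) FASTA."""

    genes: dict[str, list[Isoform]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    @staticmethod
    def _read_fasta(path: str | Path) -> dict[tuple[str, str], str]:
        records: dict[tuple[str, str], str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            name = record.id
            if "|" not in name:
                raise ProteomeError(
                    f"{path}: header {name!r} is not of the form gene_id|isoform_id"
                )
            gene_id, isoform_id = name.split("|", 1)
            records[(gene_id, isoform_id)] = str(record.seq).upper()
        return records

    @classmethod
    def from_fasta(
        cls, protein_path: str | Path, cds_path: str | Path | None = None
    ) -> "Proteome":
        """Load a proteome; when a CDS FASTA is given, each CDS must be the
        protein's length in codons (with or without a trailing stop codon)
        and translate back to the protein under the standard genetic code."""
        proteins = cls._read_fasta(protein_path)
        cds_records = cls._read_fasta(cds_path) if cds_path is not None else {}
        genes: dict[str, list[Isoform]] = {}
        for (gene_id, isoform_id), protein in proteins.items():
            cds = cds_records.get((gene_id, isoform_id))
            if cds is not None:
                n = len(protein)
                if len(cds) not in (3 * n, 3 * n + 3):
                    raise ProteomeError(
                        f"{gene_id}|{isoform_id}: CDS length {len(cds)} does not "
                        f"fit a {n}-residue protein"
                    )
                translated = str(Seq(cds[: 3 * n]).translate())
                if translated != protein:
                    raise ProteomeError(
                        f"{gene_id}|{isoform_id}: CDS does not translate to the protein"
                    )
            genes.setdefault(gene_id, []).append(Isoform(isoform_id, protein, cds))
        return cls(genes=genes)


@dataclass
class GeneMutationMatch:
    """A validated gene-mutation pair with curator metadata."""

    doc_id: str
    gene_id: str
    gene_symbol: str
    canonical: str
    position: int
    mutation: NormalizedMutation
    valid_isoforms: list[str]
    cds_corroborated_isoforms: list[str]
    mention_count: int
    candidate_gene_count: int
    similar_mutations: list[str]
    sentence_ids: list[int]
    supporting_entities: list[EntityMatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.valid_isoforms:
            raise ValueError("only verified matches are materialized")
        if self.mention_count < 1 or self.candidate_gene_count < 1:
            raise ValueError("mention_count and candidate_gene_count must be >= 1")


def pair_and_validate(
    doc_id: str,
    normalized: Sequence[NormalizedMutation],
    entity_matches: Sequence[EntityMatch],
    proteome: Proteome,
) -> list[GeneMutationMatch]:
    """Cross every gene entity in the document with every normalized mutation
    and keep the pairs the proteome verifies.

    The protein-level residue check is authoritative; when a CDS is present
    its degenerate-codon check is recorded as corroboration.  Genes without a
    proteome record are skipped with a log line, not an error.  Results are
    ordered by (gene_id, position, canonical).
    """
    mutations = [n for n in normalized if n.status == NORMALIZED]
    by_canonical: dict[str, list[NormalizedMutation]] = {}
    for record in mutations:
        by_canonical.setdefault(record.canonical, []).append(record)

    genes: dict[str, str] = {}  # gene_id -> dictionary-cased symbol
    for match in entity_matches:
        if match.entity_class == "gene":
            genes.setdefault(match.canonical_id, match.surface_form)
    support = [m for m in entity_matches if m.entity_class != "gene"]

    kept: list[GeneMutationMatch] = []
    genes_per_canonical: dict[str, int] = {}
    for gene_id in sorted(genes):
        if gene_id not in proteome:
            logger.info(
                "%s: gene %s (%s) has no proteome record; pairs skipped",
                doc_id, gene_id, genes[gene_id],
            )
            continue
        for canonical in sorted(by_canonical):
            ref, position, _alt = parse_canonical(canonical)
            isoforms = proteome.genes[gene_id]
            valid = [
                iso.isoform_id
                for iso in isoforms
                if check_reference(iso.protein, position, ref)
            ]
            if not valid:
                continue
            corroborated = [
                iso.isoform_id
                for iso in isoforms
                if iso.cds is not None and check_reference_codon(iso.cds, position, ref)
            ]
            records = by_canonical[canonical]
            sentence_ids = sorted(
                {r.mention.sentence_id for r in records if r.mention is not None}
            )
            kept.append(
                GeneMutationMatch(
                    doc_id=doc_id,
                    gene_id=gene_id,
                    gene_symbol=genes[gene_id],
                    canonical=canonical,
                    position=position,
                    mutation=records[0],
                    valid_isoforms=valid,
                    cds_corroborated_isoforms=corroborated,
                    mention_count=len(records),
                    candidate_gene_count=1,  # finalized below
                    similar_mutations=[],
                    sentence_ids=sentence_ids,
                    supporting_entities=list(support),
                )
            )
            genes_per_canonical[canonical] = genes_per_canonical.get(canonical, 0) + 1

    by_gene_position: dict[tuple[str, int], list[str]] = {}
    for match in kept:
        by_gene_position.setdefault((match.gene_id, match.position), []).append(
            match.canonical
        )
    for match in kept:
        match.candidate_gene_count = genes_per_canonical[match.canonical]
        match.similar_mutations = sorted(
            c
            for c in by_gene_position[(match.gene_id, match.position)]
            if c != match.canonical
        )
    kept.sort(key=lambda m: (m.gene_id, m.position, m.canonical))
    return kept
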