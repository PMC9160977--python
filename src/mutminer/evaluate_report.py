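"""Curator-facing output and evaluation against gold gene-mutation matches.

The unit of evaluation is the (document, gene, canonical mutation) triple:
a prediction is a true positive iff an identical triple exists in the gold
annotations (gene symbols compared case-insensitively).  Metric identities
are computed exactly in integer arithmetic; percent strings are truncated
(not rounded) to two decimals, the convention used in curation reports —
e.g. TP=807, FP=170 prints as a precision of 82.59%.

``run_pipeline`` chains the whole method: document loading and sentence
segmentation, gated mention extraction, normalization with discard
accounting, dictionary entity matching, proteome validation, and report
assembly, with per-stage counts logged so a run summary reads like a
results paragraph.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus_io import Document, GoldAnnotation, load_document, read_gold
from .entities import EntityDictionary, load_dictionaries, match_entities
from .extraction import (
    Lexicon,
    MutationMention,
    PatternSet,
    default_lexicon,
    default_pattern_set,
    extract_all,
)
from .normalize import NORMALIZED, NormalizedMutation, discard_accounting, normalize
from .validate import GeneMutationMatch, Proteome, pair_and_validate

__all__ = [
    "EvalReport",
    "CurationRecord",
    "PipelineConfig",
    "PipelineResult",
    "evaluate",
    "to_curation_records",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger("mutminer.pipeline")


def _floor_percent(numerator: int, denominator: int) -> str | None:
    """Percentage of numerator/denominator truncated to 2 d.p. (None if 0/0)."""
    if denominator == 0:
        return None
    basis = (numerator * 10000) // denominator
    return f"{basis // 100}.{basis % 100:02d}%"


@dataclass(frozen=True)
class EvalReport:
    """TP/FP/FN counts with precision/recall/F1 (None when undefined)."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int = 0) -> "EvalReport":
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        if precision is None or recall is None:
            f1 = None
        else:
            f1 = 2 * tp / (2 * tp + fp + fn)
        return cls(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)

    @property
    def precision_percent(self) -> str | None:
        return _floor_percent(self.tp, self.tp + self.fp)

    @property
    def recall_percent(self) -> str | None:
        return _floor_percent(self.tp, self.tp + self.fn)

    @property
    def f1_percent(self) -> str | None:
        if self.f1 is None:
            return None
        return _floor_percent(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def evaluate(
    predicted: Sequence[GeneMutationMatch], gold: Sequence[GoldAnnotation]
) -> EvalReport:
    """Score predicted gene-mutation matches against gold annotations."""
    pred = {(m.doc_id, m.gene_symbol.lower(), m.canonical) for m in predicted}
    truth = {(g.doc_id, g.gene_symbol.lower(), g.normalized_mutation) for g in gold}
    tp = len(pred & truth)
    return EvalReport.from_counts(tp=tp, fp=len(pred - truth), fn=len(truth - pred))


REPORT_COLUMNS = (
    "doc_id",
    "gene_id",
    "gene_symbol",
    "mutation",
    "valid_isoforms",
    "cds_corroborated_isoforms",
    "mention_count",
    "candidate_gene_count",
    "similar_mutations",
    "strains",
    "alleles",
    "generation_methods",
    "variation_types",
    "sentences",
)


@dataclass(frozen=True)
class CurationRecord:
    """One structured output row for curator review.

    Supporting sentences are quoted verbatim from the source document."""

    doc_id: str
    gene_id: str
    gene_symbol: str
    mutation: str
    valid_isoforms: tuple[str, ...]
    cds_corroborated_isoforms: tuple[str, ...]
    mention_count: int
    candidate_gene_count: int
    similar_mutations: tuple[str, ...]
    strains: tuple[str, ...]
    alleles: tuple[str, ...]
    generation_methods: tuple[str, ...]
    variation_types: tuple[str, ...]
    sentences: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "gene_id": self.gene_id,
            "gene_symbol": self.gene_symbol,
            "mutation": self.mutation,
            "valid_isoforms": list(self.valid_isoforms),
            "cds_corroborated_isoforms": list(self.cds_corroborated_isoforms),
            "mention_count": self.mention_count,
            "candidate_gene_count": self.candidate_gene_count,
            "similar_mutations": list(self.similar_mutations),
            "strains": list(self.strains),
            "alleles": list(self.alleles),
            "generation_methods": list(self.generation_methods),
            "variation_types": list(self.variation_types),
            "sentences": list(self.sentences),
        }

    def to_row(self) -> list[str]:
        d = self.to_dict()
        row = []
        for column in REPORT_COLUMNS:
            value = d[column]
            if column == "sentences":
                row.append(" | ".join(value))
            elif isinstance(value, list):
                row.append(",".join(value))
            else:
                row.append(str(value))
        return row


def _entity_surfaces(match: GeneMutationMatch, entity_class: str) -> tuple[str, ...]:
    return tuple(
        sorted(
            {
                e.surface_form
                for e in match.supporting_entities
                if e.entity_class == entity_class
            }
        )
    )


def to_curation_records(
    matches: Sequence[GeneMutationMatch], documents: dict[str, Document]
) -> list[CurationRecord]:
    """Assemble curator rows, quoting the supporting sentences verbatim."""
    records = []
    for match in matches:
        document = documents.get(match.doc_id)
        sentences = tuple(
            document.sentences[i].text
            for i in match.sentence_ids
            if document is not None and 0 <= i < len(document.sentences)
        )
        records.append(
            CurationRecord(
                doc_id=match.doc_id,
                gene_id=match.gene_id,
                gene_symbol=match.gene_symbol,
                mutation=match.canonical,
                valid_isoforms=tuple(match.valid_isoforms),
                cds_corroborated_isoforms=tuple(match.cds_corroborated_isoforms),
                mention_count=match.mention_count,
                candidate_gene_count=match.candidate_gene_count,
                similar_mutations=tuple(match.similar_mutations),
                strains=_entity_surfaces(match, "strain"),
                alleles=_entity_surfaces(match, "allele"),
                generation_methods=_entity_surfaces(match, "generation_method"),
                variation_types=_entity_surfaces(match, "variation_type"),
                sentences=sentences,
            )
        )
    records.sort(key=lambda r: (r.doc_id, r.gene_symbol, r.gene_id, r.mutation))
    return records


def write_report(
    records: Sequence[CurationRecord], path: str | Path, format: str = "tsv"
) -> None:
    """Write curation records as TSV or JSON with deterministic row order."""
    ordered = sorted(records, key=lambda r: (r.doc_id, r.gene_symbol, r.gene_id, r.mutation))
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        lines += ["\t".join(r.to_row()) for r in ordered]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        path.write_text(
            json.dumps([r.to_dict() for r in ordered], indent=2, ensure_ascii=False)
            + "\n",
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown report format {format!r}")


@dataclass
class PipelineConfig:
    enable_natural_language: bool = True
    pattern_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    plugin: Callable | None = None
    report_format: str = "tsv"


@dataclass
class PipelineResult:
    documents: dict[str, Document]
    mentions: list[MutationMention]
    normalized: list[NormalizedMutation]
    matches: list[GeneMutationMatch]
    records: list[CurationRecord]
    report: EvalReport | None
    counts: dict


def run_pipeline(
    document_paths: Sequence[str | Path],
    protein_fasta: str | Path,
    dict_paths: Sequence[str | Path],
    cds_fasta: str | Path | None = None,
    gold_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline over a document set.

    Stage errors propagate with the stage named; per-stage counts (mentions
    per block, normalized, discarded share, validated matches) are logged
    and returned in ``counts``.
    """
    config = config or PipelineConfig()

    def stage(name: str, fn: Callable, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    patterns: PatternSet = (
        stage("patterns", PatternSet.from_tsv, config.pattern_path)
        if config.pattern_path
        else default_pattern_set()
    )
    lexicon: Lexicon = (
        stage("lexicon", Lexicon.from_tsv, config.lexicon_path)
        if config.lexicon_path
        else default_lexicon()
    )
    dictionary: EntityDictionary = stage("dictionaries", load_dictionaries, dict_paths)
    proteome: Proteome = stage(
        "proteome", Proteome.from_fasta, protein_fasta, cds_fasta
    )

    documents: dict[str, Document] = {}
    mentions: list[MutationMention] = []
    normalized: list[NormalizedMutation] = []
    matches: list[GeneMutationMatch] = []
    for path in document_paths:
        document = stage("corpus_io", load_document, path)
        documents[document.doc_id] = document
        doc_mentions = stage(
            "extraction",
            extract_all,
            document,
            patterns,
            lexicon,
            plugin=config.plugin,
            enable_natural_language=config.enable_natural_language,
        )
        doc_normalized = [stage("normalize", normalize, m) for m in doc_mentions]
        entity_matches = []
        for sentence in document.sentences:
            entity_matches.extend(
                stage("entities", match_entities, sentence, dictionary, document.doc_id)
            )
        matches.extend(
            stage(
                "validate",
                pair_and_validate,
                document.doc_id,
                doc_normalized,
                entity_matches,
                proteome,
            )
        )
        mentions.extend(doc_mentions)
        normalized.extend(doc_normalized)

    summary = discard_accounting(mentions, normalized)
    records = to_curation_records(matches, documents)
    report = None
    if gold_path is not None:
        gold = stage("evaluate", read_gold, gold_path)
        report = evaluate(matches, gold)

    per_block = {b: c.total for b, c in summary.per_block.items()}
    counts = {
        "documents": len(documents),
        "sentences": sum(len(d.sentences) for d in documents.values()),
        "mentions_total": summary.total_mentions,
        "mentions_per_block": per_block,
        "normalized": summary.total_normalized,
        "discarded": summary.total_discarded,
        "discard_percent": summary.overall_discard_percent,
        "validated_matches": len(matches),
    }
    logger.info(
        "processed %d documents (%d sentences)", counts["documents"], counts["sentences"]
    )
    logger.info(
        "mutation mentions: %d total (%s)",
        summary.total_mentions,
        ", ".join(f"{n} from {b}" for b, n in per_block.items()) or "none",
    )
    if summary.overall_discard_percent is not None:
        logger.info(
            "normalized %d mentions; %d discarded (%.1f%% of all mentions)",
            summary.total_normalized,
            summary.total_discarded,
            summary.overall_discard_percent,
        )
    logger.info("validated gene-mutation matches: %d", len(matches))
    if report is not None:
        logger.info(
            "evaluation: TP=%d FP=%d FN=%d precision=%s recall=%s",
            report.tp, report.fp, report.fn,
            report.precision_percent, report.recall_percent,
        )
    return PipelineResult(
        documents=documents,
        mentions=mentions,
        normalized=normalized,
        matches=matches,
        records=records,
        report=report,
        counts=counts,
    )
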