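# mutminer

Mine protein point mutations from scientific papers and validate them
against a reference proteome, for variant-curation triage at model-organism
databases.

Biocurators who add variants to a database like WormBase must read each new
paper, spot sequence changes, and tie every change to the right gene. Most
published protein-coding variants appear either in structured notation
(`G109E`, `Arg-107-Cys`, `c.123A>G`) or in prose ("glycine to arginine
substitution at codon 20"). mutminer automates the triage:

1. **Extract** — a regex block matches structured mention shapes in each
   sentence; sentences it leaves empty go to a rule-based natural-language
   block (or a pluggable NER tagger).
2. **Normalize** — every mention becomes a canonical one-letter
   substitution `<REF><POS><ALT>` (e.g. `V600E`), or is discarded with an
   explicit reason (indels, nucleotide-level mentions, incomplete triples).
3. **Link** — genes, strains, alleles, variation types and generation
   methods are found by whole-token dictionary lookup.
4. **Validate** — a (gene, mutation) pair is kept only if at least one
   isoform of the gene carries the claimed reference residue at the claimed
   position; with a CDS available, membership of the codon in the residue's
   degenerate set (e.g. GGN for Gly) is recorded as corroboration.
5. **Report** — curator-ready TSV/JSON rows with the verbatim supporting
   sentences, mention counts, multi-gene-ambiguity flags
   (`candidate_gene_count`), similar mutations at the same position, and
   precision/recall/F1 against gold annotations when available.

Evaluation scores (doc, gene, canonical mutation) triples:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
computed exactly and printed truncated to two decimals.

## Worked example

Generate a small synthetic corpus with known ground truth, run the full
pipeline, and score it against the generated gold annotations:

```bash
mutminer fixtures --out demo --seed 7 --n-documents 3 --n-genes 5 --mutations-per-document 2
mutminer curate demo/documents/*.txt \
    --proteome demo/proteome.protein.fasta --cds demo/proteome.cds.fasta \
    --dicts demo/dictionaries/genes.tsv --dicts demo/dictionaries/strains_alleles.tsv \
    --dicts demo/dictionaries/terms.tsv \
    --gold demo/gold.tsv --out demo/report.tsv
```

prints

```
mutminer.pipeline: processed 3 documents (25 sentences)
mutminer.pipeline: mutation mentions: 11 total (11 from regex)
mutminer.pipeline: normalized 11 mentions; 0 discarded (0.0% of all mentions)
mutminer.pipeline: validated gene-mutation matches: 6
mutminer.pipeline: evaluation: TP=6 FP=0 FN=0 precision=100.00% recall=100.00%
11 mentions ({'regex': 11}), 11 normalized, 6 validated matches -> demo/report.tsv
evaluation: TP=6 FP=0 FN=0 precision=100.00% recall=100.00% f1=100.00%
```

Eleven mutation-shaped strings were extracted; five of them are planted
decoys whose reference residue fits no gene in their document, so exactly
the six planted pairs survive validation — hence TP=6 with no false
positives or negatives. The first report row reads

```
doc000  SGENE00000  idq-10  S210W  a  a  1  1    CB500  e1000    substitution  The idq-10 mutant animals carried the S210W substitution.
```

i.e. mutation `S210W` validated against isoform `a` of gene `idq-10`
(protein check and CDS corroboration), was mentioned once, is unambiguous
(`candidate_gene_count` 1), and comes with the strain/allele context and
the verbatim sentence a curator needs.

The same machinery is available as a library:

```python
from mutminer import Document, extract_all, normalize

doc = Document.from_text("p1", "glutamic acid was substituted by valine at residue 6.")
print([normalize(m).canonical for m in extract_all(doc)])   # ['E6V']
```

## Layout

- `src/mutminer/corpus_io.py` — documents, sentence segmentation with
  stable offsets, gold TSV IO, synthetic fixture generator
- `src/mutminer/extraction.py` — regex block, natural-language block,
  gating, plugin seam; patterns/lexicon in `src/mutminer/resources/`
- `src/mutminer/normalize.py` — canonical one-letter normalization and
  discard accounting
- `src/mutminer/entities.py` — dictionary entity matching
- `src/mutminer/validate.py` — proteome loading, reference/codon checks,
  document-level pairing with curator metadata
- `src/mutminer/evaluate_report.py` — metrics, curation records, pipeline
- `src/mutminer/cli.py` — `mutminer fixtures|extract|curate|evaluate`
- `docs/methods.md` — models, assumptions, parameter choices, limitations
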