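# Methods

## The task

Model-organism databases curate sequence variants out of the primary
literature by hand. Most published protein-coding variants are written
either in structured form (`G109E`, `Arg-107-Cys`, `c.123A>G`) or in prose
("glycine to arginine substitution at codon 20"). mutminer implements a
hybrid triage pipeline for this setting: extract candidate mutation
mentions from paper text, normalize them to canonical one-letter form,
pair them with genes named in the same paper, keep only the pairs that a
reference proteome can corroborate, and hand curators a structured table
with the verbatim supporting sentences and quality-control metadata.

## Pipeline stages and their assumptions

**Sentence segmentation** (`corpus_io`). A rule-based splitter: a run of
terminal punctuation ends a sentence when it is followed by whitespace and
an upper-case/digit/opening-quote continuation, unless the preceding token
is on an abbreviation stop-list (Fig., et al., e.g., i.e., cf., approx.,
vs., ...). Offsets are 0-based half-open everywhere, and every sentence's
text is by construction the literal document slice at its span — all
downstream mentions and entity hits are sentence-relative and verifiable
against the source. The splitter is deterministic and dependency-free; it
is not claimed to reproduce any particular tokenizer's output, and tests
only rely on properties (offset fidelity, whitespace-only gaps) plus a
hand-segmented reference text.

**Extraction** (`extraction`). Two blocks with a gating rule. The regex
block runs first on every sentence; only if it finds nothing is the
sentence passed to the natural-language block (or to a registered plugin
tagger — the seam exists so a trained NER model can replace the rule-based
block without touching the pipeline). Gating is per sentence, so one
document can mix both sources but one sentence cannot.

The pattern set is authored in `resources/patterns.tsv` and covers:
one-letter substitutions with word boundaries on both sides (`G109E`, also
`G12→V`/`G12->V`), nonsense changes (`Q361*`, `Q361X`, `W58amber`),
three-letter concatenated/hyphenated/spaced forms (`Gly109Glu`,
`Arg-107-Cys`), full-name hyphen forms (`Glycine-20-Arginine`), nucleotide
substitutions (`c.123A>G`, `123A>G`), and bare `del`/`ins` tokens attached
to positions. One-letter codes are case-sensitive uppercase (lowercase
`g109e` shapes are overwhelmingly false positives); multi-letter forms are
case-insensitive. A token such as `G359A`, ambiguous between amino-acid
and nucleotide readings, is emitted once as a protein substitution:
the pipeline targets protein-coding variants and sequence validation
arbitrates downstream. Overlapping matches are resolved longest-first,
ties leftmost, then pattern order, so emitted spans are pairwise disjoint.

The natural-language block composes template grammars from a bag-of-words
lexicon (`resources/lexicon.tsv`: amino-acid names, substitution verbs and
nouns, position nouns). Covered orders: "<ref> to <alt> substitution at
codon N"; "<ref> was substituted/replaced by/with <alt> at residue N"
(subject = reference); "<alt> was substituted for <ref> at residue N"
(subject = replacement — English voice decides which name is the
reference); "substitution of <ref> by <alt> at position N". Residue-level
deletion/insertion phrases are flagged as mentions without components so
that the discard accounting sees them; their internal structure is not
parsed. Extraction deliberately over-generates — cell-line names like
`T47D` are mutation-shaped and will be extracted — because the proteome
validation stage is the precision filter.

**Normalization** (`normalize`). Residue tokens are mapped through the
standard full-name/three-letter → one-letter table to the canonical form
`<REF><POS><ALT>` with `*` for stop; `amber`/`ochre`/`opal`/`X` map to `*`.
Every mention lands in exactly one bucket: `normalized`,
`discarded_incomplete` (missing or unrecognizable ref/pos/alt, including
selenocysteine/pyrrolysine, which are outside the 20+stop universe), or
`discarded_unsupported` (indels, nucleotide-level mentions). Positions are
kept exactly as authors wrote them — no initiator-methionine renumbering —
because validation against every isoform absorbs numbering ambiguity more
honestly than a guessed offset. Normalization is idempotent on canonical
inputs, and the accounting partitions exactly: per-block discard
percentages are reported relative to the total mention count so a run
summary can state what share of *all* mentions were dropped
natural-language output.

**Entity matching** (`entities`). Plain whole-token dictionary lookup with
word boundaries on both sides, no fuzzy matching. Genes, strains and
alleles match case-insensitively (authors freely alternate mec-5/MEC-5)
but are reported with dictionary casing; variation types and generation
methods are case-sensitive when the surface is an all-caps acronym (EMS
never fires inside EMSA, and lowercase "ems" never fires at all).
Overlaps resolve longest-first, which also makes the match set independent
of dictionary row order. Dictionaries are user-supplied TSVs; the fixture
generator ships a miniature one.

**Validation and pairing** (`validate`). The curation unit is the paper:
every gene entity found anywhere in a document crosses with every
normalized mutation in that document. A pair is kept iff at least one
isoform of the gene carries the claimed reference residue at the claimed
1-based position. When a CDS is available, membership of codon *pos* in
the reference residue's degenerate codon set (e.g. GGN for glycine) is
recorded as corroboration; the protein-level check stays authoritative
because proteome FASTA is the canonical validation input. The alternate
residue is never checked — only the pre-edit state exists in the
reference. Out-of-range positions are False, not errors, since an author
may count from a different isoform. Unverified pairs are dropped with a
log line; genes with no proteome record are skipped likewise. Kept
matches carry curator metadata: mention count, the number of genes in the
document the mutation validates against (the same change validating in
two genes is improbable and worth a curator's attention), and same-gene
same-position different-alternate "similar mutations".

**Evaluation and reporting** (`evaluate_report`). A prediction is scored
against gold on the (document, gene symbol, canonical mutation) triple,
gene symbols case-insensitive. Precision, recall and F1 are computed in
exact integer arithmetic; zero-denominator metrics are `null`, never 0.
Percent strings are **truncated** to two decimals rather than rounded —
the convention under which TP=807/FP=170 prints as 82.59% — implemented as
`(n·10⁴)//d` so no floating-point path can flip the last digit. Curation
records quote supporting sentences verbatim and are written as TSV or JSON
in a deterministic order, so identical inputs give byte-identical outputs.

## The synthetic corpus

`generate_fixtures` builds the corpus the tests and the acceptance script
run on. Default study conditions, fixed once: 20 documents, 10 genes with
proteins of 120–400 residues (initial Met, optional truncated second
isoform; CDS back-translated codon-by-codon with a random synonymous
choice plus stop), 3 planted structured mutations per document cycling the
one-letter / three-letter-hyphenated / three-letter-concatenated surface
forms, and a decoy rate of 0.2. Planted mentions name a gene in the same
sentence and use the protein's true residue as reference, so they must
survive validation; decoy sentences carry mutation-shaped strings
(cell-line-style one-letter and three-letter forms) whose reference
residue matches **no** isoform of **any** gene mentioned in that document,
so they must be extracted yet rejected. Gold lists exactly the planted
pairs. Identical seeds give byte-identical files.

What the generator does not emulate: real papers' tables and figures
(text-only input is assumed), nucleotide-level variant reporting, genome
or annotation version drift, author numbering errors, and natural-language
mention phrasing beyond the template grammars. Passing the fixture suite
therefore demonstrates the mechanics — recovery of structured surface
forms, gating, normalization, dictionary pairing, and sequence
verification — not recall on free-text prose in the wild. One deliberate
property: fixture precision is below 1.0 because a planted mutation can
coincidentally validate in another co-mentioned gene (~1/20 chance per
extra gene and residue). That is not a defect of the generator; it is the
multi-gene ambiguity the `candidate_gene_count` metadata exists to flag.

## Numerical and degenerate-input choices

- Offsets 0-based half-open; protein/codon positions 1-based, residue 1 =
  first residue of the supplied isoform sequence.
- Trailing stop codon in a CDS is tolerated and ignored for position
  arithmetic; CDS length must otherwise be 3× the protein length and
  translate back to it (a mismatch is a hard error, not a warning).
- Overlap resolution everywhere is longest-first, leftmost, then a fixed
  deterministic tie-break (pattern order / entity class + surface).
- Empty documents, empty dictionaries, header-only gold files and empty
  document sets are all valid inputs producing empty outputs.
- Problem sizes in the test suite: the oracle-equivalence check runs
  10,000 random (CDS, position, residue) triples; the corpus run uses the
  20-document conditions above. Both complete in seconds.

## Known limitations

- The natural-language block is a rule-based stand-in behind the same
  interface a statistical tagger would use; prose outside its template
  grammars is missed by design and the plugin seam is the upgrade path.
- Nucleotide-level mentions are surfaced but not normalized or validated.
- No gene-name disambiguation across species, no abbreviation expansion,
  no coreference; dictionary lookup is exact-token only.
- No HGVS grammar beyond the shapes listed; frameshifts, duplications and
  complex indels are flagged at best, never parsed.
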