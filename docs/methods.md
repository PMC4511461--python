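# Methods

## Scope and design

`habminer` is a rule-based system for recognizing bacteria-habitat mentions
in text, normalizing them to an OBO-format habitat ontology, extracting
bacteria–habitat *Localization* and habitat–habitat *PartOf* relations, and
scoring such predictions with the Slot Error Rate (SER). Everything is
deterministic: two runs over the same inputs produce byte-identical output.

The pipeline assumes that habitat mentions are (subsequences of) noun-phrase
chunks, so shallow analysis — sentence segmentation, tokenization, POS tags,
lemmas, IOB2 NP chunks — is sufficient; no constituency or dependency
parsing is attempted. That assumption is also the source of the system's
known failure modes (see *Limitations*).

## Shallow analysis

Analyzers implement a small contract: document text in, sentences out, each
sentence a character span plus tokens carrying `(surface, lemma, POS, IOB2
chunk, start, end)` with 0-based, end-exclusive code-point offsets into the
*original* text. `analyze()` enforces the contract (offset round-trip,
ordered non-overlapping tokens, syntactically valid IOB2) and attaches
paragraph indices; paragraphs are maximal runs of non-blank lines, so a
leading title line followed by a blank line forms its own paragraph — which
the paragraph-based relation strategy relies on.

The packaged `LexiconAnalyzer` is a deterministic stand-in for a statistical
tagger: a TSV lexicon (`data/lexicon.tsv`, `surface<TAB>lemma<TAB>POS`)
covering the vocabulary of the fixture documents, plus suffix heuristics for
unknown words (hyphenated → adjective, digit-bearing/capitalized → proper
noun, `-s` → plural noun with the stripped lemma, `-ed`/`-ing` →
participle, else common noun). Chunking groups nominal-POS runs
(determiners, adjectives, nouns, numbers, possessives) into NPs and keeps
the conjunction *and* inside a single NP when it directly bridges two
nominal runs — this is what routes within-phrase coordination to the
coordination handler while leaving clause-level *and* alone. Sentences break
at newlines and after `.?!` followed by whitespace and an
upper-case/digit character; the fixture vocabulary contains no abbreviations,
so no abbreviation list is needed.

Hyphenated words (*iron-rich*, *2-year-old*) are single tokens, matching how
the ontology spells hyphenated labels.

## Entity recognition

Per sentence, maximal NP chunks become candidates after **simplification**:
tokens tagged DT, PRP$, PDT, WDT, or POS are dropped wherever they occur
(*"the mummy tissue"* → *"mummy tissue"*; *"its small intestine"* →
*"small intestine"*). The extension beyond determiners and possessive
pronouns to the other determiner-like tags is a conservative analogue of the
same idea. A candidate whose tokens are all dropped is discarded.

**Ontology matching** is whole-token: a label (name or synonym, normalized
by lowercasing, whitespace collapsing, and edge-punctuation stripping) must
equal a contiguous run of candidate tokens, on the surface stream or the
lemma stream (so *animals* matches the label *animal*). Both streams are
searched simultaneously; a surface hit wins over a lemma hit for the same
concept and range, and only maximal ranges per concept survive. RELATED
synonyms are indexed alongside EXACT ones by default; a config switch
restricts matching to names + EXACT synonyms.

**Boundary rules** per match: an exact match (label covers the candidate)
and an internal partial match (starts after the first token) both yield a
mention spanning the whole candidate; a prefix partial match yields a
mention spanning only the matching sub-phrase. Mentions with identical
fragments merge, concatenating concept ids. Overlapping mentions from one
candidate are all emitted — no containment suppression — because reference
annotations contain overlapping entities.

**Coordination.** A candidate containing exactly one *and* (not at either
edge) splits into `L + R[1:]` and `R` (shared-head completion), or plainly
into `L` and `R` when the right part is a single token. The completion rule
reproduces all the canonical cases: *"pharyngeal and gut mucosa"* →
*pharyngeal mucosa* / *gut mucosa*, *"iron-rich and wet environment"* →
*iron-rich environment* / *wet environment*, *"ground and surface water"* →
*ground water* / *surface water*, *"plants and animals"* → *plants* /
*animals*. Each sub-phrase maps to its best concept (exact > prefix >
internal, then longer match, then smallest id). If both map and the
concepts share a direct `is_a` parent, the whole phrase stays a single
mention — normalized to *both* concepts, which is lossless since no single
choice is canonical — unless both sub-phrases are bare single nouns, which
remain two mentions. Without a shared parent the sub-phrases become two
mentions, the first typically discontinuous (two character fragments).

**Modifier attachment** (`NP prep NP` with *in*/*of*/*with*) is implemented
but **off by default**: extending habitat boundaries across prepositions
trades precision for recall and measurably worsens SER, chiefly through
PP-attachment ambiguity — *"patient in Europe"* is a habitat boundary,
*"patient in 1993"* is not, and a chunker cannot tell them apart. The CLI
flag `--modifier-preps` enables any subset.

Only maximal NP chunks are candidates; nested NPs inside a chunk are reached
through partial matching rather than re-chunking.

## Relation extraction

**Paragraph-based Localization**: within each paragraph containing at least
one bacterium and one habitat/geographical entity, the first bacterium is
the topic and links to every habitat in the paragraph. If the anchor's text
occurs earlier in the document as a bacteria entity, the relation re-anchors
to the first document occurrence; if the anchor text contains the standalone
token *strain*, the anchor becomes the first document occurrence of the same
name with *strain* removed (whitespace renormalized), falling back to the
original anchor when none exists. Name comparison is case-sensitive on the
annotated surface.

**Sentence-based Localization**: every *specific* bacterium in a sentence
links to every habitat/geographical entity in that sentence. Generic
surfaces (*bacteria*, *bacterium*, case-insensitive; configurable) are not
specific even when annotated as bacteria entities. All specific bacteria in
the sentence participate, not just the first — co-occurrence is stated for
the sentence as a whole, and restricting to the first mention would
arbitrarily drop relations. Geographical entities are treated exactly like
habitats as Localization targets.

**Anaphora resolution** applies to sentences with no specific bacterium,
in order:

1. the sentence contains one of the configured anaphoric expressions →
   antecedent is the first bacterium of the previous sentence, else the
   first bacterium of the document (documents are typically about one
   species mentioned early);
2. the sentence *begins* with the pronoun *it* → first bacterium of the
   previous sentence (no document fallback; a document-initial *it* has no
   antecedent);
3. the sentence begins with *this strain* → first bacterium of the document.

The default keyword list has 23 expressions: the five core forms (*the
bacterium*, *this organism*, *this species*, *this genus*, *this group of
organisms*) plus systematic number/lexical variants. The full original list
is not public, so the variants approximate it; any list can be supplied via
a plain-text file, one expression per line. Matching is over lowercased
token sequences, so punctuation does not interfere.

**PartOf** between habitat mentions A ⊃ B (A's span covers B's, B's tokens a
contiguous subsequence of A's): rule 1 fires when, inside A, the token
before B's start — skipping articles/demonstratives, since annotated habitat
boundaries often exclude a leading *a*/*the* (*"… from a Lyme disease
patient in Europe"*) — is *of*, *in*, or *from*; rule 2 fires when B is a
proper prefix of A's token sequence. Both yield part = A (the more specific
mention), host = B, serialized as `PartOf Host:B Part:A`. Long-distance
PartOf between non-overlapping mentions is out of scope, as is host vs
host-part semantic typing.

## Standoff and OBO I/O

Standoff offsets are 0-based, end-exclusive code points. Discontinuous
entity text may be the exact concatenation or the single-space join of its
fragments on input; the writer emits the single-space join. Writers are
canonical — entities keep their ids but are position-ordered; normalization
and relation lines are renumbered sequentially — so serialization is
deterministic and stable under re-reading. Unknown line types are skipped
with a logged warning; offset/text mismatches and dangling references are
hard errors naming the offending record.

The OBO parser handles `[Term]` stanzas with `id`, `name`, `synonym`
(EXACT vs anything-else = related), `is_a`, and `is_obsolete`; obsolete
terms are retained but unindexed. Construction validates unique ids,
resolvable parents, and acyclicity of the `is_a` DAG. Ontology expansion
appends each annotated training surface as an EXACT synonym of its concept
unless the concept already carries that label; the "already defined" check
is case-insensitive over normalized labels (the safest reading, since
matching is itself case-insensitive), and the operation is idempotent.

## Evaluation

Per matched pair, `J` is the Jaccard coefficient over covered *character*
positions (characters rather than tokens, so fragment boundaries inside a
token are penalized proportionally), and `W` the Jaccard coefficient of the
two concepts' ancestor sets *including the concepts themselves* — inclusion
makes `W = 1` exactly for identical concepts. A mention carrying several
concepts scores with its best concept pair. Pairing admits only overlapping
pairs (`J > 0`) and maximizes total match credit `Σ M` with the Hungarian
algorithm; this is deterministic and order-independent, and a greedy
fallback (`--greedy`) exists for comparison. Unmatched references are
deletions, unmatched predictions insertions.

Because each matched pair contributes `S_pair + M = 1`, the matched-pair
count equals `S + M_total`, so corpus totals satisfy `N = S + M_total + D`.
The aggregate mode (`evaluate --from-totals S D I M`) uses this identity to
recompute `SER = (S+D+I)/N` and `recall = M_total/N` from reported totals
alone; with the two published runs' totals (S=112.70, D=89, I=141,
M=305.30 and S=115.24, D=74, I=158, M=317.75) it recovers N ≈ 507 and
reproduces the published SER (0.68/0.68) and recall (0.60/0.63). The
published *precision* values are **not** reproducible from those totals
under any simple denominator (matched + I, or prediction count), so
precision from totals is deliberately not reported; entity precision is
only computed when the prediction count is actually known
(`M_total / #predictions`). Relation scoring is exact matching on
(document, relation type, argument ids) with the usual zero-denominator
conventions (precision 0 with a flag when there are no predictions).

## Fixtures: what they emulate and what they don't

The fixture bundle exists so the full pipeline is testable offline. The
mini-ontology (20 concepts) wires exactly the parent structure the worked
examples need; ids without an established public value come from the
reserved synthetic range `MBTO:099xxxxx` (manifest:
`fixtures.SYNTHETIC_IDS`), and the exact synonym *gastrointestinal tract* on
*digestive tract* is a synthetic stand-in consistent with that concept's
published normalization behaviour. Fixture documents are one- and
two-paragraph constructions around the canonical example sentences, with
gold `.a1` entities and expected `.a2` outputs generated programmatically
(offsets computed by search, never hard-coded).

Passing on fixtures therefore demonstrates the *rules* behave exactly as
specified on the canonical cases; it does not demonstrate corpus-level
accuracy. Real corpus documents are longer, noisier (HTML remnants, headers,
unusual tokenization), carry a 1700-concept ontology with far denser label
collisions, and exercise the tagger, which here is a controlled lexicon
stand-in rather than a statistical model. Corpus-scale SER/F figures require
the original corpus and ontology and are out of scope.

## Numerical and degenerate-input choices

* Problem sizes: property suites use 200 random pairing instances (≤ 6×6,
  checked against an exhaustive permutation oracle), 250 random standoff
  documents and 250 random ontologies for round-trip stability, and
  seeded RNGs throughout; the whole suite runs in a few seconds.
* `jaccard_span` with both sides empty is an error (no convention is
  meaningful); SER with `N = 0` likewise.
* Assignment ties are broken deterministically by the solver; dropped
  zero-credit assignments (forced pairings with `J = 0`) are counted as
  deletion + insertion, never as a match.
* Tie-breaks in best-match selection: match kind, then longer token range,
  then lexicographically smallest concept id.
* Degenerate coordination (*and* at a candidate edge, or several *and*s) is
  left to plain matching rather than guessed at.

## Limitations

* PP-attachment ambiguity is unresolved by design (modifier handling off by
  default); *"isolated from a patient in 1993"* would be mis-bounded if
  enabled.
* Anaphora resolution is heuristic: it cannot handle cataphora, plural
  split antecedents, or documents about several species.
* PartOf requires textual overlap; *"humans … gut flora"* style
  long-distance relations are not extracted.
* The lexicon analyzer's heuristics are tuned for English biomedical prose;
  plugging in a statistical tagger changes chunk boundaries and hence
  recognition output.
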