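# habminer

Rule-based detection, ontology normalization, and relation extraction for
**bacteria habitat** mentions in text.

Knowing where a bacterial species lives — its *biotope*: a host, a host part,
a food, soil, water — matters for microbiology, health sciences, and food
safety, but most of that knowledge sits in unstructured text such as the web
pages of genome sequencing projects. `habminer` implements a linguistically
motivated pipeline that works from shallow syntactic analysis alone
(sentence segmentation, POS tags, lemmas, noun-phrase chunks — no full
parsing):

* **Entity detection & categorization** — noun phrases are extracted and
  simplified (determiners and possessive pronouns dropped), matched exactly
  or partially against the names and synonyms of an OBO-format habitat
  ontology (`MBTO:` concept ids) on both surface and lemma streams, and
  turned into mentions by three boundary rules. Coordinated phrases such as
  *"pharyngeal and gut mucosa"* are split with shared-head completion and
  resolved into one entity or two — including **discontinuous** entities
  (*"pharyngeal … mucosa"*) — depending on whether the mapped concepts share
  a direct `is_a` parent. The ontology can be expanded with surface forms
  harvested from annotated training data.
* **Relation extraction** — Localization relations between bacteria and
  habitat/geographical entities via a paragraph-based strategy (the first
  bacterium of a paragraph is its topic) or a sentence-based strategy with
  three-type **anaphora resolution** (*"this organism"*, sentence-initial
  *"it"*, *"this strain"*); PartOf relations between overlapping habitat
  mentions via two syntax rules.
* **Evaluation** — the Slot Error Rate used to score such systems:

  ```
  SER = (S + D + I) / N,   S = Σ (1 − M),   M = J · W
  ```

  where `J` is the Jaccard similarity of the character spans of a matched
  prediction/reference pair, `W` the Jaccard similarity of their concepts'
  self-inclusive ancestor sets, `D`/`I` count deletions (missed references)
  and insertions (spurious predictions), and `N` counts reference mentions.
  Pairing is an optimal one-to-one assignment maximizing `Σ M`. Exact-match
  precision/recall/F is provided for relations.

All I/O uses the BioNLP-ST standoff format (`.txt` / `.a1` / `.a2`, with
discontinuous spans and `OntoBiotope` normalization lines) and OBO 1.2 flat
files. A deterministic, lexicon-driven analyzer is packaged so the whole
pipeline runs offline with no external models; any other tagger can be
plugged in behind the same analyzer contract.

## Worked example

```bash
habminer fixtures --out bundle                 # mini ontology + documents
habminer detect --ontology bundle/ontology.obo \
    --input bundle/documents --output pred
cat pred/bodily-fluid.a2
```

```
T1	Habitat 4 10	animal
T2	Habitat 4 23	animal bodily fluid
N1	OntoBiotope Annotation:T1 Referent:MBTO:00001660
N2	OntoBiotope Annotation:T2 Referent:MBTO:00000921
```

The phrase *"the animal bodily fluid"* is simplified to *"animal bodily
fluid"* and matched twice: the prefix match on the concept name *animal*
yields the mention `animal` normalized to `MBTO:00001660`, and the internal
partial match on the exact synonym *bodily fluid* of *body fluid* yields a
mention spanning the whole phrase, normalized to `MBTO:00000921`.

Relations, from gold entities:

```bash
habminer relations --input bundle/documents --output rels --strategy sentence
cat rels/brucella.a2
```

```
R1	Localization Bacterium:T1 Localization:T2
R2	Localization Bacterium:T1 Localization:T3
```

Here the sentence *"This bacterium is highly infectious, …"* contains no
bacterium name; the anaphora resolver links *"This bacterium"* to *Brucella
canis* in the previous sentence and attaches the habitats *animal products*
and *air*.

Scoring, including the aggregate mode that recomputes corpus SER and recall
from reported `S D I M` totals (using the identity `N = S + M + D`):

```bash
habminer evaluate --task entities --ref bundle/documents --pred pred \
    --ontology bundle/ontology.obo
habminer evaluate --from-totals 112.70 89 141 305.30
```

```
N	507.00
SER	0.6759
Recall	0.6022
```

Other subcommands: `expand-ontology` (training-set synonym expansion with a
TSV report) and `evaluate --task relations` (exact-match P/R/F). See
`habminer --help`.

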