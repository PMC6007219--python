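# orgnorm

Organism-term recognition and normalization for figure captions.

Figure legends are dense, abbreviation-heavy text in which the same surface
form can denote different organisms: *SIN* may be the Sindbis virus or a
*Drosophila* gene, *embryos* may be zebrafish or nematode embryos depending
on the article, and strain designators such as *USA300* follow no
nomenclature at all. `orgnorm` recognizes organism mentions in captions and
links each one to an NCBI Taxonomy identifier, exploiting the caption's
*full-text article* as disambiguation context. It is aimed at biocuration
and text-mining pipelines that need species grounding for caption-level
entities (genes, proteins, mutations are species-ambiguous without it).

## Method

1. **Lexicon word-graph matching.** A lexicon of taxonomy IDs and their
   synonyms (scientific, common, strain, abbreviation, general names, plus
   rule-generated base forms such as *embryos → embryo*) is compiled into
   character-level word graphs. Captions are scanned for token-anchored
   matches; names of ≥ 10 characters are also matched approximately,
   tolerating up to 3 character edits (Levenshtein), so spelling variants of
   strain and scientific names still hit.
2. **Full-text meta-info.** Before a caption is tagged, its article is
   processed Introduction-first, then abstract, then the remaining
   sections. Unambiguous matches accumulate *pre-linked counts* per taxon
   ID; full-name/abbreviation pairs (Schwartz–Hearst-style detection) whose
   long form is an organism name register both forms as article-specific
   extra terms, and all other pairs are blacklisted. Matches sitting on
   verb tokens are discarded.
3. **Disambiguation.** An ambiguous mention (one surface, several IDs) is
   resolved by the **majority rule** — the candidate with the most
   pre-linked occurrences in the article wins — or by a compact
   **convolutional yes/no scorer** over the caption context, with word +
   signed-distance position embeddings, an entity channel built from the
   candidate's scientific name, and a bilinear context–entity agreement
   term (learning rate 0.01, kernel width 2, reserved OOV token).
   *Common terms* (larva / embryo / seedling) carry a closed candidate
   table and are resolved against the pre-linked counts.
4. **Evaluation.** Micro-averaged precision / recall / F1 at the mention
   level (strict = identical spans, overlap = any shared code point,
   one-to-one greedy matching) and at the normalization level (per-caption
   sets of unique taxonomy IDs).

Three run presets mirror the standard operating points: `run1` (majority,
candidate threshold 2), `run2` (model, threshold 10), `run3` (model, no
threshold).

## Worked example

```python
from orgnorm import make_fixture_lexicon
from orgnorm.bioc import Document, Passage
from orgnorm.pipeline import RunConfig, tag_document

lex = make_fixture_lexicon()
caption = Document("d1", (Passage(
    0, "Colonization of human skin by MRSA strain USA300 "
       "visualized by electron microscopy.", "fig_caption"),))
tagged = tag_document(caption, None, lex, RunConfig())
for a in tagged.passages[0].annotations:
    print(a.surface, a.taxon_id)
```

prints

```
human 9606
MRSA 1280
USA300 367830
```

— *MRSA* grounds to *Staphylococcus aureus* (1280), *USA300* to the
USA300 strain entry (367830), and *human* to *Homo sapiens* (9606). With a
full-text article supplied, context-dependent cases resolve too: an article
whose Introduction repeatedly mentions *Caenorhabditis elegans* makes the
caption word *Embryos* resolve to 6239, while a zebrafish-dominated article
sends the same word to 7955.

The same pipeline is available from the shell:

```sh
orgnorm fixtures --out-dir fx --seed 5 --articles 3
orgnorm tag --collection fx/collection.xml --fulltext fx/collection.xml \
            --lexicon fx/lexicon.tsv --preset run1 --out pred.xml
orgnorm eval --gold fx/collection.xml --pred pred.xml --mode all
```

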