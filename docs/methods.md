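# Methods

## Problem setting

Given a figure caption and (optionally) the full text of its article, the
task is to produce, per caption, a set of organism annotations: character
spans, and for each span either an NCBI Taxonomy ID or a type-only label
("organism") when no ID can be justified. The hard cases are (a) surfaces
linked to several IDs in the lexicon, (b) abbreviations defined ad hoc in
the article, and (c) *common terms* — words like *embryo*, *larva*,
*seedling* that denote different organisms in different articles.

## Offsets and span repair

All offsets are 0-based, half-open, counted in Unicode code points. Caption
corpora are not always consistent about this — annotations around
characters such as α or β are often off by a few units, depending on
whether the producer counted bytes or UTF-16 code units. Rather than
guessing the producer's unit, `repair_annotation_spans` re-anchors any
annotation whose declared span does not slice to its recorded surface text,
searching ± 10 code points (default) for the nearest occurrence; annotations
that cannot be re-anchored are flagged, never silently dropped. The window
default reflects that unit-confusion errors shift offsets by only a few
units per special character.

## Lexicon and matching

A lexicon row is `taxon_id TAB name TAB class` with classes scientific /
common / strain / abbreviation / general. `expand_base_forms` adds a
lowercased, singularized base form of every name (irregular-plural table —
*larvae → larva*, *mice → mouse* — then suffix rules), so plural caption
usage reaches singular lexicon entries.

Matching compiles names into character tries (the contract is the accepted
language, not the graph topology) and scans text at token boundaries.
Policy choices, all configurable:

* **Case.** Names of ≥ 5 code points match case-insensitively; shorter ones
  case-sensitively. Short abbreviations (*LV*, *SIN*) are precisely the
  surfaces where case carries signal.
* **Approximate matching.** Up to 3 character edits, but only for names of
  ≥ 10 code points. An unrestricted 3-edit budget on short names would make
  *rat* match most 3–5-letter words; the length gate keeps the tolerance
  where it helps (strain and scientific-name variants).
* **Overlap resolution.** Exactness dominates (an exact match always beats
  an approximate one it overlaps), then longest span, then start position.
  Cost-first ordering matters: otherwise an approximate match that absorbs
  neighboring words through insertions could displace a clean exact match
  it overlaps.

## Full-text processing order and meta-info

Sections are processed Introduction (or Background) first, then Abstract,
then the rest in document order; captions are excluded from this pass.
Authors typically give an organism's full name, often with its
abbreviation, at first mention in the Introduction, so processing in this
order makes the pre-linked counts most informative by the time ambiguous
surfaces appear.

Per section, abbreviation pairs are handled before scanning. A pair whose
long-form base form is an unambiguous lexicon name registers both forms as
article-specific extra terms; any other pair is blacklisted, so its short
form can never fire as an organism later. Extra-term matches are exact-only
and override overlapping lexicon matches (they carry article-specific
evidence). Ambiguous full-text matches are resolved against the counts
accumulated *so far* and increment counts only when a strict majority
exists — counts are meant to reflect successfully linked occurrences, not
guesses; this build-time use of the majority rule is a deliberate choice
where the alternative (skipping ambiguous full-text matches entirely) was
also defensible.

Abbreviation detection is the Schwartz–Hearst procedure with its canonical
constraints (short form ≤ 10 characters, ≤ 2 words, long-form window
min(|sf|+5, |sf|·2) words), with two extensions: genus-style short forms
("S. Typhimurium") are accepted regardless of length, with the long form
spanning from the genus-initial word through the epithet word; and the
reversed `SHORT (long form)` pattern uses a looser letter-matching test
(first letter word-initial, ≥ half the letters as a common subsequence),
because initialisms over non-head words ("BCF" / "the bloodstream form")
fail strict right-to-left alignment. False pairs admitted by the looser
test are harmless by construction: their long forms fail the lexicon lookup
and the pair is blacklisted.

The part-of-speech component is deliberately a small rule system (closed
verb list, -ed/-ing morphology with a noun-exception list, capitalized
default-noun). Its only load-bearing job is the verb filter — dropping
candidate matches that sit on verb tokens ("were *expressed* in…") — and it
is documented as replaceable behind `tokenize_with_pos`.

## Disambiguation

**Majority rule.** The candidate with the strictly maximal pre-linked count
wins; ties break to the earliest first-linked ID, then the smallest ID
(determinism); all-zero evidence leaves the mention ambiguous. A
candidate-count threshold then removes still-ambiguous mentions with more
candidates than the threshold (2 in the majority preset, 10 in the model
preset, ∞ to disable).

**Common terms.** A closed table maps each common term to its candidate
IDs (larva → 7227, 7955, 6239; embryo → 10090, 7955, 6239, 9031;
seedling → 3915, 3702). The candidate with the most pre-linked occurrences
wins; with no evidence the mention is emitted as type-only ("organism")
rather than guessed. One override: an organism mention within two tokens
before the term ("zebrafish embryos") fixes the ID directly when it is
among the candidates — explicit local modification beats article-level
statistics. The table is closed by default and user-overridable.

**Neural scorer.** Candidate assignment is cast as binary classification:
one example per (mention-in-context, candidate ID), labelled yes/no.
The context is the token sequence of the caption with signed distances from
the mention (the mention itself at distance 0); each token is the
concatenation of a word embedding and a position embedding of its distance.
A single convolution (kernel width 2) with max-pooling summarizes the
context; the entity channel is the mean word embedding of the candidate's
scientific name. The two channels enter the 2-way softmax both additively
(affine map on their concatenation) and through a bilinear agreement term
`pooledᵀ B e`. The bilinear term is required, not decorative: a purely
additive combination factorizes the logit difference into
f(context) + g(entity) and therefore cannot express "yes iff this entity
matches this context" — it provably cannot fit even a two-organism dataset
with disjoint context vocabularies. Training is plain SGD at learning rate
0.01, cross-entropy loss, epoch-shuffled with a seeded generator; two runs
with the same seed produce bit-identical scores.

Fixed defaults: word dimension 50 (seeded random initialization) or the
file's dimension when word2vec-text embeddings are loaded (200 for the
common PubMed sets); position dimension 5; 64 filters; context window 100
tokens centered on the mention; 50 epochs; decision cutoff 0.5. The cutoff
also applies to single-candidate mentions — the scorer may reject a
mention outright (reason `model_reject`), which is what gives the model
presets their precision. Whether "window size 2" means kernel width or
context radius is ambiguous in common usage; it is implemented as kernel
width and configurable. Checkpoints are single-file JSON (config, vocab,
arrays) — slower than binary formats but transparent and diffable at the
model sizes involved.

## Evaluation

Micro-averaged P/R/F1, pooling TP/FP/FN across captions before computing
rates. Mention level: strict (identical spans) or overlap (≥ 1 shared code
point), one-to-one greedy matching in span order — multi-overlap
resolution is underdetermined in the protocol, and greedy-in-order is the
simplest deterministic choice. Normalization level: per-caption sets of
unique IDs, set intersection/difference counts. Type-only annotations
participate at the mention level but are excluded from normalization (they
carry no ID). Zero denominators yield rate 0.

## Synthetic data

The generator emulates the *shape* of caption-annotation corpora, not their
language. Each article gets one home organism; its Introduction optionally
defines the organism's initials as an abbreviation and always pre-links the
scientific name 2–4 times; a body section adds 1–2 more links; captions
(default 4 per article) mention the organism through one of four routes —
standard name, defined abbreviation, synthetic ambiguous alias (a surface
shared between two IDs, resolvable only by majority), or common term — at
configurable rates (defaults: abbreviation 0.5, ambiguity 0.2, common term
0.2, noise 0). Noise corrupts four characters of a long mention, past the
edit budget, emulating an unmatchable variant. All randomness flows from
one seeded generator, so equal seeds give byte-identical collections.

What passing tests on this generator shows: the pipeline stages compose
correctly (end-to-end closure — the majority preset reproduces the gold ID
sets exactly on noise-free, resolvable articles), and degradation is
monotone in the corruption rate. What it does not show: performance on real
captions, whose vocabulary, panel structure, discontinuous text, and
annotation idiosyncrasies the templates do not emulate. Real-corpus scores
require the corresponding annotated corpus and are out of scope here.

Taxonomy IDs in the fixture lexicon are well-known public identifiers;
padding IDs that the fixtures invent are ≥ 10⁷ so they can never collide
with a plausible real ID, and invented surfaces (the `shared-model-*`
aliases, the placeholder plant *Plantula exempli* for ID 3915) are
explicitly synthetic.

## Known limitations

* The verb filter's rule-based tagger is tuned to caption-style English;
  exotic constructions can mislabel tokens (the filter only ever *drops*
  candidates, so errors cost recall, not precision).
* Life-cycle-stage nouns beyond the common-term table (e.g. *PCF*/*BCF*
  as trypanosome forms) need semantic interpretation and are not resolved.
* Discontinuous caption text is treated as one passage; panel boundaries
  are not reconstructed.
* The approximate matcher's length gate means misspellings of short names
  (< 10 characters) are not recovered.
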