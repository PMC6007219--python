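"""Deterministic mini-lexicon and synthetic annotated-corpus generator.

Every component of the pipeline is testable without downloading a taxonomy
dump or an annotated corpus: :func:`make_fixture_lexicon` builds a small
lexicon around taxonomy IDs that recur throughout caption-annotation work
(human 9606, zebrafish 7955, mouse 10090, C. elegans 6239, ...), and
:func:`generate_synthetic_collection` emits BioC articles — an introduction
that defines abbreviations and pre-links organisms, a body section, and
figure captions with gold annotations — together with a ground-truth report
of expected per-article link counts and per-caption ID sets.

Names for IDs whose canonical spelling the fixture does not need verbatim
(e.g. the placeholder plant for the seedling table) and all shared
"ambiguous alias" surfaces are synthetic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bioc import Collection, Document, Passage, SpanAnnotation
from .identify import CommonTermTable, default_common_terms
from .lexicon import Lexicon, expand_base_forms

__all__ = [
    "FixtureSpec",
    "make_fixture_lexicon",
    "generate_synthetic_collection",
    "HOME_ORGANISMS",
]


def make_fixture_lexicon() -> Lexicon:
    """The packaged test lexicon; identical on every call.

    Includes scientific, common, strain, and abbreviation names, two
    genuinely ambiguous surfaces ("Arabidopsis", "S. aureus"), and three
    synthetic alias names shared between two IDs each so that
    majority-rule disambiguation is exercisable.
    """
    rows = [
        (9606, "Homo sapiens", "scientific"),
        (9606, "human", "common"),
        (1280, "Staphylococcus aureus", "scientific"),
        (1280, "MRSA", "abbreviation"),
        (1280, "S. aureus", "abbreviation"),
        (367830, "Staphylococcus aureus USA300", "scientific"),
        (367830, "USA300", "strain"),
        (367830, "S. aureus", "abbreviation"),
        (7955, "Danio rerio", "scientific"),
        (7955, "zebrafish", "common"),
        (10090, "Mus musculus", "scientific"),
        (10090, "mouse", "common"),
        (6239, "Caenorhabditis elegans", "scientific"),
        (6239, "C. elegans", "abbreviation"),
        (9031, "Gallus gallus", "scientific"),
        (9031, "chicken", "common"),
        (7227, "Drosophila melanogaster", "scientific"),
        (90371, "Salmonella enterica subsp. enterica serovar Typhimurium", "scientific"),
        (90371, "Salmonella typhimurium", "scientific"),
        (90371, "S. typhimurium", "abbreviation"),
        (5691, "Trypanosoma brucei", "scientific"),
        (11646, "Lentivirus", "scientific"),
        (11646, "LV", "abbreviation"),
        (3702, "Arabidopsis thaliana", "scientific"),
        (3702, "Arabidopsis", "general"),
        (3701, "Arabidopsis", "scientific"),
        (3915, "Plantula exempli", "scientific"),  # synthetic placeholder name
        # synthetic ambiguous aliases (two IDs per surface)
        (9606, "shared-model-alpha", "general"),
        (10090, "shared-model-alpha", "general"),
        (7955, "shared-model-beta", "general"),
        (6239, "shared-model-beta", "general"),
        (7227, "shared-model-gamma", "general"),
        (7955, "shared-model-gamma", "general"),
    ]
    lex = Lexicon()
    for tid, name, cls in rows:
        lex.add(tid, name, cls)
    return expand_base_forms(lex)


@dataclass(frozen=True)
class _Organism:
    taxon_id: int
    scientific: str
    common: Optional[str]
    alias: Optional[str]  # synthetic ambiguous alias containing this ID
    common_term: Optional[str]  # common-term table key applicable to it


HOME_ORGANISMS: tuple[_Organism, ...] = (
    _Organism(9606, "Homo sapiens", "human", "shared-model-alpha", None),
    _Organism(10090, "Mus musculus", "mouse", "shared-model-alpha", "embryo"),
    _Organism(7955, "Danio rerio", "zebrafish", "shared-model-beta", "embryo"),
    _Organism(6239, "Caenorhabditis elegans", None, "shared-model-beta", "embryo"),
    _Organism(9031, "Gallus gallus", "chicken", None, "embryo"),
    _Organism(7227, "Drosophila melanogaster", None, "shared-model-gamma", "larva"),
    _Organism(5691, "Trypanosoma brucei", None, None, None),
)

_PLURALS = {"embryo": "embryos", "larva": "larvae", "seedling": "seedlings"}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_articles: int = 5
    captions_per_article: int = 4
    ambiguity_rate: float = 0.2
    abbreviation_rate: float = 0.5
    common_term_rate: float = 0.2
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ambiguity_rate", "abbreviation_rate", "common_term_rate",
                     "noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_articles <= 0 or self.captions_per_article <= 0:
            raise ValueError("article and caption counts must be positive")


def _initials(scientific: str) -> str:
    return "".join(w[0].upper() for w in scientific.split())


def _corrupt(name: str, rng: np.random.Generator) -> str:
    """Replace four interior characters so no 3-edit match survives."""
    chars = list(name)
    positions = [i for i in range(1, len(chars) - 1) if chars[i].isalpha()]
    picks = rng.choice(len(positions), size=min(4, len(positions)), replace=False)
    for p in sorted(picks):
        chars[positions[p]] = "q" if chars[positions[p]] != "q" else "x"
    return "".join(chars)


def generate_synthetic_collection(
    spec: FixtureSpec,
    lex: Optional[Lexicon] = None,
    common: Optional[CommonTermTable] = None,
) -> tuple[Collection, dict]:
    """Seeded synthetic articles with gold caption annotations.

    Each article centers on one *home organism*.  Its introduction may
    define the organism's abbreviation (``"<scientific name> (<INITIALS>)"``)
    and always pre-links the scientific name several times; the body adds
    more links.  Captions then mention the organism through one of four
    routes — standard name, defined abbreviation, ambiguous alias resolved
    by majority, or a common term ("embryos") — at the spec's rates.  With
    ``noise_rate`` > 0 a standard-name mention may be corrupted beyond the
    edit budget, emulating an unmatchable spelling variant.

    Returns the collection plus a ground-truth report with, per article,
    the expected pre-linked count of the home ID and per-caption gold ID
    sets and mention kinds.
    """
    if lex is None:
        lex = make_fixture_lexicon()
    if common is None:
        common = default_common_terms()
    rng = np.random.default_rng(spec.seed)
    documents: list[Document] = []
    report: dict = {"articles": {}}
    for a in range(spec.n_articles):
        org = HOME_ORGANISMS[int(rng.integers(len(HOME_ORGANISMS)))]
        use_abbrev = bool(rng.random() < spec.abbreviation_rate)
        abbrev = _initials(org.scientific) if use_abbrev else None
        n_prelink = int(rng.integers(2, 5))
        n_body = int(rng.integers(1, 3))

        intro_sents = []
        if use_abbrev:
            intro_sents.append(
                f"Experiments used the organism {org.scientific} ({abbrev}) throughout."
            )
        intro_sents.extend(
            f"Samples of {org.scientific} at passage {i + 1} served as controls."
            for i in range(n_prelink)
        )
        intro_text = " ".join(intro_sents)
        body_text = " ".join(
            f"Additional {org.scientific} material from batch {i + 1} is described."
            for i in range(n_body)
        )

        passages: list[Passage] = []
        offset = 0

        def add_passage(text: str, label: str,
                        anns: tuple[SpanAnnotation, ...] = ()) -> None:
            nonlocal offset
            passages.append(Passage(offset=offset, text=text,
                                    section_label=label, annotations=anns))
            offset += len(text) + 1

        add_passage(intro_text, "introduction")
        add_passage(body_text, "results")

        expected_count = (2 if use_abbrev else 0) + n_prelink + n_body
        caption_ids: list[list[int]] = []
        caption_kinds: list[str] = []
        for _c in range(spec.captions_per_article):
            kinds = ["standard"]
            if abbrev is not None:
                kinds.append("abbrev")
            if org.alias is not None and rng.random() < spec.ambiguity_rate:
                kinds = ["alias"]
            elif org.common_term is not None and rng.random() < spec.common_term_rate:
                kinds = ["common"]
            kind = kinds[int(rng.integers(len(kinds)))]
            if kind == "standard":
                surface = org.common if (org.common and rng.random() < 0.5) else org.scientific
                noisy = (spec.noise_rate > 0 and len(surface) >= 10
                         and rng.random() < spec.noise_rate)
                shown = _corrupt(surface, rng) if noisy else surface
                text = f"Quantification of {shown} cells at 24 h."
                m_start = text.index(shown)
                m_end = m_start + len(shown)
                if noisy:
                    kind = "noisy"
            elif kind == "abbrev":
                text = f"Confocal imaging of {abbrev} tissue sections."
                m_start = text.index(abbrev)
                m_end = m_start + len(abbrev)
            elif kind == "alias":
                text = f"Phenotype analysis of {org.alias} colonies."
                m_start = text.index(org.alias)
                m_end = m_start + len(org.alias)
            else:  # common term
                plural = _PLURALS[org.common_term]
                shown = plural.capitalize()
                text = f"{shown} at the indicated developmental stages."
                m_start = 0
                m_end = len(shown)
            ann = SpanAnnotation(
                start=offset + m_start,
                end=offset + m_end,
                surface=text[m_start:m_end],
                taxon_id=org.taxon_id,
            )
            add_passage(text, "fig_caption", (ann,))
            caption_ids.append([org.taxon_id])
            caption_kinds.append(kind)
        doc_id = f"synthetic-{spec.seed}-{a:03d}"
        documents.append(Document(doc_id=doc_id, passages=tuple(passages)))
        report["articles"][doc_id] = {
            "home_id": org.taxon_id,
            "expected_prelinked": {org.taxon_id: expected_count},
            "caption_ids": caption_ids,
            "caption_kinds": caption_kinds,
        }
    collection = Collection(source_id=f"synthetic-seed-{spec.seed}",
                            documents=tuple(documents))
    return collection, report
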