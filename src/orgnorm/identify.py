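"""The multistage organism-identification algorithm.

The full text of an article is processed *before* its figure captions, in a
fixed section order — Introduction first, then abstract, then the remaining
body sections — because authors typically give an organism's full name
(often with its abbreviation) the first time it appears.  Everything learned
from the full text is accumulated in a per-article :class:`MetaInfo`:

* ``prelinked_counts`` — how often each taxonomy ID has been successfully
  linked so far, the evidence base for majority-rule disambiguation;
* ``extra_terms`` — article-specific surfaces (abbreviations and their full
  names) that become matchable in addition to the lexicon;
* ``blacklist`` — abbreviation pairs whose long form is *not* an organism
  name, so the short form must never fire as one.

Captions are then scanned with the lexicon graph plus the article's extra
terms; candidate matches that sit on a verb token are discarded, and common
terms such as "embryo" are resolved against the pre-linked counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

from .bioc import Document, Passage
from .lexicon import (
    Lexicon,
    MatchGraph,
    RawMatch,
    base_form,
    build_match_graph,
    scan_text,
)
from .preprocess import detect_abbreviations, split_sentences, tokenize_with_pos

__all__ = [
    "MetaInfo",
    "Mention",
    "CommonTermTable",
    "load_common_terms",
    "default_common_terms",
    "order_sections",
    "build_meta_info",
    "tag_caption",
    "resolve_common_term",
]

_INTRO_LABELS = frozenset({"introduction", "background"})
_ABSTRACT_LABELS = frozenset({"abstract"})
_CAPTION_LABELS = frozenset({"fig_caption", "figure_caption", "caption", "fig", "figure"})


@dataclass
class MetaInfo:
    prelinked_counts: dict[int, int] = field(default_factory=dict)
    first_link_position: dict[int, int] = field(default_factory=dict)
    extra_terms: dict[str, int] = field(default_factory=dict)
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def record_link(self, taxon_id: int, position: int) -> None:
        self.prelinked_counts[taxon_id] = self.prelinked_counts.get(taxon_id, 0) + 1
        self.first_link_position.setdefault(taxon_id, position)

    def blacklisted_short_forms(self) -> set[str]:
        return {sf for _lf, sf in self.blacklist}

    def extra_graph(self) -> Optional[MatchGraph]:
        if not self.extra_terms:
            return None
        g = MatchGraph()
        for surface, tid in self.extra_terms.items():
            g.insert(surface, {tid})
        return g


@dataclass(frozen=True)
class Mention:
    start: int
    end: int
    surface: str
    candidate_ids: frozenset[int]
    resolved_id: Optional[int] = None
    status: str = "ambiguous"  # resolved | ambiguous | dropped | type_only
    drop_reason: Optional[str] = None
    type_only_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "resolved" and self.resolved_id not in self.candidate_ids:
            raise ValueError("resolved_id must be one of candidate_ids")
        if self.status == "dropped" and not self.drop_reason:
            raise ValueError("dropped mentions must record a reason")


CommonTermTable = dict[str, tuple[int, ...]]


def load_common_terms(tsv_text: str) -> CommonTermTable:
    """Parse ``term<TAB>id,id,...`` rows into a common-term table."""
    table: CommonTermTable = {}
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"row {lineno}: expected 2 columns, got {len(parts)}")
        term, ids = parts
        table[term.strip().casefold()] = tuple(int(x) for x in ids.split(","))
    return table


def default_common_terms() -> CommonTermTable:
    """The packaged table: larva, embryo, seedling with their candidate IDs."""
    text = resources.files("orgnorm.data").joinpath("common_terms.tsv").read_text("utf-8")
    return load_common_terms(text)


def _section_rank(label: str) -> int:
    lab = label.casefold().strip()
    if lab in _INTRO_LABELS:
        return 0
    if lab in _ABSTRACT_LABELS:
        return 1
    return 2


def is_caption(p: Passage) -> bool:
    return p.section_label.casefold().strip() in _CAPTION_LABELS


def order_sections(d: Document) -> list[Passage]:
    """Full-text passages in processing order: introduction, abstract, rest.

    Caption passages are excluded — they are tagged separately, after the
    article-level meta information exists.  Within a rank, document order is
    preserved (stable sort).
    """
    body = [p for p in d.passages if not is_caption(p)]
    return sorted(body, key=lambda p: _section_rank(p.section_label))


def _verb_spans(text: str) -> list[tuple[int, int]]:
    return [(t.start, t.end) for t in tokenize_with_pos(text) if t.pos_label == "verb"]


def _overlaps_verb(start: int, end: int, verbs: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in verbs)


def _scan_with_extras(text: str, g: MatchGraph, meta: MetaInfo,
                      max_mismatch: int = 3) -> list[RawMatch]:
    """Scan with the lexicon graph plus the article's extra terms.

    Extra-term matches are exact-only (they were copied verbatim from the
    article) and override lexicon matches on overlap, since they carry
    article-specific evidence.
    """
    matches = scan_text(g, text, max_mismatch=max_mismatch)
    extra = meta.extra_graph()
    if extra is not None:
        extra_matches = scan_text(extra, text, max_mismatch=0)
        keep = [
            m for m in matches
            if not any(m.start < e.end and e.start < m.end for e in extra_matches)
        ]
        matches = sorted(keep + extra_matches, key=lambda m: m.start)
    blacklisted = {s.casefold() for s in meta.blacklisted_short_forms()}
    return [m for m in matches if m.matched_name.casefold() not in blacklisted
            and text[m.start:m.end].casefold() not in blacklisted]


def _majority_pick(candidates: frozenset[int], meta: MetaInfo) -> Optional[int]:
    """Strict-majority candidate by pre-linked count; ties broken by earliest
    first link, then smallest ID; None when all counts are zero."""
    counts = {tid: meta.prelinked_counts.get(tid, 0) for tid in candidates}
    best = max(counts.values())
    if best == 0:
        return None
    top = [tid for tid, c in counts.items() if c == best]
    if len(top) == 1:
        return top[0]
    return min(top, key=lambda tid: (meta.first_link_position.get(tid, float("inf")), tid))


def build_meta_info(d: Document, lex: Lexicon, g: MatchGraph) -> MetaInfo:
    """Process the full text section-by-section into a :class:`MetaInfo`.

    Per section: abbreviation pairs are handled first (a long form whose base
    form is an unambiguous lexicon name registers both forms as extra terms;
    otherwise the pair is blacklisted), then the section is scanned.
    Unambiguous matches increment the pre-linked count of their ID;
    ambiguous matches are resolved against the counts accumulated *so far*
    and only counted when a strict majority exists.
    """
    meta = MetaInfo()
    name_index = lex.name_index
    for p in order_sections(d):
        text = p.text
        for s_start, s_end in split_sentences(text):
            for pair in detect_abbreviations(text[s_start:s_end]):
                lf, sf = pair.long_form, pair.short_form
                if (lf, sf) in meta.blacklist or sf in meta.extra_terms:
                    continue
                ids = name_index.get(base_form(lf), set()) | name_index.get(lf, set())
                if len(ids) == 1:
                    (tid,) = ids
                    meta.extra_terms[lf] = tid
                    meta.extra_terms[sf] = tid
                else:
                    meta.blacklist.add((lf, sf))
        verbs = _verb_spans(text)
        for m in _scan_with_extras(text, g, meta):
            if _overlaps_verb(m.start, m.end, verbs):
                continue
            position = p.offset + m.start
            if len(m.candidate_ids) == 1:
                (tid,) = m.candidate_ids
                meta.record_link(tid, position)
            else:
                tid = _majority_pick(m.candidate_ids, meta)
                if tid is not None:
                    meta.record_link(tid, position)
    return meta


def resolve_common_term(term: str, meta: MetaInfo, common: CommonTermTable,
                        span: tuple[int, int] = (0, 1), surface: Optional[str] = None) -> Mention:
    """Resolve a common term ("embryos") against the article's evidence.

    All table candidates are considered; the one with the most pre-linked
    occurrences wins.  When no candidate has been pre-linked, the mention is
    kept as a type-only organism annotation rather than guessed.
    """
    key = base_form(term)
    if key not in common:
        raise ValueError(f"{term!r} is not a known common term")
    candidates = frozenset(common[key])
    tid = _majority_pick(candidates, meta)
    surface = surface if surface is not None else term
    if tid is None:
        return Mention(span[0], span[1], surface, candidates,
                       status="type_only", type_only_label="organism")
    return Mention(span[0], span[1], surface, candidates,
                   resolved_id=tid, status="resolved")


def tag_caption(
    p: Passage,
    meta: MetaInfo,
    g: MatchGraph,
    common: Optional[CommonTermTable] = None,
    max_mismatch: int = 3,
) -> list[Mention]:
    """Tag one caption passage, returning mentions in span order.

    Lexicon and extra-term matches overlapping a verb token are dropped with
    reason ``pos_filter``.  Tokens whose base form is a common term are
    routed through :func:`resolve_common_term`, with an adjacency override:
    an organism mention within two tokens before the common term ("zebrafish
    embryos") fixes the ID when it is among the table candidates.  Ambiguous
    lexicon mentions are left unresolved for the disambiguation stage.
    Spans are caption-local (relative to ``p.text``).
    """
    if common is None:
        common = default_common_terms()
    text = p.text
    tokens = tokenize_with_pos(text)
    verbs = [(t.start, t.end) for t in tokens if t.pos_label == "verb"]
    mentions: list[Mention] = []
    matched_spans: list[tuple[int, int]] = []
    for m in _scan_with_extras(text, g, meta, max_mismatch=max_mismatch):
        if base_form(text[m.start:m.end]) in common:
            continue  # handled by the common-term route below
        if _overlaps_verb(m.start, m.end, verbs):
            mentions.append(Mention(m.start, m.end, text[m.start:m.end], m.candidate_ids,
                                    status="dropped", drop_reason="pos_filter"))
            continue
        matched_spans.append((m.start, m.end))
        if len(m.candidate_ids) == 1:
            (tid,) = m.candidate_ids
            mentions.append(Mention(m.start, m.end, text[m.start:m.end], m.candidate_ids,
                                    resolved_id=tid, status="resolved"))
        else:
            mentions.append(Mention(m.start, m.end, text[m.start:m.end], m.candidate_ids))
    for i, tok in enumerate(tokens):
        key = base_form(tok.surface)
        if key not in common:
            continue
        if any(tok.start < e and s < tok.end for s, e in matched_spans):
            continue
        if _overlaps_verb(tok.start, tok.end, verbs):
            continue
        mention = resolve_common_term(tok.surface, meta, common,
                                      span=(tok.start, tok.end))
        override = _adjacent_organism_id(tokens, i, mentions)
        if override is not None and override in mention.candidate_ids:
            mention = replace(mention, resolved_id=override, status="resolved",
                              type_only_label=None)
        mentions.append(mention)
    return sorted(mentions, key=lambda m: (m.start, m.end))


def _adjacent_organism_id(tokens, idx: int, mentions: list[Mention]) -> Optional[int]:
    """Resolved organism ID of a mention covering one of the two tokens
    directly before token ``idx`` ("zebrafish embryos"), if any."""
    for j in range(max(0, idx - 2), idx):
        tok = tokens[j]
        for m in mentions:
            if m.status == "resolved" and m.start <= tok.start and tok.end <= m.end:
                return m.resolved_id
    return None
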