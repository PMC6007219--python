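"""Taxonomy lexicon, base-form expansion, and word-graph text scanning.

A lexicon maps NCBI Taxonomy IDs to sets of organism names (scientific names,
common names, strain designations, abbreviations, general terms).  The
inverted ``name_index`` maps each surface form — and each generated base
form — to the set of IDs it may denote; a name indexed under more than one
ID is *ambiguous* and must be resolved downstream.

Matching compiles every name into a character-level word graph (a trie; the
contract is the accepted language, not the topology) and scans text for
matches anchored at token boundaries.  Long names are additionally matched
approximately, tolerating up to three character edits, so that minor
spelling variants of strain and scientific names ("Salmonela typhimurium")
are still recognized.

Matching policy
---------------
* Names of >= 5 code points match case-insensitively; shorter names match
  case-sensitively (protects abbreviations such as "LV" or "SIN").
* Approximate (Levenshtein <= ``max_mismatch``) matching applies only to
  names of >= 10 code points; short names would otherwise match almost
  anything.  Both gates are module constants and can be overridden per call.
* Matches must start and end at token boundaries ("rat" never fires inside
  "strategy").  Overlaps are resolved with exactness dominating (an exact
  match always beats an approximate one it overlaps), then longest-first,
  then by start position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "MatchGraph",
    "RawMatch",
    "load_lexicon",
    "expand_base_forms",
    "base_form",
    "build_match_graph",
    "scan_text",
    "token_boundaries",
    "NAME_CLASSES",
]

NAME_CLASSES = frozenset({"scientific", "common", "strain", "abbreviation", "general"})

#: Names at least this long match case-insensitively.
CASEFOLD_MIN_LEN = 5
#: Names at least this long are eligible for approximate matching.
APPROX_MIN_LEN = 10


@dataclass
class LexiconEntry:
    taxon_id: int
    names: set[tuple[str, str]] = field(default_factory=set)  # (surface, name_class)
    base_forms: set[str] = field(default_factory=set)

    def surfaces(self) -> set[str]:
        return {s for s, _ in self.names} | self.base_forms

    def scientific_name(self) -> Optional[str]:
        sci = sorted(s for s, cls in self.names if cls == "scientific")
        return sci[0] if sci else None


@dataclass
class Lexicon:
    entries: dict[int, LexiconEntry] = field(default_factory=dict)

    @property
    def name_index(self) -> dict[str, set[int]]:
        idx: dict[str, set[int]] = {}
        for tid, entry in self.entries.items():
            for surface in entry.surfaces():
                idx.setdefault(surface, set()).add(tid)
        return idx

    def is_ambiguous(self, name: str) -> bool:
        return len(self.name_index.get(name, ())) > 1

    def add(self, taxon_id: int, name: str, name_class: str = "general") -> None:
        if taxon_id <= 0:
            raise ValueError(f"taxon_id must be positive, got {taxon_id}")
        if name_class not in NAME_CLASSES:
            raise ValueError(f"unknown name class {name_class!r}")
        entry = self.entries.setdefault(taxon_id, LexiconEntry(taxon_id))
        entry.names.add((name, name_class))


def load_lexicon(tsv_text: str) -> Lexicon:
    """Load a lexicon from ``taxon_id<TAB>name<TAB>name_class`` rows.

    UTF-8, no header; lines starting with ``#`` are comments.  Duplicate
    (id, name) rows collapse; the same name under different IDs is indexed
    under all of them (and thereby ambiguous).
    """
    lex = Lexicon()
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"row {lineno}: expected 3 tab-separated columns, got {len(parts)}")
        tid_text, name, name_class = parts
        try:
            tid = int(tid_text)
        except ValueError:
            raise ValueError(f"row {lineno}: non-integer taxon ID {tid_text!r}") from None
        if name_class not in NAME_CLASSES:
            raise ValueError(f"row {lineno}: unknown name class {name_class!r}")
        lex.add(tid, name, name_class)
    return lex


# Irregular plurals seen in organism terminology; checked before suffix rules.
_IRREGULAR_PLURALS = {
    "larvae": "larva",
    "pupae": "pupa",
    "antennae": "antenna",
    "mice": "mouse",
    "lice": "louse",
    "fungi": "fungus",
    "nuclei": "nucleus",
    "bacteria": "bacterium",
    "feet": "foot",
    "geese": "goose",
    "ova": "ovum",
}

# Words ending in -s (or matching a suffix rule) that are already singular.
_PLURAL_EXCEPTIONS = {
    "species", "mus", "aureus", "virus", "elegans", "sapiens", "musculus",
    "thaliana", "gallus", "rerio", "brucei", "laevis", "dps", "this", "anopheles",
}


def base_form(word: str) -> str:
    """Lowercased singular form of a term, by irregular table then suffix rules.

    Multiword terms base-form their final word only ("zebrafish embryos" ->
    "zebrafish embryo").
    """
    w = word.casefold()
    if " " in w:
        head, _, last = w.rpartition(" ")
        return f"{head} {base_form(last)}"
    if w in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[w]
    if w in _PLURAL_EXCEPTIONS or len(w) <= 3:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith(("ses", "xes", "zes", "ches", "shes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def expand_base_forms(lex: Lexicon) -> Lexicon:
    """Add the base form of every name to its entry (in place; returns ``lex``).

    Original names are untouched; base forms join the name index so that
    e.g. "embryos" in text also reaches entries registered under "embryo".
    """
    for entry in lex.entries.values():
        for surface, _cls in list(entry.names):
            entry.base_forms.add(base_form(surface))
    return lex


def _fold(text: str) -> str:
    """Length-preserving lowercase fold (keeps offsets aligned with the original)."""
    return "".join(c if len(c.lower()) != 1 else c.lower() for c in text)


@dataclass
class _TrieNode:
    children: dict[str, "_TrieNode"] = field(default_factory=dict)
    # (original name, frozenset of taxon IDs) for names accepted here
    accepts: list[tuple[str, frozenset[int]]] = field(default_factory=list)


class MatchGraph:
    """Character word graph over a lexicon's names and base forms.

    Two tries: a case-insensitive one over casefolded long names and a
    case-sensitive one over short names.  The accepted language is exactly
    ``names ∪ base_forms``; :meth:`accepts` checks membership directly.
    """

    def __init__(self) -> None:
        self._ci_root = _TrieNode()
        self._cs_root = _TrieNode()
        self._n_names = 0

    @property
    def n_names(self) -> int:
        return self._n_names

    def insert(self, name: str, taxon_ids: Iterable[int]) -> None:
        ids = frozenset(taxon_ids)
        if not name or not ids:
            return
        if len(name) >= CASEFOLD_MIN_LEN:
            root, key = self._ci_root, _fold(name)
        else:
            root, key = self._cs_root, name
        node = root
        for ch in key:
            node = node.children.setdefault(ch, _TrieNode())
        node.accepts.append((name, ids))
        self._n_names += 1

    def accepts(self, text: str) -> frozenset[int]:
        """Taxon-ID set for ``text`` if it is an accepted name, else empty."""
        out: set[int] = set()
        for root, key in ((self._ci_root, _fold(text)), (self._cs_root, text)):
            node = root
            for ch in key:
                node = node.children.get(ch)
                if node is None:
                    break
            else:
                for _name, ids in node.accepts:
                    out |= ids
        return frozenset(out)


def build_match_graph(lex: Lexicon) -> MatchGraph:
    """Compile a lexicon (names plus base forms) into a :class:`MatchGraph`."""
    g = MatchGraph()
    for name, ids in lex.name_index.items():
        g.insert(name, ids)
    return g


@dataclass(frozen=True)
class RawMatch:
    start: int
    end: int
    matched_name: str
    candidate_ids: frozenset[int]
    edit_cost: int = 0


_TOKEN_RE = re.compile(r"\w+(?:[-'’.]\w+)*|[^\w\s]", re.UNICODE)


def token_boundaries(text: str) -> tuple[set[int], set[int]]:
    """(start, end) boundary position sets for token-anchored matching."""
    starts, ends = set(), set()
    for m in _TOKEN_RE.finditer(text):
        starts.add(m.start())
        ends.add(m.end())
        # interior boundaries at hyphens/periods so "GFP-LV" exposes "LV"
        for i in range(m.start() + 1, m.end()):
            if text[i - 1] in "-.’'":
                starts.add(i)
            if text[i] in "-.’'":
                ends.add(i)
    return starts, ends


def _exact_walk(root: _TrieNode, key: str, pos: int, raw_start: int,
                valid_ends: set[int], out: list[RawMatch]) -> None:
    node = root
    i = pos
    while i < len(key):
        node = node.children.get(key[i])
        if node is None:
            return
        i += 1
        if node.accepts and raw_start + (i - pos) in valid_ends:
            end = raw_start + (i - pos)
            for name, ids in node.accepts:
                out.append(RawMatch(raw_start, end, name, ids, 0))


def _approx_walk(root: _TrieNode, key: str, pos: int, raw_start: int,
                 valid_ends: set[int], budget: int, min_name_len: int,
                 out: list[RawMatch]) -> None:
    """Bounded-edit DFS over the trie: substitutions, insertions, deletions."""
    # visited keeps the fewest edits seen per (node, text position)
    best: dict[tuple[int, int], int] = {}
    stack = [(root, pos, 0, 0)]  # node, text idx, edits, depth-in-name
    while stack:
        node, i, edits, depth = stack.pop()
        state = (id(node), i)
        if best.get(state, budget + 1) <= edits:
            continue
        best[state] = edits
        if node.accepts and edits > 0:
            end = raw_start + (i - pos)
            if end in valid_ends and end > raw_start:
                for name, ids in node.accepts:
                    if len(name) >= min_name_len:
                        out.append(RawMatch(raw_start, end, name, ids, edits))
        for ch, child in node.children.items():
            if i < len(key):
                cost = 0 if key[i] == ch else 1
                if edits + cost <= budget:
                    stack.append((child, i + 1, edits + cost, depth + 1))
            # deletion from text's perspective (name char unmatched)
            if edits + 1 <= budget:
                stack.append((child, i, edits + 1, depth + 1))
        # insertion: skip a text char
        if i < len(key) and edits + 1 <= budget:
            stack.append((node, i + 1, edits + 1, depth))


def scan_text(
    g: MatchGraph,
    text: str,
    max_mismatch: int = 3,
    *,
    approx_min_len: int = APPROX_MIN_LEN,
) -> list[RawMatch]:
    """Find all organism-name matches in ``text``, anchored at token boundaries.

    Exact matches against both tries at every token start; approximate
    matches (edit distance <= ``max_mismatch``) against the case-insensitive
    trie for names of >= ``approx_min_len`` code points.  Overlaps are
    resolved by lowest edit cost, then longest span, then start position.
    Returned matches are non-overlapping and ordered by start.
    """
    if max_mismatch > 3:
        raise ValueError("mismatch budget above 3 is not supported")
    starts, ends = token_boundaries(text)
    folded = _fold(text)
    candidates: list[RawMatch] = []
    for s in sorted(starts):
        _exact_walk(g._ci_root, folded, s, s, ends, candidates)
        _exact_walk(g._cs_root, text, s, s, ends, candidates)
        if max_mismatch > 0:
            _approx_walk(g._ci_root, folded, s, s, ends, max_mismatch,
                         approx_min_len, candidates)
    # merge distinct names covering the same span at the same cost
    by_span: dict[tuple[int, int, int], RawMatch] = {}
    for m in candidates:
        key = (m.start, m.end, m.edit_cost)
        cur = by_span.get(key)
        if cur is None:
            by_span[key] = m
        else:
            by_span[key] = RawMatch(
                m.start, m.end, min(m.matched_name, cur.matched_name),
                cur.candidate_ids | m.candidate_ids, m.edit_cost,
            )
    # per start keep the best: exact over approximate, then longest span
    by_start: dict[int, RawMatch] = {}
    for m in by_span.values():
        cur = by_start.get(m.start)
        if cur is None or (m.edit_cost, -(m.end - m.start), -len(m.matched_name)) < (
            cur.edit_cost, -(cur.end - cur.start), -len(cur.matched_name)
        ):
            by_start[m.start] = m
    # greedy non-overlap: exactness dominates, then longest-first
    chosen: list[RawMatch] = []
    for m in sorted(by_start.values(), key=lambda m: (m.edit_cost, -(m.end - m.start), m.start)):
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.start)
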