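"""Sentence splitting, tokenization with lightweight part-of-speech labels,
and full-name/abbreviation pair detection.

These are deliberately small, rule-based components: the pipeline only needs
(a) sentence units for abbreviation detection, (b) token boundaries and a
"is this token a verb?" signal for filtering false-positive matches, and
(c) parenthetical long-form/short-form pairs in the Schwartz–Hearst style.
None of them aims at full-coverage English analysis, and each is replaceable
behind its function signature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Token",
    "AbbrevPair",
    "split_sentences",
    "tokenize_with_pos",
    "detect_abbreviations",
]


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str
    pos_label: str  # "noun" | "verb" | "other"


@dataclass(frozen=True)
class AbbrevPair:
    long_form: str
    long_span: tuple[int, int]
    short_form: str
    short_span: tuple[int, int]


def _load_protected() -> frozenset[str]:
    text = resources.files("orgnorm.data").joinpath("protected_abbrev.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


_PROTECTED = _load_protected()
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans (start, end), partitioning the non-whitespace text.

    A period does not end a sentence when it follows a single capital letter
    (genus abbreviations: "S. typhimurium") or a protected abbreviation
    ("et al.", "subsp.", "Fig.").
    """
    breaks = []
    for m in _BOUNDARY_RE.finditer(text):
        prev = text[: m.end()].rstrip(".!?")
        last_word = prev.split()[-1] if prev.split() else ""
        last_word = last_word.lstrip("([{\"'‘“")
        if re.fullmatch(r"[A-Z]", last_word):
            continue  # "S." — single-capital genus abbreviation
        if last_word.casefold() in _PROTECTED:
            continue
        breaks.append(m.end())
    spans = []
    start = 0
    for b in breaks + [len(text)]:
        chunk = text[start:b]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lstrip, b - rstrip))
        start = b
    return spans


# Closed-class verbs and common caption-style verbs; lowercase.
_VERB_LEXICON = frozenset({
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "having",
    "do", "does", "did", "done", "doing",
    "can", "could", "may", "might", "must", "shall", "should", "will", "would",
    "show", "shows", "shown", "showed", "indicate", "indicates", "indicated",
    "express", "expresses", "expressed", "reveal", "reveals", "revealed",
    "demonstrate", "demonstrates", "demonstrated", "represent", "represents",
    "represented", "use", "uses", "used", "perform", "performs", "performed",
    "treat", "treats", "treated", "infect", "infects", "infected",
    "incubate", "incubated", "stain", "stained", "fix", "fixed",
    "transfect", "transfected", "inject", "injected", "image", "imaged",
    "measure", "measured", "quantify", "quantified", "analyze", "analyzed",
    "analyse", "analysed", "compare", "compared", "observe", "observed",
})

# -ed/-ing endings that are nouns/adjectives in caption text, not verbs.
_VERBLIKE_NOUN_EXCEPTIONS = frozenset({
    "seed", "need", "breed", "feed", "speed", "indeed", "red", "bed",
    "wild", "embed", "naked", "infrared", "thing", "spring", "string",
    "ring", "wing", "king", "offspring", "during", "staining",
})

_TOKEN_RE = re.compile(r"\w+(?:[-'’]\w+)*|[^\w\s]", re.UNICODE)


def _pos_of(surface: str, prev: str | None) -> str:
    if not any(c.isalpha() for c in surface):
        return "other"
    low = surface.lower()
    if low in _VERB_LEXICON:
        return "verb"
    if low in _VERBLIKE_NOUN_EXCEPTIONS or surface[0].isupper():
        return "noun"
    # morphological cue: -ed/-ing after an auxiliary, or bare -ed past tense
    if len(low) >= 5 and low.endswith("ed"):
        return "verb"
    if len(low) >= 6 and low.endswith("ing") and prev in _VERB_LEXICON:
        return "verb"
    return "noun"


def tokenize_with_pos(text: str) -> list[Token]:
    """Tokens over maximal alphanumeric/hyphenated runs plus punctuation.

    The label set is {noun, verb, other}; only the verb distinction is load
    bearing (matches overlapping verbs are later discarded).  Unknown
    capitalized or biomedical tokens default to noun.
    """
    tokens: list[Token] = []
    prev_surface: str | None = None
    for m in _TOKEN_RE.finditer(text):
        pos = _pos_of(m.group(), prev_surface)
        tokens.append(Token(m.start(), m.end(), m.group(), pos))
        prev_surface = m.group().lower()
    return tokens


_MAX_SHORT_LEN = 10
_GENUS_SHORT_RE = re.compile(r"^[A-Z]\.\s?\w[\w-]*$")


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= _MAX_SHORT_LEN) and not _GENUS_SHORT_RE.match(sf):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _find_best_long_form(long_text: str, short: str) -> int | None:
    """Schwartz–Hearst right-to-left alignment; returns the index in
    ``long_text`` where the aligned long form starts, or None."""
    s_idx = len(short) - 1
    l_idx = len(long_text) - 1
    while s_idx >= 0:
        c = short[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            long_text[l_idx].lower() != c
            or (s_idx == 0 and l_idx > 0 and
                (long_text[l_idx - 1].isalnum() or long_text[l_idx - 1] in "-‐–"))
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    return l_idx + 1


def _reversed_pair_valid(long_text: str, short: str) -> bool:
    """Looser letter matching for the ``SHORT (long form)`` pattern.

    The short form's first letter must start a word of the long form, and at
    least half of its letters must appear, in order, in the long form.
    Initialisms over non-head words ("BCF" for "the bloodstream form") then
    still qualify; genuinely unrelated pairs are weeded out later when their
    long form fails the lexicon lookup and the pair is blacklisted.
    """
    letters = [c.lower() for c in short if c.isalpha()]
    if not letters:
        return False
    initials = {w[0].lower() for w in re.findall(r"\w+", long_text)}
    if letters[0] not in initials:
        return False
    # longest common subsequence between the short form's letters and the text
    text = long_text.lower()
    prev = [0] * (len(text) + 1)
    for c in letters:
        cur = [0]
        for j, t in enumerate(text, 1):
            cur.append(max(cur[-1], prev[j], prev[j - 1] + (t == c)))
        prev = cur
    return prev[-1] * 2 >= len(letters)


def _long_candidate_start(text: str, open_paren: int, short: str) -> int:
    """Start of the window of up to min(|sf|+5, |sf|*2) words before '('."""
    max_words = min(len(short) + 5, len(short) * 2)
    words = list(re.finditer(r"\S+", text[:open_paren]))
    if not words:
        return open_paren
    window = words[-max_words:] if max_words > 0 else []
    start = window[0].start() if window else open_paren
    # the candidate never crosses a clause boundary
    for stop in ";:!?":
        p = text.rfind(stop, start, open_paren)
        if p != -1:
            start = p + 1
    return start


def _genus_long_form(candidate: str, short: str) -> tuple[int, int] | None:
    """Long-form span for a genus-style short form like "S. typhimurium".

    The species epithet must occur as a word in the candidate; the long form
    runs from a preceding word starting with the genus initial — the leftmost
    capitalized one ("Salmonella", not "serovar"), falling back to the
    nearest case-insensitive hit.
    """
    initial = short[0]
    epithet = short.split()[-1] if " " in short else short.split(".", 1)[1].strip()
    words = list(re.finditer(r"[\w-]+", candidate))
    for j in range(len(words) - 1, -1, -1):
        if words[j].group().casefold() == epithet.casefold():
            capitalized = [i for i in range(j + 1)
                           if words[i].group()[0] == initial.upper()]
            if capitalized:
                return words[capitalized[0]].start(), words[j].end()
            for i in range(j, -1, -1):
                if words[i].group()[0].lower() == initial.lower():
                    return words[i].start(), words[j].end()
            return None
    return None


def detect_abbreviations(sentence: str) -> list[AbbrevPair]:
    """Find (long form, short form) pairs from parenthetical patterns.

    Handles both ``long form (SHORT)`` — the long form located by
    right-to-left character alignment from the short form — and
    ``SHORT (long form)``, where the preceding token is the short form and
    the parenthetical text is the long form.  Genus-style abbreviations
    ("Salmonella ... Typhimurium (S. Typhimurium)") are accepted as short
    forms regardless of length, with the long form spanning from the
    genus-initial word through the epithet word.
    """
    pairs: list[AbbrevPair] = []
    for m in re.finditer(r"\(([^()]+)\)", sentence):
        inner = m.group(1).strip()
        inner_start = m.start(1) + (len(m.group(1)) - len(m.group(1).lstrip()))
        open_paren = m.start()
        if _valid_short_form(inner):
            # pattern: long form (SHORT)
            cand_start = _long_candidate_start(sentence, open_paren, inner)
            candidate = sentence[cand_start:open_paren]
            lead_ws = len(candidate) - len(candidate.lstrip())
            candidate = candidate.strip()
            cand_start += lead_ws
            if not candidate:
                continue
            if _GENUS_SHORT_RE.match(inner):
                span = _genus_long_form(candidate, inner)
                if span is None:
                    continue
                rel, rel_end = span
                long_form = candidate[rel:rel_end]
            else:
                rel = _find_best_long_form(candidate, inner)
                if rel is None:
                    continue
                long_form = candidate[rel:]
                if len(long_form) <= len(inner):
                    continue
            long_start = cand_start + rel
            pairs.append(AbbrevPair(
                long_form=long_form,
                long_span=(long_start, long_start + len(long_form)),
                short_form=inner,
                short_span=(inner_start, inner_start + len(inner)),
            ))
        else:
            # pattern: SHORT (long form) — token before '(' is the short form
            before = sentence[:open_paren].rstrip()
            wm = re.search(r"(\S+)$", before)
            if not wm:
                continue
            sf = wm.group(1)
            if not _valid_short_form(sf) or len(inner) <= len(sf):
                continue
            if not _reversed_pair_valid(inner, sf):
                continue
            pairs.append(AbbrevPair(
                long_form=inner,
                long_span=(inner_start, inner_start + len(inner)),
                short_form=sf,
                short_span=(wm.start(1), wm.end(1)),
            ))
    return pairs
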