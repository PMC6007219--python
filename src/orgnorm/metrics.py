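"""Span-level and normalization-level micro-averaged precision/recall/F1.

Mention-level scoring compares predicted spans with gold spans per caption
under either the *strict* criterion (identical boundaries) or the *overlap*
criterion (at least one shared code point), with one-to-one greedy matching
in span order.  Normalization-level scoring compares the per-caption sets of
unique taxonomy IDs.  All counts are pooled across captions before rates are
computed (micro-averaging); a zero denominator yields a rate of 0, the usual
convention in NER evaluation.

Type-only annotations (an organism class without a taxonomy ID) take part
in mention-level scoring but are excluded from normalization scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .bioc import SpanAnnotation

__all__ = ["PRF", "score_mentions", "score_normalization"]


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


Span = tuple[int, int]


def _spans(anns: Sequence[SpanAnnotation | Span]) -> list[Span]:
    out = []
    for a in anns:
        if isinstance(a, SpanAnnotation):
            out.append((a.start, a.end))
        else:
            s, e = a
            if s >= e:
                raise ValueError(f"inconsistent span [{s},{e})")
            out.append((int(s), int(e)))
    return sorted(out)


def _match_caption(pred: list[Span], gold: list[Span], mode: str) -> PRF:
    unmatched = list(gold)
    tp = 0
    for ps, pe in pred:
        hit = None
        for i, (gs, ge) in enumerate(unmatched):
            if mode == "strict":
                ok = ps == gs and pe == ge
            else:
                ok = ps < ge and gs < pe
            if ok:
                hit = i
                break
        if hit is not None:
            unmatched.pop(hit)
            tp += 1
    return PRF(tp=tp, fp=len(pred) - tp, fn=len(unmatched))


def score_mentions(
    pred: Iterable[Sequence[SpanAnnotation | Span]],
    gold: Iterable[Sequence[SpanAnnotation | Span]],
    mode: str = "strict",
) -> PRF:
    """Micro PRF over parallel per-caption annotation sequences.

    ``mode`` is ``"strict"`` (identical spans) or ``"overlap"`` (any shared
    code point); matching is one-to-one, greedy in span order.
    """
    if mode not in ("strict", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    pred, gold = list(pred), list(gold)
    if len(pred) != len(gold):
        raise ValueError("pred and gold must have the same number of captions")
    total = PRF(0, 0, 0)
    for p_anns, g_anns in zip(pred, gold):
        total = total + _match_caption(_spans(p_anns), _spans(g_anns), mode)
    return total


def score_normalization(
    pred: Iterable[Iterable[int]],
    gold: Iterable[Iterable[int]],
) -> PRF:
    """Micro PRF over per-caption sets of unique taxonomy IDs."""
    pred, gold = list(pred), list(gold)
    if len(pred) != len(gold):
        raise ValueError("pred and gold must have the same number of captions")
    total = PRF(0, 0, 0)
    for p_ids, g_ids in zip(pred, gold):
        ps, gs = set(p_ids), set(g_ids)
        total = total + PRF(tp=len(ps & gs), fp=len(ps - gs), fn=len(gs - ps))
    return total
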