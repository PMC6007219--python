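"""End-to-end tagging: full text → meta info → caption mentions → annotations.

:func:`tag_collection` wires the stages together for whole collections and
is what the command-line ``tag`` command and the run presets call.  The
presets mirror the three standard operating points:

* ``run1`` — majority-rule disambiguation, candidate threshold 2;
* ``run2`` — neural scorer, threshold 10;
* ``run3`` — neural scorer, no threshold (the model alone decides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .bioc import Collection, Document, Passage, SpanAnnotation
from .disambig import DisambiguationModel, apply_threshold_filter, majority_resolve, model_resolve
from .identify import MetaInfo, Mention, CommonTermTable, build_meta_info, default_common_terms, is_caption, tag_caption
from .lexicon import Lexicon, build_match_graph

__all__ = ["RunConfig", "PRESETS", "tag_collection", "tag_document"]


@dataclass(frozen=True)
class RunConfig:
    disambiguator: str = "majority"  # majority | model
    threshold: float = 2
    model: Optional[DisambiguationModel] = None
    max_mismatch: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disambiguator not in ("majority", "model"):
            raise ValueError(f"unknown disambiguator {self.disambiguator!r}")
        if self.disambiguator == "model" and self.model is None:
            raise ValueError("model disambiguation requires a trained model")


def PRESETS(name: str, model: Optional[DisambiguationModel] = None) -> RunConfig:
    """The named operating points; ``model`` is required for run2/run3."""
    if name == "run1":
        return RunConfig(disambiguator="majority", threshold=2)
    if name == "run2":
        return RunConfig(disambiguator="model", threshold=10, model=model)
    if name == "run3":
        return RunConfig(disambiguator="model", threshold=math.inf, model=model)
    raise ValueError(f"unknown preset {name!r}")


def _finalize(mentions: list[Mention], text: str, cfg: RunConfig,
              meta: MetaInfo, lex: Lexicon, stats: dict[str, int]) -> list[Mention]:
    if cfg.disambiguator == "majority":
        mentions = [majority_resolve(m, meta) if m.status == "ambiguous" else m
                    for m in mentions]
        mentions = apply_threshold_filter(mentions, cfg.threshold)
    else:
        mentions = apply_threshold_filter(mentions, cfg.threshold)
        mentions = [
            model_resolve(m, text, cfg.model, lex) if m.status in ("ambiguous", "resolved")
            else m
            for m in mentions
        ]
    for m in mentions:
        if m.status == "dropped":
            stats[m.drop_reason] = stats.get(m.drop_reason, 0) + 1
    return mentions


def tag_document(
    captions: Document,
    fulltext: Optional[Document],
    lex: Lexicon,
    cfg: RunConfig,
    common: Optional[CommonTermTable] = None,
    stats: Optional[dict[str, int]] = None,
) -> Document:
    """Tag the caption passages of one document; returns it re-annotated.

    When ``fulltext`` is None the pipeline degrades to lexicon-only tagging
    with empty meta information.
    """
    if common is None:
        common = default_common_terms()
    if stats is None:
        stats = {}
    g = build_match_graph(lex)
    meta = build_meta_info(fulltext, lex, g) if fulltext is not None else MetaInfo()
    has_caption_labels = any(is_caption(q) for q in captions.passages)
    new_passages = []
    for p in captions.passages:
        # with explicit caption labels only captions are tagged; a file of
        # unlabeled passages is treated as captions throughout
        if has_caption_labels and not is_caption(p):
            new_passages.append(p)
            continue
        mentions = tag_caption(p, meta, g, common, max_mismatch=cfg.max_mismatch)
        for m in mentions:
            if m.status == "dropped":
                stats[m.drop_reason] = stats.get(m.drop_reason, 0) + 1
        live = [m for m in mentions if m.status != "dropped"]
        live = _finalize(live, p.text, cfg, meta, lex, stats)
        anns = tuple(
            SpanAnnotation(
                start=p.offset + m.start,
                end=p.offset + m.end,
                surface=m.surface,
                taxon_id=m.resolved_id if m.status == "resolved" else None,
                type_only_label=m.type_only_label if m.status == "type_only" else None,
            )
            for m in live
            if m.status in ("resolved", "type_only")
        )
        new_passages.append(replace(p, annotations=anns))
    return replace(captions, passages=tuple(new_passages))


def tag_collection(
    captions: Collection,
    fulltext: Optional[Collection],
    lex: Lexicon,
    cfg: RunConfig,
    common: Optional[CommonTermTable] = None,
) -> tuple[Collection, dict[str, int]]:
    """Tag every document of a caption collection.

    Full-text documents are matched to caption documents by identifier; a
    caption document without full text is tagged in degraded (lexicon-only)
    mode.  Returns the annotated collection and the per-stage drop counts.
    """
    ft_by_id = {d.doc_id: d for d in fulltext.documents} if fulltext is not None else {}
    stats: dict[str, int] = {}
    documents = tuple(
        tag_document(d, ft_by_id.get(d.doc_id), lex, cfg, common, stats)
        for d in captions.documents
    )
    return replace(captions, documents=documents), stats
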