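"""Disambiguation of ambiguous organism mentions.

Two strategies, mirroring the run presets:

* **Majority rule** — pick the candidate ID with the most pre-linked
  occurrences in the article's meta information (ties: earliest first link,
  then smallest ID).  Mentions that remain ambiguous can be removed by a
  candidate-count threshold.
* **Neural yes/no scorer** — a small convolutional model over the caption
  context.  Each candidate (mention, taxonomy ID) pair is scored as a binary
  decision.  A context token is the concatenation of a word embedding and a
  *position* embedding encoding its signed distance from the mention (the
  mention itself sits at distance 0); a width-``kernel_width`` convolution
  with max-pooling summarizes the context, an entity channel averages the
  word embeddings of the candidate's scientific name, and an affine map with
  a softmax yields P(yes), P(no).  Out-of-vocabulary words map to a reserved
  ``OOV`` token.  Defaults: learning rate 0.01, kernel width 2; word
  dimension 50 with seeded random initialization, or the file's dimension
  (typically 200) when pre-trained word2vec-text embeddings are loaded.

The model is implemented directly in numpy (forward and backward passes,
plain SGD); it is deliberately compact and exactly reproducible from a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .identify import MetaInfo, Mention, _majority_pick
from .lexicon import Lexicon
from .preprocess import tokenize_with_pos

__all__ = [
    "DisambiguationExample",
    "ModelConfig",
    "DisambiguationModel",
    "majority_resolve",
    "apply_threshold_filter",
    "build_disambiguation_dataset",
    "train_disambiguator",
    "score_candidate",
    "model_resolve",
    "load_word2vec_text",
]

OOV = "OOV"


@dataclass(frozen=True)
class DisambiguationExample:
    """One (mention-in-context, candidate) pair with a yes/no label.

    ``context`` is a sequence of (word, signed distance) with exactly one
    element at distance 0 — the mention surface itself; distances increase
    left to right.
    """

    context: tuple[tuple[str, int], ...]
    entity_name: str
    candidate_id: int
    label: str = "yes"  # yes | no

    def __post_init__(self) -> None:
        zeros = [d for _w, d in self.context if d == 0]
        if len(zeros) != 1:
            raise ValueError("context must contain exactly one element at distance 0")
        dists = [d for _w, d in self.context]
        if dists != sorted(dists):
            raise ValueError("context distances must increase left to right")


@dataclass(frozen=True)
class ModelConfig:
    learning_rate: float = 0.01
    kernel_width: int = 2
    word_dim: int = 50
    position_dim: int = 5
    filter_count: int = 64
    max_context_length: int = 100
    epochs: int = 50
    seed: int = 0
    decision_cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name in ("kernel_width", "word_dim", "position_dim", "filter_count",
                     "max_context_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.decision_cutoff < 1.0):
            raise ValueError("decision_cutoff must lie in (0,1)")


def majority_resolve(m: Mention, meta: MetaInfo) -> Mention:
    """Resolve an ambiguous mention by pre-linked majority.

    A unique candidate resolves immediately.  Otherwise the candidate with
    the strictly maximal pre-linked count wins; ties fall to the earliest
    first-linked ID, then the smallest ID.  With no evidence at all (every
    candidate at count zero) the mention stays ambiguous.
    """
    if m.status != "ambiguous":
        return m
    if len(m.candidate_ids) == 1:
        (tid,) = m.candidate_ids
        return replace(m, resolved_id=tid, status="resolved")
    tid = _majority_pick(m.candidate_ids, meta)
    if tid is None:
        return m
    return replace(m, resolved_id=tid, status="resolved")


def apply_threshold_filter(mentions: Sequence[Mention],
                           threshold: float) -> list[Mention]:
    """Drop still-ambiguous mentions with more than ``threshold`` candidates.

    Resolved (and type-only) mentions always pass; ``math.inf`` keeps
    everything.  Dropped mentions are retained with reason ``threshold`` so
    the pipeline can report per-stage counts.
    """
    out = []
    for m in mentions:
        if m.status == "ambiguous" and len(m.candidate_ids) > threshold:
            out.append(replace(m, status="dropped", drop_reason="threshold"))
        else:
            out.append(m)
    return out


def _context_of(text: str, mention: Mention, max_len: int) -> tuple[tuple[str, int], ...]:
    """Signed-distance context of a mention inside caption text.

    The mention (possibly multiword) is one element at distance 0; the
    remaining tokens get −k/+k by token distance, truncated to a window of
    ``max_len`` tokens centered on the mention.
    """
    tokens = tokenize_with_pos(text)
    left = [t for t in tokens if t.end <= mention.start]
    right = [t for t in tokens if t.start >= mention.end]
    radius = max(1, max_len // 2)
    left = left[-radius:]
    right = right[:radius]
    ctx = [(t.surface, -(len(left) - i)) for i, t in enumerate(left)]
    ctx.append((mention.surface, 0))
    ctx.extend((t.surface, j + 1) for j, t in enumerate(right))
    return tuple(ctx)


def build_disambiguation_dataset(
    tagged_captions: Iterable[tuple[str, Sequence[Mention]]],
    lex: Lexicon,
    max_context_length: int = 100,
) -> list[DisambiguationExample]:
    """Training examples from resolved mentions in tagged captions.

    Each resolved mention yields one *yes* example for its ID and one *no*
    example per alternative candidate.  The entity representation is the
    candidate's scientific name from the lexicon; candidates without a
    scientific name are skipped.
    """
    examples: list[DisambiguationExample] = []
    for text, mentions in tagged_captions:
        for m in mentions:
            if m.status != "resolved" or m.resolved_id is None:
                continue
            ctx = _context_of(text, m, max_context_length)
            for tid in sorted(m.candidate_ids):
                entry = lex.entries.get(tid)
                sci = entry.scientific_name() if entry is not None else None
                if sci is None:
                    continue
                examples.append(DisambiguationExample(
                    context=ctx,
                    entity_name=sci,
                    candidate_id=tid,
                    label="yes" if tid == m.resolved_id else "no",
                ))
    return examples


class DisambiguationModel:
    """Convolutional yes/no scorer with word, position, and entity channels."""

    def __init__(self, cfg: ModelConfig, vocab: Sequence[str],
                 pretrained: Optional[dict[str, np.ndarray]] = None) -> None:
        self.cfg = cfg
        if pretrained:
            dim = len(next(iter(pretrained.values())))
            cfg = replace(cfg, word_dim=dim)
            self.cfg = cfg
        self.vocab: dict[str, int] = {}
        for w in vocab:
            self.vocab.setdefault(w, len(self.vocab))
        self.vocab.setdefault(OOV, len(self.vocab))
        rng = np.random.default_rng(cfg.seed)
        V, dw, dp, k = len(self.vocab), cfg.word_dim, cfg.position_dim, cfg.filter_count
        self.radius = cfg.max_context_length  # positions clipped to ±radius
        scale = 0.1
        self.W = rng.normal(0.0, scale, size=(V, dw))
        if pretrained:
            for w, i in self.vocab.items():
                vec = pretrained.get(w)
                if vec is not None:
                    self.W[i] = vec
        self.P = rng.normal(0.0, scale, size=(2 * self.radius + 1, dp))
        width = cfg.kernel_width
        self.F = rng.normal(0.0, scale / math.sqrt(width * (dw + dp)),
                            size=(k, width * (dw + dp)))
        self.fb = np.zeros(k)
        self.U = rng.normal(0.0, scale / math.sqrt(k + dw), size=(2, k + dw))
        self.ub = np.zeros(2)
        # bilinear context-entity agreement term: without it the two
        # channels would only combine additively and could never express
        # "yes iff this entity matches this context"
        self.B = rng.normal(0.0, 1.0 / math.sqrt(k), size=(k, dw))
        self.c = np.array([1.0, -1.0])
        self.loss_history: list[float] = []

    # ---- encoding -------------------------------------------------------

    def _word_idx(self, word: str) -> int:
        return self.vocab.get(word, self.vocab.get(word.lower(), self.vocab[OOV]))

    def _entity_vec(self, entity_name: str) -> tuple[np.ndarray, list[int]]:
        idxs = [self._word_idx(w) for w in entity_name.split()]
        return self.W[idxs].mean(axis=0), idxs

    def _context_matrix(self, ex: DisambiguationExample):
        widx = [self._word_idx(w) for w, _d in ex.context]
        pidx = [min(max(d, -self.radius), self.radius) + self.radius
                for _w, d in ex.context]
        X = np.concatenate([self.W[widx], self.P[pidx]], axis=1)
        width = self.cfg.kernel_width
        if X.shape[0] < width:  # pad short contexts with zero rows
            X = np.vstack([X, np.zeros((width - X.shape[0], X.shape[1]))])
        return X, widx, pidx

    # ---- forward --------------------------------------------------------

    def _forward(self, ex: DisambiguationExample):
        X, widx, pidx = self._context_matrix(ex)
        width = self.cfg.kernel_width
        n = X.shape[0] - width + 1
        windows = np.stack([X[i : i + width].ravel() for i in range(n)])  # (n, width*d)
        conv = windows @ self.F.T + self.fb  # (n, k)
        act = np.maximum(conv, 0.0)
        pool_arg = act.argmax(axis=0)  # (k,)
        pooled = act[pool_arg, np.arange(act.shape[1])]
        evec, eidx = self._entity_vec(ex.entity_name)
        h = np.concatenate([pooled, evec])
        agree = float(pooled @ self.B @ evec)
        logits = self.U @ h + self.ub + self.c * agree
        z = logits - logits.max()
        p = np.exp(z)
        p /= p.sum()
        cache = (X, widx, pidx, windows, conv, pool_arg, pooled, evec, eidx, h, agree, p)
        return p, cache

    def score(self, ex: DisambiguationExample) -> tuple[float, float]:
        """(P(yes), P(no)) for one candidate example."""
        p, _ = self._forward(ex)
        return float(p[0]), float(p[1])

    # ---- backward / SGD -------------------------------------------------

    def _sgd_step(self, ex: DisambiguationExample, lr: float) -> float:
        p, cache = self._forward(ex)
        X, widx, pidx, windows, conv, pool_arg, pooled, evec, eidx, h, agree, _ = cache
        y = 0 if ex.label == "yes" else 1
        loss = -math.log(max(p[y], 1e-12))
        dlogits = p.copy()
        dlogits[y] -= 1.0
        dU = np.outer(dlogits, h)
        dub = dlogits
        dh = self.U.T @ dlogits
        k = self.cfg.filter_count
        dpooled, devec = dh[:k].copy(), dh[k:].copy()
        dagree = float(dlogits @ self.c)
        dc = dlogits * agree
        dpooled += dagree * (self.B @ evec)
        devec += dagree * (self.B.T @ pooled)
        dB = dagree * np.outer(pooled, evec)
        # entity channel: mean of word vectors
        dW_updates: dict[int, np.ndarray] = {}
        for i in eidx:
            dW_updates[i] = dW_updates.get(i, 0.0) + devec / len(eidx)
        # conv/max-pool
        width = self.cfg.kernel_width
        dwindows = np.zeros_like(windows)
        dF = np.zeros_like(self.F)
        dfb = np.zeros_like(self.fb)
        for j in range(k):
            if conv[pool_arg[j], j] <= 0.0:
                continue
            row = pool_arg[j]
            dF[j] += dpooled[j] * windows[row]
            dfb[j] += dpooled[j]
            dwindows[row] += dpooled[j] * self.F[j]
        d = self.cfg.word_dim + self.cfg.position_dim
        dX = np.zeros_like(X)
        for row in range(windows.shape[0]):
            dX[row : row + width] += dwindows[row].reshape(width, d)
        for pos, (wi, pi) in enumerate(zip(widx, pidx)):
            dW_updates[wi] = dW_updates.get(wi, 0.0) + dX[pos, : self.cfg.word_dim]
            self.P[pi] -= lr * dX[pos, self.cfg.word_dim :]
        for i, g in dW_updates.items():
            self.W[i] -= lr * g
        self.F -= lr * dF
        self.fb -= lr * dfb
        self.U -= lr * dU
        self.ub -= lr * dub
        self.B -= lr * dB
        self.c -= lr * dc
        return loss

    # ---- persistence ----------------------------------------------------

    def save(self, path: str) -> None:
        """Write a self-describing JSON checkpoint (config, vocab, arrays)."""
        payload = {
            "config": asdict(self.cfg),
            "vocab": list(self.vocab),
            "arrays": {
                name: getattr(self, name).tolist()
                for name in ("W", "P", "F", "fb", "U", "ub", "B", "c")
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "DisambiguationModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg = ModelConfig(**payload["config"])
        model = cls(cfg, payload["vocab"])
        for name, values in payload["arrays"].items():
            setattr(model, name, np.asarray(values, dtype=float))
        return model


def _vocab_of(data: Sequence[DisambiguationExample]) -> list[str]:
    vocab: dict[str, None] = {}
    for ex in data:
        for w, _d in ex.context:
            vocab.setdefault(w, None)
        for w in ex.entity_name.split():
            vocab.setdefault(w, None)
    return list(vocab)


def train_disambiguator(
    data: Sequence[DisambiguationExample],
    cfg: ModelConfig = ModelConfig(),
    pretrained: Optional[dict[str, np.ndarray]] = None,
) -> DisambiguationModel:
    """Train the yes/no scorer by SGD; deterministic given ``cfg.seed``.

    The vocabulary is built from the data plus the reserved OOV token.
    With ``epochs=0`` the returned model is exactly its initialization.
    """
    if not data:
        raise ValueError("cannot train on an empty example set")
    model = DisambiguationModel(cfg, _vocab_of(data), pretrained=pretrained)
    rng = np.random.default_rng(cfg.seed + 1)
    order = np.arange(len(data))
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        rng.shuffle(order)
        total = 0.0
        for i in order:
            total += model._sgd_step(data[i], cfg.learning_rate)
        history.append(total / len(data))
    model.loss_history = history
    return model


def score_candidate(model: DisambiguationModel,
                    ex: DisambiguationExample) -> tuple[float, float]:
    """(P(yes), P(no)); unseen words fall back to the OOV embedding."""
    return model.score(ex)


def model_resolve(
    m: Mention,
    context_text: str,
    model: DisambiguationModel,
    lex: Lexicon,
    cfg: Optional[ModelConfig] = None,
) -> Mention:
    """Resolve (or reject) a mention with the trained scorer.

    Every candidate — including the only candidate of an unambiguous
    mention — is scored; the argmax-P(yes) candidate wins if its probability
    reaches the decision cutoff, otherwise the mention is dropped with
    reason ``model_reject``.  Ties go to the smaller taxonomy ID.
    """
    if m.status not in ("ambiguous", "resolved"):
        return m
    cfg = cfg or model.cfg
    ctx = _context_of(context_text, m, cfg.max_context_length)
    scored: list[tuple[float, int]] = []
    for tid in sorted(m.candidate_ids):
        entry = lex.entries.get(tid)
        sci = entry.scientific_name() if entry is not None else None
        name = sci if sci is not None else OOV
        ex = DisambiguationExample(context=ctx, entity_name=name, candidate_id=tid)
        p_yes, _ = model.score(ex)
        scored.append((p_yes, tid))
    best_p = max(p for p, _t in scored)
    best_tid = min(t for p, t in scored if p == best_p)
    if best_p >= cfg.decision_cutoff:
        return replace(m, resolved_id=best_tid, status="resolved", drop_reason=None)
    return replace(m, resolved_id=None, status="dropped", drop_reason="model_reject")


def load_word2vec_text(text: str) -> dict[str, np.ndarray]:
    """Parse word2vec text format: header ``count dim``, then ``word v1 ... vd``."""
    lines = text.splitlines()
    if not lines:
        return {}
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError("word2vec text format requires a 'count dim' header line")
    dim = int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise ValueError(f"line {lineno}: expected {dim} values")
        vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    return vectors
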