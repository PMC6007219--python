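"""Majority rule, threshold filtering, dataset construction, and the scorer."""

import itertools
import math

import numpy as np
import pytest

from orgnorm.disambig import (
    DisambiguationExample,
    DisambiguationModel,
    ModelConfig,
    apply_threshold_filter,
    build_disambiguation_dataset,
    majority_resolve,
    model_resolve,
    score_candidate,
    train_disambiguator,
    load_word2vec_text,
    _vocab_of,
)
from orgnorm.identify import MetaInfo, Mention
from orgnorm.lexicon import Lexicon


def _mention(candidates, **kw):
    return Mention(0, 5, "xxxxx", frozenset(candidates), **kw)


class TestMajority:
    def test_strict_majority_wins(self):
        meta = MetaInfo()
        for _ in range(7):
            meta.record_link(7955, 0)
        for _ in range(2):
            meta.record_link(10090, 50)
        m = majority_resolve(_mention({10090, 7955}), meta)
        assert m.resolved_id == 7955
        assert m.status == "resolved"

    def test_singleton_resolves_immediately(self):
        m = majority_resolve(_mention({9606}), MetaInfo())
        assert m.resolved_id == 9606

    def test_all_zero_counts_stay_ambiguous(self):
        m = majority_resolve(_mention({9606, 10090}), MetaInfo())
        assert m.status == "ambiguous"

    def test_never_invents_an_id(self):
        meta = MetaInfo()
        for _ in range(9):
            meta.record_link(7227, 0)  # heavy evidence outside the candidates
        m = majority_resolve(_mention({9606, 10090}), meta)
        assert m.status == "ambiguous" or m.resolved_id in {9606, 10090}

    def test_tie_broken_by_earliest_first_link_all_orders(self):
        """Exhaustive over arrival orders of three tied candidates."""
        ids = [9606, 10090, 7955]
        for order in itertools.permutations(ids):
            meta = MetaInfo()
            for pos, tid in enumerate(order):
                meta.record_link(tid, pos * 100)
            for tid in ids:  # equalize counts at 3 each
                while meta.prelinked_counts[tid] < 3:
                    meta.record_link(tid, 1000)
            m = majority_resolve(_mention(set(ids)), meta)
            assert m.resolved_id == order[0]


class TestThreshold:
    def test_unresolved_above_threshold_dropped(self):
        out = apply_threshold_filter([_mention({1, 2, 3})], threshold=2)
        assert out[0].status == "dropped"
        assert out[0].drop_reason == "threshold"

    def test_resolved_always_kept(self):
        m = _mention({9606}, resolved_id=9606, status="resolved")
        for thr in (0, 2, 10, math.inf):
            assert apply_threshold_filter([m], thr)[0].status == "resolved"

    def test_five_candidates_pass_threshold_ten(self):
        out = apply_threshold_filter([_mention({1, 2, 3, 4, 5})], threshold=10)
        assert out[0].status == "ambiguous"

    def test_infinite_threshold_drops_nothing(self):
        out = apply_threshold_filter(
            [_mention(set(range(1, 40)))], threshold=math.inf)
        assert out[0].status == "ambiguous"

    def test_monotone_in_threshold(self):
        mentions = [_mention(set(range(1, n + 2))) for n in range(6)]
        kept = []
        for thr in (1, 2, 3, 10, math.inf):
            out = apply_threshold_filter(mentions, thr)
            kept.append({i for i, m in enumerate(out) if m.status != "dropped"})
        for a, b in zip(kept, kept[1:]):
            assert a <= b


def _fixture_lex():
    lex = Lexicon()
    lex.add(101, "Flya flya", "scientific")
    lex.add(102, "Fisha fisha", "scientific")
    return lex


class TestDataset:
    def test_context_encoding_signed_distances(self):
        lex = _fixture_lex()
        text = "Cells from wild S. typhimurium or its mutants."
        start = text.index("S. typhimurium")
        m = Mention(start, start + len("S. typhimurium"), "S. typhimurium",
                    frozenset({101}), resolved_id=101, status="resolved")
        data = build_disambiguation_dataset([(text, [m])], lex)
        ctx = dict(data[0].context)
        assert ctx["S. typhimurium"] == 0
        assert ctx["wild"] == -1
        assert ctx["or"] == 1
        assert ctx["its"] == 2

    def test_empty_collection(self):
        assert build_disambiguation_dataset([], _fixture_lex()) == []

    def test_yes_no_counts(self):
        lex = _fixture_lex()
        captions = []
        for i in range(4):
            text = f"Sample {i} of Flya flya larvae."
            s = text.index("Flya flya")
            captions.append((text, [Mention(s, s + 9, "Flya flya",
                                            frozenset({101, 102}),
                                            resolved_id=101, status="resolved")]))
        data = build_disambiguation_dataset(captions, lex)
        labels = [ex.label for ex in data]
        assert labels.count("yes") == 4
        assert labels.count("no") == 4

    def test_candidate_without_scientific_name_skipped(self):
        lex = _fixture_lex()
        lex.add(103, "mystery bug", "common")  # no scientific name
        text = "A mystery bug appeared."
        m = Mention(2, 13, "mystery bug", frozenset({101, 103}),
                    resolved_id=103, status="resolved")
        data = build_disambiguation_dataset([(text, [m])], lex)
        assert all(ex.candidate_id != 103 for ex in data)


def _separable_data():
    data = []
    ctxs_a = [
        (("larvae", -2), ("of", -1), ("flywing", 0), ("crawling", 1), ("plates", 2)),
        (("imaging", -2), ("the", -1), ("flywing", 0), ("wing", 1), ("discs", 2)),
    ]
    ctxs_b = [
        (("swimming", -2), ("the", -1), ("finfish", 0), ("embryo", 1), ("tank", 2)),
        (("lateral", -2), ("line", -1), ("finfish", 0), ("neuromasts", 1), ("views", 2)),
    ]
    for ctx in ctxs_a:
        data.append(DisambiguationExample(ctx, "Flya flya", 101, "yes"))
        data.append(DisambiguationExample(ctx, "Fisha fisha", 102, "no"))
    for ctx in ctxs_b:
        data.append(DisambiguationExample(ctx, "Fisha fisha", 102, "yes"))
        data.append(DisambiguationExample(ctx, "Flya flya", 101, "no"))
    return data


class TestTraining:
    def test_separable_set_reaches_perfect_accuracy(self):
        data = _separable_data()
        model = train_disambiguator(data, ModelConfig(seed=7, epochs=50))
        acc = sum((model.score(ex)[0] >= 0.5) == (ex.label == "yes")
                  for ex in data) / len(data)
        assert acc == 1.0

    def test_zero_epochs_equals_initialization(self):
        data = _separable_data()
        cfg = ModelConfig(seed=7, epochs=0)
        trained = train_disambiguator(data, cfg)
        init = DisambiguationModel(cfg, _vocab_of(data))
        for ex in data:
            assert trained.score(ex) == init.score(ex)

    def test_default_config_values(self):
        cfg = ModelConfig()
        assert cfg.learning_rate == 0.01
        assert cfg.kernel_width == 2

    def test_training_determinism(self):
        data = _separable_data()
        m1 = train_disambiguator(data, ModelConfig(seed=3, epochs=10))
        m2 = train_disambiguator(data, ModelConfig(seed=3, epochs=10))
        for ex in data:
            assert m1.score(ex) == m2.score(ex)

    def test_monitored_loss_decreases(self):
        data = _separable_data()
        model = train_disambiguator(data, ModelConfig(seed=7, epochs=50))
        assert len(model.loss_history) == 50
        assert model.loss_history[-1] < model.loss_history[0]

    def test_empty_data_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            train_disambiguator([], ModelConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        data = _separable_data()
        model = train_disambiguator(data, ModelConfig(seed=7, epochs=5))
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = DisambiguationModel.load(str(path))
        for ex in data:
            assert model.score(ex) == pytest.approx(loaded.score(ex), abs=1e-12)


@pytest.fixture(scope="module")
def trained(
):
    return train_disambiguator(_separable_data(), ModelConfig(seed=7, epochs=50))


class TestScoring:
    def test_probabilities_sum_to_one(self, trained):
        for ex in _separable_data():
            p_yes, p_no = score_candidate(trained, ex)
            assert p_yes + p_no == pytest.approx(1.0, abs=1e-6)

    def test_gold_candidate_outscores_alternatives(self, trained):
        data = _separable_data()
        by_ctx = {}
        for ex in data:
            by_ctx.setdefault(ex.context, {})[ex.label] = score_candidate(trained, ex)[0]
        for scores in by_ctx.values():
            assert scores["yes"] > scores["no"]

    def test_unseen_words_equal_oov_token(self, trained):
        ctx_unseen = (("qqqq", -1), ("wwww", 0), ("rrrr", 1))
        ctx_oov = (("OOV", -1), ("OOV", 0), ("OOV", 1))
        a = score_candidate(trained, DisambiguationExample(ctx_unseen, "Flya flya", 101))
        b = score_candidate(trained, DisambiguationExample(ctx_oov, "Flya flya", 101))
        assert a == b


class TestModelResolve:
    def test_resolves_to_matching_candidate(self, trained):
        lex = _fixture_lex()
        text = "Stacks show the flywing wing discs in detail."
        s = text.index("flywing")
        m = Mention(s, s + 7, "flywing", frozenset({101, 102}))
        out = model_resolve(m, text, trained, lex)
        assert out.status == "resolved"
        assert out.resolved_id == 101

    def test_single_candidate_can_be_rejected(self, trained):
        lex = _fixture_lex()
        # a flywing context scored against the fish entity only
        text = "Imaging the flywing wing discs."
        s = text.index("flywing")
        m = Mention(s, s + 7, "flywing", frozenset({102}))
        out = model_resolve(m, text, trained, lex)
        assert out.status == "dropped"
        assert out.drop_reason == "model_reject"

    def test_tie_prefers_smaller_taxon_id(self):
        data = _separable_data()
        cfg = ModelConfig(seed=7, epochs=0, decision_cutoff=0.4)
        model = train_disambiguator(data, cfg)
        lex = Lexicon()
        lex.add(201, "Same name", "scientific")
        lex.add(202, "Same name", "scientific")  # identical entity vectors
        text = "The flywing appeared."
        s = text.index("flywing")
        m = Mention(s, s + 7, "flywing", frozenset({201, 202}))
        out = model_resolve(m, text, model, lex)
        if out.status == "resolved":
            assert out.resolved_id == 201


def test_word2vec_text_parsing():
    text = "2 3\nhuman 0.1 0.2 0.3\nmouse -1 0 1\n"
    vecs = load_word2vec_text(text)
    assert set(vecs) == {"human", "mouse"}
    np.testing.assert_allclose(vecs["human"], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="header"):
        load_word2vec_text("not a header\n")


def test_pretrained_embeddings_set_dimension():
    data = _separable_data()
    vecs = {"flywing": np.arange(200) / 200.0}
    model = train_disambiguator(data, ModelConfig(seed=1, epochs=0), pretrained=vecs)
    assert model.cfg.word_dim == 200
    np.testing.assert_allclose(model.W[model.vocab["flywing"]], vecs["flywing"])


def test_model_beats_majority_when_counts_uninformative():
    """Planted context→ID rule; equal pre-link counts give majority 50%."""
    rng = np.random.default_rng(12)
    fly_words = ["crawling", "wing", "discs", "pupae", "instar"]
    fish_words = ["fins", "tank", "neuromasts", "swimbladder", "gills"]
    train, test = [], []
    for i in range(60):
        is_fly = bool(rng.integers(2))
        words = fly_words if is_fly else fish_words
        w1, w2 = rng.choice(words, size=2, replace=False)
        ctx = ((str(w1), -1), ("flywing" if is_fly else "finfish", 0), (str(w2), 1))
        gold = 101 if is_fly else 102
        target = train if i < 40 else test
        for cand, name in ((101, "Flya flya"), (102, "Fisha fisha")):
            target.append(DisambiguationExample(
                ctx, name, cand, "yes" if cand == gold else "no"))
    model = train_disambiguator(train, ModelConfig(seed=5, epochs=50))
    correct = sum((model.score(ex)[0] >= 0.5) == (ex.label == "yes") for ex in test)
    model_acc = correct / len(test)
    majority_acc = 0.5  # equal counts cannot separate the two candidates
    assert model_acc > majority_acc
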