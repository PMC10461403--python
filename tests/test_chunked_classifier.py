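import numpy as np
import pytest

from chunkclin.autograd import Tensor
from chunkclin.chunked_classifier import (
    AdaptationConfig,
    ChunkingConfig,
    ChunkSequence,
    ModelConfig,
    TrainConfig,
    aggregate_and_score,
    build_model,
    count_parameters,
    domain_adapt,
    embed_chunks,
    tokenize_and_chunk,
    train,
)
from chunkclin.datatypes import LABELS, ClinicalNote
from chunkclin.errors import ConfigError
from chunkclin.eval_harness import auroc
from chunkclin.nn import BackboneConfig, TinyEncoder
from chunkclin.synthetic_notes import generate_corpus, records_to_adjudicated
from chunkclin.tokenizer import CLS, PAD, SEP, WordTokenizer
from conftest import separable_spec


@pytest.fixture(scope="module")
def vocab_tokenizer():
    words = [f"w{i}" for i in range(50)]
    return WordTokenizer.build([" ".join(words)])


def _note(text, i=0):
    return ClinicalNote(note_id=f"n{i}", patient_id="p", site_id="s", text=text)


class TestTokenizeAndChunk:
    def test_long_note_splits_into_three_chunks(self, vocab_tokenizer):
        """1400 tokens at 512-token chunks (510 content) -> 3 chunks."""
        text = " ".join(f"w{i % 50}" for i in range(1400))
        seq = tokenize_and_chunk(_note(text), vocab_tokenizer, ChunkingConfig())
        assert seq.n_chunks == 3
        for chunk in seq.chunks:
            assert len(chunk) <= 512
            assert chunk[0] == CLS and chunk[-1] == SEP

    def test_short_note_is_single_chunk(self, vocab_tokenizer):
        seq = tokenize_and_chunk(
            _note("w1 w2 w3 w4 w5 w6 w7"), vocab_tokenizer, ChunkingConfig()
        )
        assert seq.n_chunks == 1

    def test_chunking_is_lossless_without_overlap(self, vocab_tokenizer):
        rng = np.random.default_rng(0)
        config = ChunkingConfig(max_tokens_per_chunk=16, max_chunks=20)
        for _ in range(20):
            n = int(rng.integers(1, 200))
            text = " ".join(f"w{rng.integers(0, 50)}" for _ in range(n))
            seq = tokenize_and_chunk(_note(text), vocab_tokenizer, config)
            assert seq.content_ids() == vocab_tokenizer.encode(text)

    def test_overlong_note_truncates_with_warning(self, vocab_tokenizer):
        config = ChunkingConfig(max_tokens_per_chunk=16, max_chunks=2)
        text = " ".join("w1" for _ in range(100))
        with pytest.warns(UserWarning, match="truncating"):
            seq = tokenize_and_chunk(_note(text), vocab_tokenizer, config)
        assert seq.n_chunks == 2

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ConfigError):
            ChunkingConfig(max_tokens_per_chunk=16, overlap=14)


class _StubEncoder:
    """Encoder with hand-set per-layer states for closed-form checks."""

    def __init__(self, states):
        self._states = states  # list of (B, L, D) arrays

    def forward(self, ids, mask, causal=False):
        return [Tensor(s) for s in self._states]


class TestEmbedChunks:
    def test_single_chunk_gives_one_row_of_encoder_width(self):
        config = BackboneConfig(vocab_size=60, max_len=32)
        encoder = TinyEncoder(config)
        seq = ChunkSequence("n0", [np.array([CLS, 7, 8, 9, SEP])])
        with pytest.warns(UserWarning, match="averaging all layers"):
            mat = embed_chunks(seq, encoder, ChunkingConfig(max_tokens_per_chunk=32))
        assert mat.shape == (1, config.width)

    def test_identical_layer_states_equal_single_layer_mean(self):
        state = np.arange(12, dtype=float).reshape(1, 3, 4)
        enc = _StubEncoder([state, state.copy()])
        seq = ChunkSequence("n0", [np.array([CLS, 7, SEP])])
        config = ChunkingConfig(max_tokens_per_chunk=8, last_n_layers_for_embedding=2)
        mat = embed_chunks(seq, enc, config)
        np.testing.assert_allclose(mat, state.mean(axis=1))

    def test_two_layer_toy_states_match_hand_computed_mean(self):
        """3-token chunk, 2 layers: row = mean over layers then tokens."""
        layer1 = np.array([[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]])
        layer2 = np.array([[[7.0, 8.0], [9.0, 10.0], [11.0, 12.0]]])
        enc = _StubEncoder([layer1, layer2])
        seq = ChunkSequence("n0", [np.array([CLS, 7, SEP])])
        config = ChunkingConfig(max_tokens_per_chunk=8, last_n_layers_for_embedding=2)
        mat = embed_chunks(seq, enc, config)
        expected = ((layer1 + layer2) / 2).mean(axis=1)  # [[6, 7]]
        np.testing.assert_allclose(mat, expected)

    def test_layer_and_token_mean_commute(self):
        rng = np.random.default_rng(1)
        states = [rng.normal(size=(2, 5, 4)) for _ in range(3)]
        enc = _StubEncoder(states)
        seq = ChunkSequence("n0", [np.array([CLS, 6, 7, 8, SEP]),
                                   np.array([CLS, 9, 10, 11, SEP])])
        config = ChunkingConfig(max_tokens_per_chunk=8, last_n_layers_for_embedding=3)
        mat = embed_chunks(seq, enc, config)
        tokens_first = np.mean([s.mean(axis=1) for s in states], axis=0)
        np.testing.assert_allclose(mat, tokens_first)

    def test_padding_positions_excluded_from_token_mean(self):
        rng = np.random.default_rng(2)
        config = BackboneConfig(vocab_size=60, max_len=32, n_layers=1)
        encoder = TinyEncoder(config)
        chunk_cfg = ChunkingConfig(
            max_tokens_per_chunk=32, last_n_layers_for_embedding=1
        )
        short = ChunkSequence("a", [np.array([CLS, 7, 8, SEP])])
        # same note alongside a longer sibling chunk forces padding
        padded = ChunkSequence(
            "b", [np.array([CLS, 7, 8, SEP]), np.array([CLS, 9, 10, 11, 12, 13, SEP])]
        )
        row_alone = embed_chunks(short, encoder, chunk_cfg)[0]
        row_padded = embed_chunks(padded, encoder, chunk_cfg)[0]
        np.testing.assert_allclose(row_alone, row_padded, atol=1e-12)


class TestAggregateAndScore:
    def _model(self, **overrides):
        cfg = ModelConfig(
            backbone=BackboneConfig(vocab_size=60, max_len=32), dropout=0.0, **overrides
        )
        from chunkclin.chunked_classifier import ChunkedClassifier

        return ChunkedClassifier(cfg)

    def test_scores_in_unit_interval_for_multitask(self):
        model = self._model()
        mat = np.random.default_rng(0).normal(size=(3, 32))
        scores = aggregate_and_score(mat, model)
        assert scores.shape == (6,)
        assert np.all((scores > 0) & (scores < 1))

    def test_single_chunk_matrix_handled_by_padding(self):
        model = self._model()
        scores = aggregate_and_score(np.ones((1, 32)), model)
        assert np.all(np.isfinite(scores))

    def test_fixed_weights_are_deterministic(self):
        model = self._model()
        mat = np.random.default_rng(1).normal(size=(2, 32))
        np.testing.assert_array_equal(
            aggregate_and_score(mat, model), aggregate_and_score(mat, model)
        )


class TestBuildModelAndParameters:
    @pytest.fixture(scope="class")
    def tokenizer(self):
        return WordTokenizer.build([" ".join(f"w{i}" for i in range(200))])

    def _config(self, tokenizer, **overrides):
        return ModelConfig(
            backbone=BackboneConfig(vocab_size=tokenizer.vocab_size), **overrides
        )

    def test_multitask_is_one_model_binary_is_six(self, tokenizer):
        multi = build_model(self._config(tokenizer), tokenizer)
        binary = build_model(self._config(tokenizer, head_mode="binary"), tokenizer)
        assert len(multi.models) == 1
        assert len(binary.models) == 6

    def test_binary_models_have_disjoint_parameters(self, tokenizer):
        binary = build_model(self._config(tokenizer, head_mode="binary"), tokenizer)
        all_params = [p for m in binary.models for p in m.parameters()]
        assert len({id(p) for p in all_params}) == len(all_params)
        # independent initializations too
        w0 = binary.models[0].backbone.tok.W.data
        w1 = binary.models[1].backbone.tok.W.data
        assert not np.array_equal(w0, w1)

    def test_parameter_ratio_rounds_to_six(self, tokenizer):
        multi = build_model(self._config(tokenizer), tokenizer)
        binary = build_model(self._config(tokenizer, head_mode="binary"), tokenizer)
        ratio = count_parameters(binary) / count_parameters(multi)
        assert 5.5 <= ratio <= 6.0
        assert round(ratio) == 6

    def test_head_size_difference_is_closed_form(self, tokenizer):
        """Multitask head has (6-1)*(feat+1) more weights than a binary head."""
        multi = build_model(self._config(tokenizer), tokenizer)
        binary = build_model(self._config(tokenizer, head_mode="binary"), tokenizer)
        feat = 64 * 2  # filters_per_width * n_kernel_widths
        per_binary = count_parameters(binary) // 6
        assert count_parameters(multi) - per_binary == 5 * (feat + 1)

    def test_truncated_equals_chunked_on_single_chunk_notes(self, tokenizer):
        note = _note("w1 w2 w3 w4 w5 w6 w7 w8")
        chunked = build_model(self._config(tokenizer), tokenizer, arch="chunked")
        truncated = build_model(self._config(tokenizer), tokenizer, arch="truncated")
        # share weights
        for mc, mt in zip(chunked.models, truncated.models):
            mt.load_state_arrays(mc.state_arrays())
        np.testing.assert_allclose(
            chunked.score([note]), truncated.score([note]), atol=1e-12
        )

    def test_invalid_head_mode_rejected(self, tokenizer):
        with pytest.raises(ConfigError):
            self._config(tokenizer, head_mode="both")


class TestTraining:
    @pytest.fixture(scope="class")
    def corpus(self):
        records = records_to_adjudicated(generate_corpus(separable_spec(seed=3)))
        return records[:200], records[200:]

    @pytest.fixture(scope="class")
    def tokenizer(self, corpus):
        train_recs, test_recs = corpus
        return WordTokenizer.build([r.note.text for r in train_recs + test_recs])

    def _model(self, tokenizer, train_config, seed=0, dropout=0.1):
        cfg = ModelConfig(
            backbone=BackboneConfig(vocab_size=tokenizer.vocab_size, max_len=64),
            chunking=ChunkingConfig(max_tokens_per_chunk=64, max_chunks=3),
            dropout=dropout,
            seed=seed,
        )
        return build_model(cfg, tokenizer, train_config)

    def test_learns_separable_corpus(self, corpus, tokenizer):
        """Held-out macro-AUROC >= 0.85 on a small separable corpus."""
        train_recs, test_recs = corpus
        tc = TrainConfig(epochs=12, learning_rate=1.5e-3, batch_size=8, seed=0)
        model = self._model(tokenizer, tc).fit(train_recs)
        trace = model.loss_traces[0]
        assert trace[-1] < trace[0]
        scores = model.score([r.note for r in test_recs])
        y = np.stack([r.labels.as_array() for r in test_recs])
        aucs = [auroc(scores[:, j], y[:, j]) for j in range(6)]
        macro = np.mean([a for a in aucs if a is not None])
        assert macro >= 0.85

    def test_zero_learning_rate_leaves_parameters_unchanged(self, corpus, tokenizer):
        train_recs, _ = corpus
        tc = TrainConfig(epochs=2, learning_rate=0.0, batch_size=8, seed=0)
        model = self._model(tokenizer, tc, dropout=0.0)
        model.fit(train_recs[:20])
        trace = model.loss_traces[0]
        assert trace[0] == pytest.approx(trace[1], abs=1e-12)
        # same init, lr=0: weights equal a freshly built model's
        fresh = self._model(tokenizer, tc, dropout=0.0)
        for a, b in zip(model.models[0].state_arrays(), fresh.models[0].state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_gives_identical_loss_trace(self, corpus, tokenizer):
        train_recs, _ = corpus
        tc = TrainConfig(epochs=2, learning_rate=1e-3, batch_size=8, seed=5)
        t1 = train(self._model(tokenizer, tc), train_recs[:30])
        t2 = train(self._model(tokenizer, tc), train_recs[:30])
        assert t1 == t2

    def test_empty_train_set_raises(self, tokenizer):
        tc = TrainConfig(epochs=1)
        with pytest.raises(ConfigError):
            self._model(tokenizer, tc).fit([])


class TestDomainAdaptation:
    @pytest.fixture(scope="class")
    def pool_and_tokenizer(self):
        from chunkclin.synthetic_notes import generate_unlabeled_pool

        spec = separable_spec(seed=9, n_notes=100)
        pool, _ = generate_unlabeled_pool(spec, 120)
        return pool, WordTokenizer.build([n.text for n in pool])

    def _backbone(self, tokenizer, seed=0):
        return TinyEncoder(
            BackboneConfig(vocab_size=tokenizer.vocab_size, max_len=64, seed=seed)
        )

    @pytest.mark.parametrize("objective", ["mlm", "clm"])
    def test_perplexity_decreases_over_epochs(self, pool_and_tokenizer, objective):
        pool, tokenizer = pool_and_tokenizer
        for seed in (0, 1):
            backbone = self._backbone(tokenizer, seed)
            _, trace = domain_adapt(
                backbone,
                pool,
                tokenizer,
                AdaptationConfig(objective=objective, epochs=3, seed=seed),
                ChunkingConfig(max_tokens_per_chunk=64, max_chunks=2),
            )
            assert trace[-1] < trace[0]

    def test_vanishing_mask_fraction_leaves_weights_unchanged(self, pool_and_tokenizer):
        pool, tokenizer = pool_and_tokenizer
        backbone = self._backbone(tokenizer)
        before = [a.copy() for a in backbone.state_arrays()]
        domain_adapt(
            backbone,
            pool[:20],
            tokenizer,
            AdaptationConfig(objective="mlm", mask_fraction=1e-12, epochs=1),
            ChunkingConfig(max_tokens_per_chunk=64, max_chunks=2),
        )
        for a, b in zip(before, backbone.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_adapted_backbone_slots_into_classifier(self, pool_and_tokenizer):
        pool, tokenizer = pool_and_tokenizer
        backbone = self._backbone(tokenizer)
        backbone, _ = domain_adapt(
            backbone,
            pool[:30],
            tokenizer,
            AdaptationConfig(objective="mlm", epochs=1),
            ChunkingConfig(max_tokens_per_chunk=64, max_chunks=2),
        )
        cfg = ModelConfig(
            backbone=BackboneConfig(vocab_size=tokenizer.vocab_size, max_len=64),
            chunking=ChunkingConfig(max_tokens_per_chunk=64, max_chunks=2),
        )
        model = build_model(cfg, tokenizer)
        model.set_backbone(backbone)
        scores = model.score([pool[0]])
        assert scores.shape == (1, 6) and np.all(np.isfinite(scores))

    def test_unknown_objective_rejected(self):
        with pytest.raises(ConfigError):
            AdaptationConfig(objective="rtd")
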