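"""Chunked-encoder classifier for notes longer than the encoder input limit.

Fixed-length contextual encoders cap input at ``max_tokens_per_chunk``
(512 for BERT-class models). Long notes are therefore:

1. tokenized and split into consecutive chunks, each wrapped in its own
   [CLS]/[SEP] markers so every chunk is a well-formed encoder input
   (content capacity = max_tokens_per_chunk - 2);
2. encoded independently; a chunk embedding is the mean over non-padding
   token positions of the mean over the encoder's last five layers (all
   layers, with a warning, for shallower encoders);
3. stacked in order into a chunk-embedding matrix, convolved along the
   chunk axis with several kernel widths, max-over-time pooled per filter
   (the Kim-style text-CNN applied to chunks instead of words), and mapped
   through dropout and a linear layer to per-label sigmoid scores.

Two head modes: ``multitask`` (one shared backbone, six outputs) and
``binary`` (six independent single-output models — roughly six times the
parameters). A *truncated* variant ignores every chunk after the first,
which is what a plain fixed-length classifier does to long notes.

Training minimizes per-label binary cross-entropy on sigmoid outputs with
Adam; domain adaptation continues pretraining the backbone on unlabeled
notes with a masked (MLM) or causal (CLM) language-modeling objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Adam, Parameter, Tensor
from .datatypes import LABELS, AdjudicatedRecord, ClinicalNote
from .errors import ConfigError
from .nn import BackboneConfig, Linear, Module, TinyEncoder
from .tokenizer import CLS, MASK, PAD, SEP, WordTokenizer


@dataclass
class ChunkingConfig:
    max_tokens_per_chunk: int = 512  # including the per-chunk [CLS]/[SEP]
    overlap: int = 0
    max_chunks: int = 3
    last_n_layers_for_embedding: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.max_tokens_per_chunk - 2:
            raise ConfigError("overlap must satisfy 0 <= overlap < chunk capacity")
        if self.max_tokens_per_chunk < 4:
            raise ConfigError("max_tokens_per_chunk must be at least 4")
        if self.max_chunks < 1:
            raise ConfigError("max_chunks must be >= 1")

    @property
    def capacity(self) -> int:
        """Content tokens per chunk (excluding [CLS]/[SEP])."""
        return self.max_tokens_per_chunk - 2


@dataclass
class ChunkSequence:
    """A note's token ids split into encoder-sized chunks, in order."""

    note_id: str
    chunks: list[np.ndarray]  # each <= max_tokens_per_chunk ids incl. specials

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def content_ids(self) -> list[int]:
        """Token ids with specials stripped, concatenated across chunks."""
        out: list[int] = []
        for chunk in self.chunks:
            out.extend(int(t) for t in chunk if t not in (CLS, SEP, PAD))
        return out


def tokenize_and_chunk(
    note: ClinicalNote, tokenizer: WordTokenizer, config: ChunkingConfig
) -> ChunkSequence:
    """Split a note into consecutive [CLS] ... [SEP] chunks.

    With overlap=0 the chunks partition the token sequence, so stripping
    specials and concatenating reproduces it. Notes longer than
    ``max_chunks`` chunks are truncated with a warning.
    """
    ids = tokenizer.encode(note.text)
    cap = config.capacity
    step = cap - config.overlap
    starts = list(range(0, max(len(ids), 1), step))
    if len(starts) > config.max_chunks:
        warnings.warn(
            f"note {note.note_id!r} spans {len(starts)} chunks; truncating to "
            f"{config.max_chunks}",
            stacklevel=2,
        )
        starts = starts[: config.max_chunks]
    chunks = [
        np.array([CLS] + ids[s : s + cap] + [SEP], dtype=np.int64) for s in starts
    ]
    return ChunkSequence(note_id=note.note_id, chunks=chunks)


def _pad_chunks(chunks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack chunks into (C, L) ids and (C, L) real-token mask."""
    L = max(len(c) for c in chunks)
    ids = np.full((len(chunks), L), PAD, dtype=np.int64)
    mask = np.zeros((len(chunks), L), dtype=np.float64)
    for i, c in enumerate(chunks):
        ids[i, : len(c)] = c
        mask[i, : len(c)] = 1.0
    return ids, mask


def _embed_chunks_t(
    seq: ChunkSequence, encoder: TinyEncoder, config: ChunkingConfig
) -> Tensor:
    """Chunk-embedding matrix as a Tensor (rows in chunk order)."""
    ids, mask = _pad_chunks(seq.chunks)
    states = encoder.forward(ids, mask)
    n_layers = min(config.last_n_layers_for_embedding, len(states))
    if n_layers < config.last_n_layers_for_embedding:
        warnings.warn(
            f"encoder has {len(states)} layers < "
            f"{config.last_n_layers_for_embedding}; averaging all layers",
            stacklevel=2,
        )
    layer_mean = states[-n_layers]
    for s in states[len(states) - n_layers + 1 :]:
        layer_mean = layer_mean + s
    layer_mean = layer_mean * (1.0 / n_layers)  # (C, L, D)
    m = Tensor(mask[:, :, None])
    counts = mask.sum(axis=1, keepdims=True)  # (C, 1)
    return (layer_mean * m).sum(axis=1) * Tensor(1.0 / counts)  # (C, D)


def embed_chunks(
    seq: ChunkSequence, encoder: TinyEncoder, config: ChunkingConfig | None = None
) -> np.ndarray:
    """Chunk-embedding matrix: n_chunks x width, mean of the last five
    layers' token states averaged over non-padding positions."""
    return _embed_chunks_t(seq, encoder, config or ChunkingConfig()).data


@dataclass
class ModelConfig:
    backbone: BackboneConfig
    head_mode: str = "multitask"  # "multitask" | "binary"
    conv_kernel_widths: tuple[int, ...] = (2, 3)
    filters_per_width: int = 64
    dropout: float = 0.1
    n_labels: int = len(LABELS)
    chunking: ChunkingConfig = field(default_factory=ChunkingConfig)
    truncate_to_first_chunk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_mode not in ("multitask", "binary"):
            raise ConfigError(f"unknown head_mode {self.head_mode!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if min(self.conv_kernel_widths) < 1:
            raise ConfigError("kernel widths must be positive")


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 5e-5  # published fine-tuning value for large
    # pretrained encoders; use ~1e-3 for the tiny from-scratch backbone
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")


class ChunkedClassifier(Module):
    """One backbone + chunk-CNN + linear head (multitask or single-label)."""

    def __init__(self, config: ModelConfig, n_outputs: int | None = None,
                 seed_offset: int = 0):
        self.config = config
        self.n_outputs = n_outputs if n_outputs is not None else config.n_labels
        self._seed_offset = seed_offset
        self._initial_backbone_state: list[np.ndarray] | None = None
        self._init_params()

    def _init_params(self) -> None:
        cfg = self.config
        backbone_cfg = BackboneConfig(**{**cfg.backbone.__dict__,
                                         "seed": cfg.backbone.seed + self._seed_offset})
        self.backbone = TinyEncoder(backbone_cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed + self._seed_offset, 7])
        )
        D = cfg.backbone.width
        self.conv_weights: list[Parameter] = []
        self.conv_biases: list[Parameter] = []
        for w in cfg.conv_kernel_widths:
            self.conv_weights.append(
                Parameter(rng.normal(0.0, 0.1, size=(w * D, cfg.filters_per_width)))
            )
            self.conv_biases.append(Parameter(np.zeros(cfg.filters_per_width)))
        feat = cfg.filters_per_width * len(cfg.conv_kernel_widths)
        self.head = Linear(feat, self.n_outputs, rng)
        if self._initial_backbone_state is not None:
            self.backbone.load_state_arrays(self._initial_backbone_state)

    def set_backbone(self, backbone: TinyEncoder) -> None:
        """Slot in a (domain-adapted) backbone with compatible shapes.

        The weights become the backbone *initialization*: they survive the
        fresh-parameter reset performed by :meth:`fit_sequences`, so
        fine-tuning starts from the adapted state.
        """
        self._initial_backbone_state = [a.copy() for a in backbone.state_arrays()]
        self.backbone.load_state_arrays(self._initial_backbone_state)

    # ---- forward --------------------------------------------------------

    def _aggregate(self, matrix: Tensor, train: bool,
                   rng: np.random.Generator | None) -> Tensor:
        """Chunk-CNN over the (C, D) matrix -> (n_outputs,) logits."""
        cfg = self.config
        C, D = matrix.shape
        w_max = max(cfg.conv_kernel_widths)
        if C < w_max:  # pad the chunk sequence so every kernel fits
            matrix = Tensor.concatenate([matrix, Tensor(np.zeros((w_max - C, D)))], axis=0)
            C = w_max
        pooled = []
        for w, W, b in zip(cfg.conv_kernel_widths, self.conv_weights, self.conv_biases):
            windows = Tensor.concatenate(
                [matrix[i : i + w].reshape(1, w * D) for i in range(C - w + 1)], axis=0
            )
            act = (windows @ W + b).relu()  # (n_windows, F)
            pooled.append(act.max(axis=0))  # (F,)
        feat = Tensor.concatenate(pooled, axis=0)
        if train and cfg.dropout > 0.0:
            if rng is None:
                raise ConfigError("training-mode dropout needs an rng")
            keep = (rng.random(feat.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            feat = feat * Tensor(keep)
        return feat @ self.head.W + self.head.b

    def _forward_note(self, seq: ChunkSequence, train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        if self.config.truncate_to_first_chunk:
            seq = ChunkSequence(note_id=seq.note_id, chunks=seq.chunks[:1])
        matrix = _embed_chunks_t(seq, self.backbone, self.config.chunking)
        return self._aggregate(matrix, train, rng)

    # ---- public API -----------------------------------------------------

    def score_sequences(self, seqs: list[ChunkSequence]) -> np.ndarray:
        out = np.zeros((len(seqs), self.n_outputs))
        for i, seq in enumerate(seqs):
            logits = self._forward_note(seq)
            out[i] = 1.0 / (1.0 + np.exp(-logits.data))
        return out

    def fit_sequences(
        self,
        seqs: list[ChunkSequence],
        y: np.ndarray,
        train_config: TrainConfig,
    ) -> list[float]:
        """Train from a fresh initialization; returns the per-epoch loss trace."""
        if not seqs:
            raise ConfigError("empty training set")
        y = np.asarray(y, dtype=np.float64).reshape(len(seqs), self.n_outputs)
        if not y.any():
            warnings.warn("training set has no positive labels", stacklevel=2)
        self._init_params()
        opt = Adam(self.parameters(), lr=train_config.learning_rate)
        rng = np.random.default_rng(train_config.seed)
        trace: list[float] = []
        n = len(seqs)
        for _epoch in range(train_config.epochs):
            perm = rng.permutation(n)
            total = 0.0
            for start in range(0, n, train_config.batch_size):
                batch = perm[start : start + train_config.batch_size]
                opt.zero_grad()
                loss_sum: Tensor | None = None
                for i in batch:
                    z = self._forward_note(seqs[int(i)], train=True, rng=rng)
                    yy = Tensor(y[int(i)])
                    # BCE with logits: softplus(z) - z*y, averaged over labels
                    note_loss = (z.softplus() - z * yy).mean()
                    loss_sum = note_loss if loss_sum is None else loss_sum + note_loss
                loss = loss_sum * (1.0 / len(batch))
                loss.backward()
                opt.step()
                total += float(loss.data) * len(batch)
            trace.append(total / n)
        return trace


class ChunkedModel:
    """User-facing model: tokenizer-aware fit/score over clinical notes.

    Wraps either one multitask :class:`ChunkedClassifier` or six
    independent binary ones, exposing the harness protocol
    (``fit(records)`` / ``score(notes)`` -> (n, 6) sigmoid scores).
    """

    def __init__(
        self,
        config: ModelConfig,
        tokenizer: WordTokenizer,
        train_config: TrainConfig | None = None,
    ):
        self.config = config
        self.tokenizer = tokenizer
        self.train_config = train_config or TrainConfig()
        if config.head_mode == "multitask":
            self.models = [ChunkedClassifier(config, n_outputs=config.n_labels)]
        else:
            self.models = [
                ChunkedClassifier(config, n_outputs=1, seed_offset=j + 1)
                for j in range(config.n_labels)
            ]
        self.loss_traces: list[list[float]] = []

    def set_backbone(self, backbone: TinyEncoder) -> None:
        """Use a (domain-adapted) backbone as initialization for all heads."""
        for m in self.models:
            m.set_backbone(backbone)

    def _sequences(self, notes: list[ClinicalNote]) -> list[ChunkSequence]:
        return [
            tokenize_and_chunk(n, self.tokenizer, self.config.chunking) for n in notes
        ]

    def fit(self, train: list[AdjudicatedRecord]) -> "ChunkedModel":
        if not train:
            raise ConfigError("empty training set")
        seqs = self._sequences([r.note for r in train])
        Y = np.stack([r.labels.as_array() for r in train]).astype(np.float64)
        self.loss_traces = []
        if self.config.head_mode == "multitask":
            self.loss_traces.append(
                self.models[0].fit_sequences(seqs, Y, self.train_config)
            )
        else:
            for j, model in enumerate(self.models):
                self.loss_traces.append(
                    model.fit_sequences(seqs, Y[:, j : j + 1], self.train_config)
                )
        return self

    def score(self, notes: list[ClinicalNote]) -> np.ndarray:
        seqs = self._sequences(notes)
        if self.config.head_mode == "multitask":
            return self.models[0].score_sequences(seqs)
        return np.concatenate(
            [m.score_sequences(seqs) for m in self.models], axis=1
        )


def build_model(
    config: ModelConfig,
    tokenizer: WordTokenizer,
    train_config: TrainConfig | None = None,
    arch: str = "chunked",
) -> ChunkedModel:
    """Build a chunked or truncated model in multitask or binary mode.

    ``arch="truncated"`` ignores every chunk after the first (the behaviour
    of a plain fixed-length classifier on long notes); on single-chunk
    notes the two variants coincide.
    """
    if arch not in ("chunked", "truncated"):
        raise ConfigError(f"unknown arch {arch!r}")
    cfg_kwargs = {**config.__dict__, "truncate_to_first_chunk": arch == "truncated"}
    cfg = ModelConfig(**cfg_kwargs)
    if cfg.backbone.vocab_size is None:  # type: ignore[comparison-overlap]
        raise ConfigError("backbone vocab_size must be set")
    return ChunkedModel(cfg, tokenizer, train_config)


def count_parameters(model) -> int:
    """Trainable parameter count; for a binary set, the sum over six models."""
    if isinstance(model, ChunkedModel):
        return sum(m.n_parameters() for m in model.models)
    if isinstance(model, Module):
        return model.n_parameters()
    raise ConfigError(f"cannot count parameters of {type(model).__name__}")


def aggregate_and_score(
    matrix: np.ndarray, model: ChunkedClassifier
) -> np.ndarray:
    """Apply the chunk-CNN head to a precomputed chunk-embedding matrix.

    Returns sigmoid scores in (0, 1), one per head output.
    """
    logits = model._aggregate(Tensor(np.atleast_2d(matrix)), train=False, rng=None)
    return 1.0 / (1.0 + np.exp(-logits.data))


def train(
    model: ChunkedModel,
    train_records: list[AdjudicatedRecord],
    train_config: TrainConfig | None = None,
) -> list[list[float]]:
    """Fit a model on adjudicated records; returns per-head loss traces."""
    if train_config is not None:
        model.train_config = train_config
    model.fit(train_records)
    return model.loss_traces


@dataclass
class AdaptationConfig:
    objective: str = "mlm"  # "mlm" | "clm"
    epochs: int = 3
    mask_fraction: float = 0.15
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("mlm", "clm"):
            raise ConfigError(f"unknown adaptation objective {self.objective!r}")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ConfigError("mask_fraction must be in [0, 1)")


def _mlm_corrupt(
    ids: np.ndarray, mask_fraction: float, vocab_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Standard 80/10/10 masking over content (non-special) positions."""
    corrupted = ids.copy()
    candidates = np.where(ids >= 5)[0]  # skip special tokens
    chosen = candidates[rng.random(len(candidates)) < mask_fraction]
    for pos in chosen:
        u = rng.random()
        if u < 0.8:
            corrupted[pos] = MASK
        elif u < 0.9:
            corrupted[pos] = int(rng.integers(5, vocab_size))
        # else: keep original token
    return corrupted, chosen


def domain_adapt(
    backbone: TinyEncoder,
    corpus: list[ClinicalNote],
    tokenizer: WordTokenizer,
    config: AdaptationConfig,
    chunking: ChunkingConfig | None = None,
) -> tuple[TinyEncoder, list[float]]:
    """Continue pretraining the backbone on unlabeled notes (MLM or CLM).

    MLM masks ``mask_fraction`` of content tokens (80% [MASK] / 10% random
    / 10% kept) and minimizes masked-token cross-entropy; CLM minimizes
    next-token cross-entropy under causal attention. The language-model
    head is trained jointly and discarded. Returns the adapted backbone
    (modified in place) and the per-epoch perplexity trace.
    """
    if not corpus:
        raise ConfigError("adaptation corpus must be non-empty")
    chunking = chunking or ChunkingConfig()
    rng = np.random.default_rng(config.seed)
    head_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lm_head = Linear(backbone.config.width, backbone.config.vocab_size, head_rng)
    params = backbone.parameters() + lm_head.parameters()
    opt = Adam(params, lr=config.learning_rate)

    chunks: list[np.ndarray] = []
    for note in corpus:
        chunks.extend(tokenize_and_chunk(note, tokenizer, chunking).chunks)

    trace: list[float] = []
    V = tokenizer.vocab_size
    for _epoch in range(config.epochs):
        perm = rng.permutation(len(chunks))
        total_nll, total_count = 0.0, 0
        for start in range(0, len(chunks), config.batch_size):
            batch_idx = perm[start : start + config.batch_size]
            opt.zero_grad()
            loss_sum: Tensor | None = None
            n_targets = 0
            for bi in batch_idx:
                ids = chunks[int(bi)]
                if config.objective == "mlm":
                    corrupted, positions = _mlm_corrupt(
                        ids, config.mask_fraction, V, rng
                    )
                    if len(positions) == 0:
                        continue
                    states = backbone.forward(
                        corrupted[None, :], np.ones((1, len(ids))), causal=False
                    )
                    logits = lm_head(states[-1])[0]  # (L, V)
                    sel = logits[positions]  # (n_masked, V)
                    targets = ids[positions]
                else:  # clm: predict token t+1 from prefix
                    if len(ids) < 2:
                        continue
                    states = backbone.forward(
                        ids[None, :-1], np.ones((1, len(ids) - 1)), causal=True
                    )
                    sel = lm_head(states[-1])[0]  # (L-1, V)
                    targets = ids[1:]
                    positions = np.arange(len(targets))
                nll = sel.logsumexp(axis=-1) - sel[np.arange(len(targets)), targets]
                chunk_loss = nll.sum()
                n_targets += len(targets)
                loss_sum = chunk_loss if loss_sum is None else loss_sum + chunk_loss
            if loss_sum is None:
                continue
            loss = loss_sum * (1.0 / n_targets)
            loss.backward()
            opt.step()
            total_nll += float(loss_sum.data)
            total_count += n_targets
        trace.append(float(np.exp(total_nll / total_count)) if total_count else 1.0)
    return backbone, trace
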