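"""Word-level tokenizer with BERT-style special tokens.

Lowercased whitespace tokenization with a vocabulary built from a corpus.
Special tokens: [PAD]=0, [UNK]=1, [CLS]=2, [SEP]=3, [MASK]=4. A word-level
scheme keeps the chunk-reconstruction invariant exact and the vocabulary
aligned with the synthetic generator's word stock; any tokenizer exposing
``encode``/``vocab_size`` and the same special ids can replace it.
"""

from __future__ import annotations

from collections import Counter

from .errors import TokenizationError

PAD, UNK, CLS, SEP, MASK = 0, 1, 2, 3, 4
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")


class WordTokenizer:
    def __init__(self, vocab: dict[str, int]):
        self.vocab = vocab
        self.inverse = {i: w for w, i in vocab.items()}

    @classmethod
    def build(
        cls, texts: list[str], min_count: int = 1, max_vocab: int | None = None
    ) -> "WordTokenizer":
        counts: Counter[str] = Counter()
        for text in texts:
            counts.update(text.lower().split())
        words = [w for w, c in counts.most_common(max_vocab) if c >= min_count]
        vocab = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
        for w in words:
            vocab[w] = len(vocab)
        return cls(vocab)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def encode(self, text: str) -> list[int]:
        if not isinstance(text, str) or not text:
            raise TokenizationError("cannot tokenize empty or non-string text")
        return [self.vocab.get(w, UNK) for w in text.lower().split()]

    def decode(self, ids: list[int]) -> str:
        return " ".join(self.inverse.get(int(i), "[UNK]") for i in ids)
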