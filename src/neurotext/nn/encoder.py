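"""Trainable token encoder: sub-word tokenizer + small transformer.

The encoder follows the standard recipe: the representation of token *i*
is the sum of a word embedding, a position embedding and a segment
embedding, passed through a stack of self-attention transformer blocks.
Hidden size and depth are configurable; the desk-scale defaults (H=32,
two layers) train in seconds on synthetic corpora while honouring the
same contract a large pretrained biomedical encoder would satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["EncoderConfig", "WordPieceTokenizer", "TransformerEncoder", "Adam"]

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"


@dataclass
class EncoderConfig:
    hidden_size: int = 32
    num_layers: int = 2
    num_heads: int = 2
    ffn_size: int = 64
    max_sequence_length: int = 64
    vocab_size: int = 0  # filled in once the tokenizer is built
    truncate: str = "warn"  # warn | error

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")
        if self.hidden_size % self.num_heads:
            raise ValueError("hidden_size must divide evenly over heads")


class WordPieceTokenizer:
    """Greedy longest-match sub-word tokenizer over a corpus vocabulary.

    Known words stay whole; unknown words are split into character pieces
    (``##``-prefixed continuations), so every sub-token maps back to the
    word it came from via the alignment the encoder returns.
    """

    def __init__(self, lowercase: bool = True):
        self.lowercase = lowercase
        self.vocab: dict[str, int] = {}
        for tok in (PAD, CLS, SEP, UNK):
            self.vocab[tok] = len(self.vocab)
        self.special_tokens: set[str] = {PAD, CLS, SEP, UNK}

    def add_special_tokens(self, tokens: list[str]) -> None:
        """Register atomic special tokens (e.g. relation entity markers)."""
        for tok in tokens:
            if tok not in self.vocab:
                self.vocab[tok] = len(self.vocab)
            self.special_tokens.add(tok)

    def fit(self, sentences: list[list[str]]) -> "WordPieceTokenizer":
        chars: set[str] = set()
        words: set[str] = set()
        for sent in sentences:
            for w in sent:
                w = self._norm(w)
                words.add(w)
                chars.update(w)
        for c in sorted(chars):
            for piece in (c, "##" + c):
                self.vocab.setdefault(piece, len(self.vocab))
        for w in sorted(words):
            self.vocab.setdefault(w, len(self.vocab))
        return self

    def _norm(self, word: str) -> str:
        return word.lower() if self.lowercase and word not in self.special_tokens else word

    def _word_pieces(self, word: str) -> list[str]:
        word = self._norm(word)
        if word in self.vocab:
            return [word]
        pieces: list[str] = []
        i = 0
        while i < len(word):
            for j in range(len(word), i, -1):
                cand = word[i:j] if i == 0 else "##" + word[i:j]
                if cand in self.vocab:
                    pieces.append(cand)
                    i = j
                    break
            else:
                return [UNK]
        return pieces

    def encode(self, words: list[str]) -> tuple[list[int], list[int]]:
        """Return sub-token ids and per-sub-token word alignment.

        The sequence is wrapped in [CLS] ... [SEP]; special positions get
        alignment -1.
        """
        ids = [self.vocab[CLS]]
        align = [-1]
        for wi, word in enumerate(words):
            for piece in self._word_pieces(word):
                ids.append(self.vocab[piece])
                align.append(wi)
        ids.append(self.vocab[SEP])
        align.append(-1)
        return ids, align

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    def __len__(self) -> int:
        return len(self.vocab)


class _Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, size: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(size), requires_grad=True)
        self.beta = Tensor(np.zeros(size), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).pow(0.5) * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _Block:
    def __init__(self, rng, cfg: EncoderConfig):
        H = cfg.hidden_size
        self.n_heads = cfg.num_heads
        self.wq, self.wk, self.wv, self.wo = (_Linear(rng, H, H) for _ in range(4))
        self.ln1, self.ln2 = _LayerNorm(H), _LayerNorm(H)
        self.ff1 = _Linear(rng, H, cfg.ffn_size)
        self.ff2 = _Linear(rng, cfg.ffn_size, H)

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        B, n, H = x.shape
        h, d = self.n_heads, H // self.n_heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, n, h, d).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(d)) + Tensor(attn_bias)
        ctx = scores.softmax(axis=-1) @ v
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, n, H)
        x = self.ln1(x + self.wo(ctx))
        return self.ln2(x + self.ff2(self.ff1(x).relu()))

    def params(self):
        out = []
        for m in (self.wq, self.wk, self.wv, self.wo, self.ln1, self.ln2, self.ff1, self.ff2):
            out.extend(m.params())
        return out


class TransformerEncoder:
    """Sum-of-embeddings input plus ``num_layers`` self-attention blocks."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        if cfg.vocab_size < 5:
            raise ValueError("vocab_size must be set from a fitted tokenizer")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        H = cfg.hidden_size
        self.word_emb = Tensor(rng.normal(0, 0.02, (cfg.vocab_size, H)), requires_grad=True)
        self.pos_emb = Tensor(rng.normal(0, 0.02, (cfg.max_sequence_length, H)), requires_grad=True)
        self.seg_emb = Tensor(rng.normal(0, 0.02, (2, H)), requires_grad=True)
        self.blocks = [_Block(rng, cfg) for _ in range(cfg.num_layers)]

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray,
                segments: np.ndarray | None = None) -> Tensor:
        """Encode a padded id batch.

        Parameters
        ----------
        ids : (B, n) int array of sub-token ids
        pad_mask : (B, n) bool array, True on real (non-pad) positions
        segments : optional (B, n) int array of segment ids (default all 0)

        Returns a ``(B, n, H)`` tensor of contextual vectors.
        """
        B, n = ids.shape
        if n > self.cfg.max_sequence_length:
            raise ValueError(f"sequence length {n} exceeds {self.cfg.max_sequence_length}")
        x = self.word_emb.take(ids) + self.pos_emb.take(np.arange(n))
        seg = np.zeros((B, n), dtype=int) if segments is None else segments
        x = x + self.seg_emb.take(seg)
        attn_bias = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]
        for block in self.blocks:
            x = block(x, attn_bias)
        return x

    def params(self):
        out = [self.word_emb, self.pos_emb, self.seg_emb]
        for b in self.blocks:
            out.extend(b.params())
        return out


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
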