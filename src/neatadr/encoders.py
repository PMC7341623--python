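"""Post-content encoders with cluster attention.

Two encoders turn a post's token sequence into a fixed-length vector:

* a single-layer bidirectional LSTM (hidden size ``e``, default 32): one
  shared attention weight per position is computed from the concatenated
  forward/backward state against a 2e-dimensional per-cluster attention
  vector, and the attention-pooled forward and backward vectors are
  concatenated (output dimension 2e);
* a bank of 1-D convolution blocks (kernel sizes 3/4/5, 100 channels each,
  tanh activation, centered zero same-padding): each block has its own
  per-cluster attention vector and is attention-pooled; block outputs are
  concatenated (output dimension K x channels).

Attention weights are a softmax over plain dot products between hidden
states and the attention vector of the author's user cluster, so users with
similar side-effect experience share what the encoder attends to. The
softmax is max-shifted for stability, which leaves the weights unchanged.

The functions here are plain-numpy single-post forwards used for encoding,
traces and extraction; training runs the same parameters through the
autodiff tape (see :mod:`neatadr.neat_core`). Both paths share the weight
arrays, and tests hold them to the same numbers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "TokenEmbeddingTable",
    "load_word_vectors",
    "pretrain_embeddings",
    "CnnEncoderParams",
    "LstmEncoderParams",
    "PostEncoding",
    "embed_tokens",
    "attention_pool",
    "encode_post_cnn",
    "encode_post_bilstm",
    "init_cnn_params",
    "init_lstm_params",
]


class TokenEmbeddingTable:
    """Token -> embedding vectors with a reproducible out-of-vocabulary policy.

    Known vectors come from a pre-trained word-vector file; any other token
    gets a random vector whose stream is keyed by (seed, token), so repeats
    agree within and across processes.
    """

    def __init__(self, dimension: int = 100, vectors: dict[str, np.ndarray] | None = None,
                 oov_seed: int = 0, oov_scale: float = 0.1):
        self.dimension = int(dimension)
        self.vectors: dict[str, np.ndarray] = dict(vectors or {})
        for tok, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {tok!r} has dimension {v.shape}, "
                                 f"expected ({self.dimension},)")
        self.oov_seed = int(oov_seed)
        self.oov_scale = float(oov_scale)
        self._oov_cache: dict[str, np.ndarray] = {}

    def vector(self, token: str) -> np.ndarray:
        if token in self.vectors:
            return self.vectors[token]
        if token not in self._oov_cache:
            key = zlib.crc32(token.encode("utf-8"))
            rng = np.random.default_rng([self.oov_seed, key])
            self._oov_cache[token] = rng.normal(0.0, self.oov_scale, self.dimension)
        return self._oov_cache[token]


def load_word_vectors(path, oov_seed: int = 0) -> TokenEmbeddingTable:
    """Read whitespace-delimited text word vectors (``token v1 ... vd``).

    Both the headerless GloVe dialect and the word2vec text dialect with a
    ``count dim`` first line are accepted.
    """
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip().split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # word2vec count header
                except ValueError:
                    pass
            token, vals = parts[0], parts[1:]
            vec = np.array([float(v) for v in vals])
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(f"{path}:{lineno}: inconsistent vector dimension")
            vectors[token] = vec
    if dim is None:
        raise ValueError(f"{path}: no vectors found")
    return TokenEmbeddingTable(dimension=dim, vectors=vectors, oov_seed=oov_seed)


def pretrain_embeddings(token_sequences, dimension: int = 100, window: int = 50,
                        rank: int = 30, shift: float = np.log(5.0),
                        oov_seed: int = 0) -> TokenEmbeddingTable:
    """Count-based distributional word vectors (shifted PPMI + truncated SVD).

    A stand-in for pre-trained vectors when none are supplied: tokens that
    occur in similar contexts get similar vectors, which is what gives
    attention a linearly detectable notion of "informative token". The PMI
    shift discards weak, sampling-noise associations and the hard rank
    truncation keeps only the dominant co-occurrence structure, so tokens
    whose profile matches the corpus-wide background end up with near-zero
    vectors. The default window spans whole posts (document-level
    co-occurrence).
    """
    vocab: dict[str, int] = {}
    for seq in token_sequences:
        for tok in seq:
            vocab.setdefault(tok, len(vocab))
    if not vocab:
        raise ValueError("no tokens to pretrain on")
    V = len(vocab)
    counts = np.zeros((V, V))
    for seq in token_sequences:
        idx = [vocab[t] for t in seq]
        for i, a in enumerate(idx):
            for b in idx[max(0, i - window):i]:
                counts[a, b] += 1
                counts[b, a] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurrence pairs (posts too short?)")
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row * row.T)) - shift
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    d = min(rank, dimension, V)
    vecs = u[:, :d] * np.sqrt(s[:d])
    vecs = np.pad(vecs, ((0, 0), (0, dimension - d)))
    return TokenEmbeddingTable(
        dimension=dimension,
        vectors={tok: vecs[i] for tok, i in vocab.items()},
        oov_seed=oov_seed,
    )


def embed_tokens(tokens, table: TokenEmbeddingTable) -> np.ndarray:
    """One row per token; shape (n, d). Empty input gives shape (0, d)."""
    if not tokens:
        return np.zeros((0, table.dimension))
    return np.stack([table.vector(t) for t in tokens])


def attention_pool(hidden: np.ndarray, a: np.ndarray):
    """Softmax-weighted pooling of hidden states against an attention vector.

    Returns ``(weights, pooled)`` where ``weights`` is a length-n simplex
    vector and ``pooled = sum_j weights_j * hidden_j``.
    """
    hidden = np.asarray(hidden, dtype=float)
    if hidden.ndim != 2 or hidden.shape[0] == 0:
        raise ValueError("attention_pool needs at least one hidden state")
    logits = hidden @ np.asarray(a, dtype=float)
    ex = np.exp(logits - logits.max())
    w = ex / ex.sum()
    return w, w @ hidden


@dataclass
class CnnEncoderParams:
    """Convolution-bank encoder parameters (autodiff tensors)."""

    kernel_sizes: tuple[int, ...]
    channels: int
    dim: int
    weights: list[Tensor]          # per block, (s*d, channels)
    biases: list[Tensor]           # per block, (channels,)
    attention: Tensor              # (n_clusters, K, channels)

    @property
    def output_dim(self) -> int:
        return len(self.kernel_sizes) * self.channels

    @property
    def tensors(self) -> list[Tensor]:
        return [*self.weights, *self.biases, self.attention]


@dataclass
class LstmEncoderParams:
    """Bidirectional LSTM encoder parameters (autodiff tensors)."""

    hidden: int
    dim: int
    wx_f: Tensor
    wh_f: Tensor
    b_f: Tensor
    wx_b: Tensor
    wh_b: Tensor
    b_b: Tensor
    attention: Tensor              # (n_clusters, 2*hidden)

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden

    @property
    def tensors(self) -> list[Tensor]:
        return [self.wx_f, self.wh_f, self.b_f, self.wx_b, self.wh_b, self.b_b,
                self.attention]


@dataclass
class PostEncoding:
    """Encoded post: vector, per-position attention trace, optional states."""

    v_p: np.ndarray
    attention: np.ndarray          # (n,) for LSTM; (K, n) for CNN; empty if n=0
    hidden: np.ndarray | None = None


def init_cnn_params(dim: int, n_clusters: int, kernel_sizes=(3, 4, 5),
                    channels: int = 100, seed: int = 0) -> CnnEncoderParams:
    rng = np.random.default_rng([seed, 11])
    weights, biases = [], []
    for s in kernel_sizes:
        scale = np.sqrt(2.0 / (s * dim + channels))
        weights.append(Tensor(rng.normal(0, scale, (s * dim, channels)),
                              requires_grad=True))
        biases.append(Tensor(np.zeros(channels), requires_grad=True))
    attn = Tensor(rng.normal(0, 0.1, (n_clusters, len(kernel_sizes), channels)),
                  requires_grad=True)
    return CnnEncoderParams(kernel_sizes=tuple(kernel_sizes), channels=channels,
                            dim=dim, weights=weights, biases=biases, attention=attn)


def init_lstm_params(dim: int, n_clusters: int, hidden: int = 32,
                     seed: int = 0) -> LstmEncoderParams:
    rng = np.random.default_rng([seed, 12])

    def mk(shape, fan):
        return Tensor(rng.normal(0, np.sqrt(1.0 / fan), shape), requires_grad=True)

    b_init = np.zeros(4 * hidden)
    b_init[hidden:2 * hidden] = 1.0  # forget-gate bias
    return LstmEncoderParams(
        hidden=hidden, dim=dim,
        wx_f=mk((dim, 4 * hidden), dim), wh_f=mk((hidden, 4 * hidden), hidden),
        b_f=Tensor(b_init.copy(), requires_grad=True),
        wx_b=mk((dim, 4 * hidden), dim), wh_b=mk((hidden, 4 * hidden), hidden),
        b_b=Tensor(b_init.copy(), requires_grad=True),
        attention=Tensor(rng.normal(0, 0.1, (n_clusters, 2 * hidden)),
                         requires_grad=True),
    )


def _conv_same_np(x: np.ndarray, W: np.ndarray, b: np.ndarray, s: int) -> np.ndarray:
    """Single-post 1-D convolution, centered zero same-padding. x: (n, d)."""
    n, d = x.shape
    left = (s - 1) // 2
    xp = np.pad(x, ((left, s - 1 - left), (0, 0)))
    cols = np.stack([xp[o:o + n] for o in range(s)], axis=1).reshape(n, s * d)
    return cols @ W + b


def encode_post_cnn(embeddings: np.ndarray, params: CnnEncoderParams,
                    cluster_id: int) -> PostEncoding:
    """Convolution-bank encoding of one post; empty posts encode to zero."""
    n = embeddings.shape[0]
    if n == 0:
        return PostEncoding(v_p=np.zeros(params.output_dim),
                            attention=np.zeros((len(params.kernel_sizes), 0)))
    pooled, traces = [], []
    for k, s in enumerate(params.kernel_sizes):
        h = np.tanh(_conv_same_np(embeddings, params.weights[k].data,
                                  params.biases[k].data, s))
        w, p = attention_pool(h, params.attention.data[cluster_id, k])
        pooled.append(p)
        traces.append(w)
    return PostEncoding(v_p=np.concatenate(pooled), attention=np.stack(traces))


def lstm_states_np(x: np.ndarray, wx: np.ndarray, wh: np.ndarray,
                   b: np.ndarray) -> np.ndarray:
    """Unidirectional LSTM hidden states for one sequence; x: (n, d) -> (n, e)."""
    e = wh.shape[0]
    h = np.zeros(e)
    c = np.zeros(e)
    out = np.empty((x.shape[0], e))
    for j in range(x.shape[0]):
        z = x[j] @ wx + h @ wh + b
        i = 1.0 / (1.0 + np.exp(-z[:e]))
        f = 1.0 / (1.0 + np.exp(-z[e:2 * e]))
        g = np.tanh(z[2 * e:3 * e])
        o = 1.0 / (1.0 + np.exp(-z[3 * e:]))
        c = f * c + i * g
        h = o * np.tanh(c)
        out[j] = h
    return out


def encode_post_bilstm(embeddings: np.ndarray, params: LstmEncoderParams,
                       cluster_id: int) -> PostEncoding:
    """BiLSTM encoding of one post with shared per-position attention weights.

    One attention weight per position is computed from the concatenated
    state [h^f_j; h^b_j] against the cluster's 2e-dimensional attention
    vector, then applied to the forward and backward sequences separately;
    the two pooled vectors are concatenated. Empty posts encode to zero.
    """
    n = embeddings.shape[0]
    if n == 0:
        return PostEncoding(v_p=np.zeros(params.output_dim), attention=np.zeros(0))
    hf = lstm_states_np(embeddings, params.wx_f.data, params.wh_f.data, params.b_f.data)
    hb = lstm_states_np(embeddings[::-1], params.wx_b.data, params.wh_b.data,
                        params.b_b.data)[::-1]
    both = np.concatenate([hf, hb], axis=1)
    if params.attention.data.shape[1] != both.shape[1]:
        raise ValueError("attention vector dimension does not match 2e states")
    w, _ = attention_pool(both, params.attention.data[cluster_id])
    return PostEncoding(v_p=np.concatenate([w @ hf, w @ hb]), attention=w,
                        hidden=both)
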