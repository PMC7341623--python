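"""Credibility-weighted thread encoding, multi-label prediction and training.

Each post is encoded to a vector ``v_p`` (cluster-attention CNN or BiLSTM),
optionally concatenated with its author's expertise vector ``v_u`` to form a
post-user complex. The thread representation is the credibility-weighted sum

    v_t = sum_i  e^{w_{u_i}} * v^p_{u_i}

where ``w_u`` is a learnable per-user score initialized to zero, so every
user starts with multiplier 1. Prediction is an affine map of ``tanh(v_t)``
through a sigmoid, one output per side effect, trained with binary
cross-entropy plus an L2 penalty on the expertise matrix and an L1 penalty
on the credibility scores.

Ablation variants gate the components:

========  ===========  ==============  =================
variant   credibility  expertise       cluster attention
========  ===========  ==============  =================
vanilla   --           --              --
wpe       yes          --              --
wpeu      yes          yes             --
neat      yes          yes             yes
========  ===========  ==============  =================

Without cluster attention a single shared attention vector is used.

The appendix-style single-label logistic probe and its closed-form
credibility gradient live here too; they are the independent oracle against
which the autodiff engine is checked. Note that correct differentiation of
the logistic loss carries a minus sign in front of ``y_s``; the sign-free
variant would make a credible user's score *fall* under gradient descent,
contradicting the truth-discovery behavior the weighting is built for.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import (
    CnnEncoderParams,
    LstmEncoderParams,
    PostEncoding,
    TokenEmbeddingTable,
    encode_post_bilstm,
    encode_post_cnn,
    init_cnn_params,
    init_lstm_params,
)
from .io_data import ForumCorpus, Post, Thread
from .user_model import (
    ExpertiseMatrix,
    UserClusterModel,
    build_experience_matrix,
    cluster_users,
    reduce_expertise,
)

__all__ = [
    "VARIANTS", "TrainConfig", "CredibilityVector", "ThreadEncoding",
    "SingleLabelLossProbe", "NeatModel",
    "compose_post_user", "encode_thread", "predict_side_effects", "compute_loss",
    "probe_loss", "credibility_gradient_closed_form", "credibility_gradient_autodiff",
    "train_model", "permute_post_authors", "save_model", "load_model",
]

VARIANTS = ("vanilla", "wpe", "wpeu", "neat")


def _uses_cw(variant: str) -> bool:
    return variant in ("wpe", "wpeu", "neat")


def _uses_ue(variant: str) -> bool:
    return variant in ("wpeu", "neat")


def _uses_ca(variant: str) -> bool:
    return variant == "neat"


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters and component gates."""

    variant: str = "neat"
    encoder: str = "cnn"               # "cnn" | "lstm"
    embedding_dim: int = 100
    kernel_sizes: tuple[int, ...] = (3, 4, 5)
    channels: int = 100
    lstm_hidden: int = 32
    g: int = 100                       # expertise components (clamped to data)
    n_clusters: int = 7                # user clusters (clamped to data)
    lambda1: float = 1e-5              # L2 on the expertise matrix
    lambda2: float = 1e-4              # L1 on the credibility vector
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    threshold: float = 0.5
    clip_eps: float = 1e-7
    att_entropy: float = 0.0           # attention-concentration penalty weight
    weight_decay: float = 0.0          # decoupled L2 on shared network weights
    train_embeddings: bool = True      # fine-tune word vectors vs keep them fixed
    permute_users: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.encoder not in ("cnn", "lstm"):
            raise ValueError("encoder must be 'cnn' or 'lstm'")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization factors must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0,1)")


@dataclass
class CredibilityVector:
    """Per-user learnable credibility scores ``w_u`` (multiplier ``e^{w_u}``)."""

    user_ids: list[str]
    w: np.ndarray

    def effective(self) -> np.ndarray:
        return np.exp(self.w)

    def score_of(self, user_id: str, default: float = 0.0) -> float:
        try:
            return float(self.w[self.user_ids.index(user_id)])
        except ValueError:
            return default


@dataclass
class ThreadEncoding:
    complexes: list[np.ndarray]
    weighted: list[np.ndarray]
    v_t: np.ndarray


def compose_post_user(v_p: np.ndarray, v_u: np.ndarray | None, variant: str) -> np.ndarray:
    """Post-user complex: ``[v_p; v_u]`` when expertise is enabled, else ``v_p``."""
    if not _uses_ue(variant):
        return np.asarray(v_p, dtype=float)
    if v_u is None:
        raise ValueError(f"variant {variant!r} needs an expertise vector")
    return np.concatenate([np.asarray(v_p, dtype=float), np.asarray(v_u, dtype=float)])


def encode_thread(complexes, credibility: CredibilityVector | None, authors,
                  variant: str) -> ThreadEncoding:
    """Credibility-weighted sum of post-user complexes (plain sum for vanilla)."""
    complexes = [np.asarray(v, dtype=float) for v in complexes]
    if len(complexes) != len(authors):
        raise ValueError("complexes and authors are not aligned")
    weighted = []
    for v, u in zip(complexes, authors):
        if variant == "vanilla" or credibility is None:
            w = 0.0
        elif u in credibility.user_ids:
            w = credibility.score_of(u)
        else:
            warnings.warn(f"unseen author {u!r}: using credibility weight 1")
            w = 0.0
        weighted.append(np.exp(w) * v)
    return ThreadEncoding(complexes=complexes, weighted=weighted,
                          v_t=np.sum(weighted, axis=0))


# ---------------------------------------------------------------------------
# single-label logistic probe and the closed-form credibility gradient
# ---------------------------------------------------------------------------

@dataclass
class SingleLabelLossProbe:
    """One thread, one label, no regularization: logistic-loss setting."""

    y_s: int                       # +1 / -1 truth for the probed label
    w_s: np.ndarray                # classifier row for that label
    b_s: float
    v_pu: list[np.ndarray]         # per-post complexes
    w_u: list[float]               # per-post author credibility scores

    def __post_init__(self):
        if self.y_s not in (-1, 1):
            raise ValueError("y_s must be +1 or -1")
        if len(self.v_pu) != len(self.w_u):
            raise ValueError("v_pu and w_u are not aligned")


def probe_loss(probe: SingleLabelLossProbe) -> float:
    """log(1 + exp(-y_s (w_s . tanh(v_t) + b_s))) with credibility-weighted v_t."""
    v_t = np.sum([np.exp(w) * v for w, v in zip(probe.w_u, probe.v_pu)], axis=0)
    f = float(probe.w_s @ np.tanh(v_t) + probe.b_s)
    return float(np.log1p(np.exp(-probe.y_s * f)))


def credibility_gradient_closed_form(probe: SingleLabelLossProbe) -> np.ndarray:
    """dL/dw_u per post author, by direct calculus.

    The magnitude is proportional to ``e^{w_u}``; a correct solo prediction
    (``y_s * w_s . v^p_u > 0`` through the tanh Jacobian) gives a negative
    gradient, so gradient descent raises that author's credibility.
    """
    v_t = np.sum([np.exp(w) * v for w, v in zip(probe.w_u, probe.v_pu)], axis=0)
    jac = 1.0 - np.tanh(v_t) ** 2
    f = float(probe.w_s @ np.tanh(v_t) + probe.b_s)
    denom = 1.0 + np.exp(probe.y_s * f)
    grads = []
    for w, v in zip(probe.w_u, probe.v_pu):
        grads.append(-probe.y_s * float(probe.w_s @ (jac * v)) * np.exp(w) / denom)
    return np.array(grads)


def credibility_gradient_autodiff(probe: SingleLabelLossProbe) -> np.ndarray:
    """The same gradient through the reverse-mode tape (independent route)."""
    w = Tensor(np.array(probe.w_u, dtype=float), requires_grad=True)
    V = Tensor(np.stack(probe.v_pu))
    ew = ad.reshape(ad.exp(w), (len(probe.w_u), 1))
    v_t = ad.sum_(V * ew, axis=0)
    f = ad.matmul(Tensor(probe.w_s), ad.tanh(v_t)) + probe.b_s
    loss = ad.log(ad.exp(f * (-probe.y_s)) + 1.0)
    loss.backward()
    return w.grad.copy()


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

@dataclass
class NeatModel:
    """All learnable parameters plus the frozen user-side preprocessing."""

    config: TrainConfig
    vocab_names: tuple[str, ...]
    token_index: dict[str, int]            # token -> embedding row; 0 is <unk>
    embedding: Tensor                      # (V, d)
    enc_params: CnnEncoderParams | LstmEncoderParams
    user_ids: list[str]
    user_index: dict[str, int]             # unknown users map to the extra slot
    user_cluster: np.ndarray               # (U+1,) attention-cluster per user
    expertise: Tensor | None               # (U+1, g)
    credibility: Tensor | None             # (U+1, 1)
    w_out: Tensor                          # (D, |S|)
    b_out: Tensor                          # (|S|,)
    cluster_model: UserClusterModel | None
    expertise_proj: ExpertiseMatrix | None

    @property
    def variant(self) -> str:
        return self.config.variant

    @property
    def n_side_effects(self) -> int:
        return len(self.vocab_names)

    def parameters(self) -> list[Tensor]:
        params = [*self.enc_params.tensors, self.w_out, self.b_out]
        if self.embedding.requires_grad:
            params.insert(0, self.embedding)
        if self.expertise is not None:
            params.append(self.expertise)
        if self.credibility is not None:
            params.append(self.credibility)
        return params

    def credibility_vector(self) -> CredibilityVector:
        w = (self.credibility.data[:len(self.user_ids), 0].copy()
             if self.credibility is not None else np.zeros(len(self.user_ids)))
        return CredibilityVector(user_ids=list(self.user_ids), w=w)

    def _user_slot(self, user_id: str) -> int:
        return self.user_index.get(user_id, len(self.user_ids))

    def encode_post(self, tokens, user_id: str) -> PostEncoding:
        """Single-post forward with attention trace (numpy path)."""
        ids = [self.token_index.get(t, 0) for t in tokens]
        emb = self.embedding.data[ids] if ids else np.zeros((0, self.config.embedding_dim))
        cluster = int(self.user_cluster[self._user_slot(user_id)])
        if self.config.encoder == "cnn":
            return encode_post_cnn(emb, self.enc_params, cluster)
        return encode_post_bilstm(emb, self.enc_params, cluster)

    def predict_threads(self, threads: list[Thread]):
        """Probabilities (T, |S|) and positive index sets for a thread list."""
        probs_t, _ = _forward_batch(self, threads)
        probs = probs_t.data
        positives = [set(np.flatnonzero(row >= self.config.threshold)) for row in probs]
        return probs, positives


def predict_side_effects(v_t: np.ndarray, model: NeatModel):
    """Scores ``W tanh(v_t) + b``, sigmoid probabilities, thresholded positives."""
    scores = model.w_out.data.T @ np.tanh(np.asarray(v_t, dtype=float)) + model.b_out.data
    probs = 1.0 / (1.0 + np.exp(-scores))
    positives = set(np.flatnonzero(probs >= model.config.threshold))
    return scores, probs, positives


def compute_loss(probabilities, labels, model: NeatModel | None = None,
                 lambda1: float = 0.0, lambda2: float = 0.0,
                 clip_eps: float = 1e-7) -> float:
    """Mean per-thread summed binary cross-entropy plus regularizers.

    The cross-entropy term is the negative log-likelihood (minimizable);
    ``lambda1`` scales the Frobenius norm of the expertise matrix and
    ``lambda2`` the L1 norm of the credibility vector.
    """
    P = np.clip(np.asarray(probabilities, dtype=float), clip_eps, 1.0 - clip_eps)
    Y = np.asarray(labels, dtype=float)
    if P.shape != Y.shape:
        raise ValueError(f"probabilities {P.shape} and labels {Y.shape} mismatch")
    if P.ndim == 1:
        P, Y = P[None, :], Y[None, :]
    if P.shape[0] < 1:
        raise ValueError("need at least one thread")
    ce = -(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)).sum(axis=1).mean()
    reg = 0.0
    if model is not None and model.expertise is not None:
        reg += lambda1 * float(np.sqrt((model.expertise.data ** 2).sum()))
    if model is not None and model.credibility is not None:
        reg += lambda2 * float(np.abs(model.credibility.data).sum())
    return float(ce + reg)


# ---------------------------------------------------------------------------
# batched tape forward
# ---------------------------------------------------------------------------

def _batch_arrays(model: NeatModel, threads: list[Thread]):
    tok_rows, authors, segs = [], [], []
    for i, t in enumerate(threads):
        if not t.posts:
            raise ValueError(f"thread {t.thread_id} has no posts")
        for p in t.posts:
            tok_rows.append([model.token_index.get(tok, 0) for tok in p.tokens])
            authors.append(model._user_slot(p.user_id))
            segs.append(i)
    P = len(tok_rows)
    n_max = max(1, max(len(r) for r in tok_rows))
    ids = np.zeros((P, n_max), dtype=np.int64)
    mask = np.zeros((P, n_max), dtype=bool)
    nonempty = np.zeros(P)
    for r, row in enumerate(tok_rows):
        if row:
            ids[r, :len(row)] = row
            mask[r, :len(row)] = True
            nonempty[r] = 1.0
        else:
            mask[r, 0] = True   # keep the softmax defined; output zeroed below
    return ids, mask, nonempty, np.array(authors), np.array(segs)


def _lstm_batch(X: Tensor, mask: np.ndarray, wx: Tensor, wh: Tensor, b: Tensor,
                reverse: bool) -> Tensor:
    """Masked batched LSTM over (P, n, d); state updates skip padding."""
    Pn, n, d = X.data.shape
    e = wh.data.shape[0]
    h = Tensor(np.zeros((Pn, e)))
    c = Tensor(np.zeros((Pn, e)))
    states: list[Tensor | None] = [None] * n
    order = range(n - 1, -1, -1) if reverse else range(n)
    for j in order:
        xj = ad.reshape(ad.narrow(X, j, j + 1, axis=1), (Pn, d))
        z = ad.matmul(xj, wx) + ad.matmul(h, wh) + b
        i_g = ad.sigmoid(ad.narrow(z, 0, e))
        f_g = ad.sigmoid(ad.narrow(z, e, 2 * e))
        g_g = ad.tanh(ad.narrow(z, 2 * e, 3 * e))
        o_g = ad.sigmoid(ad.narrow(z, 3 * e, 4 * e))
        c_new = f_g * c + i_g * g_g
        h_new = o_g * ad.tanh(c_new)
        mj = mask[:, j:j + 1].astype(float)
        c = c_new * mj + c * (1.0 - mj)
        h = h_new * mj + h * (1.0 - mj)
        states[j] = h
    return ad.stack(states, axis=1)     # (P, n, e)


def _attention_pool_t(hidden: Tensor, attn: Tensor, mask: np.ndarray):
    """Masked softmax attention pooling on the tape; weights stay differentiable."""
    logits = ad.einsum_bnc_bc(hidden, attn)
    shift = np.where(mask, logits.data, -np.inf).max(axis=1, keepdims=True)
    ex = ad.exp(logits - shift) * mask.astype(float)
    z = ad.power(ad.sum_(ex, axis=1), -1.0)
    w = ex * ad.reshape(z, (-1, 1))
    return ad.einsum_bn_bnc(w, hidden), w


def _forward_batch(model: NeatModel, threads: list[Thread]):
    """Tape forward for a batch of threads -> (probabilities (T,|S|), trace)."""
    ids, mask, nonempty, authors, segs = _batch_arrays(model, threads)
    Pn = ids.shape[0]
    T = len(threads)
    clusters = model.user_cluster[authors]

    X = ad.gather_rows(model.embedding, ids)
    X = X * mask[:, :, None].astype(float)

    enc = model.enc_params
    weight_tensors = []
    if model.config.encoder == "cnn":
        pooled_blocks = []
        n_c = enc.attention.data.shape[0]
        for k, s in enumerate(enc.kernel_sizes):
            h = ad.tanh(ad.conv1d_same(X, enc.weights[k], enc.biases[k], s))
            a_k = ad.reshape(ad.narrow(enc.attention, k, k + 1, axis=1),
                             (n_c, enc.channels))
            A = ad.gather_rows(a_k, clusters)
            pooled, w = _attention_pool_t(h, A, mask)
            pooled_blocks.append(pooled)
            weight_tensors.append(w)
        v_p = ad.concat(pooled_blocks, axis=-1)
    else:
        hf = _lstm_batch(X, mask, enc.wx_f, enc.wh_f, enc.b_f, reverse=False)
        hb = _lstm_batch(X, mask, enc.wx_b, enc.wh_b, enc.b_b, reverse=True)
        both = ad.concat([hf, hb], axis=-1)
        A = ad.gather_rows(enc.attention, clusters)
        v_p, w = _attention_pool_t(both, A, mask)
        weight_tensors = [w]
    v_p = v_p * nonempty[:, None]
    traces = [w.data for w in weight_tensors]

    if model.expertise is not None:
        v_u = ad.gather_rows(model.expertise, authors)
        complexes = ad.concat([v_p, v_u], axis=-1)
    else:
        complexes = v_p

    if model.credibility is not None:
        w_auth = ad.gather_rows(model.credibility, authors)   # (P, 1)
        complexes = complexes * ad.exp(w_auth)
    v_t = ad.segment_sum(complexes, segs, T)

    scores = ad.matmul(ad.tanh(v_t), model.w_out) + model.b_out
    probs = ad.sigmoid(scores)
    return probs, {"attention": traces, "weights": weight_tensors, "mask": mask,
                   "segments": segs, "authors": authors}


def _batch_loss(model: NeatModel, threads: list[Thread]) -> Tensor:
    cfg = model.config
    probs, aux = _forward_batch(model, threads)
    Y = np.stack([t.label for t in threads]).astype(float)
    pc = ad.clip(probs, cfg.clip_eps, 1.0 - cfg.clip_eps)
    ce = Tensor(Y) * ad.log(pc) + Tensor(1.0 - Y) * ad.log(1.0 - pc)
    loss = ad.sum_(ce) * (-1.0 / len(threads))
    if model.expertise is not None and cfg.lambda1 > 0:
        loss = loss + ad.sqrt(ad.sum_(model.expertise * model.expertise)) * cfg.lambda1
    if model.credibility is not None and cfg.lambda2 > 0:
        loss = loss + ad.sum_(ad.absval(model.credibility)) * cfg.lambda2
    if cfg.att_entropy > 0:
        # KL from uniform attention, averaged over posts and blocks: peaked
        # attention must earn its keep through the prediction loss
        mask = aux["mask"]
        n_posts = mask.shape[0]
        uniform_ent = float(np.log(mask.sum(axis=1)).mean())
        neg_ent = None
        for w in aux["weights"]:
            term = ad.sum_(w * ad.log(w + 1e-12))
            neg_ent = term if neg_ent is None else neg_ent + term
        scale = cfg.att_entropy / (len(aux["weights"]) * n_posts)
        loss = loss + (neg_ent * scale + cfg.att_entropy * uniform_ent)
    return loss


class Adam:
    """Adam with optional decoupled weight decay on a subset of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_params=()):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._decay_ids = {id(p) for p in decay_params}
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and id(p) in self._decay_ids:
                p.data -= self.lr * self.weight_decay * p.data


# ---------------------------------------------------------------------------
# model construction and training
# ---------------------------------------------------------------------------

def permute_post_authors(corpus: ForumCorpus, seed: int) -> ForumCorpus:
    """Randomly permute the post -> author mapping over the whole corpus.

    Text, thread structure and labels are untouched; only user identities
    move, which destroys the credibility/expertise/cluster signal while
    keeping everything else comparable.
    """
    rng = np.random.default_rng([seed, 77])
    authors = [p.user_id for t in corpus.threads for p in t.posts]
    perm = rng.permutation(len(authors))
    shuffled = [authors[i] for i in perm]
    new_threads = []
    k = 0
    for t in corpus.threads:
        posts = []
        for p in t.posts:
            posts.append(Post(user_id=shuffled[k], raw_text=p.raw_text,
                              tokens=list(p.tokens)))
            k += 1
        new_threads.append(Thread(thread_id=t.thread_id, posts=posts,
                                  drugs=list(t.drugs), label=t.label))
    users = {uid: type(u)(user_id=uid, thanks=u.thanks, participated_threads=[])
             for uid, u in corpus.users.items()}
    for t in new_threads:
        for p in t.posts:
            if t.thread_id not in users[p.user_id].participated_threads:
                users[p.user_id].participated_threads.append(t.thread_id)
    return ForumCorpus(threads=new_threads, users=users,
                       vocabulary=corpus.vocabulary, drug_db=corpus.drug_db,
                       folds=corpus.folds)


def build_model(corpus: ForumCorpus, train_ids, config: TrainConfig,
                embedding_table: TokenEmbeddingTable | None = None) -> NeatModel:
    """Assemble a model: user-side preprocessing on the training fold only."""
    cfg = config
    m_star = build_experience_matrix(corpus, train_ids)
    user_ids = list(m_star.user_ids)
    n_users = len(user_ids)

    expertise_t = None
    expertise_proj = None
    g_eff = 0
    expertise_scale = 1.0
    if _uses_ue(cfg.variant):
        expertise_proj = reduce_expertise(m_star, g=cfg.g)
        g_eff = expertise_proj.g
        rows = np.vstack([expertise_proj.scores,
                          expertise_proj.project(np.zeros(len(corpus.vocabulary)))])
        # standardize to unit RMS row norm: the raw PCA scores of count data
        # are orders of magnitude larger than the pooled post vector, and the
        # complex must not be dominated by one half of the concatenation
        rms = float(np.sqrt((rows ** 2).sum(axis=1).mean()))
        if rms > 0:
            expertise_scale = 1.0 / rms
        expertise_t = Tensor(rows * expertise_scale, requires_grad=True)

    cluster_model = None
    user_cluster = np.zeros(n_users + 1, dtype=np.int64)
    n_att_clusters = 1
    if _uses_ca(cfg.variant):
        n_distinct = len(np.unique((m_star.counts > 0).astype(int)[
            (m_star.counts > 0).any(axis=1)], axis=0))
        c_eff = min(cfg.n_clusters, n_distinct)
        if c_eff < 2:
            raise ValueError("too few distinct experience vectors to cluster")
        if c_eff < cfg.n_clusters:
            warnings.warn(f"n_clusters={cfg.n_clusters} clamped to {c_eff}")
        cluster_model = cluster_users(m_star, c=c_eff, seed=cfg.seed)
        n_att_clusters = cluster_model.c
        user_cluster[:n_users] = [cluster_model.assignment[u] for u in user_ids]
        user_cluster[n_users] = cluster_model.fallback_cluster

    tokens = sorted({tok for t in corpus.threads for p in t.posts for tok in p.tokens})
    token_index = {"<unk>": 0}
    for tok in tokens:
        token_index[tok] = len(token_index)
    table = embedding_table or TokenEmbeddingTable(dimension=cfg.embedding_dim,
                                                   oov_seed=cfg.seed)
    if table.dimension != cfg.embedding_dim:
        raise ValueError("embedding table dimension does not match config")
    emb = np.zeros((len(token_index), cfg.embedding_dim))
    for tok, i in token_index.items():
        emb[i] = table.vector(tok)
    embedding = Tensor(emb, requires_grad=cfg.train_embeddings)

    if cfg.encoder == "cnn":
        enc = init_cnn_params(cfg.embedding_dim, n_att_clusters,
                              kernel_sizes=cfg.kernel_sizes, channels=cfg.channels,
                              seed=cfg.seed)
    else:
        enc = init_lstm_params(cfg.embedding_dim, n_att_clusters,
                               hidden=cfg.lstm_hidden, seed=cfg.seed)

    d_in = enc.output_dim + g_eff
    n_s = len(corpus.vocabulary)
    rng = np.random.default_rng([cfg.seed, 13])
    w_out = Tensor(rng.normal(0, np.sqrt(1.0 / d_in), (d_in, n_s)), requires_grad=True)
    b_out = Tensor(np.zeros(n_s), requires_grad=True)

    credibility = (Tensor(np.zeros((n_users + 1, 1)), requires_grad=True)
                   if _uses_cw(cfg.variant) else None)

    return NeatModel(
        config=cfg,
        vocab_names=tuple(corpus.vocabulary.names),
        token_index=token_index,
        embedding=embedding,
        enc_params=enc,
        user_ids=user_ids,
        user_index={u: i for i, u in enumerate(user_ids)},
        user_cluster=user_cluster,
        expertise=expertise_t,
        credibility=credibility,
        w_out=w_out,
        b_out=b_out,
        cluster_model=cluster_model,
        expertise_proj=expertise_proj,
    )


def train_model(corpus: ForumCorpus, train_ids, config: TrainConfig,
                embedding_table: TokenEmbeddingTable | None = None,
                val_ids=None):
    """Train on the given fold with Adam; returns ``(model, log)``.

    ``config.permute_users`` applies the user-identity permutation to the
    whole corpus before any user-side statistics are built.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("training fold is empty")
    if config.permute_users:
        corpus = permute_post_authors(corpus, config.seed)
    model = build_model(corpus, train_ids, config, embedding_table)
    thread_of = {t.thread_id: t for t in corpus.threads}
    train_threads = [thread_of[i] for i in train_ids]
    decay = [model.embedding, *model.enc_params.tensors, model.w_out]
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay, decay_params=decay)
    rng = np.random.default_rng([config.seed, 42])
    log = {"train_loss": [], "val_loss": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_threads))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_threads[i] for i in order[start:start + config.batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, batch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log["train_loss"].append(float(np.mean(losses)))
        if val_ids:
            val_threads = [thread_of[i] for i in val_ids]
            probs, _ = model.predict_threads(val_threads)
            y = np.stack([t.label for t in val_threads])
            log["val_loss"].append(compute_loss(probs, y, model,
                                                config.lambda1, config.lambda2))
    return model, log


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: NeatModel, path) -> None:
    """Single-archive checkpoint (npz) with the config embedded as JSON."""
    arrays = {
        "embedding": model.embedding.data,
        "w_out": model.w_out.data,
        "b_out": model.b_out.data,
        "user_cluster": model.user_cluster,
    }
    enc = model.enc_params
    if model.config.encoder == "cnn":
        for k in range(len(enc.kernel_sizes)):
            arrays[f"cnn_w{k}"] = enc.weights[k].data
            arrays[f"cnn_b{k}"] = enc.biases[k].data
        arrays["attention"] = enc.attention.data
    else:
        for name in ("wx_f", "wh_f", "b_f", "wx_b", "wh_b", "b_b", "attention"):
            arrays[f"lstm_{name}"] = getattr(enc, name).data
    if model.expertise is not None:
        arrays["expertise"] = model.expertise.data
    if model.credibility is not None:
        arrays["credibility"] = model.credibility.data
    meta = {
        "config": asdict(model.config),
        "vocab_names": list(model.vocab_names),
        "token_index": model.token_index,
        "user_ids": model.user_ids,
    }
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> NeatModel:
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["meta"]))
        cfg_d = meta["config"]
        cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
        cfg = TrainConfig(**cfg_d)
        n_att = zf["attention"].shape[0] if cfg.encoder == "cnn" else \
            zf["lstm_attention"].shape[0]
        if cfg.encoder == "cnn":
            enc = CnnEncoderParams(
                kernel_sizes=cfg.kernel_sizes, channels=cfg.channels,
                dim=cfg.embedding_dim,
                weights=[Tensor(zf[f"cnn_w{k}"], requires_grad=True)
                         for k in range(len(cfg.kernel_sizes))],
                biases=[Tensor(zf[f"cnn_b{k}"], requires_grad=True)
                        for k in range(len(cfg.kernel_sizes))],
                attention=Tensor(zf["attention"], requires_grad=True),
            )
        else:
            enc = LstmEncoderParams(
                hidden=cfg.lstm_hidden, dim=cfg.embedding_dim,
                wx_f=Tensor(zf["lstm_wx_f"], requires_grad=True),
                wh_f=Tensor(zf["lstm_wh_f"], requires_grad=True),
                b_f=Tensor(zf["lstm_b_f"], requires_grad=True),
                wx_b=Tensor(zf["lstm_wx_b"], requires_grad=True),
                wh_b=Tensor(zf["lstm_wh_b"], requires_grad=True),
                b_b=Tensor(zf["lstm_b_b"], requires_grad=True),
                attention=Tensor(zf["lstm_attention"], requires_grad=True),
            )
        user_ids = list(meta["user_ids"])
        return NeatModel(
            config=cfg,
            vocab_names=tuple(meta["vocab_names"]),
            token_index={k: int(v) for k, v in meta["token_index"].items()},
            embedding=Tensor(zf["embedding"], requires_grad=True),
            enc_params=enc,
            user_ids=user_ids,
            user_index={u: i for i, u in enumerate(user_ids)},
            user_cluster=zf["user_cluster"].copy(),
            expertise=(Tensor(zf["expertise"], requires_grad=True)
                       if "expertise" in zf else None),
            credibility=(Tensor(zf["credibility"], requires_grad=True)
                         if "credibility" in zf else None),
            w_out=Tensor(zf["w_out"], requires_grad=True),
            b_out=Tensor(zf["b_out"], requires_grad=True),
            cluster_model=None,
            expertise_proj=None,
        )
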