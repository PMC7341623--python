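"""Seeded synthetic health-forum generator with planted ground truth.

The generator emulates the statistical structure the model assumes, not the
surface language of real forums:

* side effects are partitioned into per-cluster *themes*; drugs belong to a
  theme and draw most of their side effects from it, so drugs that are
  discussed together share side effects;
* each user carries a planted cluster and a planted credibility flag;
* a thread samples a theme, drugs from that theme, and participants biased
  toward the theme's user cluster — so a user's accumulated side-effect
  experience carries their cluster signal;
* credible users' posts embed surface forms of side effects that are true
  for the thread; non-credible users embed off-label side effects; everything
  else is filler tokens;
* "thanks" counts are Poisson with class-specific rates, so they correlate
  with planted credibility but are withheld from training.

Every mention's token span is recorded, which makes attention-based
extraction scorable without human annotation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io_data import (
    DrugSideEffectDB,
    ForumCorpus,
    Post,
    SideEffectVocabulary,
    Thread,
    UserRecord,
    build_thread_labels,
)

__all__ = ["SimConfig", "PlantedTruth", "generate_corpus", "summarize_planted_truth",
           "write_truth", "load_truth"]

# substream domains under the master seed
_D_DRUGS, _D_USERS, _D_THREAD, _D_THANKS = 0, 1, 2, 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic forum.

    Counts are desk-scale analogues of a large public health-forum crawl;
    probabilities encode how strongly credible/non-credible behavior and
    cluster structure are expressed.
    """

    n_users: int = 200
    n_threads: int = 500
    n_drugs: int = 30
    n_side_effects: int = 40
    n_clusters: int = 4
    effects_per_drug: tuple[int, int] = (3, 6)
    posts_per_thread: tuple[int, int] = (2, 6)
    drugs_per_thread: tuple[int, int] = (1, 3)
    credible_fraction: float = 0.5
    p_true_mention: float = 0.8
    p_noise_mention: float = 0.8
    mention_slots: tuple[int, int] = (2, 4)
    filler_tokens_per_post: tuple[int, int] = (12, 28)
    filler_vocab_size: int = 120
    cluster_affinity: float = 0.85
    variant_prob: float = 0.4
    long_form_prob: float = 0.45
    theme_purity: float = 0.85
    noise_scope: str = "global"    # "global": any off-label effect; "theme": confusable same-theme noise
    thanks_rate_credible: float = 5.0
    thanks_rate_noncredible: float = 1.0
    seed: int = 1

    def validate(self) -> None:
        for name in ("credible_fraction", "p_true_mention", "p_noise_mention",
                     "cluster_affinity", "variant_prob", "long_form_prob", "theme_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0,1]")
        if not 0.0 < self.credible_fraction < 1.0:
            raise ValueError("credible_fraction must be in (0,1)")
        if self.n_clusters > self.n_users:
            raise ValueError("n_clusters must not exceed n_users")
        if self.n_clusters < 1 or self.n_side_effects < self.n_clusters:
            raise ValueError("need at least one side effect per cluster theme")
        if self.effects_per_drug[1] > self.n_side_effects:
            raise ValueError("effects_per_drug upper bound exceeds n_side_effects")
        if self.n_drugs < self.n_clusters:
            raise ValueError("need at least one drug per cluster theme")
        for name in ("effects_per_drug", "posts_per_thread", "drugs_per_thread",
                     "mention_slots", "filler_tokens_per_post"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name}=({lo},{hi}) is not a valid range")
        if self.posts_per_thread[0] < 1:
            raise ValueError("threads need at least one post")
        if self.noise_scope not in ("theme", "global"):
            raise ValueError("noise_scope must be 'theme' or 'global'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for name in ("effects_per_drug", "posts_per_thread", "drugs_per_thread",
                     "mention_slots", "filler_tokens_per_post"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


@dataclass
class PlantedTruth:
    """Generator-side ground truth used by the recovery experiments."""

    user_cluster: dict[str, int]
    user_credible: dict[str, bool]
    # (thread_id, post index) -> list of (start, end, effect index, is_true_for_thread)
    mention_spans: dict[tuple[str, int], list[tuple[int, int, int, bool]]]
    config: SimConfig


def _theme_effects(cfg: SimConfig) -> list[np.ndarray]:
    """Partition side-effect indices into one theme per cluster."""
    return [np.array(part) for part in
            np.array_split(np.arange(cfg.n_side_effects), cfg.n_clusters)]


def _build_vocabulary(cfg: SimConfig) -> SideEffectVocabulary:
    names = [f"se{i:03d}" for i in range(cfg.n_side_effects)]
    variants = {
        n: tuple(f"{n}x{c}" for c in range(cfg.n_clusters)) + (f"{n} flareup",)
        for n in names
    }
    return SideEffectVocabulary.from_names(names, variants)


def _build_drug_db(cfg: SimConfig, vocab: SideEffectVocabulary) -> DrugSideEffectDB:
    rng = _rng(cfg.seed, _D_DRUGS)
    themes = _theme_effects(cfg)
    effects_of: dict[str, frozenset[int]] = {}
    for d in range(cfg.n_drugs):
        theme = themes[d % cfg.n_clusters]
        k = int(rng.integers(cfg.effects_per_drug[0], cfg.effects_per_drug[1] + 1))
        chosen: set[int] = set()
        while len(chosen) < k:
            if rng.random() < cfg.theme_purity:
                chosen.add(int(rng.choice(theme)))
            else:
                chosen.add(int(rng.integers(cfg.n_side_effects)))
        effects_of[f"drug{d:03d}"] = frozenset(chosen)
    return DrugSideEffectDB(effects_of)


def _mention_tokens(cfg: SimConfig, rng: np.random.Generator,
                    effect_idx: int, author_cluster: int) -> tuple[str, ...]:
    """A surface form for one mention: canonical token, a cluster-specific
    variant, or a multiword phrase (side effects are often verbalized as
    several words)."""
    name = f"se{effect_idx:03d}"
    r = rng.random()
    if r < cfg.variant_prob:
        head = f"{name}x{author_cluster}"
    else:
        head = name
    r2 = rng.random()
    if r2 < cfg.long_form_prob:
        return ("badly", head, "flareup")
    if r2 < 2 * cfg.long_form_prob:
        return (head, "flareup")
    return (head,)


def generate_corpus(config: SimConfig) -> tuple[ForumCorpus, PlantedTruth]:
    """Deterministic function of ``config.seed``; see module docstring.

    Per-entity random substreams are derived from the master seed, so the
    first *k* threads are identical across configs that differ only in
    ``n_threads``.
    """
    cfg = config
    cfg.validate()
    vocab = _build_vocabulary(cfg)
    db = _build_drug_db(cfg, vocab)
    themes = _theme_effects(cfg)
    drug_names = sorted(db.effects_of)
    drugs_by_theme = [[drug_names[d] for d in range(cfg.n_drugs) if d % cfg.n_clusters == c]
                      for c in range(cfg.n_clusters)]

    u_rng = _rng(cfg.seed, _D_USERS)
    user_ids = [f"u{j:04d}" for j in range(cfg.n_users)]
    user_cluster = {uid: int(u_rng.integers(cfg.n_clusters)) for uid in user_ids}
    user_credible = {uid: bool(u_rng.random() < cfg.credible_fraction) for uid in user_ids}
    users_by_cluster = [[u for u in user_ids if user_cluster[u] == c]
                        for c in range(cfg.n_clusters)]
    # a cluster can come out empty at tiny n_users; fall back to the full pool
    users_by_cluster = [us if us else list(user_ids) for us in users_by_cluster]

    all_effects = np.arange(cfg.n_side_effects)
    filler = [f"w{j:03d}" for j in range(cfg.filler_vocab_size)]
    threads: list[Thread] = []
    mention_spans: dict[tuple[str, int], list[tuple[int, int, int, bool]]] = {}

    for ti in range(cfg.n_threads):
        rng = _rng(cfg.seed, _D_THREAD, ti)
        thread_id = f"t{ti:05d}"
        theme = int(rng.integers(cfg.n_clusters))
        k_drugs = int(rng.integers(cfg.drugs_per_thread[0], cfg.drugs_per_thread[1] + 1))
        k_drugs = min(k_drugs, len(drugs_by_theme[theme]))
        drugs = [str(d) for d in rng.choice(drugs_by_theme[theme], size=k_drugs, replace=False)]
        thread = Thread(thread_id=thread_id, posts=[], drugs=drugs)
        y = build_thread_labels(thread, db, cfg.n_side_effects)
        true_effects = np.flatnonzero(y)
        # "theme" noise is confusable with the truth (side effects of related
        # drugs, not trivially filterable by topic); "global" noise may come
        # from any off-label effect
        if cfg.noise_scope == "theme":
            off_effects = np.setdiff1d(themes[theme], true_effects)
            if len(off_effects) == 0:
                off_effects = np.setdiff1d(all_effects, true_effects)
        else:
            off_effects = np.setdiff1d(all_effects, true_effects)

        n_posts = int(rng.integers(cfg.posts_per_thread[0], cfg.posts_per_thread[1] + 1))
        for pi in range(n_posts):
            if rng.random() < cfg.cluster_affinity:
                author = str(rng.choice(users_by_cluster[theme]))
            else:
                author = str(rng.choice(user_ids))
            n_fill = int(rng.integers(cfg.filler_tokens_per_post[0],
                                      cfg.filler_tokens_per_post[1] + 1))
            items: list[tuple[tuple[str, ...], int | None]] = [
                ((str(rng.choice(filler)),), None) for _ in range(n_fill)
            ]
            n_slots = int(rng.integers(cfg.mention_slots[0], cfg.mention_slots[1] + 1))
            for _ in range(n_slots):
                if user_credible[author]:
                    if rng.random() < cfg.p_true_mention and len(true_effects):
                        eff = int(rng.choice(true_effects))
                        items.append((_mention_tokens(cfg, rng, eff, user_cluster[author]), eff))
                else:
                    if rng.random() < cfg.p_noise_mention and len(off_effects):
                        eff = int(rng.choice(off_effects))
                        items.append((_mention_tokens(cfg, rng, eff, user_cluster[author]), eff))
            order = rng.permutation(len(items))
            tokens: list[str] = []
            spans: list[tuple[int, int, int, bool]] = []
            for j in order:
                toks, eff = items[j]
                if eff is not None:
                    spans.append((len(tokens), len(tokens) + len(toks) - 1, eff,
                                  bool(y[eff])))
                tokens.extend(toks)
            thread.posts.append(Post(user_id=author, raw_text=" ".join(tokens),
                                     tokens=list(tokens)))
            mention_spans[(thread_id, pi)] = spans
        thread.label = y
        threads.append(thread)

    t_rng = _rng(cfg.seed, _D_THANKS)
    users: dict[str, UserRecord] = {}
    for uid in user_ids:
        rate = cfg.thanks_rate_credible if user_credible[uid] else cfg.thanks_rate_noncredible
        users[uid] = UserRecord(user_id=uid, thanks=int(t_rng.poisson(rate)))
    for t in threads:
        for p in t.posts:
            if t.thread_id not in users[p.user_id].participated_threads:
                users[p.user_id].participated_threads.append(t.thread_id)

    corpus = ForumCorpus(threads=threads, users=users, vocabulary=vocab, drug_db=db)
    corpus.validate()
    truth = PlantedTruth(user_cluster=user_cluster, user_credible=user_credible,
                         mention_spans=mention_spans, config=cfg)
    return corpus, truth


def summarize_planted_truth(corpus: ForumCorpus, truth: PlantedTruth) -> dict[str, float]:
    """Corpus-level statistics (the usual dataset-description table)."""
    if set(truth.user_cluster) != set(corpus.users):
        raise ValueError("corpus and truth do not come from the same generate call")
    if not corpus.threads:
        raise ValueError("empty corpus")
    span_threads = {tid for tid, _ in truth.mention_spans}
    if not span_threads <= {t.thread_id for t in corpus.threads}:
        raise ValueError("truth references threads absent from the corpus")
    n_posts = sum(len(t.posts) for t in corpus.threads)
    n_words = sum(p.n for t in corpus.threads for p in t.posts)
    # experienced side effects: union over a user's threads' labels
    label_of = {t.thread_id: t.label for t in corpus.threads}
    experienced = [
        len(set().union(*[set(np.flatnonzero(label_of[tid])) for tid in u.participated_threads]))
        if u.participated_threads else 0
        for u in corpus.users.values()
    ]
    return {
        "n_users": len(corpus.users),
        "n_threads": len(corpus.threads),
        "n_drugs": len(corpus.drug_db),
        "n_side_effects": len(corpus.vocabulary),
        "avg_words_per_post": n_words / n_posts,
        "avg_posts_per_thread": n_posts / len(corpus.threads),
        "avg_threads_per_user": (
            sum(len(u.participated_threads) for u in corpus.users.values()) / len(corpus.users)
        ),
        "avg_side_effects_per_thread": (
            float(np.mean([int(t.label.sum()) for t in corpus.threads]))
        ),
        "avg_experienced_side_effects_per_user": float(np.mean(experienced)),
    }


def write_truth(truth: PlantedTruth, path) -> None:
    import json

    obj = {
        "user_cluster": truth.user_cluster,
        "user_credible": truth.user_credible,
        "mention_spans": {
            f"{tid}|{pi}": [[s, e, eff, bool(flag)] for s, e, eff, flag in spans]
            for (tid, pi), spans in truth.mention_spans.items()
        },
        "config": asdict(truth.config),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True)


def load_truth(path) -> PlantedTruth:
    import json

    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    spans = {}
    for key, lst in obj["mention_spans"].items():
        tid, pi = key.rsplit("|", 1)
        spans[(tid, int(pi))] = [(int(s), int(e), int(eff), bool(flag))
                                 for s, e, eff, flag in lst]
    return PlantedTruth(
        user_cluster={k: int(v) for k, v in obj["user_cluster"].items()},
        user_credible={k: bool(v) for k, v in obj["user_credible"].items()},
        mention_spans=spans,
        config=SimConfig.from_dict(obj["config"]),
    )
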