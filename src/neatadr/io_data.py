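"""Data model and file I/O for health-forum side-effect discovery.

The on-disk dialects are deliberately plain text:

* drug -> side-effect database: two-column TSV, ``drug<TAB>side_effect``;
* discussion corpus: JSON Lines, one thread object per line with fields
  ``thread_id``, ``posts`` (list of ``{"user_id", "text"}``) and ``drugs``;
* users: two-column TSV, ``user_id<TAB>thanks``.

A thread's label is the union of the side effects of every drug it
mentions, encoded as a binary vector over a fixed side-effect vocabulary:
the "distant supervision" signal that replaces per-statement annotation.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SideEffectVocabulary",
    "DrugSideEffectDB",
    "Post",
    "UserRecord",
    "Thread",
    "ForumCorpus",
    "CorpusFormatError",
    "default_stopwords",
    "tokenize_post",
    "load_side_effect_db",
    "write_side_effect_db",
    "build_thread_labels",
    "load_corpus",
    "write_corpus",
    "load_users",
    "write_users",
    "convert_forum_dump",
    "assign_folds",
]


class CorpusFormatError(ValueError):
    """Malformed input file (bad row, missing field, dangling reference)."""


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def default_stopwords() -> frozenset[str]:
    """The frozen English stop-word list shipped with the package."""
    text = resources.files("neatadr").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


def tokenize_post(raw_text: str, stopword_list: frozenset[str] | set[str] | None = None) -> list[str]:
    """Lowercase word tokens with stop words and pure punctuation removed.

    Order is preserved; an empty string yields an empty list. Tokenization is
    idempotent on its own output (tokens contain no uppercase, punctuation or
    stop words).
    """
    if stopword_list is None:
        stopword_list = default_stopwords()
    return [t for t in _TOKEN_RE.findall(raw_text.lower()) if t not in stopword_list]


@dataclass(frozen=True)
class SideEffectVocabulary:
    """Ordered canonical side-effect names with a stable name->index map."""

    names: tuple[str, ...]
    index: dict[str, int] = field(compare=False)
    variants: dict[str, tuple[str, ...]] = field(default_factory=dict, compare=False)

    @classmethod
    def from_names(cls, names, variants=None) -> "SideEffectVocabulary":
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("side-effect names must be unique")
        if not names:
            raise ValueError("vocabulary must contain at least one side effect")
        variants = {k: tuple(v) for k, v in (variants or {}).items()}
        return cls(names=names, index={n: i for i, n in enumerate(names)}, variants=variants)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class DrugSideEffectDB:
    """Map from lowercase drug name to the index set of its side effects."""

    effects_of: dict[str, frozenset[int]]

    def __len__(self) -> int:
        return len(self.effects_of)


@dataclass
class Post:
    """One forum message: author, raw text and its filtered token sequence."""

    user_id: str
    raw_text: str
    tokens: list[str]

    @property
    def n(self) -> int:
        return len(self.tokens)


@dataclass
class UserRecord:
    user_id: str
    thanks: int = 0
    participated_threads: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.thanks < 0:
            raise ValueError(f"thanks must be >= 0 for user {self.user_id}")


@dataclass
class Thread:
    """An ordered list of (post, author) pairs discussing a set of drugs."""

    thread_id: str
    posts: list[Post]
    drugs: list[str]
    label: np.ndarray | None = None  # binary vector over the vocabulary


@dataclass
class ForumCorpus:
    threads: list[Thread]
    users: dict[str, UserRecord]
    vocabulary: SideEffectVocabulary
    drug_db: DrugSideEffectDB
    folds: dict[str, int] | None = None

    def validate(self) -> None:
        for t in self.threads:
            for p in t.posts:
                if p.user_id not in self.users:
                    raise CorpusFormatError(
                        f"thread {t.thread_id}: post author {p.user_id!r} has no user record"
                    )
            for d in t.drugs:
                if d not in self.drug_db.effects_of:
                    raise CorpusFormatError(
                        f"thread {t.thread_id}: drug {d!r} missing from the drug database"
                    )


def load_side_effect_db(path, vocabulary: SideEffectVocabulary | None = None):
    """Read a ``drug<TAB>side_effect`` TSV.

    When no vocabulary is given one is built from the sorted union of side
    effects so indices are stable across runs. Returns ``(db, vocabulary)``.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            drug, effect = cols[0].strip().lower(), cols[1].strip()
            if not drug or not effect:
                raise CorpusFormatError(f"{path}:{lineno}: empty drug or side-effect name")
            pairs.append((drug, effect))
    if not pairs:
        raise CorpusFormatError(f"{path}: empty drug/side-effect database")
    if vocabulary is None:
        vocabulary = SideEffectVocabulary.from_names(sorted({e for _, e in pairs}))
    effects: dict[str, set[int]] = {}
    for drug, effect in pairs:
        if effect not in vocabulary.index:
            raise CorpusFormatError(f"side effect {effect!r} not in the supplied vocabulary")
        effects.setdefault(drug, set()).add(vocabulary.index[effect])
    db = DrugSideEffectDB({d: frozenset(s) for d, s in effects.items()})
    return db, vocabulary


def write_side_effect_db(db: DrugSideEffectDB, vocabulary: SideEffectVocabulary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for drug in sorted(db.effects_of):
            for idx in sorted(db.effects_of[drug]):
                fh.write(f"{drug}\t{vocabulary.names[idx]}\n")


def build_thread_labels(thread: Thread, db: DrugSideEffectDB, n_side_effects: int,
                        strict: bool = True) -> np.ndarray:
    """Binary label vector: the union of the thread's drugs' side effects."""
    y = np.zeros(n_side_effects, dtype=np.uint8)
    for drug in thread.drugs:
        d = drug.lower()
        if d not in db.effects_of:
            if strict:
                raise CorpusFormatError(f"unknown drug {drug!r} in thread {thread.thread_id}")
            warnings.warn(f"skipping unknown drug {drug!r} in thread {thread.thread_id}")
            continue
        for idx in db.effects_of[d]:
            y[idx] = 1
    return y


def load_users(path) -> dict[str, UserRecord]:
    """Read a ``user_id<TAB>thanks`` TSV."""
    users: dict[str, UserRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            uid, thanks = cols[0].strip(), cols[1].strip()
            try:
                thanks_n = int(thanks)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: thanks is not an integer") from exc
            users[uid] = UserRecord(user_id=uid, thanks=thanks_n)
    return users


def write_users(users: dict[str, UserRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for uid in sorted(users):
            fh.write(f"{uid}\t{users[uid].thanks}\n")


def load_corpus(path, db: DrugSideEffectDB, vocabulary: SideEffectVocabulary,
                users_path=None, stopword_list=None, strict: bool = True) -> ForumCorpus:
    """Read a JSON Lines thread file, tokenize posts and build labels.

    Users absent from ``users_path`` (or when no users file is given) get a
    record with zero thanks; referential integrity is always checked.
    """
    if stopword_list is None:
        stopword_list = default_stopwords()
    users = load_users(users_path) if users_path is not None else {}
    threads: list[Thread] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON") from exc
            for key in ("thread_id", "posts", "drugs"):
                if key not in obj:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: thread object missing field {key!r}"
                    )
            posts = []
            for p in obj["posts"]:
                if "user_id" not in p or "text" not in p:
                    raise CorpusFormatError(
                        f"thread {obj['thread_id']}: post missing user_id/text"
                    )
                uid = str(p["user_id"])
                posts.append(Post(user_id=uid, raw_text=p["text"],
                                  tokens=tokenize_post(p["text"], stopword_list)))
                users.setdefault(uid, UserRecord(user_id=uid))
            if not posts:
                raise CorpusFormatError(f"thread {obj['thread_id']}: no posts")
            thread = Thread(thread_id=str(obj["thread_id"]), posts=posts,
                            drugs=[str(d).lower() for d in obj["drugs"]])
            thread.label = build_thread_labels(thread, db, len(vocabulary), strict=strict)
            threads.append(thread)
    for t in threads:
        for p in t.posts:
            if t.thread_id not in users[p.user_id].participated_threads:
                users[p.user_id].participated_threads.append(t.thread_id)
    corpus = ForumCorpus(threads=threads, users=users, vocabulary=vocabulary, drug_db=db)
    corpus.validate()
    return corpus


def write_corpus(corpus: ForumCorpus, path) -> None:
    """Write the thread file back as JSON Lines (inverse of :func:`load_corpus`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in corpus.threads:
            obj = {
                "thread_id": t.thread_id,
                "posts": [{"user_id": p.user_id, "text": p.raw_text} for p in t.posts],
                "drugs": list(t.drugs),
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def convert_forum_dump(dump_path, out_corpus_path, out_users_path):
    """Stub for converting a raw forum crawl into the canonical JSON Lines.

    Public forum dumps come in site-specific layouts (HTML archives,
    per-board SQL exports, ad hoc flat files); no single parser covers
    them. This package treats the JSONL thread schema written by
    :func:`write_corpus` plus the ``user_id<TAB>thanks`` TSV as canonical,
    and a site-specific converter should produce exactly those two files:

    * one JSON object per line with ``thread_id``, ``posts`` (list of
      ``{"user_id", "text"}`` in posting order) and ``drugs`` (the
      thread-level mentioned-drug list, however it was curated);
    * one user per line with their received-thanks count.

    Implement the crawl-specific parsing here or in a separate script.
    """
    raise NotImplementedError(
        "site-specific forum dumps need a site-specific converter; "
        "produce the canonical JSONL + users TSV described in the docstring")


def assign_folds(corpus: ForumCorpus, n_folds: int = 10, seed: int = 0) -> dict[str, int]:
    """Random fold assignment for cross-validation, stored on the corpus."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    ids = [t.thread_id for t in corpus.threads]
    perm = rng.permutation(len(ids))
    folds = {ids[j]: int(i % n_folds) for i, j in enumerate(perm)}
    corpus.folds = folds
    return folds
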