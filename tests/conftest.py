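import numpy as np
import pytest

from neatadr.io_data import (
    DrugSideEffectDB,
    ForumCorpus,
    Post,
    SideEffectVocabulary,
    Thread,
    UserRecord,
    build_thread_labels,
)


@pytest.fixture()
def tiny_vocab():
    return SideEffectVocabulary.from_names(["diarrhea", "dry mouth", "headache"])


@pytest.fixture()
def tiny_db(tiny_vocab):
    return DrugSideEffectDB({
        "zoloft": frozenset({0, 1}),
        "paxil": frozenset({1, 2}),
    })


def make_thread(thread_id, posts, drugs, db, n_effects):
    t = Thread(thread_id=thread_id,
               posts=[Post(user_id=u, raw_text=" ".join(toks), tokens=list(toks))
                      for u, toks in posts],
               drugs=list(drugs))
    t.label = build_thread_labels(t, db, n_effects)
    return t


@pytest.fixture()
def tiny_corpus(tiny_vocab, tiny_db):
    threads = [
        make_thread("t0", [("alice", ["headache", "pills"]),
                           ("bob", ["fine", "thanks"])], ["zoloft"],
                    tiny_db, len(tiny_vocab)),
        make_thread("t1", [("alice", ["dry", "mouth"])], ["paxil"],
                    tiny_db, len(tiny_vocab)),
        make_thread("t2", [("carol", ["nothing"])], ["zoloft", "paxil"],
                    tiny_db, len(tiny_vocab)),
    ]
    users = {}
    for name, thanks in (("alice", 5), ("bob", 0), ("carol", 2)):
        users[name] = UserRecord(user_id=name, thanks=thanks)
    for t in threads:
        for p in t.posts:
            if t.thread_id not in users[p.user_id].participated_threads:
                users[p.user_id].participated_threads.append(t.thread_id)
    return ForumCorpus(threads=threads, users=users, vocabulary=tiny_vocab,
                       drug_db=tiny_db)


@pytest.fixture(scope="session")
def default_corpus_and_truth():
    """One default-scale synthetic corpus shared across tests (seed 1)."""
    from neatadr.synthetic import SimConfig, generate_corpus

    return generate_corpus(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
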