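# neatadr

Self-supervised discovery of drug side effects from online health-forum
discussions, with joint modeling of **user credibility**, **user
expertise**, and **cluster-sensitive attention** over post text.

## The problem

Patients discuss drugs and their adverse reactions in forum threads. Each
thread `t` is an ordered list of post–user pairs `Q_t` and mentions a set
of drugs `D_t`; looking those drugs up in a drug → side-effect database
gives the thread an *aggregated* label `S_t = ∪_{d∈D_t} S_d`, a binary
vector over a fixed side-effect vocabulary `S` — supervision for free, with
no per-statement annotation. The task is multi-label: predict `S_t` from
the thread's text. Forum content is noisy, so the model also learns *who to
believe*.

## The model

Each post is encoded by an attention encoder (BiLSTM with hidden size 32,
or a CNN with kernels 3/4/5 × 100 channels); attention weights are a
softmax over dot products between hidden states and a learnable attention
vector **per user cluster**, where clusters come from cosine K-means on
binarized user experience vectors. The post vector is concatenated with the
author's PCA-reduced **expertise vector** `v_u` (counts of threads the user
participated in per side effect), and the thread representation is the
credibility-weighted sum

    v_t = Σ_i  e^{w_{u_i}} · v^p_{u_i}

with one learnable scalar `w_u` per user, initialized to 0. Prediction is
`σ(W tanh(v_t) + b)`, trained with per-label cross-entropy plus
`λ1‖V_u‖_F + λ2‖w‖_1`, with Adam. The exponential weighting implements the
truth-discovery principle: users whose content supports correct predictions
earn a higher multiplier; for a single label the credibility gradient has
the closed form implemented (and tested against finite differences and the
autodiff tape) in `neatadr.neat_core`.

Everything runs on numpy through a small reverse-mode autodiff engine
(`neatadr.autodiff`) — no GPU framework required. Ablation variants gate
the components: `vanilla` (encoder only), `wpe` (+credibility weights),
`wpeu` (+expertise), `neat` (+cluster attention); `--permute-users` trains
the user-identity–scrambled control (uNEAT).

Because real health-forum dumps cannot ship with the package, a seeded
synthetic-forum generator (`neatadr.synthetic`) plants cluster structure,
per-user credibility, drug co-prescription themes, thanks counts, and exact
side-effect mention spans, so every mechanism is testable end to end at
desk scale.

## Worked example

Generate a synthetic forum, cluster its users, and train the full model:

```bash
neatadr simulate --seed 1 --out data/
neatadr cluster --corpus data/corpus.jsonl --db data/drug_db.tsv \
    --users data/users.tsv --c 4
neatadr train --corpus data/corpus.jsonl --db data/drug_db.tsv \
    --users data/users.tsv --variant neat --seed 1 --out model.npz
neatadr evaluate --model model.npz --corpus data/corpus.jsonl \
    --db data/drug_db.tsv --users data/users.tsv \
    --truth data/truth.json --report report.json
```

`simulate` prints the corpus statistics it generated:

```
{
  "avg_experienced_side_effects_per_user": 18.66,
  "avg_posts_per_thread": 4.006,
  "avg_side_effects_per_thread": 7.058,
  "avg_threads_per_user": 9.665,
  "avg_words_per_post": 25.704,
  "n_drugs": 30,
  "n_side_effects": 40,
  "n_threads": 500,
  "n_users": 200
}
```

i.e. 500 threads by 200 users over a 40-effect vocabulary, ~4 posts per
thread — a ~100× scale-down of a public health-forum crawl with the same
shape. `cluster` reports the cosine-K-means silhouette of the user
clustering, and `train` prints held-out example-based precision/recall/F1
of the thresholded multi-label predictions. On this corpus the full model
reaches F1 ≈ 0.56 on held-out threads versus ≈ 0.51 for its
credibility-agnostic ablation and ≈ 0.36 with user identities permuted —
the direction of the component contributions, at desk scale.

As a library:

```python
from neatadr import SimConfig, generate_corpus
from neatadr.evaluation import desk_train_config, run_discovery_experiment

corpus, truth = generate_corpus(SimConfig(seed=1))
model, report, log = run_discovery_experiment(corpus,
                                              desk_train_config("neat", seed=1))
print(report.precision, report.recall, report.f1)
```

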