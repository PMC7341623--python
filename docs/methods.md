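# Methods

## The task and the model

Health-forum threads discuss drugs, and the union of the side effects of a
thread's mentioned drugs (looked up in a drug → side-effect database) gives
every thread a binary label vector over a fixed side-effect vocabulary `S`
without any human annotation. The model predicts that vector from the
thread's text, treating discovery as multi-label classification.

A thread is an ordered list of (post, author) pairs. Each post is tokenized
(lowercase word tokens, stop words removed, using the frozen English
stop-word list shipped in the package) and encoded to a vector `v_p` by one
of two attention encoders:

* **BiLSTM encoder** — a single bidirectional LSTM layer (hidden size
  `e = 32` per direction). One attention weight per position is computed
  from the concatenated state `[h_f; h_b]` against a 2e-dimensional
  per-cluster attention vector and shared by both directions; the pooled
  forward and backward vectors are concatenated (output 2e = 64).
* **CNN encoder** — convolution blocks with kernel sizes 3/4/5 and 100
  output channels each, tanh activation, centered zero same-padding (so the
  attention trace aligns with token positions). Each block has its own
  per-cluster attention vector and is attention-pooled; block outputs are
  concatenated (output 300).

Attention logits are plain dot products `a · h_j`; the softmax is
max-shifted, which leaves the weights unchanged. For the BiLSTM, the one
ambiguity in sharing a single weight across two directions is resolved by
computing it from the concatenated bidirectional state, which realizes
"shared weights applied to both directions" exactly.

**User expertise.** The experience matrix `M*` counts, per user and side
effect, the training-fold threads that user posted in whose label includes
the effect. PCA (training fold only) reduces `M*` to `g` components
(default `g = 100`, clamped to `min(|U|, |S|)` on small data); each user's
score row, projected through the stored loadings for unseen users, is the
expertise vector `v_u`. At model assembly the expertise rows are
standardized to unit RMS row norm: raw PCA scores of count data are an
order of magnitude larger than the pooled post vector, and the post–user
complex must not be dominated by one half of the concatenation. The rows
are trainable parameters, with the loss carrying `λ1 · ‖V_u‖_F`.

**User clusters.** Binarized experience rows are L2-normalized and
clustered with K-means (10 restarts; Euclidean on the unit sphere equals
cosine K-means). The normalization is L2 precisely because it makes that
equivalence exact. All-zero rows are excluded from fitting (cosine is
undefined at zero) and assigned to the largest cluster. Cluster count
defaults to 7 and clamps to the data; silhouette scans use cosine distance.

**Credibility weighting.** Every user has a learnable scalar `w_u`,
initialized to 0, and the thread representation is
`v_t = Σ_i e^{w_{u_i}} v^p_{u_i}` — the truth-discovery principle that
content from credible sources counts for more. Prediction is
`σ(W tanh(v_t) + b)` with one sigmoid output per side effect. The loss is
the mean per-thread summed binary cross-entropy (negative log-likelihood;
the printed positive-sign form of the objective is not minimizable and the
single-label logistic rewrite confirms the NLL reading), plus
`λ1 ‖V_u‖_F + λ2 ‖w‖_1`. Probabilities are clipped at `1e-7` inside the
loss. Ablation variants gate the components: `vanilla` (encoder only),
`wpe` (+credibility), `wpeu` (+expertise), `neat` (+cluster attention);
without cluster attention a single shared attention vector is used. `uNEAT`
permutes the post → author mapping over the whole corpus before any
user-side statistic is built, destroying identity signal while keeping the
text.

**Credibility gradient.** For a single thread and label `s` the loss is the
logistic loss `log(1 + exp(−y_s(w_sᵀ tanh(v_t) + b_s)))` and

    ∂L/∂w_u = −y_s · w_sᵀ[(1 − tanh²(v_t)) ⊙ e^{w_u} v^p_u]
              / (1 + exp(y_s(w_sᵀ tanh(v_t) + b_s)))

Correct differentiation carries the leading minus sign; without it a
credible user's score would *fall* under gradient descent, contradicting
the intended behavior (small update when the prediction is already
confident and correct; score rises when the user's solo content supports
the truth; magnitude proportional to `e^{w_u}`). This closed form, central
finite differences, and the package's reverse-mode tape are held to mutual
agreement in the acceptance checks.

## Numerical engine

No GPU framework is used: the model runs on a small reverse-mode
automatic-differentiation engine over numpy (`neatadr.autodiff`). Each
needed operation (dense algebra, pointwise nonlinearities, embedding
gather, same-padded 1-D convolution via im2col, masked softmax attention,
segment sums) is one tape node with a hand-coded backward rule, so a whole
minibatch is a few dozen vectorized nodes. Training uses Adam
(β = 0.9/0.999, ε = 1e-8) with optional decoupled weight decay restricted
to the shared network weights (embeddings, encoder, classifier) — the
expertise and credibility parameters keep their own explicit regularizers.
Batches pad posts to the batch maximum; padding positions are masked out of
both the convolution inputs and the attention softmax, and LSTM state
updates are skipped on padding so left-aligned sequences encode identically
to the single-post path. Empty posts encode to the zero vector and then
contribute only expertise. Determinism: every random draw flows from
integer-keyed `numpy` generator streams; the synthetic generator gives each
entity its own substream, so corpora are byte-identical across runs and
extending `n_threads` does not perturb earlier threads.

## Word vectors

Pre-trained vector files (GloVe/word2vec text dialect) are supported; when
none is supplied, out-of-vocabulary tokens get reproducible seeded random
vectors. The experiments additionally *pre-train* vectors on the training
fold with shifted PPMI (shift `log 5`) and truncated SVD — the classic
count-based family of distributional embeddings. This matters more than it
may look: with independent random vectors, "informative token" is not
linearly detectable (hundreds of arbitrary directions in 100 dimensions),
so the attention vector cannot prefer side-effect mentions over background
text; distributional pre-training restores the shared structure that
pre-trained embeddings provide in the original setting.

## Synthetic forum generator

The generator plants the structure the model assumes and records the ground
truth needed to test recovery:

* side effects partition into per-cluster *themes*; each drug belongs to a
  theme and draws its 3–6 side effects mostly from it (purity 0.85), so
  co-discussed drugs share effects;
* each of the 200 users carries a planted cluster (uniform) and an
  independent credibility flag (probability 0.5);
* each of the 500 threads samples a theme, 1–3 of its drugs, and 2–6 posts
  whose authors come from the theme's cluster with probability 0.85
  (`cluster_affinity`), else uniformly;
* posts are 12–28 filler tokens (vocabulary of 120) plus 2–4 mention slots:
  credible authors fill a slot with a surface form of a *true* side effect
  (one in the thread's label) with probability 0.8; non-credible authors
  fill it with an *off-label* effect with probability 0.8. Off-label
  effects default to any effect outside the thread's label
  (`noise_scope="global"`); a `"theme"` option restricts noise to the same
  theme, i.e. misinformation confusable with the truth;
* surface forms are the canonical token, a cluster-specific variant (users
  in a group verbalize effects similarly), or multiword phrases (10% one
  token, 45% two, 45% three) — side effects are typically multiword
  phrases; every mention's token span and truth flag is recorded;
* "thanks" are Poisson(5) for credible and Poisson(1) for non-credible
  users, used only for evaluation.

These counts are desk-scale: the reference corpus the structure emulates
has ~15 k users, ~78 k labeled threads, |S| = 315, ~4 posts per thread and
~67 words per post; this generator keeps the posts-per-thread statistic and
scales everything else down roughly 40–150×. What the generator does *not*
model: grammar or any linguistic structure, question-versus-answer post
roles, temporal dynamics, users whose credibility varies by topic, and
label noise in the drug database itself. Recovery results on it therefore
show that the estimation machinery works when the model's assumptions hold,
not that the assumptions hold for real forums.

## Experiment protocols (desk scale)

Two training presets, both CNN-based, 12 epochs, batch 16, Adam 1e-3,
`λ1 = 1e-5`, `λ2 = 1e-4`, 4 clusters, single 80/20 thread split per seed
(in place of full 10-fold cross-validation; the split and all training are
re-run per seed):

* **discovery/credibility** (`desk_train_config`): PPMI-SVD vectors at full
  rank, fine-tuned, with decoupled weight decay 0.1 on the shared weights.
  Weight decay is what keeps a 500-thread corpus from being memorized
  through rare-token fingerprints, which would silence the error signal the
  credibility weights learn from.
* **extraction** (`extraction_train_config`): PPMI-SVD vectors truncated to
  rank 30 and frozen (background filler gets near-zero vectors), plus an
  attention-entropy penalty (weight 2.0, the KL from uniform attention
  averaged over posts and blocks) so attention concentrates only where
  concentration pays off in the loss. Both choices keep the attention trace
  interpretable as a mention locator.

The defaults in `TrainConfig` itself stay at the plain setting (trainable
embeddings, no weight decay, no entropy penalty, 30 epochs).

**Credibility recovery** is read from the credibility-weighted encoder
(`wpe`), the configuration that isolates the mechanism under test, fitted
on the whole corpus for 20 epochs — the analysis judges `w_u` against
external signals (planted flags and thanks), so no thread split is needed
and every thread contributes evidence about its authors. Seed-to-seed the
recovery AUC spans roughly 0.70–0.87 with a mean near 0.81; per-user
evidence (~10 threads) is the binding constraint. This is
a deliberate protocol choice backed by two findings from this codebase,
both reproducible at desk scale: (1) per-cluster attention learns to ignore
off-theme tokens, which filters planted off-label noise *before* the
credibility weight can be blamed for it; (2) trainable per-user expertise
vectors form an alternative identity channel that can absorb reliability
information. Both are desirable for prediction and both dilute `w_u` as a
*ranking* signal — in the full model its separation of planted classes is
real but weak (AUC ≈ 0.6–0.7 here). The findings echo the original
observation that the attention is selective about what it emphasizes.

**Extraction scoring**: positions whose attention weight (max over CNN
blocks) exceeds `τ/n` with `τ = 2` are merged into segments; a segment is
correct iff it overlaps a recorded mention span whose effect is in the
thread's label. The extraction corpus raises `p_true_mention` to 0.9 and
lowers `p_noise_mention` to 0.2: the check measures whether attention
*localizes* informative segments, with gold mentions predominantly genuine
as in the original evaluation; robustness to systematic decoys is the
credibility experiments' job, and the adversarial default corpus is where
they are measured. Note the kernel geometry: an attended position stands
for a 3–5-token window, so single-token gold spans can be missed by one
position; multiword surface forms keep the overlap test meaningful.

## Metric conventions

* **P/R/F1** are example-based: per-thread scores on predicted/true index
  sets, averaged over threads (micro-averaging is available as an option).
  Empty prediction against nonempty truth scores 0 on all three; empty
  against empty scores 1.
* **Spearman** uses average ranks on ties; constant vectors yield NaN
  (undefined), reported as such.
* **nDCG@k** (default k = 2) uses linear gains (raw thanks counts; thanks
  can be large and exponential gains would explode), `log2(rank+1)`
  discounts, ranking ties broken by user id; threads with fewer than two
  participants are skipped and counted; all-zero-relevance threads score 1.
* The question-frequency ranking baseline is omitted: the data model has no
  question/answer post typing. Post-frequency and random baselines are
  computed in-package.

## Known limitations

* Desk-scale corpora leave ~10 threads of evidence per user, so credibility
  rankings of low-activity users are noisy; the AUC numbers here would not
  transfer to users with one or two posts.
* The two training presets were fixed once for this study; no hyperparameter
  search is provided or implied.
* The attention-extraction precision depends on the kernel/receptive-field
  geometry discussed above; a span-calibrated extraction head is out of
  scope.
* Scraping, HTML parsing, and UMLS/MedDRA normalization of side-effect
  names are out of scope; the drug database is whatever TSV is supplied.
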