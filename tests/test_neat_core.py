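import dataclasses

import numpy as np
import pytest

from neatadr.neat_core import (
    Adam,
    CredibilityVector,
    NeatModel,
    SingleLabelLossProbe,
    TrainConfig,
    _batch_loss,
    _forward_batch,
    build_model,
    compose_post_user,
    compute_loss,
    credibility_gradient_autodiff,
    credibility_gradient_closed_form,
    encode_thread,
    load_model,
    permute_post_authors,
    predict_side_effects,
    probe_loss,
    save_model,
    train_model,
)
from neatadr.synthetic import SimConfig, generate_corpus

SMALL_SIM = SimConfig(n_users=16, n_threads=24, n_drugs=8, n_side_effects=10,
                      n_clusters=2, filler_vocab_size=20, posts_per_thread=(1, 3),
                      filler_tokens_per_post=(5, 10), seed=11)
SMALL_CFG = dict(embedding_dim=12, channels=5, kernel_sizes=(2, 3), g=6,
                 n_clusters=2, epochs=3, batch_size=8, lstm_hidden=4)


def small_config(**over):
    kwargs = {**SMALL_CFG, **over}
    return TrainConfig(**kwargs)


@pytest.fixture(scope="module")
def small_corpus():
    corpus, truth = generate_corpus(SMALL_SIM)
    return corpus


class TestComposition:
    def test_concatenation_when_expertise_enabled(self, rng):
        v_p, v_u = rng.normal(size=64), rng.normal(size=100)
        out = compose_post_user(v_p, v_u, "neat")
        assert out.shape == (164,)
        assert np.array_equal(out[:64], v_p)
        assert np.array_equal(out[64:], v_u)

    def test_wpe_passes_post_vector_through(self, rng):
        v_p = rng.normal(size=64)
        assert np.array_equal(compose_post_user(v_p, None, "wpe"), v_p)

    def test_missing_expertise_rejected_when_required(self, rng):
        with pytest.raises(ValueError):
            compose_post_user(rng.normal(size=8), None, "wpeu")


class TestThreadEncoding:
    def test_zero_scores_give_plain_sum(self, rng):
        vs = [rng.normal(size=5) for _ in range(3)]
        cred = CredibilityVector(user_ids=["a", "b", "c"], w=np.zeros(3))
        enc = encode_thread(vs, cred, ["a", "b", "c"], "neat")
        assert np.allclose(enc.v_t, np.sum(vs, axis=0))

    def test_log_two_score_doubles_contribution(self, rng):
        v = rng.normal(size=4)
        cred = CredibilityVector(user_ids=["a"], w=np.array([np.log(2.0)]))
        enc = encode_thread([v], cred, ["a"], "wpe")
        assert np.allclose(enc.v_t, 2.0 * v)

    def test_matches_brute_force_weighted_sum(self, rng):
        vs = [rng.normal(size=6) for _ in range(4)]
        w = rng.normal(size=4)
        users = list("abcd")
        cred = CredibilityVector(user_ids=users, w=w)
        enc = encode_thread(vs, cred, users, "neat")
        brute = np.zeros(6)
        for wi, vi in zip(w, vs):
            brute += np.exp(wi) * vi
        assert np.allclose(enc.v_t, brute, atol=1e-12)

    def test_vanilla_ignores_scores(self, rng):
        vs = [rng.normal(size=3) for _ in range(2)]
        cred = CredibilityVector(user_ids=["a", "b"], w=np.array([5.0, -5.0]))
        enc = encode_thread(vs, cred, ["a", "b"], "vanilla")
        assert np.allclose(enc.v_t, np.sum(vs, axis=0))

    def test_unseen_author_warns_and_uses_unit_weight(self, rng):
        v = rng.normal(size=3)
        cred = CredibilityVector(user_ids=["a"], w=np.array([1.0]))
        with pytest.warns(UserWarning, match="unseen"):
            enc = encode_thread([v], cred, ["ghost"], "wpe")
        assert np.allclose(enc.v_t, v)

    def test_monotone_trust_increases_influence(self, rng):
        v = np.abs(rng.normal(size=4)) + 0.1
        for w_lo, w_hi in [(-1.0, 0.0), (0.0, 0.7)]:
            lo = encode_thread([v], CredibilityVector(["a"], np.array([w_lo])),
                               ["a"], "wpe").weighted[0]
            hi = encode_thread([v], CredibilityVector(["a"], np.array([w_hi])),
                               ["a"], "wpe").weighted[0]
            assert np.all(hi > lo)


class TestPredictionAndLoss:
    def _dummy_model(self, W, b, threshold=0.5):
        from neatadr.autodiff import Tensor
        from neatadr.encoders import init_cnn_params

        cfg = small_config(threshold=threshold)
        return NeatModel(
            config=cfg, vocab_names=tuple(f"s{i}" for i in range(len(b))),
            token_index={"<unk>": 0},
            embedding=Tensor(np.zeros((1, cfg.embedding_dim))),
            enc_params=init_cnn_params(cfg.embedding_dim, 1, cfg.kernel_sizes,
                                       cfg.channels, seed=0),
            user_ids=[], user_index={}, user_cluster=np.zeros(1, dtype=int),
            expertise=None, credibility=None,
            w_out=Tensor(np.asarray(W, dtype=float).T),
            b_out=Tensor(np.asarray(b, dtype=float)),
            cluster_model=None, expertise_proj=None)

    def test_zero_input_zero_bias_gives_half_probabilities(self):
        model = self._dummy_model(np.ones((3, 4)), np.zeros(3))
        scores, probs, _ = predict_side_effects(np.zeros(4), model)
        assert np.allclose(scores, 0.0)
        assert np.allclose(probs, 0.5)

    def test_hand_computed_two_label_case(self):
        W = np.array([[1.0, 0.0], [0.0, -1.0]])
        model = self._dummy_model(W, np.zeros(2))
        v_t = np.arctanh(0.5) * np.ones(2)
        scores, probs, positives = predict_side_effects(v_t, model)
        assert np.allclose(scores, [0.5, -0.5])
        sig = 1 / (1 + np.exp(-0.5))
        assert np.allclose(probs, [sig, 1 - sig])
        assert positives == {0}

    def test_threshold_is_inclusive_boundary(self):
        model = self._dummy_model(np.eye(2), np.zeros(2))
        _, _, positives = predict_side_effects(
            np.arctanh(np.array([-0.02, 0.02])), model)
        assert positives == {1}

    def test_perfect_confident_predictions_give_tiny_loss(self):
        probs = np.array([[1.0, 0.0, 1.0, 0.0]])
        labels = np.array([[1, 0, 1, 0]])
        assert compute_loss(probs, labels) <= 4 * 1e-6

    def test_uniform_probabilities_closed_form(self):
        probs = np.full((1, 4), 0.5)
        labels = np.array([[1, 0, 1, 1]])
        assert compute_loss(probs, labels) == pytest.approx(4 * np.log(2))

    def test_l1_regularizer_contribution(self, small_corpus):
        cfg = small_config(variant="neat")
        model = build_model(small_corpus,
                            [t.thread_id for t in small_corpus.threads], cfg)
        model.credibility.data[:] = 0.0
        model.credibility.data[0, 0] = 0.3
        model.credibility.data[1, 0] = -0.2
        probs = np.array([[0.5] * 10])
        labels = np.zeros((1, 10), dtype=int)
        base = compute_loss(probs, labels)
        with_reg = compute_loss(probs, labels, model, lambda1=0.0, lambda2=1.0)
        assert with_reg - base == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_loss(np.zeros((2, 3)), np.zeros((2, 4)))


def random_probe(rng, m=None, d=None):
    m = m or int(rng.integers(1, 5))
    d = d or int(rng.integers(2, 8))
    return SingleLabelLossProbe(
        y_s=int(rng.choice([-1, 1])),
        w_s=rng.normal(0, 1, d),
        b_s=float(rng.normal()),
        v_pu=[rng.normal(0, 0.6, d) for _ in range(m)],
        w_u=[float(rng.normal(0, 0.5)) for _ in range(m)],
    )


class TestCredibilityGradient:
    def test_closed_form_matches_finite_differences(self, rng):
        for _ in range(20):
            probe = random_probe(rng)
            grad = credibility_gradient_closed_form(probe)
            h = 1e-6
            for i in range(len(probe.w_u)):
                wp = list(probe.w_u)
                wm = list(probe.w_u)
                wp[i] += h
                wm[i] -= h
                fd = (probe_loss(dataclasses.replace(probe, w_u=wp)) -
                      probe_loss(dataclasses.replace(probe, w_u=wm))) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_closed_form_matches_reverse_mode_tape(self, rng):
        for _ in range(20):
            probe = random_probe(rng)
            cf = credibility_gradient_closed_form(probe)
            ad = credibility_gradient_autodiff(probe)
            assert np.allclose(cf, ad, rtol=1e-6, atol=1e-12)

    def test_correct_solo_prediction_raises_score_under_descent(self, rng):
        for _ in range(50):
            d = 5
            w_s = np.abs(rng.normal(0, 1, d)) + 0.05
            v = np.abs(rng.normal(0, 0.5, d)) + 0.05
            y = int(rng.choice([-1, 1]))
            probe = SingleLabelLossProbe(y_s=y, w_s=y * w_s, b_s=0.0,
                                         v_pu=[v], w_u=[float(rng.normal(0, 0.3))])
            grad = credibility_gradient_closed_form(probe)[0]
            assert grad < 0          # descent step -eta*grad increases w_u
            wrong = SingleLabelLossProbe(y_s=-y, w_s=y * w_s, b_s=0.0,
                                         v_pu=[v], w_u=probe.w_u)
            assert credibility_gradient_closed_form(wrong)[0] > 0

    def test_gradient_magnitude_proportional_to_effective_weight(self, rng):
        # doubling e^{w_u} at fixed thread representation doubles the
        # e^{w_u} factor in the gradient
        d = 4
        w_s = rng.normal(0, 1, d)
        v = rng.normal(0, 0.5, d)
        v_t = rng.normal(0, 0.5, d)
        jac = 1 - np.tanh(v_t) ** 2
        f = w_s @ np.tanh(v_t)
        for y in (-1, 1):
            denom = 1 + np.exp(y * f)
            base = -y * (w_s @ (jac * v)) / denom
            for w in (0.0, np.log(2.0), np.log(4.0)):
                probe_grad = -y * (w_s @ (jac * v)) * np.exp(w) / denom
                assert probe_grad == pytest.approx(base * np.exp(w))


class TestTraining:
    def test_loss_decreases_on_small_corpus(self, small_corpus):
        ids = [t.thread_id for t in small_corpus.threads][:20]
        model, log = train_model(small_corpus, ids, small_config(epochs=10))
        assert log["train_loss"][-1] < log["train_loss"][0]

    def test_same_seed_reproduces_losses_and_parameters(self, small_corpus):
        ids = [t.thread_id for t in small_corpus.threads]
        m1, log1 = train_model(small_corpus, ids, small_config(seed=5))
        m2, log2 = train_model(small_corpus, ids, small_config(seed=5))
        assert log1["train_loss"] == log2["train_loss"]
        assert np.array_equal(m1.w_out.data, m2.w_out.data)
        assert np.array_equal(m1.credibility.data, m2.credibility.data)

    def test_vanilla_has_no_credibility_or_expertise(self, small_corpus):
        ids = [t.thread_id for t in small_corpus.threads]
        model, _ = train_model(small_corpus, ids,
                               small_config(variant="vanilla", epochs=1))
        assert model.credibility is None
        assert model.expertise is None
        assert len(model.parameters()) > 0

    def test_lstm_encoder_trains_and_agrees_with_single_post_path(
            self, small_corpus):
        ids = [t.thread_id for t in small_corpus.threads][:12]
        model, log = train_model(small_corpus, ids,
                                 small_config(encoder="lstm", epochs=2))
        assert np.isfinite(log["train_loss"]).all()
        t = small_corpus.threads[0]
        probs, _ = model.predict_threads([t])
        # consistency: batched tape forward equals composing numpy encoders
        from neatadr.neat_core import encode_thread as et

        complexes = []
        for p in t.posts:
            enc = model.encode_post(p.tokens, p.user_id)
            v_u = model.expertise.data[model._user_slot(p.user_id)]
            complexes.append(np.concatenate([enc.v_p, v_u]))
        cred = model.credibility_vector()
        v_t = et(complexes, cred, [p.user_id for p in t.posts], "neat").v_t
        _, probs2, _ = predict_side_effects(v_t, model)
        assert np.allclose(probs[0], probs2, atol=1e-8)

    def test_cnn_batched_forward_equals_single_post_encoders(self, small_corpus):
        ids = [t.thread_id for t in small_corpus.threads]
        model, _ = train_model(small_corpus, ids, small_config(epochs=1))
        t = small_corpus.threads[3]
        probs, _ = model.predict_threads([t])
        complexes = []
        for p in t.posts:
            enc = model.encode_post(p.tokens, p.user_id)
            v_u = model.expertise.data[model._user_slot(p.user_id)]
            complexes.append(np.concatenate([enc.v_p, v_u]))
        v_t = encode_thread(complexes, model.credibility_vector(),
                            [p.user_id for p in t.posts], "neat").v_t
        _, probs2, _ = predict_side_effects(v_t, model)
        assert np.allclose(probs[0], probs2, atol=1e-8)

    def test_empty_training_fold_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            train_model(small_corpus, [], small_config())

    def test_permutation_preserves_text_and_multiset_of_authors(
            self, small_corpus):
        permuted = permute_post_authors(small_corpus, seed=3)
        orig_authors = sorted(p.user_id for t in small_corpus.threads
                              for p in t.posts)
        new_authors = sorted(p.user_id for t in permuted.threads for p in t.posts)
        assert orig_authors == new_authors
        flat_orig = [p.tokens for t in small_corpus.threads for p in t.posts]
        flat_new = [p.tokens for t in permuted.threads for p in t.posts]
        assert flat_orig == flat_new
        moved = sum(p1.user_id != p2.user_id for t1, t2 in
                    zip(small_corpus.threads, permuted.threads)
                    for p1, p2 in zip(t1.posts, t2.posts))
        assert moved > 0


class TestCheckpoint:
    @pytest.mark.parametrize("encoder", ["cnn", "lstm"])
    def test_round_trip_preserves_predictions(self, small_corpus, tmp_path,
                                              encoder):
        ids = [t.thread_id for t in small_corpus.threads]
        model, _ = train_model(small_corpus, ids,
                               small_config(encoder=encoder, epochs=1))
        p = tmp_path / "model.npz"
        save_model(model, p)
        model2 = load_model(p)
        probs1, _ = model.predict_threads(small_corpus.threads[:5])
        probs2, _ = model2.predict_threads(small_corpus.threads[:5])
        assert np.allclose(probs1, probs2, atol=1e-12)


def test_adam_moves_toward_minimum():
    from neatadr.autodiff import Tensor
    from neatadr import autodiff as ad

    x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([x], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = ad.sum_(x * x)
        loss.backward()
        opt.step()
    assert np.all(np.abs(x.data) < 1e-2)
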