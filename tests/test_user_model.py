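import numpy as np
import pytest

from neatadr.io_data import DrugSideEffectDB
from neatadr.user_model import (
    ExperienceMatrix,
    assign_user_cluster,
    build_experience_matrix,
    cluster_users,
    load_cluster_model,
    reduce_expertise,
    save_cluster_model,
    silhouette_scan,
)

from conftest import make_thread


class TestExperienceMatrix:
    def test_repeat_participation_counts_threads(self, tiny_vocab):
        db = DrugSideEffectDB({"d": frozenset({1})})
        threads = [make_thread(f"t{i}", [("u", ["x"])], ["d"], db, 3)
                   for i in range(2)]
        from neatadr.io_data import ForumCorpus, UserRecord

        corpus = ForumCorpus(threads=threads,
                             users={"u": UserRecord("u")},
                             vocabulary=tiny_vocab, drug_db=db)
        m = build_experience_matrix(corpus)
        assert m.counts[m.user_index["u"], 1] == 2
        assert m.counts.sum() == 2

    def test_user_absent_from_fold_gets_zero_row(self, tiny_corpus):
        m = build_experience_matrix(tiny_corpus, fold_thread_ids=["t1"])
        assert m.counts[m.user_index["bob"]].sum() == 0
        assert m.counts[m.user_index["carol"]].sum() == 0

    def test_matches_triple_loop_brute_force(self, default_corpus_and_truth):
        corpus, _ = default_corpus_and_truth
        fold = [t.thread_id for t in corpus.threads[:60]]
        m = build_experience_matrix(corpus, fold_thread_ids=fold)
        users = sorted(corpus.users)[:20]
        thread_of = {t.thread_id: t for t in corpus.threads}
        for u in users:
            for i in range(len(corpus.vocabulary)):
                expected = 0
                for tid in fold:
                    t = thread_of[tid]
                    if t.label[i] and any(p.user_id == u for p in t.posts):
                        expected += 1
                assert m.counts[m.user_index[u], i] == expected

    def test_experience_conservation_per_effect(self, tiny_corpus):
        m = build_experience_matrix(tiny_corpus)
        for i in range(len(tiny_corpus.vocabulary)):
            incidences = sum(
                1 for t in tiny_corpus.threads if t.label[i]
                for _u in {p.user_id for p in t.posts})
            assert m.counts[:, i].sum() == incidences

    def test_empty_fold_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            build_experience_matrix(tiny_corpus, fold_thread_ids=[])


class TestExpertisePCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        base = np.array([1.0, 2.0, 0.0, 3.0])
        counts = np.outer([1, 2, 3, 4, 5], base).astype(int)
        m = ExperienceMatrix(counts=counts, user_ids=[f"u{i}" for i in range(5)])
        e = reduce_expertise(m, g=1)
        assert e.explained_variance[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        counts = rng.integers(0, 5, size=(8, 6))
        m = ExperienceMatrix(counts=counts, user_ids=[f"u{i}" for i in range(8)])
        e = reduce_expertise(m, g=6)
        assert e.explained_variance.sum() == pytest.approx(1.0)
        recon = e.scores @ e.loadings.T + e.mean
        assert np.allclose(recon, counts, atol=1e-8)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        counts = rng.integers(0, 10, size=(30, 12))
        m = ExperienceMatrix(counts=counts, user_ids=[f"u{i}" for i in range(30)])
        e = reduce_expertise(m, g=5)
        X = counts - counts.mean(axis=0)
        cov = X.T @ X / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order[:5]]
        oracle = X @ evecs
        for k in range(5):
            col, ref = e.scores[:, k], oracle[:, k]
            sign = np.sign(col @ ref) or 1.0
            assert np.allclose(col, sign * ref, atol=1e-8)

    def test_cumulative_variance_monotone_and_mean_projects_to_zero(self, rng):
        counts = rng.integers(0, 6, size=(15, 9))
        m = ExperienceMatrix(counts=counts, user_ids=[f"u{i}" for i in range(15)])
        e = reduce_expertise(m, g=9)
        assert np.all(np.diff(np.cumsum(e.explained_variance)) >= -1e-12)
        assert np.allclose(e.project(e.mean), 0.0, atol=1e-10)

    def test_oversized_g_clamps_with_warning(self, rng):
        counts = rng.integers(0, 3, size=(4, 6))
        m = ExperienceMatrix(counts=counts, user_ids=list("abcd"))
        with pytest.warns(UserWarning, match="clamped"):
            e = reduce_expertise(m, g=100)
        assert e.g == 4

    def test_nonpositive_g_rejected(self, rng):
        m = ExperienceMatrix(counts=np.ones((3, 3), dtype=int),
                             user_ids=list("abc"))
        with pytest.raises(ValueError):
            reduce_expertise(m, g=0)


def _orthogonal_groups_matrix():
    rows = [[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]] * 5
    return ExperienceMatrix(counts=np.array(rows),
                            user_ids=[f"u{i}" for i in range(10)])


class TestClustering:
    def test_orthogonal_groups_perfectly_separated(self):
        m = _orthogonal_groups_matrix()
        model = cluster_users(m, c=2, seed=0)
        groups = {model.assignment[f"u{i}"] for i in range(5)}
        assert len(groups) == 1
        assert model.assignment["u0"] != model.assignment["u9"]
        assert model.silhouette == pytest.approx(1.0)
        assert np.allclose(np.linalg.norm(model.centroids, axis=1), 1.0)

    def test_identical_users_cannot_be_split(self):
        m = ExperienceMatrix(counts=np.ones((6, 4), dtype=int),
                             user_ids=[f"u{i}" for i in range(6)])
        with pytest.raises(ValueError):
            cluster_users(m, c=2, seed=0)

    def test_zero_rows_go_to_largest_cluster(self):
        rows = [[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 2 + [[0, 0, 0, 0]]
        m = ExperienceMatrix(counts=np.array(rows),
                             user_ids=[f"u{i}" for i in range(7)])
        model = cluster_users(m, c=2, seed=0)
        assert model.assignment["u6"] == model.fallback_cluster
        assert model.fallback_cluster == model.assignment["u0"]

    def test_recovers_planted_clusters(self, default_corpus_and_truth):
        from sklearn.metrics import adjusted_rand_score

        corpus, truth = default_corpus_and_truth
        m = build_experience_matrix(corpus)
        model = cluster_users(m, c=4, seed=1)
        fitted = [u for u in m.user_ids if m.counts[m.user_index[u]].sum() > 0]
        ari = adjusted_rand_score([truth.user_cluster[u] for u in fitted],
                                  [model.assignment[u] for u in fitted])
        assert ari >= 0.5  # strong signal; the multi-seed bound lives in acceptance

    def test_round_trip_persistence(self, tmp_path):
        m = _orthogonal_groups_matrix()
        model = cluster_users(m, c=2, seed=0)
        p = tmp_path / "clusters.json"
        save_cluster_model(model, p)
        model2 = load_cluster_model(p)
        assert model2.assignment == model.assignment
        assert np.allclose(model2.centroids, model.centroids)


class TestSilhouetteScan:
    def test_two_orthogonal_groups_prefer_two_clusters(self):
        m = _orthogonal_groups_matrix()
        scan = dict(silhouette_scan(m, [2, 3], seed=0))
        assert scan[2] == pytest.approx(1.0)
        assert scan[3] <= scan[2]
        # perturbed groups: the scan strictly prefers the true cluster count
        rows = np.array([[1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0],
                         [1, 1, 0, 1, 0, 0], [0, 0, 0, 0, 1, 1],
                         [0, 0, 1, 0, 1, 1], [0, 1, 0, 0, 1, 1]])
        m2 = ExperienceMatrix(counts=rows, user_ids=[f"v{i}" for i in range(6)])
        scan2 = dict(silhouette_scan(m2, [2, 3], seed=0))
        assert scan2[2] > scan2[3]

    def test_hand_computed_two_tight_pairs(self):
        # two cosine-separated pairs; within-pair cosine distance a, across b
        rows = np.array([[4, 1, 0, 0], [1, 4, 0, 0], [0, 0, 4, 1], [0, 0, 1, 4]])
        m = ExperienceMatrix(counts=rows, user_ids=list("abcd"))
        model = cluster_users(m, c=2, seed=0)
        X = (rows > 0).astype(float)
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        cos = X @ X.T
        a = 1 - cos[0, 1]           # within-pair distance (same for both pairs)
        b = 1 - cos[0, 2]           # distance to the other pair's members
        expected = (b - a) / b
        assert model.silhouette == pytest.approx(expected, abs=1e-12)

    def test_scan_deterministic_given_seed(self):
        m = _orthogonal_groups_matrix()
        assert silhouette_scan(m, [2, 3], seed=5) == \
               silhouette_scan(m, [2, 3], seed=5)


class TestAssignment:
    def test_centroid_vector_maps_to_its_cluster(self):
        m = _orthogonal_groups_matrix()
        model = cluster_users(m, c=2, seed=0)
        for c in range(2):
            assert assign_user_cluster(model, model.centroids[c]) == c

    def test_zero_vector_falls_back(self):
        m = _orthogonal_groups_matrix()
        model = cluster_users(m, c=2, seed=0)
        assert assign_user_cluster(model, np.zeros(4)) == model.fallback_cluster

    def test_matches_brute_force_cosine_argmin(self, rng):
        m = _orthogonal_groups_matrix()
        model = cluster_users(m, c=2, seed=0)
        for _ in range(50):
            v = rng.random(4)
            vb = (v > 0.5).astype(float)
            if vb.sum() == 0:
                continue
            vn = vb / np.linalg.norm(vb)
            dists = [1 - vn @ c for c in model.centroids]
            assert assign_user_cluster(model, vb) == int(np.argmin(dists))
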