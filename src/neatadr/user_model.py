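"""User-side statistics: experience counts, PCA expertise, cosine clustering.

A user's *experience vector* counts, per side effect, the number of training
threads they posted in whose label includes that effect. PCA on the stacked
experience matrix gives a dense low-dimensional *expertise vector* per user;
K-means on the binarized, L2-normalized experience vectors groups users with
overlapping side-effect histories (Euclidean K-means on the unit sphere is
equivalent to cosine K-means).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io_data import ForumCorpus

__all__ = [
    "ExperienceMatrix",
    "ExpertiseMatrix",
    "UserClusterModel",
    "build_experience_matrix",
    "reduce_expertise",
    "cluster_users",
    "silhouette_scan",
    "assign_user_cluster",
    "save_cluster_model",
    "load_cluster_model",
]


@dataclass
class ExperienceMatrix:
    """|U| x |S| integer matrix of per-user thread-participation counts."""

    counts: np.ndarray
    user_ids: list[str]

    @property
    def user_index(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.user_ids)}


@dataclass
class ExpertiseMatrix:
    """PCA scores of the experience matrix plus the projection to apply to new users."""

    scores: np.ndarray           # |U| x g
    g: int
    explained_variance: np.ndarray
    loadings: np.ndarray         # |S| x g
    mean: np.ndarray             # length |S|
    user_ids: list[str]

    def project(self, v_star: np.ndarray) -> np.ndarray:
        """Map a raw experience vector into the expertise space."""
        return (np.asarray(v_star, dtype=float) - self.mean) @ self.loadings


@dataclass
class UserClusterModel:
    c: int
    centroids: np.ndarray        # c x |S|, unit L2 norm
    assignment: dict[str, int]
    silhouette: float
    fallback_cluster: int


def build_experience_matrix(corpus: ForumCorpus, fold_thread_ids=None) -> ExperienceMatrix:
    """Count, per (user, side effect), the fold threads the user posted in
    whose label includes that effect. Users absent from the fold get zero rows.
    """
    if fold_thread_ids is None:
        fold_thread_ids = [t.thread_id for t in corpus.threads]
    fold = set(fold_thread_ids)
    if not fold:
        raise ValueError("training fold is empty")
    user_ids = sorted(corpus.users)
    uidx = {u: i for i, u in enumerate(user_ids)}
    n_s = len(corpus.vocabulary)
    counts = np.zeros((len(user_ids), n_s), dtype=np.int64)
    for t in corpus.threads:
        if t.thread_id not in fold:
            continue
        participants = {p.user_id for p in t.posts}
        effects = np.flatnonzero(t.label)
        for u in participants:
            counts[uidx[u], effects] += 1
    return ExperienceMatrix(counts=counts, user_ids=user_ids)


def reduce_expertise(m_star: ExperienceMatrix, g: int = 100) -> ExpertiseMatrix:
    """Leading-``g`` principal-component scores of the experience matrix.

    ``g`` defaults to 100 and is clamped (with a warning) to min(|U|, |S|)
    when the data cannot support it.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    X = m_star.counts.astype(float)
    g_max = min(X.shape)
    if g > g_max:
        warnings.warn(f"g={g} clamped to {g_max} (matrix is {X.shape[0]}x{X.shape[1]})")
        g = g_max
    pca = PCA(n_components=g, svd_solver="full")
    scores = pca.fit_transform(X)
    return ExpertiseMatrix(
        scores=scores,
        g=g,
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=pca.components_.T.copy(),
        mean=pca.mean_.copy(),
        user_ids=list(m_star.user_ids),
    )


def _normalized_binary_rows(m_star: ExperienceMatrix):
    """Binarize experience rows and L2-normalize the nonzero ones."""
    B = (m_star.counts > 0).astype(float)
    norms = np.linalg.norm(B, axis=1)
    nonzero = norms > 0
    X = B[nonzero] / norms[nonzero, None]
    return X, nonzero


def cluster_users(m_star: ExperienceMatrix, c: int = 7, seed: int = 0) -> UserClusterModel:
    """K-means on binarized, L2-normalized experience vectors (cosine geometry).

    All-zero experience rows are excluded from fitting (cosine is undefined
    at zero) and assigned to the largest cluster as a fallback.
    """
    if c < 2:
        raise ValueError("c must be at least 2")
    X, nonzero = _normalized_binary_rows(m_star)
    n_distinct = len(np.unique(X, axis=0)) if len(X) else 0
    if c > len(X):
        raise ValueError(f"c={c} exceeds the {len(X)} users with nonzero experience")
    if n_distinct < 2:
        raise ValueError("all nonzero experience vectors are identical; "
                         "no cluster structure to fit")
    with warnings.catch_warnings():
        # duplicated points can make K-means report fewer distinct clusters
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=c, n_init=10, max_iter=300, random_state=seed)
        labels = km.fit_predict(X)
    cent = km.cluster_centers_
    cent_norm = np.linalg.norm(cent, axis=1, keepdims=True)
    cent = cent / np.where(cent_norm > 0, cent_norm, 1.0)
    sizes = np.bincount(labels, minlength=c)
    fallback = int(np.argmax(sizes))
    sil = float(silhouette_score(X, labels, metric="cosine")) if c < len(X) else 1.0
    assignment: dict[str, int] = {}
    j = 0
    for keep, uid in zip(nonzero, m_star.user_ids):
        if keep:
            assignment[uid] = int(labels[j])
            j += 1
        else:
            assignment[uid] = fallback
    return UserClusterModel(c=c, centroids=cent, assignment=assignment,
                            silhouette=sil, fallback_cluster=fallback)


def silhouette_scan(m_star: ExperienceMatrix, c_range, seed: int = 0):
    """Average silhouette (cosine distance) for each candidate cluster count."""
    out = []
    for c in sorted(c_range):
        model = cluster_users(m_star, c=c, seed=seed)
        out.append((int(c), model.silhouette))
    return out


def assign_user_cluster(model: UserClusterModel, v_star: np.ndarray) -> int:
    """Nearest centroid by cosine; all-zero vectors go to the fallback cluster."""
    v = (np.asarray(v_star, dtype=float) > 0).astype(float)
    norm = np.linalg.norm(v)
    if norm == 0:
        return model.fallback_cluster
    sims = model.centroids @ (v / norm)
    return int(np.argmax(sims))


def save_cluster_model(model: UserClusterModel, path) -> None:
    obj = {
        "c": model.c,
        "centroids": model.centroids.ravel().tolist(),
        "n_features": model.centroids.shape[1],
        "assignment": model.assignment,
        "silhouette": model.silhouette,
        "fallback_cluster": model.fallback_cluster,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True)


def load_cluster_model(path) -> UserClusterModel:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    cent = np.array(obj["centroids"], dtype=float).reshape(obj["c"], obj["n_features"])
    return UserClusterModel(
        c=int(obj["c"]),
        centroids=cent,
        assignment={k: int(v) for k, v in obj["assignment"].items()},
        silhouette=float(obj["silhouette"]),
        fallback_cluster=int(obj["fallback_cluster"]),
    )
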