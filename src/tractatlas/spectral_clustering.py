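"""Nystrom spectral embedding of fibers and atlas construction.

Each fiber is represented by its Gaussian-kernel affinity to many other
fibers; eigenvectors of the normalized affinity matrix give every fiber a
compact "fingerprint" coordinate in an embedding space where k-means
recovers bundles.  Computing the full affinity matrix over 10^5 fibers is
infeasible, so the Nystrom method is used: the eigendecomposition is taken
on a random sample of m fibers, and any fiber (in-sample or new) is embedded
from its affinity row to the sample alone.  This also gives the
out-of-sample extension used when applying an atlas to a new subject.

Normalization follows the normalized-cuts convention
``D^{-1/2} A D^{-1/2}``; degrees are estimated from the sample block's row
sums, and the out-of-sample degree of a fiber is the sum of its affinity
row to the samples.  Using the same estimator at fit and extension time
makes the embedding of a sample fiber reproduce its fitted coordinate
exactly, and the construction coincides with the dense normalized spectral
embedding when m equals the full fiber count.

Atlas construction iterates clustering with outlier removal: per cluster,
each fiber's probability is its mean affinity to the cluster's fibers from
*other* subjects (leave-one-out), and fibers falling more than a configured
number of standard deviations below the cluster mean probability are
rejected, then the surviving fibers are re-embedded and re-clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .fiber_geometry import (DistanceConfig, fiber_length,
                             pairwise_distance_matrix, stack_resampled)
from .tract_io import Tractogram

logger = logging.getLogger(__name__)

LOW_AFFINITY_MEAN = 1e-8  # mean affinity below this flags an off-atlas fiber

__all__ = [
    "ClusterConfig",
    "EmbeddingBasis",
    "FiberEmbedding",
    "Atlas",
    "fit_embedding_basis",
    "embed_fibers",
    "kmeans_embed",
    "fiber_probabilities",
    "reject_outliers",
    "build_atlas",
]


@dataclass
class ClusterConfig:
    """Atlas-construction settings.

    Defaults are the full-scale study conditions: 800 clusters, 2500 fibers
    sampled for the Nystrom decomposition, 10,000 fibers per subject with a
    60 mm minimum length, two rounds of outlier rejection at 2 standard
    deviations, bilateral clustering.  Desk-scale runs shrink k, the sample
    size and the per-subject fiber count.
    """

    k: int = 800
    nystrom_m: int = 2500
    fibers_per_subject: int = 10000
    min_fiber_length: float = 60.0
    sigma_cluster: float = 30.0
    n_eigenvectors: int = 20
    n_points: int = 15
    outlier_rounds: int = 2
    outlier_threshold_sd: float = 2.0
    bilateral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.n_eigenvectors <= self.nystrom_m:
            raise ValueError("need 1 <= n_eigenvectors <= nystrom_m")
        if self.outlier_threshold_sd <= 0:
            raise ValueError("outlier_threshold_sd must be positive")

    def distance_config(self) -> DistanceConfig:
        return DistanceConfig(n_points=self.n_points, bilateral=self.bilateral)


@dataclass
class EmbeddingBasis:
    """Nystrom sample fibers plus the spectral decomposition built on them."""

    sample_fibers: np.ndarray          # (m, n_points, 3), resampled
    sigma: float
    bilateral: bool
    sample_affinity_eigvecs: np.ndarray  # (m, p)
    eigvals: np.ndarray                  # (p,), nonincreasing
    degree_estimates: np.ndarray         # (m,), > 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigvals) > 1e-12):
            raise ValueError("eigvals must be nonincreasing")
        if np.any(self.degree_estimates <= 0):
            raise ValueError("degree estimates must be positive")

    @property
    def n_points(self) -> int:
        return self.sample_fibers.shape[1]

    @property
    def p(self) -> int:
        return self.eigvals.shape[0]


@dataclass
class FiberEmbedding:
    """Per-fiber embedding coordinates plus a low-affinity flag."""

    coords: np.ndarray              # (n, p)
    low_affinity: np.ndarray        # (n,) bool

    def __len__(self) -> int:
        return self.coords.shape[0]


def fit_embedding_basis(fibers: np.ndarray,
                        config: ClusterConfig) -> EmbeddingBasis:
    """Fit the Nystrom basis on a seeded random sample of the pooled fibers.

    ``fibers`` is a stacked resampled array (n, n_points, 3).  A sample of
    ``config.nystrom_m`` fibers is drawn, its (bilateral-combined when
    configured) affinity matrix is normalized-cut scaled and
    eigendecomposed, and the top ``n_eigenvectors`` pairs are retained.
    """
    n = fibers.shape[0]
    m = min(config.nystrom_m, n) if config.nystrom_m <= n else None
    if config.nystrom_m > n:
        raise ValueError(
            f"Nystrom sample size {config.nystrom_m} exceeds fiber count {n}")
    rng = np.random.default_rng(config.seed)
    idx = np.sort(rng.choice(n, size=config.nystrom_m, replace=False))
    sample = fibers[idx]
    return _fit_basis_from_sample(sample, config)


def _fit_basis_from_sample(sample: np.ndarray,
                           config: ClusterConfig) -> EmbeddingBasis:
    cfg = config.distance_config()
    D = pairwise_distance_matrix(sample, sample, cfg)
    A = np.exp(-(D ** 2) / config.sigma_cluster ** 2)
    d = A.sum(axis=1)
    scale = 1.0 / np.sqrt(d)
    A_hat = A * scale[:, None] * scale[None, :]
    m = sample.shape[0]
    p = min(config.n_eigenvectors, m)
    vals, vecs = eigh(A_hat, subset_by_index=[m - p, m - 1])
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    return EmbeddingBasis(sample_fibers=sample, sigma=config.sigma_cluster,
                          bilateral=config.bilateral,
                          sample_affinity_eigvecs=vecs, eigvals=vals,
                          degree_estimates=d)


def embed_fibers(basis: EmbeddingBasis, fibers: np.ndarray) -> FiberEmbedding:
    """Out-of-sample Nystrom extension of the spectral embedding.

    Each fiber's affinity row to the sample fibers is degree-normalized and
    projected onto the basis eigenvectors scaled by 1/eigenvalue; a sample
    fiber therefore maps exactly onto its own eigenvector coordinate.
    Fibers with (numerically) zero affinity to every sample land at the
    origin and are flagged.
    """
    if fibers.shape[0] == 0:
        return FiberEmbedding(coords=np.empty((0, basis.p)),
                              low_affinity=np.empty(0, dtype=bool))
    cfg = DistanceConfig(n_points=basis.n_points, bilateral=basis.bilateral)
    D = pairwise_distance_matrix(fibers, basis.sample_fibers, cfg)
    B = np.exp(-(D ** 2) / basis.sigma ** 2)
    dx = B.sum(axis=1)
    low = (dx / B.shape[1]) < LOW_AFFINITY_MEAN
    dx_safe = np.maximum(dx, 1e-300)
    Bn = B / np.sqrt(dx_safe)[:, None] / np.sqrt(basis.degree_estimates)[None, :]
    inv_vals = 1.0 / np.maximum(basis.eigvals, 1e-12)
    coords = (Bn @ basis.sample_affinity_eigvecs) * inv_vals[None, :]
    coords[low] = 0.0
    return FiberEmbedding(coords=coords, low_affinity=low)


def kmeans_embed(embedding: FiberEmbedding, k: int,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-means in embedding space (k-means++, 10 restarts)."""
    X = embedding.coords
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return labels.astype(np.int64), km.cluster_centers_


def fiber_probabilities(fibers: np.ndarray, labels: np.ndarray,
                        subjects: np.ndarray, sigma: float,
                        leave_one_out: str = "subject",
                        bilateral: bool = True,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out fiber probability within each cluster.

    p_i is the mean Gaussian affinity of fiber i to the fibers of its own
    cluster, excluding the fiber itself (``leave_one_out="fiber"``) or every
    fiber from the same subject (``leave_one_out="subject"``).  Fibers left
    with an empty comparison set get p_i = 0 and are flagged.
    """
    if leave_one_out not in ("fiber", "subject"):
        raise ValueError("leave_one_out must be 'fiber' or 'subject'")
    n = fibers.shape[0]
    cfg = DistanceConfig(n_points=fibers.shape[1], bilateral=bilateral)
    probs = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        member_fibers = fibers[members]
        D = pairwise_distance_matrix(member_fibers, member_fibers, cfg)
        K = np.exp(-(D ** 2) / sigma ** 2)
        if leave_one_out == "fiber":
            exclude = np.eye(len(members), dtype=bool)
        else:
            subs = subjects[members]
            exclude = subs[:, None] == subs[None, :]
        counts = (~exclude).sum(axis=1)
        K = np.where(exclude, 0.0, K)
        with np.errstate(invalid="ignore"):
            p = np.where(counts > 0, K.sum(axis=1) / np.maximum(counts, 1), 0.0)
        probs[members] = p
        flagged[members] = counts == 0
    return probs, flagged


def reject_outliers(labels: np.ndarray, probs: np.ndarray,
                    threshold_sd: float = 2.0,
                    ) -> tuple[np.ndarray, dict]:
    """Reject fibers whose probability is > threshold_sd SDs below the
    cluster mean.

    Returns a boolean keep-mask and per-cluster statistics
    ``{label: (mu, sd)}`` recorded before rejection.
    """
    keep = np.ones(labels.shape[0], dtype=bool)
    stats: dict[int, tuple[float, float]] = {}
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        p = probs[members]
        mu = float(p.mean())
        sd = float(p.std())
        stats[int(label)] = (mu, sd)
        if np.isfinite(threshold_sd):
            keep[members[p < mu - threshold_sd * sd]] = False
    return keep, stats


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

@dataclass
class Atlas:
    """Fiber-cluster atlas: embedding basis, centroids, per-cluster stats.

    ``cluster_stats`` rows are (mean probability, SD, training fiber count)
    per cluster; ``training_fibers``/``training_labels`` keep the resampled
    fibers that survived outlier removal so new subjects' fiber
    probabilities can be computed against them.  The atlas frame has its
    midsagittal plane at x = 0.
    """

    basis: EmbeddingBasis
    centroids: np.ndarray                 # (k, p)
    cluster_stats: np.ndarray             # (k, 3): mu, sd, n
    training_fibers: np.ndarray           # (n_kept, n_points, 3)
    training_labels: np.ndarray           # (n_kept,)
    training_subjects: np.ndarray         # (n_kept,) str
    training_fiber_indices: np.ndarray    # (n_kept,) index in source tractogram
    subject_presence: np.ndarray          # (k, n_subjects) bool
    subject_ids: list[str]
    config: ClusterConfig
    hierarchy: Optional[object] = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _canonicalize_labels(labels: np.ndarray, centroids: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by descending size so runs are comparable."""
    sizes = np.bincount(labels, minlength=centroids.shape[0])
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.shape[0])
    return remap[labels], centroids[order]


def build_atlas(subjects: Sequence[Tractogram],
                config: Optional[ClusterConfig] = None,
                hierarchy=None) -> Atlas:
    """Construct a fiber-cluster atlas from registered subjects.

    Orchestrates per-subject sampling of length-filtered fibers, Nystrom
    basis fitting, embedding, k-means, then ``outlier_rounds`` iterations of
    subject-level leave-one-out probability scoring, rejection of fibers
    more than ``outlier_threshold_sd`` SDs below their cluster's mean
    probability, and re-embedding/re-clustering of the survivors (the
    sample set is reused minus its rejected members).  Final cluster
    statistics are computed on the surviving fibers.
    """
    config = config or ClusterConfig()
    rng = np.random.default_rng(config.seed)

    stacks, subj_tags, orig_idx = [], [], []
    for s in subjects:
        keep = [i for i, f in enumerate(s.fibers)
                if fiber_length(f) >= config.min_fiber_length]
        if len(keep) > config.fibers_per_subject:
            pick = rng.choice(len(keep), size=config.fibers_per_subject,
                              replace=False)
            keep = [keep[i] for i in sorted(pick)]
        stacks.append(stack_resampled([s.fibers[i] for i in keep],
                                      config.n_points))
        subj_tags.extend([s.subject_id] * len(keep))
        orig_idx.extend(keep)
    fibers = np.concatenate(stacks)
    subjects_arr = np.asarray(subj_tags)
    orig_idx_arr = np.asarray(orig_idx, dtype=np.int64)
    n = fibers.shape[0]
    if n < max(config.k, config.nystrom_m):
        raise ValueError(
            f"pooled fiber count {n} below max(k, nystrom_m) = "
            f"{max(config.k, config.nystrom_m)}")

    sample_idx = np.sort(rng.choice(n, size=config.nystrom_m, replace=False))
    kept = np.ones(n, dtype=bool)

    def cluster_current():
        sample_mask = np.zeros(n, dtype=bool)
        sample_mask[sample_idx] = True
        live_sample = fibers[sample_mask & kept]
        basis = _fit_basis_from_sample(live_sample, config)
        emb = embed_fibers(basis, fibers[kept])
        labels, cents = kmeans_embed(emb, config.k, seed=config.seed)
        labels, cents = _canonicalize_labels(labels, cents)
        return basis, emb, labels, cents

    basis, emb, labels, centroids = cluster_current()
    for round_no in range(config.outlier_rounds):
        probs, _ = fiber_probabilities(
            fibers[kept], labels, subjects_arr[kept], config.sigma_cluster,
            leave_one_out="subject", bilateral=config.bilateral)
        keep_mask, _ = reject_outliers(labels, probs,
                                       config.outlier_threshold_sd)
        n_rejected = int((~keep_mask).sum())
        logger.info("outlier round %d: rejected %d of %d fibers",
                    round_no + 1, n_rejected, keep_mask.shape[0])
        live = np.flatnonzero(kept)
        kept[live[~keep_mask]] = False
        basis, emb, labels, centroids = cluster_current()

    probs, _ = fiber_probabilities(
        fibers[kept], labels, subjects_arr[kept], config.sigma_cluster,
        leave_one_out="subject", bilateral=config.bilateral)
    stats = np.zeros((config.k, 3))
    presence = np.zeros((config.k, len(subjects)), dtype=bool)
    sid_list = [s.subject_id for s in subjects]
    kept_subjects = subjects_arr[kept]
    for c in range(config.k):
        members = labels == c
        p = probs[members]
        stats[c] = (p.mean() if p.size else 0.0,
                    p.std() if p.size else 0.0, p.size)
        for j, sid in enumerate(sid_list):
            presence[c, j] = bool(np.any(members & (kept_subjects == sid)))

    return Atlas(basis=basis, centroids=centroids, cluster_stats=stats,
                 training_fibers=fibers[kept], training_labels=labels,
                 training_subjects=kept_subjects,
                 training_fiber_indices=orig_idx_arr[kept],
                 subject_presence=presence, subject_ids=sid_list,
                 config=config, hierarchy=hierarchy)
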