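"""Atlas persistence, application to new subjects, and tract extraction.

Applying the atlas to a (possibly lesioned) subject follows the same path as
training: affine registration of the subject's tractography onto the atlas
sample fibers under the entropy objective, Nystrom out-of-sample embedding of
every sufficiently long fiber, assignment to the nearest cluster centroid in
embedding space, and removal of fibers whose probability given the atlas
cluster falls more than the configured number of SDs below the cluster's
stored mean probability.  Because clusters are bilateral, identified tracts
are split into left/right hemisphere structures afterwards, and an anatomical
hierarchy (named groupings of cluster indices, e.g. "CST" or "AF") selects
clinically meaningful tracts from the parcellation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .fiber_geometry import DistanceConfig, fiber_length, \
    pairwise_distance_matrix
from .registration import RegistrationConfig, apply_transform, \
    register_affine_to_pool
from .spectral_clustering import (Atlas, ClusterConfig, EmbeddingBasis,
                                  embed_fibers)
from .fiber_geometry import stack_resampled
from .tract_io import Fiber, LinearTransform, Tractogram

__all__ = [
    "Hierarchy",
    "ClusterAssignment",
    "save_atlas",
    "load_atlas",
    "assign_subject",
    "split_hemisphere",
    "cluster_presence",
    "select_tract",
]


# ---------------------------------------------------------------------------
# Anatomical hierarchy
# ---------------------------------------------------------------------------

class Hierarchy:
    """Named, possibly nested groupings of atlas cluster indices.

    Built from a JSON-style dict: each node has a ``name`` and either
    ``children`` (a list of nodes) or ``clusters`` (a list of cluster
    indices).  A cluster may appear under several nodes.
    """

    def __init__(self, root: dict):
        self._nodes: dict[str, dict] = {}
        self._register(root, ancestry=set())
        self.root_name = root["name"]

    def _register(self, node: dict, ancestry: set) -> None:
        name = node.get("name")
        if not name:
            raise ValueError("hierarchy node missing 'name'")
        if name in ancestry:
            raise ValueError(f"hierarchy cycle through node {name!r}")
        if name in self._nodes:
            raise ValueError(f"duplicate hierarchy node name {name!r}")
        self._nodes[name] = node
        for child in node.get("children", []):
            self._register(child, ancestry | {name})

    @classmethod
    def from_json(cls, path) -> "Hierarchy":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_dict(self) -> dict:
        return self._nodes[self.root_name]

    @property
    def node_names(self) -> list[str]:
        return sorted(self._nodes)

    def leaf_clusters(self, node_name: str) -> set[int]:
        """Transitive set of cluster indices under a node."""
        if node_name not in self._nodes:
            raise KeyError(
                f"unknown hierarchy node {node_name!r}; available: "
                f"{', '.join(self.node_names)}")
        out: set[int] = set()
        stack = [self._nodes[node_name]]
        while stack:
            node = stack.pop()
            out.update(int(c) for c in node.get("clusters", []))
            stack.extend(node.get("children", []))
        return out

    def validate(self, k: int) -> None:
        for name in self._nodes:
            bad = [c for c in self.leaf_clusters(name) if not 0 <= c < k]
            if bad:
                raise ValueError(
                    f"hierarchy node {name!r} references clusters {bad} "
                    f"outside [0, {k})")


# ---------------------------------------------------------------------------
# Cluster assignment of a subject
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-fiber atlas assignment for one subject.

    ``fiber_indices`` maps rows back into the original tractogram (fibers
    below the atlas minimum length are not assigned).  Outlier fibers keep
    their cluster label but are excluded from tract selection and presence.
    """

    fiber_indices: np.ndarray       # (n,), indices into the input tractogram
    labels: np.ndarray              # (n,) cluster ids in [0, k)
    probabilities: np.ndarray       # (n,)
    outlier: np.ndarray             # (n,) bool
    hemisphere: np.ndarray          # (n,) of {"left", "right", "commissural"}

    def __len__(self) -> int:
        return self.labels.shape[0]


def split_hemisphere(assignment: ClusterAssignment,
                     fibers_atlas_frame: Sequence[np.ndarray],
                     point_fraction: float = 0.8) -> ClusterAssignment:
    """Label each fiber left/right/commissural by its points' x signs.

    A fiber is "left" if at least ``point_fraction`` of its points have
    x < 0 in the atlas frame (whose midsagittal plane is x = 0), "right"
    symmetrically, otherwise "commissural".
    """
    hemis = np.empty(len(assignment), dtype=object)
    for i, pts in enumerate(fibers_atlas_frame):
        x = np.asarray(pts)[:, 0]
        frac_left = np.mean(x < 0)
        frac_right = np.mean(x > 0)
        if frac_left >= point_fraction:
            hemis[i] = "left"
        elif frac_right >= point_fraction:
            hemis[i] = "right"
        else:
            hemis[i] = "commissural"
    assignment.hemisphere = hemis
    return assignment


def assign_subject(atlas: Atlas, subject: Tractogram,
                   reg_config: Optional[RegistrationConfig] = None,
                   ) -> tuple[ClusterAssignment, LinearTransform]:
    """Register a subject to the atlas and assign every fiber to a cluster.

    Returns the assignment plus the subject->atlas affine so selections can
    be mapped back to the subject frame.  Fiber probability is computed
    against the atlas's kept training fibers of the assigned cluster and the
    stored (mu, sd) statistics drive the outlier rule
    ``p_i < mu_c - threshold_sd * sd_c``.
    """
    cfg = atlas.config
    if len(subject) == 0:
        empty = ClusterAssignment(
            fiber_indices=np.empty(0, dtype=int),
            labels=np.empty(0, dtype=np.int64),
            probabilities=np.empty(0), outlier=np.empty(0, dtype=bool),
            hemisphere=np.empty(0, dtype=object))
        return empty, LinearTransform.identity()

    if subject.frame == "atlas":
        transform = LinearTransform.identity()
    else:
        reg_config = reg_config or RegistrationConfig(
            fibers_per_subject=300, min_fiber_length=cfg.min_fiber_length,
            seed=cfg.seed)
        pool = Tractogram(
            subject_id="atlas",
            fibers=[Fiber(a) for a in atlas.basis.sample_fibers],
            frame="atlas")
        transform = register_affine_to_pool(subject, pool, reg_config)
    registered = apply_transform(subject, transform, frame="atlas")

    idx = np.array([i for i, f in enumerate(registered.fibers)
                    if fiber_length(f) >= cfg.min_fiber_length], dtype=int)
    fibers = stack_resampled([registered.fibers[i] for i in idx],
                             cfg.n_points)
    emb = embed_fibers(atlas.basis, fibers)
    d2 = ((emb.coords[:, None, :] - atlas.centroids[None, :, :]) ** 2).sum(-1)
    labels = d2.argmin(axis=1).astype(np.int64)

    dist_cfg = DistanceConfig(n_points=cfg.n_points, bilateral=cfg.bilateral)
    probs = np.zeros(labels.shape[0])
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        train = atlas.training_fibers[atlas.training_labels == c]
        if train.shape[0] == 0:
            continue
        D = pairwise_distance_matrix(fibers[members], train, dist_cfg)
        probs[members] = np.exp(-(D ** 2) / cfg.sigma_cluster ** 2).mean(axis=1)
    mu = atlas.cluster_stats[labels, 0]
    sd = atlas.cluster_stats[labels, 1]
    outlier = probs < mu - cfg.outlier_threshold_sd * sd
    outlier |= emb.low_affinity

    assignment = ClusterAssignment(
        fiber_indices=idx, labels=labels, probabilities=probs,
        outlier=outlier, hemisphere=np.empty(labels.shape[0], dtype=object))
    split_hemisphere(assignment,
                     [registered.fibers[i].points for i in idx])
    return assignment, transform


def cluster_presence(assignment: ClusterAssignment, k: int,
                     min_fibers: int = 1) -> np.ndarray:
    """Per-cluster detection flags: >= min_fibers non-outlier fibers."""
    present = np.zeros(k, dtype=bool)
    if len(assignment) == 0:
        return present
    labels = assignment.labels[~assignment.outlier]
    counts = np.bincount(labels, minlength=k)
    return counts >= min_fibers


def select_tract(assignment: ClusterAssignment, tractogram: Tractogram,
                 hierarchy: Hierarchy, node: str,
                 hemisphere: Optional[str] = None,
                 to_subject: Optional[LinearTransform] = None) -> Tractogram:
    """Extract the named tract: non-outlier fibers of the node's clusters.

    ``tractogram`` must be the subject's fibers in the atlas frame (the
    frame the assignment was computed in).  With ``to_subject`` set to the
    subject->atlas affine, fibers are mapped back to the subject frame via
    its inverse.
    """
    clusters = hierarchy.leaf_clusters(node)
    pick = np.array(
        [lab in clusters for lab in assignment.labels]) & ~assignment.outlier
    if hemisphere is not None:
        pick &= assignment.hemisphere == hemisphere
    fibers = [tractogram.fibers[i]
              for i in assignment.fiber_indices[np.flatnonzero(pick)]]
    out = Tractogram(subject_id=tractogram.subject_id, fibers=fibers,
                     frame="atlas")
    if to_subject is not None:
        out = apply_transform(out, to_subject.inverse(), frame="subject")
    return out


# ---------------------------------------------------------------------------
# Atlas persistence
# ---------------------------------------------------------------------------

def save_atlas(atlas: Atlas, directory) -> None:
    """Write an atlas directory: arrays as .npz, config/stats/hierarchy as
    JSON, sample fibers additionally as polydata for inspection."""
    from .tract_io import write_tractogram

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "arrays.npz",
             sample_fibers=atlas.basis.sample_fibers,
             eigvecs=atlas.basis.sample_affinity_eigvecs,
             eigvals=atlas.basis.eigvals,
             degrees=atlas.basis.degree_estimates,
             centroids=atlas.centroids,
             cluster_stats=atlas.cluster_stats,
             training_fibers=atlas.training_fibers,
             training_labels=atlas.training_labels,
             training_subjects=atlas.training_subjects.astype("U"),
             training_fiber_indices=atlas.training_fiber_indices,
             subject_presence=atlas.subject_presence)
    meta = {
        "config": asdict(atlas.config),
        "basis": {"sigma": atlas.basis.sigma,
                  "bilateral": atlas.basis.bilateral},
        "subject_ids": atlas.subject_ids,
        "hierarchy": (atlas.hierarchy.to_dict()
                      if atlas.hierarchy is not None else None),
    }
    with open(directory / "atlas.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    write_tractogram(
        Tractogram(subject_id="atlas_samples",
                   fibers=[Fiber(a) for a in atlas.basis.sample_fibers],
                   frame="atlas"),
        directory / "sample_fibers.vtp")


def load_atlas(directory) -> Atlas:
    directory = Path(directory)
    for name in ("arrays.npz", "atlas.json"):
        if not (directory / name).exists():
            raise FileNotFoundError(
                f"atlas directory is missing component file {name!r}")
    with open(directory / "atlas.json") as fh:
        meta = json.load(fh)
    arr = np.load(directory / "arrays.npz", allow_pickle=False)
    config = ClusterConfig(**meta["config"])
    basis = EmbeddingBasis(
        sample_fibers=arr["sample_fibers"],
        sigma=float(meta["basis"]["sigma"]),
        bilateral=bool(meta["basis"]["bilateral"]),
        sample_affinity_eigvecs=arr["eigvecs"],
        eigvals=arr["eigvals"],
        degree_estimates=arr["degrees"])
    hierarchy = (Hierarchy(meta["hierarchy"])
                 if meta.get("hierarchy") else None)
    return Atlas(basis=basis, centroids=arr["centroids"],
                 cluster_stats=arr["cluster_stats"],
                 training_fibers=arr["training_fibers"],
                 training_labels=arr["training_labels"],
                 training_subjects=arr["training_subjects"],
                 training_fiber_indices=arr["training_fiber_indices"],
                 subject_presence=arr["subject_presence"],
                 subject_ids=list(meta["subject_ids"]),
                 config=config, hierarchy=hierarchy)
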