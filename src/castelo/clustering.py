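"""Frame clustering: density clustering of latent embeddings, the
quality-threshold RMSD reference clustering, and cluster-size series.

Two clustering routes are compared frame-for-frame:

* latent route — HDBSCAN (minimum cluster size 50, otherwise defaults) over
  the d-dimensional CVAE embeddings; noise frames get label −1;
* reference route — binding-mode clustering of the whole ligand: frames are
  rigid-body superposed on the protein atoms (least-squares fit to frame 0),
  the pairwise ligand-atom RMSD matrix is computed without further fitting,
  and a greedy quality-threshold scheme repeatedly extracts the frame with
  the most neighbours within the cutoff (default 2.0 Å) together with that
  neighbourhood as one cluster.

Either assignment is converted to a per-frame cluster-size series: sizes[t]
is the population of the cluster containing frame t (noise frames count as
singletons). A binding mode is called stable when the largest cluster's
total membership time exceeds 50 ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .contacts import Trajectory
from .cvae import LatentEmbedding
from .exceptions import AlignmentError, SelectionError

__all__ = [
    "ClusterAssignment",
    "ClusterSizeSeries",
    "cluster_latent",
    "qt_rmsd_cluster",
    "size_series",
    "is_stable",
    "pairwise_ligand_rmsd",
]

DEFAULT_MIN_CLUSTER_SIZE = 50
DEFAULT_RMSD_CUTOFF = 2.0  # Å
DEFAULT_MIN_PERSIST_NS = 50.0


@dataclass
class ClusterAssignment:
    """Per-frame integer labels; −1 marks unclustered/noise frames."""

    labels: np.ndarray
    source: str = "latent"  # latent | rmsd_reference | external

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(self.n_frames), "label": self.labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str = "external") -> "ClusterAssignment":
        df = pd.read_csv(path)
        df = df.sort_values("frame")
        frames = df["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames.size)):
            raise AlignmentError("assignment CSV must cover frames 0..T-1 exactly once")
        return cls(labels=df["label"].to_numpy(), source=source)


@dataclass
class ClusterSizeSeries:
    """sizes[t] = population of the cluster containing frame t (≥ 1)."""

    sizes: np.ndarray
    identity: str = "subtype"  # "molecule" (C_{t,S}) or "subtype" (C_{t,A})

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.sizes.ndim != 1 or (self.sizes < 1).any():
            raise ValueError("sizes must be a 1-D array of positive counts")

    @property
    def n_frames(self) -> int:
        return self.sizes.size


def cluster_latent(
    embedding, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> ClusterAssignment:
    """HDBSCAN over latent vectors; clusters smaller than the minimum never form.

    Degenerate inputs are handled explicitly: fewer frames than
    ``min_cluster_size`` yields all-noise, and an exactly constant point
    cloud yields a single cluster (density clustering cannot rank
    zero-distance points).
    """
    X = embedding.vectors if isinstance(embedding, LatentEmbedding) else np.asarray(embedding)
    X = np.asarray(X, dtype=float)
    T = X.shape[0]
    if T < min_cluster_size:
        return ClusterAssignment(labels=np.full(T, -1), source="latent")
    if np.all(X == X[0]):
        return ClusterAssignment(labels=np.zeros(T, dtype=int), source="latent")
    from sklearn.cluster import HDBSCAN

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        labels = HDBSCAN(min_cluster_size=int(min_cluster_size), copy=True).fit(X).labels_
    return ClusterAssignment(labels=labels.astype(int), source="latent")


def _superpose_to_first(traj: Trajectory) -> np.ndarray:
    """Return all-atom coords with every frame protein-fitted to frame 0."""
    from MDAnalysis.analysis.align import rotation_matrix

    ref = traj.protein_coords(0)
    ref_center = ref.mean(axis=0)
    ref0 = ref - ref_center
    out = np.empty_like(traj.coords)
    for t in range(traj.n_frames):
        mob = traj.protein_coords(t)
        center = mob.mean(axis=0)
        R, _ = rotation_matrix(mob - center, ref0)
        out[t] = (traj.coords[t] - center) @ R.T + ref_center
    return out


def pairwise_ligand_rmsd(traj: Trajectory) -> np.ndarray:
    """T×T ligand-atom RMSD matrix after protein superposition (no refitting)."""
    if traj.n_ligand == 0 or traj.n_protein == 0:
        raise SelectionError("trajectory must define ligand and protein atoms")
    coords = _superpose_to_first(traj)
    lig = coords[:, traj.ligand_indices]  # (T, N, 3)
    # ||x_i - x_j||^2 averaged over atoms, via the squared-norm expansion
    sq = np.einsum("tnd,tnd->t", lig, lig)
    cross = np.einsum("ind,jnd->ij", lig, lig)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * cross) / lig.shape[1]
    np.clip(d2, 0.0, None, out=d2)
    return np.sqrt(d2)


def qt_rmsd_cluster(
    traj: Trajectory,
    cutoff: float = DEFAULT_RMSD_CUTOFF,
    max_clusters: Optional[int] = None,
) -> ClusterAssignment:
    """Greedy quality-threshold clustering of binding modes.

    Repeatedly pick the unassigned frame with the most unassigned neighbours
    within ``cutoff`` (ties: lowest frame index), assign that whole
    neighbourhood as one cluster, and remove it. If ``max_clusters`` is set,
    frames left after that many clusters are labelled −1.
    """
    rmsd = pairwise_ligand_rmsd(traj)
    return _qt_cluster_from_matrix(rmsd, cutoff, max_clusters)


def _qt_cluster_from_matrix(
    dist: np.ndarray, cutoff: float, max_clusters: Optional[int] = None
) -> ClusterAssignment:
    T = dist.shape[0]
    neighbors = dist <= cutoff  # closed comparison; includes self
    labels = np.full(T, -1)
    remaining = np.ones(T, dtype=bool)
    next_label = 0
    while remaining.any():
        if max_clusters is not None and next_label >= max_clusters:
            break
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbors[center] & remaining
        labels[members] = next_label
        remaining &= ~members
        next_label += 1
    return ClusterAssignment(labels=labels, source="rmsd_reference")


def size_series(assign: ClusterAssignment, identity: str = "subtype") -> ClusterSizeSeries:
    """Per-frame size of the containing cluster; noise frames get size 1."""
    labels = assign.labels
    sizes = np.ones(labels.size, dtype=int)
    uniq, counts = np.unique(labels[labels >= 0], return_counts=True)
    count_of = dict(zip(uniq.tolist(), counts.tolist()))
    for t, lab in enumerate(labels):
        if lab >= 0:
            sizes[t] = count_of[lab]
    return ClusterSizeSeries(sizes=sizes, identity=identity)


def is_stable(
    series: ClusterSizeSeries,
    frame_interval_ps: float,
    min_persist_ns: float = DEFAULT_MIN_PERSIST_NS,
) -> bool:
    """True iff the largest cluster persists strictly longer than the threshold.

    Persistence is total membership time: largest cluster population ×
    frame interval. 2500 frames at 20 ps is exactly 50 ns and does not count
    as stable (strictly longer is required).
    """
    if frame_interval_ps <= 0:
        raise ValueError("frame_interval_ps must be positive")
    largest = int(series.sizes.max())
    return largest * frame_interval_ps / 1000.0 > min_persist_ns
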