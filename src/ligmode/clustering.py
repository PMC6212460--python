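"""Greedy RMSD-based (GROMOS/Daura-style) clustering of ligand poses.

All frames are first superposed on a reference over the fit selection
(one global fit per frame -- no per-pair ligand refit, which would erase
the orientational differences the clustering is meant to resolve).  The
all-pairs ligand heavy-atom RMSD matrix is then thresholded and clusters
extracted greedily: the frame with the most neighbors within the cutoff
(lowest frame index on ties) becomes a centroid, it and its neighbors
are removed, and the process repeats until no frames remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .trajio import MolecularSystem, Selection, Trajectory, superpose

__all__ = ["ClusterResult", "daura_cluster", "pairwise_rmsd_matrix",
           "rank_and_project"]


def _indices(sel) -> np.ndarray:
    return np.asarray(getattr(sel, "indices", sel), dtype=np.intp)


@dataclass
class ClusterResult:
    """Partition of frames into clusters sorted by size (descending)."""

    clusters: list[np.ndarray]    # frame indices per cluster
    centroids: list[int]          # picked frame per cluster
    cutoff: float
    rmsd_definition: str = "ligand heavy atoms, one global CA fit, no refit"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self, n_frames: int) -> np.ndarray:
        """cluster id per frame (0 = largest cluster)."""
        out = np.full(n_frames, -1, dtype=int)
        for cid, members in enumerate(self.clusters):
            out[members] = cid
        return out


def pairwise_rmsd_matrix(coords: np.ndarray,
                         block_size: int = 256) -> np.ndarray:
    """All-pairs coordinate RMSD (no refit) for (n_frames, n_atoms, 3).

    Computed in frame blocks to bound peak memory.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    out = np.empty((n, n))
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        diff = coords[i0:i1, None] - coords[None]   # (b, n, atoms, 3)
        out[i0:i1] = np.sqrt(np.mean(np.sum(diff ** 2, axis=3), axis=2))
    return out


def daura_cluster(traj: Trajectory,
                  ligand_selection: Selection | np.ndarray,
                  fit_selection: Selection | np.ndarray,
                  reference: MolecularSystem | None = None,
                  cutoff: float = 2.0,
                  stride: int = 1) -> ClusterResult:
    """Greedy neighbor clustering of ligand conformations.

    Neighborhood uses inclusive <= cutoff on the post-fit ligand RMSD.
    ``stride`` subsamples frames before clustering (cluster members are
    reported in the strided frame numbering of the input trajectory).
    """
    lig = _indices(ligand_selection)
    if len(lig) == 0:
        raise UsageError("ligand selection is empty")
    fit = _indices(fit_selection)
    if traj.n_frames < 1:
        raise UsageError("trajectory has no frames")
    if stride < 1:
        raise UsageError("stride must be >= 1")
    frame_ids = np.arange(0, traj.n_frames, stride)
    if stride > 1:
        warnings.warn(f"clustering strided to {len(frame_ids)} frames "
                      f"(stride {stride})")
    ref_coords = (reference.coords if reference is not None
                  else traj.coords[0])
    fitted = np.empty((len(frame_ids), len(lig), 3))
    for k, f in enumerate(frame_ids):
        moved, _ = superpose(traj.coords[f], ref_coords, fit)
        fitted[k] = moved[lig]

    matrix = pairwise_rmsd_matrix(fitted)
    neighbors = matrix <= cutoff
    np.fill_diagonal(neighbors, True)

    remaining = np.ones(len(frame_ids), dtype=bool)
    clusters: list[np.ndarray] = []
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbors & remaining[None]).sum(axis=1)
        counts[~remaining] = -1
        pick = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.nonzero(neighbors[pick] & remaining)[0]
        clusters.append(frame_ids[members])
        centroids.append(int(frame_ids[pick]))
        remaining[members] = False

    # greedy extraction already yields non-increasing sizes
    return ClusterResult(clusters=clusters, centroids=centroids,
                         cutoff=float(cutoff))


def rank_and_project(result: ClusterResult, angle_series: np.ndarray,
                     k: int = 7) -> list[dict]:
    """Top-k centroids with their (theta, phi) map coordinates.

    ``angle_series`` is the (n_frames, 2) output of
    :func:`ligmode.orientation.orientation_angles` for the same
    trajectory.  Truncates with a warning when k exceeds the cluster
    count.
    """
    angles = np.asarray(angle_series, dtype=np.float64)
    if k > result.n_clusters:
        warnings.warn(
            f"requested top-{k} but only {result.n_clusters} clusters exist"
        )
        k = result.n_clusters
    out = []
    for rank in range(k):
        centroid = result.centroids[rank]
        if centroid >= len(angles):
            raise UsageError(
                f"centroid frame {centroid} missing from the angle series"
            )
        theta, phi = angles[centroid]
        out.append({
            "rank": rank,
            "centroid_frame": int(centroid),
            "population": int(len(result.clusters[rank])),
            "theta": float(theta),
            "phi": float(phi),
        })
    return out
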