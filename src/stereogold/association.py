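"""Assigning gold-bead centroids to towers.

Two routes, selectable via config: ``NN`` votes over the pooled sampled
border points (the k nearest surface samples of a bead vote for their
towers; plurality wins, ties go to the smaller mean distance) and ``DT``
looks up an anisotropy-aware Euclidean distance transform of the label
volume at the bead's voxel.  Either way a bead farther than the exclusion
threshold from any surface evidence is dropped from the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import BeadSet
from .volumes import LabelVolume

__all__ = ["Assignment", "associate_nn", "associate_dt"]


@dataclass
class Assignment:
    """Per-bead association outcome.

    ``tower`` holds the assigned tower ID (0 where excluded), ``distance``
    the distance (um) to the supporting surface evidence — the nearest border
    sample for NN, the nearest labelled voxel centre for DT.
    """

    tower: np.ndarray       # (n,) int, 0 = excluded
    distance: np.ndarray    # (n,) float um
    excluded: np.ndarray    # (n,) bool
    method: str

    def apply_to(self, beads: BeadSet) -> BeadSet:
        return BeadSet(beads.centroids.copy(), self.tower.copy(), self.excluded.copy())

    @property
    def n_assigned(self) -> int:
        return int((~self.excluded).sum())


def associate_nn(
    beads: BeadSet,
    borders: dict[int, np.ndarray],
    k: int = 10,
    min_dist_thr_um: float = 100.0,
) -> Assignment:
    """k-nearest-neighbour vote over pooled border samples.

    With ``k=1`` this reduces to pure nearest-surface-sample assignment.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids, pools = zip(*((tid, p) for tid, p in borders.items() if len(p)))
    pooled = np.vstack(pools)
    owner = np.concatenate([np.full(len(p), tid) for tid, p in zip(ids, pools)])
    if k > len(pooled):
        warnings.warn(
            f"k={k} exceeds the {len(pooled)} pooled border points; clipping", stacklevel=2
        )
        k = len(pooled)

    n = len(beads)
    tower = np.zeros(n, dtype=int)
    distance = np.full(n, np.inf)
    excluded = np.ones(n, dtype=bool)
    if n == 0:
        return Assignment(tower, distance, excluded, "NN")

    tree = cKDTree(pooled)
    dists, idx = tree.query(beads.centroids, k=k)
    dists = np.atleast_2d(dists.reshape(n, -1))
    idx = np.atleast_2d(idx.reshape(n, -1))

    for i in range(n):
        distance[i] = dists[i, 0]
        if dists[i, 0] > min_dist_thr_um:
            continue
        votes = owner[idx[i]]
        cand, counts = np.unique(votes, return_counts=True)
        top = cand[counts == counts.max()]
        if len(top) > 1:  # tie: smaller mean distance wins
            means = [dists[i][votes == t].mean() for t in top]
            winner = top[int(np.argmin(means))]
        else:
            winner = top[0]
        tower[i] = int(winner)
        excluded[i] = False
    return Assignment(tower, distance, excluded, "NN")


def associate_dt(
    beads: BeadSet,
    vol: LabelVolume,
    min_dist_thr_um: float = 100.0,
) -> Assignment:
    """Distance-transform association over the label volume.

    The Euclidean distance to the nearest labelled voxel (with the physical,
    anisotropic voxel size as sampling) is computed once, with nearest-label
    propagation; each bead reads off the label and distance at its voxel.
    Beads inside a tower mask get distance 0; beads outside the volume are
    excluded with a diagnostic.
    """
    n = len(beads)
    tower = np.zeros(n, dtype=int)
    distance = np.full(n, np.inf)
    excluded = np.ones(n, dtype=bool)
    if n == 0:
        return Assignment(tower, distance, excluded, "DT")
    if vol.labels().size == 0:
        return Assignment(tower, distance, excluded, "DT")

    sampling = vol.voxel_size[::-1] / 1000.0  # (z, y, x) um
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        vol.data == 0, sampling=sampling, return_indices=True
    )
    nearest_label = vol.data[iz, iy, ix]

    # bead centroid -> containing voxel index
    vox = np.floor(beads.centroids[:, ::-1] * 1000.0 / vol.voxel_size[::-1]).astype(int)
    shape = np.asarray(vol.data.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    for i in range(n):
        if not inside[i]:
            warnings.warn(f"bead {i} lies outside the label volume; excluded", stacklevel=2)
            continue
        z, y, x = vox[i]
        d = float(dist[z, y, x])
        distance[i] = d
        if d > min_dist_thr_um:
            continue
        tower[i] = int(nearest_label[z, y, x])
        excluded[i] = False
    return Assignment(tower, distance, excluded, "DT")
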