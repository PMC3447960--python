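"""Superposition RMSD, modal-RMSD summaries and GROMOS clustering.

RMSDs are computed on the one-particle-per-residue representation after
least-squares rigid superposition (optimal rotation via the SVD/Kabsch
construction with reflection correction). Conformer families are found
with the GROMOS neighbour-counting algorithm: repeatedly take the frame
with the most neighbours within an RMSD cutoff as a cluster centroid,
assign it and its neighbours to a cluster, remove them, and recount. The
representative "middle structure" of a cluster is its RMSD medoid.
"""
from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Ensemble, SpecError


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation matrix R, translation t, RMSD nm)`` such that
    ``mobile @ R.T + t`` best fits ``reference``. Proper rotations only
    (reflections corrected). Requires >= 3 points whose centred scatter
    has rank >= 2 (collinear point sets leave the rotation undetermined).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SpecError("point sets must share shape (N, 3)")
    n = mob.shape[0]
    if n < 3:
        raise SpecError("superposition needs at least 3 points")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - mc, ref - rc
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-300):
        raise SpecError("rank-deficient scatter: rotation undetermined")
    rot, rssd = Rotation.align_vectors(b, a)
    rmsd = float(rssd / np.sqrt(n))
    r = rot.as_matrix()
    t = rc - r @ mc
    return r, t, rmsd


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of post-superposition RMSDs between all frames."""
    f = coords.shape[0]
    d = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            _, _, r = superpose(coords[j], coords[i])
            d[i, j] = d[j, i] = r
    return d


@dataclasses.dataclass
class RmsdSeries:
    reference_frame: int
    selection: str | None
    rmsd: np.ndarray          # nm, per frame
    bin_width: float
    modal_rmsd: float         # midpoint of the highest-count histogram bin

    def __post_init__(self):
        if np.any(self.rmsd < -1e-12):
            raise SpecError("RMSD must be non-negative")


def rmsd_series(ensemble: Ensemble, selection: str | None = None,
                reference_frame: int = 0, bin_width: float = 0.02) -> RmsdSeries:
    """Per-frame RMSD to a reference frame after selection-local superposition.

    Each frame is superposed on the reference using only the selected
    particles, so rigid motion of the selection (e.g. hinge bending of the
    rest of the molecule) does not inflate the series. The modal RMSD is
    the midpoint of the highest-count fixed-origin histogram bin.
    """
    if not 0 <= reference_frame < ensemble.n_frames:
        raise SpecError(f"reference frame {reference_frame} not in ensemble")
    top = ensemble.topology
    idx = top.select(selection) if selection else np.arange(top.n_particles)
    ref = ensemble.coords[reference_frame, idx]
    vals = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        if f == reference_frame:
            vals[f] = 0.0
            continue
        _, _, vals[f] = superpose(ensemble.coords[f, idx], ref)
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))
    return RmsdSeries(reference_frame=reference_frame, selection=selection,
                      rmsd=vals, bin_width=float(bin_width),
                      modal_rmsd=float((edges[k] + edges[k + 1]) / 2))


@dataclasses.dataclass
class Cluster:
    members: np.ndarray       # frame ids, ascending
    centroid: int             # max-neighbour frame that seeded the cluster


@dataclasses.dataclass
class Clustering:
    cutoff: float
    clusters: List[Cluster]
    frame_ids: np.ndarray     # ids clustered (identity or window subset)

    def sizes(self) -> np.ndarray:
        return np.array([len(c.members) for c in self.clusters])


def gromos_cluster(ensemble: Ensemble, selection: str | None = None,
                   cutoff: float = 0.1,
                   window: Tuple[float, float] | None = None) -> Clustering:
    """GROMOS conformational clustering on pairwise post-fit RMSDs.

    ``window=(t0, t1)`` restricts clustering to frames in that time range
    (e.g. the final stretch of a trajectory). Ties in neighbour count
    resolve to the lowest frame id; discovery order gives non-increasing
    cluster sizes.
    """
    if cutoff <= 0:
        raise SpecError("cutoff must be positive")
    ens = ensemble.window(*window) if window is not None else ensemble
    if window is not None:
        frame_ids = np.flatnonzero((ensemble.times >= window[0])
                                   & (ensemble.times <= window[1]))
    else:
        frame_ids = np.arange(ensemble.n_frames)
    top = ens.topology
    idx = top.select(selection) if selection else np.arange(top.n_particles)
    d = pairwise_rmsd(ens.coords[:, idx])
    return _gromos_from_matrix(d, cutoff, frame_ids)


def _gromos_from_matrix(d: np.ndarray, cutoff: float,
                        frame_ids: np.ndarray) -> Clustering:
    f = d.shape[0]
    alive = np.ones(f, dtype=bool)
    clusters: List[Cluster] = []
    while np.any(alive):
        sub = d[np.ix_(alive, alive)] <= cutoff
        counts = sub.sum(axis=1)                  # includes self
        local = int(np.argmax(counts))            # argmax -> lowest index tie-break
        alive_idx = np.flatnonzero(alive)
        centroid = int(alive_idx[local])
        members = alive_idx[sub[local]]
        clusters.append(Cluster(members=np.array([int(frame_ids[m]) for m in members]),
                                centroid=int(frame_ids[centroid])))
        alive[members] = False
    return Clustering(cutoff=float(cutoff), clusters=clusters,
                      frame_ids=frame_ids)


def representative(cluster: Cluster, ensemble: Ensemble,
                   selection: str | None = None) -> int:
    """The cluster's middle structure: the RMSD medoid (ties: lowest id)."""
    if len(cluster.members) == 0:
        raise SpecError("empty cluster has no representative")
    if len(cluster.members) == 1:
        return int(cluster.members[0])
    top = ensemble.topology
    idx = top.select(selection) if selection else np.arange(top.n_particles)
    # cluster.members holds original frame ids == positions in the ensemble
    sub = ensemble.coords[np.asarray(cluster.members)][:, idx]
    d = pairwise_rmsd(sub)
    sums = d.sum(axis=1)
    return int(cluster.members[int(np.argmin(sums))])
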