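"""Gaussian and anisotropic network models on one-particle-per-residue models.

All particles within a distance cutoff are connected by springs of equal,
unit strength. The Gaussian network model (GNM) builds the N x N Kirchhoff
(graph Laplacian) matrix and is isotropic; the anisotropic network model
(ANM) builds the 3N x 3N Hessian from directional super-elements.
Eigenvalues are in arbitrary units — only ratios and mode shapes are
interpreted. Default cutoffs: 0.7 nm (GNM), 1.3 nm (ANM).

The slow (lowest nonzero) GNM mode identifies hinge regions: residues
where the dominant eigenvector's magnitude is small are the nodes about
which the two lobes of the structure move in antiphase.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import List, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .core import ParticleModel, SpecError

GNM_CUTOFF = 0.7   # nm
ANM_CUTOFF = 1.3   # nm

#: |eigenvalue| below this fraction of the largest eigenvalue counts as zero
ZERO_MODE_REL_TOL = 1e-8


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def build_kirchhoff(model: ParticleModel | np.ndarray,
                    cutoff: float = GNM_CUTOFF) -> np.ndarray:
    """Kirchhoff (Laplacian) connectivity matrix with unit springs.

    Off-diagonal entries are -1 for pairs with 0 < d <= cutoff, else 0;
    the diagonal holds the node degree, so every row sums to zero.
    Coincident particle pairs are counted as connected, with a warning.
    """
    coords = model.coords if isinstance(model, ParticleModel) else np.asarray(model)
    n = coords.shape[0]
    if n < 2:
        raise SpecError("need at least 2 particles")
    if cutoff <= 0:
        raise SpecError("cutoff must be positive")
    d = _pair_distances(coords)
    adj = d <= cutoff
    np.fill_diagonal(adj, False)
    if np.any(d[adj] == 0.0):
        warnings.warn("coincident particles within cutoff: zero-distance "
                      "pair counted as connected", RuntimeWarning)
    k = -adj.astype(float)
    np.fill_diagonal(k, adj.sum(axis=1).astype(float))
    return k


def build_hessian(model: ParticleModel | np.ndarray,
                  cutoff: float = ANM_CUTOFF) -> np.ndarray:
    """ANM Hessian (3N x 3N) with unit springs.

    The off-diagonal super-element for a connected pair (i, j) is
    ``-(r_ij r_ij^T) / |r_ij|^2``; diagonal super-elements are minus the
    sum of their row's off-diagonal blocks. Coincident connected pairs
    have no defined spring direction and raise an error.
    """
    coords = model.coords if isinstance(model, ParticleModel) else np.asarray(model)
    n = coords.shape[0]
    if n < 2:
        raise SpecError("need at least 2 particles")
    if cutoff <= 0:
        raise SpecError("cutoff must be positive")
    d = _pair_distances(coords)
    adj = d <= cutoff
    np.fill_diagonal(adj, False)
    if np.any(d[adj] == 0.0):
        raise SpecError("coincident connected particles: spring direction undefined")
    ii, jj = np.nonzero(np.triu(adj, k=1))
    h = np.zeros((3 * n, 3 * n))
    rij = coords[jj] - coords[ii]
    d2 = np.einsum("ki,ki->k", rij, rij)
    blocks = -np.einsum("ki,kj->kij", rij, rij) / d2[:, None, None]
    for (i, j, b) in zip(ii, jj, blocks):
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += b
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += b
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= b
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= b
    return h


@dataclasses.dataclass
class NetworkModes:
    """Eigen-decomposition of a Kirchhoff or Hessian matrix."""

    kind: str                   # "gnm" | "anm"
    cutoff: float | None
    eigenvalues: np.ndarray     # ascending
    eigenvectors: np.ndarray    # columns, orthonormal
    n_zero: int
    components: np.ndarray      # connected-component label per particle
    degenerate_dominant: bool = False

    @property
    def dominant_index(self) -> int:
        """Index of the lowest nonzero-eigenvalue mode."""
        return self.n_zero

    def dominant_mode(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero]


def _graph_components(matrix: np.ndarray, kind: str) -> np.ndarray:
    if kind == "gnm":
        adj = (matrix != 0) & ~np.eye(matrix.shape[0], dtype=bool)
    else:
        n = matrix.shape[0] // 3
        m = matrix.reshape(n, 3, n, 3)
        adj = np.abs(m).sum(axis=(1, 3)) > 1e-12
        adj &= ~np.eye(n, dtype=bool)
    _, labels = connected_components(scipy.sparse.csr_matrix(adj), directed=False)
    return labels


def decompose(matrix: np.ndarray, kind: str = "gnm", cutoff: float | None = None,
              n_modes: int | None = None) -> NetworkModes:
    """Eigen-decompose a symmetric network matrix (full or ``n_modes`` lowest).

    Zero modes are those with ``|eigenvalue| < 1e-8 * max eigenvalue``; for
    a GNM their count equals the number of connected components, for an
    ANM six per component (rigid-body motions) on 3-D non-degenerate
    structures. A relative gap < 1e-6 between the dominant mode and the
    next warns of degeneracy.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise SpecError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise SpecError("matrix must be symmetric")
    n = matrix.shape[0]
    if n_modes is not None and n_modes < n:
        # shift-invert about a point just below zero targets the slow end
        sp = scipy.sparse.csr_matrix(matrix)
        vals, vecs = scipy.sparse.linalg.eigsh(sp, k=n_modes, sigma=-1e-6,
                                               which="LM")
        lam_max = float(scipy.sparse.linalg.eigsh(
            sp, k=1, which="LA", return_eigenvectors=False)[0])
    else:
        vals, vecs = scipy.linalg.eigh(matrix)
        lam_max = float(vals[-1])
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    tol = ZERO_MODE_REL_TOL * max(abs(lam_max), 1e-300)
    n_zero = int(np.sum(np.abs(vals) < tol))
    degenerate = False
    if n_zero < len(vals) - 1:
        lam1, lam2 = vals[n_zero], vals[n_zero + 1]
        if lam1 > 0 and (lam2 - lam1) / lam1 < 1e-6:
            degenerate = True
            warnings.warn("dominant mode is (near-)degenerate; both modes "
                          "should be inspected", RuntimeWarning)
    components = _graph_components(matrix, kind)
    return NetworkModes(kind=kind, cutoff=cutoff, eigenvalues=vals,
                        eigenvectors=vecs, n_zero=n_zero,
                        components=components, degenerate_dominant=degenerate)


def gnm_fluctuations(modes: NetworkModes) -> np.ndarray:
    """Per-residue mean-square fluctuations (diagonal of the pseudo-inverse)."""
    if modes.kind != "gnm":
        raise SpecError("fluctuation profile is defined for GNM modes")
    vals = modes.eigenvalues[modes.n_zero:]
    vecs = modes.eigenvectors[:, modes.n_zero:]
    return (vecs ** 2 / vals[None, :]).sum(axis=1)


@dataclasses.dataclass
class HingeRun:
    """A contiguous run of low-|eigenvector| residues on one chain."""

    chain: str
    start: int
    end: int
    min_residue: int        # residue with the smallest |component|
    sign_crossings: int     # sign changes of the mode inside the run


@dataclasses.dataclass
class SlowModeHinges:
    runs: List[HingeRun]
    mode_indices: List[int]

    @property
    def residues(self) -> np.ndarray:
        out = set()
        for r in self.runs:
            out.update(range(r.start, r.end + 1))
        return np.array(sorted(out), dtype=int)


def slow_mode_hinges(modes: NetworkModes, model: ParticleModel,
                     threshold_quantile: float = 0.1) -> SlowModeHinges:
    """Hinge regions from the slow GNM mode of each connected component.

    Within each component, residues whose dominant-mode component
    magnitude falls below the given quantile of |components| are merged
    into contiguous per-chain runs. For disconnected networks (e.g. the
    two chains of an idealised dimer at a short cutoff) each component is
    analysed with its own slowest internal mode. A quantile of 0 selects
    nothing.
    """
    if modes.kind != "gnm":
        raise SpecError("slow-mode hinge analysis requires GNM modes")
    if not 0 <= threshold_quantile <= 1:
        raise SpecError("threshold_quantile must lie in [0, 1]")
    if modes.n_zero >= len(modes.eigenvalues):
        raise SpecError("no nonzero mode available")
    if model.n_particles != modes.eigenvectors.shape[0]:
        raise SpecError("model does not match the mode dimension")

    runs: List[HingeRun] = []
    used_modes: List[int] = []
    nonzero = np.arange(modes.n_zero, len(modes.eigenvalues))
    comp_labels = modes.components
    for comp in np.unique(comp_labels):
        in_comp = comp_labels == comp
        if in_comp.sum() < 3:
            continue
        # slowest nonzero mode localised on this component
        weight = (modes.eigenvectors[in_comp][:, nonzero] ** 2).sum(axis=0)
        cand = nonzero[weight > 0.5]
        if cand.size == 0:
            continue
        mode_idx = int(cand[0])
        picked = [mode_idx]
        if modes.degenerate_dominant and mode_idx == modes.n_zero:
            picked.append(mode_idx + 1)
        for mi in picked:
            used_modes.append(mi)
            v = modes.eigenvectors[:, mi]
            mags = np.abs(v[in_comp])
            thr = np.quantile(mags, threshold_quantile)
            sel_local = mags < thr
            if not np.any(sel_local):
                continue
            sel_global = np.zeros(model.n_particles, dtype=bool)
            sel_global[np.flatnonzero(in_comp)[sel_local]] = True
            runs.extend(_contiguous_runs(model, v, sel_global))
    return SlowModeHinges(runs=runs, mode_indices=sorted(set(used_modes)))


def _contiguous_runs(model: ParticleModel, mode: np.ndarray,
                     selected: np.ndarray) -> List[HingeRun]:
    runs = []
    for chain in np.unique(model.chains[selected]):
        on_chain = (model.chains == chain) & selected
        resids = model.resids[on_chain]
        vals = mode[on_chain]
        order = np.argsort(resids)
        resids, vals = resids[order], vals[order]
        start = 0
        for k in range(1, len(resids) + 1):
            if k == len(resids) or resids[k] != resids[k - 1] + 1:
                seg_r = resids[start:k]
                seg_v = vals[start:k]
                signs = np.sign(seg_v[np.abs(seg_v) > 0])
                crossings = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0
                runs.append(HingeRun(
                    chain=str(chain), start=int(seg_r[0]), end=int(seg_r[-1]),
                    min_residue=int(seg_r[int(np.argmin(np.abs(seg_v)))]),
                    sign_crossings=crossings,
                ))
                start = k
    return runs
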