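"""Residue-level interaction fingerprints between protein copies.

A fingerprint records, per residue of a query copy and per frame, the
shortest distance from any particle of that residue to any particle of
the partner copy. Binarising at a contact threshold gives per-frame
contact sets; the Jaccard index between a frame's contact set and a
reference (time-averaged) contact set tracks how an emerging interface
converges towards a reference binding surface.
"""
from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, SpecError

#: default contact threshold at one particle per residue, nm
CONTACT_THRESHOLD = 0.8


@dataclasses.dataclass
class Fingerprint:
    """Minimum partner distance per query residue per frame (nm)."""

    query: str
    partner: str
    residues: np.ndarray        # query residue ids, ascending
    distances: np.ndarray       # (n_residues, n_frames), >= 0
    times: np.ndarray

    def __post_init__(self):
        if np.any(self.distances < 0):
            raise SpecError("distances must be non-negative")


def fingerprint(ensemble: Ensemble, query: str, partner: str) -> Fingerprint:
    """Per-residue minimum distance from a query selection to a partner.

    Selections must be non-empty and disjoint. ``D[i, t]`` is the minimum
    over partner particles of the distance to any particle of query
    residue ``i`` at frame ``t``.
    """
    top = ensemble.topology
    qi = top.select(query)
    pi = top.select(partner)
    if np.intersect1d(qi, pi).size:
        raise SpecError("query and partner selections overlap")
    q_resids = top.resids[qi]
    residues = np.unique(q_resids)
    f = ensemble.n_frames
    d = np.empty((len(residues), f))
    groups = [qi[q_resids == r] for r in residues]
    for t in range(f):
        tree = cKDTree(ensemble.coords[t, pi])
        dist_all, _ = tree.query(ensemble.coords[t, qi], k=1)
        for k, r in enumerate(residues):
            d[k, t] = dist_all[q_resids == r].min()
    return Fingerprint(query=query, partner=partner, residues=residues,
                       distances=d, times=ensemble.times.copy())


def contact_set(fp: Fingerprint, threshold: float = CONTACT_THRESHOLD,
                frame: int | None = None,
                window: Tuple[int, int] | None = None) -> np.ndarray:
    """Residues in contact in one frame, or in >= 50% of a window's frames.

    ``window`` is an inclusive frame-index range.
    """
    if threshold <= 0:
        raise SpecError("threshold must be positive")
    if (frame is None) == (window is None):
        raise SpecError("give exactly one of frame or window")
    if frame is not None:
        below = fp.distances[:, frame] < threshold
        return fp.residues[below]
    lo, hi = window
    cols = fp.distances[:, lo:hi + 1]
    if cols.shape[1] == 0:
        raise SpecError("empty frame window")
    frac = (cols < threshold).mean(axis=1)
    return fp.residues[frac >= 0.5]


@dataclasses.dataclass
class InterfaceSimilarity:
    """Per-frame Jaccard similarity to a reference contact set, in [0, 1].

    Frames where both the query and the reference contact sets are empty
    have no defined similarity; they carry NaN and are flagged.
    """

    scores: np.ndarray
    undefined: np.ndarray       # bool per frame
    reference_set: np.ndarray
    threshold: float


def interface_similarity(query_fp: Fingerprint, reference_fp: Fingerprint,
                         threshold: float = CONTACT_THRESHOLD
                         ) -> InterfaceSimilarity:
    """Jaccard index of each query frame's contacts vs the reference surface.

    The reference surface is the reference fingerprint's time-averaged
    contact set (residues in contact in at least half its frames).
    """
    if not np.array_equal(query_fp.residues, reference_fp.residues):
        raise SpecError("fingerprints must share residue indexing")
    ref_set = set(contact_set(reference_fp, threshold,
                              window=(0, reference_fp.distances.shape[1] - 1)).tolist())
    f = query_fp.distances.shape[1]
    scores = np.empty(f)
    undef = np.zeros(f, dtype=bool)
    for t in range(f):
        q = set(query_fp.residues[query_fp.distances[:, t] < threshold].tolist())
        union = q | ref_set
        if not union:
            scores[t] = np.nan
            undef[t] = True
        else:
            scores[t] = len(q & ref_set) / len(union)
    return InterfaceSimilarity(scores=scores, undefined=undef,
                               reference_set=np.array(sorted(ref_set), dtype=int),
                               threshold=float(threshold))


def smoothed(series: np.ndarray, window: int = 10) -> np.ndarray:
    """Trailing moving average (NaNs ignored) used for convergence checks."""
    if window < 1:
        raise SpecError("window must be >= 1")
    out = np.empty(len(series))
    for i in range(len(series)):
        seg = series[max(0, i - window + 1):i + 1]
        seg = seg[~np.isnan(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out
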