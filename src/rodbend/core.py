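"""Core particle containers and the selection mini-language.

All coordinates are in nanometres and all residue indices are 1-based
throughout the package; unit conversion happens only at file boundaries
(:mod:`rodbend.io`).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np


class RodbendError(ValueError):
    """Base class for errors raised by rodbend."""


class SpecError(RodbendError):
    """An invalid generator or analysis specification."""


class SelectionError(RodbendError):
    """A selection expression that fails to parse or selects nothing."""


@dataclasses.dataclass
class ParticleModel:
    """A labelled point set: one particle per residue (or per lipid).

    Parameters
    ----------
    chains : array of str
        Chain identifier per particle (for vesicles: leaflet, ``"O"``/``"I"``).
    resids : array of int
        1-based residue index per particle, unique within a chain.
    domains : array of str
        Domain label per particle (for vesicles: lipid species).
    coords : (N, 3) array of float
        Positions in nm.
    model_id : str
        Free-form identifier.
    """

    chains: np.ndarray
    resids: np.ndarray
    domains: np.ndarray
    coords: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains, dtype="U8")
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.domains = np.asarray(self.domains, dtype="U8")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise SpecError("coords must have shape (N, 3)")
        if not (len(self.chains) == len(self.resids) == len(self.domains) == n):
            raise SpecError("label arrays and coords must have equal length")
        if n and not np.all(np.isfinite(self.coords)):
            raise SpecError("coordinates must be finite")
        for chain in np.unique(self.chains):
            r = self.resids[self.chains == chain]
            if len(np.unique(r)) != len(r):
                raise SpecError(f"duplicate residue ids within chain {chain!r}")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "ParticleModel":
        return ParticleModel(
            self.chains.copy(), self.resids.copy(), self.domains.copy(),
            self.coords.copy(), self.model_id,
        )

    def subset(self, index) -> "ParticleModel":
        return ParticleModel(
            self.chains[index], self.resids[index], self.domains[index],
            self.coords[index], self.model_id,
        )

    def select(self, expr: str, allow_empty: bool = False) -> np.ndarray:
        """Evaluate a selection expression, returning particle indices."""
        mask = selection_mask(self, expr)
        idx = np.flatnonzero(mask)
        if idx.size == 0 and not allow_empty:
            raise SelectionError(f"selection {expr!r} matches no particles")
        return idx


@dataclasses.dataclass
class Ensemble:
    """Ordered frames sharing one topology.

    ``topology`` carries the labels (its own coordinates are the first
    frame); ``coords`` is ``(n_frames, N, 3)`` in nm; ``times`` are in ns
    (for Monte-Carlo output: sweeps) and strictly increasing.
    """

    topology: ParticleModel
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SpecError("ensemble coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_particles:
            raise SpecError("frame particle count does not match topology")
        if self.coords.shape[0] != self.times.shape[0]:
            raise SpecError("one time per frame required")
        if self.coords.shape[0] == 0:
            raise SpecError("ensemble must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise SpecError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> ParticleModel:
        m = self.topology.copy()
        m.coords = self.coords[i].copy()
        m.model_id = f"{self.topology.model_id}:frame{i}"
        return m

    def window(self, t0: float, t1: float) -> "Ensemble":
        """Frames with t0 <= time <= t1 (used for last-window clustering)."""
        keep = (self.times >= t0) & (self.times <= t1)
        if not np.any(keep):
            raise SpecError(f"window [{t0}, {t1}] contains no frames")
        return Ensemble(self.topology, self.coords[keep], self.times[keep])


def ensemble_from_models(models: Sequence[ParticleModel],
                         times: Iterable[float] | None = None) -> Ensemble:
    if not models:
        raise SpecError("need at least one model")
    top = models[0]
    for k, m in enumerate(models[1:], start=1):
        same = (
            m.n_particles == top.n_particles
            and np.array_equal(m.chains, top.chains)
            and np.array_equal(m.resids, top.resids)
            and np.array_equal(m.domains, top.domains)
        )
        if not same:
            raise SpecError(f"frame {k} topology differs from frame 0")
    coords = np.stack([m.coords for m in models])
    if times is None:
        times = np.arange(len(models), dtype=float)
    return Ensemble(top.copy(), coords, np.asarray(list(times), dtype=float))


# ---------------------------------------------------------------------------
# selection mini-language:  clauses joined by "and"; each clause is
#   chain <id[,id...]> | resid <a[:b][,c...]> | domain <name[,name...]>
#   | species <name[,name...]>   (species is an alias for domain)
# ---------------------------------------------------------------------------

_FIELDS = {"chain", "resid", "domain", "species"}


def selection_mask(model: ParticleModel, expr: str) -> np.ndarray:
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    if expr.strip().lower() == "all":
        return np.ones(model.n_particles, dtype=bool)
    mask = np.ones(model.n_particles, dtype=bool)
    for clause in expr.split(" and "):
        parts = clause.strip().split(None, 1)
        if len(parts) != 2:
            raise SelectionError(f"cannot parse clause {clause!r}")
        field, values = parts[0].lower(), parts[1]
        if field not in _FIELDS:
            raise SelectionError(f"unknown selection field {field!r}")
        sub = np.zeros(model.n_particles, dtype=bool)
        for tok in values.split(","):
            tok = tok.strip()
            if not tok:
                raise SelectionError(f"empty value in clause {clause!r}")
            if field == "resid":
                if ":" in tok:
                    lo_s, hi_s = tok.split(":", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {tok!r}") from exc
                    sub |= (model.resids >= lo) & (model.resids <= hi)
                else:
                    try:
                        sub |= model.resids == int(tok)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid {tok!r}") from exc
            elif field == "chain":
                sub |= model.chains == tok
            else:  # domain / species
                sub |= model.domains == tok
        mask &= sub
    return mask
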