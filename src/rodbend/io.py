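"""PDB/GRO reading and writing for one-particle-per-residue models.

MDAnalysis does the format work; this module converts between its
Angstrom-based Universe and the package's nm-based containers, preserves
chain / residue / domain labels, and implements the chain-inference rule
for GRO files (which have no chain field): a new chain starts wherever the
residue number fails to increase.

Conventions
-----------
* PDB coordinates are Angstrom on disk, converted to nm (x 0.1) on read.
* GRO coordinates are natively nm.
* Domain labels (or lipid species) are stored in the residue-name field.
* Multi-model PDB is the trajectory interchange format.
"""
from __future__ import annotations

import dataclasses
import os
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .core import Ensemble, ParticleModel, RodbendError, ensemble_from_models

NM_PER_ANGSTROM = 0.1

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


class ParseError(RodbendError):
    """A structure file that cannot be interpreted."""


@dataclasses.dataclass
class FrameIndex:
    """Maps frame ids to times and source files (one structure per entry)."""

    frame_ids: np.ndarray
    times: np.ndarray
    paths: list

    def __post_init__(self):
        self.frame_ids = np.asarray(self.frame_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(np.unique(self.frame_ids)) != len(self.frame_ids):
            raise ParseError("frame ids must be unique")
        if np.any(np.diff(self.times) < 0):
            raise ParseError("frame times must be non-decreasing")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# frame\ttime_ns\tpath\n")
            for fid, t, p in zip(self.frame_ids, self.times, self.paths):
                fh.write(f"{fid}\t{t:.6f}\t{p}\n")

    @classmethod
    def read(cls, path) -> "FrameIndex":
        fids, times, paths = [], [], []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}:{ln}: expected 3 tab-separated fields")
                fids.append(int(parts[0]))
                times.append(float(parts[1]))
                paths.append(parts[2])
        return cls(np.array(fids), np.array(times), paths)


def _format_of(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = Path(path).suffix.lstrip(".").lower()
    if f not in {"pdb", "gro"}:
        raise ParseError(f"unsupported structure format {f!r} (PDB and GRO only)")
    return f


def _universe_from_model(model: ParticleModel, name: str) -> mda.Universe:
    n = model.n_particles
    chains = model.chains
    uniq, chain_idx = np.unique(chains, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n, atom_resindex=np.arange(n),
        n_segments=len(uniq), residue_segindex=chain_idx, trajectory=True,
    )
    u.add_TopologyAttr("name", [name] * n)
    u.add_TopologyAttr("type", ["C"] * n)
    u.add_TopologyAttr("element", ["C"] * n)
    u.add_TopologyAttr("resid", model.resids)
    u.add_TopologyAttr("resname", [str(d)[:4] if d else "UNK" for d in model.domains])
    u.add_TopologyAttr("chainIDs", [str(c)[:1] if c else "A" for c in chains])
    u.add_TopologyAttr("segid", [str(c) if c else "SYS" for c in uniq])
    u.add_TopologyAttr("occupancy", np.ones(n))
    u.add_TopologyAttr("tempfactor", np.zeros(n))
    u.atoms.positions = model.coords / NM_PER_ANGSTROM
    return u


def _box_for(coords_nm: np.ndarray) -> np.ndarray:
    span = coords_nm.max(axis=0) - coords_nm.min(axis=0)
    edge = float(max(span.max() + 2.0, 1.0)) / NM_PER_ANGSTROM
    return np.array([edge, edge, edge, 90.0, 90.0, 90.0])


def write_structure(model: ParticleModel, path, fmt: str | None = None,
                    name: str = "CA") -> None:
    """Write one conformer to PDB or GRO (format from extension by default)."""
    f = _format_of(path, fmt)
    u = _universe_from_model(model, name)
    u.dimensions = _box_for(model.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_ensemble(ensemble: Ensemble, path, name: str = "CA") -> None:
    """Write an ensemble as a multi-model PDB."""
    if _format_of(path, None) != "pdb":
        raise ParseError("ensembles are written as multi-model PDB")
    u = _universe_from_model(ensemble.topology, name)
    u.load_new(ensemble.coords / NM_PER_ANGSTROM, order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True,
                        n_atoms=ensemble.topology.n_particles) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _chains_from_resids(resids: np.ndarray) -> np.ndarray:
    """GRO chain inference: a residue-number reset starts a new chain."""
    chains = np.empty(len(resids), dtype="U8")
    ci = 0
    prev = None
    for i, r in enumerate(resids):
        if prev is not None and r <= prev and r != prev:
            ci += 1
        chains[i] = _CHAIN_ALPHABET[ci % len(_CHAIN_ALPHABET)]
        prev = r
    return chains


def _model_from_universe(u: mda.Universe, fmt: str, model_id: str) -> ParticleModel:
    ag = u.atoms
    n = len(ag)
    resids = ag.resids.astype(np.int64)
    domains = np.asarray(ag.resnames, dtype="U8") if hasattr(ag, "resnames") \
        else np.full(n, "UNK", dtype="U8")
    if fmt == "pdb" and hasattr(ag, "chainIDs"):
        chains = np.asarray(ag.chainIDs, dtype="U8")
        if np.all(chains == "") or np.all(chains == " "):
            chains = _chains_from_resids(resids)
    else:
        chains = _chains_from_resids(resids)
    coords = ag.positions.astype(np.float64) * NM_PER_ANGSTROM
    try:
        return ParticleModel(chains, resids, domains, coords, model_id=model_id)
    except RodbendError as exc:
        raise ParseError(f"{model_id}: {exc}") from exc


def read_structure(path, fmt: str | None = None) -> ParticleModel:
    """Read a single conformer from a PDB or GRO file (coordinates in nm)."""
    f = _format_of(path, fmt)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise ParseError(f"{path}: {exc}") from exc
    return _model_from_universe(u, f, model_id=Path(path).stem)


def read_ensemble(source, times: Sequence[float] | None = None) -> Ensemble:
    """Read a trajectory from a multi-model PDB or a :class:`FrameIndex`.

    All frames must share one topology; a mismatch is reported with the
    offending frame number.
    """
    if isinstance(source, FrameIndex):
        models = []
        for k, p in enumerate(source.paths):
            m = read_structure(p)
            models.append(m)
        return ensemble_from_models(models, times=source.times)
    path = source
    f = _format_of(path, None)
    if f == "gro":
        return ensemble_from_models([read_structure(path)], times=times)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    top = _model_from_universe(u, f, model_id=Path(path).stem)
    frames = []
    for ts in u.trajectory:
        frames.append(u.atoms.positions.astype(np.float64) * NM_PER_ANGSTROM)
    coords = np.stack(frames)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return Ensemble(top, coords, np.asarray(list(times), dtype=float))
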