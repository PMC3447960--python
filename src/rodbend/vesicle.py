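"""Spherical two-leaflet mixed-lipid vesicles with protein anchor sites.

The builder is geometric: it emulates the shell-packing stage of vesicle
construction rather than self-assembly MD. Headgroups of each leaflet sit
on a sphere; the outer radius is solved from the lipid count and the area
per lipid, with the inner leaflet one bilayer thickness below. The
default composition is the 7:2:1 DPPE:DPPG:CL (by count) mixture of an
E. coli inner-membrane mimetic, 35,000 lipids in total, which closes to a
~70 nm outer diameter with the default 0.78 nm^2 area per lipid.

Lipid lateral dynamics is a sequential Metropolis Monte Carlo on each
leaflet sphere: a lipid in the interaction shell of a protein site gains
a species-specific well depth (in kT), moves are tangent-plane proposals
re-projected to the sphere, and a hard core enforces the minimum
headgroup separation. In the dilute limit this samples the Boltzmann
shell occupancy exp(eps) exactly, which is what the shell-enrichment
analysis recovers.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Dict, Tuple

import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import Ensemble, ParticleModel, SpecError

SPECIES = ("DPPE", "DPPG", "CL")

#: default species well depths in kT units
DEFAULT_EPSILONS = {"CL": math.log(2.0), "DPPG": math.log(1.5), "DPPE": 0.0}

#: default protein footprint radius (nm): the transmembrane cross-section
#: of a four-helix receptor dimer
DEFAULT_FOOTPRINT = 0.6

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclasses.dataclass
class VesicleSpec:
    n_lipids_total: int = 35000
    composition: Dict[str, float] = None
    area_per_lipid: float = 0.78      # nm^2, at the outer headgroup sphere
    bilayer_thickness: float = 4.0    # nm
    min_separation: float = 0.45      # nm, same-leaflet headgroups
    jitter: float = 0.03              # nm, tangential placement jitter
    seed: int = 0

    def __post_init__(self):
        if self.composition is None:
            self.composition = {"DPPE": 0.70, "DPPG": 0.20, "CL": 0.10}
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"composition sums to {total}, not 1")
        if any(v < 0 for v in self.composition.values()):
            raise SpecError("composition fractions must be non-negative")
        if self.n_lipids_total <= 0:
            raise SpecError("n_lipids_total must be positive")
        if self.area_per_lipid <= 0:
            raise SpecError("area_per_lipid must be positive")
        if self.min_separation < 0 or self.bilayer_thickness <= 0:
            raise SpecError("invalid geometry parameters")


def allocate_counts(spec: VesicleSpec) -> Dict[str, int]:
    """Integer per-species counts by largest-remainder apportionment."""
    names = list(spec.composition)
    exact = np.array([spec.composition[s] * spec.n_lipids_total for s in names])
    base = np.floor(exact).astype(int)
    short = spec.n_lipids_total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for k in range(short):
        base[order[k]] += 1
    return {s: int(c) for s, c in zip(names, base)}


def solve_radius(spec: VesicleSpec) -> Tuple[float, float]:
    """Outer and inner leaflet radii (nm) from the total-area equation.

    Solves ``4 pi (R^2 + (R - t)^2) = n * APL`` for the unique positive
    root; the inner radius is ``R - t``.
    """
    t = spec.bilayer_thickness
    rhs = spec.n_lipids_total * spec.area_per_lipid / (4.0 * math.pi)
    disc = 2.0 * rhs - t * t
    if disc <= 0:
        raise SpecError("lipid area too small for the requested thickness")
    r_out = 0.5 * (t + math.sqrt(disc))
    r_in = r_out - t
    if r_in <= 0:
        raise SpecError("parameters give a non-positive inner radius")
    return r_out, r_in


def split_leaflets(spec: VesicleSpec) -> Dict[str, Tuple[int, int]]:
    """(outer, inner) counts per species, proportional to leaflet areas."""
    r_out, r_in = solve_radius(spec)
    f_out = r_out ** 2 / (r_out ** 2 + r_in ** 2)
    out = {}
    for s, n_s in allocate_counts(spec).items():
        exact = f_out * n_s
        n_o = int(math.floor(exact))
        if exact - n_o >= 0.5:
            n_o += 1
        out[s] = (n_o, n_s - n_o)
    return out


@dataclasses.dataclass
class VesicleConfiguration:
    """Headgroup positions plus protein anchor sites on a sphere."""

    species: np.ndarray           # (n,) str
    leaflet: np.ndarray           # (n,) "outer" | "inner"
    positions: np.ndarray         # (n, 3) nm, centred on the origin
    outer_radius: float
    inner_radius: float
    min_separation: float
    protein_sites: np.ndarray     # (m, 3) anchor positions on the outer sphere
    footprint_radius: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype="U8")
        self.leaflet = np.asarray(self.leaflet, dtype="U8")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.protein_sites = np.asarray(self.protein_sites,
                                        dtype=np.float64).reshape(-1, 3)

    @property
    def n_lipids(self) -> int:
        return len(self.species)

    def counts(self) -> Dict[str, int]:
        return {s: int(np.sum(self.species == s)) for s in np.unique(self.species)}

    def to_particle_model(self) -> ParticleModel:
        chains = np.where(self.leaflet == "outer", "O", "I")
        resids = np.empty(self.n_lipids, dtype=np.int64)
        for leaf in ("outer", "inner"):
            m = self.leaflet == leaf
            resids[m] = np.arange(1, int(m.sum()) + 1)
        return ParticleModel(chains, resids, self.species.copy(),
                             self.positions.copy(), model_id="vesicle")


def fibonacci_sphere(n: int) -> np.ndarray:
    """The offset spherical Fibonacci lattice (unit vectors)."""
    if n < 1:
        raise SpecError("need at least one point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _relax_on_sphere(points: np.ndarray, iters: int = 300) -> np.ndarray:
    """Deterministic tangential-repulsion polish of points on a unit sphere."""
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    n = len(p)
    if n < 2:
        return p
    step = 0.5 * math.sqrt(4.0 * math.pi / n)
    for it in range(iters):
        diff = p[:, None, :] - p[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d2[:, :, None] ** 1.5).sum(axis=1)
        # keep only the tangential component
        force -= np.einsum("ij,ij->i", force, p)[:, None] * p
        norms = np.linalg.norm(force, axis=1)
        fmax = norms.max()
        if fmax == 0:
            break
        p = p + step * force / fmax
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        step *= 0.98
    return p


def place_lipids(spec: VesicleSpec) -> VesicleConfiguration:
    """Place headgroups on both leaflet spheres.

    Each leaflet uses a randomly rotated Fibonacci lattice with small
    tangential jitter; species labels are a seeded random permutation.
    Jittered points that violate the minimum separation revert to their
    lattice positions; an infeasible density raises an error.
    """
    rng = np.random.default_rng(spec.seed)
    r_out, r_in = solve_radius(spec)
    per_leaf = split_leaflets(spec)
    all_species, all_leaflet, all_pos = [], [], []
    for leaf, radius in (("outer", r_out), ("inner", r_in)):
        idx = 0 if leaf == "outer" else 1
        n_leaf = sum(v[idx] for v in per_leaf.values())
        if n_leaf == 0:
            continue
        # empirical minimum nearest-neighbour distance of the lattice
        lattice_min = 3.09 / math.sqrt(n_leaf) * radius if n_leaf > 1 else np.inf
        if lattice_min < spec.min_separation:
            raise SpecError(
                f"{leaf} leaflet: {n_leaf} lipids cannot honour a "
                f"{spec.min_separation} nm separation on a {radius:.2f} nm sphere")
        rot = Rotation.random(random_state=rng)
        pts = rot.apply(fibonacci_sphere(n_leaf)) * radius
        if spec.jitter > 0 and n_leaf > 1:
            jit = rng.normal(0.0, spec.jitter, size=pts.shape)
            cand = pts + jit
            cand *= radius / np.linalg.norm(cand, axis=1, keepdims=True)
            for _ in range(20):
                tree = cKDTree(cand)
                pairs = tree.query_pairs(spec.min_separation, output_type="ndarray")
                if len(pairs) == 0:
                    break
                bad = np.unique(pairs.ravel())
                cand[bad] = pts[bad]
            pts = cand
        labels = np.concatenate([
            np.full(v[idx], s, dtype="U8") for s, v in per_leaf.items()])
        labels = labels[rng.permutation(n_leaf)]
        all_species.append(labels)
        all_leaflet.append(np.full(n_leaf, leaf, dtype="U8"))
        all_pos.append(pts)
    return VesicleConfiguration(
        species=np.concatenate(all_species),
        leaflet=np.concatenate(all_leaflet),
        positions=np.concatenate(all_pos),
        outer_radius=r_out, inner_radius=r_in,
        min_separation=spec.min_separation,
        protein_sites=np.empty((0, 3)), seed=spec.seed,
    )


def place_proteins_evenly(config: VesicleConfiguration, n_sites: int,
                          footprint_radius: float = DEFAULT_FOOTPRINT
                          ) -> VesicleConfiguration:
    """Anchor proteins at near-equal-area sites on the outer sphere.

    Sites start on a Fibonacci lattice and are polished by a short
    deterministic repulsion relaxation (two sites end up antipodal, and
    larger counts approach the equal-area separation). Lipids inside any
    footprint are removed and re-placed elsewhere, preserving species and
    leaflet counts.
    """
    if n_sites < 1:
        raise SpecError("n_sites must be >= 1")
    if footprint_radius < 0:
        raise SpecError("footprint_radius must be >= 0")
    r_out, r_in = config.outer_radius, config.inner_radius
    theta_fp_out = footprint_radius / r_out
    cap_area_frac = n_sites * (1.0 - math.cos(theta_fp_out)) / 2.0
    if cap_area_frac > 0.5:
        raise SpecError("protein footprints would cover more than half the sphere")
    units = _relax_on_sphere(fibonacci_sphere(n_sites))
    sites = units * r_out
    rng = np.random.default_rng(config.seed + 7919)
    new_pos = config.positions.copy()
    for leaf, radius in (("outer", r_out), ("inner", r_in)):
        in_leaf = config.leaflet == leaf
        if not np.any(in_leaf) or footprint_radius == 0:
            continue
        theta_fp = footprint_radius / radius
        cos_fp = math.cos(theta_fp)
        pos = new_pos[in_leaf]
        cosang = (pos / radius) @ units.T
        displaced = np.flatnonzero(cosang.max(axis=1) > cos_fp)
        if displaced.size == 0:
            continue
        keep_mask = np.ones(len(pos), dtype=bool)
        keep_mask[displaced] = False
        kept = pos[keep_mask]
        placed = []
        occupied = kept
        for _ in displaced:
            p = _sample_free_point(rng, radius, units, cos_fp, occupied,
                                   config.min_separation)
            placed.append(p)
            occupied = np.vstack([occupied, p])
        pos[displaced] = np.array(placed)
        new_pos[in_leaf] = pos
    return dataclasses.replace(config, positions=new_pos, protein_sites=sites,
                               footprint_radius=float(footprint_radius))


def _sample_free_point(rng, radius, site_units, cos_fp, occupied, min_sep,
                       max_tries: int = 20000) -> np.ndarray:
    tree = cKDTree(occupied) if len(occupied) else None
    for _ in range(max_tries):
        v = rng.normal(size=3)
        v *= radius / np.linalg.norm(v)
        if len(site_units) and np.max((v / radius) @ site_units.T) > cos_fp:
            continue
        if tree is not None and tree.query(v, k=1)[0] < min_sep:
            continue
        return v
    raise SpecError("could not re-place a displaced lipid (density too high)")


@dataclasses.dataclass
class AffinityModel:
    """Species-specific square-well protein affinity, in kT units."""

    epsilons: Dict[str, float] = None
    interaction_range: float = 1.0    # nm
    step_length: float = 0.3          # nm, tangent-plane proposal sd
    n_sweeps: int = 20000
    record_stride: int = 100          # sweeps between recorded frames
    seed: int = 0

    def __post_init__(self):
        if self.epsilons is None:
            self.epsilons = dict(DEFAULT_EPSILONS)
        if self.interaction_range <= 0:
            raise SpecError("interaction_range must be positive")
        if not all(np.isfinite(list(self.epsilons.values()))):
            raise SpecError("well depths must be finite")
        if self.step_length <= 0:
            raise SpecError("step_length must be positive")
        if self.n_sweeps < 1 or self.record_stride < 1:
            raise SpecError("n_sweeps and record_stride must be >= 1")


@njit(cache=True)
def _cell_of(x, y, z, box, cell, side):
    ix = int((x + box) / cell)
    iy = int((y + box) / cell)
    iz = int((z + box) / cell)
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= side:
        ix = side - 1
    if iy >= side:
        iy = side - 1
    if iz >= side:
        iz = side - 1
    return (ix * side + iy) * side + iz


@njit(cache=True)
def _mc_kernel(pos, radii, eps, site_pos, site_units, cos_fp, range2,
               step, minsep2, n_sweeps, stride, seed, frames):
    np.random.seed(seed)
    n = pos.shape[0]
    m = site_pos.shape[0]
    box = radii.max() + 1.0
    cell = math.sqrt(minsep2) if minsep2 > 0 else 1.0
    side = int(math.ceil(2.0 * box / cell))
    head = np.full(side * side * side, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    prv = np.full(n, -1, dtype=np.int64)
    cellof = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = _cell_of(pos[i, 0], pos[i, 1], pos[i, 2], box, cell, side)
        nxt[i] = head[c]
        prv[i] = -1
        if head[c] != -1:
            prv[head[c]] = i
        head[c] = i
        cellof[i] = c
    rec = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
            r = radii[i]
            # tangent basis at p
            ux, uy, uz = px / r, py / r, pz / r
            if abs(uz) < 0.9:
                ax, ay, az = 0.0, 0.0, 1.0
            else:
                ax, ay, az = 1.0, 0.0, 0.0
            t1x = uy * az - uz * ay
            t1y = uz * ax - ux * az
            t1z = ux * ay - uy * ax
            tn = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
            t1x, t1y, t1z = t1x / tn, t1y / tn, t1z / tn
            t2x = uy * t1z - uz * t1y
            t2y = uz * t1x - ux * t1z
            t2z = ux * t1y - uy * t1x
            g1 = np.random.standard_normal() * step
            g2 = np.random.standard_normal() * step
            qx = px + g1 * t1x + g2 * t2x
            qy = py + g1 * t1y + g2 * t2y
            qz = pz + g1 * t1z + g2 * t2z
            qn = math.sqrt(qx * qx + qy * qy + qz * qz)
            qx, qy, qz = qx * r / qn, qy * r / qn, qz * r / qn
            # protein footprint is a hard wall
            blocked = False
            if m > 0 and cos_fp[i] < 1.0:
                for s in range(m):
                    ca = (qx * site_units[s, 0] + qy * site_units[s, 1]
                          + qz * site_units[s, 2]) / r
                    if ca > cos_fp[i]:
                        blocked = True
                        break
            if blocked:
                continue
            # hard core against every other headgroup
            c = _cell_of(qx, qy, qz, box, cell, side)
            cz = c % side
            cy = (c // side) % side
            cx = c // (side * side)
            clash = False
            for dx in range(-1, 2):
                x2 = cx + dx
                if x2 < 0 or x2 >= side:
                    continue
                for dy in range(-1, 2):
                    y2 = cy + dy
                    if y2 < 0 or y2 >= side:
                        continue
                    for dz in range(-1, 2):
                        z2 = cz + dz
                        if z2 < 0 or z2 >= side:
                            continue
                        j = head[(x2 * side + y2) * side + z2]
                        while j != -1:
                            if j != i:
                                ddx = qx - pos[j, 0]
                                ddy = qy - pos[j, 1]
                                ddz = qz - pos[j, 2]
                                if ddx * ddx + ddy * ddy + ddz * ddz < minsep2:
                                    clash = True
                                    break
                            j = nxt[j]
                        if clash:
                            break
                    if clash:
                        break
                if clash:
                    break
            if clash:
                continue
            # square-well energy: -eps when within range of any site
            e_old = 0.0
            e_new = 0.0
            if m > 0 and eps[i] != 0.0:
                in_old = False
                in_new = False
                for s in range(m):
                    sx, sy, sz = site_pos[s, 0], site_pos[s, 1], site_pos[s, 2]
                    if not in_old:
                        d2 = ((px - sx) ** 2 + (py - sy) ** 2 + (pz - sz) ** 2)
                        if d2 <= range2:
                            in_old = True
                    if not in_new:
                        d2 = ((qx - sx) ** 2 + (qy - sy) ** 2 + (qz - sz) ** 2)
                        if d2 <= range2:
                            in_new = True
                    if in_old and in_new:
                        break
                if in_old:
                    e_old = -eps[i]
                if in_new:
                    e_new = -eps[i]
            de = e_new - e_old
            if de > 0.0 and np.random.random() >= math.exp(-de):
                continue
            # accept
            if c != cellof[i]:
                if prv[i] != -1:
                    nxt[prv[i]] = nxt[i]
                else:
                    head[cellof[i]] = nxt[i]
                if nxt[i] != -1:
                    prv[nxt[i]] = prv[i]
                nxt[i] = head[c]
                prv[i] = -1
                if head[c] != -1:
                    prv[head[c]] = i
                head[c] = i
                cellof[i] = c
            pos[i, 0], pos[i, 1], pos[i, 2] = qx, qy, qz
        if (sweep + 1) % stride == 0:
            for i in range(n):
                frames[rec, i, 0] = pos[i, 0]
                frames[rec, i, 1] = pos[i, 1]
                frames[rec, i, 2] = pos[i, 2]
            rec += 1
    return rec


def run_lipid_dynamics(config: VesicleConfiguration,
                       model: AffinityModel) -> Ensemble:
    """Metropolis Monte Carlo of lipid lateral diffusion on the leaflets.

    Frames are recorded every ``model.record_stride`` sweeps; the frame
    "times" of the returned ensemble count sweeps. The run is exactly
    reproducible under ``model.seed``.
    """
    any_eps = any(v != 0 for v in model.epsilons.values())
    if any_eps and len(config.protein_sites) == 0:
        raise SpecError("non-zero affinities require at least one protein site")
    pos = config.positions.copy()
    radii = np.where(config.leaflet == "outer",
                     config.outer_radius, config.inner_radius).astype(float)
    eps = np.array([model.epsilons.get(s, 0.0) for s in config.species])
    site_pos = config.protein_sites.astype(float)
    site_units = (site_pos / config.outer_radius if len(site_pos)
                  else np.empty((0, 3)))
    if config.footprint_radius > 0:
        cos_fp = np.cos(config.footprint_radius / radii)
    else:
        cos_fp = np.full(len(radii), 1.0)   # cap of zero size: never blocks
    n_rec = model.n_sweeps // model.record_stride
    if n_rec < 1:
        raise SpecError("record_stride exceeds n_sweeps")
    frames = np.empty((n_rec, len(pos), 3))
    _mc_kernel(pos, radii, eps, site_pos, site_units, cos_fp,
               model.interaction_range ** 2, model.step_length,
               config.min_separation ** 2, model.n_sweeps,
               model.record_stride, model.seed & 0x7FFFFFFF, frames)
    times = (np.arange(n_rec, dtype=float) + 1.0) * model.record_stride
    return Ensemble(config.to_particle_model(), frames, times)
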