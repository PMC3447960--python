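"""Shell-based lipid enrichment around proteins and a lateral mixing statistic.

Shell membership is 3-D Euclidean distance from a headgroup to the nearest
protein anchor (the proteins, not the membrane surface, define the shell).
Three enrichment conventions are reported side by side, because they answer
slightly different questions:

``vs_bulk``
    composition ratio: (shell fraction of species s) / (global fraction of s).
``vs_dppe``
    the same ratio normalised to DPPE, the zwitterionic majority species;
    identically 1 for DPPE.
``concentration``
    per-area concentration ratio: (shell number density of s) / (bulk
    number density of s). This is the quantity that converges to the
    Boltzmann factor exp(eps_s) in the dilute limit, and the natural
    reading of "species X doubles in concentration at the protein".

The mixing statistic measures lateral demixing: the fraction of each
lipid's k nearest same-leaflet neighbours sharing its species, minus the
well-mixed expectation. A well-mixed vesicle scores ~0 for every species;
phase separation drives the index positive.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Dict, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, SpecError
from .vesicle import VesicleConfiguration


def _shell_area(radius: float, site_radius: float, n_sites: int,
                shell: float, footprint: float) -> float:
    """Accessible shell area on one leaflet sphere (disjoint caps assumed)."""
    # polar angle at which the 3-D distance to a site equals the shell width
    cos_shell = (radius ** 2 + site_radius ** 2 - shell ** 2) \
        / (2.0 * radius * site_radius)
    if cos_shell > 1.0:
        return 0.0
    cos_shell = max(cos_shell, -1.0)
    cos_fp = math.cos(footprint / radius) if footprint > 0 else 1.0
    if cos_fp <= cos_shell:
        return 0.0
    return n_sites * 2.0 * math.pi * radius ** 2 * (cos_fp - cos_shell)


def _accessible_area(radius: float, n_sites: int, footprint: float) -> float:
    cos_fp = math.cos(footprint / radius) if footprint > 0 else 1.0
    return 4.0 * math.pi * radius ** 2 \
        - n_sites * 2.0 * math.pi * radius ** 2 * (1.0 - cos_fp)


@dataclasses.dataclass
class EnrichmentSeries:
    species: list
    shell: float
    shell_counts: np.ndarray      # (S, T) integer counts
    totals: np.ndarray            # (S,) species totals
    vs_bulk: np.ndarray           # (S, T)
    vs_dppe: np.ndarray           # (S, T)
    concentration: np.ndarray     # (S, T)
    undefined: np.ndarray         # (T,) True where the shell was empty
    times: np.ndarray
    steady_window: Tuple[int, int]
    steady_vs_bulk: Dict[str, float]
    steady_vs_dppe: Dict[str, float]
    steady_concentration: Dict[str, float]

    def steady_state(self, convention: str = "vs_bulk") -> Dict[str, float]:
        return {
            "vs_bulk": self.steady_vs_bulk,
            "vs_dppe": self.steady_vs_dppe,
            "concentration": self.steady_concentration,
        }[convention.replace("-", "_")]


def shell_enrichment(ensemble: Ensemble, config: VesicleConfiguration,
                     shell: float = 1.0,
                     steady_fraction: float = 0.5) -> EnrichmentSeries:
    """Per-frame, per-species lipid enrichment within ``shell`` nm of a protein.

    Steady-state summaries pool the in-shell counts over the final
    ``steady_fraction`` of frames (pooled counts, not means of ratios, so
    frames with sparse shells do not dominate).
    """
    if shell <= 0:
        raise SpecError("shell distance must be positive")
    sites = config.protein_sites
    if len(sites) == 0:
        raise SpecError("enrichment needs at least one protein site")
    species_names = sorted(set(config.species.tolist()))
    sp_index = {s: k for k, s in enumerate(species_names)}
    sp = np.array([sp_index[s] for s in config.species])
    totals = np.bincount(sp, minlength=len(species_names)).astype(float)
    f = ensemble.n_frames
    counts = np.zeros((len(species_names), f))
    tree = cKDTree(sites)
    for t in range(f):
        dmin, _ = tree.query(ensemble.coords[t], k=1)
        in_shell = dmin <= shell
        counts[:, t] = np.bincount(sp[in_shell], minlength=len(species_names))
    shell_tot = counts.sum(axis=0)
    undefined = shell_tot == 0

    frac_global = totals / totals.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        vs_bulk = (counts / shell_tot[None, :]) / frac_global[:, None]

    a_shell = (_shell_area(config.outer_radius, config.outer_radius,
                           len(sites), shell, config.footprint_radius)
               + _shell_area(config.inner_radius, config.outer_radius,
                             len(sites), shell, config.footprint_radius))
    a_total = (_accessible_area(config.outer_radius, len(sites),
                                config.footprint_radius)
               + _accessible_area(config.inner_radius, len(sites),
                                  config.footprint_radius))
    a_bulk = a_total - a_shell
    if a_shell <= 0:
        raise SpecError("shell thinner than the protein footprint: no "
                        "accessible shell area")
    with np.errstate(divide="ignore", invalid="ignore"):
        concentration = (counts / a_shell) / ((totals[:, None] - counts) / a_bulk)

    if "DPPE" in sp_index:
        k_ref = sp_index["DPPE"]
        with np.errstate(divide="ignore", invalid="ignore"):
            num = counts / counts[k_ref][None, :]
            den = (totals / totals[k_ref])[:, None]
            vs_dppe = num / den
    else:
        vs_dppe = np.full_like(vs_bulk, np.nan)

    w0 = int(math.floor(f * (1.0 - steady_fraction)))
    w0 = min(max(w0, 0), f - 1)
    wc = counts[:, w0:]
    wtot = wc.sum()
    nw = f - w0
    steady_vb, steady_vd, steady_cc = {}, {}, {}
    pooled = wc.sum(axis=1)
    for s, k in sp_index.items():
        steady_vb[s] = float((pooled[k] / wtot) / frac_global[k]) \
            if wtot > 0 else float("nan")
        mean_shell = pooled[k] / nw
        mean_bulk = totals[k] - mean_shell
        steady_cc[s] = float((mean_shell / a_shell) / (mean_bulk / a_bulk)) \
            if mean_bulk > 0 else float("nan")
    if "DPPE" in sp_index:
        k_ref = sp_index["DPPE"]
        for s, k in sp_index.items():
            if pooled[k_ref] > 0:
                steady_vd[s] = float((pooled[k] / pooled[k_ref])
                                     / (totals[k] / totals[k_ref]))
            else:
                steady_vd[s] = float("nan")
    return EnrichmentSeries(
        species=species_names, shell=float(shell), shell_counts=counts,
        totals=totals, vs_bulk=vs_bulk, vs_dppe=vs_dppe,
        concentration=concentration, undefined=undefined,
        times=ensemble.times.copy(), steady_window=(w0, f - 1),
        steady_vs_bulk=steady_vb, steady_vs_dppe=steady_vd,
        steady_concentration=steady_cc,
    )


@dataclasses.dataclass
class MixingStatistic:
    species: list
    observed: np.ndarray          # (S, T) mean same-species NN fraction
    expected: np.ndarray          # (S,) well-mixed expectation
    times: np.ndarray

    @property
    def demixing_index(self) -> np.ndarray:
        """observed - expected, per species and frame; ~0 when well mixed."""
        return self.observed - self.expected[:, None]


def mixing_statistic(ensemble: Ensemble, config: VesicleConfiguration,
                     k_neighbours: int = 6) -> MixingStatistic:
    """Same-species fraction among each lipid's k nearest leaflet neighbours.

    Neighbours are found within a lipid's own leaflet (3-D distances on
    the leaflet sphere approximate surface distances at this scale). The
    well-mixed expectation for a lipid of species s in a leaflet of n
    lipids is (n_s - 1) / (n - 1).
    """
    species_names = sorted(set(config.species.tolist()))
    sp_index = {s: i for i, s in enumerate(species_names)}
    sp = np.array([sp_index[s] for s in config.species])
    f = ensemble.n_frames
    observed = np.zeros((len(species_names), f))
    leaflets = [np.flatnonzero(config.leaflet == leaf)
                for leaf in ("outer", "inner")]
    leaflets = [ix for ix in leaflets if ix.size]
    for ix in leaflets:
        if k_neighbours >= ix.size:
            raise SpecError("k_neighbours must be below the leaflet size")
    expected = np.zeros(len(species_names))
    weight = np.zeros(len(species_names))
    for ix in leaflets:
        n_leaf = ix.size
        for s, k in sp_index.items():
            n_s = int(np.sum(sp[ix] == k))
            if n_s and n_leaf > 1:
                expected[k] += n_s * (n_s - 1) / (n_leaf - 1)
                weight[k] += n_s
    expected = np.divide(expected, weight, out=np.zeros_like(expected),
                         where=weight > 0)
    for t in range(f):
        for ix in leaflets:
            pts = ensemble.coords[t, ix]
            tree = cKDTree(pts)
            _, nbr = tree.query(pts, k=k_neighbours + 1)
            same = (sp[ix][nbr[:, 1:]] == sp[ix][:, None]).mean(axis=1)
            for s, k in sp_index.items():
                mask = sp[ix] == k
                if np.any(mask):
                    observed[k, t] += same[mask].sum()
    for s, k in sp_index.items():
        if weight[k] > 0:
            observed[k] /= weight[k]
    return MixingStatistic(species=species_names, observed=observed,
                           expected=expected, times=ensemble.times.copy())
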