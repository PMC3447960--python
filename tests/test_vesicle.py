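import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from rodbend.core import SpecError
from rodbend.vesicle import (AffinityModel, VesicleSpec, allocate_counts,
                             fibonacci_sphere, place_lipids,
                             place_proteins_evenly, run_lipid_dynamics,
                             solve_radius, split_leaflets, _relax_on_sphere)


def brute_largest_remainder(fractions, total):
    exact = [f * total for f in fractions]
    base = [math.floor(e) for e in exact]
    rem = sorted(range(len(base)), key=lambda i: exact[i] - base[i],
                 reverse=True)
    for i in range(total - sum(base)):
        base[rem[i]] += 1
    return base


class TestAllocation:
    def test_default_spec_reproduces_reference_counts(self):
        counts = allocate_counts(VesicleSpec())
        assert counts == {"DPPE": 24500, "DPPG": 7000, "CL": 3500}

    def test_single_species(self):
        spec = VesicleSpec(n_lipids_total=10,
                           composition={"DPPE": 1.0, "DPPG": 0.0, "CL": 0.0})
        assert allocate_counts(spec) == {"DPPE": 10, "DPPG": 0, "CL": 0}

    def test_matches_brute_force_largest_remainder(self):
        spec = VesicleSpec(n_lipids_total=7,
                           composition={"DPPE": 0.5, "DPPG": 0.3, "CL": 0.2})
        counts = allocate_counts(spec)
        assert sum(counts.values()) == 7
        brute = brute_largest_remainder([0.5, 0.3, 0.2], 7)
        assert [counts["DPPE"], counts["DPPG"], counts["CL"]] == brute
        for s, f in (("DPPE", 0.5), ("DPPG", 0.3), ("CL", 0.2)):
            assert abs(counts[s] - f * 7) <= 1

    def test_bad_composition_rejected(self):
        with pytest.raises(SpecError, match="sums"):
            VesicleSpec(composition={"DPPE": 0.5, "DPPG": 0.2, "CL": 0.2})

    def test_leaflet_split_conserves_species_totals(self):
        spec = VesicleSpec(n_lipids_total=2000, seed=0)
        split = split_leaflets(spec)
        counts = allocate_counts(spec)
        for s, (o, i) in split.items():
            assert o + i == counts[s]
            assert o > i    # outer leaflet has more area


class TestRadius:
    def test_default_outer_diameter_rounds_to_70(self):
        r_out, _ = solve_radius(VesicleSpec())
        assert round(2 * r_out / 10) * 10 == 70

    def test_zero_lipids_is_an_error(self):
        with pytest.raises(SpecError):
            VesicleSpec(n_lipids_total=0)

    def test_area_equation_residual(self):
        spec = VesicleSpec(n_lipids_total=12345, area_per_lipid=0.64,
                           bilayer_thickness=3.5)
        r_out, r_in = solve_radius(spec)
        area = 4 * math.pi * (r_out ** 2 + r_in ** 2)
        target = spec.n_lipids_total * spec.area_per_lipid
        assert abs(area - target) / target < 1e-6

    def test_non_positive_inner_radius_rejected(self):
        # 200 lipids at the default area cannot wrap a 4 nm bilayer
        with pytest.raises(SpecError, match="inner radius"):
            solve_radius(VesicleSpec(n_lipids_total=200))
        with pytest.raises(SpecError, match="too small"):
            solve_radius(VesicleSpec(n_lipids_total=4,
                                     bilayer_thickness=40.0))


@pytest.fixture(scope="module")
def placed_2000():
    return place_lipids(VesicleSpec(n_lipids_total=2000, seed=1))


class TestPlacement:
    @pytest.fixture
    def config(self, placed_2000):
        return placed_2000

    def test_counts_conserved(self, config):
        spec = VesicleSpec(n_lipids_total=2000, seed=1)
        assert config.counts() == allocate_counts(spec)

    def test_headgroups_on_their_leaflet_sphere(self, config):
        r = np.linalg.norm(config.positions, axis=1)
        outer = config.leaflet == "outer"
        assert np.abs(r[outer] - config.outer_radius).max() < 0.1
        assert np.abs(r[~outer] - config.inner_radius).max() < 0.1

    def test_min_separation_within_leaflets(self, config):
        for leaf in ("outer", "inner"):
            pts = config.positions[config.leaflet == leaf]
            d, _ = cKDTree(pts).query(pts, k=2)
            assert d[:, 1].min() >= 0.45

    def test_deterministic_under_seed(self):
        a = place_lipids(VesicleSpec(n_lipids_total=500, seed=3))
        b = place_lipids(VesicleSpec(n_lipids_total=500, seed=3))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.species, b.species)

    def test_infeasible_density_rejected(self):
        with pytest.raises(SpecError, match="cannot honour"):
            place_lipids(VesicleSpec(n_lipids_total=2000, area_per_lipid=0.05,
                                     bilayer_thickness=1.0))


class TestProteinPlacement:
    def test_two_sites_antipodal(self):
        u = _relax_on_sphere(fibonacci_sphere(2))
        ang = math.degrees(math.acos(np.clip(np.dot(u[0], u[1]), -1, 1)))
        assert abs(ang - 180.0) < 1.0

    def test_thirty_sites_near_equal_area_separation(self):
        u = _relax_on_sphere(fibonacci_sphere(30))
        dots = u @ u.T
        np.fill_diagonal(dots, -1.0)
        min_sep = np.arccos(np.clip(dots.max(axis=1), -1, 1)).min()
        ideal = math.sqrt(4 * math.pi / 30)
        assert min_sep >= 0.8 * ideal

    @pytest.mark.parametrize("n_sites", [30, 10])
    def test_lipid_counts_preserved_and_footprints_cleared(self, n_sites):
        config = place_lipids(VesicleSpec(n_lipids_total=2000, seed=2))
        out = place_proteins_evenly(config, n_sites, footprint_radius=0.6)
        assert out.counts() == config.counts()
        assert len(out.protein_sites) == n_sites
        units = out.protein_sites / out.outer_radius
        for leaf, radius in (("outer", out.outer_radius),
                             ("inner", out.inner_radius)):
            pts = out.positions[out.leaflet == leaf]
            cosang = (pts / radius) @ units.T
            assert cosang.max() <= math.cos(0.6 / radius) + 1e-12

    def test_excessive_footprints_rejected(self):
        config = place_lipids(VesicleSpec(n_lipids_total=500, seed=4))
        with pytest.raises(SpecError, match="half the sphere"):
            place_proteins_evenly(config, 40, footprint_radius=4.0)


@pytest.fixture(scope="module")
def small_config():
    return place_proteins_evenly(
        place_lipids(VesicleSpec(n_lipids_total=600, seed=5)), 2)


class TestDynamics:

    def test_fixed_seed_reproducible(self, small_config):
        am = AffinityModel(n_sweeps=200, record_stride=50, seed=11)
        a = run_lipid_dynamics(small_config, am)
        b = run_lipid_dynamics(small_config, am)
        assert np.array_equal(a.coords, b.coords)

    def test_counts_and_leaflet_radii_conserved(self, small_config):
        am = AffinityModel(n_sweeps=500, record_stride=100, seed=1)
        ens = run_lipid_dynamics(small_config, am)
        top = ens.topology
        assert np.array_equal(np.sort(top.domains),
                              np.sort(small_config.species))
        radii = np.where(small_config.leaflet == "outer",
                         small_config.outer_radius,
                         small_config.inner_radius)
        for f in range(ens.n_frames):
            r = np.linalg.norm(ens.coords[f], axis=1)
            assert np.abs(r - radii).max() < 1e-9

    def test_hard_core_respected_throughout(self, small_config):
        am = AffinityModel(n_sweeps=500, record_stride=100, seed=2)
        ens = run_lipid_dynamics(small_config, am)
        for f in range(ens.n_frames):
            for leaf in ("outer", "inner"):
                pts = ens.coords[f][small_config.leaflet == leaf]
                d, _ = cKDTree(pts).query(pts, k=2)
                assert d[:, 1].min() >= small_config.min_separation - 1e-9

    def test_zero_step_length_rejected(self):
        with pytest.raises(SpecError, match="step_length"):
            AffinityModel(step_length=0.0)

    def test_affinity_without_sites_rejected(self):
        config = place_lipids(VesicleSpec(n_lipids_total=400, seed=6))
        with pytest.raises(SpecError, match="protein site"):
            run_lipid_dynamics(config, AffinityModel(n_sweeps=10))
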