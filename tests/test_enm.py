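import numpy as np
import pytest

import rodbend as rb
from rodbend.core import ParticleModel, SpecError
from rodbend.enm import (ANM_CUTOFF, GNM_CUTOFF, build_hessian,
                         build_kirchhoff, decompose, gnm_fluctuations,
                         slow_mode_hinges)


def brute_kirchhoff(coords, cutoff):
    n = len(coords)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                k[i, j] = -1.0
    for i in range(n):
        k[i, i] = -k[i].sum()
    return k


def brute_hessian(coords, cutoff):
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = coords[j] - coords[i]
            d = np.linalg.norm(r)
            if d > cutoff:
                continue
            block = -np.outer(r, r) / d ** 2
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    return h


def _cloud(rng, n, spread=1.0):
    return rng.uniform(-spread, spread, size=(n, 3))


class TestKirchhoff:
    def test_two_particle_closed_form(self):
        k = build_kirchhoff(np.array([[0.0, 0, 0], [0.5, 0, 0]]), 0.7)
        assert np.array_equal(k, [[1, -1], [-1, 1]])
        assert np.allclose(np.linalg.eigvalsh(k), [0, 2])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            coords = _cloud(rng, int(rng.integers(5, 20)))
            cutoff = float(rng.uniform(0.5, 2.0))
            assert np.array_equal(build_kirchhoff(coords, cutoff),
                                  brute_kirchhoff(coords, cutoff))

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(9)
        k = build_kirchhoff(_cloud(rng, 30), 1.0)
        assert np.abs(k.sum(axis=1)).max() == 0

    def test_coincident_pair_warns(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [0.5, 0, 0]])
        with pytest.warns(RuntimeWarning, match="coincident"):
            build_kirchhoff(coords, 0.7)


class TestHessian:
    def test_axis_pair_closed_form(self):
        h = build_hessian(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1.3)
        nz = np.abs(h) > 0
        # only x-x couplings for a spring along x
        assert set(zip(*np.nonzero(nz))) == {(0, 0), (0, 3), (3, 0), (3, 3)}
        vals = np.linalg.eigvalsh(h)
        assert np.allclose(sorted(vals), [0, 0, 0, 0, 0, 2], atol=1e-12)

    def test_rigid_body_motions_cost_nothing(self):
        rng = np.random.default_rng(5)
        coords = _cloud(rng, 10)
        h = build_hessian(coords, 2.5)
        centred = coords - coords.mean(axis=0)
        for vec in np.eye(3):
            trans = np.tile(vec, 10)
            assert np.abs(h @ trans).max() < 1e-8
            rotv = np.cross(centred, vec).ravel()
            assert np.abs(h @ rotv).max() < 1e-8

    def test_matches_per_pair_block_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            coords = _cloud(rng, 15)
            cutoff = float(rng.uniform(0.8, 2.0))
            assert np.allclose(build_hessian(coords, cutoff),
                               brute_hessian(coords, cutoff), atol=1e-12)

    def test_coincident_connected_pair_is_an_error(self):
        with pytest.raises(SpecError, match="coincident"):
            build_hessian(np.zeros((2, 3)), 1.3)


class TestDecompose:
    def test_connected_laplacian_has_one_zero_mode(self):
        rng = np.random.default_rng(2)
        rod = rb.helical_rod(40)
        modes = decompose(build_kirchhoff(rod, GNM_CUTOFF), kind="gnm")
        assert modes.n_zero == 1

    def test_spectral_reconstruction(self):
        rng = np.random.default_rng(8)
        k = build_kirchhoff(_cloud(rng, 25), 1.2)
        modes = decompose(k, kind="gnm")
        recon = (modes.eigenvectors * modes.eigenvalues) @ modes.eigenvectors.T
        assert np.abs(recon - k).max() < 1e-7

    def test_partial_agrees_with_full_on_rod(self):
        rod = rb.build_rod(rb.RodSpec(noise_sd=0.05, seed=1))
        k = build_kirchhoff(rod, GNM_CUTOFF)
        full = decompose(k, kind="gnm")
        part = decompose(k, kind="gnm", n_modes=10)
        assert np.abs(part.eigenvalues[:10] - full.eigenvalues[:10]).max() < 1e-8
        for m in range(10):
            overlap = abs(part.eigenvectors[:, m] @ full.eigenvectors[:, :10])
            assert overlap.max() > 1.0 - 1e-6

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(SpecError, match="symmetric"):
            decompose(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_fluctuations_invariant_to_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(12)
        coords = _cloud(rng, 30)
        msf = gnm_fluctuations(decompose(build_kirchhoff(coords, 1.2),
                                         kind="gnm"))
        moved = Rotation.from_rotvec([0.3, 0.1, -0.7]).apply(coords) + 5.0
        msf2 = gnm_fluctuations(decompose(build_kirchhoff(moved, 1.2),
                                          kind="gnm"))
        assert np.abs(msf - msf2).max() < 1e-8


class TestSlowModeHinges:
    def test_dumbbell_hinge_centred_in_linker(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 0.35, size=(20, 3))
        blob2 = rng.normal(0, 0.35, size=(20, 3)) + np.array([0, 0, 4.0])
        linker = np.column_stack([np.zeros(5), np.zeros(5),
                                  np.linspace(0.8, 3.2, 5)])
        coords = np.vstack([blob1, linker, blob2])
        m = ParticleModel(np.full(45, "A"), np.arange(1, 46),
                          np.full(45, "D"), coords)
        modes = decompose(build_kirchhoff(m, 1.0), kind="gnm")
        hinges = slow_mode_hinges(modes, m, 0.15)
        # linker residues are 21..25; some run must cover its centre
        assert any(r.start <= 23 <= r.end for r in hinges.runs)

    def test_zero_quantile_selects_nothing(self, bent_dimer):
        modes = decompose(build_kirchhoff(bent_dimer, GNM_CUTOFF), kind="gnm")
        assert slow_mode_hinges(modes, bent_dimer, 0.0).residues.size == 0

    def test_bent_dimer_hinge_overlaps_bisection(self, bent_dimer):
        modes = decompose(build_kirchhoff(bent_dimer, GNM_CUTOFF), kind="gnm")
        hinges = slow_mode_hinges(modes, bent_dimer, 0.1)
        bis = rb.bisection_msd_profile(bent_dimer).hinge
        assert np.any(np.abs(hinges.residues - bis) <= 5)


class TestRodPhysics:
    def test_straight_rod_anm_six_zero_modes_and_degenerate_bending(self):
        """A cylindrically symmetric straight rod: 6 rigid-body modes and a
        near-degenerate pair of transverse bending modes."""
        rod = rb.helical_rod(150)
        modes = decompose(build_hessian(rod, ANM_CUTOFF), kind="anm")
        assert modes.n_zero == 6
        l1 = modes.eigenvalues[6]
        l2 = modes.eigenvalues[7]
        assert l2 / l1 < 1.05
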