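import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rodbend as rb
from rodbend.core import ParticleModel, SpecError, ensemble_from_models
from rodbend.conformers import (gromos_cluster, pairwise_rmsd, representative,
                                rmsd_series, superpose)


def kabsch_oracle_rmsd(mobile, reference, n_axes=400, angle_step_deg=2.0):
    """Coarse rotation-grid search over SO(3) (axis lattice x angle sweep)."""
    from rodbend.vesicle import fibonacci_sphere
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    best = np.inf
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    for axis in fibonacci_sphere(n_axes):
        rots = Rotation.from_rotvec(np.outer(angles, axis))
        for r in rots:
            d = r.apply(mob) - ref
            best = min(best, float(np.sqrt((d ** 2).sum() / len(mob))))
    return best


def _models_from(frames):
    n = frames[0].shape[0]
    return ensemble_from_models([
        ParticleModel(np.full(n, "A"), np.arange(1, n + 1), np.full(n, "D"), f)
        for f in frames])


class TestSuperpose:
    def test_identity_for_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        r, t, rmsd = superpose(pts, pts)
        assert rmsd < 1e-7
        assert np.allclose(r, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        moved = Rotation.from_rotvec([0.4, -0.8, 0.3]).apply(pts) + [1, 2, 3]
        _, _, rmsd = superpose(moved, pts)
        assert rmsd < 1e-9

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, opt = superpose(a, b)
        grid = kabsch_oracle_rmsd(a, b)
        assert opt <= grid + 1e-9          # optimal cannot lose to the grid
        assert grid - opt < 0.12           # grid resolution bound

    def test_reflection_never_chosen(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        r, _, _ = superpose(mirrored, pts)
        assert np.isclose(np.linalg.det(r), 1.0, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SpecError, match="3 points"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(SpecError, match="rank"):
            superpose(line, line)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(10, 3))
        ens = _models_from([f, f.copy(), f.copy()])
        series = rmsd_series(ens)
        assert np.abs(series.rmsd).max() < 1e-12
        assert series.modal_rmsd < 0.011   # midpoint of the first 0.02 bin

    def test_mean_rmsd_matches_direct_simulation(self):
        """Post-fit RMSD of Gaussian-perturbed copies vs a direct
        simulation that uses its own SVD superposition."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1.0, size=(60, 3))
        sd = 0.1
        frames = [base] + [base + rng.normal(0, sd, size=base.shape)
                           for _ in range(120)]
        ens = _models_from(frames)
        measured = rmsd_series(ens).rmsd[1:].mean()

        def oracle_rmsd(a, b):
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            u, s, vt = np.linalg.svd(ac.T @ bc)
            d = np.sign(np.linalg.det(u @ vt))
            s[-1] *= d
            return np.sqrt(max((ac ** 2).sum() + (bc ** 2).sum()
                               - 2 * s.sum(), 0) / len(a))

        sim = np.mean([oracle_rmsd(base + rng.normal(0, sd, size=base.shape),
                                   base) for _ in range(300)])
        assert abs(measured - sim) / sim < 0.1

    def test_domain_local_superposition_ignores_hinge_bending(self):
        """Within-domain RMSD is blind to rigid motion about a distant
        hinge when superposition is domain-local."""
        spec = rb.RodSpec(n_residues_per_chain=100, hinge_residue=50,
                          noise_sd=0.0)
        base = rb.build_rod(spec)
        frames = [base.coords]
        rng = np.random.default_rng(6)
        for angle in (0.0, 60.0):
            bent = rb.bend_at_hinge(base, 50, angle, axis_seed=1)
            frames.append(bent.coords + rng.normal(0, 0.01,
                                                   size=bent.coords.shape))
        ens = ensemble_from_models([
            ParticleModel(base.chains, base.resids, base.domains, f)
            for f in frames])
        series = rmsd_series(ens, selection="resid 1:40")
        assert abs(series.rmsd[1] - series.rmsd[2]) < 0.005

    def test_missing_reference_frame_rejected(self):
        rng = np.random.default_rng(7)
        ens = _models_from([rng.normal(size=(5, 3))])
        with pytest.raises(SpecError, match="reference frame"):
            rmsd_series(ens, reference_frame=3)


class TestGromosClustering:
    def _three_groups(self, sizes=(4, 3, 2), noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        shapes = [rng.normal(size=(12, 3)) * 2 for _ in sizes]
        frames = []
        for shape, size in zip(shapes, sizes):
            frames.extend(shape + rng.normal(0, noise, size=shape.shape)
                          for _ in range(size))
        return _models_from(frames)

    def test_identical_frames_single_cluster(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(8, 3))
        ens = _models_from([f] * 4)
        cl = gromos_cluster(ens, cutoff=0.1)
        assert len(cl.clusters) == 1
        assert list(cl.clusters[0].members) == [0, 1, 2, 3]
        assert cl.clusters[0].centroid == 0

    def test_three_separable_groups_recovered(self):
        ens = self._three_groups()
        cl = gromos_cluster(ens, cutoff=0.3)
        assert [len(c.members) for c in cl.clusters] == [4, 3, 2]
        assert list(cl.clusters[0].members) == [0, 1, 2, 3]
        # brute-force neighbour counting agrees on the first centroid
        d = pairwise_rmsd(ens.coords)
        counts = (d <= 0.3).sum(axis=1)
        assert counts[cl.clusters[0].centroid] == counts.max()

    def test_cluster_sizes_partition_all_frames(self):
        ens = self._three_groups(sizes=(5, 4, 3), seed=1)
        cl = gromos_cluster(ens, cutoff=0.3)
        members = np.concatenate([c.members for c in cl.clusters])
        assert sorted(members) == list(range(ens.n_frames))
        sizes = [len(c.members) for c in cl.clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_window_restricts_to_time_range(self):
        ens = self._three_groups(sizes=(3, 3, 3), seed=2)
        cl = gromos_cluster(ens, cutoff=0.3, window=(3.0, 8.0))
        members = np.concatenate([c.members for c in cl.clusters])
        assert sorted(members) == list(range(3, 9))

    def test_invalid_cutoff_rejected(self):
        ens = self._three_groups()
        with pytest.raises(SpecError, match="cutoff"):
            gromos_cluster(ens, cutoff=0.0)


class TestRepresentative:
    def test_singleton_cluster(self):
        rng = np.random.default_rng(9)
        ens = _models_from([rng.normal(size=(6, 3))])
        cl = gromos_cluster(ens, cutoff=0.5)
        assert representative(cl.clusters[0], ens) == 0

    def test_middle_structure_is_the_medoid(self):
        """Three frames at RMSD positions 0, 1, 2: the middle one wins."""
        rng = np.random.default_rng(10)
        base = rng.normal(size=(20, 3))
        direction = rng.normal(size=(20, 3))
        direction /= np.sqrt((direction ** 2).sum() / 20)   # unit RMSD step
        frames = [base, base + 1.0 * direction, base + 2.0 * direction]
        ens = _models_from(frames)
        cl = gromos_cluster(ens, cutoff=10.0)
        assert representative(cl.clusters[0], ens) == 1

    def test_invariant_to_frame_relabelling(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(15, 3))
        frames = [base + rng.normal(0, s, size=base.shape)
                  for s in (0.05, 0.01, 0.08, 0.03)]
        ens_fwd = _models_from(frames)
        ens_rev = _models_from(frames[::-1])
        cl_f = gromos_cluster(ens_fwd, cutoff=5.0)
        cl_r = gromos_cluster(ens_rev, cutoff=5.0)
        rep_f = representative(cl_f.clusters[0], ens_fwd)
        rep_r = representative(cl_r.clusters[0], ens_rev)
        assert rep_r == len(frames) - 1 - rep_f
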