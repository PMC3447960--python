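import numpy as np
import pytest

import rodbend as rb


@pytest.fixture(scope="session")
def straight_dimer():
    """Noise-free 500-residue dimer rod."""
    return rb.build_rod(rb.RodSpec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def bent_dimer(straight_dimer):
    """The dimer rod kinked 30 degrees at residue 268."""
    return rb.bend_at_hinge(straight_dimer, 268, 30.0, axis_seed=3)


@pytest.fixture(scope="session")
def kink_ensemble():
    """50 frames, fixed 30-degree kink, fresh axes, 0.05 nm noise, seed 1."""
    ens, angles = rb.sample_bending_ensemble(
        rb.RodSpec(noise_sd=0.05, seed=1),
        rb.BendingDistribution(mode_deg=30.0, spread_deg=0.0, max_deg=60.0),
        n_frames=50, seed=1)
    return ens, angles


def random_particle_model(rng, n=12, spread=1.0):
    return rb.ParticleModel(
        np.full(n, "A"), np.arange(1, n + 1), np.full(n, "D"),
        rng.normal(0.0, spread, size=(n, 3)))
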