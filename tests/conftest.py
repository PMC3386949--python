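import numpy as np
import pytest

from cutoffmd import (
    Electrostatics,
    NonbondedScheme,
    ParticleSystem,
    build_lj_fluid,
    build_random_neutral_box,
)


@pytest.fixture(scope="session")
def neutral_box():
    """Fixed 40-particle random neutral charge box shared across tests."""
    return build_random_neutral_box(20, box_edge=30.0, seed=7)


@pytest.fixture(scope="session")
def small_lj_fluid():
    return build_lj_fluid(16, seed=2)


@pytest.fixture()
def charge_pair():
    """A +1/-1 pair 3 A apart in a large box."""
    return ParticleSystem(
        positions=[[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]],
        box_edge=60.0,
        charges=[1.0, -1.0],
        masses=1.0,
    )


def ewald_scheme(cutoff=8.0, alpha=0.45, kmax=8):
    return NonbondedScheme(
        Electrostatics.EWALD, cutoff, ewald_alpha=alpha, ewald_kmax=kmax
    )


def numerical_forces(system, energy_fn, h=1e-5):
    """Central-difference gradient of a scalar energy function of the
    system's positions; the independent oracle for every analytic force."""
    base = system.positions.copy()
    out = np.zeros_like(base)
    for i in range(system.n_particles):
        for d in range(3):
            for sgn in (+1, -1):
                p = base.copy()
                p[i, d] += sgn * h
                system.positions = p
                out[i, d] -= sgn * energy_fn(system) / (2 * h)
    system.positions = base
    return out
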