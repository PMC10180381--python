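import math

import numpy as np
import pytest

from d4refit import (
    Atom,
    ClusterGenSpec,
    MockEnergySpec,
    ReferenceGeometry,
    Structure,
    gen_dataset,
    ladder_specs,
    load_parameters,
)

REF = ReferenceGeometry()


def monomer_at(origin, r1=None, r2=None, theta=None, sid="m"):
    """Water monomer in the xy plane with explicit internal coordinates."""
    r1 = REF.r_oh if r1 is None else r1
    r2 = REF.r_oh if r2 is None else r2
    theta = REF.theta_hoh if theta is None else theta
    t = math.radians(theta)
    o = np.asarray(origin, dtype=float)
    return Structure(
        sid,
        [
            Atom("O", o),
            Atom("H", o + np.array([r1, 0.0, 0.0])),
            Atom("H", o + np.array([r2 * math.cos(t), r2 * math.sin(t), 0.0])),
        ],
    )


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def b3lyp(params):
    return params.functional("b3lyp")


def random_small_structure(rng, max_atoms=10, min_dist=1.2):
    """Random H/O cluster with all pair distances above min_dist."""
    n = int(rng.integers(2, max_atoms + 1))
    pos = [rng.uniform(0, 6.0, size=3)]
    while len(pos) < n:
        cand = rng.uniform(0, 6.0, size=3)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pos):
            pos.append(cand)
    elements = rng.choice(["H", "O"], size=n)
    return Structure(
        "rand", [Atom(e, p) for e, p in zip(elements, pos)]
    )


@pytest.fixture(scope="session")
def noiseless_ladder(params):
    """Small noiseless ladder with known factors (1.0, 2.0) for fast tests."""
    specs = ladder_specs([6, 9], 6, seed=11)
    mock = MockEnergySpec(s6_true=1.0, s8_true=2.0, noise_sigma=0.0, seed=11)
    return gen_dataset(specs, mock, params)
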