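from __future__ import annotations

import numpy as np
import pytest

from pihelix.fixtures import build_helix
from pihelix.structure_io import BackboneResidue, Chain


@pytest.fixture(scope="session")
def alpha12():
    return build_helix("alpha", 12)


@pytest.fixture(scope="session")
def pi12():
    return build_helix("pi", 12)


@pytest.fixture(scope="session")
def pi14():
    return build_helix("pi", 14)


@pytest.fixture(scope="session")
def threeten12():
    return build_helix("threeten", 12)


def make_fake_chain(n, phi=None, psi=None, chain_id="A"):
    """A chain with dummy coordinates but controllable dihedrals (for
    annotation-rule tests that operate on bond lists directly)."""
    chain = Chain(chain_id=chain_id)
    for i in range(n):
        r = BackboneResidue(
            chain_id=chain_id, res_seq=i + 1, aa="A",
            N=np.array([3.0 * i, 0.0, 0.0]),
            CA=np.array([3.0 * i + 1.0, 0.0, 0.0]),
            C=np.array([3.0 * i + 2.0, 0.0, 0.0]),
            O=np.array([3.0 * i + 2.0, 1.2, 0.0]),
        )
        r.phi = None if (phi is None or phi[i] is None) else float(phi[i])
        r.psi = None if (psi is None or psi[i] is None) else float(psi[i])
        chain.residues.append(r)
    return chain


def random_annotation_instance(rng, n=30):
    """Random bonds + dihedrals + labels for oracle-equivalence tests."""
    phi = []
    psi = []
    for i in range(n):
        if i == 0:
            phi.append(None)
        elif rng.random() < 0.1:
            phi.append(float(rng.uniform(0, 180)))  # outside the window
        else:
            phi.append(float(rng.uniform(-170, -10)))
        if i == n - 1:
            psi.append(None)
        elif rng.random() < 0.1:
            psi.append(float(rng.uniform(50, 180)))
        else:
            psi.append(float(rng.uniform(-110, 40)))
    bonds = []
    for donor in range(2, n):
        if rng.random() < 0.6:
            n_alt = 1 + int(rng.random() < 0.4)
            offsets = rng.choice([3, 4, 5], size=n_alt, replace=False)
            for off in offsets:
                acc = donor - int(off)
                if acc < 0:
                    continue
                e = float(np.round(rng.uniform(-4.0, -0.6), 3))
                bonds.append((donor, acc, e))
    labels8 = "".join(rng.choice(list("HGIEBSTC"), size=n))
    return phi, psi, bonds, labels8
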