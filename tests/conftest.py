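"""Shared fixtures: graph-built molecules for typing tests.

Atom typing depends only on the bond graph, so these builders place
atoms at arbitrary well-separated coordinates and fill hydrogens
automatically from default valences.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from solvcontact.chem import Bond, Molecule, make_atom

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

_FILL_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
                 "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}
_ORDER_SUM = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


def graph_molecule(name, elements, bonds, h_counts=None):
    """Molecule from connectivity: heavy atoms + (i, j, order) bonds.

    Hydrogens are appended automatically: valence minus bond-order sum
    (aromatic counts 1.5), overridable per atom via `h_counts`.
    Coordinates are synthetic and well separated; only graph-dependent
    code should consume these molecules.
    """
    h_counts = h_counts or {}
    n = len(elements)
    order_sum = [0.0] * n
    bond_objs = []
    for i, j, order in bonds:
        bond_objs.append(Bond(i, j, order))
        order_sum[i] += _ORDER_SUM[order]
        order_sum[j] += _ORDER_SUM[order]

    coords = [(2.0 * k, 0.7 * (k % 3), 0.3 * (k % 5)) for k in range(n)]
    symbols = list(elements)
    h_dirs = [(0.6, 0.6, 0.6), (-0.6, 0.6, -0.6), (0.6, -0.6, -0.6),
              (-0.6, -0.6, 0.6)]
    for k in range(n):
        n_h = h_counts.get(k, int(round(
            max(0.0, _FILL_VALENCE[elements[k]] - order_sum[k]))))
        for m in range(n_h):
            idx = len(symbols)
            base = np.array(coords[k])
            coords.append(tuple(base + np.array(h_dirs[m % 4]) * (1.0 + 0.1 * m)))
            symbols.append("H")
            bond_objs.append(Bond(k, idx, "single"))
    atoms = [make_atom(i, s, c) for i, (s, c) in enumerate(zip(symbols, coords))]
    return Molecule(name, atoms, bond_objs)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ethanol():
    return graph_molecule("ethanol", ["C", "C", "O"],
                          [(0, 1, "single"), (1, 2, "single")])


@pytest.fixture
def benzene():
    ring = [(k, (k + 1) % 6, "aromatic") for k in range(6)]
    return graph_molecule("benzene", ["C"] * 6, ring)


@pytest.fixture
def acetic_acid():
    return graph_molecule(
        "acetic acid", ["C", "C", "O", "O"],
        [(0, 1, "single"), (1, 2, "double"), (1, 3, "single")])


@pytest.fixture
def nitromethane():
    return graph_molecule(
        "nitromethane", ["C", "N", "O", "O"],
        [(0, 1, "single"), (1, 2, "double"), (1, 3, "double")])
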