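"""Shared fixtures: hand-built reference geometries and small datasets."""

from __future__ import annotations

import numpy as np
import pytest

from jcouple.geometry import BondGraph
from jcouple.io import Dataset, Molecule
from jcouple.synthetic import SyntheticConfig, generate_dataset


def make_molecule(name, elements, coords):
    return Molecule(name=name, elements=list(elements), coords=np.asarray(coords, float))


@pytest.fixture
def h2():
    return make_molecule("h2", ["H", "H"], [[0, 0, 0], [0, 0, 0.74]])


@pytest.fixture
def methane_ideal():
    """CH4 with exact tetrahedral geometry (H along cube diagonals)."""
    s = 1.09 / np.sqrt(3.0)
    coords = [[0, 0, 0], [s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]
    return make_molecule("ch4", ["C", "H", "H", "H", "H"], coords)


def staggered_ethane(cc=1.54, ch=1.09, offset_deg=60.0):
    """C2H6 with ideal tetrahedral angles; the two methyl groups are
    rotated ``offset_deg`` apart about the C-C axis (60 = staggered)."""
    theta = np.radians(180.0 - 109.4712206)  # polar angle of C-H from C-C axis
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, cc]]
    elements = ["C", "C"]
    for az_deg in (0.0, 120.0, 240.0):
        az = np.radians(az_deg)
        coords.append(
            [ch * np.sin(theta) * np.cos(az), ch * np.sin(theta) * np.sin(az), -ch * np.cos(theta)]
        )
        elements.append("H")
    for az_deg in (offset_deg, offset_deg + 120.0, offset_deg + 240.0):
        az = np.radians(az_deg)
        coords.append(
            [ch * np.sin(theta) * np.cos(az), ch * np.sin(theta) * np.sin(az), cc + ch * np.cos(theta)]
        )
        elements.append("H")
    return make_molecule("ethane", elements, coords)


def ethane_bonds(mol):
    edges = {(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6), (1, 7)}
    lengths = {
        (i, j): float(np.linalg.norm(mol.coords[i] - mol.coords[j])) for i, j in edges
    }
    return BondGraph(n_atoms=8, edges=edges, lengths=lengths)


@pytest.fixture
def ethane():
    return staggered_ethane()


def random_molecule(rng, n_atoms=6, elements=("C", "H", "N", "O", "F")):
    """Random non-degenerate point cloud labelled with valid elements."""
    while True:
        coords = rng.uniform(-3, 3, size=(n_atoms, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if np.all(d[np.triu_indices(n_atoms, 1)] > 0.3):
            break
    els = [str(e) for e in rng.choice(elements, size=n_atoms)]
    return make_molecule("rand", els, coords)


@pytest.fixture
def small_dataset():
    """20 labelled synthetic molecules, all coupling types."""
    ds, _ = generate_dataset(SyntheticConfig(n_molecules=20, seed=11))
    return ds


@pytest.fixture
def tiny_3jhh_dataset():
    """Small noise-free torsion-only dataset for optimisation smoke tests."""
    ds, _ = generate_dataset(
        SyntheticConfig(n_molecules=12, noise_sd=0.0, types=("3JHH",), seed=5)
    )
    return ds
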