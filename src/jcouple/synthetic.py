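"""Synthetic Karplus-labelled molecules in the public CSV dialect.

Generates desk-scale acyclic molecules (random heavy-atom trees of C/N/O
with hydrogens filling standard valences) and labels every H-containing
coupled pair whose bond path has length N ≤ 3 with an N-appropriate
geometric law evaluated on the true geometry:

* 3-bond: the Karplus equation J = A·cos²φ + B·cosφ + C on the path
  torsion φ (defaults A,B,C = 7, −1, 5 Hz — classic vicinal H–H
  constants used here as an arbitrary ground truth);
* 2-bond: affine in cos θ of the path's central bond angle
  (default −10 + 6·cosθ Hz);
* 1-bond: affine in the bond length (default 180 − 60·(d − 1.0) Hz);

plus a per-type additive offset (so CH/NH/HH types are separable) and
Gaussian noise.  Because the labels depend on angles *by construction*,
angle sensitivity of any downstream model is recoverable on this data,
which is what the test suite exploits.  No attempt is made at realistic
conformer ensembles; trees keep the bond-path length of a pair identical
to the N of its coupling type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import BondGraph, bond_angle, coupling_path, dihedral_angle
from .io import (
    COUPLING_TYPES,
    CouplingRecord,
    Dataset,
    Molecule,
    write_couplings_csv,
    write_structures_csv,
)

_HEAVY = ("C", "N", "O")
_HEAVY_P = (0.70, 0.15, 0.15)
_VALENCE = {"C": 4, "N": 3, "O": 2}
_TET_COS = -1.0 / 3.0  # cos(109.471°)


@dataclass
class KarplusCoeffs:
    """Ground-truth label laws per coupling-path length.

    ``three_j`` are the Karplus (A, B, C); ``two_j``/``one_j`` are the
    (intercept, slope) of the affine laws in cos θ and (d − 1 Å)
    respectively.  ``offsets`` shift each coupling type additively.
    """

    three_j: tuple[float, float, float] = (7.0, -1.0, 5.0)
    two_j: tuple[float, float] = (-10.0, 6.0)
    one_j: tuple[float, float] = (180.0, -60.0)
    offsets: dict[str, float] = field(
        default_factory=lambda: {
            "1JHC": 0.0,
            "1JHN": -40.0,
            "2JHC": 3.0,
            "2JHN": 2.0,
            "2JHH": 0.0,
            "3JHC": 2.0,
            "3JHN": 1.0,
            "3JHH": 0.0,
        }
    )


@dataclass
class SyntheticConfig:
    """Conditions of the synthetic study.

    Defaults: molecules of 2–6 heavy atoms, 3° of angular jitter around
    ideal tetrahedral placement, 0.5 Hz of label noise, 80/20 split by
    molecule.  ``types`` optionally restricts emitted records to a subset
    of coupling types (e.g. ``("3JHH",)`` for the torsion-recovery
    experiment).
    """

    n_molecules: int = 100
    heavy_min: int = 2
    heavy_max: int = 6
    angle_jitter_deg: float = 3.0
    coeffs: KarplusCoeffs = field(default_factory=KarplusCoeffs)
    noise_sd: float = 0.5
    seed: int = 0
    train_frac: float = 0.8
    types: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.heavy_min < 1 or self.heavy_max < self.heavy_min:
            raise ValueError("counts must be positive and heavy_max >= heavy_min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.types is not None:
            bad = set(self.types) - set(COUPLING_TYPES)
            if bad:
                raise ValueError(f"unknown coupling types {sorted(bad)}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _new_direction(
    existing: list[np.ndarray], rng: np.random.Generator, jitter_deg: float
) -> np.ndarray:
    """Pick a bond direction roughly tetrahedral to the existing ones.

    Scores random candidate directions by squared deviation of their
    cosines to cos(109.47°) against every existing bond direction, takes
    the best, then perturbs it by Gaussian jitter.
    """
    if not existing:
        d = _unit(rng.normal(size=3))
    else:
        cands = rng.normal(size=(200, 3))
        cands /= np.linalg.norm(cands, axis=1, keepdims=True)
        ex = np.stack(existing, axis=0)
        cosines = cands @ ex.T
        score = ((cosines - _TET_COS) ** 2).sum(axis=1)
        d = cands[int(np.argmin(score))]
    if jitter_deg > 0:
        d = _unit(d + rng.normal(scale=np.radians(jitter_deg), size=3))
    return d


def generate_molecule(
    config: SyntheticConfig, rng: np.random.Generator, name: str = "mol"
) -> tuple[Molecule, BondGraph]:
    """Grow one random molecule; returns it with its ground-truth bonds."""
    n_heavy = int(rng.integers(config.heavy_min, config.heavy_max + 1))
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bond_dirs: list[list[np.ndarray]] = []  # per-atom unit bond directions
    edges: list[tuple[int, int]] = []

    def add_atom(el: str, pos: np.ndarray, parent: Optional[int]) -> int:
        idx = len(elements)
        elements.append(el)
        coords.append(pos)
        bond_dirs.append([])
        if parent is not None:
            edges.append((min(parent, idx), max(parent, idx)))
            d = _unit(pos - coords[parent])
            bond_dirs[parent].append(d)
            bond_dirs[idx].append(-d)
        return idx

    add_atom(str(rng.choice(_HEAVY, p=_HEAVY_P)), np.zeros(3), None)
    for _ in range(n_heavy - 1):
        open_heavy = [
            i
            for i, e in enumerate(elements)
            if e in _VALENCE and len(bond_dirs[i]) < _VALENCE[e]
        ]
        if not open_heavy:
            break
        parent = int(rng.choice(open_heavy))
        el = str(rng.choice(_HEAVY, p=_HEAVY_P))
        for _attempt in range(20):
            d = _new_direction(bond_dirs[parent], rng, config.angle_jitter_deg)
            pos = coords[parent] + 1.5 * d
            if all(np.linalg.norm(pos - c) > 1.0 for c in coords):
                break
        add_atom(el, pos, parent)
    # hydrogens fill remaining valence
    for i in list(range(len(elements))):
        while len(bond_dirs[i]) < _VALENCE[elements[i]]:
            for _attempt in range(20):
                d = _new_direction(bond_dirs[i], rng, config.angle_jitter_deg)
                pos = coords[i] + 1.09 * d
                if all(np.linalg.norm(pos - c) > 0.9 for c in coords):
                    break
            add_atom("H", pos, i)
    mol = Molecule(name=name, elements=elements, coords=np.stack(coords))
    lengths = {
        (a, b): float(np.linalg.norm(mol.coords[a] - mol.coords[b])) for a, b in edges
    }
    bonds = BondGraph(n_atoms=mol.n_atoms, edges=set(edges), lengths=lengths)
    return mol, bonds


def noise_free_scc(
    mol: Molecule,
    bonds: BondGraph,
    path: Sequence[int],
    ctype: str,
    coeffs: KarplusCoeffs,
) -> Optional[float]:
    """Evaluate the ground-truth label law on one bond path; None if degenerate."""
    n = len(path) - 1
    offset = coeffs.offsets.get(ctype, 0.0)
    if n == 1:
        a, b = coeffs.one_j
        return a + b * (bonds.length(path[0], path[1]) - 1.0) + offset
    if n == 2:
        a, b = coeffs.two_j
        theta = bond_angle(mol, path[0], path[1], path[2])
        return a + b * np.cos(np.radians(theta)) + offset
    if n == 3:
        A, B, C = coeffs.three_j
        phi = dihedral_angle(mol, *path)
        if phi is None:
            return None
        c = np.cos(np.radians(phi))
        return A * c**2 + B * c + C + offset
    return None


def label_couplings(
    mol: Molecule,
    bonds: BondGraph,
    coeffs: KarplusCoeffs,
    noise_sd: float,
    rng: np.random.Generator,
    types: Optional[Sequence[str]] = None,
) -> list[CouplingRecord]:
    """Enumerate and label all supported coupled pairs of one molecule.

    Pairs must have a bond path of length ≤ 3 and contain at least one
    hydrogen; pairs whose (N, elements) fall outside the eight supported
    types (e.g. couplings to O or F) are skipped.
    """
    records: list[CouplingRecord] = []
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = mol.elements[i], mol.elements[j]
            if "H" not in (ei, ej):
                continue
            path = coupling_path(bonds, i, j, max_len=3)
            if path is None:
                continue
            nb = len(path) - 1
            # canonicalise: H is atom0
            if ei == "H":
                a0, a1 = i, j
            else:
                a0, a1 = j, i
                path = list(reversed(path))
            ctype = f"{nb}JH{mol.elements[a1]}"
            if ctype not in COUPLING_TYPES:
                continue
            if types is not None and ctype not in types:
                continue
            scc = noise_free_scc(mol, bonds, path, ctype, coeffs)
            if scc is None:
                continue
            if noise_sd > 0:
                scc += float(rng.normal(scale=noise_sd))
            records.append(
                CouplingRecord(
                    molecule=mol.name,
                    atom_index_0=a0,
                    atom_index_1=a1,
                    ctype=ctype,
                    scc=float(scc),
                )
            )
    return records


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[Dataset, dict[str, BondGraph]]:
    """Generate a fully labelled dataset and its ground-truth bond graphs."""
    rng = np.random.default_rng(config.seed)
    molecules: dict[str, Molecule] = {}
    bonds_map: dict[str, BondGraph] = {}
    records: list[CouplingRecord] = []
    width = max(6, len(str(config.n_molecules)))
    for k in range(config.n_molecules):
        name = f"mol_{k:0{width}d}"
        mol, bonds = generate_molecule(config, rng, name=name)
        molecules[name] = mol
        bonds_map[name] = bonds
        records.extend(
            label_couplings(
                mol, bonds, config.coeffs, config.noise_sd, rng, types=config.types
            )
        )
    for i, rec in enumerate(records):
        rec.row_id = i
    ds = Dataset(molecules=molecules, records=records).validate()
    return ds, bonds_map


def split_dataset(
    dataset: Dataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Deterministic molecule-level split (no molecule straddles the sets)."""
    names = sorted(dataset.molecules)
    rng = np.random.default_rng(seed)
    rng.shuffle(names)
    n_train = int(round(train_frac * len(names)))
    train_names = set(names[:n_train])
    train = Dataset(
        molecules={n: m for n, m in dataset.molecules.items() if n in train_names},
        records=[r for r in dataset.records if r.molecule in train_names],
    )
    test = Dataset(
        molecules={n: m for n, m in dataset.molecules.items() if n not in train_names},
        records=[r for r in dataset.records if r.molecule not in train_names],
    )
    return train, test


def make_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate, split and write structures.csv / train.csv / test.csv.

    ``test.csv`` omits the label column (competition layout); the held
    back labels are written alongside as ``test_labels.csv`` for offline
    evaluation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, _ = generate_dataset(config)
    train, test = split_dataset(dataset, train_frac=config.train_frac, seed=config.seed)
    paths = {
        "structures": outdir / "structures.csv",
        "train": outdir / "train.csv",
        "test": outdir / "test.csv",
        "test_labels": outdir / "test_labels.csv",
    }
    write_structures_csv(dataset.molecules, paths["structures"])
    write_couplings_csv(train.records, paths["train"])
    unlabelled = [replace(r, scc=None) for r in test.records]
    write_couplings_csv(unlabelled, paths["test"])
    write_couplings_csv(test.records, paths["test_labels"])
    return paths
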