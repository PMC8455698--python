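"""Geometric quantities: distances, bond perception, angles.

All angles are returned in degrees; features downstream carry their
cosines.  Dihedral angles are unsigned (range [0, 180]) because only
cos φ and cos² φ ever enter the Karplus-form expressions used here, so
the sign carries no information.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import Molecule

#: Single-value covalent radii (Å) for the five-element alphabet.
COVALENT_RADII: dict[str, float] = {"C": 0.76, "H": 0.31, "N": 0.71, "O": 0.66, "F": 0.57}

#: Default multiplier on the radius sum for the bond distance cutoff.
BOND_SCALE: float = 1.3

_DEGENERACY_EPS = 1e-10


@dataclass
class BondGraph:
    """Chemical bonds of one molecule as an undirected graph.

    ``edges`` holds unordered index pairs stored as sorted tuples;
    ``lengths`` maps each edge to its bond length in Å.
    """

    n_atoms: int
    edges: set[tuple[int, int]]
    lengths: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on atom {i}")
        self._adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in sorted(self.edges):
            self._adj[i].append(j)
            self._adj[j].append(i)

    def neighbors(self, i: int) -> list[int]:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    @property
    def n_bonds(self) -> int:
        return len(self.edges)

    def length(self, i: int, j: int) -> float:
        return self.lengths[(min(i, j), max(i, j))]


@dataclass
class AnglePack:
    """Cosines of the angle features attached to one coupled atom pair.

    ``cos_dihedral`` is populated for 3-bond couplings (torsion along the
    bond path), ``cos_bond_angle`` for 2-bond couplings (angle at the
    central atom), and ``cos_angle0``/``cos_angle1`` are the geometric
    angles formed with each coupled atom's nearest neighbour.  ``None``
    marks an undefined/degenerate value; featurisation imputes 0 with a
    cleared presence flag so records are never dropped.
    """

    cos_dihedral: Optional[float] = None
    cos_bond_angle: Optional[float] = None
    cos_angle0: Optional[float] = None
    cos_angle1: Optional[float] = None


def pairwise_distances(mol: Molecule) -> np.ndarray:
    """Symmetric Euclidean distance matrix in Å (zero diagonal)."""
    if mol.n_atoms == 1:
        return np.zeros((1, 1))
    return squareform(pdist(mol.coords))


def infer_bonds(
    mol: Molecule,
    radii: Optional[dict[str, float]] = None,
    scale: float = BOND_SCALE,
) -> BondGraph:
    """Perceive chemical bonds from interatomic distances.

    Atoms i, j are bonded iff d(i,j) ≤ scale·(r_i + r_j) with per-element
    covalent radii.  Hydrogen is restricted to at most one bond (its
    shortest candidate).  A disconnected result triggers a warning, not an
    error: bond perception feeds features, and a conservative miss is
    recoverable downstream.
    """
    radii = radii if radii is not None else COVALENT_RADII
    d = pairwise_distances(mol)
    r = np.array([radii[e] for e in mol.elements])
    cutoff = scale * (r[:, None] + r[None, :])
    cand = (d <= cutoff) & (d > 0)
    edges: set[tuple[int, int]] = set()
    lengths: dict[tuple[int, int], float] = {}
    # hydrogens keep only their shortest candidate bond
    for i in range(mol.n_atoms):
        if mol.elements[i] == "H":
            js = np.flatnonzero(cand[i])
            if len(js) > 1:
                keep = js[np.argmin(d[i, js])]
                cand[i, :] = False
                cand[:, i] = False
                cand[i, keep] = cand[keep, i] = True
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if cand[i, j]:
                edges.add((i, j))
                lengths[(i, j)] = float(d[i, j])
    graph = BondGraph(n_atoms=mol.n_atoms, edges=edges, lengths=lengths)
    if mol.n_atoms > 1 and _n_components(graph) > 1:
        warnings.warn(
            f"{mol.name}: bond perception left the molecule disconnected",
            stacklevel=2,
        )
    return graph


def _n_components(graph: BondGraph) -> int:
    seen = [False] * graph.n_atoms
    n = 0
    for start in range(graph.n_atoms):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            for w in graph.neighbors(v):
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
    return n


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERACY_EPS or nv < _DEGENERACY_EPS:
        raise ValueError("zero-length arm in angle computation")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def bond_angle(mol: Molecule, i: int, j: int, k: int) -> float:
    """Angle ∠(i, j, k) in degrees with vertex j, in [0, 180]."""
    return _angle_between(mol.coords[i] - mol.coords[j], mol.coords[k] - mol.coords[j])


def dihedral_angle(mol: Molecule, a: int, b: int, c: int, d: int) -> Optional[float]:
    """Unsigned dihedral between planes (a,b,c) and (b,c,d), degrees in [0, 180].

    Returns ``None`` when either plane is degenerate (three collinear
    atoms), in which case the torsion is undefined.
    """
    p = mol.coords
    b1, b2, b3 = p[b] - p[a], p[c] - p[b], p[d] - p[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERACY_EPS or np.linalg.norm(n2) < _DEGENERACY_EPS:
        return None
    return _angle_between(n1, n2)


def nearest_neighbor(mol: Molecule, i: int, dmat: Optional[np.ndarray] = None) -> int:
    """Index of the closest other atom to atom i (ties broken by index)."""
    d = dmat if dmat is not None else pairwise_distances(mol)
    row = d[i].copy()
    row[i] = np.inf
    return int(np.argmin(row))


def geometric_angles(
    mol: Molecule,
    i0: int,
    i1: int,
    dmat: Optional[np.ndarray] = None,
) -> tuple[Optional[float], Optional[float]]:
    """Angles formed by a coupled pair and each member's nearest atom.

    ``angle0`` has its vertex at atom0 with arms to atom1 and to atom0's
    nearest neighbour; ``angle1`` is the mirror image with the roles of
    the two atoms swapped.  An angle is ``None`` when the molecule has
    fewer than 3 atoms or when the nearest neighbour *is* the coupled
    partner (the angle would be identically zero and carries no
    information).  Exact ties in the nearest-neighbour distance (common
    in idealised geometries where equivalent bonds share one length) are
    resolved by taking the smallest resulting angle, a purely geometric
    key that keeps the feature invariant under atom relabelling.
    """
    if mol.n_atoms < 3:
        return None, None
    d = dmat if dmat is not None else pairwise_distances(mol)
    out: list[Optional[float]] = []
    for center, partner in ((i0, i1), (i1, i0)):
        row = d[center].copy()
        row[center] = np.inf
        dmin = row.min()
        tied = np.flatnonzero(row <= dmin * (1 + 1e-9))
        if len(tied) == 1 and tied[0] == partner:
            out.append(None)
            continue
        cands = [int(j) for j in tied if j != partner]
        if not cands:
            out.append(None)
            continue
        out.append(min(bond_angle(mol, partner, center, j) for j in cands))
    return out[0], out[1]


def coupling_path(
    bonds: BondGraph, i0: int, i1: int, max_len: int = 3
) -> Optional[list[int]]:
    """Shortest bond path from i0 to i1 as an atom-index list, or ``None``.

    Paths longer than ``max_len`` bonds (or absent entirely) return
    ``None``.  Among equal-length shortest paths the one with the
    lexicographically smallest intermediate index sequence is returned,
    making the result deterministic.
    """
    if i0 == i1:
        return [i0]
    dist = {i0: 0}
    q = deque([i0])
    while q:
        v = q.popleft()
        if dist[v] >= max_len:
            continue
        for w in bonds.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    if i1 not in dist or dist[i1] > max_len:
        return None
    return _lex_smallest_shortest_path(bonds, i0, i1, dist)


def _lex_smallest_shortest_path(
    bonds: BondGraph, i0: int, i1: int, dist_from_i0: dict[int, int]
) -> list[int]:
    """Forward greedy walk over BFS layers; smallest next index that still
    reaches i1 along a shortest path."""
    total = dist_from_i0[i1]
    # distances from i1 to prune forward choices
    dist_back = {i1: 0}
    q = deque([i1])
    while q:
        v = q.popleft()
        for w in bonds.neighbors(v):
            if w not in dist_back:
                dist_back[w] = dist_back[v] + 1
                q.append(w)
    path = [i0]
    cur = i0
    step = 0
    while cur != i1:
        step += 1
        nxt = min(
            w
            for w in bonds.neighbors(cur)
            if dist_from_i0.get(w) == step and dist_back.get(w) == total - step
        )
        path.append(nxt)
        cur = nxt
    return path


def angle_pack(
    mol: Molecule,
    bonds: BondGraph,
    i0: int,
    i1: int,
    n_bonds: int,
    dmat: Optional[np.ndarray] = None,
) -> AnglePack:
    """Assemble the angle features of one coupled pair.

    The bond path defines which path-derived angle applies: the torsion
    along a 3-bond path, the vertex angle of a 2-bond path.  ``n_bonds``
    is the N declared by the record's coupling type; when the perceived
    path length disagrees with it the declared N wins (the label defines
    the type, bond perception is only a heuristic) and the path-derived
    angle is left absent.
    """
    pack = AnglePack()
    a0, a1 = geometric_angles(mol, i0, i1, dmat=dmat)
    pack.cos_angle0 = None if a0 is None else float(np.cos(np.radians(a0)))
    pack.cos_angle1 = None if a1 is None else float(np.cos(np.radians(a1)))
    path = coupling_path(bonds, i0, i1)
    if path is not None and len(path) - 1 != n_bonds:
        path = None
    if n_bonds == 3 and path is not None:
        phi = dihedral_angle(mol, *path)
        pack.cos_dihedral = None if phi is None else float(np.cos(np.radians(phi)))
    elif n_bonds == 2 and path is not None:
        theta = bond_angle(mol, path[0], path[1], path[2])
        pack.cos_bond_angle = float(np.cos(np.radians(theta)))
    return pack
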