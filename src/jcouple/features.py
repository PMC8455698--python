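"""Feature engineering: atom / bond / coupling-edge / molecule blocks.

Four raw feature blocks are built per molecule:

* **atom** — element one-hot (C,H,N,O,F) ⊕ bonded degree ⊕ mean/min
  neighbour distance;
* **bond** (per *directed* bond w→v) — length, 1/length, ordered
  endpoint-element-pair one-hot (25), neighbour-angle count M and mean
  cos θ over the angles between the bond and its neighbouring bonds at
  the head atom v (the same angles feed the attention term);
* **coupling edge** (per record) — coupling-type one-hot (8), coupled-atom
  distance d, 1/d, 1/d³, and the four angle cosines (dihedral, bond
  angle, geometric angle0/angle1) each with a presence flag;
* **molecule** — element counts, bond count, mean pairwise distance.

Undirected bonds become two directed edges because the message-passing
update aggregates into a head atom per direction.  Scale-carrying columns
are z-scored with training-set statistics; one-hots, flags and cosines
are exempt.  A layout manifest (slot names, widths, normalisation
eligibility) travels with any fitted model so checkpoints can verify
feature compatibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    BondGraph,
    angle_pack,
    bond_angle,
    infer_bonds,
    pairwise_distances,
)
from .io import COUPLING_TYPES, CouplingRecord, Dataset, ELEMENTS, Molecule

_TYPE_INDEX = {t: i for i, t in enumerate(COUPLING_TYPES)}
_ELEM_INDEX = {e: i for i, e in enumerate(ELEMENTS)}


@dataclass
class FeatureConfig:
    """Featurisation switches.

    ``use_angle_features=False`` zeroes the four angle-cosine slots and
    their presence flags in the coupling block (the "no angle features"
    ablation arm); distances and one-hots are unaffected.
    """

    normalize: bool = True
    use_angle_features: bool = True
    bond_scale: float = 1.3


def _layout() -> dict[str, list[tuple[str, int, bool]]]:
    """Slot table per block: (name, width, z-score eligible)."""
    return {
        "atom": [
            ("element_onehot", len(ELEMENTS), False),
            ("degree", 1, True),
            ("mean_neighbor_dist", 1, True),
            ("min_neighbor_dist", 1, True),
        ],
        "bond": [
            ("length", 1, True),
            ("inv_length", 1, True),
            ("elem_pair_onehot", len(ELEMENTS) ** 2, False),
            ("n_neighbor_angles", 1, True),
            ("mean_cos_neighbor_angle", 1, False),
        ],
        "coupling": [
            ("type_onehot", len(COUPLING_TYPES), False),
            ("distance", 1, True),
            ("inv_distance", 1, True),
            ("inv_distance_cubed", 1, True),
            ("cos_dihedral", 1, False),
            ("has_dihedral", 1, False),
            ("cos_bond_angle", 1, False),
            ("has_bond_angle", 1, False),
            ("cos_angle0", 1, False),
            ("has_angle0", 1, False),
            ("cos_angle1", 1, False),
            ("has_angle1", 1, False),
        ],
        "molecule": [
            ("element_counts", len(ELEMENTS), False),
            ("n_bonds", 1, True),
            ("mean_pairwise_dist", 1, True),
        ],
    }


def layout_manifest() -> dict:
    """Serialisable feature-layout manifest with block widths and a hash."""
    lay = _layout()
    manifest = {
        "blocks": {
            name: [
                {"slot": s, "width": w, "normalize": n} for (s, w, n) in slots
            ]
            for name, slots in lay.items()
        },
        "widths": {name: sum(w for _, w, _ in slots) for name, slots in lay.items()},
    }
    digest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest["hash"] = digest
    return manifest


def _norm_mask(block: str) -> np.ndarray:
    mask = []
    for _, width, normalizable in _layout()[block]:
        mask.extend([normalizable] * width)
    return np.array(mask, dtype=bool)


@dataclass
class MolFeatures:
    """Raw feature arrays and graph indexing for one molecule."""

    name: str
    n_atoms: int
    atom: np.ndarray  # (n, FA)
    bond_src: np.ndarray  # (eb,) directed tail (message source w)
    bond_dst: np.ndarray  # (eb,) directed head (updated atom v)
    bond: np.ndarray  # (eb, FB)
    angle_cos: np.ndarray  # flattened cos(theta) of neighbour angles
    angle_edge: np.ndarray  # directed-edge index per angle entry
    cpl_src: np.ndarray  # (2*R,)
    cpl_dst: np.ndarray
    cpl_x: np.ndarray  # (2*R, FC)
    mol: np.ndarray  # (FM,)
    rec_atom0: np.ndarray  # (R,) local indices, H-canonical order
    rec_atom1: np.ndarray
    rec_type: np.ndarray  # (R,) int type ids
    rec_pos: np.ndarray  # (R,) positions in the originating record list
    y: Optional[np.ndarray]  # (R,) Hz or None


@dataclass
class FeatureStats:
    """Per-column mean/sd for the z-scored slots of each block."""

    mean: dict[str, np.ndarray] = field(default_factory=dict)
    std: dict[str, np.ndarray] = field(default_factory=dict)

    @staticmethod
    def fit(mols: Sequence[MolFeatures]) -> "FeatureStats":
        stats = FeatureStats()
        stacks = {
            "atom": np.concatenate([m.atom for m in mols], axis=0),
            "bond": np.concatenate(
                [m.bond for m in mols if len(m.bond)] or [np.zeros((0, _width("bond")))],
                axis=0,
            ),
            "coupling": np.concatenate(
                [m.cpl_x for m in mols if len(m.cpl_x)]
                or [np.zeros((0, _width("coupling")))],
                axis=0,
            ),
            "molecule": np.stack([m.mol for m in mols], axis=0),
        }
        for block, arr in stacks.items():
            mask = _norm_mask(block)
            mean = np.zeros(arr.shape[1])
            std = np.ones(arr.shape[1])
            if len(arr):
                mean[mask] = arr[:, mask].mean(axis=0)
                s = arr[:, mask].std(axis=0)
                std[mask] = np.where(s > 1e-12, s, 1.0)
            stats.mean[block] = mean
            stats.std[block] = std
        return stats

    def apply(self, mols: Sequence[MolFeatures]) -> None:
        """Z-score the eligible columns in place."""
        for m in mols:
            m.atom = (m.atom - self.mean["atom"]) / self.std["atom"]
            if len(m.bond):
                m.bond = (m.bond - self.mean["bond"]) / self.std["bond"]
            if len(m.cpl_x):
                m.cpl_x = (m.cpl_x - self.mean["coupling"]) / self.std["coupling"]
            m.mol = (m.mol - self.mean["molecule"]) / self.std["molecule"]

    def to_dict(self) -> dict:
        return {
            "mean": {k: v.tolist() for k, v in self.mean.items()},
            "std": {k: v.tolist() for k, v in self.std.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "FeatureStats":
        stats = FeatureStats()
        stats.mean = {k: np.asarray(v) for k, v in d["mean"].items()}
        stats.std = {k: np.asarray(v) for k, v in d["std"].items()}
        return stats


def _width(block: str) -> int:
    return sum(w for _, w, _ in _layout()[block])


def featurize_molecule(
    mol: Molecule,
    records: Sequence[CouplingRecord],
    record_positions: Sequence[int],
    config: FeatureConfig,
    bonds: Optional[BondGraph] = None,
) -> MolFeatures:
    """Build the raw feature blocks for one molecule and its records."""
    n = mol.n_atoms
    d = pairwise_distances(mol)
    if bonds is None:
        bonds = infer_bonds(mol, scale=config.bond_scale)

    # ---- atom block ----
    atom = np.zeros((n, _width("atom")))
    for i in range(n):
        atom[i, _ELEM_INDEX[mol.elements[i]]] = 1.0
        nbrs = bonds.neighbors(i)
        atom[i, 5] = len(nbrs)
        if nbrs:
            nd = d[i, nbrs]
            atom[i, 6] = nd.mean()
            atom[i, 7] = nd.min()

    # ---- directed bond block + neighbour angles ----
    src_list: list[int] = []
    dst_list: list[int] = []
    bond_rows: list[np.ndarray] = []
    angle_cos: list[float] = []
    angle_edge: list[int] = []
    for i, j in sorted(bonds.edges):
        for w_at, v_at in ((i, j), (j, i)):  # message flows w -> v
            e_idx = len(src_list)
            src_list.append(w_at)
            dst_list.append(v_at)
            row = np.zeros(_width("bond"))
            length = bonds.length(i, j)
            row[0] = length
            row[1] = 1.0 / length
            pair = _ELEM_INDEX[mol.elements[w_at]] * 5 + _ELEM_INDEX[mol.elements[v_at]]
            row[2 + pair] = 1.0
            # angles between bond (w->v) and the other bonds at the head v
            cosines = []
            for x in bonds.neighbors(v_at):
                if x == w_at:
                    continue
                theta = bond_angle(mol, w_at, v_at, x)
                cosines.append(np.cos(np.radians(theta)))
                angle_cos.append(float(np.cos(np.radians(theta))))
                angle_edge.append(e_idx)
            row[27] = len(cosines)
            row[28] = float(np.mean(cosines)) if cosines else 0.0
            bond_rows.append(row)

    # ---- coupling-edge block ----
    cpl_rows: list[np.ndarray] = []
    cpl_src: list[int] = []
    cpl_dst: list[int] = []
    a0s, a1s, tids = [], [], []
    ys: list[float] = []
    any_label = any(r.scc is not None for r in records)
    for rec in records:
        i0, i1 = rec.atom_index_0, rec.atom_index_1
        row = np.zeros(_width("coupling"))
        row[_TYPE_INDEX[rec.ctype]] = 1.0
        dist = d[i0, i1]
        row[8] = dist
        row[9] = 1.0 / dist
        row[10] = 1.0 / dist**3
        if config.use_angle_features:
            pack = angle_pack(mol, bonds, i0, i1, rec.n_bonds, dmat=d)
            for off, val in (
                (11, pack.cos_dihedral),
                (13, pack.cos_bond_angle),
                (15, pack.cos_angle0),
                (17, pack.cos_angle1),
            ):
                if val is not None:
                    row[off] = val
                    row[off + 1] = 1.0
        cpl_rows.append(row)
        # one undirected coupling edge = two directed messages
        cpl_src.extend([i0, i1])
        cpl_dst.extend([i1, i0])
        a0s.append(i0)
        a1s.append(i1)
        tids.append(_TYPE_INDEX[rec.ctype])
        if any_label:
            ys.append(rec.scc if rec.scc is not None else np.nan)

    # ---- molecule block ----
    molrow = np.zeros(_width("molecule"))
    for e in mol.elements:
        molrow[_ELEM_INDEX[e]] += 1.0
    molrow[5] = bonds.n_bonds
    if n > 1:
        iu = np.triu_indices(n, k=1)
        molrow[6] = d[iu].mean()

    cpl_x = np.array(cpl_rows) if cpl_rows else np.zeros((0, _width("coupling")))
    cpl_x = np.repeat(cpl_x, 2, axis=0) if len(cpl_x) else cpl_x

    return MolFeatures(
        name=mol.name,
        n_atoms=n,
        atom=atom,
        bond_src=np.array(src_list, dtype=int),
        bond_dst=np.array(dst_list, dtype=int),
        bond=np.array(bond_rows) if bond_rows else np.zeros((0, _width("bond"))),
        angle_cos=np.array(angle_cos, dtype=float),
        angle_edge=np.array(angle_edge, dtype=int),
        cpl_src=np.array(cpl_src, dtype=int),
        cpl_dst=np.array(cpl_dst, dtype=int),
        cpl_x=cpl_x,
        mol=molrow,
        rec_atom0=np.array(a0s, dtype=int),
        rec_atom1=np.array(a1s, dtype=int),
        rec_type=np.array(tids, dtype=int),
        rec_pos=np.array(list(record_positions), dtype=int),
        y=np.array(ys, dtype=float) if any_label else None,
    )


def featurize(
    dataset: Dataset,
    config: Optional[FeatureConfig] = None,
    bonds_map: Optional[dict[str, BondGraph]] = None,
) -> list[MolFeatures]:
    """Featurize every molecule that appears in the dataset's records.

    Molecules with no records still contribute (they simply carry no
    coupling edges) only if explicitly present in ``dataset.molecules``
    and referenced; records referencing unknown molecules raise.
    """
    config = config or FeatureConfig()
    by_mol: dict[str, list[int]] = {name: [] for name in dataset.molecules}
    for pos, rec in enumerate(dataset.records):
        if rec.molecule not in dataset.molecules:
            raise KeyError(f"record references unknown molecule {rec.molecule!r}")
        by_mol[rec.molecule].append(pos)
    out = []
    for name, positions in by_mol.items():
        mol = dataset.molecules[name]
        recs = [dataset.records[p] for p in positions]
        bonds = bonds_map.get(name) if bonds_map else None
        out.append(featurize_molecule(mol, recs, positions, config, bonds=bonds))
    return out


# ---------------------------------------------------------------------------
# batch collation
# ---------------------------------------------------------------------------


@dataclass
class Batch:
    """Concatenated arrays for a set of molecules, ready for the network."""

    atom_x: np.ndarray
    bond_src: np.ndarray
    bond_dst: np.ndarray
    bond_x: np.ndarray
    angle_cos: np.ndarray
    angle_edge: np.ndarray
    cpl_src: np.ndarray
    cpl_dst: np.ndarray
    cpl_x: np.ndarray
    mol_x: np.ndarray
    tokens: np.ndarray  # (B, L) global atom indices (padded with 0)
    token_mask: np.ndarray  # (B, L) 1 = real token
    rec_tok0: np.ndarray  # (R,) flat indices into the (B*L) token table
    rec_tok1: np.ndarray
    rec_mol: np.ndarray  # (R,) molecule slot per record
    rec_type: np.ndarray  # (R,) coupling-type ids
    rec_pos: np.ndarray  # (R,) positions in the originating record list
    y: Optional[np.ndarray]

    @property
    def n_records(self) -> int:
        return len(self.rec_type)


def collate(mols: Sequence[MolFeatures]) -> Batch:
    """Concatenate per-molecule features into one batch with global indices."""
    atom_offset = 0
    bond_edge_offset = 0
    atom_x, bond_x, cpl_x, mol_x = [], [], [], []
    bond_src, bond_dst, angle_cos, angle_edge = [], [], [], []
    cpl_src, cpl_dst = [], []
    token_lists: list[list[int]] = []
    rec_entries: list[tuple[int, int, int, int, int]] = []  # (mol, tok0, tok1, type, pos)
    ys = []
    has_y = all(m.y is not None for m in mols) and any(
        m.y is not None and len(m.y) for m in mols
    )
    for b, m in enumerate(mols):
        atom_x.append(m.atom)
        mol_x.append(m.mol)
        bond_x.append(m.bond)
        bond_src.append(m.bond_src + atom_offset)
        bond_dst.append(m.bond_dst + atom_offset)
        angle_cos.append(m.angle_cos)
        angle_edge.append(m.angle_edge + bond_edge_offset)
        cpl_x.append(m.cpl_x)
        cpl_src.append(m.cpl_src + atom_offset)
        cpl_dst.append(m.cpl_dst + atom_offset)
        toks = sorted(set(m.rec_atom0.tolist()) | set(m.rec_atom1.tolist()))
        tok_index = {a: k for k, a in enumerate(toks)}
        token_lists.append([a + atom_offset for a in toks])
        for a0, a1, t, pos in zip(m.rec_atom0, m.rec_atom1, m.rec_type, m.rec_pos):
            rec_entries.append((b, tok_index[int(a0)], tok_index[int(a1)], int(t), int(pos)))
        if has_y:
            ys.append(m.y)
        atom_offset += m.n_atoms
        bond_edge_offset += len(m.bond_src)
    L = max((len(t) for t in token_lists), default=1) or 1
    B = len(mols)
    tokens = np.zeros((B, L), dtype=int)
    token_mask = np.zeros((B, L))
    for b, toks in enumerate(token_lists):
        tokens[b, : len(toks)] = toks
        token_mask[b, : len(toks)] = 1.0
    rec_mol = np.array([e[0] for e in rec_entries], dtype=int)
    rec_tok0 = np.array([e[0] * L + e[1] for e in rec_entries], dtype=int)
    rec_tok1 = np.array([e[0] * L + e[2] for e in rec_entries], dtype=int)
    rec_type = np.array([e[3] for e in rec_entries], dtype=int)
    rec_pos = np.array([e[4] for e in rec_entries], dtype=int)
    return Batch(
        atom_x=np.concatenate(atom_x, axis=0),
        bond_src=np.concatenate(bond_src).astype(int)
        if bond_src
        else np.zeros(0, dtype=int),
        bond_dst=np.concatenate(bond_dst).astype(int)
        if bond_dst
        else np.zeros(0, dtype=int),
        bond_x=np.concatenate(bond_x, axis=0),
        angle_cos=np.concatenate(angle_cos) if angle_cos else np.zeros(0),
        angle_edge=np.concatenate(angle_edge).astype(int)
        if angle_edge
        else np.zeros(0, dtype=int),
        cpl_src=np.concatenate(cpl_src).astype(int) if cpl_src else np.zeros(0, dtype=int),
        cpl_dst=np.concatenate(cpl_dst).astype(int) if cpl_dst else np.zeros(0, dtype=int),
        cpl_x=np.concatenate(cpl_x, axis=0),
        mol_x=np.stack(mol_x, axis=0),
        tokens=tokens,
        token_mask=token_mask,
        rec_tok0=rec_tok0,
        rec_tok1=rec_tok1,
        rec_mol=rec_mol,
        rec_type=rec_type,
        rec_pos=rec_pos,
        y=np.concatenate(ys) if has_y else None,
    )
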