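"""Structure and coupling-table I/O.

Reads and writes standard XYZ files and the CSV dialect of the public
scalar-coupling competition data: ``structures.csv`` (one row per atom),
``train.csv``/``test.csv`` (one row per coupled atom pair) and the
two-column submission file.  Coordinates are Å, couplings are Hz, atom
indices are 0-based within each molecule.

Coupling types follow the ``<N>J<El0><El1>`` grammar with N ∈ {1,2,3}.
Every supported type involves hydrogen; rows are canonicalised so that the
hydrogen atom is ``atom_index_0`` and the type string names H first
(``"1JCH"`` on input becomes ``"1JHC"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "F")

#: The eight supported coupling types in canonical (H-first) spelling.
COUPLING_TYPES: tuple[str, ...] = (
    "1JHC",
    "1JHN",
    "2JHC",
    "2JHN",
    "2JHH",
    "3JHC",
    "3JHN",
    "3JHH",
)

_TYPE_RE = re.compile(r"^([123])J([CHNOF])([CHNOF])$")


class FormatError(ValueError):
    """Raised when an input file or record violates the expected format."""


def canonicalize_type(ctype: str) -> str:
    """Normalise a coupling-type string to its canonical H-first spelling.

    ``"1JCH"`` and ``"1JHC"`` both map to ``"1JHC"``.  Raises
    :class:`FormatError` for strings outside the supported grammar or for
    the (N, element-pair) combinations not among the eight supported types.
    """
    m = _TYPE_RE.match(str(ctype).strip())
    if not m:
        raise FormatError(f"unrecognised coupling type {ctype!r}")
    n, e0, e1 = m.group(1), m.group(2), m.group(3)
    if "H" not in (e0, e1):
        raise FormatError(f"coupling type {ctype!r} involves no hydrogen")
    if e0 != "H" and e1 == "H":
        e0, e1 = e1, e0
    canon = f"{n}J{e0}{e1}"
    if canon not in COUPLING_TYPES:
        raise FormatError(f"unsupported coupling type {ctype!r}")
    return canon


def coupling_n_bonds(ctype: str) -> int:
    """Number of bonds N on the coupling path encoded in the type string."""
    return int(canonicalize_type(ctype)[0])


@dataclass
class Molecule:
    """A named molecule: element symbols plus Cartesian coordinates in Å."""

    name: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise FormatError(
                f"{self.name}: {len(self.elements)} elements but "
                f"{len(self.coords)} coordinate rows"
            )
        if len(self.elements) < 1:
            raise FormatError(f"{self.name}: empty molecule")
        bad = [e for e in self.elements if e not in ELEMENTS]
        if bad:
            raise FormatError(f"{self.name}: unsupported element(s) {sorted(set(bad))}")
        # duplicate-position check; exact duplicates only (degenerate input)
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) != len(self.coords):
            raise FormatError(f"{self.name}: two atoms at identical coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class CouplingRecord:
    """One coupled atom pair with its type and (optionally) its SCC in Hz."""

    molecule: str
    atom_index_0: int
    atom_index_1: int
    ctype: str
    scc: Optional[float] = None
    row_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.ctype = canonicalize_type(self.ctype)
        if self.atom_index_0 == self.atom_index_1:
            raise FormatError(
                f"{self.molecule}: record couples atom {self.atom_index_0} to itself"
            )

    @property
    def n_bonds(self) -> int:
        return int(self.ctype[0])


@dataclass
class Dataset:
    """Molecules plus coupling records; every record names a known molecule."""

    molecules: dict[str, Molecule] = field(default_factory=dict)
    records: list[CouplingRecord] = field(default_factory=list)

    def validate(self) -> "Dataset":
        """Check record/molecule consistency and canonicalise atom order.

        The hydrogen member of each pair is moved to ``atom_index_0`` (HH
        pairs are left as given).  Indices are checked against the atom
        count and the type's element letters against the actual elements.
        """
        for rec in self.records:
            mol = self.molecules.get(rec.molecule)
            if mol is None:
                raise FormatError(f"record references unknown molecule {rec.molecule!r}")
            for idx in (rec.atom_index_0, rec.atom_index_1):
                if not 0 <= idx < mol.n_atoms:
                    raise FormatError(
                        f"{rec.molecule}: atom index {idx} out of range "
                        f"(molecule has {mol.n_atoms} atoms)"
                    )
            e0, e1 = mol.elements[rec.atom_index_0], mol.elements[rec.atom_index_1]
            t0, t1 = rec.ctype[2], rec.ctype[3]
            if (e0, e1) == (t0, t1):
                pass
            elif (e1, e0) == (t0, t1):
                rec.atom_index_0, rec.atom_index_1 = rec.atom_index_1, rec.atom_index_0
            else:
                raise FormatError(
                    f"{rec.molecule}: type {rec.ctype} does not match elements "
                    f"({e0}, {e1}) at indices ({rec.atom_index_0}, {rec.atom_index_1})"
                )
        return self


def read_xyz(path: str | Path) -> Molecule:
    """Parse a standard XYZ file (count line, comment line, atom lines)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:1: expected an atom count") from exc
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != n:
        raise FormatError(
            f"{path}: header declares {n} atoms but {len(atom_lines)} atom lines found"
        )
    elements: list[str] = []
    coords: list[list[float]] = []
    for lineno, ln in enumerate(atom_lines, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected 'El x y z'")
        el = parts[0]
        if el not in ELEMENTS:
            raise FormatError(f"{path}:{lineno}: unsupported element {el!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed coordinate") from exc
        elements.append(el)
        coords.append(xyz)
    return Molecule(name=path.stem, elements=elements, coords=np.array(coords))


def write_xyz(mol: Molecule, path: str | Path, comment: str = "") -> None:
    """Write a molecule as a standard XYZ file."""
    path = Path(path)
    lines = [str(mol.n_atoms), comment]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + "\n")


def read_structures_csv(path: str | Path) -> dict[str, Molecule]:
    """Read a ``structures.csv`` table into per-molecule atom lists.

    Rows may appear in any order; within each molecule ``atom_index`` must
    be dense from 0 with no duplicates.
    """
    df = pd.read_csv(path)
    required = {"molecule_name", "atom_index", "atom", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    molecules: dict[str, Molecule] = {}
    for name, group in df.groupby("molecule_name", sort=False):
        group = group.sort_values("atom_index")
        idx = group["atom_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise FormatError(f"{path}: duplicate atom_index in molecule {name!r}")
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(
                f"{path}: atom_index of molecule {name!r} is not dense from 0"
            )
        molecules[str(name)] = Molecule(
            name=str(name),
            elements=[str(e) for e in group["atom"]],
            coords=group[["x", "y", "z"]].to_numpy(dtype=float),
        )
    return molecules


def read_couplings_csv(
    path: str | Path,
    labelled: bool = True,
    molecules: Optional[Mapping[str, Molecule]] = None,
) -> list[CouplingRecord]:
    """Read a ``train.csv``/``test.csv`` style coupling table.

    With ``labelled=True`` the ``scalar_coupling_constant`` column is
    required.  If ``molecules`` is given, indices and element/type
    consistency are validated and atom order canonicalised (H first).
    """
    df = pd.read_csv(path)
    required = {"molecule_name", "atom_index_0", "atom_index_1", "type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if labelled and "scalar_coupling_constant" not in df.columns:
        raise FormatError(f"{path}: labelled table lacks scalar_coupling_constant")
    has_id = "id" in df.columns
    has_scc = "scalar_coupling_constant" in df.columns
    records: list[CouplingRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = CouplingRecord(
            molecule=str(row.molecule_name),
            atom_index_0=int(row.atom_index_0),
            atom_index_1=int(row.atom_index_1),
            ctype=str(row.type),
            scc=float(row.scalar_coupling_constant) if has_scc else None,
            row_id=int(row.id) if has_id else i,
        )
        records.append(rec)
    if molecules is not None:
        Dataset(molecules=dict(molecules), records=records).validate()
    return records


def write_couplings_csv(records: Sequence[CouplingRecord], path: str | Path) -> None:
    """Write coupling records in the train/test table layout."""
    rows = []
    labelled = any(r.scc is not None for r in records)
    for i, r in enumerate(records):
        row = {
            "id": r.row_id if r.row_id is not None else i,
            "molecule_name": r.molecule,
            "atom_index_0": r.atom_index_0,
            "atom_index_1": r.atom_index_1,
            "type": r.ctype,
        }
        if labelled:
            row["scalar_coupling_constant"] = r.scc
        rows.append(row)
    cols = ["id", "molecule_name", "atom_index_0", "atom_index_1", "type"]
    if labelled:
        cols.append("scalar_coupling_constant")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_structures_csv(molecules: Mapping[str, Molecule], path: str | Path) -> None:
    """Write molecules in the ``structures.csv`` layout."""
    rows = []
    for name, mol in molecules.items():
        for i, (el, (x, y, z)) in enumerate(zip(mol.elements, mol.coords)):
            rows.append(
                {"molecule_name": name, "atom_index": i, "atom": el, "x": x, "y": y, "z": z}
            )
    pd.DataFrame(rows, columns=["molecule_name", "atom_index", "atom", "x", "y", "z"]).to_csv(
        path, index=False
    )


def write_predictions_csv(
    records: Sequence[CouplingRecord],
    predictions: Iterable[float],
    path: str | Path,
) -> None:
    """Write a submission-shaped file: one row id and one SCC per record."""
    preds = np.asarray(list(predictions), dtype=float)
    if len(preds) != len(records):
        raise FormatError(
            f"{len(records)} records but {len(preds)} predictions"
        )
    ids = [r.row_id if r.row_id is not None else i for i, r in enumerate(records)]
    pd.DataFrame({"id": ids, "scalar_coupling_constant": preds}).to_csv(path, index=False)


def load_dataset(
    structures_path: str | Path,
    couplings_path: str | Path,
    labelled: bool = True,
) -> Dataset:
    """Assemble and validate a :class:`Dataset` from the two CSV files."""
    molecules = read_structures_csv(structures_path)
    records = read_couplings_csv(couplings_path, labelled=labelled, molecules=molecules)
    return Dataset(molecules=molecules, records=records)
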