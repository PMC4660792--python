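"""Molecular structure model, file I/O and van der Waals volume.

Molecules are plain containers: atoms with 3-D coordinates in angstrom,
bonds with integer-coded orders, and an optional experimental hydration
free energy label in kcal/mol.  SDF and MOL2 files are parsed through
RDKit with sanitization disabled so that the connectivity and aromatic
flags written in the file are preserved verbatim; XYZ and PDB carry no
bonds and get distance-based bond inference against a bundled covalent
radius table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SolvContactError, UnsupportedElementError

log = logging.getLogger(__name__)

SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: multiple of the covalent-radius sum below which two atoms are bonded
BOND_INFERENCE_FACTOR = 1.3

BOND_ORDERS = ("single", "double", "triple", "aromatic")


def _load_radius_csv(name: str) -> dict[str, float]:
    with resources.files("solvcontact.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["element"], df["radius_angstrom"].astype(float)))


@lru_cache(maxsize=None)
def bondi_radii() -> dict[str, float]:
    """Bundled Bondi van der Waals radii (angstrom)."""
    return _load_radius_csv("bondi_radii.csv")


@lru_cache(maxsize=None)
def covalent_radii() -> dict[str, float]:
    """Bundled single-bond covalent radii (angstrom)."""
    return _load_radius_csv("covalent_radii.csv")


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based index, element symbol, coordinates (angstrom)."""

    index: int
    element: str
    coords: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(self.element, f"atom {self.index}")
        if not np.all(np.isfinite(self.coords)):
            raise SolvContactError(f"atom {self.index}: non-finite coordinates")
        if not self.vdw_radius > 0:
            raise SolvContactError(f"atom {self.index}: vdw_radius must be > 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices i and j."""

    i: int
    j: int
    order: str = "single"

    def __post_init__(self):
        if self.i == self.j:
            raise SolvContactError("self-bond is not allowed")
        if self.order not in BOND_ORDERS:
            raise SolvContactError(f"unknown bond order {self.order!r}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    """A solute: named atom/bond lists plus an optional ΔG_hyd label."""

    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    exp_dg: Optional[float] = None  # kcal/mol
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        for k, a in enumerate(self.atoms):
            if a.index != k:
                raise SolvContactError(
                    f"{self.name}: atom index {a.index} at position {k}"
                )
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise SolvContactError(f"{self.name}: bond {b.i}-{b.j} out of range")
            if b.key in seen:
                raise SolvContactError(f"{self.name}: duplicate bond {b.key}")
            seen.add(b.key)
        if n and not self.has_hydrogens() and self._looks_undersaturated():
            msg = "no explicit hydrogens; atom typing will fail for typical organics"
            if msg not in self.warnings:
                self.warnings.append(msg)

    _MIN_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
    _ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

    def _looks_undersaturated(self) -> bool:
        """Some organic atom has fewer bonds than its minimum valence —
        the signature of stripped hydrogens."""
        order_sum = [0.0] * len(self.atoms)
        for b in self.bonds:
            order_sum[b.i] += self._ORDER_VALUE[b.order]
            order_sum[b.j] += self._ORDER_VALUE[b.order]
        return any(
            order_sum[a.index] < self._MIN_VALENCE.get(a.element, 0)
            for a in self.atoms
        )

    # -- convenience views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        key = (i, j) if i < j else (j, i)
        for b in self.bonds:
            if b.key == key:
                return b
        return None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j, {"order": b.order}) for b in self.bonds)
        return g

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new_xyz = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            Atom(a.index, a.element, tuple(new_xyz[k]), a.vdw_radius)
            for k, a in enumerate(self.atoms)
        ]
        return Molecule(self.name, atoms, list(self.bonds), self.exp_dg,
                        list(self.warnings))


def make_atom(index: int, element: str, coords: Iterable[float]) -> Atom:
    """Atom with its Bondi radius filled from the bundled table."""
    radii = bondi_radii()
    if element not in radii:
        raise UnsupportedElementError(element, f"atom {index}")
    x, y, z = (float(c) for c in coords)
    return Atom(index, element, (x, y, z), radii[element])


def distance(mol: Molecule, i: int, j: int) -> float:
    """Euclidean distance r_ij between two atoms, in angstrom."""
    n = mol.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: {i}, {j} (n={n})")
    return float(np.linalg.norm(mol.atoms[i].xyz - mol.atoms[j].xyz))


def infer_bonds(elements: list[str], xyz: np.ndarray) -> list[Bond]:
    """Distance-based bond inference: bonded iff r < 1.3 x covalent-radius sum."""
    radii = covalent_radii()
    bonds = []
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, n):
            rmax = BOND_INFERENCE_FACTOR * (radii[elements[i]] + radii[elements[j]])
            if np.linalg.norm(xyz[i] - xyz[j]) < rmax:
                bonds.append(Bond(i, j, "single"))
    return bonds


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_RDKIT_ORDER = {}


def _rdkit_order_map():
    global _RDKIT_ORDER
    if not _RDKIT_ORDER:
        from rdkit import Chem

        _RDKIT_ORDER = {
            Chem.BondType.SINGLE: "single",
            Chem.BondType.DOUBLE: "double",
            Chem.BondType.TRIPLE: "triple",
            Chem.BondType.AROMATIC: "aromatic",
        }
    return _RDKIT_ORDER


def _from_rdkit(rdmol, fallback_name: str) -> Molecule:
    order_map = _rdkit_order_map()
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(make_atom(a.GetIdx(), a.GetSymbol(), (pos.x, pos.y, pos.z)))
    bonds = []
    for b in rdmol.GetBonds():
        order = order_map.get(b.GetBondType())
        if order is None:
            # dative/quadruple etc. never occur in V2000; treat as single
            order = "single"
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return Molecule(name or fallback_name, atoms, bonds)


def _read_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for k, rd in enumerate(supplier):
        if rd is None:
            raise SolvContactError(f"{path}: unparseable SDF record {k}")
        mols.append(_from_rdkit(rd, f"{path.stem}_{k}"))
    return mols


def _read_mol2(path: Path) -> list[Molecule]:
    from rdkit import Chem

    text = path.read_text()
    blocks = []
    marker = "@<TRIPOS>MOLECULE"
    idx = [k for k in range(len(text)) if text.startswith(marker, k)]
    for start, end in zip(idx, idx[1:] + [len(text)]):
        blocks.append(text[start:end])
    mols = []
    for k, block in enumerate(blocks):
        rd = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
        if rd is None:
            raise SolvContactError(f"{path}: unparseable MOL2 record {k}")
        mols.append(_from_rdkit(rd, f"{path.stem}_{k}"))
    return mols


def _read_xyz(path: Path) -> list[Molecule]:
    lines = path.read_text().splitlines()
    mols = []
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].split()[0])
        comment = lines[pos + 1].strip() if pos + 1 < len(lines) else ""
        elements, xyz = [], []
        for ln in lines[pos + 2 : pos + 2 + n]:
            parts = ln.split()
            elements.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        xyz = np.asarray(xyz)
        atoms = [make_atom(i, e, xyz[i]) for i, e in enumerate(elements)]
        bonds = infer_bonds(elements, xyz)
        mols.append(Molecule(comment or f"{path.stem}_{rec}", atoms, bonds))
        pos += 2 + n
        rec += 1
    return mols


_PDB_ELEMENT_FIX = {"CL": "Cl", "BR": "Br"}


def _read_pdb(path: Path) -> list[Molecule]:
    elements, xyz = [], []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        elem = line[76:78].strip() if len(line) >= 78 else ""
        if not elem:
            elem = line[12:16].strip().rstrip("0123456789")
        elem = _PDB_ELEMENT_FIX.get(elem.upper(), elem.capitalize())
        if len(elem) == 1:
            elem = elem.upper()
        elements.append(elem)
        xyz.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not elements:
        return []
    xyz = np.asarray(xyz)
    atoms = [make_atom(i, e, xyz[i]) for i, e in enumerate(elements)]
    return [Molecule(path.stem, atoms, infer_bonds(elements, xyz))]


_READERS = {"sdf": _read_sdf, "mol": _read_sdf, "mol2": _read_mol2,
            "xyz": _read_xyz, "pdb": _read_pdb}


def read_structures(path, fmt: Optional[str] = None) -> list[Molecule]:
    """Read molecules from SDF, MOL2, XYZ or PDB.

    Atom order is preserved from the file; multi-record files yield one
    Molecule per record.  XYZ/PDB bonds are inferred from interatomic
    distances.  An empty file returns an empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _READERS:
        raise SolvContactError(f"unknown structure format {fmt!r}")
    if path.stat().st_size == 0 or not path.read_text().strip():
        log.warning("%s: empty structure file", path)
        return []
    mols = _READERS[fmt](path)
    for m in mols:
        for w in m.warnings:
            warnings.warn(f"{m.name}: {w}", stacklevel=2)
    return mols


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_sdf(molecules: list[Molecule], path,
              atom_tags: Optional[dict[str, list[list]]] = None) -> None:
    """Write an SDF (V2000).  `atom_tags` maps tag name -> per-molecule
    per-atom values, serialized one atom per line as an SD data field."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rev = {"single": Chem.BondType.SINGLE, "double": Chem.BondType.DOUBLE,
           "triple": Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mi, mol in enumerate(molecules):
            rw = Chem.RWMol()
            for a in mol.atoms:
                ra = Chem.Atom(a.element)
                ra.SetNoImplicit(True)
                rw.AddAtom(ra)
            for b in mol.bonds:
                rw.AddBond(b.i, b.j, rev[b.order])
            conf = Chem.Conformer(mol.n_atoms)
            for k, a in enumerate(mol.atoms):
                conf.SetAtomPosition(k, Point3D(*a.coords))
            rw.AddConformer(conf)
            out = rw.GetMol()
            out.SetProp("_Name", mol.name)
            if mol.exp_dg is not None:
                out.SetProp("dg_exp_kcal_mol", f"{mol.exp_dg:.4f}")
            if atom_tags:
                for tag, values in atom_tags.items():
                    lines = "\n".join(str(v) for v in values[mi])
                    out.SetProp(tag, lines)
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# van der Waals molecular volume
# ---------------------------------------------------------------------------

class VolumeResult(NamedTuple):
    """Sphere-union volume in cubic angstrom; stderr is None for grid."""

    value: float
    stderr: Optional[float]


def vdw_volume(mol: Molecule, method: str = "montecarlo",
               n_samples: int = 200_000, spacing: float = 0.2,
               seed: Optional[int] = None) -> VolumeResult:
    """Volume of the union of Bondi spheres.

    montecarlo: uniform rejection sampling over the padded bounding box
    (requires a seed; reports the binomial standard error).
    grid: deterministic occupancy count on a regular grid with the given
    spacing (default 0.2 angstrom).
    """
    if mol.n_atoms == 0:
        raise SolvContactError("vdw_volume of an empty molecule")
    centers = mol.coords
    radii = np.array([a.vdw_radius for a in mol.atoms])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)

    if method == "montecarlo":
        if seed is None:
            raise SolvContactError("montecarlo volume requires a seed")
        rng = np.random.default_rng(seed)
        box_vol = float(np.prod(hi - lo))
        inside = 0
        remaining = int(n_samples)
        while remaining > 0:
            chunk = min(remaining, 100_000)
            pts = rng.uniform(lo, hi, size=(chunk, 3))
            d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            inside += int((d2 <= radii[None, :] ** 2).any(axis=1).sum())
            remaining -= chunk
        p = inside / n_samples
        value = box_vol * p
        stderr = box_vol * float(np.sqrt(p * (1.0 - p) / n_samples))
        return VolumeResult(value, stderr)

    if method == "grid":
        axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        occupied = np.zeros(len(pts), dtype=bool)
        for c, r in zip(centers, radii):
            occupied |= ((pts - c) ** 2).sum(axis=1) <= r * r
        return VolumeResult(float(occupied.sum()) * spacing ** 3, None)

    raise SolvContactError(f"unknown volume method {method!r}")


def sphere_volumes(mol: Molecule) -> np.ndarray:
    """Isolated-atom Bondi sphere volumes (4/3) pi r^3, per atom."""
    radii = np.array([a.vdw_radius for a in mol.atoms])
    return (4.0 / 3.0) * np.pi * radii ** 3
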