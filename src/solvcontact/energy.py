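"""The solvent-contact hydration free energy function.

For a solute with atoms i, the model reads

    dG_hyd = sum_i S_i * ( O_i_max - sum_{j != i} V_j * exp(-r_ij^2 / (2 sigma^2)) )

where S_i is the atomic solvation parameter of atom i's type (kcal/mol
per cubic angstrom), O_i_max its maximum atomic occupancy (cubic
angstrom), V_j the fragmental volume of neighbor j (cubic angstrom), and
r_ij the interatomic distance.  The Gaussian envelope (width sigma,
default 3.5 angstrom) measures how much of atom i's solvation shell is
occluded by the rest of the molecule; the bracket is the volume left
accessible to water.  All atoms, hydrogens included, contribute as
occluding neighbors.

The envelope decays with distance.  (A typeset form with a positive
exponent would diverge as neighbors recede and could not define an
occupied volume; the decaying Gaussian is the form of the underlying
solvent-contact model.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .atomtypes import AtomTypeAssignment
from .chem import Molecule
from .errors import ConsistencyError, ParameterCoverageError, SolvContactError
from .params import TypeParameterTable


@dataclass(frozen=True)
class EnergyConfig:
    """Settings of the energy function.

    sigma: Gaussian envelope width in angstrom.
    clamp_occupancy: if set, the accessible volume (O_max - occupied) is
        floored at zero instead of being allowed to go negative.
    neighbor_cutoff: optional distance cutoff (angstrom) beyond which
        neighbor contributions are skipped; None evaluates the full
        double loop.  With a cutoff >= 8 sigma the truncation error is
        below 1e-8 of V_j per pair.
    """

    sigma: float = 3.5
    clamp_occupancy: bool = False
    neighbor_cutoff: Optional[float] = None

    def __post_init__(self):
        if not self.sigma > 0:
            raise SolvContactError("sigma must be positive")


@dataclass
class AtomVolumes:
    """Per-atom fragmental volumes V (cubic angstrom), in atom order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SolvContactError("AtomVolumes must be one-dimensional")
        if not np.all(self.values > 0):
            raise SolvContactError("all fragmental volumes must be positive")

    def __len__(self) -> int:
        return len(self.values)


def _check_aligned(mol: Molecule, volumes: AtomVolumes) -> None:
    if len(volumes) != mol.n_atoms:
        raise ConsistencyError(
            f"{mol.name}: {len(volumes)} volumes for {mol.n_atoms} atoms"
        )


def occupied_volumes(mol: Molecule, volumes: AtomVolumes,
                     cfg: EnergyConfig = EnergyConfig()) -> np.ndarray:
    """Occluded volume around every atom: sum_j V_j exp(-r_ij^2/(2 sigma^2))."""
    _check_aligned(mol, volumes)
    xyz = mol.coords
    if not np.all(np.isfinite(xyz)):
        raise SolvContactError(f"{mol.name}: non-finite coordinates")
    if mol.n_atoms == 1:
        return np.zeros(1)
    diff = xyz[:, None, :] - xyz[None, :, :]
    r2 = (diff ** 2).sum(axis=2)
    w = np.exp(-r2 / (2.0 * cfg.sigma ** 2))
    np.fill_diagonal(w, 0.0)
    if cfg.neighbor_cutoff is not None:
        w[r2 > cfg.neighbor_cutoff ** 2] = 0.0
    return w @ volumes.values


def occupied_volume(mol: Molecule, volumes: AtomVolumes, i: int,
                    cfg: EnergyConfig = EnergyConfig()) -> float:
    """Occluded volume around atom i (cubic angstrom)."""
    if not 0 <= i < mol.n_atoms:
        raise IndexError(f"atom index {i} out of range")
    return float(occupied_volumes(mol, volumes, cfg)[i])


@dataclass
class EnergyBreakdown:
    """Total dG_hyd plus the per-atom contributions that sum to it."""

    total: float                    # kcal/mol
    per_atom: np.ndarray            # kcal/mol, one entry per atom
    occupied: np.ndarray            # cubic angstrom, per atom


def hydration_free_energy(mol: Molecule, assignment: AtomTypeAssignment,
                          table: TypeParameterTable, volumes: AtomVolumes,
                          cfg: EnergyConfig = EnergyConfig()) -> EnergyBreakdown:
    """Evaluate the solvent-contact energy for one molecule (kcal/mol)."""
    _check_aligned(mol, volumes)
    if len(assignment.final_types) != mol.n_atoms:
        raise ConsistencyError(
            f"{mol.name}: assignment covers {len(assignment.final_types)} atoms"
        )
    for code in assignment.final_types:
        if code not in table:
            raise ParameterCoverageError(code, table.scheme)
    occ = occupied_volumes(mol, volumes, cfg)
    s = np.array([table.entries[c].S for c in assignment.final_types])
    o_max = np.array([table.entries[c].O_max for c in assignment.final_types])
    accessible = o_max - occ
    if cfg.clamp_occupancy:
        accessible = np.maximum(accessible, 0.0)
    per_atom = s * accessible
    return EnergyBreakdown(float(per_atom.sum()), per_atom, occ)
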