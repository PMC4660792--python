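"""End-to-end prediction: structures in, hydration free energies out.

Chains the pieces together: atom typing, intramolecular hydrogen bond
detection and retyping, per-atom fragmental volumes, and the
solvent-contact energy under a chosen parameter table.

When no fitted fragmental volumes are supplied, each atom gets its Bondi
sphere volume rescaled proportionally so that the per-molecule sum equals
the molecule's van der Waals (sphere-union) volume — the same sum
constraint the volume-fitting stage enforces, without requiring training
data.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atomtypes import AtomTypeAssignment, assign_atom_types
from .chem import Molecule, sphere_volumes, vdw_volume
from .energy import AtomVolumes, EnergyBreakdown, EnergyConfig, hydration_free_energy
from .ihb import detect_ihb, retype_for_ihb
from .params import TypeParameterTable, load_table


def default_atom_volumes(mol: Molecule, method: str = "grid",
                         seed: Optional[int] = None,
                         spacing: float = 0.2) -> AtomVolumes:
    """Bondi sphere volumes rescaled so their sum is the molecular volume."""
    spheres = sphere_volumes(mol)
    total = vdw_volume(mol, method, seed=seed, spacing=spacing).value
    return AtomVolumes(spheres * (total / spheres.sum()))


def prepare_assignment(mol: Molecule, scheme: str = "FSD",
                       use_ihb: bool = True,
                       cutoff: float = 2.5) -> AtomTypeAssignment:
    """Type a molecule, optionally retyping IHB participants."""
    assignment = assign_atom_types(mol, scheme)
    if use_ihb:
        contacts = detect_ihb(mol, cutoff=cutoff)
        if contacts:
            assignment = retype_for_ihb(assignment, contacts, scheme)
    return assignment


def predict_hydration(molecules: Sequence[Molecule], scheme: str = "FSD",
                      table: Optional[TypeParameterTable] = None,
                      cfg: EnergyConfig = EnergyConfig(),
                      use_ihb: bool = True,
                      volumes: Optional[Sequence[AtomVolumes]] = None,
                      ) -> tuple[pd.DataFrame, list[EnergyBreakdown]]:
    """Predict dG_hyd (kcal/mol) for a batch of molecules.

    Returns a per-molecule summary frame (name, n_atoms, n_ihb_contacts,
    dg_calc, and dg_exp where labels are present) plus the per-atom
    energy breakdowns.
    """
    if table is None:
        table = load_table(scheme)
    rows, breakdowns = [], []
    for k, mol in enumerate(molecules):
        contacts = detect_ihb(mol) if use_ihb else []
        assignment = assign_atom_types(mol, scheme)
        if contacts:
            assignment = retype_for_ihb(assignment, contacts, scheme)
        v = volumes[k] if volumes is not None else default_atom_volumes(mol)
        bd = hydration_free_energy(mol, assignment, table, v, cfg)
        rows.append({
            "name": mol.name,
            "n_atoms": mol.n_atoms,
            "n_ihb_contacts": len(contacts),
            "dg_calc": bd.total,
            "dg_exp": mol.exp_dg if mol.exp_dg is not None else np.nan,
        })
        breakdowns.append(bd)
    return pd.DataFrame(rows), breakdowns
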