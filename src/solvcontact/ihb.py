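"""Geometric detection of intramolecular hydrogen bonds (IHBs).

An IHB here is a purely distance-defined contact: a hydrogen and a polar
acceptor atom (N, O, F or Cl by default) of the same molecule closer than
2.5 angstrom, not covalently bonded to each other, and at least three
bonds apart along the shortest through-bond path (which excludes geminal
and vicinal pairs that are trivially close).  Participating atoms are
retyped to the ``*.intra`` codes where the active scheme defines them:
H.intra always, O.intra/F.intra/Cl.intra for acceptors.  Nitrogen
acceptors keep their base type — no N.intra code exists.

An optional donor-H...acceptor angle filter is available but off by
default; the model's published criterion is distance-only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .atomtypes import AtomTypeAssignment
from .chem import Molecule
from .errors import ConsistencyError
from .params import TypeParameterTable, load_table

DEFAULT_CUTOFF = 2.5           # angstrom, strict (< cutoff)
DEFAULT_ACCEPTORS = frozenset({"N", "O", "F", "Cl"})
DEFAULT_MIN_PATH = 3           # bonds

_ACCEPTOR_INTRA = {"O": "O.intra", "F": "F.intra", "Cl": "Cl.intra"}


@dataclass(frozen=True)
class HBondContact:
    """One detected H...acceptor contact."""

    h_index: int
    acceptor_index: int
    distance: float       # angstrom
    path_length: int      # bonds along the shortest through-bond path


def detect_ihb(mol: Molecule, cutoff: float = DEFAULT_CUTOFF,
               acceptors: frozenset[str] | set[str] = DEFAULT_ACCEPTORS,
               min_path: int = DEFAULT_MIN_PATH,
               min_angle_deg: float | None = None) -> list[HBondContact]:
    """All H...acceptor contacts strictly closer than `cutoff`.

    Pairs covalently bonded to each other or fewer than `min_path` bonds
    apart are excluded.  Contacts are returned sorted by distance (ties by
    atom indices), so detection is deterministic.  If `min_angle_deg` is
    given, contacts whose donor-H...acceptor angle falls below it are
    dropped.
    """
    h_indices = [a.index for a in mol.atoms if a.element == "H"]
    if not h_indices:
        warnings.warn(f"{mol.name}: no hydrogens, no IHB possible", stacklevel=2)
        return []
    acc_indices = [a.index for a in mol.atoms if a.element in acceptors]
    if not acc_indices:
        return []

    g = mol.graph()
    xyz = mol.coords
    contacts = []
    for h in h_indices:
        lengths = nx.single_source_shortest_path_length(g, h)
        for a in acc_indices:
            if a == h or mol.bond_between(h, a) is not None:
                continue
            path_len = lengths.get(a, 10 ** 9)  # disconnected -> unbounded
            if path_len < min_path:
                continue
            d = float(np.linalg.norm(xyz[h] - xyz[a]))
            if not d < cutoff:
                continue
            if min_angle_deg is not None:
                donors = [j for j in mol.neighbors(h)]
                if donors:
                    dv = xyz[donors[0]] - xyz[h]
                    av = xyz[a] - xyz[h]
                    cosang = float(dv @ av / (np.linalg.norm(dv) * np.linalg.norm(av)))
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle < min_angle_deg:
                        continue
            contacts.append(HBondContact(h, a, d, path_len))
    contacts.sort(key=lambda c: (c.distance, c.h_index, c.acceptor_index))
    return contacts


def retype_for_ihb(assignment: AtomTypeAssignment,
                   contacts: list[HBondContact],
                   scheme: str | TypeParameterTable | None = None) -> AtomTypeAssignment:
    """Retype IHB participants to the scheme's ``*.intra`` codes.

    Base types are preserved; the returned assignment carries updated
    final types.  Idempotent: retyping an already-retyped assignment is a
    no-op.
    """
    if scheme is None:
        scheme = assignment.scheme
    table = scheme if isinstance(scheme, TypeParameterTable) else load_table(scheme)

    n = len(assignment.base_types)
    final = list(assignment.final_types)
    for c in contacts:
        if not (0 <= c.h_index < n and 0 <= c.acceptor_index < n):
            raise ConsistencyError(
                f"contact {c.h_index}-{c.acceptor_index} outside assignment "
                f"for {assignment.mol_name} ({n} atoms)"
            )
        final[c.h_index] = "H.intra"
        acc_base = assignment.base_types[c.acceptor_index]
        element = acc_base.split(".")[0]
        intra = _ACCEPTOR_INTRA.get(element)
        if intra is None:
            continue  # e.g. nitrogen acceptors: no *.intra code defined
        if intra in table:
            final[c.acceptor_index] = intra
        else:
            warnings.warn(
                f"{assignment.mol_name}: acceptor atom {c.acceptor_index} "
                f"({element}) has no {intra} code in scheme {table.scheme}; "
                "keeping base type", stacklevel=2,
            )
    return replace(assignment, final_types=final)
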