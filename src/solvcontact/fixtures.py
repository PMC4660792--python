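"""Deterministic synthetic molecules and labeled training sets.

Everything the test and fitting machinery needs can be generated here:
idealized chain molecules (standard bond lengths, tetrahedral angles,
explicit hydrogens), a planar enol/carbonyl fragment whose hydroxyl
hydrogen is placed at an exact requested distance from the carbonyl
oxygen (the classic intramolecular-hydrogen-bond motif), and labeled
training sets whose hydration free energies come from a known
ground-truth parameter table plus optional Gaussian noise.

Idealized geometry is sufficient because the energy model depends only
on interatomic distances and graph-derived atom types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atomtypes import assign_atom_types
from .chem import Atom, Bond, Molecule, bondi_radii, covalent_radii, make_atom
from .energy import AtomVolumes, EnergyConfig, hydration_free_energy
from .errors import SolvContactError
from .fitting import TrainingSet
from .ihb import detect_ihb, retype_for_ihb
from .params import TypeParameterTable, load_table

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}

_BOND_LENGTHS = {("C", "C"): 1.54, ("C", "O"): 1.43, ("C", "N"): 1.47,
                 ("C", "S"): 1.81, ("C", "H"): 1.09, ("O", "H"): 0.96,
                 ("N", "H"): 1.01, ("S", "H"): 1.34}


def _bond_length(a: str, b: str) -> float:
    key = (a, b) if (a, b) in _BOND_LENGTHS else (b, a)
    if key in _BOND_LENGTHS:
        return _BOND_LENGTHS[key]
    cov = covalent_radii()
    return cov[a] + cov[b]


def _fibonacci_directions(n: int = 60) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


_H_CANDIDATES = _fibonacci_directions()


def _best_direction(coords, k, occupied, length):
    """Candidate direction from atom k maximizing the smaller of the
    angular separation from existing bonds (radians) and the clearance
    from all other atoms (angstrom) — a crude but deterministic blend
    that avoids both eclipsed bonds and steric clashes."""
    others = np.array([c for j, c in enumerate(coords) if j != k]) \
        if len(coords) > 1 else None
    best, best_score = None, -np.inf
    for cand in _H_CANDIDATES:
        ang = min((float(np.arccos(np.clip(cand @ o, -1, 1)))
                   for o in occupied), default=np.pi)
        pos = coords[k] + length * cand
        clearance = (float(np.linalg.norm(others - pos, axis=1).min())
                     if others is not None else np.inf)
        score = min(ang, clearance)
        if score > best_score:
            best_score, best = score, cand
    return best


def make_chain_molecule(n_heavy: int, elements: list[str] | None = None,
                        seed: int = 0, name: str | None = None) -> Molecule:
    """A chemically plausible single-bonded chain with hydrogens filled in.

    Heavy atoms zig-zag with tetrahedral angles and standard bond
    lengths; each heavy atom is saturated with hydrogens to its valence.
    Hydrogen directions are chosen greedily to maximize separation from
    existing neighbors.  A small seeded coordinate jitter (<= 0.01 A)
    makes distinct seeds distinguishable while keeping the geometry
    essentially ideal.
    """
    if n_heavy < 1:
        raise SolvContactError("n_heavy must be >= 1")
    if elements is None:
        elements = ["C"] * n_heavy
    if len(elements) != n_heavy:
        raise SolvContactError("elements length must equal n_heavy")
    for e in elements:
        if e not in _VALENCE:
            raise SolvContactError(f"unsupported chain element {e!r}")

    half = np.deg2rad(109.47 / 2.0)
    up = np.array([np.sin(half), 0.0, np.cos(half)])
    down = np.array([np.sin(half), 0.0, -np.cos(half)])

    heavy_xyz = [np.zeros(3)]
    for k in range(1, n_heavy):
        step = up if k % 2 else down
        length = _bond_length(elements[k - 1], elements[k])
        heavy_xyz.append(heavy_xyz[-1] + length * step)

    coords: list[np.ndarray] = list(heavy_xyz)
    symbols: list[str] = list(elements)
    bonds = [Bond(k - 1, k, "single") for k in range(1, n_heavy)]

    for k in range(n_heavy):
        n_h = _VALENCE[elements[k]] - sum(1 for b in bonds if k in (b.i, b.j)
                                          and b.key[0] < n_heavy and b.key[1] < n_heavy)
        occupied = []
        for b in bonds:
            if k in (b.i, b.j):
                other = b.j if b.i == k else b.i
                v = coords[other] - coords[k]
                occupied.append(v / np.linalg.norm(v))
        length = _bond_length(elements[k], "H")
        for _ in range(max(n_h, 0)):
            direction = _best_direction(coords, k, occupied, length)
            pos = coords[k] + length * direction
            idx = len(coords)
            coords.append(pos)
            symbols.append("H")
            bonds.append(Bond(k, idx, "single"))
            occupied.append(direction)

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.01, 0.01, size=(len(coords), 3))
    atoms = [make_atom(i, s, np.asarray(c) + jitter[i])
             for i, (s, c) in enumerate(zip(symbols, coords))]
    return Molecule(name or f"chain_{''.join(elements)}_{seed}", atoms, bonds)


# ---------------------------------------------------------------------------
# intramolecular hydrogen bond fixture
# ---------------------------------------------------------------------------

def make_ihb_fixture(h_acceptor_distance: float, seed: int = 0) -> Molecule:
    """Planar enol/carbonyl fragment with a tunable H...O=C distance.

    The fragment is HO-C=C-CHO (a malonaldehyde-type enol).  The hydroxyl
    hydrogen is placed on its 0.96 A bonding circle around the hydroxyl
    oxygen at exactly the requested distance from the carbonyl oxygen;
    the through-bond path between them is 5 bonds.  Geometry is
    deterministic; `seed` is accepted for interface uniformity.
    """
    if h_acceptor_distance < 0.5:
        raise SolvContactError("requested H...acceptor distance is infeasible")

    deg = np.deg2rad
    c1 = np.array([0.0, 0.0])
    c2 = np.array([1.34, 0.0])
    o1 = c1 + 1.36 * np.array([np.cos(deg(120)), np.sin(deg(120))])
    h1 = c1 + 1.08 * np.array([np.cos(deg(240)), np.sin(deg(240))])
    c3 = c2 + 1.45 * np.array([np.cos(deg(60)), np.sin(deg(60))])
    h2 = c2 + 1.08 * np.array([np.cos(deg(-60)), np.sin(deg(-60))])
    o2 = c3 + 1.22 * np.array([np.cos(deg(120)), np.sin(deg(120))])
    h3 = c3 + 1.08 * np.array([1.0, 0.0])

    # hydroxyl H: intersection of the O1 bonding circle (r1 = 0.96) with
    # the circle of the requested radius around O2
    r1, r2 = 0.96, float(h_acceptor_distance)
    d = float(np.linalg.norm(o2 - o1))
    if not abs(r1 - r2) < d < r1 + r2:
        raise SolvContactError(
            f"H...O distance {r2:.2f} A is unreachable on the hydroxyl "
            f"bonding circle (O...O separation {d:.2f} A)"
        )
    ex = (o2 - o1) / d
    ey = np.array([-ex[1], ex[0]])
    a = (r1 * r1 - r2 * r2 + d * d) / (2.0 * d)
    h = float(np.sqrt(max(r1 * r1 - a * a, 0.0)))
    candidates = [o1 + a * ex + h * ey, o1 + a * ex - h * ey]
    centroid = (c1 + c2 + c3 + o1 + o2) / 5.0
    h_oh = min(candidates, key=lambda p: float(np.linalg.norm(p - centroid)))

    xy = [o1, c1, c2, c3, o2, h_oh, h1, h2, h3]
    symbols = ["O", "C", "C", "C", "O", "H", "H", "H", "H"]
    atoms = [make_atom(i, s, (p[0], p[1], 0.0))
             for i, (s, p) in enumerate(zip(symbols, xy))]
    bonds = [Bond(0, 1, "single"), Bond(1, 2, "double"), Bond(2, 3, "single"),
             Bond(3, 4, "double"), Bond(0, 5, "single"), Bond(1, 6, "single"),
             Bond(2, 7, "single"), Bond(3, 8, "single")]
    return Molecule(f"enol_ihb_{h_acceptor_distance:.2f}", atoms, bonds)


# ---------------------------------------------------------------------------
# labeled training sets with known ground truth
# ---------------------------------------------------------------------------

def make_alkane_tree(n_heavy: int, seed: int = 0,
                     name: str | None = None) -> Molecule:
    """A random branched alkane with idealized geometry.

    Carbons are attached one by one to a randomly chosen carbon that
    still has at most two heavy neighbors (so no quaternary centers
    arise), in the direction that maximizes clearance from the existing
    atoms; hydrogens then fill every carbon to valence four.  Alkanes
    carry no hydrogen-bond acceptors, so the generated set is free of
    intramolecular hydrogen bonds by construction.
    """
    if n_heavy < 1:
        raise SolvContactError("n_heavy must be >= 1")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = [np.zeros(3)]
    heavy_nbrs: list[list[int]] = [[]]
    bonds: list[Bond] = []
    for _ in range(1, n_heavy):
        open_sites = [k for k, nb in enumerate(heavy_nbrs) if len(nb) <= 2]
        k = int(rng.choice(open_sites))
        occupied = [(coords[j] - coords[k]) / np.linalg.norm(coords[j] - coords[k])
                    for j in heavy_nbrs[k]]
        best, best_score = None, -np.inf
        for cand in _H_CANDIDATES:
            pos = coords[k] + 1.54 * cand
            ang = min((float(np.arccos(np.clip(cand @ o, -1, 1)))
                       for o in occupied), default=np.pi)
            clearance = min((float(np.linalg.norm(pos - c))
                             for j, c in enumerate(coords) if j != k),
                            default=np.inf)
            score = min(ang, clearance)
            if score > best_score:
                best_score, best = score, pos
        idx = len(coords)
        coords.append(best)
        heavy_nbrs[k].append(idx)
        heavy_nbrs.append([k])
        bonds.append(Bond(k, idx, "single"))

    symbols = ["C"] * n_heavy
    for k in range(n_heavy):
        occupied = [(coords[j] - coords[k]) / np.linalg.norm(coords[j] - coords[k])
                    for j in heavy_nbrs[k]]
        for _ in range(4 - len(heavy_nbrs[k])):
            direction = _best_direction(coords, k, occupied, 1.09)
            idx = len(coords)
            coords.append(coords[k] + 1.09 * direction)
            symbols.append("H")
            bonds.append(Bond(k, idx, "single"))
            occupied.append(direction)

    jitter = rng.uniform(-0.01, 0.01, size=(len(coords), 3))
    atoms = [make_atom(i, s, np.asarray(c) + jitter[i])
             for i, (s, c) in enumerate(zip(symbols, coords))]
    return Molecule(name or f"alkane_{n_heavy}_{seed}", atoms, bonds)


#: ground-truth fragmental volumes (cubic angstrom) for the default
#: 4-type synthetic universe (branched alkanes)
DEFAULT_TRUTH_VOLUMES = {"C.3_1": 20.0, "C.3_2": 17.0, "C.3_3": 14.0, "H.C": 7.0}


def default_truth_table() -> TypeParameterTable:
    """Ground truth for recovery experiments: the published FSD values of
    the four types realized by branched alkanes."""
    fsd = load_table("FSD")
    codes = sorted(DEFAULT_TRUTH_VOLUMES)
    return TypeParameterTable(
        "truth",
        {c: fsd.entries[c] for c in codes},
        provenance="published FSD values restricted to the alkane-universe types",
    )


@dataclass
class LabeledTrainingSet:
    """A TrainingSet plus the ground truth that generated its labels."""

    train: TrainingSet
    truth_table: TypeParameterTable
    truth_volumes: dict[str, float]
    noise_sd: float
    seed: int


def make_labeled_training_set(n_molecules: int = 30,
                              truth_table: TypeParameterTable | None = None,
                              truth_volumes: dict[str, float] | None = None,
                              noise_sd: float = 0.0, seed: int = 0,
                              cfg: EnergyConfig = EnergyConfig(),
                              scheme: str = "FSD") -> LabeledTrainingSet:
    """Generate labeled branched alkanes from ground-truth parameters.

    Molecules are random branched alkanes (3-8 heavy atoms), realizing
    exactly the four atom types C.3_1, C.3_2, C.3_3 and H.C.  Labels are
    the solvent-contact energy under the truth parameters plus
    N(0, noise_sd) noise.  The full typing pipeline — including IHB
    detection — runs on every generated molecule, so the labels are
    exactly what prediction under the truth parameters reproduces.
    """
    if truth_table is None:
        truth_table = default_truth_table()
    if truth_volumes is None:
        truth_volumes = dict(DEFAULT_TRUTH_VOLUMES)

    rng = np.random.default_rng(seed)
    molecules, assignments, volumes = [], [], []
    for k in range(n_molecules):
        n_heavy = int(rng.integers(3, 9))
        mol = make_alkane_tree(n_heavy, seed=int(rng.integers(0, 2 ** 31)),
                               name=f"synth_{k:03d}")
        assignment = assign_atom_types(mol, scheme)
        contacts = detect_ihb(mol)
        if contacts:
            assignment = retype_for_ihb(assignment, contacts, scheme)
        missing = [c for c in assignment.final_types if c not in truth_table]
        if missing:
            raise SolvContactError(
                f"{mol.name}: generated type {missing[0]!r} not covered by "
                "the truth table"
            )
        v = AtomVolumes(np.array([truth_volumes[c]
                                  for c in assignment.final_types]))
        dg = hydration_free_energy(mol, assignment, truth_table, v, cfg).total
        if noise_sd > 0:
            dg += float(rng.normal(0.0, noise_sd))
        mol.exp_dg = float(dg)
        molecules.append(mol)
        assignments.append(assignment)
        volumes.append(v)

    train = TrainingSet(molecules, assignments, volumes)
    return LabeledTrainingSet(train, truth_table, dict(truth_volumes),
                              noise_sd, seed)


def truth_molecular_volumes(labeled: LabeledTrainingSet) -> np.ndarray:
    """Exact per-molecule sums of the ground-truth atomic volumes."""
    return np.array([float(v.values.sum()) for v in labeled.train.volumes])


# ---------------------------------------------------------------------------
# volume-recovery universe
# ---------------------------------------------------------------------------

#: ground-truth fragmental volumes for the perhalocarbon universe
HALO_TRUTH_VOLUMES = {"C.3_4": 10.0, "F": 9.0, "Cl": 17.0}


def make_halocarbon_chain(n_carbons: int, seed: int = 0,
                          name: str | None = None) -> Molecule:
    """A perhalogenated alkane chain (every carbon fully F/Cl substituted).

    Such molecules carry no hydrogens, so the per-molecule atom-type
    count vectors of the three realized types (C.3_4, F, Cl) are linearly
    independent across a varied set — which makes per-type fragmental
    volumes identifiable from molecular-volume sums.  (In any
    hydrogen-containing universe they are not: every type code fixes its
    hydrogen count, so hydrogen-type counts are exact linear combinations
    of heavy-type counts.)
    """
    if n_carbons < 1:
        raise SolvContactError("n_carbons must be >= 1")
    rng = np.random.default_rng(seed)
    half = np.deg2rad(109.47 / 2.0)
    up = np.array([np.sin(half), 0.0, np.cos(half)])
    down = np.array([np.sin(half), 0.0, -np.cos(half)])

    coords = [np.zeros(3)]
    for k in range(1, n_carbons):
        coords.append(coords[-1] + 1.54 * (up if k % 2 else down))
    symbols = ["C"] * n_carbons
    bonds = [Bond(k - 1, k, "single") for k in range(1, n_carbons)]
    halo_length = {"F": 1.35, "Cl": 1.77}

    for k in range(n_carbons):
        occupied = []
        for b in list(bonds):
            if k in (b.i, b.j):
                other = b.j if b.i == k else b.i
                v = coords[other] - coords[k]
                occupied.append(v / np.linalg.norm(v))
        n_x = 4 - len(occupied)
        for _ in range(n_x):
            halogen = "F" if rng.random() < 0.5 else "Cl"
            direction = _best_direction(coords, k, occupied,
                                        halo_length[halogen])
            idx = len(coords)
            coords.append(coords[k] + halo_length[halogen] * direction)
            symbols.append(halogen)
            bonds.append(Bond(k, idx, "single"))
            occupied.append(direction)

    atoms = [make_atom(i, s, c) for i, (s, c) in enumerate(zip(symbols, coords))]
    return Molecule(name or f"halo_{n_carbons}_{seed}", atoms, bonds)


def make_volume_recovery_set(n_molecules: int = 30, seed: int = 0,
                             truth_volumes: dict[str, float] | None = None,
                             scheme: str = "FSD"):
    """Perhalocarbon molecules with exact-sum molecular-volume targets.

    Returns (molecules, assignments, targets, truth_volumes) where each
    target is exactly the sum of the ground-truth per-type volumes over
    the molecule's atoms — the construction under which a volume fit can
    be checked against a known answer.
    """
    if truth_volumes is None:
        truth_volumes = dict(HALO_TRUTH_VOLUMES)
    rng = np.random.default_rng(seed)
    molecules, assignments, targets = [], [], []
    for k in range(n_molecules):
        n_c = int(rng.integers(1, 7))
        mol = make_halocarbon_chain(n_c, seed=int(rng.integers(0, 2 ** 31)),
                                    name=f"halo_{k:03d}")
        a = assign_atom_types(mol, scheme)
        targets.append(sum(truth_volumes[c] for c in a.final_types))
        molecules.append(mol)
        assignments.append(a)
    return molecules, assignments, np.array(targets), dict(truth_volumes)
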