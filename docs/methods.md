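# Methods

## The model

`solvcontact` implements an additive solvent-contact estimate of the
hydration free energy of a rigid 3-D solute conformer:

    ΔG_hyd = Σ_i S_i · ( O_i^max − Σ_{j≠i} V_j · exp(−r_ij² / 2σ²) )

Each atom i has a *maximum atomic occupancy* `O_i^max` (Å³), the solvation
volume available to water around a fully exposed atom of its type. The
inner sum is the part of that shell occluded by the rest of the molecule:
every other atom j contributes its *fragmental volume* `V_j` (Å³) damped by
a Gaussian of its distance. The accessible remainder is converted to energy
by the per-type *atomic solvation parameter* `S_i` (kcal/mol·Å³): strongly
negative for hydrogen-bonding heteroatoms and their hydrogens, near zero or
positive for hydrocarbon atoms. The model is a sum over pairwise distances,
so it is exactly invariant under rigid motion and additive over fragments
separated by many σ (both asserted in the test suite).

Two conventions deserve emphasis:

* **Sign of the exponent.** The envelope is implemented as a *decaying*
  Gaussian, `exp(−r²/2σ²)`. A growing exponential could not define an
  occluded volume (it diverges as neighbors recede); the decaying form is
  the one used by solvent-contact models since their introduction.
* **σ is a free constant**, default 3.5 Å, configurable via
  `EnergyConfig(sigma=...)`. No published value is available for this
  parameterization; all shipped results state the σ they used. Absolute
  energies scale strongly with σ and with the V assignment, so predictions
  are comparable only within one (σ, V) calibration.

All atoms, hydrogens included, act as occluding neighbors. The accessible
volume `O_i^max − occupied` is *not* clamped at zero by default (the model
equation has no clamp); `EnergyConfig(clamp_occupancy=True)` floors it for
experimentation. An optional neighbor cutoff skips far pairs; at ≥ 8σ it is
indistinguishable from the full double loop at 10⁻⁸ kcal/mol (tested
against the brute-force evaluation).

## Atom typing

Types are assigned from the bond graph alone — element, hybridization,
aromaticity, functional context, substituent count — so typing is invariant
under rigid motion and atom relabeling. "Substituent" means non-hydrogen
neighbor throughout; this is what makes `O.3_1` (hydroxyl O) vs `O.3_2`
(ether O) consistent with the existence of a separate type for the hydroxyl
hydrogen. Functional-group rules fire before generic hybridization rules:
nitro > amide > carboxylic acid/ester > carbonyl > aromatic > generic.

Perception is deliberately minimal and deterministic. Hybridization comes
from bond orders (triple or two doubles → sp; any double or aromatic bond →
sp2; else sp3). Aromaticity follows the input file's aromatic flags when
present; otherwise ring-basis cycles of size 5–7 are tested with a Hückel
4n+2 count (one π electron per in-ring double bond, a lone pair for
pyrrole/furan/thiophene-type heteroatoms). This covers kekulized and
flagged aromatic inputs alike but does not attempt full aromaticity
perception for exotic fused systems. RDKit's perception machinery is *not*
used here: its valence sanitization rejects the neutral-form nitro,
hypervalent-sulfur and pentavalent-phosphorus groups (`N.no2`, `S.12`,
`P.10`) that the vocabulary requires.

Boundary decisions (each one line in the rules, all exercised by tests):
methane maps to `C.3_1` and formaldehyde's carbon to `C.CO_1` (no
0-substituent codes exist); carbonyl-carbon substituent counts exclude the
carbonyl oxygen; amide nitrogens take `N.am_n` under FSD and fall to the
planar codes `N.pl_n` under SAMPL4, which has no amide rows; phenolic and
aryl-ether oxygens take the planar codes `O.pl_1`/`O.pl_2` (and their H
`H.Op`) under SAMPL4 but the generic sp³ oxygen codes under FSD — the only
reading under which both schemes type phenols; sulfoxide sulfur and
trivalent phosphorus have no code in either scheme and raise a typing
error naming the atom and its environment.

## Intramolecular hydrogen bonds

A contact is an (H, acceptor) pair of the same molecule with distance
strictly below 2.5 Å, not covalently bonded, and at least 3 bonds apart
along the shortest through-bond path. The acceptor set is {N, O, F, Cl}.
The path-length floor excludes geminal/vicinal pairs that are trivially
close in any conformer; note that even 1,4 H···O pairs in gauche
arrangements sit at 2.1–2.5 Å in ideal tetrahedral geometry, so the
distance-only criterion is hair-trigger by design and conformer choice
matters. No angle criterion is applied by default (the definition is
distance-only); an optional donor–H···acceptor angle floor is available.

Participants are retyped: the hydrogen to `H.intra`, the acceptor to
`O.intra`/`F.intra`/`Cl.intra` where the active scheme defines that code
(SAMPL4 lacks `F.intra`/`Cl.intra`; a warning is emitted and the base type
kept). Nitrogen acceptors always keep their base type — no `N.intra`
exists. Retyping is idempotent and an atom in several contacts is retyped
once. Only the given conformer is analyzed; no conformational search.

## Fragmental volumes

The per-atom `V` values are tied to the molecular van der Waals volume, the
union of Bondi spheres, computed either by Monte Carlo rejection sampling
(default 200 000 points, seeded, with a binomial standard error) or on a
deterministic grid (default 0.2 Å spacing).

Fitting them is a two-stage procedure. Stage 1 searches one *base volume
per atom type* minimizing Σ_molecules |vdW volume − Σ_atoms V(type)|.
Stage 2 rescales the base volumes proportionally within each molecule so
the sum constraint holds exactly (to 10⁻⁶ Å³; tested); this is what lets
the same type carry different per-atom values in different molecules.
When no fit is wanted, the prediction pipeline defaults to Bondi sphere
volumes rescaled to the molecular vdW volume — the same sum constraint
without training data.

**Identifiability caveat.** Per-type base volumes are only identified when
the per-molecule type-count matrix has full column rank. In any
hydrogen-containing universe it cannot: each type code fixes its hydrogen
count (a `C.3_2` carbon always carries two H), so hydrogen-type count
columns are exact integer combinations of heavy-type columns (for alkanes,
n_H.C = 3·n_C.3_1 + 2·n_C.3_2 + n_C.3_3 identically). Only certain volume
combinations are then determined; the sum constraint and all predictions
remain well-defined. The recovery experiment therefore uses a constructed
perhalocarbon universe (types `C.3_4`, `F`, `Cl`, no hydrogens), where the
count matrix is full-rank and the generating volumes are recovered
essentially exactly.

## Parameter optimization

`(S, O_max)` pairs for every type realized in the training set are
optimized against experimental ΔG_hyd with an elitist genetic algorithm,
scored by the error hypersurface F_s = Σ_molecules |ΔG_exp − ΔG_calc|.
Defaults: population 100, the best 50 survive each generation; the other 50
are clones of survivors modified by per-element mutation (probability 0.01,
multiply by a factor uniform on [0.8, 1.2], clipped to bounds) and
single-point crossover (probability 0.6, partner uniform among the
offspring); parents and offspring then compete for the next top 50, so the
best fitness never increases (asserted on every run). Stopping: 2000
generations or 200 generations without improvement. Bounds: S ∈ [−20, 5]
kcal/mol·Å³, O_max ∈ [150, 600] Å³, V ∈ [0.5, 80] Å³, chosen to bracket the
published parameter ranges with wide margins. Initialization is uniform in
the box, or jittered around a supplied table. Runs are exactly
reproducible from `GAConfig.seed`. When mutation is enabled at all, each
offspring receives at least one mutated element — with short parameter
vectors the nominal 1% per-element rate would otherwise leave most
offspring as exact clones whose evaluations are wasted.

**Convex refinement.** The energy is bilinear in (S, O_max): predictions
are linear in S and in the product P = S·O_max, so in (S, P) coordinates
the L1 fitting problem is convex. Coordinate-wise multiplicative search
cannot exploit this and measurably plateaus at a few percent relative
error on ridge-shaped regions of the (S, O_max) surface. Both fitting
stages therefore end with a deterministic refinement started from the GA
optimum: iteratively reweighted least squares solves the convex L1 problem
(pinning S), and a bounded least squares back-solves an O_max vector within
bounds; the refined vector is accepted only if it improves F_s. The GA
still provides the global search and the box constraints; the refinement
removes the precision floor. On noiseless synthetic data the combination
recovers the generating predictions to ~10⁻¹² kcal/mol RMSE. When the
count matrix has collinear columns only the products are identified; any
feasible back-solution predicts identically, so recovered O_max values may
legitimately differ from the generating ones.

## Synthetic data

The generators produce everything the tests and recovery experiments need,
with idealized geometry (standard bond lengths, tetrahedral or trigonal
angles, greedy clash-avoiding hydrogen placement, ≤ 0.01 Å seeded jitter) —
sufficient because the model sees only distances and graph-derived types.

* `make_chain_molecule` — linear heavy-atom chains (C/N/O/S) with hydrogens
  filled to valence.
* `make_alkane_tree` — random branched alkanes without quaternary carbons,
  realizing exactly the four types `C.3_1`, `C.3_2`, `C.3_3`, `H.C`.
  Alkanes carry no hydrogen-bond acceptors, so the generated sets are
  closed under the full typing-plus-IHB pipeline with a 4-type truth table.
  (Ether chains were rejected for this role: their gauche 1,4 H···O pairs
  fall below the 2.5 Å criterion at ideal geometry and would retype.)
* `make_ihb_fixture` — a planar HO–C=C–CHO (malonaldehyde-enol) fragment
  whose hydroxyl hydrogen is placed *exactly* at a requested distance from
  the carbonyl oxygen (5-bond through-bond path), by intersecting the 0.96 Å
  O–H circle with the requested sphere; infeasible distances raise.
* `make_labeled_training_set` — default 30 branched alkanes (3–8 heavy
  atoms) labeled by the model under a ground-truth table (the published FSD
  values of the four alkane types; fragmental volumes 20/17/14/7 Å³ for
  C.3_1/C.3_2/C.3_3/H.C) plus optional Gaussian noise. With the published
  S/O_max scale, vdW-scale volumes and σ = 3.5 Å, these labels land at a
  few hundred kcal/mol — the model's absolute scale is not calibrated
  without the original per-atom volumes and σ, and no rescaling is applied.
  Recovery at RMSE < 0.2 kcal/mol on labels of this magnitude is a
  correspondingly strict relative test.
* `make_volume_recovery_set` — perhalocarbon chains with exact-sum
  molecular-volume targets (see the identifiability caveat above).

What passing these tests shows: the pipeline is internally consistent
(typing, detection, energy, optimization, and generators agree to machine
precision) and the optimizer recovers generating parameters where they are
identifiable. What it does not show: predictive accuracy on real
experimental data, which would require the original training structures,
their per-atom volumes, and the σ calibration.

## Numerical choices and degenerate inputs

* Contacts are sorted by (distance, H index, acceptor index); GA selection
  uses stable argsort — all outputs are deterministic for fixed seeds.
* Strict inequality at the 2.5 Å IHB cutoff ("shorter than"), verified at
  2.49/2.50/2.51 Å.
* Disconnected H–acceptor pairs get an infinite through-bond path and so
  pass the path-length floor.
* Empty structure files yield an empty list with a logged warning;
  molecules without hydrogens yield no contacts with a warning; unsupported
  elements, missing type parameters, misaligned volume vectors and foreign
  contact indices raise typed errors naming the offender.
* Monte Carlo volume requires an explicit seed; the grid method is the
  deterministic alternative.
* Bond inference for XYZ/PDB inputs: bonded iff distance < 1.3 × sum of
  covalent radii; SDF/MOL2 connectivity is always taken as given
  (sanitization disabled so file aromatic flags and bond orders survive).

## Known limitations

Single-conformer analysis only; no entropy term; no charges, tautomers or
protonation states; simplified aromaticity perception; absolute energy
scale uncalibrated without the original σ and volume assignments; the
published headline accuracies on the FSD/SAMPL4 sets are not reproducible
here because those structure sets and per-atom volumes are not bundled.
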