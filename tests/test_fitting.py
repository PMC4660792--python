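"""Two-stage parameterization: volume fit and the elitist GA."""

import numpy as np
import pytest

import solvcontact as sc
from solvcontact.atomtypes import AtomTypeAssignment
from solvcontact.energy import EnergyConfig
from solvcontact.fitting import (GAConfig, TrainingSet, fit_atomic_volumes,
                                 optimize_parameters, run_ga)
from solvcontact.fixtures import (HALO_TRUTH_VOLUMES, make_volume_recovery_set,
                                  truth_molecular_volumes)
from solvcontact.params import TypeParameterTable


def single_atom_training_set(n=6, exp_dg=-5.0):
    """n isolated atoms of one type, all labeled exp_dg."""
    mols, assigns, vols = [], [], []
    for k in range(n):
        mol = sc.Molecule(f"atom_{k}", [sc.make_atom(0, "C", (0, 0, 0))], [],
                          exp_dg=exp_dg)
        mols.append(mol)
        assigns.append(AtomTypeAssignment(mol.name, "toy", ["C.3_1"]))
        vols.append(sc.AtomVolumes([15.0]))
    return TrainingSet(mols, assigns, vols)


class TestFitness:
    def test_perfect_fit_is_zero(self):
        labeled = sc.make_labeled_training_set(8, seed=1)
        assert sc.fitness(labeled.truth_table, labeled.train) == 0.0

    def test_sum_of_absolute_errors(self):
        """Three molecules with per-molecule absolute errors 0.43, 4.56
        and 3.79 give F_s = 8.78 (the benchmark's first three rows)."""
        train = single_atom_training_set(3)
        for mol, err in zip(train.molecules, (0.43, -4.56, 3.79)):
            mol.exp_dg = -5.0 + err
        table = TypeParameterTable.from_values("toy", {"C.3_1": (-5.0 / 300.0, 300.0)})
        assert sc.fitness(table, train) == pytest.approx(8.78, abs=1e-9)

    def test_single_molecule_error(self):
        train = single_atom_training_set(1, exp_dg=-3.0)
        table = TypeParameterTable.from_values("toy", {"C.3_1": (-5.0 / 300.0, 300.0)})
        assert sc.fitness(table, train) == pytest.approx(2.0, abs=1e-9)

    def test_coverage_gap_raises(self):
        train = single_atom_training_set(1)
        with pytest.raises(sc.ParameterCoverageError):
            sc.fitness(TypeParameterTable.from_values("toy", {"X": (1.0, 1.0)}),
                       train)


class TestGAEngine:
    bounds = np.array([[0.0, 10.0], [0.0, 10.0]])

    @staticmethod
    def quadratic(pop):
        return ((pop - np.array([3.0, 7.0])) ** 2).sum(axis=1)

    def test_monotone_best_fitness(self):
        res = run_ga(self.quadratic, self.bounds, GAConfig(seed=1,
                                                           max_generations=300))
        best = res.trace["best_fitness"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)

    def test_seed_determinism(self):
        a = run_ga(self.quadratic, self.bounds, GAConfig(seed=42))
        b = run_ga(self.quadratic, self.bounds, GAConfig(seed=42))
        assert np.array_equal(a.best, b.best)
        assert a.trace.equals(b.trace)

    def test_different_seeds_differ(self):
        a = run_ga(self.quadratic, self.bounds, GAConfig(seed=1,
                                                         max_generations=50))
        b = run_ga(self.quadratic, self.bounds, GAConfig(seed=2,
                                                         max_generations=50))
        assert not np.array_equal(a.best, b.best)

    def test_stationary_without_mutation_or_crossover(self):
        cfg = GAConfig(seed=3, mutation_prob=0.0, crossover_prob=0.0,
                       max_generations=80, stall_generations=1000)
        res = run_ga(self.quadratic, self.bounds, cfg)
        best = res.trace["best_fitness"].to_numpy()
        assert np.all(best == best[0])

    def test_respects_bounds(self):
        res = run_ga(self.quadratic, np.array([[4.0, 5.0], [8.0, 9.0]]),
                     GAConfig(seed=5, max_generations=100))
        assert 4.0 <= res.best[0] <= 5.0
        assert 8.0 <= res.best[1] <= 9.0


class TestVolumeFit:
    def test_single_atom_forced_by_sum(self):
        mol = sc.Molecule("c", [sc.make_atom(0, "C", (0, 0, 0))], [])
        a = AtomTypeAssignment("c", "toy", ["C.3_1"])
        res = fit_atomic_volumes([mol], [a], GAConfig(seed=1, max_generations=50),
                                 targets=np.array([20.58]))
        assert res.volumes[0].values[0] == pytest.approx(20.58, abs=1e-9)

    def test_homonuclear_diatomic_splits_evenly(self):
        atoms = [sc.make_atom(0, "C", (0, 0, 0)), sc.make_atom(1, "C", (1.54, 0, 0))]
        mol = sc.Molecule("cc", atoms, [sc.Bond(0, 1)])
        a = AtomTypeAssignment("cc", "toy", ["C.3_1", "C.3_1"])
        res = fit_atomic_volumes([mol], [a], GAConfig(seed=1, max_generations=50),
                                 targets=np.array([35.0]))
        assert np.allclose(res.volumes[0].values, 17.5, atol=1e-9)

    def test_recovery_on_constructed_data(self):
        """Exact-sum targets over a full-rank universe: the fitted base
        volumes match the generating values within 5% and the objective
        drops below 0.1 cubic angstrom per molecule."""
        mols, assigns, targets, truth = make_volume_recovery_set(30, seed=4)
        res = fit_atomic_volumes(mols, assigns, GAConfig(seed=5),
                                 targets=targets)
        per_mol = np.abs([v.values.sum() - t
                          for v, t in zip(res.volumes, targets)]).max()
        assert per_mol < 1e-6
        for code, value in truth.items():
            assert res.base_volumes[code] == pytest.approx(value, rel=0.05)
        resid = sum(abs(sum(res.base_volumes[c] for c in a.final_types) - t)
                    for a, t in zip(assigns, targets))
        assert resid / len(mols) < 0.1

    def test_sum_constraint_with_computed_volumes(self):
        labeled = sc.make_labeled_training_set(4, seed=9)
        mols = labeled.train.molecules
        res = fit_atomic_volumes(mols, labeled.train.assignments,
                                 GAConfig(seed=2, max_generations=100),
                                 volume_method="grid")
        for mol, v, target in zip(mols, res.volumes, res.molecular_volumes):
            assert v.values.sum() == pytest.approx(target, abs=1e-6)


class TestOptimizeParameters:
    def test_single_type_closed_form(self):
        """Isolated atoms labeled -5: the optimum satisfies S*O_max = -5."""
        train = single_atom_training_set()
        res = optimize_parameters(train, GAConfig(seed=7), EnergyConfig())
        p = res.table.entries["C.3_1"]
        assert res.ga_result.trace["best_fitness"].iloc[-1] >= 0
        assert sc.fitness(res.table, train) < 0.01
        assert p.S * p.O_max == pytest.approx(-5.0, rel=0.01)

    def test_noiseless_recovery(self):
        labeled = sc.make_labeled_training_set(30, seed=3)
        model = sc.SolventContactModel(labeled.train)
        res = model.fit(sc.GAConfig(seed=11))
        assert res.rmse < 0.2
        assert len(res.params) == 4

    def test_best_fitness_trace_non_increasing(self):
        labeled = sc.make_labeled_training_set(10, seed=5)
        res = optimize_parameters(labeled.train,
                                  GAConfig(seed=2, max_generations=200))
        best = res.trace["best_fitness"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)

    def test_fitness_recomputed_matches_returned(self):
        labeled = sc.make_labeled_training_set(10, seed=6)
        model = sc.SolventContactModel(labeled.train)
        res = model.fit(sc.GAConfig(seed=4, max_generations=300))
        assert res.fs == pytest.approx(res.recomputed_fs(), abs=1e-8)

    def test_seed_determinism_end_to_end(self):
        labeled = sc.make_labeled_training_set(8, seed=2)
        runs = []
        for _ in range(2):
            res = optimize_parameters(labeled.train,
                                      GAConfig(seed=9, max_generations=150))
            runs.append(res.table)
        assert runs[0].entries == runs[1].entries

    def test_initial_table_jitter_start(self):
        labeled = sc.make_labeled_training_set(8, seed=2)
        res = optimize_parameters(labeled.train,
                                  GAConfig(seed=1, max_generations=100),
                                  initial=labeled.truth_table)
        assert sc.fitness(res.table, labeled.train) < 1e-6

    def test_empty_training_set_rejected(self):
        with pytest.raises(sc.SolvContactError):
            optimize_parameters(TrainingSet([], [], []), GAConfig(seed=0))

    def test_population_must_be_even(self):
        with pytest.raises(sc.SolvContactError):
            GAConfig(population=99)
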