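"""Model/Results interface over the solvent-contact parameterization.

`SolventContactModel` holds a labeled training set (molecules, atom-type
assignments, fragmental volumes) and an energy configuration; `fit()`
runs the elitist genetic algorithm and returns a
`SolventContactResults` carrying the optimized parameter table, the
convergence trace, fitted values, residuals and summary statistics —
the familiar fit-then-inspect workflow of statistical modelling
packages.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Molecule
from .energy import AtomVolumes, EnergyConfig, hydration_free_energy
from .errors import SolvContactError
from .fitting import (GAConfig, ParameterFitResult, TrainingSet,
                      fit_atomic_volumes, fitness, optimize_parameters)
from .metrics import PredictionRecord, aue, r_squared, rmse
from .params import TypeParameterTable
from .pipeline import default_atom_volumes, prepare_assignment


class SolventContactModel:
    """Solvent-contact hydration model bound to a training set."""

    def __init__(self, training_set: TrainingSet, scheme: str = "FSD",
                 energy_config: Optional[EnergyConfig] = None):
        self.train = training_set
        self.scheme = scheme
        self.energy_config = energy_config or EnergyConfig()

    @classmethod
    def from_molecules(cls, molecules: Sequence[Molecule], scheme: str = "FSD",
                       use_ihb: bool = True,
                       energy_config: Optional[EnergyConfig] = None,
                       fit_volumes: bool = False,
                       ga_config: Optional[GAConfig] = None,
                       ) -> "SolventContactModel":
        """Build a model from labeled molecules.

        Types every molecule (with IHB retyping unless disabled) and
        attaches fragmental volumes: sphere-rescaled defaults, or the
        two-stage GA volume fit when `fit_volumes` is set.
        """
        mols = list(molecules)
        if not mols:
            raise SolvContactError("no molecules supplied")
        assignments = [prepare_assignment(m, scheme, use_ihb) for m in mols]
        if fit_volumes:
            vr = fit_atomic_volumes(mols, assignments, ga_config or GAConfig())
            volumes = vr.volumes
        else:
            volumes = [default_atom_volumes(m) for m in mols]
        return cls(TrainingSet(mols, assignments, volumes), scheme, energy_config)

    @classmethod
    def from_dataframe(cls, structures: Sequence[Molecule],
                       labels: pd.DataFrame, name_col: str = "name",
                       dg_col: str = "dg_exp_kcal_mol",
                       **kwargs) -> "SolventContactModel":
        """Attach a label table (name -> experimental dG_hyd) and build."""
        lookup = dict(zip(labels[name_col].astype(str), labels[dg_col]))
        mols = []
        for m in structures:
            if m.name not in lookup:
                raise SolvContactError(f"no label for molecule {m.name!r}")
            m.exp_dg = float(lookup[m.name])
            mols.append(m)
        return cls.from_molecules(mols, **kwargs)

    def fit(self, ga_config: Optional[GAConfig] = None,
            initial: Optional[TypeParameterTable] = None) -> "SolventContactResults":
        """Run the elitist GA over (S, O_max) and wrap the outcome."""
        ga = ga_config or GAConfig()
        res = optimize_parameters(self.train, ga, self.energy_config,
                                  initial=initial,
                                  scheme_name=f"{self.scheme}-refit")
        return SolventContactResults(self, res, ga)

    def evaluate(self, table: TypeParameterTable) -> np.ndarray:
        """Predicted dG_hyd for the training molecules under `table`."""
        out = []
        for mol, a, v in zip(self.train.molecules, self.train.assignments,
                             self.train.volumes):
            out.append(hydration_free_energy(mol, a, table, v,
                                             self.energy_config).total)
        return np.array(out)


class SolventContactResults:
    """Fit results: parameter table, trace, diagnostics, summary."""

    def __init__(self, model: SolventContactModel, fit_result: ParameterFitResult,
                 ga_config: GAConfig):
        self.model = model
        self.params = fit_result.table
        self.ga_result = fit_result.ga_result
        self.ga_config = ga_config
        self.fittedvalues = model.evaluate(self.params)

    # -- diagnostics -------------------------------------------------------

    @property
    def nobs(self) -> int:
        return len(self.model.train)

    @property
    def exog_names(self) -> list[str]:
        return self.params.codes

    @property
    def resid(self) -> np.ndarray:
        return self.model.train.exp_dg - self.fittedvalues

    @property
    def fs(self) -> float:
        """The GA objective at the optimum: sum of |residuals| (kcal/mol)."""
        return float(np.abs(self.resid).sum())

    @property
    def records(self) -> list[PredictionRecord]:
        return [PredictionRecord(m.name, m.exp_dg, f)
                for m, f in zip(self.model.train.molecules, self.fittedvalues)]

    @property
    def rmse(self) -> float:
        return rmse(self.records)

    @property
    def aue(self) -> float:
        return aue(self.records)

    @property
    def rsquared(self) -> float:
        return r_squared(self.model.train.exp_dg, self.fittedvalues)

    @property
    def trace(self) -> pd.DataFrame:
        return self.ga_result.trace

    def recomputed_fs(self) -> float:
        """F_s recomputed from scratch (guards against caching drift)."""
        return fitness(self.params, self.model.train, self.model.energy_config)

    def predict(self, molecules: Optional[Sequence[Molecule]] = None,
                use_ihb: bool = True) -> pd.DataFrame:
        """dG_hyd for new molecules under the fitted table."""
        from .pipeline import predict_hydration

        if molecules is None:
            return pd.DataFrame({
                "name": [m.name for m in self.model.train.molecules],
                "dg_calc": self.fittedvalues,
                "dg_exp": self.model.train.exp_dg,
            })
        frame, _ = predict_hydration(molecules, self.model.scheme,
                                     table=self.params,
                                     cfg=self.model.energy_config,
                                     use_ihb=use_ihb)
        return frame

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model fits."""
        lines = []
        add = lines.append
        add("        Solvent-Contact Hydration Model Fit")
        add("=" * 58)
        add(f"Scheme:              {self.model.scheme}")
        add(f"No. molecules:       {self.nobs}")
        add(f"No. atom types:      {len(self.params)}")
        add(f"sigma (A):           {self.model.energy_config.sigma}")
        add(f"GA generations:      {self.ga_result.n_generations}"
            f" (seed {self.ga_config.seed})")
        add(f"F_s (kcal/mol):      {self.fs:.4f}")
        add(f"RMSE (kcal/mol):     {self.rmse:.4f}")
        add(f"AUE (kcal/mol):      {self.aue:.4f}")
        if self.nobs >= 3:
            add(f"R-squared:           {self.rsquared:.4f}")
        add("-" * 58)
        add(f"{'type':<10}{'S (kcal/mol A^3)':>20}{'O_max (A^3)':>16}")
        for code in self.params.codes:
            p = self.params.entries[code]
            add(f"{code:<10}{p.S:>20.4f}{p.O_max:>16.1f}")
        add("=" * 58)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Experimental vs. calculated dG_hyd scatter with the y=x line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        exp = self.model.train.exp_dg
        ax.scatter(exp, self.fittedvalues, s=18)
        lims = [min(exp.min(), self.fittedvalues.min()) - 1,
                max(exp.max(), self.fittedvalues.max()) + 1]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(r"experimental $\Delta G_{hyd}$ (kcal/mol)")
        ax.set_ylabel(r"calculated $\Delta G_{hyd}$ (kcal/mol)")
        return ax

    def plot_trace(self, ax=None):
        """Best/mean GA fitness per generation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["generation"], self.trace["best_fitness"],
                label="best")
        ax.plot(self.trace["generation"], self.trace["mean_fitness"],
                label="mean", alpha=0.6)
        ax.set_xlabel("generation")
        ax.set_ylabel(r"$F_s$ (kcal/mol)")
        ax.legend()
        return ax
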