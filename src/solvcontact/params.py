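"""Published atom-type parameter tables and summary statistics over them.

Two parameterizations of the solvent-contact energy function ship with the
package: ``FSD`` (52 atom types, trained on Free Solvation Database
molecules) and ``SAMPL4`` (36 atom types, trained on the reference set for
the SAMPL4 blind challenge).  Each atom type carries an atomic solvation
parameter S (kcal/mol per cubic angstrom) and a maximum atomic occupancy
O_max (cubic angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SolvContactError, TableValidationError

SCHEMES = ("FSD", "SAMPL4")

_BUNDLED = {"FSD": "params_fsd.csv", "SAMPL4": "params_sampl4.csv"}

#: the full 55-code atom-type vocabulary (union of both schemes)
VOCABULARY = (
    "C.3_1", "C.3_2", "C.3_3", "C.3_4",
    "C.2_1", "C.2_2", "C.2_3",
    "C.1_1", "C.1_2",
    "C.ar_2", "C.ar_3",
    "C.CO_1", "C.CO_2",
    "N.1_1", "N.2_2",
    "N.3_1", "N.3_2", "N.3_3",
    "N.ar",
    "N.pl_1", "N.pl_2", "N.pl_3",
    "N.am_1", "N.am_2", "N.am_3",
    "N.no2",
    "O.3_1", "O.3_2",
    "O.pl_1", "O.pl_2",
    "O.es_1", "O.es_2",
    "O.2", "O.no2", "O.intra",
    "S.12", "S.3_1", "S.3_2", "S.2", "S.pl",
    "F", "F.intra", "Cl", "Cl.intra", "Br", "I",
    "P.10",
    "H.C", "H.N3", "H.Np", "H.O3", "H.Op", "H.Oa", "H.S",
    "H.intra",
)


@dataclass(frozen=True)
class TypeParameters:
    """S (kcal/mol A^3) and O_max (A^3) for one atom type."""

    S: float
    O_max: float


@dataclass
class TypeParameterTable:
    """A named set of per-type (S, O_max) parameters."""

    scheme: str
    entries: dict[str, TypeParameters]
    provenance: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for code, p in self.entries.items():
            if not p.O_max > 0:
                raise TableValidationError(
                    f"{self.scheme}: O_max must be positive for {code!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    @property
    def codes(self) -> list[str]:
        return list(self.entries)

    def s_values(self, codes: Iterable[str]) -> np.ndarray:
        return np.array([self.entries[c].S for c in codes])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type_code": code,
                "description": self.descriptions.get(code, ""),
                "o_max_A3": p.O_max,
                "s_kcal_per_molA3": p.S,
            }
            for code, p in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scheme: str,
                   provenance: str = "") -> "TypeParameterTable":
        required = {"type_code", "o_max_A3", "s_kcal_per_molA3"}
        missing = required - set(df.columns)
        if missing:
            raise TableValidationError(f"missing columns: {sorted(missing)}")
        entries: dict[str, TypeParameters] = {}
        descriptions: dict[str, str] = {}
        for row_num, row in enumerate(df.itertuples(index=False)):
            code = str(row.type_code)
            if code in entries:
                raise TableValidationError(f"row {row_num}: duplicate code {code!r}")
            o_max = float(row.o_max_A3)
            if not np.isfinite(o_max) or o_max <= 0:
                raise TableValidationError(
                    f"row {row_num} ({code}): non-positive O_max {o_max}"
                )
            entries[code] = TypeParameters(float(row.s_kcal_per_molA3), o_max)
            if "description" in df.columns:
                descriptions[code] = str(getattr(row, "description", ""))
        return cls(scheme, entries, provenance, descriptions)

    @classmethod
    def from_values(cls, scheme: str, values: Mapping[str, tuple[float, float]],
                    provenance: str = "") -> "TypeParameterTable":
        """Build a table from a {code: (S, O_max)} mapping."""
        return cls(scheme,
                   {c: TypeParameters(float(s), float(o)) for c, (s, o) in values.items()},
                   provenance)


def load_table(scheme: str, path=None) -> TypeParameterTable:
    """Load a bundled (FSD/SAMPL4) or external parameter table.

    The bundled tables exclude the atom types not populated for the scheme
    (e.g. sulfur types under SAMPL4), so FSD has 52 entries and SAMPL4 36.
    """
    if path is None:
        if scheme not in _BUNDLED:
            raise SolvContactError(f"unknown bundled scheme {scheme!r}")
        with resources.files("solvcontact.data").joinpath(_BUNDLED[scheme]).open() as fh:
            df = pd.read_csv(fh)
        provenance = f"bundled table, scheme {scheme}"
    else:
        df = pd.read_csv(path)
        provenance = f"user table {path}"
    table = TypeParameterTable.from_frame(df, scheme, provenance)
    if path is None:
        unknown = set(table.codes) - set(VOCABULARY)
        if unknown:
            raise TableValidationError(f"codes outside vocabulary: {sorted(unknown)}")
    return table


def group_mean_S(table: TypeParameterTable, type_codes: Iterable[str]) -> float:
    """Arithmetic mean of S over the given type codes (kcal/mol A^3)."""
    codes = list(type_codes)
    if not codes:
        raise SolvContactError("group_mean_S of an empty code set")
    missing = [c for c in codes if c not in table]
    if missing:
        raise SolvContactError(f"codes not in table {table.scheme}: {missing}")
    return float(table.s_values(codes).mean())


def cross_scheme_r2(a: TypeParameterTable, b: TypeParameterTable,
                    field: str = "S") -> float:
    """Squared Pearson correlation of a field over the shared type codes."""
    if field not in ("S", "O_max"):
        raise SolvContactError(f"unknown field {field!r}")
    shared = [c for c in a.codes if c in b]
    if len(shared) < 3:
        raise SolvContactError(f"only {len(shared)} shared codes (need >= 3)")
    xa = np.array([getattr(a.entries[c], field) for c in shared])
    xb = np.array([getattr(b.entries[c], field) for c in shared])
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)
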