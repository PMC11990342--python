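"""Scalar post-processing of molecular-docking binding affinities.

A docking score dG (kcal/mol, negative = favourable) converts to an
inhibition-constant exponent via dG = -RT ln(Ki):

    pKi = -dG / (ln(10) * R * T),   R = 1.9872e-3 kcal/(mol K)

and to a size-normalised ligand efficiency LE = |dG| / N_heavy. Running the
docking itself is out of scope; only printed affinities are processed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "CALOTHRIXIN_A_HEAVY_ATOMS",
    "DockingSummary",
    "pki_from_affinity",
    "affinity_from_pki",
    "ligand_efficiency",
    "summarize",
]

GAS_CONSTANT_KCAL = 1.9872e-3   # kcal / (mol K)
STANDARD_TEMPERATURE_K = 298.15

#: Non-hydrogen atom count of calothrixin A (C19 H10 N2 O3).
CALOTHRIXIN_A_HEAVY_ATOMS = 24


def pki_from_affinity(dG: float, T: float = STANDARD_TEMPERATURE_K) -> float:
    """pKi = -dG / (ln(10) R T); favourable (negative) dG gives positive pKi."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got T={T}")
    return -dG / (math.log(10.0) * GAS_CONSTANT_KCAL * T)


def affinity_from_pki(pki: float, T: float = STANDARD_TEMPERATURE_K) -> float:
    """Inverse of :func:`pki_from_affinity`."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got T={T}")
    return -pki * math.log(10.0) * GAS_CONSTANT_KCAL * T


def ligand_efficiency(dG: float, heavy_atoms: int) -> float:
    """LE = |dG| / heavy_atoms, in kcal/mol per heavy atom."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy-atom count must be >= 1, got {heavy_atoms}")
    return abs(dG) / heavy_atoms


@dataclass(frozen=True)
class DockingSummary:
    """One docking result with its derived thermodynamic descriptors."""

    target: str
    affinity: float                 # kcal/mol
    heavy_atoms: int = CALOTHRIXIN_A_HEAVY_ATOMS
    temperature: float = STANDARD_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.heavy_atoms < 1:
            raise ValueError("heavy-atom count must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def pki(self) -> float:
        return pki_from_affinity(self.affinity, self.temperature)

    @property
    def ligand_efficiency(self) -> float:
        return ligand_efficiency(self.affinity, self.heavy_atoms)


def summarize(
    affinities: pd.DataFrame,
    heavy_atoms: int = CALOTHRIXIN_A_HEAVY_ATOMS,
    T: float = STANDARD_TEMPERATURE_K,
) -> pd.DataFrame:
    """Derive pKi and ligand efficiency for a table of docking affinities.

    ``affinities`` needs columns `target` and `affinity_kcal_per_mol`; the
    returned copy adds `pKi` and `ligand_efficiency_kcal_per_mol`.
    """
    required = {"target", "affinity_kcal_per_mol"}
    if not required.issubset(affinities.columns):
        raise ValueError(f"affinity table must have columns {sorted(required)}")
    out = affinities.copy()
    out["pKi"] = [pki_from_affinity(g, T) for g in out["affinity_kcal_per_mol"]]
    out["ligand_efficiency_kcal_per_mol"] = [
        ligand_efficiency(g, heavy_atoms) for g in out["affinity_kcal_per_mol"]
    ]
    return out
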