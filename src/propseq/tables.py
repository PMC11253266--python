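"""Amino-acid property and factor tables.

Two kinds of lookup tables drive every encoding in this package:

* :class:`PropertyTable` — one measured physicochemical quantity per residue
  (e.g. side-chain volume in cubic angstroms, isoelectric point, octanol
  partition free energy).  A gapped sequence re-expressed through such a table
  becomes a *property wave*: a numeric string with 0 at gap positions.

* :class:`FactorTable` — a 5-vector of state-space coordinates per residue,
  derived by multivariate reduction of a large panel of measured properties
  (the widely used five-factor solution: polarity, secondary-structure
  propensity, size, codon composition, charge).  A sequence becomes an
  ``m x 5`` matrix with all-zero rows at gaps.

The shipped factor coordinates are re-standardized per axis over the 20
amino acids (mean 0, sd 1), so that the zero vector used for gaps coincides
with the centroid of the residue cloud; the raw published transcription is
kept in :data:`FACTOR_SCORES_RAW` for users who want the original scale.
All algorithms accept user-supplied tables, which can also be loaded from
CSV (one row per residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError

#: Canonical one-letter codes of the 20 standard amino acids, alphabetical.
AA_LETTERS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters accepted in alignments but carrying no property information
#: (ambiguity codes and the rare 21st/22nd residues); encoded like gaps
#: unless strict mode is requested.
AMBIGUOUS_LETTERS: frozenset = frozenset("BJOUXZ")

GAP: str = "-"


# --------------------------------------------------------------------------
# Embedded constants.
#
# Provenance note: transcriptions of published experimental compilations —
# residue volumes (A^3), isoelectric points (pH units), octanol partition
# free energies (kcal/mol, interface-to-octanol scale), and the five-factor
# state-space solution obtained by factor analysis of ~500 measured amino
# acid attributes.  They are shipped as replaceable data: every algorithm
# takes the table as an argument and no test depends on the exact numbers.
# --------------------------------------------------------------------------

VOLUME: Mapping[str, float] = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
    "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
    "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
    "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6,
}

ISOELECTRIC_POINT: Mapping[str, float] = {
    "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48,
    "G": 5.97, "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98,
    "M": 5.74, "N": 5.41, "P": 6.30, "Q": 5.65, "R": 10.76,
    "S": 5.68, "T": 5.60, "V": 5.96, "W": 5.89, "Y": 5.66,
}

OCTANOL: Mapping[str, float] = {
    "A": 0.50, "C": -0.02, "D": 3.64, "E": 3.63, "F": -1.71,
    "G": 1.15, "H": 2.33, "I": -1.12, "K": 2.80, "L": -1.25,
    "M": -0.67, "N": 0.85, "P": 0.14, "Q": 0.77, "R": 1.81,
    "S": 0.46, "T": 0.25, "V": -0.46, "W": -2.09, "Y": -0.71,
}

#: Raw five-factor scores as published (standardized over the source protein
#: dataset, not over the 20 residues; per-axis sd across the letters is ~1-2).
FACTOR_SCORES_RAW: Mapping[str, tuple] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


@dataclass(frozen=True)
class PropertyTable:
    """One measured physicochemical value per standard amino acid."""

    property_name: str
    values: Mapping[str, float]

    def __post_init__(self):
        keys = set(self.values)
        if keys != set(AA_LETTERS):
            missing = sorted(set(AA_LETTERS) - keys)
            extra = sorted(keys - set(AA_LETTERS))
            raise ConfigError(
                f"property table {self.property_name!r} must cover exactly the 20 "
                f"standard residues (missing {missing}, extra {extra})"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ConfigError(f"property table {self.property_name!r} has non-finite values")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def as_series(self) -> pd.Series:
        return pd.Series({a: self.values[a] for a in AA_LETTERS}, name=self.property_name)


@dataclass(frozen=True)
class FactorTable:
    """5-dimensional state-space coordinates per standard amino acid.

    The ``check_normalized`` flag enforces the mean-0 / sd-1 per-axis
    convention (tolerance 0.05) under which the all-zero gap row sits at the
    centroid of the residue cloud.
    """

    coords: Mapping[str, np.ndarray] = field(default=None)
    check_normalized: bool = True

    def __post_init__(self):
        coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}
        if set(coords) != set(AA_LETTERS):
            raise ConfigError("factor table must cover exactly the 20 standard residues")
        for aa, vec in coords.items():
            if vec.shape != (5,):
                raise ConfigError(f"factor coordinates for {aa!r} are not a 5-vector")
            if not np.all(np.isfinite(vec)):
                raise ConfigError(f"factor coordinates for {aa!r} are not finite")
        object.__setattr__(self, "coords", coords)
        if self.check_normalized:
            mat = self.matrix()
            mu = mat.mean(axis=0)
            sd = mat.std(axis=0)
            if np.any(np.abs(mu) > 0.05) or np.any(np.abs(sd - 1.0) > 0.05):
                raise ConfigError(
                    "factor axes are not normalized to mean 0 / sd 1 over the 20 "
                    f"residues (means {np.round(mu, 3)}, sds {np.round(sd, 3)}); "
                    "pass check_normalized=False to accept raw scales"
                )

    def __getitem__(self, residue: str) -> np.ndarray:
        return self.coords[residue]

    def matrix(self) -> np.ndarray:
        """20x5 array in alphabetical residue order."""
        return np.stack([self.coords[a] for a in AA_LETTERS])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix(), index=list(AA_LETTERS),
                            columns=[f"E{k}" for k in range(1, 6)])


def default_property_tables() -> dict[str, PropertyTable]:
    """The three shipped property tables keyed by name."""
    return {
        "volume": PropertyTable("volume", VOLUME),
        "isoelectric_point": PropertyTable("isoelectric_point", ISOELECTRIC_POINT),
        "octanol": PropertyTable("octanol", OCTANOL),
    }


def factor_table(raw: bool = False) -> FactorTable:
    """The shipped 20x5 factor table.

    By default the published scores are re-standardized per axis over the 20
    amino acids so each axis has mean 0 and sd 1 (making the gap encoding
    ``(0,0,0,0,0)`` the residue centroid).  ``raw=True`` returns the
    transcription on its original scale.
    """
    if raw:
        return FactorTable(FACTOR_SCORES_RAW, check_normalized=False)
    mat = np.array([FACTOR_SCORES_RAW[a] for a in AA_LETTERS], dtype=float)
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    return FactorTable({a: z[i] for i, a in enumerate(AA_LETTERS)})


def average_amino_acid(table: FactorTable) -> np.ndarray:
    """Hypothetical 'average amino acid': componentwise mean of the 20 coordinate vectors.

    Used as the reference point of mutability heatmaps.  For a normalized
    table this is (numerically) the zero vector.
    """
    return table.matrix().mean(axis=0)


# --------------------------------------------------------------------------
# CSV interchange: one row per residue, first column the one-letter code.
# --------------------------------------------------------------------------

def read_property_table(path: str | Path, property_name: str | None = None) -> PropertyTable:
    """Read a single-property CSV (columns: residue, value or residue, <name>)."""
    df = pd.read_csv(path)
    res_col = df.columns[0]
    val_col = property_name if property_name in df.columns else df.columns[1]
    values = dict(zip(df[res_col].astype(str).str.upper(), df[val_col].astype(float)))
    return PropertyTable(property_name or str(val_col), values)


def read_factor_table(path: str | Path, check_normalized: bool = True) -> FactorTable:
    """Read a factor CSV (columns: residue, E1..E5)."""
    df = pd.read_csv(path)
    res = df[df.columns[0]].astype(str).str.upper()
    coords = {r: df.iloc[i, 1:6].to_numpy(dtype=float) for i, r in enumerate(res)}
    return FactorTable(coords, check_normalized=check_normalized)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    table.as_series().rename_axis("residue").reset_index().to_csv(path, index=False)


def write_factor_table(table: FactorTable, path: str | Path) -> None:
    table.as_frame().rename_axis("residue").reset_index().to_csv(path, index=False)
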