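"""Physicochemical property scales for the 20 amino acids.

The encoder attaches 14 property values to every flanking residue of a
window.  The default table below is curated from standard literature scales
(AAIndex-style): Kyte-Doolittle hydrophobicity, Grantham polarity,
Charton-Charton polarizability, residue accessible surface area, net charge
index of side chains, molecular weight, alpha-amino and alpha-carboxyl pKa,
melting point, specific optical rotation, entropy of formation, heat
capacity, absolute entropy, and — in the configurable 14th slot —
Hopp-Woods hydrophilicity.  The table is deliberately editable: any 20x14
TSV with the same shape can be swapped in, and a model records a checksum of
the table it was trained with.

The dummy residue X contributes 0 for every property.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import AMINO_ACIDS, PAD_CHAR

PROPERTY_NAMES = [
    "hydrophobicity",
    "polarity",
    "polarizability",
    "solvent_accessibility",
    "net_charge_index",
    "molecular_weight",
    "pk_n",
    "pk_c",
    "melting_point",
    "optical_rotation",
    "entropy_of_formation",
    "heat_capacity",
    "absolute_entropy",
    "hydrophilicity",
]

# Rows: A C D E F G H I K L M N P Q R S T V W Y (alphabetical one-letter).
_DEFAULT_VALUES = {
    #       hyphob polar  polz   acc    nci       mw      pkn    pkc   melt   optrot  entf    heatc  absent hyphil
    "A": [  1.8,   8.1, 0.046, 115.0,  0.007187,  89.09,  9.69, 2.34, 297.0,   1.80, 154.33, 29.22, 30.88, -0.5],
    "C": [  2.5,   5.5, 0.128, 135.0, -0.036610, 121.16, 10.28, 1.96, 178.0, -16.50, 219.79, 50.70, 53.83, -1.0],
    "D": [ -3.5,  13.0, 0.105, 150.0, -0.023820, 133.10,  9.60, 1.88, 270.0,   5.05, 194.91, 37.09, 40.66,  3.0],
    "E": [ -3.5,  12.3, 0.151, 190.0,  0.006802, 147.13,  9.67, 2.19, 249.0,  12.00, 223.16, 41.84, 44.98,  3.0],
    "F": [  2.8,   5.2, 0.290, 210.0,  0.037552, 165.19,  9.13, 1.83, 283.0, -34.50, 204.74, 48.52, 51.06, -2.5],
    "G": [ -0.4,   9.0, 0.000,  75.0,  0.179052,  75.07,  9.60, 2.34, 290.0,   0.00, 127.90, 23.71, 24.74,  0.0],
    "H": [ -3.2,  10.4, 0.230, 195.0, -0.010690, 155.16,  9.17, 1.82, 287.0, -38.50, 242.54, 59.64, 65.99, -0.5],
    "I": [  4.5,   5.2, 0.186, 175.0,  0.021631, 131.17,  9.68, 2.36, 284.0,  12.40, 233.21, 45.00, 49.71, -1.8],
    "K": [ -3.9,  11.3, 0.219, 200.0,  0.017708, 146.19,  8.95, 2.18, 224.0,  14.60, 300.46, 57.10, 63.21,  3.0],
    "L": [  3.8,   4.9, 0.186, 170.0,  0.051672, 131.17,  9.60, 2.36, 337.0, -11.00, 232.30, 48.03, 50.62, -1.8],
    "M": [  1.9,   5.7, 0.221, 185.0,  0.002683, 149.21,  9.21, 2.28, 283.0, -10.00, 202.65, 69.32, 55.32, -1.3],
    "N": [ -3.5,  11.6, 0.134, 160.0,  0.005392, 132.12,  8.80, 2.02, 236.0,  -5.60, 207.90, 38.30, 41.70,  0.2],
    "P": [ -1.6,   8.0, 0.131, 145.0,  0.239531, 115.13, 10.60, 1.99, 222.0, -86.20, 179.93, 36.13, 39.21,  0.0],
    "Q": [ -3.5,  10.5, 0.180, 180.0,  0.049211, 146.15,  9.13, 2.17, 185.0,   6.30, 235.51, 44.02, 46.62,  0.2],
    "R": [ -4.5,  10.5, 0.291, 225.0,  0.043587, 174.20,  9.04, 2.17, 238.0,  12.50, 341.01, 26.37, 68.43,  3.0],
    "S": [ -0.8,   9.2, 0.062, 115.0,  0.004627, 105.09,  9.15, 2.21, 228.0,  -7.50, 174.06, 32.40, 35.65,  0.3],
    "T": [ -0.7,   8.6, 0.108, 140.0,  0.003352, 119.12,  9.10, 2.09, 253.0, -28.00, 205.80, 35.20, 36.50, -0.4],
    "V": [  4.2,   5.9, 0.140, 155.0,  0.057004, 117.15,  9.62, 2.32, 293.0,   5.63, 207.60, 40.35, 42.75, -1.5],
    "W": [ -0.9,   5.4, 0.409, 255.0,  0.037977, 204.23,  9.39, 2.83, 282.0, -33.70, 237.01, 56.92, 60.00, -3.4],
    "Y": [ -1.3,   6.2, 0.298, 230.0,  0.023599, 181.19,  9.11, 2.20, 344.0, -10.00, 229.15, 51.73, 51.15, -2.3],
}


class PropertyTable:
    """A 20x14 table of per-residue physicochemical values.

    Lookups return a 14-vector per residue; the dummy residue X maps to the
    zero vector by definition.
    """

    def __init__(self, frame: pd.DataFrame):
        if list(frame.index) != list(AMINO_ACIDS):
            frame = frame.reindex(list(AMINO_ACIDS))
        if frame.isna().any().any():
            raise ValueError("property table must cover all 20 amino acids")
        if frame.shape != (20, 14):
            raise ValueError(f"property table must be 20x14, got {frame.shape}")
        self.frame = frame.astype(float)
        self.frame.index.name = "residue"
        self._lookup = {aa: self.frame.loc[aa].to_numpy() for aa in AMINO_ACIDS}
        self._lookup[PAD_CHAR] = np.zeros(14)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, residue: str) -> np.ndarray:
        try:
            return self._lookup[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in property table") from None

    def checksum(self) -> str:
        payload = self.frame.round(6).to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="residue")


def default_property_table() -> PropertyTable:
    frame = pd.DataFrame.from_dict(_DEFAULT_VALUES, orient="index", columns=PROPERTY_NAMES)
    return PropertyTable(frame)
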