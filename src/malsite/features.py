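"""Three-part sequence feature encoding for lysine-centered windows.

Every window is converted to a fixed-layout numeric vector built from three
ingredients:

* **Block A+B — basic k-gram spectrum** (k = 1, 2): occurrence counts of
  every 1-gram (21 symbols) and every adjacent 2-gram (21^2 = 441 pairs)
  in the window, 462 components for the default 16-mer.
* **Block C — position-specific 1-gram codes**: for each of the 15 flanking
  positions (-6..-1, +1..+9; the invariant center K is excluded), the
  integer code of the residue.  The 20 native amino acids are numbered 1-20
  in alphabetical order of their one-letter code (A=1 ... Y=20) and the
  dummy X is 21.
* **Block D — physicochemical values**: for each flanking position (same
  order), the 14 property-scale values of its residue (X contributes zeros),
  210 components.

The concatenation A||B||C||D is 21 + 441 + 15 + 210 = 687 components for the
default window geometry.  Features that are constant over a training matrix
carry no information and are dropped by a fitted :class:`ReductionMask`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .properties import PropertyTable, default_property_table
from .windows import ALPHABET, PeptideWindow, WindowConfig

#: residue -> integer code 1..21 (alphabetical; X=21)
AA_CODE = {aa: i + 1 for i, aa in enumerate(ALPHABET)}
#: integer code -> residue
CODE_AA = {v: k for k, v in AA_CODE.items()}

N_SYMBOLS = len(ALPHABET)  # 21

BLOCK_A = N_SYMBOLS                # 21 one-gram counts
BLOCK_B = N_SYMBOLS * N_SYMBOLS    # 441 two-gram counts


def flank_positions(config: WindowConfig = WindowConfig()) -> list[int]:
    """Window position labels excluding the center: -xi..-1, +1..+eta."""
    return list(range(-config.xi, 0)) + list(range(1, config.eta + 1))


def n_features(config: WindowConfig = WindowConfig()) -> int:
    n_flank = config.xi + config.eta
    return BLOCK_A + BLOCK_B + n_flank + 14 * n_flank


def _check(window: PeptideWindow, config: WindowConfig) -> None:
    if len(window) != config.length:
        raise ValueError(
            f"window length {len(window)} != configured {config.length}"
        )


def encode_basic_kgrams(
    window: PeptideWindow,
    config: WindowConfig = WindowConfig(),
    binary: bool = False,
) -> np.ndarray:
    """k-gram spectrum for k=1,2: 21 + 441 = 462 counts.

    With ``binary=True`` the spectrum records presence/absence instead of
    occurrence counts.
    """
    _check(window, config)
    vec = np.zeros(BLOCK_A + BLOCK_B)
    codes = [AA_CODE[ch] for ch in window.residues]
    for c in codes:
        vec[c - 1] += 1
    for c1, c2 in zip(codes, codes[1:]):
        vec[BLOCK_A + (c1 - 1) * N_SYMBOLS + (c2 - 1)] += 1
    if binary:
        vec = (vec > 0).astype(float)
    return vec


def encode_position_codes(
    window: PeptideWindow, config: WindowConfig = WindowConfig()
) -> np.ndarray:
    """Integer residue code at each flanking position, -xi..-1 then +1..+eta.

    The center position is excluded: it is K by construction for every
    benchmark window and so carries no information.
    """
    _check(window, config)
    c = config.center_index
    flanks = window.residues[:c] + window.residues[c + 1 :]
    return np.array([AA_CODE[ch] for ch in flanks], dtype=float)


def encode_physicochemical(
    window: PeptideWindow,
    table: PropertyTable,
    config: WindowConfig = WindowConfig(),
) -> np.ndarray:
    """14 property values per flanking position (position-major), 210-D.

    The dummy X contributes 0 for every property.
    """
    _check(window, config)
    c = config.center_index
    flanks = window.residues[:c] + window.residues[c + 1 :]
    return np.concatenate([table.values_for(ch) for ch in flanks])


def encode(
    window: PeptideWindow,
    table: PropertyTable | None = None,
    config: WindowConfig = WindowConfig(),
    binary_kgrams: bool = False,
) -> np.ndarray:
    """Full feature vector A||B||C||D; 687 components under defaults."""
    if table is None:
        table = default_property_table()
    return np.concatenate(
        [
            encode_basic_kgrams(window, config, binary=binary_kgrams),
            encode_position_codes(window, config),
            encode_physicochemical(window, table, config),
        ]
    )


def encode_matrix(
    windows: Sequence[PeptideWindow],
    table: PropertyTable | None = None,
    config: WindowConfig = WindowConfig(),
    binary_kgrams: bool = False,
) -> np.ndarray:
    """Encode a collection of windows into an (n, n_features) matrix."""
    if table is None:
        table = default_property_table()
    return np.array(
        [encode(w, table, config, binary_kgrams) for w in windows]
    )


def feature_names(
    config: WindowConfig = WindowConfig(),
    property_names: Sequence[str] | None = None,
) -> list[str]:
    """Stable human-readable name for every feature index."""
    if property_names is None:
        property_names = default_property_table().names
    names = [f"g1_{CODE_AA[c]}" for c in range(1, N_SYMBOLS + 1)]
    names += [
        f"g2_{CODE_AA[c1]}{CODE_AA[c2]}"
        for c1 in range(1, N_SYMBOLS + 1)
        for c2 in range(1, N_SYMBOLS + 1)
    ]
    positions = flank_positions(config)
    names += [f"pos_{p:+d}_code" for p in positions]
    for p in positions:
        names += [f"pc_{p:+d}_{prop}" for prop in property_names]
    return names


# ---------------------------------------------------------------------------
# Constant-feature reduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionMask:
    """Keep-flags for the non-constant features of a training matrix."""

    keep: np.ndarray  # boolean, one flag per feature

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


def fit_reduction_mask(X: np.ndarray) -> ReductionMask:
    """Flag features that take a single value across all rows (both classes
    pooled) for removal."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("reduction mask requires a matrix with >= 2 rows")
    keep = (X != X[0]).any(axis=0)
    return ReductionMask(keep=keep)


def apply_reduction(X: np.ndarray, mask: ReductionMask) -> np.ndarray:
    """Order-preserving projection onto the kept features."""
    X = np.asarray(X)
    if X.shape[-1] != mask.keep.shape[0]:
        raise ValueError(
            f"feature length {X.shape[-1]} does not match mask length {mask.keep.shape[0]}"
        )
    return X[..., mask.keep]
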