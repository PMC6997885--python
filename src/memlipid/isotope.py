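"""Natural-abundance correction of 13C mass-isotopomer distributions.

A measured isotopologue vector M+0..M+n mixes tracer labeling with
natural 13C.  With each non-tracer carbon independently 13C with
probability ``p_natural``, the observed distribution is a linear
transform of the tracer-labeled ("skeleton") distribution; the
correction inverts that transform by non-negative least squares and the
labeled fraction of the pool is 100 x (1 - corrected M+0).

Derivatization carbons (e.g. the methyl ester from FAME preparation)
contribute natural abundance but can never carry tracer label; oxygen,
hydrogen and silicon isotopes are not corrected (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "IsotopologueVector",
    "IsotopeConfig",
    "correction_matrix",
    "correct_mid",
    "fraction_labeled",
]

#: IUPAC natural abundance of 13C
P_NATURAL_13C = 0.0107


@dataclass(frozen=True)
class IsotopologueVector:
    metabolite: str
    n_carbons: int
    intensities: tuple[float, ...]  # M+0 .. M+n

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", tuple(self.intensities))
        if len(self.intensities) != self.n_carbons + 1:
            raise ValueError("need n_carbons + 1 intensities (M+0..M+n)")
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")
        if not any(self.intensities):
            raise ValueError("all-zero isotopologue vector")


@dataclass(frozen=True)
class IsotopeConfig:
    p_natural: float = P_NATURAL_13C
    derivatization_carbons: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_natural < 1.0:
            raise ValueError("p_natural must lie in [0, 1)")
        if self.derivatization_carbons < 0:
            raise ValueError("derivatization_carbons must be >= 0")


def correction_matrix(n_carbons: int, config: IsotopeConfig = IsotopeConfig()) -> np.ndarray:
    """(n+1) x (n+1) natural-abundance matrix.

    Entry [i, j] is the probability of observing mass shift i given j
    tracer-labeled skeleton carbons: the remaining
    ``n_carbons - j + derivatization_carbons`` carbons pick up ``i - j``
    natural 13C atoms binomially.  Columns sum to <= 1 because shifts
    beyond M+n are truncated.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    n = n_carbons
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        free = n - j + config.derivatization_carbons
        for i in range(j, n + 1):
            mat[i, j] = binom.pmf(i - j, free, config.p_natural)
    return mat


def correct_mid(measured: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Corrected fractional MID solving measured ~ matrix @ corrected.

    Solved by non-negative least squares (robust to counting noise) and
    renormalized to sum to 1.
    """
    y = np.asarray(measured, dtype=float)
    if y.ndim != 1 or matrix.shape != (y.size, y.size):
        raise ValueError("measured vector and matrix dimensions disagree")
    if np.linalg.cond(matrix) > 1e12:
        raise ValueError("correction matrix is ill-conditioned")
    total = y.sum()
    if total <= 0:
        raise ValueError("measured intensities sum to zero")
    x, _ = nnls(matrix, y / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero distribution")
    return x / s


def fraction_labeled(corrected: np.ndarray) -> float:
    """Percent of the pool carrying one or more 13C atoms: 100 (1 - M+0)."""
    x = np.asarray(corrected, dtype=float)
    return 100.0 * (1.0 - x[0] / x.sum())
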