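"""DEMATEL influence analysis of expert impact judgements.

The Decision-Making Trial and Evaluation Laboratory (DEMATEL) method turns
an expert pairwise-impact matrix ``B`` (``b_ij`` = strength of the direct
impact of variable *i* on variable *j*, small non-negative integers, zero
diagonal) into a *total-influence* matrix capturing direct plus all
indirect effects:

1. normalise: ``BN = B / lambda`` with
   ``lambda = max(max row sum, max column sum)``;
2. total influence: ``T = BN + BN^2 + ... = BN (I - BN)^{-1}``,
   which converges because the spectral radius of ``BN`` is below 1 for
   any non-degenerate admissible matrix;
3. per-variable indicators from row sums ``R_i = sum_j t_ij`` and column
   sums ``C_i = sum_j t_ji``:

   * prominence ``t+ = R + C`` — the variable's overall involvement in
     the system's dependency structure;
   * relation ``t- = R - C`` — positive for net causes (the variable
     drives others), negative for net effects; the relations sum to zero
     across variables by construction.

The inverse is evaluated through a linear solve, never an explicit
matrix inverse, and inputs whose normalised spectral radius reaches 1
(within 1e-9) are rejected with a :class:`~kpibench.errors.ConvergenceError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateInputError

__all__ = [
    "ImpactMatrix",
    "NormalizedImpactMatrix",
    "TotalInfluenceMatrix",
    "InfluenceIndicators",
    "normalization_factor",
    "normalize",
    "total_influence",
    "influence_indicators",
    "analyse",
]

#: Default admissible judgement scale: 0 (no impact) .. 3 (huge impact).
DEFAULT_SCALE_MAX = 3

_SPECTRAL_TOL = 1e-9


@dataclass(frozen=True)
class ImpactMatrix:
    """Square integer expert-judgement matrix of direct impacts.

    ``scale_max`` bounds the admissible cell values; pass ``None`` to skip
    the scale check (the structural checks — square, non-negative integers,
    zero diagonal — always apply).
    """

    labels: tuple[str, ...]
    cells: np.ndarray
    scale_max: int | None = DEFAULT_SCALE_MAX

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
            raise DegenerateInputError("impact matrix must be square")
        if not np.issubdtype(cells.dtype, np.integer):
            as_int = cells.astype(int)
            if not np.array_equal(as_int, cells):
                raise DegenerateInputError("impact matrix cells must be integers")
            cells = as_int
        n = cells.shape[0]
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != n:
            raise DegenerateInputError(f"{len(labels)} labels for a {n}x{n} matrix")
        if n < 2:
            raise DegenerateInputError("impact matrix needs at least two variables")
        if np.any(cells < 0):
            raise DegenerateInputError("impact values must be non-negative")
        if np.any(np.diag(cells) != 0):
            raise DegenerateInputError("diagonal must be zero (no self-impact)")
        if self.scale_max is not None and np.any(cells > self.scale_max):
            raise DegenerateInputError(
                f"impact values exceed the admissible scale 0..{self.scale_max}"
            )
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_max: int | None = DEFAULT_SCALE_MAX) -> "ImpactMatrix":
        return cls(labels=tuple(str(c) for c in frame.columns), cells=frame.to_numpy(), scale_max=scale_max)


@dataclass(frozen=True)
class NormalizedImpactMatrix:
    labels: tuple[str, ...]
    cells: np.ndarray
    lambda_used: float


@dataclass(frozen=True)
class TotalInfluenceMatrix:
    """Total influence ``T`` and its indirect part ``B_hat = T - BN``."""

    labels: tuple[str, ...]
    cells: np.ndarray
    indirect: np.ndarray


@dataclass(frozen=True)
class InfluenceIndicators:
    """Per-variable prominence (``t_plus``) and relation (``t_minus``)."""

    labels: tuple[str, ...]
    t_plus: np.ndarray
    t_minus: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_plus": self.t_plus, "t_minus": self.t_minus},
            index=pd.Index(list(self.labels), name="variable"),
        )


def normalization_factor(matrix: ImpactMatrix) -> float:
    """Largest of all row sums and column sums of the impact matrix."""
    cells = matrix.cells
    lam = float(max(cells.sum(axis=1).max(), cells.sum(axis=0).max()))
    if lam == 0.0:
        raise DegenerateInputError("all-zero impact matrix: normalization factor would be zero")
    return lam


def normalize(matrix: ImpactMatrix) -> NormalizedImpactMatrix:
    lam = normalization_factor(matrix)
    return NormalizedImpactMatrix(labels=matrix.labels, cells=matrix.cells / lam, lambda_used=lam)


def total_influence(normalized: NormalizedImpactMatrix) -> TotalInfluenceMatrix:
    """Closed-form total influence ``T = BN (I - BN)^{-1}``.

    Equivalent to the matrix-geometric series ``sum_{k>=1} BN^k``; the
    indirect part is ``T - BN``.  Computed by solving the transposed
    system ``(I - BN)^T X^T = BN^T`` rather than forming an inverse.
    """
    bn = np.asarray(normalized.cells, dtype=float)
    n = bn.shape[0]
    rho = float(np.max(np.abs(np.linalg.eigvals(bn))))
    if rho >= 1.0 - _SPECTRAL_TOL:
        raise ConvergenceError(
            f"influence series diverges: spectral radius of the normalized matrix is "
            f"{rho:.9f} (must be < 1)"
        )
    t = np.linalg.solve((np.eye(n) - bn).T, bn.T).T
    return TotalInfluenceMatrix(labels=normalized.labels, cells=t, indirect=t - bn)


def influence_indicators(total: TotalInfluenceMatrix) -> InfluenceIndicators:
    """Prominence ``t+ = R + C`` and relation ``t- = R - C`` per variable."""
    rows = total.cells.sum(axis=1)
    cols = total.cells.sum(axis=0)
    return InfluenceIndicators(labels=total.labels, t_plus=rows + cols, t_minus=rows - cols)


def analyse(matrix: ImpactMatrix) -> InfluenceIndicators:
    """Full pipeline: impact matrix -> normalisation -> T -> (t+, t-)."""
    return influence_indicators(total_influence(normalize(matrix)))
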