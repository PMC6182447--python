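"""Difference sequences and the differencing matrix.

A difference sequence of order ``m`` is a weight vector ``(d_0, ..., d_m)``
with zero sum and unit sum of squares.  Applied as a moving filter, it
annihilates locally-constant signals (and attenuates smooth ones at rate
O(1/n)), which is what lets ordinary least squares on the differenced data
ignore the nonparametric component of a partially linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dols import PLMData

__all__ = [
    "DifferenceSequence",
    "DifferencedData",
    "SequenceConstraintError",
    "make_simple_sequence",
    "validate_sequence",
    "build_difference_matrix",
    "apply_differencing",
]

#: largest n for which a dense differencing matrix is materialized
_DENSE_LIMIT = 10_000


class SequenceConstraintError(ValueError):
    """A candidate weight vector violates a difference-sequence constraint."""


@dataclass(frozen=True)
class DifferenceSequence:
    """Validated difference-sequence weights.

    Attributes
    ----------
    order : int
        The differencing order ``m``; the filter has ``m + 1`` taps.
    weights : numpy.ndarray
        Weights ``(d_0, ..., d_m)`` with ``sum(d) == 0`` and
        ``sum(d**2) == 1``.
    """

    order: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.order < 1:
            raise SequenceConstraintError("differencing order must be >= 1")
        if w.ndim != 1 or w.size != self.order + 1:
            raise SequenceConstraintError(
                f"expected {self.order + 1} weights for order {self.order}, "
                f"got shape {w.shape}"
            )


def make_simple_sequence(m: int) -> DifferenceSequence:
    """Return the simple difference sequence of order ``m``.

    Weights are ``d_0 = sqrt(m/(m+1))`` and ``d_q = -1/sqrt(m(m+1))`` for
    ``q >= 1``; for ``m = 3`` this is the classical choice
    ``(sqrt(3/4), -sqrt(1/12), -sqrt(1/12), -sqrt(1/12))``.
    """
    if m < 1:
        raise SequenceConstraintError(f"differencing order must be >= 1, got {m}")
    w = np.full(m + 1, -1.0 / np.sqrt(m * (m + 1.0)))
    w[0] = np.sqrt(m / (m + 1.0))
    return DifferenceSequence(order=m, weights=w)


def validate_sequence(weights, atol: float = 1e-8) -> DifferenceSequence:
    """Check user-supplied weights against the sequence constraints.

    Parameters
    ----------
    weights : array-like
        Candidate weights ``(d_0, ..., d_m)``, length at least 2.
    atol : float
        Absolute tolerance on both constraint residuals.  The default is
        loose enough for weights entered as decimal literals.

    Raises
    ------
    SequenceConstraintError
        Naming the violated constraint and its residual.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise SequenceConstraintError(
            f"weights must be a 1-d vector of length >= 2, got shape {w.shape}"
        )
    s = w.sum()
    if abs(s) > atol:
        raise SequenceConstraintError(
            f"sum constraint violated: sum(d) = {s:.3e} (|residual| > {atol:g})"
        )
    ss = w @ w
    if abs(ss - 1.0) > atol:
        raise SequenceConstraintError(
            f"sum-of-squares constraint violated: sum(d^2) = {ss:.6g}, "
            f"residual {ss - 1.0:.3e} (|residual| > {atol:g})"
        )
    return DifferenceSequence(order=w.size - 1, weights=w)


@dataclass(frozen=True)
class DifferencedData:
    """The differenced response and design, each with ``n - m`` rows."""

    y_tilde: np.ndarray
    X_tilde: np.ndarray

    def __post_init__(self) -> None:
        if self.y_tilde.shape[0] != self.X_tilde.shape[0]:
            raise ValueError("y_tilde and X_tilde must have the same row count")


def build_difference_matrix(seq: DifferenceSequence, n: int) -> np.ndarray:
    """Return the dense ``(n - m) x n`` banded differencing matrix.

    Row ``i`` carries the weights in columns ``i .. i + m``.  Dense output is
    capped at ``n = 10_000``; above that use :func:`apply_differencing`,
    which never materializes the matrix.
    """
    m = seq.order
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    if n > _DENSE_LIMIT:
        raise ValueError(
            f"dense differencing matrix capped at n={_DENSE_LIMIT}; "
            "use apply_differencing for larger samples"
        )
    D = np.zeros((n - m, n))
    for q, d in enumerate(seq.weights):
        idx = np.arange(n - m)
        D[idx, idx + q] = d
    return D


def _difference_columns(seq: DifferenceSequence, a: np.ndarray) -> np.ndarray:
    """Apply the filter along axis 0 of a vector or matrix (banded, O(n))."""
    w = seq.weights
    if a.ndim == 1:
        return np.correlate(a, w, mode="valid")
    return np.column_stack([np.correlate(a[:, j], w, mode="valid") for j in range(a.shape[1])])


def apply_differencing(seq: DifferenceSequence, data: "PLMData") -> DifferencedData:
    """Difference a partially linear sample: ``ỹ_i = Σ_q d_q y_{i+q}``, same for X."""
    y = np.asarray(data.y, dtype=float)
    X = np.asarray(data.X, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"y has {y.shape[0]} rows but X has {X.shape[0]}")
    if y.shape[0] <= seq.order:
        raise ValueError(f"need n > m, got n={y.shape[0]}, m={seq.order}")
    return DifferencedData(
        y_tilde=_difference_columns(seq, y),
        X_tilde=_difference_columns(seq, X),
    )
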