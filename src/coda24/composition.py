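"""Simplex arithmetic for the 4-part daily activity composition.

A day is partitioned into sleep, sedentary time (ST), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA).  The
four durations carry only relative information and are analysed on the
simplex after *closure* to a constant total (1440 min).  This module
provides closure, multiplicative zero replacement, compositional
(geometric-mean) descriptives, the pivot isometric log-ratio (ILR)
transform and its inverse, and the conversion between first-pivot
regression coefficients and centred log-ratio (clr) coefficients.

Canonical part order is ``(sleep, st, lpa, mvpa)`` everywhere.  Pivot
coordinate systems cycle the pivot part to the front and keep the
remaining parts in canonical order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Canonical behaviour order used throughout the package.
PARTS: tuple[str, ...] = ("sleep", "st", "lpa", "mvpa")

#: Closure total: minutes in a 24-h day.
TOTAL_MINUTES: float = 1440.0

_SQRT34 = math.sqrt(3.0 / 4.0)  # first-pivot normalisation, D = 4


class DegenerateCompositionError(ValueError):
    """Raised when a composition has no positive information (all zero)."""


class InfeasibleReplacementError(ValueError):
    """Raised when a zero-replacement floor cannot fit inside the total."""


def _part_index(part: str) -> int:
    try:
        return PARTS.index(part)
    except ValueError:
        raise KeyError(f"unknown behaviour {part!r}; expected one of {PARTS}") from None


@dataclass(frozen=True)
class ActivityComposition:
    """A closed 4-part daily time-use vector, in minutes per day."""

    sleep: float
    st: float
    lpa: float
    mvpa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sleep, self.st, self.lpa, self.mvpa], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float] | np.ndarray) -> "ActivityComposition":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise ValueError(f"expected 4 parts, got shape {x.shape}")
        return cls(*x.tolist())

    def __getitem__(self, part: str) -> float:
        return float(self.as_array()[_part_index(part)])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


@dataclass(frozen=True)
class PivotIlrCoordinates:
    """The three pivot ILR coordinates of a 4-part composition.

    ``z1`` contrasts the pivot part against the geometric mean of the
    remaining three parts; it is the only coordinate whose value does
    not depend on how the rest is ordered.
    """

    pivot_part: str
    z1: float
    z2: float
    z3: float
    part_order_used: tuple[str, str, str]

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3], dtype=float)


@dataclass(frozen=True)
class ClrCoefficients:
    """Centred log-ratio regression coefficients, one per behaviour.

    Units are outcome units per unit of log-minutes; a valid clr vector
    sums to zero.
    """

    a_sleep: float
    a_st: float
    a_lpa: float
    a_mvpa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a_sleep, self.a_st, self.a_lpa, self.a_mvpa], dtype=float)

    def __getitem__(self, part: str) -> float:
        return float(self.as_array()[_part_index(part)])

    @property
    def sum(self) -> float:
        return float(self.as_array().sum())


def close(raw: Sequence[float] | np.ndarray, total: float = TOTAL_MINUTES) -> ActivityComposition:
    """Rescale a raw nonnegative 4-vector so its parts sum to ``total``.

    Ratios between parts are preserved; this is the closure operation of
    compositional data analysis ("linear adjustment" to a constant sum).
    """
    x = np.asarray(raw, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"expected 4 parts, got shape {x.shape}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("parts must be finite and nonnegative")
    if total <= 0:
        raise ValueError("closure total must be positive")
    s = x.sum()
    if s == 0:
        raise DegenerateCompositionError("cannot close an all-zero composition")
    return ActivityComposition.from_array(x * (total / s))


def replace_zeros(
    raw: Sequence[float] | np.ndarray, floor: float = 1.0
) -> np.ndarray:
    """Multiplicative replacement of parts below ``floor`` minutes.

    Parts below the floor are raised to it and the remaining parts are
    multiplicatively shrunk so the input total is preserved, keeping the
    log-ratios among untouched parts intact.
    """
    x = np.asarray(raw, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"expected 4 parts, got shape {x.shape}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    total = x.sum()
    if total == 0:
        raise DegenerateCompositionError("cannot replace zeros in an all-zero composition")
    if 4 * floor >= total:
        raise InfeasibleReplacementError(
            f"floor {floor} min x 4 parts does not fit inside total {total} min"
        )
    low = x < floor
    if not low.any():
        return x.copy()
    shrink = (total - low.sum() * floor) / x[~low].sum()
    out = x * shrink
    out[low] = floor
    return out


def compositional_mean(
    rows: Iterable[ActivityComposition | Sequence[float]],
    total: float = TOTAL_MINUTES,
) -> ActivityComposition:
    """Part-wise geometric mean across rows, closed to ``total``.

    This is the compositional centre: the descriptive statistic that
    respects the relative (ratio) nature of time-use data.
    """
    mat = np.array(
        [r.as_array() if isinstance(r, ActivityComposition) else np.asarray(r, float) for r in rows]
    )
    if mat.size == 0:
        raise ValueError("compositional_mean needs at least one row")
    if np.any(mat <= 0):
        raise ValueError("all parts must be strictly positive for a geometric mean")
    gm = np.exp(np.log(mat).mean(axis=0))
    return close(gm, total=total)


def composition_percentages(c: ActivityComposition) -> dict[str, float]:
    """Share of the day spent in each behaviour, in percent (sums to 100)."""
    x = c.as_array()
    pct = x / x.sum() * 100.0
    return dict(zip(PARTS, pct.tolist()))


def pivot_order(pivot: str) -> tuple[str, ...]:
    """Part order for a pivot system: pivot first, rest in canonical order."""
    _part_index(pivot)
    return (pivot,) + tuple(p for p in PARTS if p != pivot)


def pivot_basis(pivot: str) -> np.ndarray:
    """Orthonormal ILR contrast matrix (4 x 3) for a pivot, canonical row order.

    Column ``k`` holds the log-contrast weights of coordinate ``z_{k+1}``:
    ``z = V.T @ ln(x)``.  Columns each sum to zero (closure invariance)
    and are orthonormal, so the basis change between two pivots is a
    rotation and model fit is pivot-invariant.
    """
    order = pivot_order(pivot)
    V_ordered = np.zeros((4, 3))
    for k in range(3):  # coordinate z_{k+1} contrasts part k against parts k+1..3
        r = 3 - k  # number of parts in the denominator geometric mean
        coef = math.sqrt(r / (r + 1.0))
        V_ordered[k, k] = coef
        V_ordered[k + 1 :, k] = -coef / r
    # reorder rows back to canonical (sleep, st, lpa, mvpa)
    V = np.zeros((4, 3))
    for i, part in enumerate(order):
        V[_part_index(part)] = V_ordered[i]
    return V


def _ilr_from_log(logx: np.ndarray, pivot: str) -> np.ndarray:
    """Vectorised pivot ILR of log-minutes; ``logx`` has shape (..., 4)."""
    return logx @ pivot_basis(pivot)


def pivot_ilr(c: ActivityComposition | Sequence[float], pivot: str) -> PivotIlrCoordinates:
    """Pivot ILR coordinates of one composition.

    ``z1 = sqrt(3/4) * ln(x_pivot / g(rest))`` with ``g`` the geometric
    mean; ``z2``/``z3`` complete the orthonormal basis over the rest in
    canonical order.  The result is invariant to closure scaling.
    """
    x = c.as_array() if isinstance(c, ActivityComposition) else np.asarray(c, float)
    if np.any(x <= 0):
        raise ValueError("pivot ILR requires strictly positive parts")
    z = _ilr_from_log(np.log(x), pivot)
    rest = tuple(p for p in PARTS if p != pivot)
    return PivotIlrCoordinates(pivot, float(z[0]), float(z[1]), float(z[2]), rest)


def pivot_ilr_with_order(
    c: ActivityComposition | Sequence[float], pivot: str, rest_order: Sequence[str]
) -> PivotIlrCoordinates:
    """Pivot ILR with an explicit ordering of the three non-pivot parts.

    Only ``z2``/``z3`` depend on the ordering; ``z1`` never does.
    """
    x = c.as_array() if isinstance(c, ActivityComposition) else np.asarray(c, float)
    if np.any(x <= 0):
        raise ValueError("pivot ILR requires strictly positive parts")
    rest = tuple(rest_order)
    if sorted(rest) != sorted(p for p in PARTS if p != pivot):
        raise ValueError(f"rest_order must be a permutation of the non-pivot parts, got {rest}")
    order = (pivot,) + rest
    lx = np.log(x[[ _part_index(p) for p in order ]])
    z = np.empty(3)
    for k in range(3):
        r = 3 - k
        z[k] = math.sqrt(r / (r + 1.0)) * (lx[k] - lx[k + 1 :].mean())
    return PivotIlrCoordinates(pivot, float(z[0]), float(z[1]), float(z[2]), rest)


def inverse_pivot_ilr(
    z: PivotIlrCoordinates | Sequence[float],
    pivot: str | None = None,
    total: float = TOTAL_MINUTES,
) -> ActivityComposition:
    """Map pivot ILR coordinates back to a closed composition.

    Inverse of :func:`pivot_ilr` up to closure: ``ln x = V z`` followed
    by exponentiation and closure to ``total``.
    """
    if isinstance(z, PivotIlrCoordinates):
        pivot = z.pivot_part
        zv = z.as_array()
    else:
        if pivot is None:
            raise ValueError("pivot must be given when z is a bare 3-vector")
        zv = np.asarray(z, dtype=float)
    if zv.shape != (3,) or not np.all(np.isfinite(zv)):
        raise ValueError("z must be a finite 3-vector")
    logx = pivot_basis(pivot) @ zv
    return close(np.exp(logx - logx.max()), total=total)


def clr_from_pivot_beta1(beta1: Sequence[float]) -> ClrCoefficients:
    """Convert four first-pivot coefficients (canonical order) to clr scale.

    The first-pivot coefficient for behaviour *j* equals the clr
    coefficient ``a_j`` divided by ``sqrt(3/4)``, so ``a_j =
    sqrt(3/4) * beta1_j``.  Because clr coefficients sum to zero exactly,
    a printed-and-rounded beta1 quadruple should sum to ~0; a deviation
    beyond 0.02 (the worst case for 2-dp rounding) triggers a warning.
    """
    b = np.asarray(beta1, dtype=float)
    if b.shape != (4,):
        raise ValueError("expected 4 first-pivot coefficients in canonical part order")
    if abs(b.sum()) > 0.02 + 1e-9:
        warnings.warn(
            f"first-pivot coefficients sum to {b.sum():.4f}, beyond 2-dp rounding "
            "tolerance 0.02; they may not come from one model",
            stacklevel=2,
        )
    a = _SQRT34 * b
    return ClrCoefficients(*a.tolist())


def clr_from_ilr(coeffs: Sequence[float], pivot: str) -> ClrCoefficients:
    """Project a fitted 3-vector of ILR coefficients onto the clr scale."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (3,):
        raise ValueError("expected 3 ILR coefficients")
    return ClrCoefficients(*(pivot_basis(pivot) @ c).tolist())
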