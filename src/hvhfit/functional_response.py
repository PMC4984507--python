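"""Hassell-Varley-Holling trophic function and consumer growth rate.

The per-capita foraging rate of a consumer at resource availability ``R``
(mg of basal resource) and conspecific density ``C`` (cells/mL) is modelled
as

    f(R, C) = a R C^m / (1 + a h R C^m)

where ``a`` is the attack rate, ``h`` the handling time (hours) and ``m``
the mutual-interference exponent.  ``m = 0`` is a purely exploitative
(Holling type II) system in which foraging depends on resources only;
``m = -1`` is fully ratio-dependent: foraging is set by resource per
consumer.  Consumer dynamics follow a MacArthur-Rosenzweig consumer
equation with conversion efficiency ``e`` and density-independent
mortality ``mu``:

    dC/dt = C (e f(R, C) - mu).

The HVH form is not dimensionally homogeneous in ``m``; the attack rate
``a`` carries whatever compensating units ``C^m`` requires.  Units are
fixed throughout the package as mg (R), cells/mL (C) and hours (t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "HVHParams",
    "FixedParams",
    "M_BOUNDS",
    "foraging_rate",
    "consumer_growth",
    "saturation_limit",
    "response_surface",
]

#: Conventional bounds for the interference exponent.  They bracket the
#: empirically reported range for ciliate microcosms (about -1 to 0) with
#: margin; fitting routines accept custom bounds.
M_BOUNDS = (-2.0, 1.0)


@dataclass(frozen=True)
class HVHParams:
    """Free parameters of the Hassell-Varley-Holling trophic function.

    Parameters
    ----------
    a : float
        Attack rate (per mg per hour, carrying the compensating units of
        ``C^m``).  Must be positive.
    h : float
        Handling time in hours.  Must be nonnegative; sets the foraging
        ceiling ``1/h``.
    m : float or ndarray
        Mutual-interference exponent (dimensionless).  May be an array when
        a batch of microcosms with heterogeneous interference is evaluated
        at once.
    m_bounds : tuple of float
        Admissible range for ``m``; defaults to :data:`M_BOUNDS`.
    """

    a: float
    h: float
    m: float | np.ndarray
    m_bounds: tuple[float, float] = field(default=M_BOUNDS, compare=False)

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.a) > 0):
            raise DomainError(f"attack rate must be positive, got a={self.a!r}")
        if not np.all(np.asarray(self.h) >= 0):
            raise DomainError(f"handling time must be nonnegative, got h={self.h!r}")
        lo, hi = self.m_bounds
        m = np.asarray(self.m, dtype=float)
        if not (np.all(m >= lo) and np.all(m <= hi)):
            raise DomainError(
                f"interference exponent m={self.m!r} outside bounds {self.m_bounds}"
            )


@dataclass(frozen=True)
class FixedParams:
    """Constants of the consumer equation held fixed during estimation.

    ``e`` is the conversion efficiency (dimensionless fraction of consumed
    resource turned into consumer growth) and ``mu`` the natural mortality
    rate (per hour).
    """

    e: float = 0.8
    mu: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.e <= 1:
            raise DomainError(f"conversion efficiency must be in (0, 1], got {self.e}")
        if self.mu < 0:
            raise DomainError(f"mortality must be nonnegative, got {self.mu}")


def foraging_rate(R, C, p: HVHParams):
    """Per-capita foraging rate ``f(R, C) = aRC^m / (1 + ahRC^m)``.

    Vectorized over ``R``, ``C`` and ``p.m`` (numpy broadcasting).  ``C``
    must be strictly positive because ``C^m`` is singular at zero for
    negative ``m``; the consumer equation handles extinction separately.

    Raises
    ------
    DomainError
        If any ``R <= 0`` or ``C <= 0``.
    """
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(R <= 0):
        raise DomainError("resource availability R must be positive")
    if np.any(C <= 0):
        raise DomainError("consumer density C must be positive (C^m singular at 0)")
    x = p.a * R * np.power(C, p.m)
    f = x / (1.0 + p.a * p.h * R * np.power(C, p.m))
    if f.ndim == 0:
        return float(f)
    return f


def consumer_growth(C, R, p: HVHParams, fx: FixedParams):
    """MacArthur-Rosenzweig consumer growth rate ``dC/dt = C(e f - mu)``.

    ``C = 0`` is an absorbing state and returns exactly 0 without
    evaluating the (singular) trophic function.  Vectorized.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("consumer density must be nonnegative")
    # avoid evaluating C^m at C = 0; masked entries are forced to 0 below
    C_safe = np.where(C > 0, C, 1.0)
    f = foraging_rate(R, C_safe, p)
    dCdt = np.where(C > 0, C * (fx.e * np.asarray(f) - fx.mu), 0.0)
    if dCdt.ndim == 0:
        return float(dCdt)
    return dCdt


def saturation_limit(p: HVHParams) -> float:
    """Supremum ``1/h`` of the foraging rate over all (R, C).

    Returns positive infinity when handling time is zero (the linear,
    unsaturated response).
    """
    if p.h == 0:
        return float("inf")
    return 1.0 / p.h


def response_surface(R, C_grid, m_grid, a: float, h: float) -> pd.DataFrame:
    """Evaluate the trophic function over a (C, m) grid at fixed R.

    Produces the long-format table behind the response-surface figure: one
    row per (C, m) combination with columns ``R, C, m, a, h, f``.  For any
    fixed ``R`` and ``C > 1``, ``f`` is nondecreasing in ``m``; all curves
    cross at ``C = 1`` where ``C^m = 1`` for every ``m``.
    """
    C_grid = np.asarray(C_grid, dtype=float)
    m_grid = np.asarray(m_grid, dtype=float)
    if C_grid.size == 0 or m_grid.size == 0:
        raise DomainError("C and m grids must be nonempty")
    rows = []
    for m in m_grid:
        p = HVHParams(a=a, h=h, m=float(m))
        f = foraging_rate(R, C_grid, p)
        rows.append(
            pd.DataFrame(
                {
                    "R": float(R),
                    "C": C_grid,
                    "m": float(m),
                    "a": a,
                    "h": h,
                    "f": np.atleast_1d(f),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
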