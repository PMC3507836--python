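"""Parameterisations of the growth-zone activation model.

The model describes ``n`` growth zones (the polarisome complexes at the cell
tips, optionally plus a lateral site) competing for a single cytosolic
substrate whose total amount is proportional to cell length.  Two
parameterisations are supported:

* :class:`DimensionalParams` — mass-action rates and amounts, the form in
  which the biochemistry is stated.
* :class:`NondimParams` — the non-dimensional form used throughout the
  analysis, with basal activation strength ``epsilon``, autocatalytic
  strength ``beta`` and zone weights ``a`` (the share of total polarisome
  held by each zone).  The substrate/length parameter ``l`` is carried
  separately because it is the bifurcation parameter.

The non-dimensional state ``x_i`` is the *active fraction* of zone ``i``
(range [0, 1]); ``l = 1`` means the substrate is exactly sufficient to fully
activate every zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "DimensionalParams",
    "NondimParams",
    "NondimensionalMap",
    "nondimensionalize",
]

_WEIGHT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class NondimParams:
    """Non-dimensional model parameters (without the bifurcation parameter l).

    Parameters
    ----------
    epsilon : float
        Basal activation strength (dimensionless, >= 0).  ``epsilon = 0`` is
        accepted here for exact analysis of the degenerate inactive state but
        is rejected by the continuation and phenotype layers.
    beta : float
        Autocatalytic activation strength (dimensionless, >= 0).
    a : tuple of float
        Zone weights, the proportion of total polarisome on each zone.
        Must be non-negative and sum to one.
    """

    epsilon: float
    beta: float
    a: Tuple[float, ...]

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.a)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "epsilon", float(self.epsilon))
        object.__setattr__(self, "beta", float(self.beta))
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if len(a) < 2:
            raise ValueError("need at least two growth zones")
        if any(v < 0 for v in a):
            raise ValueError("zone weights must be non-negative")
        if abs(sum(a) - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(
                f"zone weights must sum to 1 within {_WEIGHT_SUM_TOL}; got sum {sum(a)!r}"
            )

    @property
    def n_zones(self) -> int:
        return len(self.a)

    @property
    def a_array(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float)

    def with_(self, **kwargs) -> "NondimParams":
        """Return a copy with the given fields replaced."""
        d = {"epsilon": self.epsilon, "beta": self.beta, "a": self.a}
        d.update(kwargs)
        return NondimParams(**d)

    def to_dict(self) -> dict:
        return {"epsilon": self.epsilon, "beta": self.beta, "a": list(self.a)}


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional (mass-action) parameters.

    Rates follow the activation scheme: inactive polarisome is activated by
    free substrate at rate ``(k_basal + k_auto * A_i**2)`` per unit substrate
    and inactive amount, where ``A_i`` is the active amount on zone ``i``;
    active polarisome inactivates at first-order rate ``k_off``, releasing
    its substrate.

    Fields
    ------
    k_basal : basal activation rate, 1/(amount * time)
    k_auto  : autocatalytic coefficient, 1/(amount**3 * time)
    k_off   : inactivation rate, 1/time
    T       : per-zone total polarisome amounts, length n >= 2
    sigma   : substrate amount per unit cell length
    L       : cell length
    """

    k_basal: float
    k_auto: float
    k_off: float
    T: Tuple[float, ...]
    sigma: float
    L: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "T", tuple(float(v) for v in self.T))
        for name in ("k_basal", "k_auto", "k_off", "sigma", "L"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if min(self.k_basal, self.k_auto, self.k_off) <= 0:
            raise ValueError("all rates must be strictly positive")
        if self.sigma <= 0 or self.L <= 0:
            raise ValueError("sigma and L must be strictly positive")
        if len(self.T) < 2:
            raise ValueError("need at least two growth zones")
        if any(t < 0 for t in self.T):
            raise ValueError("zone totals must be non-negative")
        if sum(t > 0 for t in self.T) < 2:
            raise ValueError("at least two zone totals must be positive")

    @property
    def T_total(self) -> float:
        return float(sum(self.T))

    def rhs(self, A: Sequence[float]) -> np.ndarray:
        """Time derivative of the active amounts ``A`` (dimensional form)."""
        A = np.asarray(A, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if A.shape != T.shape:
            raise ValueError("state dimension does not match number of zones")
        S = self.sigma * self.L - A.sum()
        return (self.k_basal + self.k_auto * A**2) * S * (T - A) - self.k_off * A

    def to_dict(self) -> dict:
        return {
            "k_basal": self.k_basal,
            "k_auto": self.k_auto,
            "k_off": self.k_off,
            "T": list(self.T),
            "sigma": self.sigma,
            "L": self.L,
        }


@dataclass(frozen=True)
class NondimensionalMap:
    """The change of variables between the dimensional and non-dimensional forms.

    ``x_i = A_i / T_i``, ``tau = k_off * t``, ``l = sigma * L / T_total``.
    The map is exact for arbitrary zone totals: autocatalysis quadratic in
    the active *amount* turns into ``beta * (a_i * x_i)**2`` with a single
    shared ``beta = k_auto * T_total**3 / k_off``.
    """

    params: NondimParams
    l: float
    time_scale: float  # one unit of tau equals `time_scale` units of t
    T: Tuple[float, ...] = field(repr=False)

    def state_to_nondim(self, A: Sequence[float]) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        return A / np.asarray(self.T, dtype=float)

    def state_to_dim(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x * np.asarray(self.T, dtype=float)


def nondimensionalize(dim: DimensionalParams) -> NondimensionalMap:
    """Map dimensional parameters onto the non-dimensional parameterisation.

    Returns a :class:`NondimensionalMap` carrying the ``NondimParams``, the
    substrate/length parameter ``l``, the time scale ``1/k_off`` and the
    state maps.  Integrating the dimensional system and mapping the result
    equals mapping the initial state and integrating the non-dimensional
    system (trajectory equivalence).
    """
    T_tot = dim.T_total
    if T_tot <= 0:
        raise ValueError("total polarisome amount must be positive")
    a = tuple(t / T_tot for t in dim.T)
    epsilon = dim.k_basal * T_tot / dim.k_off
    beta = dim.k_auto * T_tot**3 / dim.k_off
    l = dim.sigma * dim.L / T_tot
    params = NondimParams(epsilon=epsilon, beta=beta, a=a)
    return NondimensionalMap(params=params, l=l, time_scale=1.0 / dim.k_off, T=dim.T)
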