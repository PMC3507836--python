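"""Steady-state enumeration and linear stability.

The quasi-static view of cell growth treats the substrate parameter ``l``
as frozen for the fast activation dynamics, so the biologically relevant
objects are the equilibria of the activation system at each ``l`` and their
stability.  :func:`enumerate_equilibria` is the brute-force oracle used to
validate the continuation machinery: Newton refinement seeded from every
node of a regular grid over the unit box, deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import model
from .params import NondimParams

__all__ = [
    "Equilibrium",
    "ConvergenceError",
    "EnumerationError",
    "refine_equilibrium",
    "enumerate_equilibria",
    "classify_stability",
]

RESIDUAL_TOL = 1e-10
TOL_EIG = 1e-8          # stability margin on eigenvalue real parts
DEDUP_TOL = 1e-6        # max-norm separation below which points are one equilibrium
BOX_TOL = 1e-9
DEFAULT_RESOLUTION = {2: 41, 3: 21}


class ConvergenceError(RuntimeError):
    """Newton refinement failed to converge to an equilibrium."""


class EnumerationError(RuntimeError):
    """Internal failure: no equilibrium found (impossible for the true flow)."""


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the activation system at fixed ``l``."""

    x: Tuple[float, ...]
    l: float
    eigenvalues: Tuple[complex, ...]
    stability: str  # "stable" | "unstable" | "marginal"
    residual: float

    @property
    def x_array(self) -> np.ndarray:
        return np.asarray(self.x, dtype=float)

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def _stability_label(eigvals: np.ndarray, tol_eig: float = TOL_EIG) -> str:
    re = eigvals.real
    if np.any(np.abs(re) <= tol_eig):
        return "marginal"
    return "stable" if np.all(re < -tol_eig) else "unstable"


def classify_stability(
    params: NondimParams, l: float, x, tol_eig: float = TOL_EIG
) -> Tuple[np.ndarray, str]:
    """Eigenvalues of the analytic Jacobian at an equilibrium and its label.

    Refuses to classify points that are not equilibria (residual >= 1e-8).
    """
    x = np.asarray(x, dtype=float)
    res = float(np.max(np.abs(model.rhs(params, l, x))))
    if res >= 1e-8:
        raise ValueError(f"not an equilibrium: residual {res:.3e} >= 1e-8")
    eigvals = np.linalg.eigvals(model.jacobian(params, l, x))
    return eigvals, _stability_label(eigvals, tol_eig)


def _make_equilibrium(params: NondimParams, l: float, x: np.ndarray) -> Equilibrium:
    res = float(np.max(np.abs(model.rhs(params, l, x))))
    eigvals = np.linalg.eigvals(model.jacobian(params, l, x))
    return Equilibrium(
        x=tuple(float(v) for v in x),
        l=float(l),
        eigenvalues=tuple(complex(v) for v in eigvals),
        stability=_stability_label(eigvals),
        residual=res,
    )


def refine_equilibrium(
    params: NondimParams,
    l: float,
    guess,
    max_iter: int = 60,
    tol: float = 1e-13,
) -> Equilibrium:
    """Damped-Newton refinement of ``guess`` to an equilibrium.

    Uses a backtracking line search on the residual norm; if the Jacobian is
    singular at an iterate, falls back to a least-squares step.  Raises
    :class:`ConvergenceError` on non-convergence or if the converged point
    lies outside ``[-1e-9, 1+1e-9]^n``.
    """
    x = np.asarray(guess, dtype=float).copy()
    if x.shape != (params.n_zones,):
        raise ValueError("guess dimension does not match number of zones")
    f = model.rhs(params, l, x)
    for _ in range(max_iter):
        nf = float(np.max(np.abs(f)))
        if nf < tol:
            break
        J = model.jacobian(params, l, x)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        # backtracking line search on the 2-norm of the residual
        base = float(np.linalg.norm(f))
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            f_new = model.rhs(params, l, x_new)
            if np.all(np.isfinite(f_new)) and float(np.linalg.norm(f_new)) < base:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("line search stalled during Newton refinement")
        x, f = x_new, f_new
    res = float(np.max(np.abs(f)))
    if res >= RESIDUAL_TOL:
        raise ConvergenceError(f"Newton did not reach residual < {RESIDUAL_TOL}: {res:.3e}")
    if np.any(x < -BOX_TOL) or np.any(x > 1.0 + BOX_TOL):
        raise ConvergenceError(f"converged point {x} lies outside the unit box")
    return _make_equilibrium(params, l, x)


def _newton_batch(
    params: NondimParams, l: float, seeds: np.ndarray, max_iter: int = 80
) -> np.ndarray:
    """Vectorised plain-Newton iteration from many seeds; returns converged points."""
    X = seeds.astype(float).copy()
    for _ in range(max_iter):
        F = model.rhs(params, l, X)
        done = np.max(np.abs(F), axis=1) < 1e-13
        if np.all(done):
            break
        J = model.jacobian(params, l, X)
        try:
            steps = np.linalg.solve(J, -F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular Jacobians on some seeds: regularise those slightly
            J = J + 1e-12 * np.eye(X.shape[1])
            steps = np.linalg.solve(J, -F[..., None])[..., 0]
        # cap the step to keep iterates from flying far outside the box
        steps = np.clip(steps, -0.5, 0.5)
        X = np.where(done[:, None], X, X + steps)
        bad = ~np.isfinite(X).all(axis=1) | (np.abs(X - 0.5).max(axis=1) > 3.0)
        X[bad] = np.nan
    F = model.rhs(params, l, X)
    ok = (
        np.isfinite(X).all(axis=1)
        & (np.max(np.abs(F), axis=1) < RESIDUAL_TOL)
        & (X >= -BOX_TOL).all(axis=1)
        & (X <= 1.0 + BOX_TOL).all(axis=1)
    )
    return X[ok]


def enumerate_equilibria(
    params: NondimParams,
    l: float,
    resolution: int | None = None,
) -> List[Equilibrium]:
    """All equilibria at fixed ``l`` found by grid-seeded Newton refinement.

    Seeds every node of a ``resolution``-per-axis grid over the unit box
    (default 41 per axis for two zones, 21 for three).  The returned list is
    deduplicated at max-norm tolerance 1e-6 and each point is classified for
    stability.  For equal weights the set is closed under the corresponding
    coordinate permutations.  A generic parameter point yields an odd count;
    an even count flags proximity to a bifurcation.
    """
    n = params.n_zones
    if resolution is None:
        resolution = DEFAULT_RESOLUTION.get(n, 15)
    if resolution < 20 and n == 2:
        raise ValueError("resolution must be >= 20 per axis")
    axis = np.linspace(0.0, 1.0, resolution)
    grids = np.meshgrid(*([axis] * n), indexing="ij")
    seeds = np.stack([g.ravel() for g in grids], axis=1)
    pts = _newton_batch(params, l, seeds)
    uniq: List[np.ndarray] = []
    for p in pts:
        for q in uniq:
            if np.max(np.abs(p - q)) < DEDUP_TOL:
                break
        else:
            uniq.append(p)
    if not uniq:
        raise EnumerationError(
            "no equilibrium found: the flow on the compact invariant box must "
            "have at least one steady state, so this is an internal failure"
        )
    eqs = [_make_equilibrium(params, l, p) for p in uniq]
    eqs.sort(key=lambda e: e.x)
    return eqs
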