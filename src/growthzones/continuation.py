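"""Branch continuation and bifurcation-diagram assembly.

Solution families of the activation system are traced in the substrate
parameter ``l`` by pseudo-arclength continuation (secant predictor, Newton
corrector), which passes through saddle-node folds.  Special points are
detected along each traced curve:

* **folds** — sign change of ``dl/ds`` along the curve (the branch's ``l``
  is locally extremal), refined to ``|dl| < 1e-8``.  The fold terminating
  the stable monopolar branch is the model's reading of NETO.
* **branch points** — a Jacobian eigenvalue crosses zero while ``l`` is
  locally monotone (pitchforks of the symmetric branch, including their
  imperfect descendants).  On an exactly symmetric diagonal branch the
  antisymmetric eigenmode provides the test function, honouring the
  symmetry rather than perturbing it; elsewhere the Jacobian determinant
  is used.

:func:`build_diagram` orchestrates tracing, branch switching at pitchforks,
and — crucially — *oracle seeding*: equilibria enumerated at a spread of
``l`` values seed additional branches so that disconnected islands are
found even though they touch no traced branch.  The assembled diagram is
validated against brute-force enumeration at sampled ``l`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from . import model
from .equilibria import (
    ConvergenceError,
    Equilibrium,
    enumerate_equilibria,
    refine_equilibrium,
    TOL_EIG,
)
from .params import NondimParams

__all__ = [
    "ContinuationSettings",
    "SpecialPoint",
    "Branch",
    "BifurcationDiagram",
    "BranchSwitchError",
    "NO_NETO",
    "trace_branch",
    "detect_special_points",
    "switch_branch",
    "classify_branch",
    "build_diagram",
    "neto_length",
]

#: Sentinel returned by :func:`neto_length` when the branch persists to l_max.
NO_NETO = float("inf")

ACTIVITY_THRESHOLD = 0.3  # a zone is "active" above this fraction


class BranchSwitchError(RuntimeError):
    """Branch switching failed on both sides of a detected branch point."""


@dataclass(frozen=True)
class ContinuationSettings:
    """Numerical settings for pseudo-arclength continuation."""

    ds0: float = 1e-3          # initial arclength step
    ds_min: float = 1e-6
    ds_max: float = 5e-2
    newton_tol: float = 1e-11
    newton_max: int = 8
    grow: float = 1.4
    shrink: float = 0.5
    max_steps: int = 20000
    max_angle: float = 0.25        # max tangent turn per step (radians)
    special_l_tol: float = 1e-8    # refinement tolerance for special-point l
    seed_l_count: int = 9          # oracle-seeding l values for island discovery
    seed_resolution: Optional[int] = None   # None -> enumerate_equilibria default
    gap_seeding: bool = True       # extra seeds between special points (islands)
    validate: bool = True
    validation_quantiles: Tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)
    validation_tol: float = 1e-5
    activity_threshold: float = ACTIVITY_THRESHOLD
    max_curves: int = 40

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


#: Reduced-accuracy settings for parameter-plane scans.
FAST_SETTINGS = ContinuationSettings(
    ds0=2e-3, seed_l_count=5, seed_resolution=21, gap_seeding=False, validate=False
)


@dataclass(frozen=True)
class SpecialPoint:
    kind: str          # "fold" | "branch_point"
    l: float
    x: Tuple[float, ...]
    test_value: float  # value of the detection test function at the point

    @property
    def x_array(self) -> np.ndarray:
        return np.asarray(self.x, dtype=float)


@dataclass
class Branch:
    """A continued solution family: ordered points ``(l, x)`` with stability."""

    params: NondimParams
    l: np.ndarray                      # (m,)
    x: np.ndarray                      # (m, n)
    stability: List[str]               # per point
    label: Optional[str] = None
    special_points: List[SpecialPoint] = field(default_factory=list)
    closed: bool = False               # island branches form a closed curve
    truncated: bool = False            # step collapse / step cap hit

    def __len__(self) -> int:
        return len(self.l)

    @property
    def n_zones(self) -> int:
        return self.x.shape[1]

    def stable_mask(self) -> np.ndarray:
        return np.array([s == "stable" for s in self.stability])

    def solutions_at(self, l0: float) -> List[Tuple[np.ndarray, str]]:
        """Solve the branch's crossings of the plane ``l = l0`` exactly.

        Polyline segments bracketing ``l0`` are refined by Newton at fixed
        ``l``, so the returned states carry full accuracy rather than the
        arclength sampling resolution.
        """
        out: List[Tuple[np.ndarray, str]] = []
        for k in range(len(self.l) - 1):
            la, lb = self.l[k], self.l[k + 1]
            if (la - l0) * (lb - l0) > 0:
                continue
            if la == lb:
                continue
            t = (l0 - la) / (lb - la)
            guess = self.x[k] + t * (self.x[k + 1] - self.x[k])
            try:
                eq = refine_equilibrium(self.params, l0, guess)
            except ConvergenceError:
                continue
            for xo, _ in out:
                if np.max(np.abs(xo - eq.x_array)) < 1e-8:
                    break
            else:
                out.append((eq.x_array, eq.stability))
        return out


@dataclass
class BifurcationDiagram:
    params: NondimParams
    l_range: Tuple[float, float]
    branches: List[Branch]
    provenance: dict = field(default_factory=dict)
    incomplete: bool = False

    def labels(self) -> List[str]:
        return sorted({b.label for b in self.branches if b.label})

    def branches_labelled(self, label: str) -> List[Branch]:
        return [b for b in self.branches if b.label == label]

    def stable_states_at(self, l0: float) -> List[np.ndarray]:
        pts: List[np.ndarray] = []
        for b in self.branches:
            for x, stab in b.solutions_at(l0):
                if stab != "stable":
                    continue
                for q in pts:
                    if np.max(np.abs(q - x)) < 1e-8:
                        break
                else:
                    pts.append(x)
        return pts

    def special_points(self, kind: Optional[str] = None) -> List[SpecialPoint]:
        out = [sp for b in self.branches for sp in b.special_points]
        if kind is not None:
            out = [sp for sp in out if sp.kind == kind]
        return out


# ----------------------------------------------------------------------------
# core continuation
# ----------------------------------------------------------------------------


def _stab_label(params: NondimParams, l: float, x: np.ndarray) -> str:
    eig = np.linalg.eigvals(model.jacobian(params, l, x))
    re = eig.real
    if np.any(np.abs(re) <= TOL_EIG):
        return "marginal"
    return "stable" if np.all(re < -TOL_EIG) else "unstable"


def _initial_tangent(params: NondimParams, x: np.ndarray, l: float) -> np.ndarray:
    """Unit tangent of the solution curve at (x, l), oriented toward +l if possible."""
    J = model.jacobian(params, l, x)
    fl = model.rhs_dl(params, x)
    A = np.hstack([J, fl[:, None]])            # n x (n+1)
    _, _, vt = np.linalg.svd(A)
    t = vt[-1]
    if t[-1] < 0:
        t = -t
    return t / np.linalg.norm(t)


def _corrector(
    params: NondimParams,
    u_pred: np.ndarray,
    tangent: np.ndarray,
    settings: ContinuationSettings,
) -> Optional[np.ndarray]:
    """Newton-correct the predictor onto the curve, orthogonally to `tangent`."""
    n = len(u_pred) - 1
    u = u_pred.copy()
    for _ in range(settings.newton_max):
        x, l = u[:n], u[n]
        f = model.rhs(params, l, x)
        g = float(tangent @ (u - u_pred))
        if max(np.max(np.abs(f)), abs(g)) < settings.newton_tol:
            return u
        J = model.jacobian(params, l, x)
        fl = model.rhs_dl(params, x)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = fl
        A[n, :] = tangent
        try:
            du = np.linalg.solve(A, -np.concatenate([f, [g]]))
        except np.linalg.LinAlgError:
            return None
        u = u + du
        if not np.all(np.isfinite(u)):
            return None
    x, l = u[:n], u[n]
    f = model.rhs(params, l, x)
    g = float(tangent @ (u - u_pred))
    if max(np.max(np.abs(f)), abs(g)) < settings.newton_tol:
        return u
    return None


def _solve_at_l(
    params: NondimParams, l: float, guess: np.ndarray
) -> Optional[np.ndarray]:
    try:
        return refine_equilibrium(params, l, guess).x_array
    except ConvergenceError:
        return None


def trace_branch(
    params: NondimParams,
    start: Equilibrium,
    l_range: Tuple[float, float],
    settings: ContinuationSettings = ContinuationSettings(),
    direction: int = +1,
) -> Branch:
    """Pseudo-arclength continuation from ``start`` in the given l direction.

    Traversal continues through folds; it terminates at the ``l_range``
    boundaries (the final point is corrected onto the boundary), upon
    closing a loop (island; ``closed`` flag set), or on step collapse below
    ``ds_min`` (``truncated`` flag set, never a silent gap).
    """
    n = params.n_zones
    l_min, l_max = l_range
    u0 = np.concatenate([start.x_array, [start.l]])
    tangent = _initial_tangent(params, start.x_array, start.l) * (1 if direction >= 0 else -1)

    us = [u0]
    ds = settings.ds0
    closed = False
    truncated = False
    arc = 0.0
    u = u0
    for _ in range(settings.max_steps):
        u_pred = u + ds * tangent
        u_new = _corrector(params, u_pred, tangent, settings)
        if u_new is None:
            ds *= settings.shrink
            if ds < settings.ds_min:
                truncated = True
                break
            continue
        step_vec = u_new - u
        step_len = float(np.linalg.norm(step_vec))
        if step_len == 0.0:
            truncated = True
            break
        # curvature control: keep the polyline geometrically faithful
        new_tan = step_vec / step_len
        if float(new_tan @ tangent) < np.cos(settings.max_angle) and ds > 2 * settings.ds_min:
            ds *= settings.shrink
            continue
        arc += step_len
        # loop closure: returned to the starting point after a full circuit
        d0 = float(np.linalg.norm(u_new - u0))
        if arc > max(0.12, 10 * ds) and d0 < max(ds, 2 * settings.ds0):
            us.append(u0.copy())
            closed = True
            break
        us.append(u_new)
        tangent = step_vec / step_len
        u = u_new
        if u[n] > l_max or u[n] < l_min:
            bound = l_max if u[n] > l_max else l_min
            xb = _solve_at_l(params, bound, u[:n])
            if xb is not None:
                us[-1] = np.concatenate([xb, [bound]])
            break
        ds = min(ds * settings.grow, settings.ds_max)
    else:
        truncated = True

    U = np.asarray(us)
    L = U[:, n]
    X = U[:, :n]
    stab = [_stab_label(params, li, xi) for li, xi in zip(L, X)]
    return Branch(
        params=params, l=L, x=X, stability=stab, closed=closed, truncated=truncated
    )


def _trace_both(
    params: NondimParams,
    start: Equilibrium,
    l_range: Tuple[float, float],
    settings: ContinuationSettings,
) -> Branch:
    """Trace in both directions from ``start`` and merge into one curve."""
    fwd = trace_branch(params, start, l_range, settings, direction=+1)
    if fwd.closed:
        return fwd
    bwd = trace_branch(params, start, l_range, settings, direction=-1)
    if bwd.closed:
        return bwd
    L = np.concatenate([bwd.l[::-1], fwd.l[1:]])
    X = np.concatenate([bwd.x[::-1], fwd.x[1:]])
    stab = bwd.stability[::-1] + fwd.stability[1:]
    return Branch(
        params=params,
        l=L,
        x=X,
        stability=stab,
        closed=False,
        truncated=fwd.truncated or bwd.truncated,
    )


# ----------------------------------------------------------------------------
# special points
# ----------------------------------------------------------------------------


def _is_diagonal_symmetric(branch: Branch) -> bool:
    """True when all weights are equal and the branch lies on the full diagonal."""
    a = branch.params.a
    if max(a) - min(a) > 1e-12:
        return False
    return bool(np.max(np.abs(branch.x - branch.x[:, :1])) < 1e-9)


def _antisym_eig(params: NondimParams, l: float, x: np.ndarray) -> float:
    """Antisymmetric-mode eigenvalue J11 - J12 on an equal-weight diagonal state."""
    J = model.jacobian(params, l, x)
    return float(J[0, 0] - J[0, 1])


def _det_jac(params: NondimParams, l: float, x: np.ndarray) -> float:
    return float(np.linalg.det(model.jacobian(params, l, x)))


def _chord_point(
    params: NondimParams,
    u_a: np.ndarray,
    u_b: np.ndarray,
    sigma: float,
    settings: ContinuationSettings,
) -> Optional[np.ndarray]:
    """Correct the chord interpolant at parameter ``sigma`` back onto the curve."""
    chord = u_b - u_a
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return u_a
    t = chord / nrm
    return _corrector(params, u_a + sigma * chord, t, settings)


def _probe_is_branch_point(
    params: NondimParams, l_star: float, x_star: np.ndarray, outside: float
) -> bool:
    """Discriminate a pitchfork crossed at an l-extremum from a true fold.

    At a branch point a second solution curve passes straight through the
    point, so an equilibrium persists arbitrarily close to ``x_star`` on the
    *outside* of the extremum; at a saddle-node fold no nearby solution
    exists there.
    """
    h = 1e-4
    l_probe = l_star + outside * h
    x = _solve_at_l(params, l_probe, x_star)
    return x is not None and float(np.max(np.abs(x - x_star))) < 0.02


def detect_special_points(
    branch: Branch, settings: ContinuationSettings = ContinuationSettings()
) -> List[SpecialPoint]:
    """Folds and branch points along a traced branch.

    Candidates where the branch's ``l`` is locally extremal (sign change of
    ``dl`` along the curve) are refined by extremising ``l`` along a local
    chord parametrisation, then classified: a true fold has no nearby
    solution on the outside of the extremum, whereas a branch point crossed
    transversally (e.g. a pitchfork met along the asymmetric family) does.
    Branch points crossed with ``l`` locally monotone are bracketed by sign
    changes of the eigenvalue test function — the antisymmetric eigenmode on
    an exactly symmetric diagonal branch, the Jacobian determinant otherwise
    — and refined by bisection.
    """
    if len(branch) < 3:
        return []
    params = branch.params
    n = branch.n_zones
    U = np.hstack([branch.x, branch.l[:, None]])
    L = branch.l
    out: List[SpecialPoint] = []

    dl = np.diff(L)
    sign = np.zeros_like(dl)
    last = 1.0
    for k, v in enumerate(dl):
        if v != 0:
            last = np.sign(v)
        sign[k] = last

    extremum_vertices: List[int] = []
    for k in range(len(dl) - 1):
        if sign[k] * sign[k + 1] < 0:
            extremum_vertices.append(k + 1)
            u_a, u_b = U[k], U[k + 2]

            def neg_l(s, _a=u_a, _b=u_b, _sg=sign[k]):
                p = _chord_point(params, _a, _b, s, settings)
                if p is None:
                    return 1e9
                return -_sg * p[n]

            r = minimize_scalar(neg_l, bounds=(0.0, 1.0), method="bounded",
                                options={"xatol": 1e-8})
            p = _chord_point(params, u_a, u_b, float(r.x), settings)
            if p is None:
                p = U[k + 1]
            # outside of a local max lies at larger l, of a local min at smaller l
            outside = +1.0 if sign[k] > 0 else -1.0
            kind = (
                "branch_point"
                if _probe_is_branch_point(params, float(p[n]), p[:n], outside)
                else "fold"
            )
            out.append(
                SpecialPoint(kind=kind, l=float(p[n]),
                             x=tuple(float(v) for v in p[:n]),
                             test_value=0.0)
            )

    diag = _is_diagonal_symmetric(branch)
    testf = _antisym_eig if diag else _det_jac
    tv = np.array([testf(params, L[k], branch.x[k]) for k in range(len(L))])
    for k in range(len(L) - 1):
        if tv[k] == 0.0 or tv[k] * tv[k + 1] >= 0:
            continue
        if any(abs(k - fv) <= 1 for fv in extremum_vertices):
            # eigenvalue sign change caused by the extremum itself
            continue
        u_a, u_b = U[k], U[k + 1]
        lo, hi = 0.0, 1.0
        f_lo = tv[k]
        p = None
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            p = _chord_point(params, u_a, u_b, mid, settings)
            if p is None:
                break
            fm = testf(params, p[n], p[:n])
            if fm == 0.0:
                break
            if np.sign(fm) == np.sign(f_lo):
                lo = mid
            else:
                hi = mid
            if abs(u_b[n] - u_a[n]) * (hi - lo) < settings.special_l_tol:
                break
        if p is None:
            continue
        out.append(
            SpecialPoint(kind="branch_point", l=float(p[n]),
                         x=tuple(float(v) for v in p[:n]),
                         test_value=float(testf(params, p[n], p[:n])))
        )
    out.sort(key=lambda sp: sp.l)
    return out


def switch_branch(
    params: NondimParams,
    at: SpecialPoint,
    delta: float = 0.02,
    settings: ContinuationSettings = ContinuationSettings(),
) -> List[Equilibrium]:
    """Starting equilibria on the branches emanating from a branch point.

    Perturbs along the critical eigenvector with both signs and refines at
    nearby ``l``.  For equal weights the two starts are mutual swaps.
    Raises ``ValueError`` for a fold and :class:`BranchSwitchError` if
    refinement fails on both sides (identifying the point as spurious).
    """
    if at.kind != "branch_point":
        raise ValueError("switch_branch requires a branch point, not a fold")
    x0 = at.x_array
    J = model.jacobian(params, at.l, x0)
    eigvals, eigvecs = np.linalg.eig(J)
    k = int(np.argmin(np.abs(eigvals.real)))
    v = eigvecs[:, k].real
    v = v / np.linalg.norm(v)

    starts: List[Equilibrium] = []
    for sgn in (+1.0, -1.0):
        found = None
        # fixed l offsets (independent of the perturbation size) so that the
        # accepted start converges to the emanating branch as delta shrinks
        for dl in (2e-3, -2e-3, 8e-3, -8e-3, 3e-2, -3e-2):
            l_try = at.l + dl
            on_through = _solve_at_l(params, l_try, x0)
            amp = delta
            while found is None and amp <= 0.32:
                guess = x0 + sgn * amp * v
                amp *= 2.0
                try:
                    eq = refine_equilibrium(params, l_try, guess)
                except ConvergenceError:
                    continue
                if on_through is not None and np.max(np.abs(eq.x_array - on_through)) < 1e-3:
                    continue  # fell back onto the branch passing through the point
                found = eq
            if found is not None:
                break
        if found is not None:
            starts.append(found)
    if not starts:
        raise BranchSwitchError(
            f"no emanating branch found at l={at.l:.6g}; point may be spurious"
        )
    return starts


# ----------------------------------------------------------------------------
# labelling, assembly
# ----------------------------------------------------------------------------


def classify_branch(
    branch: Branch, activity_threshold: float = ACTIVITY_THRESHOLD
) -> str:
    """Label a branch by the modal set of active zones along its stable part.

    A zone is active where its fraction exceeds ``activity_threshold``.
    No active zone -> ``orb``; one -> ``monopolar_i``; two -> ``bipolar``
    (two-zone) or ``bipolar_ij``; three -> ``tripolar``.  If the active set
    changes along the stable part the branch is ``mixed``; a branch with no
    stable points that stays on the symmetric diagonal is
    ``symmetric_unstable``.
    """
    if len(branch) == 0:
        raise ValueError("cannot classify an empty branch")
    n = branch.n_zones
    mask = branch.stable_mask()
    if not mask.any():
        if np.max(branch.x.max(axis=1) - branch.x.min(axis=1)) < 1e-6:
            return "symmetric_unstable"
        return "unstable"
    pts = branch.x[mask]
    active_sets = {tuple(np.nonzero(row > activity_threshold)[0]) for row in pts}
    if len(active_sets) > 1:
        return "mixed"
    (act,) = active_sets
    if len(act) == 0:
        return "orb"
    if len(act) == 1:
        return f"monopolar_{act[0] + 1}"
    if len(act) == 2:
        return "bipolar" if n == 2 else f"bipolar_{act[0] + 1}{act[1] + 1}"
    return "tripolar"


def _point_polyline_dist(U: np.ndarray, p: np.ndarray) -> float:
    """Min distance from point ``p`` to the polyline with vertices ``U``."""
    A = U[:-1]
    B = U[1:]
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - A, AB) / denom, 0.0, 1.0)
    proj = A + t[:, None] * AB
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def _same_curve(a: Branch, b: Branch, tol: float = 0.03) -> bool:
    """True when two traced curves sample the same solution family."""
    if abs(a.l.min() - b.l.min()) > 0.05 or abs(a.l.max() - b.l.max()) > 0.05:
        return False
    Ua = np.hstack([a.x, a.l[:, None]])
    Ub = np.hstack([b.x, b.l[:, None]])
    if len(Ub) < 2 or len(Ua) < 2:
        return False
    probe = Ua[:: max(1, len(Ua) // 9)]
    return all(_point_polyline_dist(Ub, p) < tol for p in probe)


def _on_existing(
    curves: Sequence[Branch], params: NondimParams, l0: float, x0: np.ndarray
) -> bool:
    """Is the equilibrium (l0, x0) already represented by one of `curves`?"""
    u0 = np.concatenate([x0, [l0]])
    for c in curves:
        if not (c.l.min() - 1e-6 <= l0 <= c.l.max() + 1e-6):
            continue
        U = np.hstack([c.x, c.l[:, None]])
        if len(U) >= 2 and _point_polyline_dist(U, u0) < 5e-3:
            return True
        # confirm geometrically ambiguous cases by exact solve on the curve
        for x, _ in c.solutions_at(l0):
            if np.max(np.abs(x - x0)) < 1e-6:
                return True
        for k in (0, len(c) - 1):
            if abs(c.l[k] - l0) < 1e-6 and np.max(np.abs(c.x[k] - x0)) < 1e-6:
                return True
    return False


def _piece_contains(piece: Branch, sp: SpecialPoint) -> bool:
    U = np.hstack([piece.x, piece.l[:, None]])
    d = np.linalg.norm(U - np.concatenate([sp.x_array, [sp.l]]), axis=1)
    return bool(np.min(d) < 0.08)


def _make_piece(branch: Branch, idx: np.ndarray) -> Branch:
    piece = Branch(
        params=branch.params,
        l=branch.l[idx].copy(),
        x=branch.x[idx].copy(),
        stability=[branch.stability[i] for i in idx],
        closed=False,
        truncated=branch.truncated,
    )
    piece.special_points = [
        sp for sp in branch.special_points if _piece_contains(piece, sp)
    ]
    return piece


def _insert_branch_points(branch: Branch) -> List[int]:
    """Insert each branch point exactly into the polyline; return their indices."""
    bps = [sp for sp in branch.special_points if sp.kind == "branch_point"]
    idxs: List[int] = []
    for bp in bps:
        u = np.concatenate([bp.x_array, [bp.l]])
        U = np.hstack([branch.x, branch.l[:, None]])
        d_pts = np.linalg.norm(U - u, axis=1)
        j = int(np.argmin(d_pts))
        if d_pts[j] < 1e-9:
            idxs.append(j)
            continue
        # nearest segment
        A, B = U[:-1], U[1:]
        AB = B - A
        denom = np.einsum("ij,ij->i", AB, AB)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", u - A, AB) / denom, 0.0, 1.0)
        proj = A + t[:, None] * AB
        k = int(np.argmin(np.linalg.norm(proj - u, axis=1)))
        branch.l = np.insert(branch.l, k + 1, bp.l)
        branch.x = np.insert(branch.x, k + 1, bp.x_array, axis=0)
        branch.stability.insert(k + 1, "marginal")
        idxs = [i + 1 if i > k else i for i in idxs]
        idxs.append(k + 1)
    return sorted(set(idxs))


def _split_at_branch_points(branch: Branch) -> List[Branch]:
    """Split a curve at its branch points so each piece is label-coherent.

    Closed curves with branch points (the asymmetric family of an exactly
    symmetric cell, which runs pitchfork-to-pitchfork through both mirror
    monopolar branches) are cut open at them; closed curves without branch
    points — islands — are kept whole so they retain the ``closed`` flag.
    """
    if not any(sp.kind == "branch_point" for sp in branch.special_points):
        return [branch]
    idxs = _insert_branch_points(branch)
    m = len(branch)
    if branch.closed:
        # drop the duplicated closure point and cut the cycle at each bp
        idxs = sorted({i % (m - 1) for i in idxs})
        if len(idxs) < 2:
            return [branch]
        pieces = []
        for a, b in zip(idxs, idxs[1:] + [idxs[0] + (m - 1)]):
            idx = np.arange(a, b + 1) % (m - 1)
            pieces.append(_make_piece(branch, idx))
        return pieces
    idxs = [i for i in idxs if 0 < i < m - 1]
    if not idxs:
        return [branch]
    pieces = []
    bounds = [0] + idxs + [m - 1]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            pieces.append(_make_piece(branch, np.arange(a, b + 1)))
    return pieces


def _split_mixed_at_stability(piece: Branch, threshold: float) -> List[Branch]:
    """Split a piece whose stable runs carry different active sets.

    Stability changes only at special points, so cutting at stability
    transitions yields pure stable runs (orb / monopolar / bipolar …) and
    unstable connector runs.
    """
    mask = piece.stable_mask()
    if not mask.any() or mask.all():
        return [piece]
    sets = {
        tuple(np.nonzero(row > threshold)[0]) for row in piece.x[mask]
    }
    if len(sets) <= 1:
        return [piece]
    # indices where stability flips
    flips = np.nonzero(mask[:-1] != mask[1:])[0]
    bounds = [0] + [int(i) + 1 for i in flips] + [len(piece)]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.append(_make_piece(piece, np.arange(a, b)))
    return out


def build_diagram(
    params: NondimParams,
    l_range: Tuple[float, float] = (0.05, 2.5),
    settings: ContinuationSettings = ContinuationSettings(),
) -> BifurcationDiagram:
    """Assemble the labelled bifurcation diagram over ``l_range``.

    Starts from the equilibria at ``l_min``, traces, switches branches at
    detected branch points, seeds further branches from brute-force
    enumeration at ``seed_l_count`` interior ``l`` values (finding islands),
    splits curves at branch points, labels every piece, and optionally
    validates stable sets against the enumeration oracle at quantile ``l``
    values.  An oracle mismatch marks the diagram ``incomplete`` rather than
    raising.
    """
    if params.epsilon <= 0:
        raise ValueError("build_diagram requires epsilon > 0")
    l_min, l_max = l_range
    if not (0 < l_min < l_max):
        raise ValueError("l_range must satisfy 0 < l_min < l_max")

    curves: List[Branch] = []
    queue: List[Equilibrium] = list(
        enumerate_equilibria(params, l_min, resolution=settings.seed_resolution)
    )
    # oracle seeding for disconnected branches
    seed_ls = np.linspace(l_min, l_max, settings.seed_l_count + 2)[1:-1]
    switch_log: List[str] = []

    def _process(start: Equilibrium) -> None:
        if len(curves) >= settings.max_curves:
            return
        if _on_existing(curves, params, start.l, start.x_array):
            return
        curve = _trace_both(params, start, l_range, settings)
        if any(_same_curve(curve, c) for c in curves):
            return
        curve.special_points = detect_special_points(curve, settings)
        curves.append(curve)
        for sp in curve.special_points:
            if sp.kind != "branch_point":
                continue
            try:
                new_starts = switch_branch(params, sp, settings=settings)
            except BranchSwitchError as exc:
                switch_log.append(str(exc))
                continue
            for eq in new_starts:
                _process(eq)

    while queue:
        _process(queue.pop(0))
    for l0 in seed_ls:
        for eq in enumerate_equilibria(params, float(l0), resolution=settings.seed_resolution):
            _process(eq)
    # second-pass seeding: islands live between the special points of the
    # families found so far, so probe the gaps between consecutive special-l
    # values (uniform seeding alone can straddle a small island)
    special_ls = sorted(
        {round(sp.l, 6) for c in curves for sp in c.special_points}
        | {l_min, l_max}
    ) if settings.gap_seeding else []
    for la, lb in zip(special_ls[:-1], special_ls[1:]):
        gap = lb - la
        if gap < 0.02:
            continue
        k = min(12, max(3, int(gap / 0.04)))
        for q in np.linspace(0, 1, k + 2)[1:-1]:
            l0 = la + q * gap
            for eq in enumerate_equilibria(params, float(l0), resolution=settings.seed_resolution):
                _process(eq)

    branches: List[Branch] = []
    for curve in curves:
        for piece in _split_at_branch_points(curve):
            for sub in _split_mixed_at_stability(piece, settings.activity_threshold):
                sub.label = classify_branch(sub, settings.activity_threshold)
                branches.append(sub)

    diagram = BifurcationDiagram(
        params=params,
        l_range=(float(l_min), float(l_max)),
        branches=branches,
        provenance={
            "settings": settings.to_dict(),
            "switch_failures": switch_log,
        },
    )

    if settings.validate:
        report = validate_against_oracle(diagram, settings)
        diagram.provenance["validation"] = report
        if report["max_distance"] > settings.validation_tol or report["count_mismatch"]:
            diagram.incomplete = True
    return diagram


def validate_against_oracle(
    diagram: BifurcationDiagram, settings: ContinuationSettings = ContinuationSettings()
) -> dict:
    """Compare the diagram's stable sets with brute-force enumeration.

    At each validation ``l`` the bidirectional (Hausdorff, max-norm) distance
    between the two stable sets is computed.
    """
    l_min, l_max = diagram.l_range
    ls = [l_min + q * (l_max - l_min) for q in settings.validation_quantiles]
    max_d = 0.0
    mismatch = False
    per_l = []
    for l0 in ls:
        oracle = [
            e.x_array
            for e in enumerate_equilibria(diagram.params, l0, resolution=settings.seed_resolution)
            if e.is_stable
        ]
        mine = diagram.stable_states_at(l0)
        if len(oracle) != len(mine):
            mismatch = True
            d = float("inf")
        else:
            d = _hausdorff(oracle, mine)
        per_l.append({"l": l0, "n_oracle": len(oracle), "n_diagram": len(mine), "distance": d})
        max_d = max(max_d, d if np.isfinite(d) else 1.0)
    return {"per_l": per_l, "max_distance": max_d, "count_mismatch": mismatch}


def _hausdorff(A: List[np.ndarray], B: List[np.ndarray]) -> float:
    if not A and not B:
        return 0.0
    if not A or not B:
        return float("inf")
    d_ab = max(min(float(np.max(np.abs(a - b))) for b in B) for a in A)
    d_ba = max(min(float(np.max(np.abs(a - b))) for a in A) for b in B)
    return max(d_ab, d_ba)


def neto_length(diagram: BifurcationDiagram, initial_branch: str = "monopolar_1") -> float:
    """The ``l`` at which the given stable branch ceases to exist.

    For monopolar branches this is the saddle-node fold terminating the
    stable segment — the model's NETO length.  Returns the :data:`NO_NETO`
    sentinel (``inf``) when the branch persists to the diagram's ``l_max``.
    Raises ``KeyError`` when the label is absent.
    """
    matches = diagram.branches_labelled(initial_branch)
    if not matches:
        raise KeyError(f"no branch labelled {initial_branch!r} in diagram")
    l_end = -np.inf
    best: Optional[Tuple[Branch, float]] = None
    for b in matches:
        mask = b.stable_mask()
        if not mask.any():
            continue
        m = float(b.l[mask].max())
        if m > l_end:
            l_end = m
            best = (b, m)
    if best is None:
        raise KeyError(f"branch {initial_branch!r} has no stable segment")
    b, m = best
    if m >= diagram.l_range[1] - 1e-9:
        return NO_NETO
    folds = [sp for sp in b.special_points if sp.kind == "fold" and sp.l >= m - 5e-3]
    if folds:
        return float(max(sp.l for sp in folds))
    return m
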