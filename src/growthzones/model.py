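"""The non-dimensional growth-zone activation ODE system.

Each of ``n`` growth zones carries an active fraction ``x_i`` in [0, 1].
All zones draw on a shared pool of free substrate

    s = l - sum_j a_j * x_j ,

where ``l`` is total substrate in units of total polarisome and ``a_j`` is
the share of polarisome on zone ``j``.  Activation of the inactive fraction
``1 - x_i`` is basal plus autocatalytic in the active *amount* ``a_i x_i``,
and active complexes decay at unit rate:

    dx_i/dtau = (epsilon + beta * (a_i x_i)**2) * s * (1 - x_i) - x_i .

For ``l < 1`` the substrate is insufficient to activate every zone fully;
for ``l > 1`` it is in excess.  The unit box [0,1]^n together with ``s >= 0``
is forward invariant.

All operations accept a state of shape ``(n,)`` or a batch ``(m, n)``.
States marginally outside the box (integrator overshoot) are accepted and
the smooth formula applied as-is; clamping would break the differentiability
that Newton refinement and continuation rely on.
"""

from __future__ import annotations

import numpy as np

from .params import NondimParams

__all__ = ["rhs", "free_substrate", "jacobian", "nullcline_curve", "rhs_dl"]


def _check_state(params: NondimParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_zones:
        raise ValueError(
            f"state has {x.shape[-1]} zones but parameters define {params.n_zones}"
        )
    return x


def free_substrate(params: NondimParams, l: float, state) -> np.ndarray | float:
    """Free (unbound) substrate ``s = l - sum_i a_i x_i``."""
    x = _check_state(params, state)
    s = l - x @ params.a_array
    return float(s) if x.ndim == 1 else s


def rhs(params: NondimParams, l: float, state) -> np.ndarray:
    """Time derivative of the active fractions.

    Swap-equivariant: permuting zones with equal weights permutes the output.
    """
    x = _check_state(params, state)
    a = params.a_array
    s = l - x @ a
    act = params.epsilon + params.beta * (a * x) ** 2
    return act * (np.expand_dims(s, -1) if x.ndim > 1 else s) * (1.0 - x) - x


def rhs_dl(params: NondimParams, state) -> np.ndarray:
    """Partial derivative of :func:`rhs` with respect to ``l``."""
    x = _check_state(params, state)
    a = params.a_array
    act = params.epsilon + params.beta * (a * x) ** 2
    return act * (1.0 - x)


def jacobian(params: NondimParams, l: float, state) -> np.ndarray:
    """Analytic Jacobian ``d rhs_i / d x_j`` (shape ``(n, n)`` or ``(m, n, n)``).

    At a symmetric state with equal weights the matrix commutes with the
    coordinate swap.
    """
    x = _check_state(params, state)
    a = params.a_array
    batched = x.ndim > 1
    s = l - x @ a
    if batched:
        s = s[..., None]
    act = params.epsilon + params.beta * (a * x) ** 2
    # off-diagonal contribution: -a_j * act_i * (1 - x_i), also present on the diagonal
    J = -(act * (1.0 - x))[..., :, None] * a[None, :]
    diag = 2.0 * params.beta * a**2 * x * s * (1.0 - x) - act * s - 1.0
    idx = np.arange(params.n_zones)
    J[..., idx, idx] += diag
    return J


def nullcline_curve(params: NondimParams, l: float, zone: int, x_zone) -> np.ndarray | float:
    """Closed-form nullcline of a two-zone system.

    For ``rhs[zone] = 0`` at given ``x_zone``, returns the coordinate of the
    other zone:

        x_other = ( l - a_z x_z - x_z / ((eps + beta (a_z x_z)^2)(1 - x_z)) ) / a_other

    The curve is affine in ``l``: increasing ``l`` by ``delta`` shifts it by
    exactly ``delta / a_other``, so under asymmetric weights the two
    nullclines translate at different rates.

    Raises
    ------
    ValueError
        If the system is not two-zone, at the pole ``x_zone = 1``, or when
        the other zone has zero weight (curve undefined).
    """
    if params.n_zones != 2:
        raise ValueError("nullcline_curve is defined for two-zone systems only")
    if zone not in (0, 1):
        raise ValueError("zone must be 0 or 1")
    other = 1 - zone
    a_z = params.a[zone]
    a_o = params.a[other]
    if a_o == 0:
        raise ValueError("nullcline undefined: the other zone has zero weight")
    xz = np.asarray(x_zone, dtype=float)
    if np.any(xz >= 1.0) or np.any(xz < 0.0):
        raise ValueError("x_zone must lie in [0, 1); the curve has a pole at 1")
    act = params.epsilon + params.beta * (a_z * xz) ** 2
    with np.errstate(divide="raise"):
        x_other = (l - a_z * xz - xz / (act * (1.0 - xz))) / a_o
    return float(x_other) if np.isscalar(x_zone) else x_other
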