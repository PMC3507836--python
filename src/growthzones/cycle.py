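"""Quasi-static cell-cycle simulation, division rules and growth patterns.

Activation dynamics are fast (unit inactivation rate sets the time scale);
growth is slow.  The separation is controlled by ``rho``, the ratio of the
growth time scale to the activation time scale: the substrate parameter
``l`` increases by order one over a time ``rho`` while activation relaxes
in order-one time.  In the quasi-static limit the cell tracks stable
equilibria of the frozen-``l`` system and jumps at saddle-node folds — the
simulated NETO length converges to the continuation fold as ``rho`` grows.

Growth laws:

* ``linear_l`` — ``dl/dt = rate * (l_div - l_birth) / rho`` (cycle duration
  ``rho / rate``); the form under which NETO cycle fractions are quoted.
* ``activity_proportional`` — ``dl/dt = rate * sum_i x_i / rho``; growth
  speed proportional to total polarisome activity.

At division each daughter receives a ``split`` fraction of the substrate,
keeps the activity of its inherited (old) tip and starts the new end at a
configurable small residual (default exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model
from .params import NondimParams

__all__ = [
    "GrowthLaw",
    "Trajectory",
    "GrowthPattern",
    "NoiseModel",
    "DaughterInit",
    "simulate_cycle",
    "divide",
    "classify_growth_pattern",
    "simulate_lineage",
]

# a zone activates crossing this level upward and deactivates below the
# lower edge of the hysteresis band (suppresses threshold chatter)
ACTIVE_ON = 0.30
ACTIVE_OFF = 0.25


@dataclass(frozen=True)
class GrowthLaw:
    mode: str = "activity_proportional"   # or "linear_l"
    rate: float = 1.0
    rho: float = 100.0                    # growth / activation time-scale ratio

    def __post_init__(self) -> None:
        if self.mode not in ("activity_proportional", "linear_l"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.rho < 10:
            raise ValueError("rho must be >= 10 (quasi-static regime)")
        if self.rate == 0:
            raise ValueError("rate must be non-zero; use zero-growth via rate -> see simulate_cycle")

    def dl_dt(self, x: np.ndarray, l_birth: float, l_div: float) -> float:
        if self.mode == "linear_l":
            return self.rate * (l_div - l_birth) / self.rho
        return self.rate * float(np.sum(x)) / self.rho


@dataclass
class Trajectory:
    t: np.ndarray
    l: np.ndarray
    x: np.ndarray                      # (m, n)
    events: List[Tuple[float, str, Optional[int]]]
    params: NondimParams
    growth_law: Optional[GrowthLaw]
    l_birth: float
    l_div: float

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def end_state(self) -> np.ndarray:
        return self.x[-1]

    @property
    def end_l(self) -> float:
        return float(self.l[-1])

    def events_of(self, kind: str) -> List[Tuple[float, str, Optional[int]]]:
        return [e for e in self.events if e[1] == kind]


@dataclass(frozen=True)
class GrowthPattern:
    label: str
    neto_cycle_fraction: Optional[float]
    active_history: Tuple[Tuple[float, Tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        allowed = (
            "monopolar_then_NETO",
            "tip_switch_then_NETO",
            "bipolar_from_birth",
            "monopolar_no_NETO",
            "orb",
        )
        if self.label not in allowed:
            raise ValueError(f"unknown growth pattern {self.label!r}")
        if "NETO" in self.label and not self.label.endswith("no_NETO"):
            f = self.neto_cycle_fraction
            if f is None or not (0 < f <= 1):
                raise ValueError("NETO patterns require a cycle fraction in (0, 1]")


def simulate_cycle(
    params: NondimParams,
    l_birth: float,
    init_state: Sequence[float],
    growth_law: Optional[GrowthLaw] = GrowthLaw(),
    l_div: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_max: Optional[float] = None,
    n_samples: int = 600,
) -> Trajectory:
    """Integrate one cycle of coupled fast activation and slow growth.

    ``growth_law=None`` freezes ``l`` (pure relaxation at fixed substrate).
    The cycle ends when ``l`` reaches ``l_div`` (default ``2 * l_birth``,
    the doubling of cell length) or at ``t_max``.  Zone activations and
    deactivations are located by integrator event functions on the
    hysteresis thresholds; NETO and tip-switch events are derived from the
    persistent active-set sequence.
    """
    x0 = np.asarray(init_state, dtype=float)
    if x0.shape != (params.n_zones,):
        raise ValueError("init_state dimension mismatch")
    if np.any(x0 < 0) or np.any(x0 > 1):
        raise ValueError("init_state must lie in [0, 1]^n")
    if l_div is None:
        l_div = 2.0 * l_birth
    n = params.n_zones

    if growth_law is None:
        def rhs_t(t, y):
            return np.concatenate([model.rhs(params, y[n], y[:n]), [0.0]])
        horizon = t_max if t_max is not None else 200.0
        events = []
    else:
        def rhs_t(t, y):
            dx = model.rhs(params, y[n], y[:n])
            dl = growth_law.dl_dt(y[:n], l_birth, l_div)
            return np.concatenate([dx, [dl]])
        horizon = t_max if t_max is not None else 80.0 * growth_law.rho

        def div_event(t, y):
            return y[n] - l_div
        div_event.terminal = True
        div_event.direction = float(np.sign(l_div - l_birth)) or 1.0
        events = [div_event]

    # threshold-crossing event functions per zone
    def make_cross(i: int, level: float, direction: float):
        def ev(t, y):
            return y[i] - level
        ev.terminal = False
        ev.direction = direction
        return ev

    up_events = [make_cross(i, ACTIVE_ON, +1.0) for i in range(n)]
    down_events = [make_cross(i, ACTIVE_OFF, -1.0) for i in range(n)]

    y0 = np.concatenate([x0, [l_birth]])
    sol = solve_ivp(
        rhs_t,
        (0.0, horizon),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events + up_events + down_events,
        max_step=horizon / 50.0,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}; last state {sol.y[:, -1]}")
    t_end = float(sol.t[-1])
    ts = np.linspace(0.0, t_end, n_samples)
    Y = sol.sol(ts)
    x = Y[:n].T
    l = Y[n]

    # hysteresis state machine over the chronological crossing events
    offset = len(events)
    crossings: List[Tuple[float, str, int]] = []
    for i in range(n):
        for tt in sol.t_events[offset + i]:
            crossings.append((float(tt), "up", i))
        for tt in sol.t_events[offset + n + i]:
            crossings.append((float(tt), "down", i))
    crossings.sort()
    active = [bool(v >= ACTIVE_ON) for v in x0]
    raw_events: List[Tuple[float, str, Optional[int]]] = []
    set_history: List[Tuple[float, Tuple[int, ...]]] = [
        (0.0, tuple(i for i in range(n) if active[i]))
    ]
    for tt, kind, i in crossings:
        if kind == "up" and not active[i]:
            active[i] = True
            raw_events.append((tt, "activation", i))
            set_history.append((tt, tuple(j for j in range(n) if active[j])))
        elif kind == "down" and active[i]:
            active[i] = False
            raw_events.append((tt, "deactivation", i))
            set_history.append((tt, tuple(j for j in range(n) if active[j])))

    events_out = list(raw_events)
    events_out += _derived_events(set_history, t_end)
    if growth_law is not None and sol.t_events[0].size > 0:
        events_out.append((float(sol.t_events[0][0]), "division", None))
    events_out.sort()
    return Trajectory(
        t=ts, l=l, x=x, events=events_out, params=params,
        growth_law=growth_law, l_birth=float(l_birth), l_div=float(l_div),
    )


def _persistent_sets(
    set_history: List[Tuple[float, Tuple[int, ...]]],
    t_end: float,
    dwell_min: Optional[float] = None,
) -> List[Tuple[float, Tuple[int, ...]]]:
    """Collapse short-lived active sets (transition transients) from the history."""
    if dwell_min is None:
        dwell_min = max(3.0, 0.02 * t_end)
    out: List[Tuple[float, Tuple[int, ...]]] = []
    times = [t for t, _ in set_history] + [t_end]
    for k, (t0, s) in enumerate(set_history):
        dwell = times[k + 1] - t0
        if dwell >= dwell_min or k == len(set_history) - 1:
            if not out or out[-1][1] != s:
                out.append((t0, s))
    if not out:
        out = [set_history[-1]]
    return out


def _derived_events(
    set_history: List[Tuple[float, Tuple[int, ...]]], t_end: float
) -> List[Tuple[float, str, Optional[int]]]:
    seq = _persistent_sets(set_history, t_end)
    out: List[Tuple[float, str, Optional[int]]] = []
    for (t0, s0), (t1, s1) in zip(seq[:-1], seq[1:]):
        if len(s0) == 1 and len(s1) == 2 and s0[0] in s1:
            new_zone = [z for z in s1 if z != s0[0]][0]
            out.append((t1, "NETO", new_zone))
        elif len(s0) == 1 and len(s1) == 1 and s0 != s1:
            out.append((t1, "tip_switch", s1[0]))
    return out


def classify_growth_pattern(
    traj: Trajectory, dwell_min: Optional[float] = None
) -> GrowthPattern:
    """Map the event sequence of a full cycle onto a growth-pattern label."""
    set_history = [(0.0, _active_set_at(traj, 0))]
    for t, kind, zone in traj.events:
        if kind in ("activation", "deactivation"):
            set_history.append((t, _active_set_at(traj, t)))
    seq = _persistent_sets(set_history, traj.duration, dwell_min)
    sets = [s for _, s in seq]
    birth = sets[0]
    neto = traj.events_of("NETO")
    switch = traj.events_of("tip_switch")
    frac = None
    if neto:
        frac = float(min(1.0, max(1e-12, neto[0][0] / traj.duration)))
    if len(birth) >= 2:
        return GrowthPattern("bipolar_from_birth", None, tuple(seq))
    if switch and neto:
        return GrowthPattern("tip_switch_then_NETO", frac, tuple(seq))
    if neto:
        return GrowthPattern("monopolar_then_NETO", frac, tuple(seq))
    if any(len(s) >= 1 for s in sets):
        return GrowthPattern("monopolar_no_NETO", None, tuple(seq))
    return GrowthPattern("orb", None, tuple(seq))


def _active_set_at(traj: Trajectory, t: float) -> Tuple[int, ...]:
    k = int(np.searchsorted(traj.t, t + 1e-12))
    k = min(k, len(traj.t) - 1)
    x = traj.x[k]
    # hysteresis-free sampling here; the event machinery provides timing
    return tuple(int(i) for i in np.nonzero(x >= ACTIVE_ON)[0])


# ----------------------------------------------------------------------------
# division and lineages
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class DaughterInit:
    params: NondimParams
    l_birth: float
    init_state: Tuple[float, ...]


def divide(
    params: NondimParams,
    end_state: Sequence[float],
    end_l: float,
    split: float = 0.5,
    x_new: float = 0.0,
    inheritance_rule: Optional[Callable[[NondimParams, int], Sequence[float]]] = None,
) -> Tuple[DaughterInit, DaughterInit]:
    """Divide a two-zone cell into two daughters.

    Daughter ``i`` inherits parent tip ``i`` as its old end (zone 1) with
    that tip's activity; its new end (zone 2) starts at ``x_new`` (default
    exactly zero; a small residual models remnant actin patches at the
    division scar).  Substrate splits as ``split * l`` / ``(1-split) * l``.
    ``inheritance_rule(params, daughter_index) -> a`` reassigns zone weights
    (e.g. polarisome mis-segregation); by default both daughters keep the
    parent weights.
    """
    if params.n_zones != 2:
        raise ValueError("division is defined for two-zone cells")
    if not (0.0 < split < 1.0):
        raise ValueError("split must lie in (0, 1)")
    x = np.asarray(end_state, dtype=float)
    daughters = []
    for i, frac in ((0, split), (1, 1.0 - split)):
        if inheritance_rule is not None:
            a = tuple(float(v) for v in inheritance_rule(params, i))
            p = params.with_(a=a)
        else:
            p = params
        daughters.append(
            DaughterInit(
                params=p,
                l_birth=float(frac * end_l),
                init_state=(float(np.clip(x[i], 0.0, 1.0)), float(x_new)),
            )
        )
    return daughters[0], daughters[1]


@dataclass(frozen=True)
class NoiseModel:
    """Independent lognormal multiplicative noise applied per cell."""

    cv_eps: float = 0.0
    cv_beta: float = 0.0
    cv_split: float = 0.0
    cv_x_new: float = 0.0

    @property
    def any(self) -> bool:
        return any(v > 0 for v in (self.cv_eps, self.cv_beta, self.cv_split, self.cv_x_new))

    def draw(self, rng: np.random.Generator, value: float, cv: float) -> float:
        if cv <= 0:
            return value
        sigma = float(np.sqrt(np.log1p(cv**2)))
        return float(value * np.exp(rng.normal(0.0, sigma)))


def simulate_lineage(
    params: NondimParams,
    generations: int,
    l_birth: float,
    growth_law: GrowthLaw = GrowthLaw(),
    init_state: Optional[Sequence[float]] = None,
    noise_model: Optional[NoiseModel] = None,
    seed: Optional[int] = None,
    split: float = 0.5,
    x_new: float = 0.0,
    inheritance_rule: Optional[Callable[[NondimParams, int], Sequence[float]]] = None,
    max_cells: int = 16,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Tuple[List[dict], pd.DataFrame]:
    """Follow both daughters over generations; summarise pattern frequencies.

    Returns ``(records, summary)``: one record per simulated cell with its
    trajectory and classified pattern, and a generation-by-pattern count
    table (exact counts).  A ``seed`` is mandatory whenever the noise model
    is active; with zero noise the lineage is fully deterministic.  The
    binary tree is capped at ``max_cells`` per generation (first come).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    noise = noise_model or NoiseModel()
    if noise.any and seed is None:
        raise ValueError("a seed is mandatory when the noise model is active")
    rng = np.random.default_rng(seed)
    if init_state is None:
        init_state = [0.8, x_new] + [0.0] * (params.n_zones - 2)

    cells = [DaughterInit(params=params, l_birth=float(l_birth),
                          init_state=tuple(float(v) for v in init_state))]
    records: List[dict] = []
    for gen in range(generations):
        next_cells: List[DaughterInit] = []
        for cid, cell in enumerate(cells):
            p = cell.params
            if noise.any:
                p = p.with_(
                    epsilon=noise.draw(rng, p.epsilon, noise.cv_eps),
                    beta=noise.draw(rng, p.beta, noise.cv_beta),
                )
            traj = simulate_cycle(
                p, cell.l_birth, cell.init_state, growth_law, rtol=rtol, atol=atol
            )
            pattern = classify_growth_pattern(traj)
            records.append(
                {"generation": gen, "cell": cid, "trajectory": traj, "pattern": pattern}
            )
            s = noise.draw(rng, split, noise.cv_split) if noise.cv_split > 0 else split
            s = float(np.clip(s, 0.05, 0.95))
            xn = noise.draw(rng, x_new, noise.cv_x_new) if noise.cv_x_new > 0 else x_new
            d1, d2 = divide(
                p, traj.end_state, traj.end_l, split=s, x_new=xn,
                inheritance_rule=inheritance_rule,
            )
            next_cells += [d1, d2]
        cells = next_cells[:max_cells]
    summary = (
        pd.DataFrame(
            [{"generation": r["generation"], "pattern": r["pattern"].label} for r in records]
        )
        .groupby(["generation", "pattern"])
        .size()
        .unstack(fill_value=0)
    )
    return records, summary
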