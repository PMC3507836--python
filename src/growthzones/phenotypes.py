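"""Parameter-plane scanning and growth-phenotype classification.

A cell cycle corresponds to a window ``(l_birth, l_div)`` of the substrate
parameter (``l_div = 2 * l_birth`` for a cell that doubles its length).
Which solution branches exist and overlap across that window determines the
growth phenotype: wild-type NETO partway through the cycle, delayed or
absent NETO (tea-like mutants, low basal activation), bipolar growth from
birth (high basal activation), the round orb phenotype (no activation), or
mixed-population behaviour where the orb state stays stable throughout the
window.

:func:`wt_constraint_solve` constructs wild-type-like parameters by
requiring a monopolar branch at birth and NETO at a target fraction of the
cycle; the solution is deliberately non-unique — a curve of valid (eps,
beta) pairs exists, and either coordinate may be fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .continuation import (
    ACTIVITY_THRESHOLD,
    BifurcationDiagram,
    Branch,
    ContinuationSettings,
    FAST_SETTINGS,
    NO_NETO,
    build_diagram,
    neto_length,
    trace_branch,
    detect_special_points,
)
from .equilibria import enumerate_equilibria
from .params import NondimParams

__all__ = [
    "PhenotypeLabel",
    "RegionMap",
    "classify_phenotype",
    "scan_parameter_plane",
    "wt_constraint_solve",
    "monopolar_neto_l",
]

PHENOTYPES = (
    "WT_NETO",
    "delayed_NETO",
    "no_NETO_monopolar",
    "orb",
    "premature_bipolar",
    "weak_monopolar_early_NETO",
    "mixed",
)

# cycle-fraction bands for NETO timing; wild type takes off in the first
# half of the cycle (observed NETO at 0.3-0.4 of the cycle)
EARLY_FRACTION = 0.25
LATE_FRACTION = 0.5


@dataclass(frozen=True)
class PhenotypeLabel:
    label: str
    neto_cycle_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPES:
            raise ValueError(f"unknown phenotype label {self.label!r}")


def _active_set(x: np.ndarray, threshold: float) -> Tuple[int, ...]:
    return tuple(int(i) for i in np.nonzero(np.asarray(x) > threshold)[0])


def _stable_sets_at(
    diagram: BifurcationDiagram, l0: float, threshold: float
) -> List[Tuple[np.ndarray, Tuple[int, ...]]]:
    return [(x, _active_set(x, threshold)) for x in diagram.stable_states_at(l0)]


def _neto_from_branch(
    diagram: BifurcationDiagram, branch: Branch, lb: float, threshold: float
) -> Optional[float]:
    """The l at which growth becomes bipolar when the cell sits on `branch`.

    Either the branch turns fully active smoothly (strong asymmetry) — the
    interpolated threshold crossing is returned — or it terminates in a fold
    before the diagram's ``l_max`` (the saddle-node jump).  ``None`` means
    the branch persists with incomplete activation.
    """
    mask = branch.stable_mask()
    if not mask.any():
        return None
    order = np.argsort(branch.l[mask])
    L = branch.l[mask][order]
    X = branch.x[mask][order]
    min_frac = X.min(axis=1)
    above = min_frac > threshold
    for k in range(len(L)):
        if L[k] >= lb - 1e-9 and above[k]:
            if k == 0 or not (L[k - 1] >= lb - 1e-9):
                return float(L[k])
            # interpolate the crossing of the least-active zone
            f0, f1 = min_frac[k - 1], min_frac[k]
            t = (threshold - f0) / (f1 - f0)
            return float(L[k - 1] + t * (L[k] - L[k - 1]))
    m = float(L.max())
    if m < diagram.l_range[1] - 1e-9:
        folds = [sp for sp in branch.special_points if sp.kind == "fold" and sp.l >= m - 5e-3]
        return float(max(sp.l for sp in folds)) if folds else m
    return None


def classify_phenotype(
    diagram: BifurcationDiagram,
    cycle_window: Tuple[float, float],
    init_rule: str = "old_end",
    activity_threshold: float = ACTIVITY_THRESHOLD,
) -> PhenotypeLabel:
    """Deterministic growth-phenotype call from branch structure.

    The initial branch is chosen by ``init_rule`` (default ``"old_end"``:
    the monopolar state of zone 1, the inherited old end, wins when stable
    at birth).  Classification rules, in order:

    * the orb state stable across the *entire* window while monopolar
      growth also exists -> ``mixed`` (part of a population falls onto the
      orb branch and never leaves it);
    * no single-active-zone state at birth: bipolar state at birth ->
      ``premature_bipolar``; orb only and no later activation -> ``orb``;
    * otherwise the cell starts monopolar; NETO at cycle fraction f:
      f < 0.25 -> ``weak_monopolar_early_NETO``; 0.25 <= f <= 0.5 ->
      ``WT_NETO``; f > 0.5 -> ``delayed_NETO``; no NETO inside the window
      -> ``no_NETO_monopolar``.
    """
    lb, ld = cycle_window
    lo, hi = diagram.l_range
    if not (lo <= lb < ld <= hi):
        raise ValueError("cycle_window must lie within the diagram's l range")

    states_lb = _stable_sets_at(diagram, lb, activity_threshold)
    orb_at_lb = any(len(act) == 0 for _, act in states_lb)
    mono_states = [(x, act) for x, act in states_lb if len(act) == 1]
    bip_at_lb = any(len(act) >= 2 for _, act in states_lb)
    has_mono_anywhere = bool(mono_states) or any(
        (b.label or "").startswith("monopolar") for b in diagram.branches
    )

    if orb_at_lb and has_mono_anywhere:
        states_ld = _stable_sets_at(diagram, ld, activity_threshold)
        if any(len(act) == 0 for _, act in states_ld):
            return PhenotypeLabel("mixed")

    if not mono_states:
        if bip_at_lb:
            return PhenotypeLabel("premature_bipolar")
        if orb_at_lb:
            return _classify_from_orb_start(diagram, lb, ld, activity_threshold)
        return PhenotypeLabel("mixed")

    # old-end rule: prefer the zone-1 monopolar state
    init = None
    if init_rule == "old_end":
        for x, act in mono_states:
            if act == (0,):
                init = x
                break
    if init is None:
        init = mono_states[0][0]

    branch = _branch_containing(diagram, lb, init)
    if branch is None:
        return PhenotypeLabel("mixed")
    l_star = _neto_from_branch(diagram, branch, lb, activity_threshold)
    if l_star is None or l_star >= ld:
        return PhenotypeLabel("no_NETO_monopolar")
    frac = (l_star - lb) / (ld - lb)
    if frac < EARLY_FRACTION:
        return PhenotypeLabel("weak_monopolar_early_NETO", frac)
    if frac <= LATE_FRACTION:
        return PhenotypeLabel("WT_NETO", frac)
    return PhenotypeLabel("delayed_NETO", frac)


def _classify_from_orb_start(
    diagram: BifurcationDiagram, lb: float, ld: float, threshold: float
) -> PhenotypeLabel:
    """Cell born on the orb state with no monopolar state available at birth.

    If the orb state survives to division the cell never activates: orb
    phenotype.  Otherwise the cell departs when the orb state disappears
    (largest stable l of the low-activity branch) and lands on whatever is
    stable there — a monopolar branch (NETO later, at its terminating fold)
    or directly the bipolar branch (both tips activate at the departure
    point); the NETO cycle fraction is computed accordingly.
    """
    states_ld = _stable_sets_at(diagram, ld, threshold)
    if any(len(act) == 0 for _, act in states_ld):
        return PhenotypeLabel("orb")
    # find where the low-activity state disappears
    orb_end = None
    for b in diagram.branches:
        mask = b.stable_mask()
        if not mask.any():
            continue
        sets = {_active_set(row, threshold) for row in b.x[mask]}
        if sets == {()}:
            m = float(b.l[mask].max())
            orb_end = m if orb_end is None else max(orb_end, m)
    if orb_end is None or orb_end >= ld:
        return PhenotypeLabel("orb")
    # what is stable just past the departure point?
    probe_l = min(orb_end * 1.01 + 1e-3, ld)
    states = _stable_sets_at(diagram, probe_l, threshold)
    mono = [(x, act) for x, act in states if len(act) == 1]
    if mono:
        branch = _branch_containing(diagram, probe_l, mono[0][0])
        l_star = (
            _neto_from_branch(diagram, branch, probe_l, threshold)
            if branch is not None else None
        )
    else:
        l_star = orb_end  # straight jump to bipolar growth
    if l_star is None or l_star >= ld:
        return PhenotypeLabel("no_NETO_monopolar")
    frac = (l_star - lb) / (ld - lb)
    if frac < EARLY_FRACTION:
        return PhenotypeLabel("weak_monopolar_early_NETO", frac)
    if frac <= LATE_FRACTION:
        return PhenotypeLabel("WT_NETO", frac)
    return PhenotypeLabel("delayed_NETO", frac)


def _branch_containing(
    diagram: BifurcationDiagram, l0: float, x0: np.ndarray
) -> Optional[Branch]:
    best = None
    best_d = np.inf
    for b in diagram.branches:
        for x, stab in b.solutions_at(l0):
            if stab != "stable":
                continue
            d = float(np.max(np.abs(x - x0)))
            if d < best_d:
                best_d = d
                best = b
    return best if best_d < 1e-6 else best


# ----------------------------------------------------------------------------
# (eps, beta) plane scanning
# ----------------------------------------------------------------------------


@dataclass
class RegionMap:
    eps_grid: np.ndarray
    beta_grid: np.ndarray
    cells: List[List[dict]]            # cells[i][j] for (eps_grid[i], beta_grid[j])
    l_range: Tuple[float, float]
    a: Tuple[float, ...]
    settings: dict = field(default_factory=dict)

    def cell(self, i: int, j: int) -> dict:
        return self.cells[i][j]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.eps_grid):
            for j, b in enumerate(self.beta_grid):
                rec = dict(self.cells[i][j])
                rec["epsilon"] = float(e)
                rec["beta"] = float(b)
                rec["branch_types_present"] = ";".join(rec.get("branch_types_present", []))
                rows.append(rec)
        return pd.DataFrame(rows)


def _overlap(iv1, iv2) -> bool:
    return iv1 is not None and iv2 is not None and min(iv1[1], iv2[1]) - max(iv1[0], iv2[0]) > 0


def _stable_interval(diagram: BifurcationDiagram, prefix: str):
    ls = []
    for b in diagram.branches:
        if b.label and (b.label == prefix or b.label.startswith(prefix)):
            mask = b.stable_mask()
            if mask.any():
                ls += [float(b.l[mask].min()), float(b.l[mask].max())]
    return (min(ls), max(ls)) if ls else None


def describe_diagram(diagram: BifurcationDiagram) -> dict:
    """Per-cell record for a region map."""
    labels = [b.label for b in diagram.branches if b.label]
    mono = _stable_interval(diagram, "monopolar")
    orb = _stable_interval(diagram, "orb")
    bip = _stable_interval(diagram, "bipolar")
    n_special = len(diagram.special_points())
    try:
        neto = min(
            neto_length(diagram, lab)
            for lab in set(labels)
            if lab.startswith("monopolar")
        )
    except (KeyError, ValueError):
        neto = None
    return {
        "branch_types_present": sorted(set(labels)),
        "orb_monopolar_overlap": _overlap(orb, mono),
        "monopolar_bipolar_overlap": _overlap(mono, bip),
        "neto_l": None if neto is None or not np.isfinite(neto) else float(neto),
        "no_bifurcation_flag": n_special == 0,
        "n_special_points": n_special,
        "failed": False,
    }


def scan_parameter_plane(
    eps_range: Tuple[float, float],
    beta_range: Tuple[float, float],
    grid: Tuple[int, int] = (10, 10),
    l_range: Tuple[float, float] = (0.05, 2.5),
    a: Tuple[float, ...] = (0.5, 0.5),
    settings: ContinuationSettings = FAST_SETTINGS,
) -> RegionMap:
    """Classify branch existence and overlap over an (eps, beta) grid.

    Each cell gets a reduced-validation bifurcation diagram; individual cell
    failures are recorded in the cell record, never aborting the scan.
    Deterministic for fixed settings.
    """
    if grid[0] < 10 or grid[1] < 10:
        raise ValueError("grid must be at least 10x10")
    eps_grid = np.linspace(*eps_range, grid[0])
    beta_grid = np.linspace(*beta_range, grid[1])
    cells: List[List[dict]] = []
    for e in eps_grid:
        row = []
        for b in beta_grid:
            params = NondimParams(float(e), float(b), a)
            try:
                d = build_diagram(params, l_range, settings)
                rec = describe_diagram(d)
            except Exception as exc:  # record, do not abort the scan
                rec = {"failed": True, "error": str(exc)}
            row.append(rec)
        cells.append(row)
    return RegionMap(
        eps_grid=eps_grid,
        beta_grid=beta_grid,
        cells=cells,
        l_range=l_range,
        a=tuple(a),
        settings=settings.to_dict(),
    )


# ----------------------------------------------------------------------------
# wild-type construction
# ----------------------------------------------------------------------------


def monopolar_neto_l(
    params: NondimParams,
    l_range: Tuple[float, float] = (0.05, 2.5),
    settings: ContinuationSettings = FAST_SETTINGS,
) -> Optional[float]:
    """Fast NETO length: trace only the zone-1 monopolar family.

    Finds a stable single-active-zone equilibrium by enumeration over a
    spread of l values, traces its branch, and returns the largest l of the
    stable monopolar segment (the terminating fold), or the smooth
    full-activation crossing for strongly asymmetric cells.  ``None`` when
    no monopolar state exists.
    """
    thr = settings.activity_threshold
    start = None
    for l0 in np.linspace(l_range[0], l_range[1], 17)[1:-1]:
        for eq in enumerate_equilibria(params, float(l0), resolution=21):
            if eq.is_stable and _active_set(eq.x_array, thr) == (0,):
                start = eq
                break
        if start is not None:
            break
    if start is None:
        return None
    branch = trace_branch(params, start, l_range, settings, direction=+1)
    branch.special_points = detect_special_points(branch, settings)
    # treat as a one-branch diagram for the NETO reading
    dummy = BifurcationDiagram(params=params, l_range=l_range, branches=[branch])
    neto = _neto_from_branch(dummy, branch, l_range[0], thr)
    if neto is None:
        return NO_NETO  # monopolar branch persists to l_max
    return neto


def wt_constraint_solve(
    l_birth: float,
    neto_fraction_target: float = 1.0 / 3.0,
    beta_fixed: Optional[float] = None,
    eps_fixed: Optional[float] = None,
    bracket: Tuple[float, float] = (0.01, 0.4),
    l_range: Tuple[float, float] = (0.05, 2.5),
    tol: float = 1e-4,
    settings: ContinuationSettings = FAST_SETTINGS,
) -> Tuple[float, float, dict]:
    """Solve for (eps, beta) putting NETO at a target cycle fraction.

    With linear growth in length and division at ``2 * l_birth``, NETO at
    cycle fraction ``f`` means the monopolar branch must terminate at
    ``l* = l_birth * (1 + f)``; the monopolar state must also be stable at
    ``l_birth``.  One of ``beta_fixed`` / ``eps_fixed`` pins the line along
    which the one-dimensional root is searched (the choice is not unique —
    a whole curve of valid pairs exists).  Raises ``ValueError`` when the
    bracket does not straddle the target.
    """
    if not 0 < neto_fraction_target < 1:
        raise ValueError("target fraction must lie in (0, 1)")
    if (beta_fixed is None) == (eps_fixed is None):
        raise ValueError("fix exactly one of beta_fixed / eps_fixed")
    l_target = l_birth * (1.0 + neto_fraction_target)

    def params_for(p: float) -> NondimParams:
        if beta_fixed is not None:
            return NondimParams(p, beta_fixed, (0.5, 0.5))
        return NondimParams(eps_fixed, p, (0.5, 0.5))

    def g(p: float) -> float:
        neto = monopolar_neto_l(params_for(p), l_range, settings)
        if neto is None:
            # no monopolar branch: behaves like NETO before birth
            return -10.0
        if not np.isfinite(neto):
            # branch persists to l_max: NETO beyond the scan range
            return +10.0
        return neto - l_target

    lo, hi = bracket
    g_lo, g_hi = g(lo), g(hi)
    # NETO length decreases with both eps and beta; orient the bracket
    if g_lo < 0 < g_hi:
        lo, hi, g_lo, g_hi = hi, lo, g_hi, g_lo
    if not (g_lo > 0 > g_hi):
        raise ValueError(
            f"no root in bracket: residuals g({bracket[0]})={g_lo:.4g}, "
            f"g({bracket[1]})={g_hi:.4g}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if gm > 0:
            lo = mid
        else:
            hi = mid
        if abs(gm) < tol and abs(hi - lo) < 1e-6 * max(1.0, abs(mid)):
            break
    p_star = 0.5 * (lo + hi)
    params = params_for(p_star)
    # verify the monopolar state is stable at birth
    mono_at_birth = any(
        eq.is_stable and len(_active_set(eq.x_array, settings.activity_threshold)) == 1
        for eq in enumerate_equilibria(params, l_birth, resolution=31)
    )
    neto = monopolar_neto_l(params, l_range, settings)
    residuals = {
        "neto_l": neto,
        "neto_l_target": l_target,
        "neto_residual": None if neto is None else neto - l_target,
        "monopolar_stable_at_birth": mono_at_birth,
    }
    if not mono_at_birth:
        raise ValueError(
            f"constraint solve found NETO at l={neto} but no stable monopolar "
            f"state at l_birth={l_birth}"
        )
    return params.epsilon, params.beta, residuals
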