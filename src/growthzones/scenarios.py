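"""Archetypal parameter regimes (wild type and mutant analogues).

No numerical parameter set is copied from anywhere: every archetype is
*derived procedurally* from the wild-type construction.  Wild type is built
by :func:`growthzones.phenotypes.wt_constraint_solve` — a monopolar branch
stable at birth and NETO at one third of the cycle — and each mutant
archetype applies the corresponding directional change until its defining
property holds (e.g. tea-like: lower basal activation until NETO leaves the
cycle window; high basal activation: raise it until the bifurcations
disappear and growth is bipolar from birth).  All derivations are logged in
the scenario's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .continuation import FAST_SETTINGS, build_diagram, ContinuationSettings
from .cycle import GrowthLaw
from .params import NondimParams
from .phenotypes import classify_phenotype, monopolar_neto_l, wt_constraint_solve

__all__ = ["Scenario", "generate_scenarios", "ARCHETYPES", "clear_cache"]

# reference conditions for the wild-type construction: birth just inside the
# monopolar window of the reference autocatalytic strength, division at
# doubled length, NETO targeted at one third of the cycle
BETA_REF = 20.0
L_BIRTH_REF = 1.05
WT_NETO_FRACTION = 1.0 / 3.0

ARCHETYPES = (
    "wt",
    "orb_like",
    "tea_like_low_eps",
    "high_eps_bipolar",
    "low_beta",
    "high_beta",
    "asym_weak",
    "asym_moderate",
    "asym_strong",
    "for3_like_overlap",
    "three_zone_symmetric",
    "three_zone_weak_lateral",
)


@dataclass(frozen=True)
class Scenario:
    name: str
    params: NondimParams
    l_birth: float
    growth_law: GrowthLaw
    init_rule: str
    intended_phenotype: str
    provenance: Tuple[Tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def l_div(self) -> float:
        return 2.0 * self.l_birth

    @property
    def cycle_window(self) -> Tuple[float, float]:
        return (self.l_birth, self.l_div)

    @property
    def suggested_l_range(self) -> Tuple[float, float]:
        """An l range comfortably covering the cycle window of this scenario."""
        return (0.05, max(2.5, 1.25 * self.l_div))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "l_birth": self.l_birth,
            "growth_law": {
                "mode": self.growth_law.mode,
                "rate": self.growth_law.rate,
                "rho": self.growth_law.rho,
            },
            "init_rule": self.init_rule,
            "intended_phenotype": self.intended_phenotype,
            "provenance": [list(p) for p in self.provenance],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            name=d["name"],
            params=NondimParams(
                epsilon=d["params"]["epsilon"],
                beta=d["params"]["beta"],
                a=tuple(d["params"]["a"]),
            ),
            l_birth=float(d["l_birth"]),
            growth_law=GrowthLaw(**d["growth_law"]),
            init_rule=d["init_rule"],
            intended_phenotype=d["intended_phenotype"],
            provenance=tuple(tuple(p) for p in d.get("provenance", [])),
        )


_cache: Dict[str, Scenario] = {}


def clear_cache() -> None:
    _cache.clear()


def _default_law() -> GrowthLaw:
    return GrowthLaw(mode="linear_l", rate=1.0, rho=100.0)


def _wt() -> Scenario:
    if "wt" in _cache:
        return _cache["wt"]
    eps, beta, res = wt_constraint_solve(
        l_birth=L_BIRTH_REF,
        neto_fraction_target=WT_NETO_FRACTION,
        beta_fixed=BETA_REF,
        bracket=(0.01, 0.4),
    )
    sc = Scenario(
        name="wt",
        params=NondimParams(eps, beta, (0.5, 0.5)),
        l_birth=L_BIRTH_REF,
        growth_law=_default_law(),
        init_rule="old_end",
        intended_phenotype="WT_NETO",
        provenance=(
            ("construction", "wt_constraint_solve"),
            ("constraints",
             f"monopolar stable at l_birth={L_BIRTH_REF}; NETO at cycle "
             f"fraction {WT_NETO_FRACTION:.4f} (l*={res['neto_l']:.6f})"),
            ("beta_fixed", str(BETA_REF)),
        ),
    )
    _cache["wt"] = sc
    return sc


def _phenotype_of(params: NondimParams, l_birth: float) -> str:
    d = build_diagram(params, (0.05, 2.5), FAST_SETTINGS)
    return classify_phenotype(d, (l_birth, 2 * l_birth)).label


def _search_scale(
    base: NondimParams,
    l_birth: float,
    field_name: str,
    factor: float,
    want: str,
    max_iter: int = 14,
) -> Tuple[NondimParams, int]:
    """Scale one parameter geometrically until the phenotype call matches."""
    p = base
    for k in range(1, max_iter + 1):
        p = p.with_(**{field_name: getattr(p, field_name) * factor})
        if _phenotype_of(p, l_birth) == want:
            return p, k
    raise RuntimeError(
        f"could not reach phenotype {want!r} scaling {field_name} by {factor} "
        f"from {getattr(base, field_name)} within {max_iter} steps"
    )


def _derived(name: str, want: str, field_name: str, factor: float) -> Scenario:
    if name in _cache:
        return _cache[name]
    wt = _wt()
    p, k = _search_scale(wt.params, wt.l_birth, field_name, factor, want)
    sc = replace(
        wt,
        name=name,
        params=p,
        intended_phenotype=want,
        provenance=wt.provenance + (
            ("derivation",
             f"{field_name} scaled by {factor}^{k} from wt until phenotype {want}"),
        ),
    )
    _cache[name] = sc
    return sc


def _island_info(params: NondimParams) -> Optional[Tuple[float, float]]:
    """(l_min, l_max) of a closed island branch, or None."""
    d = build_diagram(params, (0.05, 2.5), ContinuationSettings(validate=False))
    for b in d.branches:
        if b.closed:
            return float(b.l.min()), float(b.l.max())
    return None


def _bipolar_onset(params: NondimParams) -> Optional[float]:
    d = build_diagram(params, (0.05, 2.5), FAST_SETTINGS)
    ls = []
    for b in d.branches:
        if b.label == "bipolar" and b.stable_mask().any():
            ls.append(float(b.l[b.stable_mask()].min()))
    return min(ls) if ls else None


def _asym(name: str) -> Scenario:
    """Asymmetric-tip archetypes from the wild-type (eps, beta).

    weak: smallest probed asymmetry with an island overlapping the bipolar
    onset (direct NETO from either branch); moderate: island present but a
    gap to the bipolar branch remains (tip-switch pattern); strong: the
    island has vanished.
    """
    if name in _cache:
        return _cache[name]
    wt = _wt()
    eps, beta = wt.params.epsilon, wt.params.beta
    bip_on = _bipolar_onset(wt.params)

    chosen = None
    note = ""
    if name == "asym_strong":
        for delta in (0.08, 0.12, 0.2):
            p = NondimParams(eps, beta, (0.5 + delta, 0.5 - delta))
            if _island_info(p) is None:
                chosen = p
                note = f"delta={delta}: island absent"
                break
    else:
        for delta in (0.0025, 0.005, 0.01, 0.02, 0.03, 0.04):
            p = NondimParams(eps, beta, (0.5 + delta, 0.5 - delta))
            isl = _island_info(p)
            if isl is None:
                continue
            gap = bip_on is not None and isl[1] < bip_on - 1e-3
            if name == "asym_weak" and not gap:
                chosen = p
                note = f"delta={delta}: island [{isl[0]:.4f},{isl[1]:.4f}] overlaps bipolar onset {bip_on:.4f}"
                break
            if name == "asym_moderate" and gap:
                chosen = p
                note = f"delta={delta}: island [{isl[0]:.4f},{isl[1]:.4f}] with gap to bipolar onset {bip_on:.4f}"
                break
    if chosen is None:
        raise RuntimeError(f"no suitable asymmetry found for {name}")
    intended = {
        "asym_weak": "monopolar_then_NETO on either tip",
        "asym_moderate": "tip_switch_then_NETO when the weak tip starts",
        "asym_strong": "monopolar_then_NETO; anomalous pattern gone",
    }[name]
    sc = replace(
        wt,
        name=name,
        params=chosen,
        intended_phenotype=intended,
        provenance=wt.provenance + (("derivation", note),),
    )
    _cache[name] = sc
    return sc


def _for3_like() -> Scenario:
    """Monopolar and bipolar branches coexisting across the whole cycle window.

    Lower basal activation stretches the monopolar branch; birth length is
    placed just above the bipolar onset so that both branches are stable
    from birth to division, letting monopolar and bipolar patterns persist
    in alternating generations.
    """
    if "for3_like_overlap" in _cache:
        return _cache["for3_like_overlap"]
    wt = _wt()
    p = wt.params
    ext_range = (0.05, 3.2)
    for k in range(1, 12):
        p = p.with_(epsilon=p.epsilon * 0.8)
        onset = _bipolar_onset(p)
        neto = monopolar_neto_l(p, l_range=ext_range)
        if onset is None or neto is None:
            continue
        lb = onset * 1.02
        if np.isinf(neto) or neto >= 2 * lb:
            sc = replace(
                wt,
                name="for3_like_overlap",
                params=p,
                l_birth=float(lb),
                init_rule="alternating",
                intended_phenotype="monopolar_no_NETO and bipolar_from_birth coexisting",
                provenance=wt.provenance + (
                    ("derivation",
                     f"epsilon scaled by 0.8^{k} until monopolar branch spans the "
                     f"cycle window; l_birth={lb:.4f} just above bipolar onset {onset:.4f}"),
                ),
            )
            _cache["for3_like_overlap"] = sc
            return sc
    raise RuntimeError("for3-like overlap construction failed")


def _three_zone(name: str) -> Scenario:
    if name in _cache:
        return _cache[name]
    wt = _wt()
    if name == "three_zone_symmetric":
        # per-zone autocatalysis beta * a_i**2 matched to the two-zone
        # reference (beta_ref / 4) by beta = 9/4 * beta_ref at a_i = 1/3
        beta = BETA_REF * 9.0 / 4.0
        params = NondimParams(0.1, beta, (1 / 3, 1 / 3, 1 / 3))
        intended = ("monopolar, bipolar and tripolar branches; six stable states "
                    "where one- and two-active-zone regimes overlap")
        note = (f"three equal zones; beta={beta} matches per-zone autocatalysis "
                f"beta*a^2 of the two-zone reference")
        l_birth = 0.9
    else:
        # tips keep the two-zone per-zone autocatalysis; the lateral zone is
        # weaker and joins the competition only at large l
        beta = BETA_REF / 4.0 / 0.4**2
        params = NondimParams(wt.params.epsilon, beta, (0.4, 0.4, 0.2))
        intended = ("tips follow the symmetric two-zone pattern; lateral zone "
                    "activates only beyond the normal division length")
        note = (f"tips a=0.4 with beta={beta:.4f} matching the two-zone per-zone "
                f"autocatalysis; lateral a=0.2 is excluded from the competition "
                f"at cycle lengths")
        l_birth = L_BIRTH_REF
    sc = replace(
        wt,
        name=name,
        params=params,
        l_birth=l_birth,
        intended_phenotype=intended,
        provenance=wt.provenance + (("derivation", note),),
    )
    _cache[name] = sc
    return sc


def _build(archetype: str) -> Scenario:
    if archetype == "wt":
        return _wt()
    if archetype == "orb_like":
        return _derived("orb_like", "orb", "beta", 0.8)
    if archetype == "tea_like_low_eps":
        return _derived("tea_like_low_eps", "no_NETO_monopolar", "epsilon", 0.8)
    if archetype == "high_eps_bipolar":
        return _derived("high_eps_bipolar", "premature_bipolar", "epsilon", 1.3)
    if archetype == "low_beta":
        return _derived("low_beta", "delayed_NETO", "beta", 0.88)
    if archetype == "high_beta":
        return _derived("high_beta", "weak_monopolar_early_NETO", "beta", 1.15)
    if archetype in ("asym_weak", "asym_moderate", "asym_strong"):
        return _asym(archetype)
    if archetype == "for3_like_overlap":
        return _for3_like()
    if archetype in ("three_zone_symmetric", "three_zone_weak_lateral"):
        return _three_zone(archetype)
    raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")


def generate_scenarios(
    archetype: str,
    n: int = 1,
    noise: float = 0.0,
    seed: Optional[int] = None,
) -> List[Scenario]:
    """Generate ``n`` scenarios of the given archetype.

    With ``noise > 0`` (mandatory ``seed``), each replicate draws lognormal
    multiplicative factors with coefficient of variation ``noise`` on
    epsilon and beta; replicate derivations are recorded in provenance.
    Re-running with the same seed returns an identical list.
    """
    if noise > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise > 0")
    base = _build(archetype)
    if n == 1 and noise == 0:
        return [base]
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise**2))) if noise > 0 else 0.0
    out = []
    for k in range(n):
        if noise > 0:
            fe, fb = np.exp(rng.normal(0.0, sigma, size=2))
        else:
            fe = fb = 1.0
        p = base.params.with_(
            epsilon=base.params.epsilon * fe, beta=base.params.beta * fb
        )
        out.append(
            replace(
                base,
                name=f"{archetype}_{k}" if n > 1 else archetype,
                params=p,
                provenance=base.provenance + (
                    ("replicate", f"k={k}, noise cv={noise}, seed={seed}, "
                                  f"factors eps={fe:.6f} beta={fb:.6f}"),
                ),
            )
        )
    return out
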