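"""Configuration loading and CSV/JSON serialisation.

Every output embeds a metadata header (tool version, fully resolved
configuration, seed) so a run can be reproduced from its artefacts alone.
CSV files carry the metadata as leading ``#`` comment lines above the
column header; JSON documents carry it under a ``"metadata"`` key.
Configs are flat YAML mappings; unknown keys are a hard error so typos
never silently fall back to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .continuation import BifurcationDiagram, Branch
from .cycle import Trajectory
from .params import DimensionalParams, NondimParams
from .phenotypes import RegionMap
from .scenarios import Scenario

__all__ = ["ConfigError", "load_config", "write_outputs", "load_scenarios"]

_ALLOWED_KEYS = {
    "epsilon": float,
    "beta": float,
    "a": list,
    "n_zones": int,
    "l": float,
    "l_range": list,
    "l_birth": float,
    "seed": int,
    "activity_threshold": float,
    "rho": float,
    "growth_mode": str,
    # optional dimensional block
    "k_basal": float,
    "k_auto": float,
    "k_off": float,
    "T": list,
    "sigma": float,
    "L": float,
}

_DIM_KEYS = ("k_basal", "k_auto", "k_off", "T", "sigma", "L")


class ConfigError(ValueError):
    pass


def load_config(path: Union[str, Path]) -> dict:
    """Load and validate a flat YAML config.

    Returns the raw mapping plus constructed parameter objects under
    ``"params"`` (:class:`NondimParams`) and, when the dimensional block is
    present, ``"dimensional"``.  Unknown keys and invariant violations are
    hard errors.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat mapping")
    unknown = set(raw) - set(_ALLOWED_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _ALLOWED_KEYS.items():
        if key in raw and typ in (float, int) and not isinstance(raw[key], (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric")
    out = dict(raw)
    if "epsilon" in raw or "beta" in raw or "a" in raw:
        try:
            a = tuple(raw.get("a", (0.5, 0.5)))
            out["params"] = NondimParams(
                epsilon=float(raw.get("epsilon", 0.1)),
                beta=float(raw.get("beta", 20.0)),
                a=a,
            )
        except ValueError as exc:
            raise ConfigError(f"invalid model parameters: {exc}") from exc
        if "n_zones" in raw and raw["n_zones"] != out["params"].n_zones:
            raise ConfigError("n_zones does not match the length of a")
    if any(k in raw for k in _DIM_KEYS):
        missing = [k for k in _DIM_KEYS if k not in raw]
        if missing:
            raise ConfigError(f"incomplete dimensional block; missing {missing}")
        try:
            out["dimensional"] = DimensionalParams(
                k_basal=raw["k_basal"], k_auto=raw["k_auto"], k_off=raw["k_off"],
                T=tuple(raw["T"]), sigma=raw["sigma"], L=raw["L"],
            )
        except ValueError as exc:
            raise ConfigError(f"invalid dimensional parameters: {exc}") from exc
    return out


# ----------------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------------


def _metadata(config: Optional[dict], seed: Optional[int]) -> dict:
    return {
        "tool": "growthzones",
        "version": __version__,
        "config": _jsonable(config or {}),
        "seed": seed,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (NondimParams, DimensionalParams)):
        return obj.to_dict()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {json.dumps(_jsonable(v))}\n")
        df.to_csv(fh, index=False)


def _branch_json(b: Branch, branch_id: int) -> dict:
    return {
        "branch_id": branch_id,
        "label": b.label,
        "closed": b.closed,
        "truncated": b.truncated,
        "l": b.l.tolist(),
        "x": b.x.tolist(),
        "stability": list(b.stability),
        "special_points": [
            {"kind": sp.kind, "l": sp.l, "x": list(sp.x), "test_value": sp.test_value}
            for sp in b.special_points
        ],
    }


def _diagram_frame(d: BifurcationDiagram) -> pd.DataFrame:
    n = d.params.n_zones
    rows = []
    for bid, b in enumerate(d.branches):
        for k in range(len(b)):
            row = {"branch_id": bid, "label": b.label, "point_index": k, "l": b.l[k]}
            for j in range(n):
                row[f"x_{j + 1}"] = b.x[k, j]
            row["stability"] = b.stability[k]
            rows.append(row)
    cols = ["branch_id", "label", "point_index", "l"] + [
        f"x_{j + 1}" for j in range(n)
    ] + ["stability"]
    return pd.DataFrame(rows, columns=cols)


def write_outputs(
    obj,
    prefix: Union[str, Path],
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> List[Path]:
    """Write an analysis object as ``<prefix>.csv`` + ``<prefix>.json``.

    Supported objects: :class:`BifurcationDiagram`, :class:`RegionMap`,
    a list of :class:`Trajectory`, a list of :class:`Scenario`, or a plain
    :class:`pandas.DataFrame`.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = _metadata(config, seed)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")

    if isinstance(obj, BifurcationDiagram):
        _write_csv(_diagram_frame(obj), csv_path, meta)
        doc = {
            "metadata": meta,
            "params": obj.params.to_dict(),
            "l_range": list(obj.l_range),
            "incomplete": obj.incomplete,
            "branches": [_branch_json(b, i) for i, b in enumerate(obj.branches)],
            "provenance": _jsonable(obj.provenance),
        }
    elif isinstance(obj, RegionMap):
        _write_csv(obj.to_dataframe(), csv_path, meta)
        doc = {
            "metadata": meta,
            "eps_grid": obj.eps_grid.tolist(),
            "beta_grid": obj.beta_grid.tolist(),
            "l_range": list(obj.l_range),
            "a": list(obj.a),
            "cells": _jsonable(obj.cells),
            "settings": _jsonable(obj.settings),
        }
    elif isinstance(obj, list) and obj and isinstance(obj[0], Trajectory):
        rows = []
        n = obj[0].params.n_zones
        for tid, tr in enumerate(obj):
            for k in range(len(tr.t)):
                row = {"trajectory_id": tid, "time": tr.t[k], "l": tr.l[k]}
                for j in range(n):
                    row[f"x_{j + 1}"] = tr.x[k, j]
                rows.append(row)
        _write_csv(pd.DataFrame(rows), csv_path, meta)
        doc = {
            "metadata": meta,
            "trajectories": [
                {
                    "trajectory_id": tid,
                    "params": tr.params.to_dict(),
                    "l_birth": tr.l_birth,
                    "l_div": tr.l_div,
                    "events": [[t, k, z] for t, k, z in tr.events],
                }
                for tid, tr in enumerate(obj)
            ],
        }
    elif isinstance(obj, list) and obj and isinstance(obj[0], Scenario):
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "name": s.name,
                        "epsilon": s.params.epsilon,
                        "beta": s.params.beta,
                        "a": ";".join(str(v) for v in s.params.a),
                        "l_birth": s.l_birth,
                        "intended_phenotype": s.intended_phenotype,
                    }
                    for s in obj
                ]
            ),
            csv_path,
            meta,
        )
        doc = {"metadata": meta, "scenarios": [s.to_dict() for s in obj]}
    elif isinstance(obj, pd.DataFrame):
        _write_csv(obj, csv_path, meta)
        doc = {"metadata": meta, "table": _jsonable(obj.to_dict(orient="records"))}
    else:
        raise TypeError(f"don't know how to serialise {type(obj)!r}")

    json_path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return [csv_path, json_path]


def load_scenarios(path: Union[str, Path]) -> List[Scenario]:
    """Load a scenario list written by :func:`write_outputs` (round trip)."""
    doc = json.loads(Path(path).read_text())
    return [Scenario.from_dict(d) for d in doc["scenarios"]]
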