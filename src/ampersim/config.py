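"""Configuration files and solver profiles.

A run is described by a small YAML document::

    schema_version: 1
    profile: fast                 # or "default"
    geometry:
      shape: cone_up
      alpha: 0.93                 # or a2 directly
      gamma: 0.5                  # or b3 directly
      a3: 0.1
      b1: 2.0
      b2: 4.0
      b4: 14.0
      b5: 16.0
    params:                       # dimensionless block ...
      sigma2: 3.33e4
      S0: 1.0
      D2: 3.0
      D3: 6.0
    # dimensional: {...}          # ... or a dimensional block, never both
    solver: {dt: 0.01, t_max: 400.0}   # optional overrides
    mesh: {h: 0.4}                     # optional overrides

The *default* profile resolves the reaction boundary layer
(``h_min ~ sqrt(D2 (1+S0)/sigma2) / 4``); the *fast* profile coarsens the
mesh and accelerates the time-step ramp for parameter sweeps and CI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from math import sqrt

import yaml

from .fem import SolverConfig
from .geometry import GeometrySpec, Shape, filling_height, throat_from_alpha
from .model import DimensionalParams, DimensionlessParams, nondimensionalize

__all__ = ["RunConfig", "ConfigError", "load_config", "resolve_config", "config_hash", "PROFILES"]

SCHEMA_VERSION = 1

PROFILES = {
    "default": {
        "mesh": {"h": 0.4, "growth": 1.3, "n_r_inner": 6, "n_r_outer": 8, "bl_factor": 4.0},
        "solver": {"dt": 0.01, "dt_max": 0.2, "dt_growth": 1.04, "t_max": 400.0},
    },
    "fast": {
        "mesh": {"h": 0.8, "growth": 1.5, "n_r_inner": 4, "n_r_outer": 5, "bl_factor": 2.0},
        "solver": {"dt": 0.02, "dt_max": 0.5, "dt_growth": 1.08, "t_max": 400.0},
    },
}

_STUDY_GEOMETRY = {"a3": 0.1, "b1": 2.0, "b2": 4.0, "b4": 14.0, "b5": 16.0}
_STUDY_PARAMS = {"sigma2": 3.33e4, "S0": 1.0, "D2": 3.0, "D3": 6.0}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved run description."""

    params: DimensionlessParams
    solver: SolverConfig
    mesh: dict
    profile: str
    raw: dict = field(default_factory=dict)

    @property
    def geometry(self) -> GeometrySpec:
        return self.params.geometry

    def mesh_kwargs(self) -> dict:
        m = dict(self.mesh)
        bl_factor = m.pop("bl_factor", 4.0)
        if m.get("h_min") is None:
            p = self.params
            if p.sigma2 > 0:
                bl = sqrt(p.D2 * (1.0 + p.S0) / p.sigma2)
                m["h_min"] = min(m["h"] / 4, max(bl / bl_factor, 1e-4))
            else:
                m["h_min"] = m["h"] / 4
        return m

    def canonical_dict(self) -> dict:
        g = self.geometry
        return {
            "schema_version": SCHEMA_VERSION,
            "profile": self.profile,
            "geometry": {
                "shape": g.shape.value,
                "a2": g.a2,
                "a3": g.a3,
                "b": [g.b1, g.b2, g.b3, g.b4, g.b5],
                "flip_orientation": g.flip_orientation,
            },
            "params": {
                "sigma2": self.params.sigma2,
                "S0": self.params.S0,
                "D2": self.params.D2,
                "D3": self.params.D3,
            },
            "solver": asdict(self.solver),
            "mesh": self.mesh_kwargs(),
        }


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _geometry_from(block: dict) -> GeometrySpec:
    b = {**_STUDY_GEOMETRY, **block}
    if "shape" not in b:
        raise ConfigError("geometry.shape is required")
    shape = Shape(b["shape"])
    if ("a2" in b) == ("alpha" in b):
        if "a2" not in b:
            raise ConfigError("geometry needs exactly one of a2 / alpha")
        raise ConfigError("geometry: give a2 or alpha, not both")
    a2 = b.get("a2", None)
    if a2 is None:
        a2 = throat_from_alpha(float(b["alpha"]))
    if ("b3" in b) and ("gamma" in b):
        raise ConfigError("geometry: give b3 or gamma, not both")
    b3 = b.get("b3")
    if b3 is None:
        gamma = float(b.get("gamma", 1.0))
        b3 = filling_height(gamma, float(b["b2"]), float(b["b4"]))
    a3 = max(float(b["a3"]), a2) if shape is Shape.CYLINDER else float(b["a3"])
    return GeometrySpec(
        shape=shape,
        a2=float(a2),
        a3=a3,
        b1=float(b["b1"]),
        b2=float(b["b2"]),
        b3=float(b3),
        b4=float(b["b4"]),
        b5=float(b["b5"]),
        flip_orientation=bool(b.get("flip_orientation", False)),
    )


def resolve_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    profile = raw.get("profile", "default")
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose {sorted(PROFILES)}")
    prof = PROFILES[profile]

    if "params" in raw and "dimensional" in raw:
        raise ConfigError("give a dimensionless 'params' or a 'dimensional' block, never both")
    if "dimensional" in raw:
        d = raw["dimensional"]
        try:
            dp = DimensionalParams(**d)
        except TypeError as exc:
            raise ConfigError(f"dimensional block: {exc}") from None
        params = nondimensionalize(dp)
        if "geometry" in raw:
            raise ConfigError("dimensional block carries its own geometry; drop 'geometry'")
    else:
        p = {**_STUDY_PARAMS, **raw.get("params", {})}
        unknown = set(p) - {"sigma2", "S0", "D2", "D3"}
        if unknown:
            raise ConfigError(f"unknown params keys: {sorted(unknown)}")
        geometry = _geometry_from(raw.get("geometry", {}))
        params = DimensionlessParams(
            sigma2=float(p["sigma2"]),
            S0=float(p["S0"]),
            D2=float(p["D2"]),
            D3=float(p["D3"]),
            geometry=geometry,
        )

    solver_kwargs = {**prof["solver"], **raw.get("solver", {})}
    try:
        solver = SolverConfig(**solver_kwargs)
    except TypeError as exc:
        raise ConfigError(f"solver block: {exc}") from None
    mesh = {**prof["mesh"], **raw.get("mesh", {})}
    return RunConfig(params=params, solver=solver, mesh=mesh, profile=profile, raw=raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return resolve_config(raw or {})
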