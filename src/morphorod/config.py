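"""Configuration schema, parameter presets, and structured-text loading.

Config files are YAML mappings; every physical quantity may be given either
as an SI float or as a string with a unit ("20 h", "0.5 mm", "10 MPa").
Unknown keys are rejected with field-level messages. The "baseline" preset
bundles the baseline parameter set of the model organism (an Arabidopsis-
like shoot): gravitropic sensitivity 0.8, proprioceptive sensitivity 20,
statolith avalanche time 2 min, endogenous period 20 min, all tropic memory
and reaction times 12 min, lignification time 6 d with stiffening ratio
200, radius 0.5 mm, Poisson ratio 0.5, density 1e3 kg/m^3, initial modulus
10 MPa, growth zone 5 cm. The endogenous sensitivity alpha and the growth
time tau_g are deliberately free (alpha in [0, 1], tau_g 20-40 h).
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .elastostatics import ElasticParams
from .growth import GrowthParams, LignificationParams
from .reduced import Perturbation, ReducedConfig
from .simulator import SimulationConfig
from .stimuli import StimulusParams
from .units import parse_quantity

__all__ = ["SchemaError", "PRESETS", "preset", "load_config", "load_config_dict",
           "dump_config"]


class SchemaError(ValueError):
    pass


_BASELINE = {
    "stimulus": {
        "alpha": 0.0,
        "tau_e": 1200.0,
        "beta": 0.8,
        "tau_m": 720.0,
        "tau_r": 720.0,
        "eta": 20.0,
        "tau_m_p": 720.0,
        "tau_r_p": 720.0,
        "tau_a": 120.0,
        "radius": 5e-4,
    },
    "elastic": {
        "E": 1.0e7,
        "r": 5e-4,
        "nu_poisson": 0.5,
        "rho": 1.0e3,
        "g_accel": 9.81,
    },
    "lignification": {"E0": 1.0e7, "E1": 2.0e9, "tau_l": 518400.0},
    "growth": {"ell0": 0.01, "ell_g": 0.05},
    "note": (
        "baseline bundle: beta = 0.8, eta = 20, tau_a = 2 min, tau_e = 20 min, "
        "memory/reaction times 12 min, tau_l = 6 d, r = 0.5 mm, nu = 0.5, "
        "rho = 1e3 kg/m^3, E0 = 10 MPa, E1/E0 = 200, growth zone 5 cm; "
        "alpha (0-1) and tau_g (20-40 h) are free"
    ),
}

PRESETS: dict[str, dict] = {"baseline": _BASELINE}


def preset(name: str) -> dict:
    try:
        return PRESETS[name]
    except KeyError:
        raise SchemaError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


_STR_FIELDS = {"scenario", "shear_modulus_convention"}
_INT_FIELDS = {"n_nodes", "record_every", "seed", "endogenous_sign", "rotation_bias"}
_BOOL_FIELDS = {"curvature_dilution", "freeze_growth"}


def _convert(key: str, value: Any, ctx: str):
    if value is None:
        return None
    if key in _STR_FIELDS:
        return str(value)
    if key in _BOOL_FIELDS:
        if not isinstance(value, bool):
            raise SchemaError(f"{ctx}{key}: expected a boolean, got {value!r}")
        return value
    if key in _INT_FIELDS:
        try:
            return int(value)
        except (TypeError, ValueError):
            raise SchemaError(f"{ctx}{key}: expected an integer, got {value!r}")
    try:
        return parse_quantity(value, field=f"{ctx}{key}")
    except ValueError as err:
        raise SchemaError(str(err))


def _section(cls, data: dict | None, defaults: dict, ctx: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    kwargs = dict(defaults)
    for key, value in (data or {}).items():
        if key not in allowed:
            raise SchemaError(f"{ctx}{key}: unknown field (allowed: {sorted(allowed)})")
        kwargs[key] = _convert(key, value, ctx)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise SchemaError(f"{ctx.rstrip('.')}: {err}")


_REDUCED_KEYS = {
    "kind", "preset", "scenario", "ell", "tau_g", "stimulus", "elastic",
    "perturbation", "horizon", "dt", "n_nodes", "record_every",
}
_SIM_KEYS = {
    "kind", "preset", "growth", "lignification", "stimulus", "elastic",
    "t_end", "dt", "out_every", "seed", "initial_tilt", "tilt_direction",
    "n_nodes", "curvature_dilution", "freeze_growth",
}


def load_config_dict(data: dict):
    """Validate a configuration mapping into a Reduced/SimulationConfig."""
    if not isinstance(data, dict):
        raise SchemaError("config must be a mapping")
    kind = data.get("kind")
    if kind not in ("reduced", "simulate"):
        raise SchemaError("config needs kind: 'reduced' or 'simulate'")
    base = preset(data["preset"]) if "preset" in data else {}
    allowed = _REDUCED_KEYS if kind == "reduced" else _SIM_KEYS
    for key in data:
        if key not in allowed:
            raise SchemaError(f"{key}: unknown field for kind={kind} "
                              f"(allowed: {sorted(allowed)})")
    stimulus = _section(
        StimulusParams, data.get("stimulus"), base.get("stimulus", {}), "stimulus."
    )
    elastic = _section(
        ElasticParams, data.get("elastic"), base.get("elastic", {}), "elastic."
    )
    if kind == "reduced":
        for req in ("ell", "tau_g"):
            if req not in data:
                raise SchemaError(f"{req}: required for kind=reduced")
        pert = _section(
            Perturbation, data.get("perturbation"), {}, "perturbation."
        )
        kwargs = {}
        for key in ("scenario", "horizon", "dt", "n_nodes", "record_every"):
            if key in data:
                kwargs[key] = _convert(key, data[key], "")
        try:
            return ReducedConfig(
                ell=_convert("ell", data["ell"], ""),
                tau_g=_convert("tau_g", data["tau_g"], ""),
                stimulus=stimulus,
                elastic=elastic,
                perturbation=pert,
                **kwargs,
            )
        except ValueError as err:
            raise SchemaError(str(err))
    # simulate
    gdata = dict(data.get("growth") or {})
    if "tau_g" not in gdata:
        raise SchemaError("growth.tau_g: required for kind=simulate")
    growth = _section(GrowthParams, gdata, base.get("growth", {}), "growth.")
    lign = _section(
        LignificationParams,
        data.get("lignification"),
        base.get("lignification", {}),
        "lignification.",
    )
    if "t_end" not in data:
        raise SchemaError("t_end: required for kind=simulate")
    kwargs = {}
    for key in ("dt", "out_every", "seed", "initial_tilt", "tilt_direction",
                "n_nodes", "curvature_dilution", "freeze_growth"):
        if key in data:
            kwargs[key] = _convert(key, data[key], "")
    try:
        return SimulationConfig(
            growth=growth,
            lignification=lign,
            stimulus=stimulus,
            elastic=elastic,
            t_end=_convert("t_end", data["t_end"], ""),
            **kwargs,
        )
    except ValueError as err:
        raise SchemaError(str(err))


def load_config(path):
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return load_config_dict(data)


def dump_config(config) -> dict:
    """Configuration as a plain SI-valued mapping (reloadable round trip)."""
    if isinstance(config, ReducedConfig):
        d = dataclasses.asdict(config)
        d["kind"] = "reduced"
    elif isinstance(config, SimulationConfig):
        d = dataclasses.asdict(config)
        d["kind"] = "simulate"
    else:
        raise SchemaError(f"cannot dump {type(config).__name__}")
    return d
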