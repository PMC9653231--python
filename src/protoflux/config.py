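"""Run configuration: TOML files, presets, grids.

One config dialect (TOML).  A run config selects an experiment, a seed,
an output directory and integrator tolerances, and overrides model
parameters on top of the shipped default preset.  Unknown keys are
rejected rather than ignored, and the effective configuration is echoed
into every output manifest so a run can be reproduced bit-identically.

Grids accept either explicit lists::

    [grids]
    kcn = [0.0, 10.0, 1000.0]

or (start, stop, n, scale) quadruples, with scale ``linear`` or ``log``
(log grids take start/stop as exponents of 10)::

    [grids]
    kcn = { start = 0, stop = 4, n = 6, scale = "log" }
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .params import BRANCHES, ConfigurationError, ModelParams, validate_params

__all__ = ["RunConfig", "load_preset", "load_config", "save_config",
           "parse_grid", "params_to_dict"]

_RUN_KEYS = {"experiment", "seed", "output_dir", "rtol", "atol", "verbosity",
             "params", "grids"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass
class RunConfig:
    params: ModelParams
    experiment: str | None = None
    seed: int = 0
    output_dir: str = "."
    rtol: float = 1e-8
    atol: float = 1e-10
    verbosity: int = 1
    grids: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)  # echo of what the file set


def params_to_dict(p: ModelParams) -> dict:
    d = dataclasses.asdict(p)
    d["k_in"] = dict(d["k_in"])
    d["n_c2"] = dict(d["n_c2"])
    return d


def load_preset(name: str = "table1") -> ModelParams:
    """Load a packaged parameter preset by name."""
    ref = resources.files("protoflux.presets").joinpath(f"{name}.toml")
    try:
        raw = tomllib.loads(ref.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"unknown preset {name!r}") from None
    return _params_from_dict(raw)


def _params_from_dict(raw: dict, base: ModelParams | None = None) -> ModelParams:
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
    for key in ("k_in", "n_c2"):
        if key in raw:
            sub = raw[key]
            if not isinstance(sub, dict):
                raise ConfigurationError(f"{key} must be a table of branch values")
            bad = set(sub) - set(BRANCHES)
            if bad:
                raise ConfigurationError(f"unknown {key} branches: {sorted(bad)}")
    if base is None:
        base = ModelParams()
    return base.with_(**raw)


def parse_grid(spec) -> list[float]:
    """Turn a config grid entry (list or quadruple table) into values."""
    if isinstance(spec, (list, tuple)):
        return [float(v) for v in spec]
    if isinstance(spec, dict):
        missing = {"start", "stop", "n"} - set(spec)
        if missing:
            raise ConfigurationError(f"grid table missing keys {sorted(missing)}")
        scale = spec.get("scale", "linear")
        n = int(spec["n"])
        if n < 1:
            raise ConfigurationError(f"grid n must be >= 1, got {n}")
        if scale == "linear":
            return list(np.linspace(float(spec["start"]), float(spec["stop"]), n))
        if scale == "log":
            return list(np.logspace(float(spec["start"]), float(spec["stop"]), n))
        raise ConfigurationError(f"grid scale must be 'linear' or 'log', got {scale!r}")
    raise ConfigurationError(f"cannot parse grid spec {spec!r}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run-config file; defaults come from the
    shipped preset, so an empty file is a valid config."""
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as err:
        raise ConfigurationError(f"{path}: parse error: {err}") from err
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys: {sorted(unknown)}")
    overrides = raw.get("params", {})
    params = validate_params(_params_from_dict(overrides, base=load_preset()))
    grids = {k: parse_grid(v) for k, v in raw.get("grids", {}).items()}
    return RunConfig(
        params=params,
        experiment=raw.get("experiment"),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        rtol=float(raw.get("rtol", 1e-8)),
        atol=float(raw.get("atol", 1e-10)),
        verbosity=int(raw.get("verbosity", 1)),
        grids=grids,
        overrides=overrides,
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigurationError(f"cannot serialize {v!r} to TOML")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    lines = []
    if cfg.experiment is not None:
        lines.append(f'experiment = "{cfg.experiment}"')
    lines += [f"seed = {cfg.seed}",
              f'output_dir = "{cfg.output_dir}"',
              f"rtol = {_toml_value(cfg.rtol)}",
              f"atol = {_toml_value(cfg.atol)}",
              f"verbosity = {cfg.verbosity}"]
    # full effective parameter set, so the file stands alone
    d = params_to_dict(cfg.params)
    k_in, n_c2 = d.pop("k_in"), d.pop("n_c2")
    lines.append("\n[params]")
    lines += [f"{k} = {_toml_value(v)}" for k, v in d.items()]
    lines.append("\n[params.k_in]")
    lines += [f"{b} = {_toml_value(k_in[b])}" for b in BRANCHES]
    lines.append("\n[params.n_c2]")
    lines += [f"{b} = {_toml_value(n_c2[b])}" for b in BRANCHES]
    if cfg.grids:
        lines.append("\n[grids]")
        lines += [f"{k} = {_toml_value(list(v))}" for k, v in cfg.grids.items()]
    Path(path).write_text("\n".join(lines) + "\n")
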