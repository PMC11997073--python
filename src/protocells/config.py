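"""Configuration files, run manifests and deterministic test fixtures.

One YAML schema is shared by every entry point: the flat key set is the
union of the :class:`~protocells.params.ModelParams` fields and the run
options (grid size ``d``, horizon ``T_max``, ``snapshot_every``,
``stats_every``, ``out_dir``).  An empty file yields the reference
parameterization.  Scenario files for the four shipped model variants live
in ``protocells/configs``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .grid import build_grid
from .params import ModelParams

__all__ = [
    "ConfigError",
    "RunOptions",
    "RunManifest",
    "load_config",
    "scenario_path",
    "make_fixture",
]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_INT_PARAMS = {"n", "rho0", "U00", "seed"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunOptions:
    d: int = 500
    T_max: int = 200_000
    snapshot_every: int = 0
    stats_every: int = 1
    out_dir: str = "runs"


_OPTION_KEYS = {f.name for f in dataclasses.fields(RunOptions)}


def load_config(path) -> tuple[ModelParams, RunOptions]:
    """Parse and validate a run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _PARAM_KEYS - _OPTION_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")

    p_kwargs = {}
    for key in _PARAM_KEYS & set(raw):
        value = raw[key]
        if key in _INT_PARAMS and value is not None:
            value = int(value)
        p_kwargs[key] = value
    o_kwargs = {k: raw[k] for k in _OPTION_KEYS & set(raw)}
    for k in ("d", "T_max", "snapshot_every", "stats_every"):
        if k in o_kwargs:
            o_kwargs[k] = int(o_kwargs[k])
    try:
        params = ModelParams(**p_kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc
    return params, RunOptions(**o_kwargs)


def scenario_path(name: str) -> Path:
    """Path of a shipped scenario config (``model_a`` ... ``model_d``)."""
    ref = resources.files("protocells") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(f"unknown scenario {name!r}")
    return Path(str(ref))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    params: dict
    d: int
    T_max: int
    snapshot_every: int
    label: str
    seed: int
    started: str = ""
    finished: str = ""
    invariant_check: dict | None = None
    code_version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic objects for tests and demos.

    * ``tiny-grid``: a 20x20 grid with its kernel and parameters;
    * ``two-bump``: a grid plus a field holding two Gaussian bumps with
      known centers, and the centers themselves;
    * ``plateau-series``: a three-plateau food curve with its two
      constructed change points.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny-grid":
        from .kernel import build_sparse_kernel

        params = ModelParams(eps_eta=0.2, eps_zeta=1.5, rho0=10**6, seed=seed)
        grid = build_grid(20, params.L)
        return grid, build_sparse_kernel(grid, params), params
    if kind == "two-bump":
        grid = build_grid(50, 25.0)
        centers = ((-0.5, 12.5), (0.5, 12.5))
        eta, zeta = grid.eta_flat, grid.zeta_flat
        U = np.zeros(grid.n_nodes)
        for ce, cz in centers:
            U += np.exp(-(((eta - ce) / 0.08) ** 2) - (((zeta - cz) / 1.0) ** 2))
        U[U < 1e-12] = 0.0
        return grid, U, centers
    if kind == "plateau-series":
        def ramp(a, b, m):
            return np.linspace(a, b, m, endpoint=False)

        # plateau / drop / plateau / drop / plateau; expected boundaries are
        # first-drop end, second-drop start, second-drop end
        change_points = (40, 80, 90)
        series = np.concatenate(
            [
                np.full(30, 90.0),
                ramp(90.0, 55.0, 10),       # drop ends at step 40
                np.full(40, 55.0),
                ramp(55.0, 20.0, 10),       # drop starts at 80, ends at 90
                np.full(40, 20.0),
            ]
        )
        series = series + 0.01 * rng.standard_normal(series.size)
        return series, change_points
    raise ValueError(f"unknown fixture kind {kind!r}")
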