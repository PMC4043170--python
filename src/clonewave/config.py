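"""Config-file loading and run manifests.

Config files are flat key/value JSON or YAML.  Recognised keys: ``preset``
plus the :class:`~clonewave.params.HierarchyParams` fields
(``n_compartments``, ``gamma``, ``r0``, ``u``, ``epsilon``, ``n0``,
``founder_compartment``, ``k_max``) and ``seed``.  Command-line overrides win
over file values; the merged set must pass validation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import yaml

from . import __version__
from .params import HierarchyParams, ParameterError, preset, validate_params

__all__ = ["load_config", "RunManifest", "PARAM_KEYS"]

PARAM_KEYS = {
    "n_compartments",
    "gamma",
    "r0",
    "u",
    "epsilon",
    "n0",
    "founder_compartment",
    "k_max",
}
_OPTION_KEYS = {"seed"}


class ConfigError(ValueError):
    pass


def _read_mapping(path) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse failure in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config parse failure: {path} is not a mapping")
    return data


def load_config(path=None, overrides: dict | None = None):
    """Build validated parameters plus run options from file and overrides.

    Returns ``(HierarchyParams, options)`` where ``options`` currently holds
    ``seed``.  Unknown keys, parse failures and validation failures raise
    :class:`ConfigError` / :class:`~clonewave.params.ParameterError` with
    distinct messages.
    """
    data: dict = {}
    if path is not None:
        data.update(_read_mapping(path))
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val

    unknown = set(data) - PARAM_KEYS - _OPTION_KEYS - {"preset"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    base = preset(data.pop("preset")) if "preset" in data else HierarchyParams()
    options = {"seed": data.pop("seed", None)}
    fields = {k: v for k, v in data.items() if k in PARAM_KEYS}
    params = dataclasses.replace(base, _eps_table=None, **fields)
    return validate_params(params), options


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce its outputs."""

    subcommand: str
    parameters: dict
    seed: object
    outputs: list
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.datetime.now().isoformat(timespec="seconds")

    @classmethod
    def for_run(cls, subcommand: str, params: HierarchyParams, seed, outputs):
        pdict = {
            k: getattr(params, k) for k in sorted(PARAM_KEYS)
        }
        if not isinstance(pdict["epsilon"], (int, float)):
            pdict["epsilon"] = params.eps_table.tolist()
        return cls(
            subcommand=subcommand,
            parameters=pdict,
            seed=seed,
            outputs=[str(o) for o in outputs],
        )

    def write(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
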