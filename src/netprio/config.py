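"""Run configuration with layered resolution: flag > config file > default.

The resolved value of every key, together with where it came from, is echoed
to the log before any computation so a run is reproducible from its log
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "RunConfig", "load_config_file"]

DEFAULTS: dict[str, Any] = {
    "restart_probability": 0.3,
    "normalization": "column-stochastic",
    "tol": 1e-10,
    "max_iter": 1000,
    "dense_node_cap": 20_000,
    "combine_rule": "max",
    "seed_policy": "excluded",
    "top_k": 300,
    "null": "degree-matched",
    "n_bins": 10,
    "rng_seed": 0,
    # synthetic generator
    "n_background": 500,
    "module_size": 50,
    "p_in": 0.30,
    "p_out": 0.01,
    "seed_fraction": 0.5,
    "background_model": "erdos-renyi",
}


def load_config_file(path: str) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    unknown = set(data) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return data


@dataclass
class RunConfig:
    """Fully-resolved configuration plus the provenance of each value."""

    values: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def resolve(cls, file_values: Mapping[str, Any] | None = None,
                flag_values: Mapping[str, Any] | None = None) -> "RunConfig":
        """Layer flag over file over default; ``None`` flags mean 'not given'."""
        values: dict[str, Any] = {}
        provenance: dict[str, str] = {}
        file_values = file_values or {}
        flag_values = {k: v for k, v in (flag_values or {}).items()
                       if v is not None}
        for key, default in DEFAULTS.items():
            if key in flag_values:
                values[key], provenance[key] = flag_values[key], "flag"
            elif key in file_values:
                values[key], provenance[key] = file_values[key], "file"
            else:
                values[key], provenance[key] = default, "default"
        return cls(values=values, provenance=provenance)

    def log_resolved(self, keys: list[str] | None = None) -> None:
        for key in keys or sorted(self.values):
            logger.info("config: %s = %r  (%s)", key, self.values[key],
                        self.provenance[key])

    def __getitem__(self, key: str) -> Any:
        return self.values[key]
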