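"""YAML run configuration with strict schema validation.

A run config binds the pipeline settings, the GWO settings, the
hyperparameter ranges, the model choice and the seeds in one document.
Unknown keys are rejected so typos fail before any work starts.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict] = {
    "pipeline": {
        "input_dir": str,
        "output_dir": str,
        "empty_threshold": (int, float),
        "test_fraction": (int, float),
        "validation_fraction": (int, float),
        "image_format": str,
        "by_subject": bool,
    },
    "gwo": {
        "n_wolves": int,
        "n_iterations": int,
        "tolerance": (int, float, type(None)),
    },
    "hyperparameters": None,  # list of [name, kind, lower, upper]
    "model": {"name": str, "dense_units": list, "dropout_rate": (int, float)},
    "seed": int,
    "trainer_seed": int,
    "output_dir": str,
}


class RunConfig(dict):
    """Validated run configuration (a thin dict with attribute access)."""

    def section(self, name: str, default=None):
        return self.get(name, {} if default is None else default)


def _check(section: str, doc: dict, schema: dict):
    for key, value in doc.items():
        if key not in schema:
            raise ConfigError(f"unknown key {section}.{key!r}")
        expected = schema[key]
        if expected is not None and not isinstance(value, expected):
            raise ConfigError(
                f"{section}.{key}: expected {expected}, got {type(value).__name__}"
            )


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    for key, value in doc.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown top-level key {key!r}")
        sub = _SCHEMA[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{key} must be a mapping")
            _check(key, value, sub)
        elif sub is not None and not isinstance(value, sub):
            raise ConfigError(f"{key}: expected {sub}, got {type(value).__name__}")
    if "hyperparameters" in doc:
        hps = doc["hyperparameters"]
        if not isinstance(hps, list) or any(len(d) != 4 for d in hps):
            raise ConfigError("hyperparameters must be a list of [name, kind, lower, upper]")
    return RunConfig(doc)
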