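"""Config round-trip: model parameters and regimen definitions as YAML.

The packaged default config (``data/default_model.yaml``) carries the
calibrated parameter set; every value can be overridden by a user config of
the same shape:

    model:
      cl_ref: 0.11
      ...
    regimens:
      scig: {formulation: scig, dose_per_kg: 0.15, interval: 7, horizon: 140}
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .pkmodel import PopulationParameters
from .scenario import Regimen

__all__ = ["load_config", "save_config", "load_default_parameters",
           "default_config_path"]


def default_config_path() -> Path:
    return Path(resources.files("igsim") / "data" / "default_model.yaml")


def load_config(path=None) -> dict:
    """Parse a config file into {'model': PopulationParameters,
    'regimens': {name: Regimen}}; missing sections fall back to defaults."""
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = PopulationParameters.from_dict(raw.get("model", {})) \
        if raw.get("model") else PopulationParameters()
    regimens = {}
    for name, spec in (raw.get("regimens") or {}).items():
        regimens[name] = Regimen(**spec)
    if not regimens:
        regimens = {"scig": Regimen.scig(), "fscig": Regimen.fscig()}
    return {"model": model, "regimens": regimens}


def save_config(model: PopulationParameters, path, regimens=None) -> None:
    doc = {"model": {k: float(v) for k, v in model.to_dict().items()}}
    if regimens:
        doc["regimens"] = {name: r.to_dict() for name, r in regimens.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_parameters() -> PopulationParameters:
    """The calibrated parameter set shipped with the package."""
    return load_config(default_config_path())["model"]
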