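"""Model registry and default calibration bounds.

All fourteen models are keyed by their field-standard abbreviations:
emergence TT, TTs, PTT, PTTs, M1, AT, SQ, DP and senescence WM, DM, JM,
DPDI, DMs, DPDIs.  Default parameter bounds ship in ``bounds.yaml`` next to
this module and can be overridden from a user YAML file of the same shape.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Mapping, Tuple

import yaml

from .emergence import EMERGENCE_MODELS
from .senescence import SENESCENCE_MODELS

MODELS = {**EMERGENCE_MODELS, **SENESCENCE_MODELS}

Bounds = Dict[str, Tuple[float, float]]


def get_model(name: str):
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}") from None


def _load_yaml(path=None) -> Mapping:
    if path is None:
        text = resources.files("leafphen").joinpath("bounds.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def default_bounds(model_name: str, path=None) -> Bounds:
    """Bounds for one model, validated against its declared parameter set."""
    model = get_model(model_name)
    table = _load_yaml(path)
    if model_name not in table:
        raise KeyError(f"no bounds for model {model_name!r} in config")
    raw = table[model_name]
    if set(raw) != set(model.param_names):
        raise ValueError(
            f"bounds parameters {sorted(raw)} do not match "
            f"{model_name} parameters {sorted(model.param_names)}"
        )
    out: Bounds = {}
    for name in model.param_names:
        lo, hi = (float(v) for v in raw[name])
        if not lo <= hi:
            raise ValueError(f"{model_name}.{name}: low {lo} > high {hi}")
        out[name] = (lo, hi)
    return out
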