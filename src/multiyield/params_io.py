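"""Flat key-value parameter files (YAML or JSON) for the model layer."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core_model import (
    EnergyParams,
    PrecursorEffects,
    PrecursorSpec,
    TwoDegradableEffects,
)

__all__ = ["load_params_file", "energy_params_from_dict", "dump_params_file"]


def _read(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def energy_params_from_dict(data: dict) -> EnergyParams:
    return EnergyParams(
        g_X=float(data["g_X"]),
        g_cat={str(k): float(v) for k, v in dict(data["g_cat"]).items()},
        g_an=float(data.get("g_an", 0.0)),
        g_an_excl=float(data.get("g_an_excl", 0.0)),
        g_bsyn=float(data.get("g_bsyn", 0.0)),
    )


def load_params_file(path) -> dict:
    """Load a parameter file into model objects.

    Recognised top-level keys: the EnergyParams fields, optional
    ``effects_two_degradable`` / ``effects_precursor`` mappings, and
    optional ``q_req``.  Returns a dict with keys ``params`` and any of
    ``two_degradable_effects``, ``precursor_effects``, ``precursor_spec``.
    """
    data = _read(path)
    out: dict = {"params": energy_params_from_dict(data)}
    if "effects_two_degradable" in data:
        out["two_degradable_effects"] = TwoDegradableEffects(
            **{k: float(v) for k, v in data["effects_two_degradable"].items()}
        )
    if "effects_precursor" in data:
        out["precursor_effects"] = PrecursorEffects(
            **{k: float(v) for k, v in data["effects_precursor"].items()}
        )
    if "q_req" in data:
        out["precursor_spec"] = PrecursorSpec(q_req=float(data["q_req"]))
    return out


def dump_params_file(path, params: EnergyParams, **extra) -> None:
    data: dict = {
        "g_X": params.g_X,
        "g_cat": dict(params.g_cat),
        "g_an": params.g_an,
        "g_an_excl": params.g_an_excl,
        "g_bsyn": params.g_bsyn,
    }
    data.update(extra)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
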