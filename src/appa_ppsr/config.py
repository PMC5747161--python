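"""Flat YAML (de)serialization of parameter sets and trajectory export."""

from __future__ import annotations

import math

import pandas as pd
import yaml

from .core_model import ModelParams
from .errors import DomainError
from .fitting import OxygenMap
from .promoter import PromoterParams

__all__ = [
    "model_params_to_dict",
    "model_params_from_dict",
    "promoter_params_from_dict",
    "oxygen_map_from_dict",
    "load_params_yaml",
    "dump_params_yaml",
    "trajectory_to_tsv",
]

_MODEL_KEYS = ("I", "alpha", "beta", "gamma", "delta", "K_eq")
_PROMOTER_KEYS = ("M_max", "K_ox", "n_ox", "K_red", "n_red", "PpsR_total",
                  "case")


def _parse_keq(v):
    if isinstance(v, str):
        if v.strip().lower() in ("inf", "infinity", "∞"):
            return math.inf
        return float(v)
    return float(v)


def model_params_to_dict(params: ModelParams) -> dict:
    d = {k: getattr(params, k) for k in _MODEL_KEYS}
    if math.isinf(d["K_eq"]):
        d["K_eq"] = "inf"
    return d


def model_params_from_dict(d: dict) -> ModelParams:
    unknown = set(d) - set(_MODEL_KEYS)
    if unknown:
        raise DomainError(f"unknown model parameter keys {sorted(unknown)}")
    kwargs = {k: float(d[k]) for k in ("I", "alpha", "beta", "gamma")
              if k in d}
    if "delta" in d:
        kwargs["delta"] = float(d["delta"])
    if "K_eq" in d:
        kwargs["K_eq"] = _parse_keq(d["K_eq"])
    return ModelParams(**kwargs)


def promoter_params_from_dict(d: dict) -> PromoterParams:
    unknown = set(d) - set(_PROMOTER_KEYS)
    if unknown:
        raise DomainError(f"unknown promoter parameter keys {sorted(unknown)}")
    kwargs = {k: (d[k] if k == "case" else float(d[k]))
              for k in _PROMOTER_KEYS if k in d}
    return PromoterParams(**kwargs)


def oxygen_map_from_dict(d: dict) -> OxygenMap:
    kwargs = {}
    if "O_max" in d:
        kwargs["O_max"] = float(d["O_max"])
    if "pct_max" in d:
        kwargs["pct_max"] = float(d["pct_max"])
    if "aerobic_dissolved_range" in d:
        low, high = d["aerobic_dissolved_range"]
        kwargs["aerobic_dissolved_range"] = (float(low), float(high))
    return OxygenMap(**kwargs)


def load_params_yaml(path):
    """Load a YAML file with optional ``model``, ``promoter`` and
    ``oxygen_map`` sections (a flat file is treated as model parameters)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not any(k in raw for k in ("model", "promoter", "oxygen_map")):
        raw = {"model": raw}
    out = {}
    if "model" in raw:
        out["model"] = model_params_from_dict(raw["model"])
    if "promoter" in raw:
        out["promoter"] = promoter_params_from_dict(raw["promoter"])
    if "oxygen_map" in raw:
        out["oxygen_map"] = oxygen_map_from_dict(raw["oxygen_map"])
    return out


def dump_params_yaml(path, model: ModelParams = None,
                     promoter: PromoterParams = None,
                     oxygen_map: OxygenMap = None) -> None:
    doc = {}
    if model is not None:
        doc["model"] = model_params_to_dict(model)
    if promoter is not None:
        doc["promoter"] = {k: getattr(promoter, k) for k in _PROMOTER_KEYS}
    if oxygen_map is not None:
        doc["oxygen_map"] = {
            "O_max": oxygen_map.O_max, "pct_max": oxygen_map.pct_max,
            "aerobic_dissolved_range": list(
                oxygen_map.aerobic_dissolved_range)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def trajectory_to_tsv(times, states, path) -> None:
    """Export a simulated trajectory as named-column TSV."""
    df = pd.DataFrame({
        "time": times,
        "a": [s.a for s in states], "b": [s.b for s in states],
        "p": [s.p for s in states], "r": [s.r for s in states],
        "c": [s.c for s in states]})
    df.to_csv(path, sep="\t", index=False)
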