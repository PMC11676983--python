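"""YAML (de)serialization of constructs, initial states and protocols.

All numeric fields are coerced with float()/int() on load so that YAML
representations that parse as strings (e.g. ``1e-5`` without a decimal
point) still round-trip losslessly.  Missing keys raise ConfigError naming
the offending key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .errors import ConfigError
from .reaction_model import ReactionState, TMSDRSystem
from .synthetic_data import SyntheticProtocol

__all__ = [
    "system_to_dict",
    "system_from_dict",
    "state_to_dict",
    "state_from_dict",
    "protocol_to_dict",
    "protocol_from_dict",
    "load_config",
    "save_config",
]


def _require(mapping: Dict[str, Any], key: str, context: str) -> Any:
    if key not in mapping or mapping[key] is None:
        raise ConfigError(f"missing required key `{key}` in {context} section")
    return mapping[key]


def system_to_dict(system: TMSDRSystem) -> Dict[str, Any]:
    return {
        "toehold_orientation": system.toehold_orientation.value,
        "modification": system.modification.value,
        "reporter_species": system.reporter_species.value,
        "ka": float(system.ka),
        "kd": float(system.kd),
        "toehold_length": int(system.toehold_length),
        "recognition_length": int(system.recognition_length),
    }


def system_from_dict(d: Dict[str, Any]) -> TMSDRSystem:
    try:
        return TMSDRSystem(
            ka=float(_require(d, "ka", "system")),
            kd=float(_require(d, "kd", "system")),
            toehold_orientation=d.get("toehold_orientation", "five_prime"),
            modification=d.get("modification", "symmetric"),
            reporter_species=d.get("reporter_species", "X4"),
            toehold_length=int(d.get("toehold_length", 6)),
            recognition_length=int(d.get("recognition_length", 20)),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid system configuration: {exc}") from exc


def state_to_dict(state: ReactionState) -> Dict[str, float]:
    return {"x1": state.x1, "x2": state.x2, "x3": state.x3, "x4": state.x4}


def state_from_dict(d: Dict[str, Any]) -> ReactionState:
    try:
        return ReactionState(
            x1=float(_require(d, "x1", "initial")),
            x2=float(_require(d, "x2", "initial")),
            x3=float(d.get("x3", 0.0)),
            x4=float(d.get("x4", 0.0)),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid initial state: {exc}") from exc


def protocol_to_dict(protocol: SyntheticProtocol) -> Dict[str, Any]:
    return {
        "seed": int(protocol.seed),
        "sample_interval": float(protocol.sample_interval),
        "duration": float(protocol.duration),
        "n_replicates": int(protocol.n_replicates),
        "noise_sd": float(protocol.noise_sd),
        "f0": float(protocol.f0),
        "f100": float(protocol.f100),
        "drift_per_hour": float(protocol.drift_per_hour),
    }


def protocol_from_dict(d: Dict[str, Any], seed: Optional[int] = None) -> SyntheticProtocol:
    if seed is None:
        seed = _require(d, "seed", "protocol")
    try:
        return SyntheticProtocol(
            seed=int(seed),
            sample_interval=float(d.get("sample_interval", 10.0)),
            duration=float(d.get("duration", 5400.0)),
            n_replicates=int(d.get("n_replicates", 3)),
            noise_sd=float(d.get("noise_sd", 0.02)),
            f0=float(d.get("f0", 100.0)),
            f100=float(d.get("f100", 1000.0)),
            drift_per_hour=float(d.get("drift_per_hour", 0.0)),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid protocol configuration: {exc}") from exc


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def save_config(config: Dict[str, Any], path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
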