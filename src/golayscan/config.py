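"""Run configuration: parsing, validation and unit handling.

Configs are JSON (canonical) or YAML.  Validation is strict — unknown
keys raise with the offending field path, so a typo never silently
falls back to a default.  All internal quantities are SI (meters,
seconds, Hz, Rayls, volts); config values may be plain numbers or
strings with an explicit unit suffix ("75 kHz", "1 mm", "10 cm").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .channel import (
    AIR,
    ChannelConfig,
    DefectRegion,
    Medium,
    PINE,
    ReceiverChain,
    Specimen,
    TransducerModel,
)
from .scan import Pipeline, ScanPlan
from .waveforms import ModulationSpec

__all__ = ["RunConfig", "load_config", "save_config", "parse_quantity",
           "load_specimen", "specimen_to_dict"]

_UNIT_FACTORS = {
    "hz": 1.0, "khz": 1e3, "mhz": 1e6,
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "v": 1.0, "mv": 1e-3,
    "db": 1.0, "rayl": 1.0, "rayls": 1.0,
}


def parse_quantity(value, path: str = "value") -> float:
    """A number, or a string with an explicit unit suffix, to SI."""
    if isinstance(value, bool):
        raise ValueError(f"{path}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        try:
            if len(parts) == 1:
                return float(parts[0])
            if len(parts) == 2:
                return float(parts[0]) * _UNIT_FACTORS[parts[1].lower()]
        except (ValueError, KeyError):
            pass
        raise ValueError(f"{path}: cannot parse quantity {value!r}")
    raise ValueError(f"{path}: expected a number or 'value unit' string")


def _take(section: dict, path: str, known: dict) -> dict:
    """Pop known keys (with parsing); reject anything left over."""
    out = {}
    section = dict(section)
    for key, parser in known.items():
        if key in section:
            raw = section.pop(key)
            out[key] = parser(raw, f"{path}.{key}") if parser else raw
    if section:
        bad = ", ".join(f"{path}.{k}" for k in sorted(section))
        raise ValueError(f"unknown config key(s): {bad}")
    return out


def _passthrough(v, path):
    return v


def _int(v, path):
    if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
        raise ValueError(f"{path}: expected an integer, got {v!r}")
    return int(v)


def _bool(v, path):
    if not isinstance(v, bool):
        raise ValueError(f"{path}: expected a boolean, got {v!r}")
    return v


def _medium(section, path):
    kw = _take(section, path, {
        "impedance": parse_quantity,
        "sound_speed": parse_quantity,
        "attenuation_coeff": parse_quantity,
        "attenuation_exponent": parse_quantity,
    })
    return kw


def _defect(section, path):
    kw = _take(section, path, {
        "shape": _passthrough,
        "center": _passthrough,
        "size": _passthrough,
        "label": _passthrough,
        "impedance_multiplier": parse_quantity,
        "thickness_fraction": parse_quantity,
        "scatter_loss_db": parse_quantity,
    })
    for req in ("shape", "center", "size", "label"):
        if req not in kw:
            raise ValueError(f"{path}.{req} is required")
    kw["center"] = tuple(parse_quantity(c, f"{path}.center")
                         for c in kw["center"])
    if kw["shape"] == "circle":
        kw["size"] = parse_quantity(kw["size"], f"{path}.size")
    elif kw["shape"] == "ellipse":
        kw["size"] = tuple(parse_quantity(s, f"{path}.size")
                           for s in kw["size"])
    elif kw["shape"] == "polygon":
        kw["size"] = [tuple(parse_quantity(c, f"{path}.size") for c in v)
                      for v in kw["size"]]
    try:
        return DefectRegion(**kw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _specimen_from_dict(section: dict, path: str = "specimen") -> Specimen:
    kw = _take(section, path, {
        "nominal_thickness": parse_quantity,
        "width": parse_quantity,
        "height": parse_quantity,
        "base": _passthrough,
        "defects": _passthrough,
    })
    for req in ("nominal_thickness", "width", "height"):
        if req not in kw:
            raise ValueError(f"{path}.{req} is required")
    base = PINE
    if "base" in kw:
        base_kw = _medium(kw.pop("base"), f"{path}.base")
        defaults = {"impedance": PINE.impedance,
                    "sound_speed": PINE.sound_speed,
                    "attenuation_coeff": PINE.attenuation_coeff,
                    "attenuation_exponent": PINE.attenuation_exponent}
        defaults.update(base_kw)
        base = Medium(**defaults)
    defects = tuple(
        _defect(d, f"{path}.defects[{i}]")
        for i, d in enumerate(kw.pop("defects", []))
    )
    try:
        return Specimen(base=base, defects=defects, **kw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from None


def load_specimen(path) -> Specimen:
    """Load a parametric board definition from a JSON/YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: specimen file must hold a mapping")
    return _specimen_from_dict(data)


def specimen_to_dict(specimen: Specimen) -> dict:
    d = {
        "nominal_thickness": specimen.nominal_thickness,
        "width": specimen.width,
        "height": specimen.height,
        "base": {
            "impedance": specimen.base.impedance,
            "sound_speed": specimen.base.sound_speed,
            "attenuation_coeff": specimen.base.attenuation_coeff,
            "attenuation_exponent": specimen.base.attenuation_exponent,
        },
        "defects": [],
    }
    for reg in specimen.defects:
        rd = {"shape": reg.shape, "center": list(reg.center),
              "label": reg.label}
        rd["size"] = (list(reg.size) if isinstance(reg.size, (tuple, list))
                      else reg.size)
        if reg.label == "knot":
            rd["impedance_multiplier"] = reg.impedance_multiplier
            rd["scatter_loss_db"] = reg.scatter_loss_db
        else:
            rd["thickness_fraction"] = reg.thickness_fraction
        d["defects"].append(rd)
    return d


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for a pipeline run."""

    pipeline: Pipeline = field(default_factory=Pipeline)
    plan: ScanPlan = field(default_factory=ScanPlan)
    specimen: Specimen | None = None
    classifier_k: float = 1.0
    snr_db: float | None = None
    base_seed: int = 0
    out_dir: str = "."


def _config_from_dict(data: dict) -> RunConfig:
    top = _take(dict(data), "config", {
        "code": _passthrough,
        "modulation": _passthrough,
        "transducer": _passthrough,
        "receiver": _passthrough,
        "channel": _passthrough,
        "scan": _passthrough,
        "classifier": _passthrough,
        "specimen": _passthrough,
        "method": _passthrough,
        "feature": _passthrough,
        "snr_db": parse_quantity,
        "base_seed": _int,
        "out_dir": _passthrough,
    })

    code = _take(top.get("code", {}), "code", {
        "family": _passthrough, "order": _int,
    })
    order = code.get("order", 3)

    mod_kw = _take(top.get("modulation", {}), "modulation", {
        "carrier_freq": parse_quantity,
        "cycles_per_chip": _int,
        "fs": parse_quantity,
        "amplitude": parse_quantity,
        "chip_period": parse_quantity,
    })
    trans_kw = _take(top.get("transducer", {}), "transducer", {
        "center_freq": parse_quantity,
        "quality_factor": parse_quantity,
        "sensitivity": parse_quantity,
    })
    recv_kw = _take(top.get("receiver", {}), "receiver", {
        "dc_block_cutoff": parse_quantity,
        "gain": parse_quantity,
        "bp_center": parse_quantity,
        "bp_bandwidth_3db": parse_quantity,
        "filter_order": _int,
    })
    chan_section = top.get("channel", {})
    chan_kw = _take(chan_section, "channel", {
        "air": _passthrough,
        "air_path_length": parse_quantity,
        "noise_sigma": parse_quantity,
        "rng_seed": _int,
    })
    if "air" in chan_kw:
        air_kw = _medium(chan_kw.pop("air"), "channel.air")
        defaults = {"impedance": AIR.impedance,
                    "sound_speed": AIR.sound_speed,
                    "attenuation_coeff": AIR.attenuation_coeff,
                    "attenuation_exponent": AIR.attenuation_exponent}
        defaults.update(air_kw)
        chan_kw["air"] = Medium(**defaults)

    scan_kw = _take(top.get("scan", {}), "scan", {
        "x0": parse_quantity, "y0": parse_quantity,
        "width": parse_quantity, "height": parse_quantity,
        "interval": parse_quantity, "serpentine": _bool,
    })
    cls_kw = _take(top.get("classifier", {}), "classifier", {
        "k": parse_quantity, "scale_low": parse_quantity,
        "scale_high": parse_quantity,
    })

    specimen = None
    if "specimen" in top:
        spec_section = top["specimen"]
        if isinstance(spec_section, str):
            specimen = load_specimen(spec_section)
        else:
            specimen = _specimen_from_dict(spec_section)

    try:
        pipeline = Pipeline(
            order=order,
            spec=ModulationSpec(**mod_kw),
            tx=TransducerModel(**trans_kw),
            rx=TransducerModel(**trans_kw),
            chain=ReceiverChain(**recv_kw),
            channel=ChannelConfig(**chan_kw),
            method=top.get("method", "golay8"),
            feature=top.get("feature", "auto"),
        )
        plan = ScanPlan(**scan_kw)
    except ValueError as exc:
        raise ValueError(str(exc)) from None

    return RunConfig(
        pipeline=pipeline,
        plan=plan,
        specimen=specimen,
        classifier_k=cls_kw.get("k", 1.0),
        snr_db=top.get("snr_db"),
        base_seed=top.get("base_seed", 0),
        out_dir=top.get("out_dir", "."),
    )


def load_config(path) -> RunConfig:
    """Load and strictly validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must hold a mapping")
    return _config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    p = cfg.pipeline
    d = {
        "code": {"family": "golay", "order": p.order},
        "modulation": {
            "carrier_freq": p.spec.carrier_freq,
            "cycles_per_chip": p.spec.cycles_per_chip,
            "fs": p.spec.fs,
            "amplitude": p.spec.amplitude,
            "chip_period": p.spec.chip_period,
        },
        "transducer": {
            "center_freq": p.tx.center_freq,
            "quality_factor": p.tx.quality_factor,
            "sensitivity": p.tx.sensitivity,
        },
        "receiver": {
            "dc_block_cutoff": p.chain.dc_block_cutoff,
            "gain": p.chain.gain,
            "bp_center": p.chain.bp_center,
            "bp_bandwidth_3db": p.chain.bp_bandwidth_3db,
            "filter_order": p.chain.filter_order,
        },
        "channel": {
            "air": {
                "impedance": p.channel.air.impedance,
                "sound_speed": p.channel.air.sound_speed,
                "attenuation_coeff": p.channel.air.attenuation_coeff,
                "attenuation_exponent": p.channel.air.attenuation_exponent,
            },
            "air_path_length": p.channel.air_path_length,
            "noise_sigma": p.channel.noise_sigma,
            "rng_seed": p.channel.rng_seed,
        },
        "scan": {
            "x0": cfg.plan.x0, "y0": cfg.plan.y0,
            "width": cfg.plan.width, "height": cfg.plan.height,
            "interval": cfg.plan.interval,
            "serpentine": cfg.plan.serpentine,
        },
        "classifier": {"k": cfg.classifier_k},
        "method": p.method,
        "feature": p.feature,
        "base_seed": cfg.base_seed,
        "out_dir": cfg.out_dir,
    }
    if cfg.snr_db is not None:
        d["snr_db"] = cfg.snr_db
    if cfg.specimen is not None:
        d["specimen"] = specimen_to_dict(cfg.specimen)
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back out (JSON canonical; .yaml/.yml for YAML)."""
    path = Path(path)
    data = config_to_dict(cfg)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=True)
        else:
            json.dump(data, fh, indent=2, sort_keys=True)
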