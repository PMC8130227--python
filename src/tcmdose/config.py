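"""Protocol configuration: scanner constants keyed by model and kVp."""

from __future__ import annotations

from importlib import resources

import yaml

from .dosimetry import ScannerModel
from .tcm import ATCMParams

__all__ = ["load_protocols", "get_protocol", "scanner_model", "atcm_params"]


def load_protocols(path=None) -> dict:
    """All protocol blocks, from a YAML file or the packaged defaults."""
    if path is None:
        text = resources.files("tcmdose.data").joinpath("protocols.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def get_protocol(scanner: str = "Force", kvp: int = 120, path=None) -> dict:
    key = f"{scanner.lower()}_{int(kvp)}"
    protocols = load_protocols(path)
    if key not in protocols:
        raise KeyError(f"no protocol {key!r}; available: {sorted(protocols)}")
    return protocols[key]


def scanner_model(protocol: dict) -> ScannerModel:
    return ScannerModel(
        name=protocol["scanner"],
        kvp=float(protocol["kvp"]),
        ctdi_per_mas=float(protocol["ctdi_per_mas"]),
        collimation=float(protocol["collimation_cm"]),
        pitch=float(protocol["pitch"]),
        rotation_time=float(protocol["rotation_time_s"]),
    )


def atcm_params(protocol: dict, **overrides) -> ATCMParams:
    kwargs = dict(
        qrm=float(protocol["qrm"]),
        rotation_time=float(protocol["rotation_time_s"]),
        pitch=float(protocol["pitch"]),
        collimation=float(protocol["collimation_cm"]),
    )
    kwargs.update(overrides)
    return ATCMParams(**kwargs)
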