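"""Parameter bundles as structured text config files (YAML)."""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path

import yaml

from salif.lif import LIFParams, NoiseParams, WTAParams

__all__ = ["load_params", "save_params", "default_params"]

Bundle = tuple[LIFParams, WTAParams, NoiseParams]


def _from_dict(doc: dict) -> Bundle:
    return (LIFParams(**doc.get("lif", {})),
            WTAParams(**doc.get("wta", {})),
            NoiseParams(**doc.get("noise", {})))


def load_params(path: str | Path) -> Bundle:
    """Read (LIFParams, WTAParams, NoiseParams) from a YAML file."""
    with open(path) as fh:
        return _from_dict(yaml.safe_load(fh))


def save_params(bundle: Bundle, path: str | Path) -> None:
    lif, wta, noise = bundle
    doc = {"lif": asdict(lif), "wta": asdict(wta), "noise": asdict(noise)}
    doc = {k: {f: float(v) for f, v in d.items()} for k, d in doc.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_params() -> Bundle:
    """The canonical defaults shipped with the package."""
    text = resources.files("salif").joinpath("configs/defaults.yaml").read_text()
    return _from_dict(yaml.safe_load(text))
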