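"""YAML (de)serialization of detector configuration and boundary parameters.

The shipped defaults (``data/default_params.yaml``) encode the traditional
two-branch windows and the published best three-branch parameters for both
fiducial kinds, plus the sliding-window configuration.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path

import yaml

from .core import BoundaryParams, SWAConfig

__all__ = ["load_params", "save_params", "load_config", "default_params_text"]


def _params_to_dict(p: BoundaryParams) -> dict:
    d = asdict(p)
    d["breakpoints"] = list(p.breakpoints)
    d["lower_intercepts"] = list(p.lower_intercepts)
    d["upper_intercepts"] = list(p.upper_intercepts)
    return d


def _params_from_dict(d: dict) -> BoundaryParams:
    d = dict(d)
    for key in ("breakpoints", "lower_intercepts", "upper_intercepts"):
        d[key] = tuple(d[key])
    return BoundaryParams(**d)


def save_params(path: str | Path, onset: BoundaryParams | None = None,
                offset: BoundaryParams | None = None,
                cfg: SWAConfig | None = None) -> None:
    doc: dict = {}
    if onset is not None:
        doc["onset"] = _params_to_dict(onset)
    if offset is not None:
        doc["offset"] = _params_to_dict(offset)
    if cfg is not None:
        doc["swa"] = asdict(cfg)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: str | Path) -> tuple[BoundaryParams | None, BoundaryParams | None, SWAConfig]:
    """Returns (onset params, offset params, SWA config) from a YAML file."""
    doc = yaml.safe_load(Path(path).read_text())
    known = {"onset", "offset", "swa"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}; expected {sorted(known)}")
    onset = _params_from_dict(doc["onset"]) if "onset" in doc else None
    offset = _params_from_dict(doc["offset"]) if "offset" in doc else None
    cfg = SWAConfig(**doc.get("swa", {}))
    return onset, offset, cfg


def default_params_text() -> str:
    return resources.files("swadelin").joinpath("data/default_params.yaml").read_text()


def load_config(path: str | Path | None = None):
    """Load a params file, falling back to the shipped defaults."""
    if path is not None:
        return load_params(path)
    doc = yaml.safe_load(default_params_text())
    return (_params_from_dict(doc["onset"]), _params_from_dict(doc["offset"]),
            SWAConfig(**doc.get("swa", {})))
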