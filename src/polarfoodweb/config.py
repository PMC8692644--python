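"""Master YAML configuration loading.

A config file holds optional blocks that overlay the shipped defaults:

``geometry:`` DomainGeometry fields; ``presence:`` guild → 12 monthly
fractions; ``fleet:`` offal_fraction and a gears list of Gear fields;
``parameters:`` dotted-path overrides onto the default ParameterSet
(e.g. ``consumers.fish_p.u_max: 0.01``), which also covers the trophic
topology (``consumers.<name>.prey.<pool>: weight``) and the ``ice``
optics/biology blocks (``ice_bio.u_max``, ``optics.k_ice``, ...).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from polarfoodweb.errors import FormatError
from polarfoodweb.fleet import FleetConfig, Gear, default_fleet
from polarfoodweb.geometry import DomainGeometry
from polarfoodweb.params import (
    ParameterSet,
    PresenceSchedule,
    default_parameters,
    default_presence,
)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        path = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, path))
        else:
            out[path] = v
    return out


def load_config(path) -> dict:
    """Load a YAML config into model objects (defaults where unspecified).

    Returns a dict with keys ``params``, ``geometry``, ``presence``,
    ``fleet``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")

    geometry = DomainGeometry(**raw.get("geometry", {}))

    params = default_parameters()
    for p, v in _flatten(raw.get("parameters", {})).items():
        params.set(p, v)

    if "presence" in raw:
        presence = PresenceSchedule(fractions={
            g: list(v) for g, v in raw["presence"].items()})
    else:
        presence = default_presence()

    if "fleet" in raw:
        fl = raw["fleet"]
        gears = [Gear(**g) for g in fl.get("gears", [])]
        if not gears:
            raise FormatError("fleet block must list at least one gear")
        fleet = FleetConfig(gears=gears,
                            offal_fraction=fl.get("offal_fraction", 0.05))
    else:
        fleet = default_fleet()

    return {"params": params, "geometry": geometry,
            "presence": presence, "fleet": fleet}
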