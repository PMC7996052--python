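"""Configuration files, RSML export, CSV ledgers, run manifests.

The configuration is human-editable YAML mirroring the parameter
dataclasses (nested sections per root class, soil, simulation).  Root
architectures are exported as RSML (Root System Markup Language), the
community XML standard for root-system interchange, with the root class
carried as a per-root property; child roots are nested inside their
parents.  A run manifest (JSON) records the config snapshot, seeds and
output files so any stochastic stage can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import RootSystem
from .params import (ConfigError, HairParams, Params, RootClassParams,
                     SimulationParams, SoilP, TruncLogNorm, TruncNorm)

__all__ = [
    "params_to_dict", "params_from_dict", "dump_config", "load_config",
    "params_to_csv", "export_rsml", "write_manifest",
]


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def params_to_dict(params: Params) -> dict:
    """Plain nested dict (YAML/JSON-safe) of a parameter set."""
    d = dataclasses.asdict(params)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return clean(d)


def params_from_dict(d: dict) -> Params:
    """Rebuild a :class:`Params` from :func:`params_to_dict` output."""
    try:
        classes = {}
        for cid, c in d["classes"].items():
            c = dict(c)
            c["hair"] = HairParams(**c["hair"])
            c["ibd_by_child"] = {k: TruncNorm(**v)
                                 for k, v in c["ibd_by_child"].items()}
            c["rate_multiplier"] = TruncLogNorm(**c["rate_multiplier"])
            classes[cid] = RootClassParams(**c)
        sim = dict(d["sim"])
        sim["tiller_days"] = tuple(sim["tiller_days"])
        return Params(classes=classes, soil=SoilP(**d["soil"]),
                      sim=SimulationParams(**sim))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def dump_config(params: Params, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params),
                                         sort_keys=True))


def load_config(path: str | Path) -> Params:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


def params_to_csv(params: Params, path: str | Path) -> None:
    """Flat CSV data dictionary: one (parameter path, value) row per leaf."""
    rows: list[tuple[str, object]] = []

    def walk(prefix: str, x) -> None:
        if isinstance(x, dict):
            for k, v in x.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(x, (list, tuple)):
            for i, v in enumerate(x):
                walk(f"{prefix}[{i}]", v)
        else:
            rows.append((prefix, x))

    walk("", params_to_dict(params))
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RSML
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6f}"


def export_rsml(system: RootSystem, path: str | Path,
                at: float | None = None, label: str = "DJ123") -> None:
    """Write the architecture as RSML with per-root class labels.

    Main axes become top-level roots of the single plant; laterals are
    nested inside their parent root.  Each root carries ``class_id``,
    ``birth`` (day) and ``multiplier`` properties; polylines are in cm with
    z positive downward.
    """
    at = system.clock if at is None else at
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = f"oryzaroot {__version__}"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id="1", label=label)

    elements: dict[int, ET.Element] = {}

    def add_root(parent_el: ET.Element, axis_id: int, class_id: str,
                 birth: float, multiplier: float,
                 points: np.ndarray) -> ET.Element:
        el = ET.SubElement(parent_el, "root", ID=str(axis_id),
                           label=class_id)
        geom = ET.SubElement(el, "geometry")
        poly = ET.SubElement(geom, "polyline")
        for p in points:
            ET.SubElement(poly, "point", x=_fmt(p[0]), y=_fmt(p[1]),
                          z=_fmt(p[2]))
        props = ET.SubElement(el, "properties")
        for name, value in (("class_id", class_id), ("birth", _fmt(birth)),
                            ("multiplier", _fmt(multiplier))):
            ET.SubElement(props, "property", name=name, value=str(value))
        elements[axis_id] = el
        return el

    for a in system.main_axes:
        pts = np.asarray(a.points)
        times = np.asarray(a.times)
        keep = times <= at + 1e-12
        if keep.sum() < 1:
            continue
        add_root(plant, a.axis_id, a.class_id, a.birth, a.multiplier,
                 pts[keep])

    # laterals, parents first (ltype before stype; stype may sit on ltype)
    for c in ("ltype", "stype"):
        arr = system.lateral_arrays(c)
        lengths = system.lateral_lengths(c, at)
        for i in range(len(lengths)):
            if arr["birth"][i] > at:
                continue
            parent_el = elements.get(int(arr["parent_axis"][i]), plant)
            tip = arr["origin"][i] + arr["heading"][i] * lengths[i]
            add_root(parent_el, int(arr["axis_id"][i]), c,
                     float(arr["birth"][i]), float(arr["multiplier"][i]),
                     np.vstack([arr["origin"][i], tip]))

    ET.indent(rsml)
    tree = ET.ElementTree(rsml)
    tree.write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, params: Params, seed: int,
                   stage: str, outputs: list[str],
                   extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "seed": int(seed),
        "code_version": __version__,
        "outputs": outputs,
        "config": params_to_dict(params),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
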