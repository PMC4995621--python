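"""Configuration reading and snapshot / time-series serialization.

Configuration is a JSON document with two top-level blocks, ``params``
(keys are the model's parameter names, e.g. ``OxygenSecretionAmount``)
and ``scenario`` (world dims, placement mode, horizon, flags).

Snapshots serialize as JSON-lines (one object per entity, plus one block
per molecular field and the vessel topology) and, for viewer
compatibility, as an XML element stream with the same content model.
All writers are byte-deterministic: keys are emitted in a fixed order
and floats are formatted to 6 significant digits; full precision is kept
in memory only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .params import Params, ParamsError

__all__ = [
    "Snapshot",
    "read_config",
    "write_config",
    "write_snapshot",
    "read_snapshot",
    "write_field_csv",
    "write_timeseries",
    "read_timeseries",
    "write_events",
]

_SCENARIO_KEYS = {
    "name", "dims", "placement", "horizon", "proliferative",
    "angiogenesis", "initial_tumor",
}


def _fmt(x: float) -> str:
    """Fixed 6-significant-digit float formatting used by every writer."""
    return format(float(x), ".6g")


@dataclass
class Snapshot:
    """Full spatial dump of one simulation instant."""

    tick: int
    dims: tuple[int, int, int]
    #: list of (cell id, kind, state, x, y, z)
    cells: list[tuple]
    #: species name -> 3D array of amounts
    fields: dict[str, np.ndarray]
    #: vessel id -> {"members": [...], "parent": id|None, "joined_to": id|None}
    vessels: dict[int, dict]

    def canonical(self) -> dict:
        """Representation used for cross-format equality: floats at export precision."""
        return {
            "tick": int(self.tick),
            "dims": [int(d) for d in self.dims],
            "cells": sorted(
                [int(c[0]), str(c[1]), str(c[2]), int(c[3]), int(c[4]), int(c[5])]
                for c in self.cells
            ),
            "fields": {
                s: [_fmt(v) for v in np.asarray(a, dtype=float).ravel()]
                for s, a in sorted(self.fields.items())
            },
            "vessels": {
                str(k): {
                    "members": [int(m) for m in v["members"]],
                    "parent": v.get("parent"),
                    "joined_to": v.get("joined_to"),
                }
                for k, v in sorted(self.vessels.items(), key=lambda kv: int(kv[0]))
            },
        }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path) -> tuple[Params, "ScenarioSpec"]:
    """Read a JSON configuration into (Params, ScenarioSpec).

    Unknown keys are an error (listing the valid ones); parameter
    invariants are validated on construction.
    """
    from .simulation import ScenarioSpec

    doc = json.loads(Path(path).read_text())
    unknown_top = sorted(set(doc) - {"params", "scenario"})
    if unknown_top:
        raise ParamsError(f"unknown top-level keys {unknown_top}; valid: ['params', 'scenario']")
    params = Params.from_config(doc.get("params", {}))
    sc_doc = dict(doc.get("scenario", {}))
    unknown = sorted(set(sc_doc) - _SCENARIO_KEYS)
    if unknown:
        raise ParamsError(f"unknown scenario keys {unknown}; valid keys: {sorted(_SCENARIO_KEYS)}")
    if "dims" in sc_doc:
        sc_doc["dims"] = tuple(int(d) for d in sc_doc["dims"])
    scenario = ScenarioSpec(params=params, **sc_doc)
    return params, scenario


def write_config(path, params: Params, scenario=None) -> None:
    doc: dict = {"params": params.to_config()}
    if scenario is not None:
        doc["scenario"] = {
            "name": scenario.name,
            "dims": list(scenario.dims),
            "placement": scenario.placement,
            "horizon": scenario.horizon,
            "proliferative": scenario.proliferative,
            "angiogenesis": scenario.angiogenesis,
            "initial_tumor": scenario.initial_tumor,
        }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def write_snapshot(snapshot: Snapshot, path, format: str = "json") -> None:
    """Write a snapshot as JSON-lines (default) or as an XML stream."""
    if format == "json":
        _write_snapshot_json(snapshot, path)
    elif format == "xml":
        _write_snapshot_xml(snapshot, path)
    else:
        raise ValueError(f"unknown snapshot format {format!r} (expected 'json' or 'xml')")


def _write_snapshot_json(snapshot: Snapshot, path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({
            "type": "meta", "tick": int(snapshot.tick),
            "dims": [int(d) for d in snapshot.dims],
        }) + "\n")
        for c in sorted(snapshot.cells, key=lambda c: int(c[0])):
            fh.write(json.dumps({
                "type": "cell", "id": int(c[0]), "kind": c[1], "state": c[2],
                "x": int(c[3]), "y": int(c[4]), "z": int(c[5]),
            }) + "\n")
        for species in sorted(snapshot.fields):
            arr = np.asarray(snapshot.fields[species], dtype=float)
            fh.write(json.dumps({
                "type": "field", "species": species,
                "data": [_fmt(v) for v in arr.ravel()],
            }) + "\n")
        for vid, v in sorted(snapshot.vessels.items(), key=lambda kv: int(kv[0])):
            fh.write(json.dumps({
                "type": "vessel", "id": int(vid),
                "members": [int(m) for m in v["members"]],
                "parent": v.get("parent"), "joined_to": v.get("joined_to"),
            }) + "\n")


def _write_snapshot_xml(snapshot: Snapshot, path) -> None:
    root = ET.Element("snapshot", tick=str(int(snapshot.tick)),
                      dims=",".join(str(int(d)) for d in snapshot.dims))
    for c in sorted(snapshot.cells, key=lambda c: int(c[0])):
        ET.SubElement(root, "cell", id=str(int(c[0])), kind=str(c[1]), state=str(c[2]),
                      x=str(int(c[3])), y=str(int(c[4])), z=str(int(c[5])))
    for species in sorted(snapshot.fields):
        arr = np.asarray(snapshot.fields[species], dtype=float)
        el = ET.SubElement(root, "field", species=species)
        el.text = " ".join(_fmt(v) for v in arr.ravel())
    for vid, v in sorted(snapshot.vessels.items(), key=lambda kv: int(kv[0])):
        el = ET.SubElement(root, "vessel", id=str(int(vid)),
                           members=",".join(str(int(m)) for m in v["members"]))
        if v.get("parent") is not None:
            el.set("parent", str(int(v["parent"])))
        if v.get("joined_to") is not None:
            el.set("joined_to", str(int(v["joined_to"])))
    ET.ElementTree(root).write(path, encoding="unicode")


def read_snapshot(path, format: str = "json") -> Snapshot:
    if format == "json":
        return _read_snapshot_json(path)
    if format == "xml":
        return _read_snapshot_xml(path)
    raise ValueError(f"unknown snapshot format {format!r} (expected 'json' or 'xml')")


def _read_snapshot_json(path) -> Snapshot:
    tick, dims = 0, (0, 0, 0)
    cells, fields, vessels = [], {}, {}
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            t = obj["type"]
            if t == "meta":
                tick, dims = obj["tick"], tuple(obj["dims"])
            elif t == "cell":
                cells.append((obj["id"], obj["kind"], obj["state"],
                              obj["x"], obj["y"], obj["z"]))
            elif t == "field":
                fields[obj["species"]] = np.array(
                    [float(v) for v in obj["data"]], dtype=float).reshape(dims)
            elif t == "vessel":
                vessels[obj["id"]] = {"members": obj["members"],
                                      "parent": obj.get("parent"),
                                      "joined_to": obj.get("joined_to")}
    return Snapshot(tick=tick, dims=dims, cells=cells, fields=fields, vessels=vessels)


def _read_snapshot_xml(path) -> Snapshot:
    root = ET.parse(path).getroot()
    dims = tuple(int(d) for d in root.get("dims").split(","))
    cells, fields, vessels = [], {}, {}
    for el in root:
        if el.tag == "cell":
            cells.append((int(el.get("id")), el.get("kind"), el.get("state"),
                          int(el.get("x")), int(el.get("y")), int(el.get("z"))))
        elif el.tag == "field":
            data = [float(v) for v in (el.text or "").split()]
            fields[el.get("species")] = np.array(data, dtype=float).reshape(dims)
        elif el.tag == "vessel":
            members = [int(m) for m in el.get("members").split(",")] if el.get("members") else []
            parent = el.get("parent")
            joined = el.get("joined_to")
            vessels[int(el.get("id"))] = {
                "members": members,
                "parent": int(parent) if parent is not None else None,
                "joined_to": int(joined) if joined is not None else None,
            }
    return Snapshot(tick=int(root.get("tick")), dims=dims, cells=cells,
                    fields=fields, vessels=vessels)


def write_field_csv(snapshot: Snapshot, path) -> None:
    """Flat per-site CSV (x,y,z,species,amount) of every field."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "species", "amount"])
        for species in sorted(snapshot.fields):
            arr = np.asarray(snapshot.fields[species], dtype=float)
            for (x, y, z), v in np.ndenumerate(arr):
                w.writerow([x, y, z, species, _fmt(v)])


# ---------------------------------------------------------------------------
# time series and events
# ---------------------------------------------------------------------------

def write_timeseries(series: pd.DataFrame, path) -> None:
    """One CSV row per tick with the fixed metric header."""
    out = series.copy()
    for col in ("vegf_mass", "oxygen_mass"):
        if col in out:
            out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)
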