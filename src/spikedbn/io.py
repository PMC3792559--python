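"""File formats: event CSV streams, model containers, flat config files.

Events are serialized as CSV with header ``t_us,layer,unit`` and integer
microsecond timestamps.  Models are saved as a zipped archive of named
numeric arrays plus a JSON manifest; round trips are bitwise stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np

from .dbn import ConnectionSpec, DbnModel, LayerSpec
from .events import EventStream
from .neuron import LifParams
from .rbm import RbmParameters

__all__ = ["read_events", "write_events", "save_model", "load_model",
           "read_config", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def write_events(stream: EventStream, path, force: bool = False) -> None:
    """Write an event stream as ``t_us,layer,unit`` CSV."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    with open(path, "w") as fh:
        fh.write("t_us,layer,unit\n")
        for t, l, u in zip(stream.t_us, stream.layer, stream.unit):
            fh.write(f"{t},{l},{u}\n")


def read_events(path) -> EventStream:
    """Read an event CSV, validating column counts, types and ordering."""
    times, layers, units = [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "t_us,layer,unit":
            raise ValueError(f"{path}: unexpected header {header!r}")
        prev = -1
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, "
                                 f"got {len(parts)}")
            try:
                t = int(parts[0])
                u = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if t < prev:
                raise ValueError(f"{path}:{lineno}: timestamps not "
                                 f"non-decreasing ({t} after {prev})")
            prev = t
            times.append(t)
            layers.append(parts[1])
            units.append(u)
    return EventStream(np.array(times, np.int64), np.array(units, np.int64),
                       np.array(layers, dtype=object))


def save_model(model: DbnModel, path, force: bool = False) -> None:
    """Save a model as named arrays + JSON manifest (.npz archive)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    manifest = {
        "version": FORMAT_VERSION,
        "layers": [{"name": l.name, "size": l.size, "role": l.role}
                   for l in model.layers],
        "connections": [{"source": c.source, "target": c.target,
                         "direction": c.direction, "enabled": c.enabled}
                        for c in model.connections],
        "neuron": {k: getattr(model.neuron, k)
                   for k in ("v_rest", "v_reset", "v_th", "tau_m", "t_ref",
                             "tau_syn")},
        "activation": model.activation,
        "rate_mass": model.rate_mass,
        "n_rbms": len(model.rbms),
        "metadata": model.metadata,
    }
    arrays: Dict[str, np.ndarray] = {}
    for i, c in enumerate(model.connections):
        arrays[f"conn_{i}"] = c.weights
    for name, b in model.biases.items():
        arrays[f"bias_{name}"] = b
    for i, r in enumerate(model.rbms):
        arrays[f"rbm{i}_w"] = r.w
        arrays[f"rbm{i}_bv"] = r.b_v
        arrays[f"rbm{i}_bh"] = r.b_h
    np.savez(path, manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> DbnModel:
    """Load a model container; rejects files from a newer format version."""
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest["version"] > FORMAT_VERSION:
            raise ValueError(
                f"model file version {manifest['version']} is newer than "
                f"supported version {FORMAT_VERSION}")
        layers = [LayerSpec(**l) for l in manifest["layers"]]
        connections = [
            ConnectionSpec(c["source"], c["target"], data[f"conn_{i}"],
                           c["direction"], c["enabled"])
            for i, c in enumerate(manifest["connections"])]
        biases = {l.name: data[f"bias_{l.name}"] for l in layers
                  if f"bias_{l.name}" in data}
        rbms = [RbmParameters(data[f"rbm{i}_w"], data[f"rbm{i}_bv"],
                              data[f"rbm{i}_bh"])
                for i in range(manifest["n_rbms"])]
    return DbnModel(layers=layers, connections=connections,
                    neuron=LifParams(**manifest["neuron"]), biases=biases,
                    rbms=rbms, activation=manifest["activation"],
                    rate_mass=manifest["rate_mass"],
                    metadata=manifest.get("metadata", {}))


def read_config(path) -> Dict[str, str]:
    """Flat dotted-key configuration file: ``neuron.tau_m = 0.8`` lines."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
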