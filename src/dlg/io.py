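"""Serialization and run manifests.

Circuits, stimulation protocols and population specifications round-trip
through YAML or JSON documents (chosen by file suffix); protocols also export
their stimulation-event table as CSV.  Every CLI run writes exactly one
:class:`RunManifest` next to its outputs recording the configuration hash,
seed and package version, so any artifact can be traced to the exact inputs
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import CircuitSpec, CircuitValidationError
from .events import StimulationProtocol
from .hh import HHNeuronParams, PopulationSpec

__all__ = [
    "load_circuit",
    "save_circuit",
    "load_protocol",
    "save_protocol",
    "load_population",
    "save_population",
    "protocol_frame",
    "RunManifest",
    "config_hash",
]


def _load_document(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        raise ValueError(f"unknown config suffix {path.suffix!r} (use .yaml/.yml/.json)")
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: top-level document must be a mapping")
    return doc


def _dump_document(doc: dict, path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        raise ValueError(f"unknown config suffix {path.suffix!r} (use .yaml/.yml/.json)")


def load_circuit(path: str | Path) -> CircuitSpec:
    """Load and validate a circuit; schema errors name the offending field."""
    path = Path(path)
    doc = _load_document(path)
    try:
        circuit = CircuitSpec.from_dict(doc)
        circuit.validate()
    except CircuitValidationError as exc:
        raise CircuitValidationError(f"{path}: {exc}") from exc
    return circuit


def save_circuit(circuit: CircuitSpec, path: str | Path) -> Path:
    path = Path(path)
    _dump_document(circuit.to_dict(), path)
    return path


def save_protocol(protocol: StimulationProtocol, path: str | Path) -> Path:
    doc = dataclasses.asdict(protocol)
    if doc["times"] is not None:
        doc["times"] = {k: list(v) for k, v in doc["times"].items()}
    doc["moderation"] = {k: list(v) for k, v in doc["moderation"].items()}
    path = Path(path)
    _dump_document(doc, path)
    return path


def load_protocol(path: str | Path) -> StimulationProtocol:
    path = Path(path)
    doc = _load_document(path)
    try:
        times = doc.get("times")
        return StimulationProtocol(
            count=doc["count"],
            rate_hz=doc.get("rate_hz", 10.0),
            probabilities=dict(doc.get("probabilities", {})),
            moderation={k: tuple(v) for k, v in doc.get("moderation", {}).items()},
            times=None if times is None else {k: tuple(v) for k, v in times.items()},
            seed=doc.get("seed", 0),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed protocol document: {exc}") from exc


def save_population(spec: PopulationSpec, path: str | Path) -> Path:
    doc = dataclasses.asdict(spec)
    path = Path(path)
    _dump_document(doc, path)
    return path


def load_population(path: str | Path) -> PopulationSpec:
    path = Path(path)
    doc = _load_document(path)
    try:
        neuron = HHNeuronParams(**doc.pop("neuron", {}))
        return PopulationSpec(neuron=neuron, **doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed population document: {exc}") from exc


def protocol_frame(protocol: StimulationProtocol, inputs: list[str]) -> pd.DataFrame:
    """Nominal stimulation-event table: one row per (round, input).

    With the common clock, round r is delivered at ``r * period`` ms; explicit
    per-input times override the clock.  Delivery probabilities/moderation are
    annotated, not sampled — the table is the protocol, not one realization.
    """
    rows = []
    if protocol.times is not None:
        for name, ts in protocol.times.items():
            for i, t in enumerate(ts):
                rows.append({"round": i, "input": name, "time_ms": t, "probability": 1.0})
    else:
        for r in range(protocol.count):
            t = r * protocol.period
            for name in inputs:
                rows.append(
                    {"round": r, "input": name, "time_ms": t,
                     "probability": protocol.probability(name, r)}
                )
    return pd.DataFrame(rows, columns=["round", "input", "time_ms", "probability"])


def config_hash(obj) -> str:
    """Stable SHA-256 over a dataclass/dict configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        doc = dataclasses.asdict(obj)
    elif hasattr(obj, "to_dict"):
        doc = obj.to_dict()
    else:
        doc = obj
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config_hash: str
    seed: int | None
    version: str
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def start(cls, command: str, config_obj, seed: int | None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config_hash=config_hash(config_obj) if config_obj is not None else "",
            seed=seed,
            version=__version__,
            started=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        )

    def finish(self, outputs: list[str | Path]) -> "RunManifest":
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        self.outputs = [str(o) for o in outputs]
        return self

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
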