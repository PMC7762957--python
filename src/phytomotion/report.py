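"""Run configuration and report serialization.

Reports embed the full run configuration and SHA-256 checksums of the
input files so any printed number can be traced back to the exact inputs
and parameters that produced it.  Serialization is deterministic (sorted
keys, fixed float precision), so identical runs give byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

SCHEMA_VERSION = "1.0"
TOOL_VERSION = "0.1.0"

#: decimal places by quantity, applied when a payload key ends with the
#: suffix: angles to 0.1 deg, distances to 0.01 A, closure to 0.1 point
_PRECISION_SUFFIXES = {
    "angle": 1,
    "closure": 1,
    "distance": 2,
    "rmsd": 2,
    "displacement": 2,
    "pitch": 2,
    "occupancy": 2,
}
_DEFAULT_FLOAT_PRECISION = 4


@dataclass
class RunConfig:
    command: str
    parameters: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    verbosity: int = 0


@dataclass
class AnalysisReport:
    config: RunConfig
    payload: dict
    provenance: dict = field(default_factory=dict)
    tool_version: str = TOOL_VERSION
    schema_version: str = SCHEMA_VERSION


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _precision_for(key: str | None) -> int:
    if key:
        k = key.lower()
        for suffix, prec in _PRECISION_SUFFIXES.items():
            if k.endswith(suffix):
                return prec
    return _DEFAULT_FLOAT_PRECISION


def _normalize(obj, key: str | None = None):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _normalize(asdict(obj), key)
    if isinstance(obj, dict):
        return {str(k): _normalize(v, str(k)) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(items, key=str)
        return [_normalize(v, key) for v in items]
    if isinstance(obj, np.ndarray):
        return [_normalize(float(v), key) for v in obj.ravel().tolist()]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), _precision_for(key))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_to_dict(report: AnalysisReport) -> dict:
    return _normalize(
        {
            "tool_version": report.tool_version,
            "schema_version": report.schema_version,
            "config": asdict(report.config),
            "provenance": report.provenance,
            "payload": report.payload,
        }
    )


def write_report(report: AnalysisReport, path: str | Path) -> None:
    data = report_to_dict(report)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_tsv(rows: list[dict], path: str | Path) -> None:
    """Plain deterministic TSV with a header from the first row's keys."""
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(str(_normalize(row.get(c), c)) for c in cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")
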