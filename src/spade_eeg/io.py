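"""Plain-text readers and writers for records, labels, and matrices.

Records travel as delimited text, channels × samples with a header row of
channel names; labels as one integer per line; distance matrices as dense
delimited text with a one-line ``#`` header naming kind and symmetrization.
Configurations are YAML. Every pipeline run can write a manifest with a
config hash and seeds for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureMatrix
from .geometry import DistanceMatrix
from .pipeline import MicrostateSequence
from .segment import EEGRecord

__all__ = [
    "read_record", "write_record",
    "read_labels", "write_labels",
    "read_distance_matrix", "write_distance_matrix",
    "write_features",
    "write_runs", "load_config", "dump_config", "write_manifest",
]


def read_record(path: str | Path, srate_hz: float, delimiter: str = "\t") -> EEGRecord:
    """Read a channels × samples delimited text file with a channel-name header."""
    path = Path(path)
    with path.open() as fh:
        names = fh.readline().strip().split(delimiter)
    data = np.loadtxt(path, skiprows=1, delimiter=delimiter, ndmin=2)
    return EEGRecord(data=data, srate_hz=srate_hz, channel_names=names)


def write_record(path: str | Path, record: EEGRecord, delimiter: str = "\t") -> None:
    header = delimiter.join(record.channel_names)
    np.savetxt(path, record.data, delimiter=delimiter, header=header, comments="")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64, ndmin=1)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def write_distance_matrix(path: str | Path, D: DistanceMatrix,
                          delimiter: str = "\t") -> None:
    header = f"kind={D.kind} symmetrized={D.symmetrized}"
    np.savetxt(path, D.values, delimiter=delimiter, header=header)


def read_distance_matrix(path: str | Path, delimiter: str = "\t") -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=") for item in header.split())
    values = np.loadtxt(path, skiprows=1, delimiter=delimiter, ndmin=2)
    return DistanceMatrix(values=values, kind=fields["kind"],
                          symmetrized=fields["symmetrized"] == "True")


def write_features(path: str | Path, F: FeatureMatrix,
                   delimiter: str = "\t") -> None:
    """Feature matrix as delimited text with a block-annotated column header."""
    cols = []
    for name, sl in F.block_slices.items():
        cols += [f"{name}_{k}" for k in range(sl.stop - sl.start)]
    np.savetxt(path, F.values, delimiter=delimiter,
               header=delimiter.join(cols), comments="")


def write_runs(path: str | Path, seq: MicrostateSequence) -> None:
    """Runs table: state, start_ms, end_ms (tab-separated, half-open intervals)."""
    with Path(path).open("w") as fh:
        fh.write("state\tstart_ms\tend_ms\n")
        for state, lo, hi in seq.runs:
            fh.write(f"{state}\t{lo:.6g}\t{hi:.6g}\n")


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh) or {}


def dump_config(path: str | Path, config) -> None:
    obj = asdict(config) if is_dataclass(config) else dict(config)
    with Path(path).open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_manifest(path: str | Path, config, seeds: dict[str, int]) -> None:
    """Provenance record: config hash, seeds, package version."""
    from . import __version__
    obj = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": obj,
        "seeds": {k: int(v) for k, v in seeds.items()},
        "version": __version__,
    }
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
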