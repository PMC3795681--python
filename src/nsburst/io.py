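"""File formats: rasters (CSV/HDF5), configurations (YAML), manifests (JSON).

A raster is stored as a two-column CSV ``time_s,unit_id`` with a JSON
metadata sidecar (``<name>.meta.json``) carrying the unit count,
duration, provenance (simulated | synthetic | experimental) and seed.
An HDF5 twin layout (``/spikes/time``, ``/spikes/unit``, ``/meta``) is
available for large recordings.  Times are stored in seconds with
microsecond resolution, which covers the 25 µs integration step.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import NetworkConfig, SpikeRecord, config_from_dict, config_to_dict
from .params import ParameterError

logger = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_raster(record: SpikeRecord, path) -> None:
    """Write a SpikeRecord as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": np.round(record.times, 6),
                       "unit_id": record.units})
    df.to_csv(path, index=False)
    meta = dict(record.meta)
    meta.setdefault("n_units", record.n_units)
    meta.setdefault("duration", record.duration)
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def read_raster(path) -> SpikeRecord:
    """Read a CSV raster (with optional sidecar); sorts unsorted input."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValueError(f"cannot parse raster {path}: {exc}") from exc
    for col in ("time_s", "unit_id"):
        if col not in df.columns:
            raise ValueError(f"raster {path} lacks required column '{col}'")
    bad = df[df.time_s.isna() | df.unit_id.isna()]
    if len(bad):
        raise ValueError(f"raster {path}: malformed row at line "
                         f"{int(bad.index[0]) + 2}")
    times = df.time_s.to_numpy(dtype=float)
    units = df.unit_id.to_numpy(dtype=np.int64)
    if times.size and np.any(np.diff(times) < 0):
        logger.info("raster %s unsorted; sorting on load", path)
        order = np.argsort(times, kind="stable")
        times, units = times[order], units[order]
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    n_units = int(meta.get("n_units", units.max() + 1 if units.size else 1))
    duration = float(meta.get("duration",
                              times[-1] if times.size else 0.0))
    return SpikeRecord(times=times, units=units, n_units=n_units,
                       duration=duration, meta=meta)


def write_raster_hdf5(record: SpikeRecord, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("time", data=record.times)
        g.create_dataset("unit", data=record.units)
        meta = dict(record.meta)
        meta.setdefault("n_units", record.n_units)
        meta.setdefault("duration", record.duration)
        f.create_dataset("meta", data=json.dumps(meta, default=str))


def read_raster_hdf5(path) -> SpikeRecord:
    import h5py

    with h5py.File(path, "r") as f:
        times = f["spikes/time"][:]
        units = f["spikes/unit"][:].astype(np.int64)
        meta = json.loads(f["meta"][()])
    return SpikeRecord(times=times, units=units,
                       n_units=int(meta["n_units"]),
                       duration=float(meta["duration"]), meta=meta)


def load_config(path) -> NetworkConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    if not isinstance(d, dict):
        raise ParameterError(f"config {path} must be a mapping")
    return config_from_dict(d)


def save_config(config: NetworkConfig, path) -> None:
    """Save a configuration with every parameter explicit (round-trips)."""
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(config), f, sort_keys=True)


def write_manifest(path, *, command: str, inputs: dict, outputs: dict,
                   seed) -> None:
    """One-file-per-run provenance manifest."""
    from . import __version__

    manifest = {"command": command, "inputs": inputs, "outputs": outputs,
                "seed": seed, "nsburst_version": __version__}
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
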