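"""Format adapters: TIFF movies, localization tables, contours, traces,
configuration and provenance."""
from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__

TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "bg_photons",
                 "wx_nm", "wy_nm", "precision_nm"]


def write_movie(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a localization table as CSV or HDF5 (by extension)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with pd.HDFStore(path, mode="w") as store:
            store.put("localizations", table, format="table")
    else:
        table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with pd.HDFStore(path, mode="r") as store:
            return store.get("localizations")
    return pd.read_csv(path)


def read_trace(path: str | Path) -> pd.DataFrame:
    """Two-column (t_s, intensity) CSV, with or without a header line."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace file needs two columns (t_s, intensity)")
    try:
        float(df.columns[0])
    except ValueError:
        pass
    else:  # headerless file: first row was data
        df = pd.read_csv(path, header=None)
    df = df.iloc[:, :2]
    df.columns = ["t_s", "intensity"]
    return df.astype(float)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def provenance(config: dict, seed: int | None) -> dict:
    """Machine-readable provenance block echoed into every run's outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": seed,
            "cryopalm_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version()}


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
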