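"""CSV interchange for recordings and feature tables.

A recording is stored as rows = channels, columns = samples, with a header
row of channel names and a JSON metadata sidecar (``<stem>.meta.json``)
carrying the sampling rate and any config echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, feature_dictionary
from .preprocess import Recording


class IOFormatError(ValueError):
    pass


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_recording(rec: Recording, path, metadata: dict | None = None) -> None:
    path = Path(path)
    header = ",".join(rec.channel_names)
    lines = [header]
    for row in rec.data:
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    meta = {"fs": rec.fs}
    meta.update(metadata or {})
    _meta_path(path).write_text(json.dumps(meta, indent=2))


def read_recording(path) -> Recording:
    path = Path(path)
    mpath = _meta_path(path)
    if not mpath.exists():
        raise IOFormatError(f"missing metadata sidecar {mpath.name} (needs fs)")
    meta = json.loads(mpath.read_text())
    if "fs" not in meta:
        raise IOFormatError(f"metadata {mpath.name} lacks 'fs'")
    lines = path.read_text().strip().splitlines()
    names = lines[0].split(",")
    rows = []
    width = None
    for i, line in enumerate(lines[1:], start=2):
        vals = line.split(",")
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise IOFormatError(f"ragged CSV: row {i} has {len(vals)} values, expected {width}")
        rows.append([float(v) for v in vals])
    # recording rows are channels; header names them
    data = np.array(rows)
    if data.shape[0] != len(names):
        raise IOFormatError(
            f"{data.shape[0]} channel rows but {len(names)} header names"
        )
    return Recording(data=data, fs=float(meta["fs"]), channel_names=names)


def write_feature_table(table: pd.DataFrame, path, with_dictionary: bool = True) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    if with_dictionary:
        feature_dictionary().to_csv(path.with_name(path.stem + ".dictionary.csv"),
                                    index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    required = set(FEATURE_COLUMNS) | {"label"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise IOFormatError(f"feature table missing columns: {missing}")
    return table
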