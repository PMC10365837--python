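"""Shared I/O: TIFF stacks with sidecar metadata, tabular results, configs.

Movies are interchanged as multi-page grayscale TIFF with a JSON sidecar
(`<stem>.json`) carrying ``pixel_size_um`` and ``frame_interval_s``; tables
are CSV with a deterministic column order and 9-significant-digit floats;
configs are JSON. Every result file is accompanied by a provenance record
(config hash + package version) so outputs are traceable to the exact
parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_METADATA = {"pixel_size_um": 0.1, "frame_interval_s": 0.2}

__all__ = ["read_stack", "write_stack", "write_results", "read_config", "config_hash", "write_provenance"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page grayscale TIFF and its sidecar metadata.

    Returns ``(frames x height x width array, metadata)``. RGB input is
    rejected; a missing sidecar falls back to the defaults (0.1 µm/px,
    200 ms) with a logged warning.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape} (RGB rejected)")
    meta = dict(DEFAULT_METADATA)
    sc = _sidecar(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    else:
        logger.warning("%s: no metadata sidecar; using defaults %s", path, DEFAULT_METADATA)
    return arr, meta


def write_stack(path: str | Path, movie: np.ndarray, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(movie), photometric="minisblack")
    meta = dict(DEFAULT_METADATA)
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_results(records, path: str | Path, fmt: str = "csv") -> None:
    """Write tabular results deterministically (sorted columns, %.9g floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df = df.reindex(sorted(df.columns), axis=1)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.9g")
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", double_precision=9, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a JSON object")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def write_provenance(out_dir: str | Path, config: dict) -> Path:
    """Drop a provenance record (config + hash + version) next to outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = {"config": config, "config_hash": config_hash(config), "axonquant_version": __version__}
    p = out / "provenance.json"
    p.write_text(json.dumps(rec, indent=1, sort_keys=True, default=str))
    return p
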