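"""Disk formats: multi-page TIFF stacks, masks, CSV tables, JSON, YAML config.

Frame stacks are stored as 16-bit unsigned multi-page TIFF (counts clipped to
the uint16 range) with a JSON sidecar holding timing, trial annotations and
session metadata; masks as single-page 8-bit TIFF; tables as CSV; ground
truth and reports as JSON; configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .ratio import FrameStack


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: Path | str, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def read_json(path: Path | str):
    return json.loads(Path(path).read_text())


def write_frame_stack(path: Path | str, stack: FrameStack) -> None:
    """Multi-page 16-bit TIFF plus a JSON sidecar (same stem, .json)."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames)
    sidecar = {
        "frame_ms": stack.frame_ms,
        "trial_index": stack.trial_index,
        "prestim_ref_index": stack.prestim_ref_index,
        "trial_start_s": stack.trial_start_s,
        "meta": stack.meta,
    }
    write_json(path.with_suffix(".json"), sidecar)


def read_frame_stack(path: Path | str) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    side = read_json(path.with_suffix(".json"))
    return FrameStack(
        frames=frames,
        frame_ms=side["frame_ms"],
        trial_index=np.asarray(side["trial_index"], dtype=int),
        prestim_ref_index=np.asarray(side["prestim_ref_index"], dtype=int),
        trial_start_s=(
            np.asarray(side["trial_start_s"]) if side.get("trial_start_s") is not None else None
        ),
        meta=side.get("meta", {}),
    )


def write_mask(path: Path | str, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool)).astype(np.uint8) * 255)


def read_mask(path: Path | str) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_rgb(path: Path | str, raster: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(raster, dtype=np.uint8))


def read_rgb(path: Path | str) -> np.ndarray:
    return tifffile.imread(Path(path))


def load_config(path: Path | str | None, defaults: dict | None = None) -> dict:
    """YAML config merged over defaults (shallow)."""
    cfg = dict(defaults or {})
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a YAML mapping")
        cfg.update(loaded)
    return cfg


def save_config(path: Path | str, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(cfg), sort_keys=True))


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
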