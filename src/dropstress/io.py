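"""Shared readers/writers and run configuration.

Tabular data travels as CSV with unit-suffixed headers, images as TIFF,
ground truth and resolved configurations as JSON sidecars. Every analysis
run serializes its fully-resolved parameters next to its outputs so results
stay traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageFrame

__all__ = [
    "RunConfig",
    "read_contour_csv",
    "write_contour_csv",
    "read_series_csv",
    "read_image",
    "write_image",
    "write_sidecar",
]


_KNOWN_KEYS = {
    "units", "paths", "seed", "pixel_size", "threshold", "ring_width",
    "gamma", "E", "radius", "delta_rho", "log_level", "out_dir",
}


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one analysis run.

    Unknown keys are rejected at construction so a misspelled parameter can
    never fall back to a silent default.
    """

    params: dict[str, Any]

    def __post_init__(self) -> None:
        unknown = set(self.params) - _KNOWN_KEYS
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known keys are "
                f"{sorted(_KNOWN_KEYS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError("config file must contain a mapping")
        return cls(dict(data))

    @property
    def digest(self) -> str:
        """Stable hash of the resolved config, for output traceability."""
        blob = json.dumps(self.params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        payload = {"config": self.params, "config_hash": self.digest}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Read an (N, 2) contour from a CSV with x,y header columns (pixels)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: contour CSV must have 'x' and 'y' columns")
    return df[[cols["x"], cols["y"]]].to_numpy(dtype=float)


def write_contour_csv(path: str | Path, contour: np.ndarray) -> None:
    pd.DataFrame(np.asarray(contour, dtype=float), columns=["x", "y"]).to_csv(
        path, index=False
    )


def read_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time, tension) series; expects time_s and gamma_mN_per_m
    (or unsuffixed time/gamma, taken as s and mN/m) columns."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = cols.get("time_s") or cols.get("time")
    gcol = cols.get("gamma_mn_per_m") or cols.get("gamma")
    if tcol is None or gcol is None:
        raise ValueError(f"{path}: need time_s and gamma_mN_per_m columns")
    t = df[tcol].to_numpy(dtype=float)
    g = df[gcol].to_numpy(dtype=float) * 1e-3  # mN/m -> N/m
    return t, g


def read_image(path: str | Path, pixel_size: float) -> list[ImageFrame]:
    """Read a single- or multi-frame TIFF into ImageFrames."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D frame or a stack, got shape {arr.shape}")
    return [
        ImageFrame(frame.astype(float), pixel_size, time_index=i)
        for i, frame in enumerate(arr)
    ]


def write_image(path: str | Path, frames: "ImageFrame | list[ImageFrame]") -> None:
    if isinstance(frames, ImageFrame):
        data = frames.pixels
    else:
        data = np.stack([f.pixels for f in frames])
    tifffile.imwrite(path, data.astype(np.float32))


def write_sidecar(path: str | Path, payload: Mapping[str, Any]) -> None:
    """JSON truth/parameter sidecar; numpy arrays serialized as lists."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    Path(path).write_text(json.dumps(dict(payload), indent=2, default=default))
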