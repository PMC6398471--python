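"""Kymograph container and disk round-trip.

A kymograph is a space-time image: rows are camera frames, columns are
positions along a microtubule. Physical calibration (frame interval in
seconds, pixel size in micrometres) travels with the array so downstream
rate estimates come out in physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Kymograph", "write_kymograph", "read_kymograph"]


@dataclass
class Kymograph:
    """Space-time intensity image with calibration metadata.

    Attributes
    ----------
    data : ndarray, shape (n_frames, n_pixels)
        Intensity values; frame ``f`` integrates the time window
        ``[f*frame_interval, (f+1)*frame_interval)``.
    frame_interval : float
        Seconds per frame.
    pixel_size : float
        Micrometres per pixel. Columns run minus-end to plus-end unless
        ``metadata['polarity']`` says otherwise.
    metadata : dict
        Free-form extras (simulation ground truth, channel info, polarity).
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (frames x pixels)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def length(self) -> float:
        """Field of view along the microtubule axis, in micrometres."""
        return self.n_pixels * self.pixel_size

    def times(self) -> np.ndarray:
        """Frame mid-exposure times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval

    def positions(self) -> np.ndarray:
        """Pixel-centre positions in micrometres."""
        return (np.arange(self.n_pixels) + 0.5) * self.pixel_size


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph to disk with a JSON metadata sidecar.

    ``.tif``/``.tiff`` suffixes write single-channel TIFF; ``.csv`` writes a
    plain frames-by-pixels matrix. Either way ``<stem>.json`` records
    ``frame_interval_s``, ``pixel_size_um`` and any extra metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.data.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, kymo.data, delimiter=",")
    else:
        raise ValueError(f"unsupported kymograph format: {path.suffix}")
    meta = {
        "frame_interval_s": kymo.frame_interval,
        "pixel_size_um": kymo.pixel_size,
        **_jsonable(kymo.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_kymograph(path: str | Path) -> Kymograph:
    """Read a kymograph written by :func:`write_kymograph`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".csv":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported kymograph format: {path.suffix}")
    meta = json.loads(path.with_suffix(".json").read_text())
    frame_interval = meta.pop("frame_interval_s")
    pixel_size = meta.pop("pixel_size_um")
    return Kymograph(np.asarray(data, dtype=float), frame_interval, pixel_size, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
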