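"""Reading and writing image stacks, label masks and result tables.

Scenes are stored as multi-dimensional TIFFs with axes normalised to
``(frame, channel, row, col)``; metadata (channel names, pixel size, frame
interval) rides along in the TIFF description and falls back to the
analysis config when absent.  Result tables are plain CSV and round-trip
losslessly at full float precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig, ConfigError

logger = logging.getLogger(__name__)

#: A label mask is a 2-D integer array; 0 = background, k > 0 = object k.
LabelMask = np.ndarray


@dataclass
class Scene:
    """A multi-channel, optionally multi-frame image with physical metadata.

    ``pixels`` is indexed ``[frame][channel][row][col]`` and must be
    non-negative.  ``channel_names`` must include ``"nuclei"`` and
    ``"aggregate"``; an ``"mrna"`` channel is optional.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_interval_s: Optional[float] = None
    bit_depth: int = 16
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("Scene.pixels must be 4-D (frame, channel, row, col)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 2:
            raise ValueError("Scene needs at least 1 frame and 2 channels")
        if self.pixels.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.pixels.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        for required in ("nuclei", "aggregate"):
            if required not in self.channel_names:
                raise ValueError(f"channel_names must include {required!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if np.any(self.pixels < 0):
            raise ValueError("Scene.pixels must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str, frame: int = 0) -> np.ndarray:
        """Return one channel of one frame as a float64 image."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"scene has no channel {name!r}") from None
        return np.asarray(self.pixels[frame, idx], dtype=np.float64)

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def write_scene(scene: Scene, path: str | Path) -> Path:
    """Write a Scene as a TIFF with embedded metadata (axes TCYX)."""
    path = Path(path)
    data = np.ascontiguousarray(scene.pixels, dtype=np.float32)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "TCYX",
            "channel_names": list(scene.channel_names),
            "pixel_size_um": float(scene.pixel_size_um),
            "frame_interval_s": (
                None if scene.frame_interval_s is None else float(scene.frame_interval_s)
            ),
            "bit_depth": int(scene.bit_depth),
        },
    )
    return path


_AXIS_ALIASES = {"T": "T", "Z": "T", "Q": "T", "I": "T", "C": "C", "S": "C", "Y": "Y", "X": "X"}


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Transpose any TIFF axis dialect into (frame, channel, row, col)."""
    axes = "".join(_AXIS_ALIASES.get(a, a) for a in axes.upper())
    if sorted(set(axes)) != sorted(axes):
        # e.g. TZCYX: merge duplicate frame-like axes into one
        order = []
        seen: dict[str, int] = {}
        for a in axes:
            seen[a] = seen.get(a, 0) + 1
            order.append(a)
        if axes.count("T") > 1:
            t_dims = [i for i, a in enumerate(axes) if a == "T"]
            keep = [i for i in range(data.ndim) if i not in t_dims]
            data = data.reshape(
                (int(np.prod([data.shape[i] for i in t_dims])),)
                + tuple(data.shape[i] for i in keep)
            )
            axes = "T" + "".join(axes[i] for i in keep)
        else:
            raise ValueError(f"cannot resolve TIFF axes {axes!r}")
    for a in axes:
        if a not in "TCYX":
            raise ValueError(f"unsupported TIFF axis {a!r}")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"TIFF axes {axes!r} lack row/col dimensions")
    for missing in "TC":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    perm = [axes.index(a) for a in "TCYX"]
    return np.transpose(data, perm)


def read_scene(path: str | Path, config: AnalysisConfig) -> Scene:
    """Read a TIFF/OME-TIFF into a Scene, filling metadata from ``config``.

    Frame and channel order are preserved exactly as stored in the file.
    Missing pixel size falls back to ``config.pixel_size_um`` with a logged
    warning; the channel count must match the config channel map.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta: Mapping = {}
            if tif.shaped_metadata:
                meta = tif.shaped_metadata[0]
            elif tif.imagej_metadata:
                meta = tif.imagej_metadata
    except (OSError, ValueError, IndexError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    data = _normalize_axes(np.asarray(data), axes)

    # Plain 3-D stacks are ambiguous (channels vs frames): when the file
    # declares no channel axis but the stack depth matches the config
    # channel map, interpret the stack as channels.
    if (
        not meta.get("channel_names")
        and data.shape[1] == 1
        and data.shape[0] == len(config.channels)
    ):
        data = np.transpose(data, (1, 0, 2, 3))

    channel_names = list(meta.get("channel_names") or [])
    if not channel_names:
        # Build names from the config channel map, index -> name.
        by_index = sorted(config.channels.items(), key=lambda kv: kv[1])
        channel_names = [name for name, _ in by_index][: data.shape[1]]
    if len(channel_names) != data.shape[1]:
        raise ConfigError(
            f"{path}: file has {data.shape[1]} channels but config names "
            f"{len(channel_names)}: {channel_names}"
        )
    for required in ("nuclei", "aggregate"):
        if required not in channel_names:
            raise ConfigError(
                f"{path}: channel map {channel_names} lacks required {required!r}"
            )

    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        pixel_size = config.pixel_size_um
        logger.warning(
            "%s: no pixel size in file metadata; using config value %g um",
            path,
            pixel_size,
        )
    frame_interval = meta.get("frame_interval_s")
    if frame_interval is None:
        frame_interval = config.frame_interval_s
    bit_depth = int(meta.get("bit_depth", 16))

    return Scene(
        pixels=np.asarray(data, dtype=np.float32),
        channel_names=channel_names,
        pixel_size_um=float(pixel_size),
        frame_interval_s=None if frame_interval is None else float(frame_interval),
        bit_depth=bit_depth,
        name=path.stem,
    )


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as a 16-bit single-channel TIFF."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask exceeds 16-bit range")
    tifffile.imwrite(path, mask.astype(np.uint16))
    return path


def read_label_mask(path: str | Path) -> LabelMask:
    return np.asarray(tifffile.imread(path), dtype=np.int32)


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write one CSV per result table; never overwrite within one call.

    Floats are written with 17 significant digits, so re-reading reproduces
    the values exactly.  Name collisions get a numeric suffix.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    used: set[Path] = set()
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        k = 1
        while path in used or path.exists():
            path = out_dir / f"{name}_{k}.csv"
            k += 1
        table.to_csv(path, index=False, float_format="%.17g")
        used.add(path)
        written[name] = path
    return written


def read_results(paths: Mapping[str, Path]) -> dict[str, pd.DataFrame]:
    return {
        name: pd.read_csv(path, float_precision="round_trip")
        for name, path in paths.items()
    }
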