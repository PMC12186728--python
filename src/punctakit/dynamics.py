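"""Time-lapse puncta-mobility statistic from a three-frame overlay.

Three frames of the aggregate channel are binarized with the same
constant-threshold puncta recipe; within each nucleus the "white" area is
the triple intersection of the three masks and the "colored" area is their
union.  Their ratio is a Jaccard-style overlap statistic in [0, 1]: 1 for
immobile puncta (identical frames), 0 for fully displaced puncta.  Higher
ratio means lower puncta dynamics.  The alternative reading of "colored"
as union-minus-intersection is available via ``colored="nonwhite"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SegmentationParams
from .io import Scene
from .segment import NucleusROI, puncta_mask

logger = logging.getLogger(__name__)


@dataclass
class DynamicsResult:
    nucleus_id: int
    frame_indices: tuple[int, int, int]
    white_area_px: int
    union_area_px: int
    white_to_colored_ratio: Optional[float]


def _times_to_frames(scene: Scene, times_s: Sequence[float]) -> tuple[int, int, int]:
    if scene.n_frames < 3:
        raise ValueError("overlay dynamics needs a scene with >= 3 frames")
    if scene.frame_interval_s is None:
        raise ValueError("scene has no frame interval; cannot map times to frames")
    if len(times_s) != 3:
        raise ValueError("exactly three time points are required")
    idx = []
    for t in times_s:
        i = int(round(t / scene.frame_interval_s))
        i = min(max(i, 0), scene.n_frames - 1)
        idx.append(i)
    if len(set(idx)) < 3:
        raise ValueError(
            f"times {tuple(times_s)} map to non-distinct frames {idx} "
            f"at interval {scene.frame_interval_s} s"
        )
    for t, i in zip(times_s, idx):
        if abs(i * scene.frame_interval_s - t) > 1e-9:
            logger.info("time %g s rounded to frame %d (%g s)", t, i, i * scene.frame_interval_s)
    return tuple(idx)  # type: ignore[return-value]


def overlay_dynamics(
    scene: Scene,
    rois: list[NucleusROI],
    params: SegmentationParams,
    times_s: Sequence[float] = (0.0, 130.0, 260.0),
    threshold: str = "low",
    colored: str = "union",
) -> list[DynamicsResult]:
    """Per-nucleus white/colored overlap ratio across three frames."""
    if colored not in ("union", "nonwhite"):
        raise ValueError("colored must be 'union' or 'nonwhite'")
    thr = params.threshold(threshold)
    frames = _times_to_frames(scene, times_s)
    ps = scene.pixel_size_um

    masks = [
        puncta_mask(scene.channel("aggregate", frame=i), params, ps, thr) for i in frames
    ]
    white_all = masks[0] & masks[1] & masks[2]
    union_all = masks[0] | masks[1] | masks[2]

    results: list[DynamicsResult] = []
    for roi in rois:
        white = int((white_all & roi.mask).sum())
        union = int((union_all & roi.mask).sum())
        denom = union if colored == "union" else union - white
        ratio = None if denom == 0 else white / denom
        if union == 0:
            logger.info("nucleus %d: empty mask union across frames", roi.nucleus_id)
        results.append(
            DynamicsResult(
                nucleus_id=roi.nucleus_id,
                frame_indices=frames,
                white_area_px=white,
                union_area_px=union,
                white_to_colored_ratio=ratio,
            )
        )
    return results


def dynamics_to_frame(results: Sequence[DynamicsResult]) -> pd.DataFrame:
    rows = [
        {
            "nucleus_id": d.nucleus_id,
            "frame_0": d.frame_indices[0],
            "frame_1": d.frame_indices[1],
            "frame_2": d.frame_indices[2],
            "white_area_px": d.white_area_px,
            "union_area_px": d.union_area_px,
            "white_to_colored_ratio": (
                np.nan if d.white_to_colored_ratio is None else d.white_to_colored_ratio
            ),
        }
        for d in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "frame_0",
            "frame_1",
            "frame_2",
            "white_area_px",
            "union_area_px",
            "white_to_colored_ratio",
        ],
    )


def export_overlay_png(
    scene: Scene,
    params: SegmentationParams,
    path: str | Path,
    times_s: Sequence[float] = (0.0, 130.0, 260.0),
    threshold: str = "low",
) -> Path:
    """Write an RGB overlay (frame masks in red/green/blue, overlap white)."""
    import imageio.v3 as iio

    thr = params.threshold(threshold)
    frames = _times_to_frames(scene, times_s)
    ps = scene.pixel_size_um
    rgb = np.zeros(scene.shape + (3,), dtype=np.uint8)
    for ch, i in enumerate(frames):
        mask = puncta_mask(scene.channel("aggregate", frame=i), params, ps, thr)
        rgb[..., ch] = mask.astype(np.uint8) * 255
    path = Path(path)
    iio.imwrite(path, rgb)
    return path
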