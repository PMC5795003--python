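"""Reading and writing the pipeline's file formats.

Tracks travel as tidy CSV (one row per track x frame), image stacks and ROI
label masks as TIFF (16-bit for raw images, 32-bit float for corrected
ones), and configuration echoes as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .correction import ImageStack
from .errors import DataError
from .trajectory import CellTrack

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "time_min",
    "area_px",
    "intensity_au",
    "is_division_frame",
]


def tracks_to_frame(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    """Tidy per-frame table of a track set."""
    rows = []
    for track in tracks:
        division = np.zeros(track.n_frames, dtype=int)
        division[track.division_frames] = 1
        rows.append(
            pd.DataFrame(
                {
                    "track_id": track.track_id,
                    "frame": np.arange(track.n_frames),
                    "time_min": track.time_min,
                    "area_px": track.area,
                    "intensity_au": track.intensity,
                    "is_division_frame": division,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_tracks_csv(tracks: Sequence[CellTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def tracks_from_frame(df: pd.DataFrame) -> list[CellTrack]:
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for track_id, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        division_frames = group.loc[group["is_division_frame"] > 0, "frame"].to_numpy()
        tracks.append(
            CellTrack(
                track_id=int(track_id),
                time_min=group["time_min"].to_numpy(),
                area=group["area_px"].to_numpy(),
                intensity=group["intensity_au"].to_numpy(),
                division_frames=division_frames.astype(int),
            )
        )
    return tracks


def read_tracks_csv(path: str | Path) -> list[CellTrack]:
    return tracks_from_frame(pd.read_csv(path))


def write_stack_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as TIFF: uint16 for raw roles, float32 for corrected."""
    if stack.role == "corrected":
        data = stack.frames.astype(np.float32)
    else:
        data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_stack_tiff(path: str | Path, role: str = "experimental") -> ImageStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data.astype(float), role=role, position_id=Path(path).stem)


def write_masks_tiff(masks: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(masks, dtype=np.int32))


def read_masks_tiff(path: str | Path) -> np.ndarray:
    masks = tifffile.imread(str(path))
    if masks.ndim == 2:
        masks = masks[None]
    return masks.astype(np.int32)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
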