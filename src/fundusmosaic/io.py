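"""Readers, writers, and configuration.

Formats:

* frames — a directory of PNG/JPEG stills (lexicographic order) or a video
  file decodable by imageio;
* detections CSV — header ``source_id,frame_index,x_min,y_min,x_max,y_max,
  score,method``; empty geometry cells encode "no detection";
* annotations — corner-pair CSV (``image_id,x_min,y_min,x_max,y_max``) or
  YOLO-txt (``class cx cy w h`` normalized to [0, 1] by image dims, one
  ``.txt`` file per image);
* homography CSV — ``image_id`` plus 9 row-major matrix entries.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import BBox, Frame, Homography

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_frames",
    "write_frames",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
    "read_homographies",
    "write_homographies",
    "frame_id",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_DETECTION_HEADER = [
    "source_id", "frame_index", "x_min", "y_min", "x_max", "y_max", "score", "method",
]


@dataclass
class PipelineConfig:
    """Flat configuration for every pipeline stage, with defaults.

    Unknown keys in a config file are rejected on load.
    """

    # detection
    min_radius_frac: float = 0.10
    max_radius_frac: float = 0.45
    accumulator_threshold: float = 0.25
    min_center_distance_frac: float = 0.10
    blur_kernel: int = 9
    # crop
    canvas_side: int = 400
    # mosaic
    ratio: float = 0.8
    ransac_threshold: float = 3.0
    min_inliers: int = 10
    # synthetic motion bounds
    max_shift: float = 30.0
    max_rot_deg: float = 5.0
    illum_jitter: float = 0.0
    # normalization
    normalize_per_channel: bool = False
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat YAML config; unknown keys raise ``ValueError``."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value document")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys are {sorted(known)}"
        )
    return PipelineConfig(**data)


def frame_id(source_id: str, index: int) -> str:
    """Canonical image id for a frame: ``<source>_<index>``."""
    return f"{source_id}_{index}"


def read_frames(path: str | Path) -> list[Frame]:
    """Load frames from a directory of stills or a video file.

    Directory entries are taken in lexicographic order; frame indices are
    assigned 0, 1, 2, ... either way.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    frames: list[Frame] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"directory {path} contains no image files")
        for i, f in enumerate(files):
            pixels = np.asarray(iio.imread(f))
            if pixels.ndim == 2:
                pixels = np.stack([pixels] * 3, axis=-1)
            frames.append(Frame(pixels[:, :, :3], source_id=f.stem, index=i))
        return frames
    try:
        for i, pixels in enumerate(iio.imiter(path)):
            pixels = np.asarray(pixels)
            if pixels.ndim == 2:
                pixels = np.stack([pixels] * 3, axis=-1)
            frames.append(Frame(pixels[:, :, :3], source_id=path.stem, index=i))
    except Exception as exc:
        raise IOError(f"cannot decode {path}: {exc}") from exc
    if not frames:
        raise IOError(f"no frames decoded from {path}")
    return frames


def write_frames(frames: list[Frame], out_dir: str | Path) -> list[Path]:
    """Write frames as ``<source>_<index>.png`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = out_dir / f"{frame_id(f.source_id, f.index)}.png"
        iio.imwrite(p, f.pixels)
        paths.append(p)
    return paths


def write_detections(rows: list[dict], path: str | Path) -> None:
    """Write the detection CSV; ``bbox`` None leaves geometry cells empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DETECTION_HEADER)
        for row in rows:
            b: BBox | None = row.get("bbox")
            geom = list(b.as_tuple()) if b is not None else ["", "", "", ""]
            score = row.get("score")
            writer.writerow(
                [row["source_id"], row["frame_index"], *geom,
                 "" if score is None else f"{score:.6f}", row.get("method", "")]
            )


def read_detections(path: str | Path) -> list[dict]:
    """Read the detection CSV back into dicts with a ``bbox`` (or None)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _DETECTION_HEADER:
            raise ValueError(
                f"{path}: expected header {_DETECTION_HEADER}, got {reader.fieldnames}"
            )
        for lineno, rec in enumerate(reader, start=2):
            geom = [rec["x_min"], rec["y_min"], rec["x_max"], rec["y_max"]]
            if all(g == "" for g in geom):
                bbox = None
            elif any(g == "" for g in geom):
                raise ValueError(f"{path}:{lineno}: partially empty geometry")
            else:
                bbox = BBox(*(int(g) for g in geom))
            rows.append(
                {
                    "source_id": rec["source_id"],
                    "frame_index": int(rec["frame_index"]),
                    "bbox": bbox,
                    "score": float(rec["score"]) if rec["score"] else None,
                    "method": rec["method"],
                }
            )
    return rows


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    img_w: int | None = None,
    img_h: int | None = None,
) -> dict[str, BBox]:
    """Read ground-truth boxes in the CSV or YOLO-txt dialect.

    The CSV dialect is read directly. For YOLO (``class cx cy w h``,
    normalized), ``path`` may be a single ``.txt`` file or a directory of
    them (image id = file stem); ``img_w``/``img_h`` are required to convert
    to pixel boxes.
    """
    path = Path(path)
    if dialect == "csv":
        out: dict[str, BBox] = {}
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or row[0] in ("image_id", ""):
                    continue
                if len(row) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
                try:
                    out[row[0]] = BBox(*(int(v) for v in row[1:]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return out
    if dialect == "yolo":
        if img_w is None or img_h is None:
            raise ValueError("YOLO dialect requires img_w and img_h")
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        out = {}
        for f in files:
            with open(f) as fh:
                for lineno, line in enumerate(fh, start=1):
                    parts = line.split()
                    if not parts:
                        continue
                    if len(parts) != 5:
                        raise ValueError(
                            f"{f}:{lineno}: expected 'class cx cy w h', got {line!r}"
                        )
                    cx, cy, w, h = (float(v) for v in parts[1:])
                    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                        if not (0.0 <= v <= 1.0):
                            raise ValueError(
                                f"{f}:{lineno}: normalized {name}={v} outside [0, 1]"
                            )
                    out[f.stem] = BBox(
                        _round_half_up((cx - w / 2) * img_w),
                        _round_half_up((cy - h / 2) * img_h),
                        _round_half_up((cx + w / 2) * img_w),
                        _round_half_up((cy + h / 2) * img_h),
                    )
        return out
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotations(
    boxes: dict[str, BBox],
    path: str | Path,
    dialect: str = "csv",
    img_w: int | None = None,
    img_h: int | None = None,
) -> None:
    """Write boxes in the CSV dialect (one file) or YOLO-txt (a directory)."""
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "x_min", "y_min", "x_max", "y_max"])
            for image_id, b in sorted(boxes.items()):
                writer.writerow([image_id, *b.as_tuple()])
        return
    if dialect == "yolo":
        if img_w is None or img_h is None:
            raise ValueError("YOLO dialect requires img_w and img_h")
        path.mkdir(parents=True, exist_ok=True)
        for image_id, b in boxes.items():
            cx = (b.x_min + b.x_max) / 2 / img_w
            cy = (b.y_min + b.y_max) / 2 / img_h
            w = b.width / img_w
            h = b.height / img_h
            (path / f"{image_id}.txt").write_text(
                f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n"
            )
        return
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_homographies(
    entries: list[tuple[str, Homography | None]], path: str | Path
) -> None:
    """Homography CSV: image id + 9 row-major entries (blank when skipped)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id"] + [f"h{i}{j}" for i in range(3) for j in range(3)])
        for image_id, h in entries:
            if h is None:
                writer.writerow([image_id] + [""] * 9)
            else:
                writer.writerow([image_id] + [f"{v:.10g}" for v in h.h.ravel()])


def read_homographies(path: str | Path) -> list[tuple[str, Homography | None]]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if all(v == "" for v in row[1:]):
                out.append((row[0], None))
            else:
                out.append(
                    (row[0], Homography(np.array([float(v) for v in row[1:]]).reshape(3, 3)))
                )
    return out
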