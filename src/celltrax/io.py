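"""Readers and writers: TIFF stacks, CTC result/GT directories, CSV tables.

The on-disk tracking interchange format follows the Cell Tracking
Challenge convention: per-frame 16-bit labeled TIFFs named ``mask%03d.tif``
(results) or ``man_track%03d.tif`` (ground truth), with a 4-column text
table ``res_track.txt`` / ``man_track.txt`` whose rows are

    label  begin_frame  end_frame  parent_label

(0 = no parent).  A track's label is stable across frames; a closed gap
simply has no pixels for that label in the skipped frames, and reading
reconstructs the gap from pixel presence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionParams
from .linking import LinkParams
from .metrics import AogmWeights
from .model import FrameStack, LabeledMasks, Lineage, Roi, Track, masks_from_rois
from .seqtrack import SeqTrackParams
from .synthetic import SynthConfig


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF, or a directory of per-frame TIFFs in name order."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF files in {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise ValueError("RGB TIFF is not supported; provide grayscale frames")
    if arr.ndim not in (3, 4):
        raise ValueError(f"unsupported TIFF geometry {arr.shape}")
    return FrameStack(arr)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    # explicit photometric: a (T, H, W) stack with small T must not be
    # mistaken for RGB component planes
    tifffile.imwrite(Path(path), stack.pixels, photometric="minisblack")


# ---------------------------------------------------------------------------
# CTC directories
# ---------------------------------------------------------------------------


def _frame_name(prefix: str, t: int, pad: int) -> str:
    return f"{prefix}{t:0{pad}d}.tif"


def masks_for_lineage(
    lineage: Lineage, rois: Sequence[Sequence[Roi]], shape: tuple[int, int]
) -> LabeledMasks:
    """Rasterize tracked ROIs with their track id as the pixel label."""
    labels = {
        node: tid for tid, tr in lineage.tracks.items() for node in tr.nodes
    }
    tracked = [
        [r for r in frame if (t, r.roi_id) in labels]
        for t, frame in enumerate(rois)
    ]
    return masks_from_rois(
        tracked, shape, labels={k: v for k, v in labels.items()}
    )


def write_ctc(
    lineage: Lineage,
    masks: LabeledMasks,
    directory: str | Path,
    ground_truth: bool = False,
    pad: int = 3,
) -> None:
    """Write a CTC-layout directory; mask labels must equal track ids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    max_label = max((int(f.max()) for f in masks.frames), default=0)
    if max_label > 65535:
        raise ValueError(f"label {max_label} exceeds the 16-bit mask range")
    prefix = "man_track" if ground_truth else "mask"
    table = "man_track.txt" if ground_truth else "res_track.txt"
    for t, frame in enumerate(masks.frames):
        tifffile.imwrite(
            directory / _frame_name(prefix, t, pad), frame.astype(np.uint16)
        )
    rows = []
    for tid in sorted(lineage.tracks):
        tr = lineage.tracks[tid]
        rows.append(
            f"{tid} {tr.start_frame} {tr.end_frame} {tr.parent_id or 0}"
        )
    (directory / table).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_ctc(directory: str | Path) -> tuple[Lineage, LabeledMasks]:
    """Read a CTC-layout directory (result or ground truth)."""
    directory = Path(directory)
    table = directory / "res_track.txt"
    prefix = "mask"
    if not table.exists():
        table = directory / "man_track.txt"
        prefix = "man_track"
    if not table.exists():
        raise ValueError(f"no res_track.txt or man_track.txt in {directory}")
    files = sorted(directory.glob(f"{prefix}*.tif"))
    frames = [tifffile.imread(f).astype(np.int32) for f in files]
    masks = LabeledMasks(frames)
    lineage = Lineage()
    declared: dict[int, tuple[int, int, int]] = {}
    for line in table.read_text().splitlines():
        if not line.strip():
            continue
        label, begin, end, parent = (int(x) for x in line.split())
        declared[label] = (begin, end, parent)
    for label, (begin, end, parent) in declared.items():
        if parent != 0 and parent not in declared:
            raise ValueError(f"track {label} references unknown parent {parent}")
        nodes = [
            (t, label)
            for t in range(begin, end + 1)
            if t < len(frames) and np.any(frames[t] == label)
        ]
        if not nodes:
            raise ValueError(f"track {label} has no pixels in frames {begin}..{end}")
        lineage.add(Track(track_id=label, nodes=nodes, parent_id=parent or None))
    return lineage, masks


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_ROI_BASE_COLUMNS = [
    "frame", "track_id", "roi_id", "centroid_row", "centroid_col",
    "bbox_row_min", "bbox_col_min", "bbox_row_max", "bbox_col_max",
]


def _sig6(x: float) -> float:
    # six decimal places (not significant digits): coordinates in the
    # hundreds still round-trip to 1e-4 px
    return float(f"{x:.6f}")


def write_tables(
    lineage: Lineage, rois: Sequence[Sequence[Roi]], directory: str | Path
) -> tuple[Path, Path]:
    """Write rois.csv and tracks.csv; floats at 6 significant digits."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_to_track = {
        node: tid for tid, tr in lineage.tracks.items() for node in tr.nodes
    }
    feature_names = sorted(
        {name for frame in rois for r in frame for name in r.features}
    )
    roi_rows = []
    for t, frame in enumerate(rois):
        for r in sorted(frame, key=lambda x: x.roi_id):
            row: dict = {
                "frame": t,
                "track_id": node_to_track.get((t, r.roi_id), 0),
                "roi_id": r.roi_id,
                "centroid_row": _sig6(r.centroid[0]),
                "centroid_col": _sig6(r.centroid[1]),
                "bbox_row_min": r.bbox[0],
                "bbox_col_min": r.bbox[1],
                "bbox_row_max": r.bbox[2],
                "bbox_col_max": r.bbox[3],
            }
            for name in feature_names:
                val = r.features.get(name)
                row[name] = _sig6(val) if val is not None else ""
            roi_rows.append(row)
    roi_path = directory / "rois.csv"
    pd.DataFrame(roi_rows, columns=_ROI_BASE_COLUMNS + feature_names).to_csv(
        roi_path, index=False
    )
    track_rows = [
        {
            "track_id": tid,
            "parent_id": tr.parent_id or 0,
            "begin": tr.start_frame,
            "end": tr.end_frame,
            "length": len(tr.nodes),
        }
        for tid, tr in sorted(lineage.tracks.items())
    ]
    track_path = directory / "tracks.csv"
    pd.DataFrame(
        track_rows, columns=["track_id", "parent_id", "begin", "end", "length"]
    ).to_csv(track_path, index=False)
    return roi_path, track_path


def read_rois_csv(path: str | Path) -> list[list[Roi]]:
    """Re-import a rois.csv written by ``write_tables`` (geometry only)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    n_frames = int(df["frame"].max()) + 1
    out: list[list[Roi]] = [[] for _ in range(n_frames)]
    base = set(_ROI_BASE_COLUMNS)
    for _, row in df.iterrows():
        features = {
            c: float(row[c]) for c in df.columns
            if c not in base and pd.notna(row[c]) and row[c] != ""
        }
        out[int(row["frame"])].append(
            Roi(
                roi_id=int(row["roi_id"]),
                frame=int(row["frame"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                bbox=(
                    int(row["bbox_row_min"]), int(row["bbox_col_min"]),
                    int(row["bbox_row_max"]), int(row["bbox_col_max"]),
                ),
                features=features,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """One flat configuration for a whole run, loadable from YAML.

    YAML sections map to the parameter dataclasses: ``detection``,
    ``linking``, ``seqtrack``, ``metrics``, ``synthetic``; top-level keys
    are ``detect_channel``, ``rng_seed`` and ``log_level``.  Unknown keys
    are rejected.
    """

    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    linking: LinkParams = dataclasses.field(default_factory=LinkParams)
    seqtrack: SeqTrackParams = dataclasses.field(default_factory=SeqTrackParams)
    metrics: AogmWeights = dataclasses.field(default_factory=AogmWeights)
    synthetic: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    detect_channel: int = 0
    rng_seed: int = 0
    log_level: str = "INFO"


_SECTION_TYPES = {
    "detection": DetectionParams,
    "linking": LinkParams,
    "seqtrack": SeqTrackParams,
    "metrics": AogmWeights,
    "synthetic": SynthConfig,
}


def _build_section(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    top = {"detect_channel", "rng_seed", "log_level"}
    unknown = set(data) - set(_SECTION_TYPES) - top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {})
    for key in top:
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig) -> str:
    """YAML form of the effective configuration (for reproducibility logs)."""
    out: dict = {}
    for name in _SECTION_TYPES:
        section = dataclasses.asdict(getattr(cfg, name))
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in section.items()
        }
    out["detect_channel"] = cfg.detect_channel
    out["rng_seed"] = cfg.rng_seed
    out["log_level"] = cfg.log_level
    return yaml.safe_dump(out, sort_keys=True)
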