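"""Core domain model: image stacks, ROIs, tracks, lineages, labeled masks.

All coordinates are 0-based ``(row, col)``; frame indices are 0-based;
bounding boxes are half-open ``(row_min, col_min, row_max, col_max)``.
A ROI id is unique within its frame only — the pair ``(frame, roi_id)``
is the global key. File-format numbering conventions are handled at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A time-lapse image volume.

    ``pixels`` is ``(T, H, W)`` for single-channel data or ``(T, C, H, W)``
    for multi-channel data.  Calibration fields carry acquisition metadata
    (e.g. physical pixel size, seconds between frames); they are never used
    by the algorithms themselves.
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"pixels must be (T, H, W) or (T, C, H, W), got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1:
            raise ValueError("stack needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1] if self.pixels.ndim == 4 else 1

    @property
    def height(self) -> int:
        return self.pixels.shape[-2]

    @property
    def width(self) -> int:
        return self.pixels.shape[-1]

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        """Return one 2D frame (the given channel for 4D stacks)."""
        if self.pixels.ndim == 4:
            return self.pixels[t, channel]
        if channel != 0:
            raise IndexError("single-channel stack has only channel 0")
        return self.pixels[t]


@dataclass
class Roi:
    """One object instance in one frame.

    ``region``, when present, is an ``(n, 2)`` integer array of pixel
    coordinates forming a single 8-connected component; ``centroid`` is then
    the unweighted mean of those coordinates and ``bbox`` their tight
    half-open bounding box.  Spot-only ROIs carry just a centroid and a box.
    """

    roi_id: int
    frame: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    region: np.ndarray | None = None
    features: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, int]:
        return (self.frame, self.roi_id)

    def copy(self) -> "Roi":
        return replace(
            self,
            region=None if self.region is None else self.region.copy(),
            features=dict(self.features),
        )


@dataclass
class Track:
    """An ordered chain of ROIs sharing one identity.

    ``nodes`` is a list of ``(frame, roi_id)`` with strictly increasing
    frames.  Non-adjacent consecutive frames indicate a closed gap (no
    interpolated ROIs are stored for skipped frames).
    """

    track_id: int
    nodes: list[tuple[int, int]]
    parent_id: int | None = None

    @property
    def start_frame(self) -> int:
        return self.nodes[0][0]

    @property
    def end_frame(self) -> int:
        return self.nodes[-1][0]

    def copy(self) -> "Track":
        return Track(self.track_id, list(self.nodes), self.parent_id)


@dataclass
class Lineage:
    """All tracks plus mother→daughter relations: a DAG over tracks."""

    tracks: dict[int, Track] = field(default_factory=dict)

    def add(self, track: Track) -> None:
        if track.track_id in self.tracks:
            raise ValueError(f"duplicate track_id {track.track_id}")
        self.tracks[track.track_id] = track

    def children_of(self, track_id: int) -> list[int]:
        return sorted(
            tid for tid, t in self.tracks.items() if t.parent_id == track_id
        )

    def next_track_id(self) -> int:
        return max(self.tracks, default=0) + 1

    def copy(self) -> "Lineage":
        return Lineage({tid: t.copy() for tid, t in self.tracks.items()})


@dataclass
class LabeledMasks:
    """Per-frame integer label images; 0 is background.

    ``label_to_roi`` optionally maps ``(frame, label) -> roi_id``; when
    absent the label is the roi_id.
    """

    frames: list[np.ndarray]
    label_to_roi: dict[tuple[int, int], int] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def roi_id_for(self, frame: int, label: int) -> int:
        if self.label_to_roi is None:
            return int(label)
        return self.label_to_roi[(frame, label)]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Violation:
    """One structured lineage-invariant breach."""

    kind: str  # "cycle" | "frame-order" | "duplicate-roi" | "children-cap" | ...
    track_id: int | None
    message: str


def validate_lineage(lineage: Lineage, max_children: int = 2) -> list[Violation]:
    """Check every lineage invariant; return one violation per breach.

    Flags exactly the pathologies that surface as broken trajectories or
    unnatural branching in a lineage display: parent cycles, children that
    start before their mother ends, a ROI claimed by two tracks, more than
    ``max_children`` daughters, dangling parent references and empty or
    frame-disordered tracks.
    """
    out: list[Violation] = []
    for tid, track in lineage.tracks.items():
        if tid != track.track_id:
            out.append(Violation("id-mismatch", tid, f"keyed {tid} but track_id {track.track_id}"))
        if not track.nodes:
            out.append(Violation("empty-track", tid, "track has no nodes"))
            continue
        frames = [f for f, _ in track.nodes]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            out.append(Violation("frame-order", tid, "node frames not strictly increasing"))
        if track.parent_id is not None:
            parent = lineage.tracks.get(track.parent_id)
            if parent is None:
                out.append(Violation("dangling-parent", tid, f"parent {track.parent_id} missing"))
            elif parent.nodes and parent.end_frame >= track.start_frame:
                out.append(
                    Violation(
                        "frame-order",
                        tid,
                        f"parent {track.parent_id} ends at {parent.end_frame}, "
                        f"child starts at {track.start_frame}",
                    )
                )
    # duplicate ROI membership across all tracks
    seen: dict[tuple[int, int], int] = {}
    for tid, track in lineage.tracks.items():
        for node in track.nodes:
            if node in seen and seen[node] != tid:
                out.append(
                    Violation("duplicate-roi", tid, f"node {node} also in track {seen[node]}")
                )
            else:
                seen[node] = tid
    # children cap
    counts: dict[int, int] = {}
    for track in lineage.tracks.values():
        if track.parent_id is not None:
            counts[track.parent_id] = counts.get(track.parent_id, 0) + 1
    for pid, n in counts.items():
        if n > max_children:
            out.append(Violation("children-cap", pid, f"{n} children exceeds cap {max_children}"))
    # cycles in the parent relation
    for tid in lineage.tracks:
        slow = tid
        visited = set()
        while slow is not None and slow in lineage.tracks:
            if slow in visited:
                if slow == tid:
                    out.append(Violation("cycle", tid, "parent chain forms a cycle"))
                break
            visited.add(slow)
            slow = lineage.tracks[slow].parent_id
    return out


# ---------------------------------------------------------------------------
# Mask <-> ROI bridging
# ---------------------------------------------------------------------------


def _roi_from_coords(
    roi_id: int, frame: int, coords: np.ndarray, features: dict[str, float] | None = None
) -> Roi:
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    centroid = tuple(coords.mean(axis=0))
    return Roi(
        roi_id=roi_id,
        frame=frame,
        centroid=(float(centroid[0]), float(centroid[1])),
        bbox=(int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
        region=coords.astype(np.int64),
        features=features or {},
    )


def rois_from_masks(
    masks: LabeledMasks, stack: FrameStack | None = None
) -> list[list[Roi]]:
    """Convert per-frame label images into per-frame ROI lists.

    Labels are processed in ascending order within each frame and roi_ids
    equal the labels, so the assignment is deterministic.  When ``stack``
    is given, intensity features are computed per channel.
    """
    from .detection import compute_features  # local import to avoid a cycle

    if stack is not None:
        if stack.n_frames != masks.n_frames or (stack.height, stack.width) != masks.shape:
            raise ValueError(
                f"mask geometry {masks.n_frames}x{masks.shape} does not match "
                f"stack {stack.n_frames}x{(stack.height, stack.width)}"
            )
    out: list[list[Roi]] = []
    for t, lab in enumerate(masks.frames):
        rois: list[Roi] = []
        for label in np.unique(lab):
            if label == 0:
                continue
            coords = np.argwhere(lab == label)
            roi = _roi_from_coords(masks.roi_id_for(t, int(label)), t, coords)
            if stack is not None:
                roi.features = compute_features(roi, stack)
            rois.append(roi)
        out.append(rois)
    return out


def masks_from_rois(
    rois: Sequence[Sequence[Roi]],
    shape: tuple[int, int],
    labels: dict[tuple[int, int], int] | None = None,
) -> LabeledMasks:
    """Rasterize ROIs into per-frame label images.

    ``labels`` maps ``(frame, roi_id) -> label``; by default the roi_id is
    the label.  Region ROIs paint their pixels; spot-only ROIs paint their
    bounding box.  A pixel claimed by several ROIs goes to the one whose
    centroid is nearest (ties to the smaller roi_id), so rasterization is
    deterministic and labels stay disjoint.
    """
    frames: list[np.ndarray] = []
    for t, frame_rois in enumerate(rois):
        lab = np.zeros(shape, dtype=np.int32)
        dist = np.full(shape, np.inf)
        for roi in sorted(frame_rois, key=lambda r: r.roi_id):
            label = labels[(t, roi.roi_id)] if labels is not None else roi.roi_id
            if roi.region is not None:
                rr, cc = roi.region[:, 0], roi.region[:, 1]
            else:
                r0, c0, r1, c1 = roi.bbox
                r0, c0 = max(r0, 0), max(c0, 0)
                r1, c1 = min(r1, shape[0]), min(c1, shape[1])
                grid = np.mgrid[r0:r1, c0:c1]
                rr, cc = grid[0].ravel(), grid[1].ravel()
            d = (rr - roi.centroid[0]) ** 2 + (cc - roi.centroid[1]) ** 2
            take = d < dist[rr, cc]
            lab[rr[take], cc[take]] = label
            dist[rr[take], cc[take]] = d[take]
        frames.append(lab)
    return LabeledMasks(frames)


def largest_component(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Keep only the largest 8-connected component of a coordinate set."""
    img = np.zeros(shape, dtype=bool)
    img[coords[:, 0], coords[:, 1]] = True
    lab, n = ndi.label(img, structure=_STRUCT8)
    if n <= 1:
        return coords
    sizes = ndi.sum_labels(img, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return np.argwhere(lab == best)


def check_roi(roi: Roi, shape: tuple[int, int] | None = None) -> list[str]:
    """Return human-readable breaches of the ROI invariants (empty if valid)."""
    problems: list[str] = []
    r0, c0, r1, c1 = roi.bbox
    if not (r0 <= roi.centroid[0] < r1 and c0 <= roi.centroid[1] < c1):
        problems.append(f"centroid {roi.centroid} outside bbox {roi.bbox}")
    if roi.region is not None:
        coords = roi.region
        if len(coords) == 0:
            problems.append("empty region")
            return problems
        tight = (
            int(coords[:, 0].min()),
            int(coords[:, 1].min()),
            int(coords[:, 0].max()) + 1,
            int(coords[:, 1].max()) + 1,
        )
        if tight != tuple(roi.bbox):
            problems.append(f"bbox {roi.bbox} is not the tight box {tight}")
        cen = coords.mean(axis=0)
        if abs(cen[0] - roi.centroid[0]) > 1e-6 or abs(cen[1] - roi.centroid[1]) > 1e-6:
            problems.append(f"centroid {roi.centroid} != region centroid {tuple(cen)}")
        if shape is not None:
            span = shape
        else:
            span = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
        img = np.zeros(span, dtype=bool)
        img[coords[:, 0], coords[:, 1]] = True
        _, n = ndi.label(img, structure=_STRUCT8)
        if n != 1:
            problems.append(f"region has {n} 8-connected components")
    return problems
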