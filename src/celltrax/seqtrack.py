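"""Sequential search tracking of a single ROI with a particle filter.

One user-selected ROI is followed frame by frame (forward or backward in
time) by matching the luminance pattern around candidate positions against
a template taken at initialization.  Candidates are particles propagated by
a Gaussian random walk; each is weighted by the normalized cross-correlation
(or negated SSD) of the template with the patch at its position, and the
cloud is systematically resampled when the effective sample size collapses.
The position estimate per frame is the weighted particle mean.

Tracking can be cancelled, corrected and resumed: ``resume_from`` truncates
a produced track at a corrected frame, re-initializes the template at the
corrected position and continues over the remaining frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import FrameStack, Roi, Track


@dataclass
class SeqTrackParams:
    n_particles: int = 300
    motion_sigma: float = 5.0          # random-walk std, px/frame
    patch_half: int | None = None      # template half-size; default from the ROI bbox
    similarity: str = "ncc"            # "ncc" or "ssd"
    beta: float = 10.0                 # weight sharpness: w ~ exp(beta * sim)
    template_update: str = "none"      # "none" or "ema"
    ema_alpha: float = 0.1
    resample_threshold: float = 0.5    # resample when ESS < threshold * n
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.motion_sigma <= 0:
            raise ValueError("motion_sigma must be positive")
        if not 0 <= self.ema_alpha <= 1:
            raise ValueError("ema_alpha must lie in [0, 1]")
        if self.similarity not in ("ncc", "ssd"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.template_update not in ("none", "ema"):
            raise ValueError(f"unknown template_update {self.template_update!r}")


@dataclass
class ParticleCloud:
    positions: np.ndarray              # (n, 2) float (row, col)
    weights: np.ndarray                # (n,) non-negative, sums to 1
    template: np.ndarray               # (2h+1, 2h+1) float
    estimate: tuple[float, float]
    rng: np.random.Generator
    best_similarity: float = 1.0
    lost: bool = False


class TrackingLost(RuntimeError):
    """Raised when every particle's appearance score degenerates.

    Carries the last good estimate so a caller can correct and resume.
    """

    def __init__(self, estimate: tuple[float, float]):
        super().__init__(f"tracking lost near {estimate}")
        self.estimate = estimate


def extract_patch(frame: np.ndarray, center: tuple[float, float], half: int) -> np.ndarray:
    """Patch of side 2*half+1 centered at the rounded position, edge-replicated."""
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    r, c = int(round(center[0])), int(round(center[1]))
    rows = np.clip(np.arange(r - half, r + half + 1), 0, h - 1)
    cols = np.clip(np.arange(c - half, c + half + 1), 0, w - 1)
    return frame[np.ix_(rows, cols)]


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation in [-1, 1]; 0 for zero-variance patches."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _similarity(template: np.ndarray, patch: np.ndarray, params: SeqTrackParams) -> float:
    if params.similarity == "ncc":
        return ncc(template, patch)
    var = template.var()
    if var == 0:
        return 0.0
    return float(-np.mean((template - patch) ** 2) / var)


def _default_half(roi: Roi) -> int:
    r0, c0, r1, c1 = roi.bbox
    return max(2, max(r1 - r0, c1 - c0) // 2)


def init_tracker(stack: FrameStack, roi: Roi, params: SeqTrackParams,
                 channel: int = 0) -> ParticleCloud:
    """Template at the ROI centroid; all particles on the centroid."""
    h, w = stack.height, stack.width
    r, c = roi.centroid
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"roi centroid {roi.centroid} outside the image")
    half = params.patch_half if params.patch_half is not None else _default_half(roi)
    frame = stack.frame(roi.frame, channel)
    template = extract_patch(frame, (r, c), half)
    n = params.n_particles
    return ParticleCloud(
        positions=np.tile([r, c], (n, 1)).astype(np.float64),
        weights=np.full(n, 1.0 / n),
        template=template,
        estimate=(float(r), float(c)),
        rng=np.random.default_rng(params.rng_seed),
    )


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def step(cloud: ParticleCloud, next_frame: np.ndarray, params: SeqTrackParams) -> ParticleCloud:
    """Advance the cloud one frame: propagate, weight, resample, estimate."""
    frame = np.asarray(next_frame, dtype=np.float64)
    h, w = frame.shape
    half = cloud.template.shape[0] // 2
    pos = cloud.positions + cloud.rng.normal(0, params.motion_sigma, cloud.positions.shape)
    pos[:, 0] = np.clip(pos[:, 0], 0, h - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, w - 1)
    sims = np.array(
        [_similarity(cloud.template, extract_patch(frame, p, half), params) for p in pos]
    )
    logw = params.beta * sims
    weights = np.exp(logw - logw.max())
    total = weights.sum()
    if not np.isfinite(total) or total == 0:
        raise TrackingLost(cloud.estimate)
    weights = weights / total
    if sims.max() <= -1.0 + 1e-12 and params.similarity == "ncc":
        raise TrackingLost(cloud.estimate)
    ess = 1.0 / np.sum(weights**2)
    if ess < params.resample_threshold * len(weights):
        idx = _systematic_resample(weights, cloud.rng)
        pos = pos[idx]
        weights = np.full(len(weights), 1.0 / len(weights))
    est = (float(np.average(pos[:, 0], weights=weights)),
           float(np.average(pos[:, 1], weights=weights)))
    template = cloud.template
    if params.template_update == "ema":
        patch = extract_patch(frame, est, half)
        template = (1 - params.ema_alpha) * template + params.ema_alpha * patch
    return ParticleCloud(
        positions=pos,
        weights=weights,
        template=template,
        estimate=est,
        rng=cloud.rng,
        best_similarity=float(sims.max()),
    )


def track_sequential(
    stack: FrameStack,
    roi: Roi,
    start_frame: int,
    end_frame: int,
    params: SeqTrackParams | None = None,
    track_id: int = 1,
    channel: int = 0,
) -> tuple[Track, list[Roi], list[float]]:
    """Follow one ROI over a frame range; backward when end < start.

    Returns the track, one spot-only ROI per visited frame (bbox = template
    footprint) and a per-frame confidence (best particle similarity).  On
    tracking loss the partial track up to the last good frame is returned.
    """
    params = params or SeqTrackParams()
    if not (0 <= start_frame < stack.n_frames and 0 <= end_frame < stack.n_frames):
        raise ValueError("frame range outside the stack")
    if roi.frame != start_frame:
        roi = replace(roi, frame=start_frame)
    cloud = init_tracker(stack, roi, params, channel)
    half = cloud.template.shape[0] // 2
    direction = 1 if end_frame >= start_frame else -1
    frames = list(range(start_frame, end_frame + direction, direction))

    rois: list[Roi] = []
    confidences: list[float] = []

    def emit(frame_idx: int, est: tuple[float, float], conf: float) -> None:
        r, c = int(round(est[0])), int(round(est[1]))
        rois.append(
            Roi(
                roi_id=len(rois) + 1,
                frame=frame_idx,
                centroid=(float(est[0]), float(est[1])),
                bbox=(r - half, c - half, r + half + 1, c + half + 1),
            )
        )
        confidences.append(conf)

    emit(start_frame, cloud.estimate, 1.0)
    for f in frames[1:]:
        try:
            cloud = step(cloud, stack.frame(f, channel), params)
        except TrackingLost:
            break
        emit(f, cloud.estimate, cloud.best_similarity)

    ordered = sorted(rois, key=lambda r: r.frame)
    track = Track(track_id=track_id, nodes=[(r.frame, r.roi_id) for r in ordered])
    return track, ordered, confidences


def resume_from(
    stack: FrameStack,
    track: Track,
    rois: Sequence[Roi],
    frame: int,
    corrected_position: tuple[float, float],
    end_frame: int,
    params: SeqTrackParams | None = None,
    channel: int = 0,
) -> tuple[Track, list[Roi], list[float]]:
    """Cancel-correct-resume: keep nodes before ``frame``, restart there.

    The template is re-taken at ``corrected_position`` in ``frame`` and
    tracking continues to ``end_frame``; nodes strictly before ``frame``
    are unchanged.
    """
    params = params or SeqTrackParams()
    span = [f for f, _ in track.nodes]
    lo, hi = min(span + [end_frame]), max(span + [end_frame])
    if not lo <= frame <= hi:
        raise ValueError(f"frame {frame} outside the track's range [{lo}, {hi}]")
    direction = 1 if end_frame >= frame else -1
    keep = [r for r in rois if (r.frame - frame) * direction < 0]
    half = params.patch_half if params.patch_half is not None else (
        rois[0].bbox[2] - rois[0].bbox[0]
    ) // 2 if rois else 5
    r, c = corrected_position
    seed = Roi(
        roi_id=1,
        frame=frame,
        centroid=(float(r), float(c)),
        bbox=(int(round(r)) - half, int(round(c)) - half,
              int(round(r)) + half + 1, int(round(c)) + half + 1),
    )
    new_track, new_rois, confs = track_sequential(
        stack, seed, frame, end_frame, params, track.track_id, channel
    )
    merged = sorted(keep + new_rois, key=lambda x: x.frame)
    for i, roi in enumerate(merged):
        roi.roi_id = i + 1
    out = Track(track_id=track.track_id, nodes=[(x.frame, x.roi_id) for x in merged],
                parent_id=track.parent_id)
    return out, merged, confs
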