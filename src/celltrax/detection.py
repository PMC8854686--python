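"""Built-in recognition: LoG spot detection, seeded watershed regions, features.

The default recognizer targets fluorescence/emission imagery: bright
blob-like nuclei on a dark background.  Spots are maxima of a
scale-normalized, negated Laplacian-of-Gaussian response; region shapes are
formed by a marker-controlled watershed of the inverted smoothed intensity,
restricted to a foreground mask.  External detectors (e.g. deep-learning
segmenters that emit label images) plug in through a name registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .model import FrameStack, LabeledMasks, Roi, largest_component, rois_from_masks


@dataclass
class DetectionParams:
    """Tunable parameters of the built-in recognizer.

    sigma
        LoG scale in pixels; match it to the object radius / sqrt(2).
    threshold
        Minimum scale-normalized LoG response at a local maximum.  The
        response at the center of a Gaussian blob of amplitude A and size
        s under a filter of scale sigma is 2*A*sigma^2*s^2 / (sigma^2+s^2)^2,
        so thresholds transfer across scales.
    min_distance
        Minimum separation between returned spots, in pixels.
    make_regions
        Grow a watershed region around every spot when True.
    fg_method
        Foreground rule for the watershed: "otsu" or "fixed" (uses fg_value).
    smoothing_sigma
        Gaussian pre-smoothing of the watershed relief.
    region_level
        Per-object relative cut applied after the watershed: each region is
        trimmed to pixels whose smoothed intensity exceeds
        ``background + region_level * (peak - background)``, i.e. the
        full-width-at-half-maximum contour at the default 0.5.  A global
        threshold systematically over-extends dim objects; the half-maximum
        rule delineates each object at its own scale.  ``None`` keeps the
        raw watershed support.
    """

    sigma: float = 3.5
    threshold: float = 10.0
    min_distance: int = 5
    make_regions: bool = True
    fg_method: str = "otsu"
    fg_value: float = 0.0
    smoothing_sigma: float = 1.0
    region_level: float | None = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.fg_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown fg_method {self.fg_method!r}")


def spot_bbox(centroid: tuple[float, float], sigma: float) -> tuple[int, int, int, int]:
    """Square half-open bbox of side 2*ceil(2*sigma)+1 centered on the spot."""
    half = int(np.ceil(2 * sigma))
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    return (r - half, c - half, r + half + 1, c + half + 1)


def log_response(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negated Laplacian of Gaussian.

    Bright blobs produce positive peaks; the sigma^2 factor makes responses
    comparable across scales.  The operator is linear in the input.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    raw = ndi.gaussian_laplace(frame, sigma, mode="nearest")
    # the truncated discrete kernel does not sum exactly to zero; subtract
    # its DC gain (times the smoothed image) so constants map to zero
    dc = float(ndi.gaussian_laplace(np.ones((1, 1)), sigma, mode="nearest")[0, 0])
    if dc != 0.0:
        raw = raw - dc * ndi.gaussian_filter(frame, sigma, mode="nearest")
    return -(sigma**2) * raw


def detect_spots(frame: np.ndarray, params: DetectionParams) -> list[Roi]:
    """LoG spot detection with greedy non-maximum suppression.

    Local maxima of the LoG response above ``params.threshold`` are kept
    greedily from strongest to weakest so that no two returned spots are
    closer than ``params.min_distance`` (ties broken by (row, col) order).
    Returned ROIs are spot-only, sorted by descending response.
    """
    resp = log_response(frame, params.sigma)
    # 8-neighborhood plateaus count once: a pixel is a maximum if no
    # neighbor is strictly greater and it is the lexicographically first
    # pixel of its plateau.
    footprint = np.ones((3, 3), dtype=bool)
    maxfilt = ndi.maximum_filter(resp, footprint=footprint, mode="nearest")
    cand = np.argwhere((resp >= maxfilt) & (resp > params.threshold))
    if len(cand) == 0:
        return []
    values = resp[cand[:, 0], cand[:, 1]]
    # strongest first; ties by (row, col)
    order = np.lexsort((cand[:, 1], cand[:, 0], -values))
    cand, values = cand[order], values[order]
    kept: list[int] = []
    kept_pos: list[np.ndarray] = []
    min_d2 = params.min_distance**2
    for i, pos in enumerate(cand):
        if all(((pos - p) ** 2).sum() >= min_d2 for p in kept_pos):
            kept.append(i)
            kept_pos.append(pos)
    rois = []
    for rank, i in enumerate(kept):
        r, c = float(cand[i, 0]), float(cand[i, 1])
        rois.append(
            Roi(
                roi_id=rank + 1,
                frame=0,
                centroid=(r, c),
                bbox=spot_bbox((r, c), params.sigma),
                features={"log_response": float(values[i])},
            )
        )
    return rois


def _foreground(frame: np.ndarray, params: DetectionParams) -> tuple[np.ndarray, np.ndarray]:
    smoothed = ndi.gaussian_filter(np.asarray(frame, dtype=np.float64), params.smoothing_sigma)
    if params.fg_method == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fg_value
    return smoothed, smoothed > thr


def segment_regions(
    frame: np.ndarray, spots: Sequence[Roi], params: DetectionParams
) -> tuple[LabeledMasks, list[Roi], list[int]]:
    """Marker-controlled watershed region formation around detected spots.

    The smoothed frame is thresholded into a foreground mask; the watershed
    of the inverted smoothed intensity, seeded with one marker per spot and
    restricted to the foreground, partitions the foreground into one region
    per spot.  Returns the single-frame label image, the spots upgraded to
    region ROIs, and the roi_ids whose marker fell on background (their
    regions are empty and they are returned unchanged).
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    markers = np.zeros(frame.shape, dtype=np.int32)
    for roi in spots:
        r, c = int(round(roi.centroid[0])), int(round(roi.centroid[1]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot {roi.roi_id} at {roi.centroid} outside frame {frame.shape}")
        markers[r, c] = roi.roi_id
    smoothed, fg = _foreground(frame, params)
    lab = watershed(-smoothed, markers=markers, mask=fg)
    background = float(np.median(smoothed[~fg])) if (~fg).any() else 0.0
    out_rois: list[Roi] = []
    empty: list[int] = []
    final = np.zeros_like(lab)
    for roi in spots:
        coords = np.argwhere(lab == roi.roi_id)
        if len(coords) > 0 and params.region_level is not None:
            vals = smoothed[coords[:, 0], coords[:, 1]]
            cut = background + params.region_level * (vals.max() - background)
            trimmed = coords[vals >= cut]
            if len(trimmed) > 0:
                coords = trimmed
        if len(coords) == 0:
            empty.append(roi.roi_id)
            out_rois.append(roi)
            continue
        coords = largest_component(coords, frame.shape)
        rmin, cmin = coords.min(axis=0)
        rmax, cmax = coords.max(axis=0)
        cen = coords.mean(axis=0)
        out_rois.append(
            Roi(
                roi_id=roi.roi_id,
                frame=roi.frame,
                centroid=(float(cen[0]), float(cen[1])),
                bbox=(int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
                region=coords.astype(np.int64),
                features=dict(roi.features),
            )
        )
        final[coords[:, 0], coords[:, 1]] = roi.roi_id
    return LabeledMasks([final]), out_rois, empty


def compute_features(roi: Roi, stack: FrameStack) -> dict[str, float]:
    """Quantify one ROI: area, centroid, intensity per channel, circularity.

    Area is the region pixel count (bbox area for spot-only ROIs); intensity
    statistics are taken over the same support.  Circularity is 4*pi*A/P^2
    with P the perimeter estimate of the rasterized region; it is only
    reported for region ROIs.
    """
    if roi.region is not None and len(roi.region) == 0:
        raise ValueError("cannot compute features of an empty region")
    h, w = stack.height, stack.width
    if roi.region is not None:
        rr, cc = roi.region[:, 0], roi.region[:, 1]
    else:
        r0, c0, r1, c1 = roi.bbox
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        if r1 <= r0 or c1 <= c0:
            raise ValueError("bbox does not intersect the frame")
        grid = np.mgrid[r0:r1, c0:c1]
        rr, cc = grid[0].ravel(), grid[1].ravel()
    feats: dict[str, float] = {
        "area": float(len(rr)),
        "centroid_row": float(roi.centroid[0]),
        "centroid_col": float(roi.centroid[1]),
    }
    for ch in range(stack.n_channels):
        img = stack.frame(roi.frame, ch)
        vals = img[rr, cc].astype(np.float64)
        suffix = "" if stack.n_channels == 1 else f"_c{ch}"
        feats[f"mean_intensity{suffix}"] = float(vals.mean())
        feats[f"sum_intensity{suffix}"] = float(vals.sum())
    if roi.region is not None:
        r0, c0, r1, c1 = roi.bbox
        patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        patch[rr - r0, cc - c0] = True
        # Crofton perimeter: near-unbiased on rasterized disks, so the
        # circularity of a circle stays close to 1
        perim = measure.perimeter_crofton(patch, directions=4)
        if perim > 0:
            feats["circularity"] = float(4 * np.pi * len(rr) / perim**2)
    return feats


# ---------------------------------------------------------------------------
# Plugin registry
# ---------------------------------------------------------------------------

# A detector plugin is a callable (frame, params) -> list[Roi] for one frame.
_REGISTRY: dict[str, Callable] = {}


def register_detector(name: str, fn: Callable) -> None:
    _REGISTRY[name] = fn


def detector_names() -> list[str]:
    return sorted(_REGISTRY)


def run_detector_plugin(name: str, frame, params) -> list[Roi]:
    """Dispatch a single frame to a registered detector by name.

    The plugin's output is checked against the ROI invariants; a violation
    is reported as a contract error naming the plugin.
    """
    from .model import check_roi

    if name not in _REGISTRY:
        raise KeyError(f"no detector named {name!r}; registered: {detector_names()}")
    rois = _REGISTRY[name](frame, params)
    for roi in rois:
        problems = check_roi(roi)
        if problems:
            raise ValueError(f"plugin {name!r} returned an invalid ROI {roi.key}: {problems}")
    return rois


def _plugin_log_spots(frame, params: DetectionParams) -> list[Roi]:
    return detect_spots(frame, params)


def _plugin_log_watershed(frame, params: DetectionParams) -> list[Roi]:
    spots = detect_spots(frame, params)
    _, rois, empty = segment_regions(frame, spots, params)
    return [r for r in rois if r.roi_id not in empty]


def _plugin_masks(frame, params) -> list[Roi]:
    """Wrap an externally produced single-frame label image (the DL path)."""
    lab = np.asarray(frame)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("the 'masks' plugin expects an integer label image")
    per_frame = rois_from_masks(LabeledMasks([lab]))
    return per_frame[0]


register_detector("log_spots", _plugin_log_spots)
register_detector("log_watershed", _plugin_log_watershed)
register_detector("masks", _plugin_masks)


def detect_stack(
    stack: FrameStack,
    params: DetectionParams,
    detector: str = "log_watershed",
    detect_channel: int = 0,
) -> list[list[Roi]]:
    """Run a detector over every frame of a stack (one designated channel)."""
    if not params.make_regions and detector == "log_watershed":
        detector = "log_spots"
    out: list[list[Roi]] = []
    for t in range(stack.n_frames):
        rois = run_detector_plugin(detector, stack.frame(t, detect_channel), params)
        for roi in rois:
            roi.frame = t
            roi.features.update(compute_features(roi, stack))
        out.append(rois)
    return out
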