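"""Combined tracking-and-correction workflows.

Link-type tracking, sequential tracking and editing are designed to be
used together: run the link-type tracker over the whole movie, locate the
mis-tracked sites, correct them with sequential tracking or ROI edits, and
relink the entire frame set.  This module implements the two documented
correction recipes for the classic failure modes of tracking-by-detection:

* two cells moving in close contact are recognized as a single object —
  re-track each member with the particle filter from a user-supplied seed
  and split the merged region between the tracked positions
  (:func:`resplit_merged_rois`);
* a cell swelling before division is over-segmented into several objects,
  which the linker misreads as an early division — replace the fragments
  with their union via an edit script (:func:`merge_roi_fragments`).

Both return an edited ROI set; running :func:`celltrax.linking.track_rois`
on it relinks every frame, exactly like re-applying link-type tracking
after interactive edits.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .editing import EditCommand, EditScript, apply_script
from .model import Lineage, Roi, largest_component
from .seqtrack import SeqTrackParams, track_sequential
from .model import FrameStack


def _region_roi(roi_id: int, frame: int, coords: np.ndarray,
                shape: tuple[int, int]) -> Roi:
    coords = largest_component(coords, shape)
    cen = coords.mean(axis=0)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    return Roi(
        roi_id=roi_id,
        frame=frame,
        centroid=(float(cen[0]), float(cen[1])),
        bbox=(int(r0), int(c0), int(r1) + 1, int(c1) + 1),
        region=coords.astype(np.int64),
    )


def resplit_merged_rois(
    stack: FrameStack,
    rois: Sequence[Sequence[Roi]],
    seed_a: tuple[float, float],
    seed_b: tuple[float, float],
    params: SeqTrackParams | None = None,
    start_frame: int = 0,
    end_frame: int | None = None,
    patch_half: int = 6,
) -> list[list[Roi]]:
    """Split a two-cell merge by particle-filter re-tracking.

    ``seed_a``/``seed_b`` are the user-identified positions of the two
    cells in ``start_frame``.  Each is followed with the sequential
    tracker; in every frame where both estimates land in (or nearest to)
    one detected region ROI, that ROI is replaced by two region ROIs
    obtained by assigning its pixels to the nearer tracked position.
    Frames where the estimates already fall into distinct ROIs are left
    untouched.
    """
    if end_frame is None:
        end_frame = stack.n_frames - 1
    params = params or SeqTrackParams(motion_sigma=2.0)
    shape = (stack.height, stack.width)
    estimates: dict[int, dict[int, tuple[float, float]]] = {}
    for i, seed in enumerate((seed_a, seed_b)):
        r, c = seed
        roi = Roi(1, start_frame, (float(r), float(c)),
                  (int(round(r)) - patch_half, int(round(c)) - patch_half,
                   int(round(r)) + patch_half + 1, int(round(c)) + patch_half + 1))
        seed_params = SeqTrackParams(**{**params.__dict__, "rng_seed": params.rng_seed + i})
        _, srois, _ = track_sequential(stack, roi, start_frame, end_frame, seed_params)
        estimates[i] = {x.frame: x.centroid for x in srois}

    out = [[r.copy() for r in frame] for frame in rois]
    for t in range(len(out)):
        pa, pb = estimates[0].get(t), estimates[1].get(t)
        if pa is None or pb is None or not out[t]:
            continue
        regions = [r for r in out[t] if r.region is not None]
        if not regions:
            continue

        def nearest(p):
            return min(regions, key=lambda r: (r.centroid[0] - p[0]) ** 2
                       + (r.centroid[1] - p[1]) ** 2)

        ra, rb = nearest(pa), nearest(pb)
        if ra.roi_id != rb.roi_id:
            continue  # already resolved in this frame
        reg = ra.region
        da = (reg[:, 0] - pa[0]) ** 2 + (reg[:, 1] - pa[1]) ** 2
        db = (reg[:, 0] - pb[0]) ** 2 + (reg[:, 1] - pb[1]) ** 2
        half_a, half_b = reg[da <= db], reg[da > db]
        if len(half_a) == 0 or len(half_b) == 0:
            continue  # estimates collapsed onto one point; nothing to split
        nid = max(r.roi_id for r in out[t]) + 1
        out[t] = [r for r in out[t] if r.roi_id != ra.roi_id]
        out[t].append(_region_roi(nid, t, half_a, shape))
        out[t].append(_region_roi(nid + 1, t, half_b, shape))
    return out


def merge_roi_fragments(
    rois: Sequence[Sequence[Roi]],
    frame: int,
    fragment_ids: Sequence[int],
    shape: tuple[int, int],
) -> tuple[list[list[Roi]], EditScript]:
    """Replace over-segmented fragments of one cell by their union.

    Builds and applies an edit script (delete each fragment, add one ROI
    carrying the union region) so the correction is replayable.  Returns
    the edited ROI set and the script.
    """
    frags = [r for r in rois[frame] if r.roi_id in set(fragment_ids)]
    if len(frags) < 2:
        raise ValueError(f"need at least 2 fragments in frame {frame}, found {len(frags)}")
    if any(r.region is None for r in frags):
        raise ValueError("fragments must carry pixel regions")
    union = np.unique(np.concatenate([r.region for r in frags]), axis=0)
    union = largest_component(union, shape)
    nid = max(r.roi_id for r in rois[frame]) + 1
    cen = union.mean(axis=0)
    commands = [
        EditCommand("delete_roi", {"frame": frame, "roi_id": r.roi_id}) for r in frags
    ]
    commands.append(
        EditCommand("add_roi", {
            "frame": frame, "roi_id": nid,
            "row": float(cen[0]), "col": float(cen[1]),
            "region": union,
        })
    )
    script = EditScript(commands)
    _, edited = apply_script(Lineage(), rois, script)
    return edited, script
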