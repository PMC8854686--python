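"""Synthetic fluorescence time-lapse movies with exact ground truth.

Cells are isotropic 2D Gaussian blobs on a dark background, moving by
Brownian diffusion plus a common drift with reflecting boundaries.  A
dividing cell first "swells" for two frames — rendered as a dumbbell of two
lobes whose separation grows with ``swell_factor`` — and then splits into
two daughters recorded as mother→daughter edges in the ground-truth
lineage.  Ground-truth masks are the 50%-of-peak contour of each cell's own
noiseless intensity field (contested pixels go to the brighter cell), so
the truth is independent of the noise realization.

Two error-inducing regimes are available on top of the well-separated
default:

* ``contact_fraction`` seeds pairs of cells that travel in close contact
  (``contact_distance`` apart, sharing their diffusion), which blob
  detection merges into a single object;
* a raised ``swell_factor`` makes the pre-division dumbbell wide enough
  that detection over-segments the still-single mother, producing a
  spurious early division.

Everything is determined by ``rng_seed``.  The RNG draw order is fixed and
documented in ``generate_movie`` so re-simulation oracles can replay it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import FrameStack, LabeledMasks, Lineage, Roi, Track, largest_component
from .editing import delete_node, set_parent
from .model import validate_lineage


@dataclass
class SynthConfig:
    n_frames: int = 30
    height: int = 256
    width: int = 256
    n_cells_initial: int = 15
    blob_sigma_range: tuple[float, float] = (3.0, 4.0)
    amplitude_range: tuple[float, float] = (80.0, 120.0)
    background_level: float = 10.0
    noise_gaussian_sigma: float = 2.0
    noise_poisson: bool = False
    diffusion_sigma: float = 0.5        # px/frame
    drift: tuple[float, float] = (0.3, 0.2)  # px/frame
    division_prob: float = 0.0          # per live cell per frame
    n_forced_divisions: int = 2
    division_separation: float = 12.0   # px between daughters
    min_separation: float = 28.0        # px between unrelated cells at seeding
    contact_fraction: float = 0.0       # fraction of initial cells seeded in contact pairs
    contact_distance: float = 6.0       # px between contact-pair members
    swell_factor: float = 1.2           # dumbbell width during the 2 pre-division frames
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.height, self.width, self.n_cells_initial) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.division_prob <= 1 or not 0 <= self.contact_fraction <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.swell_factor < 1:
            raise ValueError("swell_factor must be >= 1")


@dataclass
class _Cell:
    cid: int
    pos: np.ndarray                 # (row, col) float
    sigma: float
    amplitude: float
    birth: int
    parent: int | None = None
    division_frame: int | None = None   # frame at which daughters appear
    division_dir: np.ndarray | None = None
    contact_leader: int | None = None   # cid whose diffusion this cell copies
    alive: bool = True
    positions: dict[int, np.ndarray] = field(default_factory=dict)


def _render_lobes(cell: _Cell, frame: int, cfg: SynthConfig) -> list[tuple[np.ndarray, float, float]]:
    """Gaussian lobes (center, sigma, amplitude) rendering a cell in a frame."""
    pos = cell.positions[frame]
    if cell.division_frame is not None and cell.division_frame - 2 <= frame < cell.division_frame:
        # swell phase: dumbbell with separation growing toward division
        phase = frame - (cell.division_frame - 2) + 1   # 1 or 2
        sep = 3.0 * cell.sigma * (cfg.swell_factor - 1.0) * phase
        u = cell.division_dir
        a = cell.amplitude * 0.8
        return [
            (pos + u * sep / 2, cell.sigma, a),
            (pos - u * sep / 2, cell.sigma, a),
        ]
    return [(pos, cell.sigma, cell.amplitude)]


def _cell_field(
    lobes: list[tuple[np.ndarray, float, float]], shape: tuple[int, int]
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cell intensity field on a tight local window; returns (field, origin)."""
    h, w = shape
    margin = max(int(np.ceil(4 * s)) for _, s, _ in lobes)
    r0 = max(0, int(min(c[0] for c, _, _ in lobes)) - margin)
    r1 = min(h, int(max(c[0] for c, _, _ in lobes)) + margin + 1)
    c0 = max(0, int(min(c[1] for c, _, _ in lobes)) - margin)
    c1 = min(w, int(max(c[1] for c, _, _ in lobes)) + margin + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    f = np.zeros(rr.shape, dtype=np.float64)
    for center, sigma, amp in lobes:
        f += amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))
    return f, (r0, c0)


def _reflect(pos: np.ndarray, lo: float, hi_r: float, hi_c: float) -> np.ndarray:
    out = pos.copy()
    for k, hi in enumerate((hi_r, hi_c)):
        span = hi - lo
        x = (out[k] - lo) % (2 * span)
        out[k] = lo + (x if x <= span else 2 * span - x)
    return out


def generate_movie(cfg: SynthConfig) -> tuple[FrameStack, LabeledMasks, Lineage]:
    """Simulate a movie; return (stack, GT masks, GT lineage).

    RNG draw order (one ``numpy`` Generator seeded with ``cfg.rng_seed``):

    1. per initial cell, in id order: position draws (rejection sampling:
       2 uniforms per attempt), one uniform for sigma, one for amplitude;
       contact-pair partners additionally draw one direction angle;
    2. per forced division, one direction angle (scheduling is
       deterministic: the last eligible cells, frames spread over the
       middle third, never in the last 2 frames);
    3. per frame t = 1..T-1, per live cell in id order: 2 normals for
       diffusion (contact followers consume none — they copy the leader);
    4. per frame, per live cell in id order, one uniform division decision
       (only drawn when ``division_prob > 0``), plus one direction angle
       when a division fires;
    5. per frame: the noise field (Poisson and/or Gaussian).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.height, cfg.width
    smax = cfg.blob_sigma_range[1]
    margin = 4 * smax
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("field too small for the configured blob size")

    n_pairs = int(round(cfg.contact_fraction * cfg.n_cells_initial / 2))
    cells: list[_Cell] = []
    placed: list[np.ndarray] = []
    for i in range(cfg.n_cells_initial):
        pair_follower = i < 2 * n_pairs and i % 2 == 1
        if pair_follower:
            leader = cells[-1]
            ang = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(ang), np.sin(ang)])
            pos = _reflect(leader.pos + u * cfg.contact_distance, margin, h - margin, w - margin)
        else:
            for _ in range(10_000):
                pos = np.array([
                    rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin),
                ])
                if all(np.linalg.norm(pos - p) >= cfg.min_separation for p in placed):
                    break
            else:
                raise ValueError(
                    f"cannot place {cfg.n_cells_initial} cells with separation "
                    f"{cfg.min_separation} in a {h}x{w} field"
                )
        sigma = rng.uniform(*cfg.blob_sigma_range)
        amp = rng.uniform(*cfg.amplitude_range)
        cell = _Cell(cid=i + 1, pos=pos, sigma=sigma, amplitude=amp, birth=0)
        if pair_follower:
            cell.contact_leader = cells[-1].cid
        else:
            placed.append(pos)
        cells.append(cell)

    # forced division schedule: last eligible (non-contact) cells, frames in
    # the middle third of the movie, never in the last 2 frames
    eligible = [c for c in cells if c.contact_leader is None
                and all(x.contact_leader != c.cid for x in cells)]
    if cfg.n_forced_divisions > len(eligible):
        raise ValueError("not enough non-contact cells for the forced divisions")
    lo_f = max(3, cfg.n_frames // 3)
    hi_f = min(cfg.n_frames - 3, 2 * cfg.n_frames // 3)
    for k in range(cfg.n_forced_divisions):
        cell = eligible[-(k + 1)]
        frac = 0.5 if cfg.n_forced_divisions == 1 else k / (cfg.n_forced_divisions - 1)
        cell.division_frame = int(round(lo_f + frac * (hi_f - lo_f)))
        ang = rng.uniform(0, 2 * np.pi)
        cell.division_dir = np.array([np.cos(ang), np.sin(ang)])

    by_id: dict[int, _Cell] = {c.cid: c for c in cells}
    drift = np.asarray(cfg.drift, dtype=np.float64)

    for c in cells:
        c.positions[0] = c.pos.copy()

    for t in range(1, cfg.n_frames):
        live = sorted((c for c in cells if c.alive), key=lambda c: c.cid)
        steps: dict[int, np.ndarray] = {}
        for c in live:
            if c.contact_leader is not None and c.contact_leader in steps:
                step_v = steps[c.contact_leader]
            else:
                step_v = rng.normal(0, cfg.diffusion_sigma, 2)
            steps[c.cid] = step_v
            c.pos = _reflect(c.pos + step_v + drift, margin, h - margin, w - margin)
        # divisions taking effect at this frame
        for c in list(live):
            if c.division_frame == t:
                u = c.division_dir
                half = u * cfg.division_separation / 2
                c.alive = False
                for s, sign in enumerate((1.0, -1.0)):
                    nid = max(by_id) + 1
                    d = _Cell(
                        cid=nid,
                        pos=_reflect(c.pos + sign * half, margin, h - margin, w - margin),
                        sigma=c.sigma,
                        amplitude=c.amplitude,
                        birth=t,
                        parent=c.cid,
                    )
                    d.positions[t] = d.pos.copy()
                    cells.append(d)
                    by_id[nid] = d
        if cfg.division_prob > 0:
            for c in sorted((x for x in cells if x.alive), key=lambda x: x.cid):
                if c.birth == t or c.division_frame is not None:
                    continue
                if t >= cfg.n_frames - 4:  # daughters must be observable >= 2 frames
                    continue
                if rng.uniform() < cfg.division_prob:
                    c.division_frame = t + 3  # swell for 2 frames, then split
                    ang = rng.uniform(0, 2 * np.pi)
                    c.division_dir = np.array([np.cos(ang), np.sin(ang)])
        for c in cells:
            if c.alive:
                c.positions[t] = c.pos.copy()

    # ---- rasterize ----------------------------------------------------
    pixels = np.full((cfg.n_frames, h, w), cfg.background_level, dtype=np.float64)
    mask_frames = [np.zeros((h, w), dtype=np.int32) for _ in range(cfg.n_frames)]
    for t in range(cfg.n_frames):
        claim_val = np.zeros((h, w), dtype=np.float64)
        lab = mask_frames[t]
        for c in cells:
            if t not in c.positions:
                continue
            lobes = _render_lobes(c, t, cfg)
            f, (r0, c0) = _cell_field(lobes, (h, w))
            sl = (slice(r0, r0 + f.shape[0]), slice(c0, c0 + f.shape[1]))
            pixels[t][sl] += f
            mask = f >= 0.5 * f.max()
            win_claim = claim_val[sl]
            take = mask & (f > win_claim)
            lab[sl][take] = c.cid
            claim_val[sl] = np.where(take, f, win_claim)
        # contested pixels may fragment a mask; keep each label's largest piece
        for label in np.unique(lab):
            if label == 0:
                continue
            coords = np.argwhere(lab == label)
            keep = largest_component(coords, (h, w))
            if len(keep) != len(coords):
                drop = set(map(tuple, coords)) - set(map(tuple, keep))
                for r, cc_ in drop:
                    lab[r, cc_] = 0

    if cfg.noise_poisson:
        pixels = rng.poisson(np.clip(pixels, 0, None)).astype(np.float64)
    if cfg.noise_gaussian_sigma > 0:
        pixels = pixels + rng.normal(0, cfg.noise_gaussian_sigma, pixels.shape)
    pixels = np.clip(pixels, 0, None)

    lineage = Lineage()
    for c in sorted(cells, key=lambda x: x.cid):
        frames_present = sorted(c.positions)
        if not frames_present:
            continue
        lineage.add(
            Track(
                track_id=c.cid,
                nodes=[(t, c.cid) for t in frames_present],
                parent_id=c.parent,
            )
        )
    assert validate_lineage(lineage) == []
    stack = FrameStack(pixels)
    return stack, LabeledMasks(mask_frames), lineage


def ground_truth_rois(masks: LabeledMasks, stack: FrameStack | None = None) -> list[list[Roi]]:
    """Per-frame ROIs for the GT masks (roi_id = cell id = track label)."""
    from .model import rois_from_masks

    return rois_from_masks(masks, stack)


# ---------------------------------------------------------------------------
# Deterministic error injection
# ---------------------------------------------------------------------------


def inject_errors(
    lineage: Lineage,
    masks: LabeledMasks,
    spec: Sequence[dict],
) -> tuple[Lineage, LabeledMasks, list[str]]:
    """Corrupt a (lineage, masks) pair with named, logged error events.

    Supported entries:
      {"type": "merge_masks", "frame": t, "labels": (a, b)}  — b absorbed by a
      {"type": "split_mask", "frame": t, "label": a}         — a split in two
      {"type": "drop_link", "track": id, "frame": t}         — cut after t
      {"type": "drop_object", "frame": t, "label": a}        — node + pixels removed
      {"type": "false_division", "child": id, "parent": id}  — spurious edge

    Mask labels are assumed to equal track ids.  An empty spec is the
    identity.  Returns the corrupted copies plus a log line per event.
    """
    from .editing import cut_track

    lin = lineage.copy()
    frames = [f.copy() for f in masks.frames]
    log: list[str] = []
    for entry in spec:
        kind = entry["type"]
        if kind == "merge_masks":
            t, (a, b) = entry["frame"], entry["labels"]
            frames[t][frames[t] == b] = a
            if any((t, b) in tr.nodes for tr in lin.tracks.values()):
                lin = delete_node(lin, t, b)
            log.append(f"merge_masks frame={t} {b}->{a}")
        elif kind == "split_mask":
            t, a = entry["frame"], entry["label"]
            coords = np.argwhere(frames[t] == a)
            if len(coords) < 2:
                raise ValueError(f"label {a} too small to split in frame {t}")
            med = np.median(coords[:, 1])
            new_label = int(max(int(f.max()) for f in frames)) + 1
            right = coords[coords[:, 1] > med]
            if len(right) == 0 or len(right) == len(coords):
                right = coords[len(coords) // 2 :]
            frames[t][right[:, 0], right[:, 1]] = new_label
            if any((t, a) in tr.nodes for tr in lin.tracks.values()):
                lin.add(Track(track_id=new_label, nodes=[(t, new_label)]))
            log.append(f"split_mask frame={t} {a}->+{new_label}")
        elif kind == "drop_link":
            lin = cut_track(lin, entry["track"], entry["frame"])
            log.append(f"drop_link track={entry['track']} after frame={entry['frame']}")
        elif kind == "drop_object":
            t, a = entry["frame"], entry["label"]
            frames[t][frames[t] == a] = 0
            if any((t, a) in tr.nodes for tr in lin.tracks.values()):
                lin = delete_node(lin, t, a)
            log.append(f"drop_object frame={t} label={a}")
        elif kind == "false_division":
            lin = set_parent(lin, entry["child"], entry["parent"])
            log.append(f"false_division child={entry['child']} parent={entry['parent']}")
        else:
            raise ValueError(f"unknown error type {kind!r}")
    return lin, LabeledMasks(frames), log
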