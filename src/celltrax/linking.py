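"""Link-type tracking: LAP frame-pair assignment, then gap closing / division.

Stage 1 solves one linear assignment problem per adjacent frame pair.  The
cost matrix follows the standard augmented construction: an n x m link block
(squared centroid distance, optionally inflated by relative feature
differences), diagonal death and birth blocks priced just above the worst
accepted link, and a lower-right completion block.  Chained pairwise links
give track segments.

Stage 2 runs a second LAP over segment endpoints: segment ends may close
gaps to segment starts (cost d^2 * gap length), and segment starts may
attach to the frame-before node of another segment as a division, which
cuts the mother there and records parent->daughter edges.  Both event types
compete against a "no event" alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Lineage, Roi, Track

#: marker for forbidden assignments in cost matrices
FORBIDDEN = np.inf


@dataclass
class LinkParams:
    max_link_dist: float = 15.0
    alt_cost_factor: float = 1.05
    cost_features: dict[str, float] = field(default_factory=dict)
    max_gap_frames: int = 2
    max_split_dist: float = 15.0
    allow_splits: bool = True

    def __post_init__(self) -> None:
        if self.max_link_dist <= 0:
            raise ValueError("max_link_dist must be positive")
        if self.alt_cost_factor <= 1:
            raise ValueError("alt_cost_factor must exceed 1")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class Assignment:
    pairs: list[tuple[int, int]]
    births: list[int]
    deaths: list[int]
    total_cost: float


def _feature_penalty(a: Roi, b: Roi, weights: dict[str, float]) -> float:
    """Relative feature-difference penalty: sum_k w_k * |da_k| / max(ref_k)."""
    pen = 0.0
    for name, w in weights.items():
        va, vb = a.features.get(name), b.features.get(name)
        if va is None or vb is None:
            continue
        ref = max(abs(va), abs(vb))
        if ref > 0:
            pen += w * abs(va - vb) / ref
    return pen


def frame_cost_matrix(
    rois_t: Sequence[Roi], rois_t1: Sequence[Roi], params: LinkParams
) -> np.ndarray:
    """Augmented (n+m) x (n+m) cost matrix for one frame pair."""
    n, m = len(rois_t), len(rois_t1)
    link = np.full((n, m), FORBIDDEN)
    max_d2 = params.max_link_dist**2
    for i, a in enumerate(rois_t):
        for j, b in enumerate(rois_t1):
            d2 = (a.centroid[0] - b.centroid[0]) ** 2 + (a.centroid[1] - b.centroid[1]) ** 2
            if d2 <= max_d2:
                link[i, j] = d2 * (1.0 + _feature_penalty(a, b, params.cost_features))
    finite = link[np.isfinite(link)]
    b_cost = params.alt_cost_factor * (finite.max() if finite.size else max_d2)
    if b_cost == 0:
        b_cost = params.alt_cost_factor  # all-zero links still need a positive alternative
    return augment_cost_matrix(link, b_cost)


def augment_cost_matrix(link: np.ndarray, alt_cost: float) -> np.ndarray:
    """Standard LAP augmentation: death/birth diagonals + completion block."""
    n, m = link.shape
    full = np.full((n + m, n + m), FORBIDDEN)
    full[:n, :m] = link
    for i in range(n):
        full[i, m + i] = alt_cost  # death of source i
    for j in range(m):
        full[n + j, j] = alt_cost  # birth of target j
    # completion block: transposed feasibility at negligible cost
    lower = np.full((m, n), FORBIDDEN)
    lower[np.isfinite(link).T] = 0.0
    full[n:, m:] = lower
    return full


def solve_lap(cost: np.ndarray, n_sources: int | None = None, n_targets: int | None = None) -> Assignment:
    """Minimum-cost complete assignment of an augmented matrix.

    ``n_sources``/``n_targets`` identify the real (non-auxiliary) rows and
    columns; by default the matrix is assumed square-augmented with
    n = m = size/2 unavailable, so they must be given for rectangular link
    blocks.  Forbidden entries are ``inf``.
    """
    if cost.size == 0:
        return Assignment([], [], [], 0.0)
    if cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    size = cost.shape[0]
    if n_sources is None or n_targets is None:
        raise ValueError("n_sources and n_targets are required")
    if n_sources + n_targets != size:
        raise ValueError("n_sources + n_targets must equal the matrix size")
    # replace inf by a large finite sentinel for the solver, then verify
    finite = cost[np.isfinite(cost)]
    big = (finite.max() if finite.size else 1.0) * size + 1.0
    work = np.where(np.isfinite(cost), cost, big)
    rows, cols = linear_sum_assignment(work)
    if any(not np.isfinite(cost[r, c]) and work[r, c] >= big for r, c in zip(rows, cols)):
        # a forbidden entry was used: check it was truly unavoidable
        raise RuntimeError("no feasible complete assignment")
    pairs, births, deaths = [], [], []
    total = 0.0
    for r, c in zip(rows, cols):
        total += cost[r, c]
        if r < n_sources and c < n_targets:
            pairs.append((int(r), int(c)))
        elif r < n_sources:
            deaths.append(int(r))
        elif c < n_targets:
            births.append(int(c))
    return Assignment(sorted(pairs), sorted(births), sorted(deaths), float(total))


def link_frame_pair(
    rois_t: Sequence[Roi], rois_t1: Sequence[Roi], params: LinkParams
) -> Assignment:
    cost = frame_cost_matrix(rois_t, rois_t1, params)
    return solve_lap(cost, len(rois_t), len(rois_t1))


def link_all_frames(
    rois: Sequence[Sequence[Roi]], params: LinkParams
) -> list[list[tuple[int, int]]]:
    """Chain pairwise LAP links into maximal track segments.

    Every ROI (detected, imported or user-created alike) ends up in exactly
    one segment; unlinked ROIs form singleton segments.  Segments are
    returned sorted by (first frame, first roi_id).
    """
    if len(rois) < 2:
        return [[(0, r.roi_id)] for r in (rois[0] if rois else [])]
    open_segments: dict[int, list[tuple[int, int]]] = {}  # index into rois[t] -> nodes
    finished: list[list[tuple[int, int]]] = []
    open_segments = {i: [(0, r.roi_id)] for i, r in enumerate(rois[0])}
    for t in range(len(rois) - 1):
        asg = link_frame_pair(rois[t], rois[t + 1], params)
        linked_to: dict[int, int] = {j: i for i, j in asg.pairs}
        next_open: dict[int, list[tuple[int, int]]] = {}
        carried: set[int] = set()
        for j, r in enumerate(rois[t + 1]):
            node = (t + 1, r.roi_id)
            if j in linked_to:
                seg = open_segments[linked_to[j]]
                seg.append(node)
                next_open[j] = seg
                carried.add(linked_to[j])
            else:
                next_open[j] = [node]
        for i, seg in open_segments.items():
            if i not in carried:
                finished.append(seg)
        open_segments = next_open
    finished.extend(open_segments.values())
    finished.sort(key=lambda s: (s[0][0], s[0][1]))
    return finished


def _roi_index(rois: Sequence[Sequence[Roi]]) -> dict[tuple[int, int], Roi]:
    return {(t, r.roi_id): r for t, frame in enumerate(rois) for r in frame}


def close_gaps_and_split(
    segments: list[list[tuple[int, int]]],
    rois: Sequence[Sequence[Roi]],
    params: LinkParams,
) -> Lineage:
    """Second-stage LAP turning segments into a lineage.

    Candidate events:
      * gap closing — end of segment a to start of segment b, b starting
        1..max_gap_frames+1 frames after a ends, within max_link_dist of the
        end; cost = d^2 * frame offset;
      * division — start of segment b attaches to the node of another
        segment one frame earlier (a non-terminal node within
        max_split_dist); the mother segment is cut after that node and both
        continuations become daughters.

    With splits disabled and max_gap_frames = 0 the output is the input
    segments, one track each.
    """
    index = _roi_index(rois)
    segs = [list(s) for s in segments]
    n_seg = len(segs)

    gap_cands: list[tuple[int, int, float]] = []  # (src segment, dst segment, cost)
    split_cands: list[tuple[int, int, int, float]] = []  # (src seg, node idx, dst seg, cost)
    if n_seg and (params.max_gap_frames > 0 or params.allow_splits):
        starts = [(s[0][0], index[s[0]].centroid) for s in segs]
        for a, seg_a in enumerate(segs):
            end_f, end_c = seg_a[-1][0], index[seg_a[-1]].centroid
            for b, (sf, sc) in enumerate(starts):
                if a == b:
                    continue
                off = sf - end_f
                if 1 <= off <= params.max_gap_frames + 1 and off >= 2:
                    d2 = (end_c[0] - sc[0]) ** 2 + (end_c[1] - sc[1]) ** 2
                    if d2 <= params.max_link_dist**2:
                        gap_cands.append((a, b, d2 * off))
        if params.allow_splits:
            node_at: dict[tuple[int, int], tuple[tuple[float, float], bool]] = {}
            for a, seg_a in enumerate(segs):
                for k, node in enumerate(seg_a):
                    terminal = k == len(seg_a) - 1
                    for b, (sf, sc) in enumerate(starts):
                        if a == b or terminal:
                            continue
                        if node[0] == sf - 1:
                            c = index[node].centroid
                            d2 = (c[0] - sc[0]) ** 2 + (c[1] - sc[1]) ** 2
                            if d2 <= params.max_split_dist**2:
                                split_cands.append((a, k, b, d2))

    chosen_gaps: list[tuple[int, int]] = []
    chosen_splits: list[tuple[int, int, int]] = []
    if gap_cands or split_cands:
        # rows: segment ends (gap sources) then split sources; cols: starts
        sources: list[tuple[str, int, int]] = [("end", a, -1) for a in range(n_seg)]
        split_keys = sorted({(a, k) for a, k, _, _ in split_cands})
        sources += [("mid", a, k) for a, k in split_keys]
        src_pos = {("end", a, -1): i for i, (kind, a, k) in enumerate(sources) if kind == "end"}
        src_pos.update(
            {("mid", a, k): i for i, (kind, a, k) in enumerate(sources) if kind == "mid"}
        )
        link = np.full((len(sources), n_seg), FORBIDDEN)
        for a, b, cost in gap_cands:
            link[src_pos[("end", a, -1)], b] = cost
        for a, k, b, cost in split_cands:
            link[src_pos[("mid", a, k)], b] = cost
        finite = link[np.isfinite(link)]
        alt = params.alt_cost_factor * (finite.max() if finite.size else 1.0)
        if alt == 0:
            alt = params.alt_cost_factor
        asg = solve_lap(augment_cost_matrix(link, alt), len(sources), n_seg)
        for i, b in asg.pairs:
            kind, a, k = sources[i]
            if kind == "end":
                chosen_gaps.append((a, b))
            else:
                chosen_splits.append((a, k, b))

    # --- apply events -------------------------------------------------
    # pieces: list of (nodes, parent_piece | None); segment s maps to a
    # chain of pieces after splits cut it.
    pieces: list[dict] = []
    seg_pieces: dict[int, list[int]] = {}
    for s, seg in enumerate(segs):
        pieces.append({"nodes": list(seg), "parent": None})
        seg_pieces[s] = [s]

    def piece_containing(node: tuple[int, int]) -> int:
        for pi, p in enumerate(pieces):
            if node in p["nodes"]:
                return pi
        raise KeyError(node)

    # splits first (they reference nodes, which are stable identifiers)
    for a, k, b in sorted(chosen_splits, key=lambda x: segs[x[0]][x[1]][0]):
        cut_node = segs[a][k]
        head = piece_containing(cut_node)
        nodes = pieces[head]["nodes"]
        idx = nodes.index(cut_node)
        if idx == len(nodes) - 1:
            continue  # became terminal after an earlier cut; no continuation
        tail_nodes = nodes[idx + 1 :]
        pieces[head]["nodes"] = nodes[: idx + 1]
        pieces.append({"nodes": tail_nodes, "parent": head})
        seg_pieces[a].append(len(pieces) - 1)
        start_piece = piece_containing(segs[b][0])
        pieces[start_piece]["parent"] = head

    # then gap closures: append the target chain's first piece to the
    # source chain's last piece
    for a, b in sorted(chosen_gaps, key=lambda x: segs[x[0]][-1][0]):
        src_piece = piece_containing(segs[a][-1])
        dst_piece = piece_containing(segs[b][0])
        if pieces[dst_piece]["parent"] is not None or src_piece == dst_piece:
            continue
        pieces[src_piece]["nodes"].extend(pieces[dst_piece]["nodes"])
        # re-point anything whose parent was the absorbed piece
        for p in pieces:
            if p["parent"] == dst_piece:
                p["parent"] = src_piece
        pieces[dst_piece]["nodes"] = []

    live = [pi for pi, p in enumerate(pieces) if p["nodes"]]
    order = sorted(live, key=lambda pi: (pieces[pi]["nodes"][0][0], pieces[pi]["nodes"][0][1]))
    ids = {pi: i + 1 for i, pi in enumerate(order)}
    lineage = Lineage()
    for pi in order:
        parent = pieces[pi]["parent"]
        lineage.add(
            Track(
                track_id=ids[pi],
                nodes=pieces[pi]["nodes"],
                parent_id=ids.get(parent) if parent is not None else None,
            )
        )
    return lineage


def track_rois(rois: Sequence[Sequence[Roi]], params: LinkParams | None = None) -> Lineage:
    """Full link-type tracking: stage-1 linking then stage-2 gap/split."""
    params = params or LinkParams()
    segments = link_all_frames(rois, params)
    return close_gaps_and_split(segments, rois, params)
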