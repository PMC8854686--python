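"""SEG / DET / TRA evaluation of a tracking result against ground truth.

Both sides are given as per-frame label images plus a lineage.  A
ground-truth object G in one frame is matched to a result object R iff R
covers strictly more than half of G's pixels; the rule makes the match
unique per G, while one R may absorb several G (a node split).

SEG is the mean, over all ground-truth objects in all frames, of the
Jaccard index with the matched result object (zero when unmatched).

DET and TRA are acyclic-oriented-graph-matching (AOGM) scores.  Each
lineage becomes a directed graph whose nodes are objects-in-frames and
whose edges are track links (consecutive nodes of a track, including
across closed gaps) and parent links (mother's last node to daughter's
first).  The weighted minimum number of edit operations turning the result
graph into the ground-truth graph — node splits (NS), false negatives
(FN), false positives (FP), redundant-edge deletions (ED), missing-edge
additions (EA) and edge-semantics changes (EC) — is normalized against the
cost AOGM0 of building the ground-truth graph from nothing:

    TRA = 1 - min(AOGM, AOGM0) / AOGM0

DET is identical with node operations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import LabeledMasks, Lineage


@dataclass
class AogmWeights:
    """Weights of the graph-edit operations (published evaluation defaults)."""

    w_ns: float = 5.0
    w_fn: float = 10.0
    w_fp: float = 1.0
    w_ed: float = 1.0
    w_ea: float = 1.5
    w_ec: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_ns, self.w_fn, self.w_fp, self.w_ed, self.w_ea, self.w_ec) < 0:
            raise ValueError("AOGM weights must be non-negative")


@dataclass
class FrameMatching:
    """Per-frame object correspondence.

    ``gt_to_res`` maps each matched GT label to its result label;
    ``jaccard`` carries the IoU of those pairs.
    """

    gt_labels: list[int]
    res_labels: list[int]
    gt_to_res: dict[int, int]
    jaccard: dict[int, float]


@dataclass
class MetricsReport:
    seg: float
    det: float
    tra: float
    counts: dict[str, int] = field(default_factory=dict)
    aogm: float = 0.0
    aogm0: float = 0.0
    aogm_d: float = 0.0
    aogm_d0: float = 0.0
    matchings: list[FrameMatching] = field(default_factory=list)


def match_objects(gt_frame: np.ndarray, res_frame: np.ndarray) -> FrameMatching:
    """Strict-majority matching of one frame.

    G matches R iff |G ∩ R| > 0.5 |G| (exact halves do not match).
    """
    gt_frame = np.asarray(gt_frame)
    res_frame = np.asarray(res_frame)
    if gt_frame.shape != res_frame.shape:
        raise ValueError(f"shape mismatch {gt_frame.shape} vs {res_frame.shape}")
    gt_labels = [int(v) for v in np.unique(gt_frame) if v != 0]
    res_labels = [int(v) for v in np.unique(res_frame) if v != 0]
    gt_to_res: dict[int, int] = {}
    jaccard: dict[int, float] = {}
    gt_sizes = {g: int(np.sum(gt_frame == g)) for g in gt_labels}
    res_sizes = {r: int(np.sum(res_frame == r)) for r in res_labels}
    both = (gt_frame > 0) & (res_frame > 0)
    pairs, counts = np.unique(
        np.stack([gt_frame[both], res_frame[both]]), axis=1, return_counts=True
    ) if both.any() else (np.empty((2, 0), dtype=int), np.empty(0, dtype=int))
    for (g, r), inter in zip(pairs.T, counts):
        g, r, inter = int(g), int(r), int(inter)
        if inter * 2 > gt_sizes[g]:
            gt_to_res[g] = r
            union = gt_sizes[g] + res_sizes[r] - inter
            jaccard[g] = inter / union
    return FrameMatching(gt_labels, res_labels, gt_to_res, jaccard)


def match_stacks(gt: LabeledMasks, res: LabeledMasks) -> list[FrameMatching]:
    if gt.n_frames != res.n_frames:
        raise ValueError("ground truth and result differ in frame count")
    return [match_objects(g, r) for g, r in zip(gt.frames, res.frames)]


def seg_score(gt: LabeledMasks, res: LabeledMasks) -> float:
    """Mean Jaccard over all GT objects in all frames (0 when unmatched)."""
    matchings = match_stacks(gt, res)
    total, n = 0.0, 0
    for m in matchings:
        for g in m.gt_labels:
            total += m.jaccard.get(g, 0.0)
            n += 1
    if n == 0:
        raise ValueError("ground truth contains no objects; SEG undefined")
    return total / n


def _graph_edges(
    lineage: Lineage, masks: LabeledMasks, roi_to_label: dict | None = None
) -> tuple[set[tuple[tuple[int, int], tuple[int, int]]],
           set[tuple[tuple[int, int], tuple[int, int]]]]:
    """Track-link and parent edges as ((frame, label), (frame, label)) sets.

    By default a track's label in the masks is assumed to be its track_id
    (the CTC convention); ``roi_to_label`` overrides per (frame, roi_id).
    """
    def lab(node: tuple[int, int], track_id: int) -> tuple[int, int]:
        frame, roi_id = node
        if roi_to_label is not None:
            return (frame, roi_to_label[(frame, roi_id)])
        return (frame, track_id)

    links: set = set()
    parents: set = set()
    for t in lineage.tracks.values():
        for a, b in zip(t.nodes, t.nodes[1:]):
            links.add((lab(a, t.track_id), lab(b, t.track_id)))
        if t.parent_id is not None and t.parent_id in lineage.tracks:
            p = lineage.tracks[t.parent_id]
            if p.nodes and t.nodes:
                parents.add((lab(p.nodes[-1], p.track_id), lab(t.nodes[0], t.track_id)))
    return links, parents


def aogm(
    gt_lineage: Lineage,
    gt_masks: LabeledMasks,
    res_lineage: Lineage,
    res_masks: LabeledMasks,
    weights: AogmWeights | None = None,
) -> MetricsReport:
    """Graph-edit comparison of two tracking graphs.

    Node labels in each mask stack must equal the owning track_id (the CTC
    convention used throughout this package's I/O).
    """
    w = weights or AogmWeights()
    matchings = match_stacks(gt_masks, res_masks)

    gt_nodes: set[tuple[int, int]] = set()
    res_nodes: set[tuple[int, int]] = set()
    node_match: dict[tuple[int, int], tuple[int, int]] = {}  # GT node -> result node
    ns = fn = fp = 0
    for t, m in enumerate(matchings):
        gt_here = {(t, g) for g in m.gt_labels}
        res_here = {(t, r) for r in m.res_labels}
        gt_nodes |= gt_here
        res_nodes |= res_here
        hits_per_res: dict[int, int] = {}
        for g in m.gt_labels:
            r = m.gt_to_res.get(g)
            if r is None:
                fn += 1
            else:
                node_match[(t, g)] = (t, r)
                hits_per_res[r] = hits_per_res.get(r, 0) + 1
        for r in m.res_labels:
            k = hits_per_res.get(r, 0)
            if k == 0:
                fp += 1
            elif k > 1:
                ns += k - 1

    gt_links, gt_parents = _graph_edges(gt_lineage, gt_masks)
    res_links, res_parents = _graph_edges(res_lineage, res_masks)
    for e in gt_links | gt_parents:
        for node in e:
            if node not in gt_nodes:
                raise ValueError(f"lineage references GT node {node} absent from masks")
    for e in res_links | res_parents:
        for node in e:
            if node not in res_nodes:
                raise ValueError(f"lineage references result node {node} absent from masks")

    # unique (one-to-one) node correspondences induce the comparable edges
    res_hit_count: dict[tuple[int, int], int] = {}
    for rn in node_match.values():
        res_hit_count[rn] = res_hit_count.get(rn, 0) + 1
    unique_res_to_gt = {
        rn: gn for gn, rn in node_match.items() if res_hit_count[rn] == 1
    }

    res_edges = {e: "link" for e in res_links}
    res_edges.update({e: "parent" for e in res_parents})
    gt_edges = {e: "link" for e in gt_links}
    gt_edges.update({e: "parent" for e in gt_parents})

    ed = ec = 0
    covered: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for (ra, rb), kind in sorted(res_edges.items()):
        ga, gb = unique_res_to_gt.get(ra), unique_res_to_gt.get(rb)
        if ga is None or gb is None or (ga, gb) not in gt_edges:
            ed += 1
            continue
        covered.add((ga, gb))
        if gt_edges[(ga, gb)] != kind:
            ec += 1
    ea = len(gt_edges) - len(covered)

    cost = w.w_ns * ns + w.w_fn * fn + w.w_fp * fp + w.w_ed * ed + w.w_ea * ea + w.w_ec * ec
    cost0 = w.w_fn * len(gt_nodes) + w.w_ea * len(gt_edges)
    cost_d = w.w_ns * ns + w.w_fn * fn + w.w_fp * fp
    cost_d0 = w.w_fn * len(gt_nodes)
    if cost0 == 0:
        raise ValueError("empty ground-truth graph; DET/TRA undefined")
    report = MetricsReport(
        seg=float("nan"),
        det=1.0 - min(cost_d, cost_d0) / cost_d0 if cost_d0 > 0 else float("nan"),
        tra=1.0 - min(cost, cost0) / cost0,
        counts={"NS": ns, "FN": fn, "FP": fp, "ED": ed, "EA": ea, "EC": ec},
        aogm=cost,
        aogm0=cost0,
        aogm_d=cost_d,
        aogm_d0=cost_d0,
        matchings=matchings,
    )
    return report


def det_score(gt_lineage, gt_masks, res_lineage, res_masks, weights=None) -> float:
    return aogm(gt_lineage, gt_masks, res_lineage, res_masks, weights).det


def tra_score(gt_lineage, gt_masks, res_lineage, res_masks, weights=None) -> float:
    return aogm(gt_lineage, gt_masks, res_lineage, res_masks, weights).tra


def relabel_masks_to_tracks(lineage: Lineage, masks: LabeledMasks) -> LabeledMasks:
    """Rewrite mask labels so each object carries its track's id.

    Nodes are interpreted as (frame, current mask label).  Needed after
    trajectory edits, which give the tail of a cut track a fresh id while
    the pixels still carry the old label.  Labels with no owning node are
    kept (shifted past the track-id range on collision) so spurious objects
    stay visible to the evaluation.
    """
    node_to_tid = {
        (f, rid): tid for tid, tr in lineage.tracks.items() for (f, rid) in tr.nodes
    }
    max_tid = max(lineage.tracks, default=0)
    out: list[np.ndarray] = []
    for t, frame in enumerate(masks.frames):
        new = np.zeros_like(frame)
        spare = max_tid
        for label in np.unique(frame):
            if label == 0:
                continue
            tid = node_to_tid.get((t, int(label)))
            if tid is None:
                spare += 1
                tid = spare
            new[frame == label] = tid
        out.append(new)
    return LabeledMasks(out)


def evaluate(
    gt_lineage: Lineage,
    gt_masks: LabeledMasks,
    res_lineage: Lineage,
    res_masks: LabeledMasks,
    weights: AogmWeights | None = None,
) -> MetricsReport:
    """Full report: SEG plus the AOGM-based DET and TRA."""
    report = aogm(gt_lineage, gt_masks, res_lineage, res_masks, weights)
    report.seg = seg_score(gt_masks, res_masks)
    return report
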