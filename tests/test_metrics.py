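"""Metric unit tests plus an independent AOGM re-computation.

The reference scorer below re-derives SEG/DET/TRA from the published
definitions with plain dictionaries and nested loops — no shared code with
``celltrax.metrics`` — and is used as the parity oracle on a set of small
hand-built tracking scenarios.
"""

import numpy as np
import pytest

import celltrax as ct
from celltrax.metrics import AogmWeights, match_objects


# ---------------------------------------------------------------------------
# Independent reference scorer
# ---------------------------------------------------------------------------

W = dict(ns=5.0, fn=10.0, fp=1.0, ed=1.0, ea=1.5, ec=1.0)


def reference_scores(gt_frames, gt_rows, res_frames, res_rows):
    """Straight-line AOGM computation from label images + track tables.

    ``*_rows`` are CTC-style rows (label, begin, end, parent).
    """
    def nodes_of(frames):
        out = set()
        for t, f in enumerate(frames):
            for lab in set(int(v) for v in np.unique(f)) - {0}:
                out.add((t, lab))
        return out

    def edges_of(frames, rows):
        links, parents = set(), set()
        for (lab, b, e, par) in rows:
            present = [t for t in range(b, e + 1) if (t < len(frames))
                       and np.any(frames[t] == lab)]
            for u, v in zip(present, present[1:]):
                links.add(((u, lab), (v, lab)))
            if par:
                par_present = [t for t, f in enumerate(frames) if np.any(f == par)]
                if par_present and present:
                    parents.add(((par_present[-1], par), (present[0], lab)))
        return links, parents

    gt_nodes, res_nodes = nodes_of(gt_frames), nodes_of(res_frames)
    # strict-majority matching, frame by frame
    match = {}
    for t in range(len(gt_frames)):
        gt_f, res_f = gt_frames[t], res_frames[t]
        for g in set(int(v) for v in np.unique(gt_f)) - {0}:
            gsize = np.sum(gt_f == g)
            for r in set(int(v) for v in np.unique(res_f)) - {0}:
                inter = np.sum((gt_f == g) & (res_f == r))
                if inter * 2 > gsize:
                    match[(t, g)] = (t, r)
    fn = len([n for n in gt_nodes if n not in match])
    res_hits = {}
    for rn in match.values():
        res_hits[rn] = res_hits.get(rn, 0) + 1
    fp = len([n for n in res_nodes if n not in res_hits])
    ns = sum(k - 1 for k in res_hits.values() if k > 1)

    gt_links, gt_parents = edges_of(gt_frames, gt_rows)
    res_links, res_parents = edges_of(res_frames, res_rows)
    uniq = {rn: gn for gn, rn in match.items() if res_hits[rn] == 1}
    gt_all = {e: "link" for e in gt_links}
    gt_all.update({e: "parent" for e in gt_parents})
    ed = ec = 0
    covered = set()
    for e, kind in list({e: "link" for e in res_links}.items()) + list(
        {e: "parent" for e in res_parents}.items()
    ):
        ra, rb = e
        if ra in uniq and rb in uniq and (uniq[ra], uniq[rb]) in gt_all:
            covered.add((uniq[ra], uniq[rb]))
            if gt_all[(uniq[ra], uniq[rb])] != kind:
                ec += 1
        else:
            ed += 1
    ea = len(gt_all) - len(covered)

    aogm = W["ns"] * ns + W["fn"] * fn + W["fp"] * fp + W["ed"] * ed \
        + W["ea"] * ea + W["ec"] * ec
    aogm0 = W["fn"] * len(gt_nodes) + W["ea"] * len(gt_all)
    aogm_d = W["ns"] * ns + W["fn"] * fn + W["fp"] * fp
    aogm_d0 = W["fn"] * len(gt_nodes)
    # SEG
    seg_vals = []
    for t in range(len(gt_frames)):
        gt_f, res_f = gt_frames[t], res_frames[t]
        for g in set(int(v) for v in np.unique(gt_f)) - {0}:
            if (t, g) in match:
                r = match[(t, g)][1]
                inter = np.sum((gt_f == g) & (res_f == r))
                union = np.sum(gt_f == g) + np.sum(res_f == r) - inter
                seg_vals.append(inter / union)
            else:
                seg_vals.append(0.0)
    return dict(
        seg=float(np.mean(seg_vals)),
        det=1 - min(aogm_d, aogm_d0) / aogm_d0,
        tra=1 - min(aogm, aogm0) / aogm0,
    )


def square(frames_shape, t_frames, center, side, label):
    """Stack of label frames with one square object in given frames."""
    out = []
    for t in range(frames_shape[0]):
        f = np.zeros(frames_shape[1:], dtype=np.int32)
        out.append(f)
    for t in t_frames:
        r, c = center
        out[t][r : r + side, c : c + side] = label
    return out


def combine(*stacks):
    n = len(stacks[0])
    out = [np.zeros_like(stacks[0][0]) for _ in range(n)]
    for s in stacks:
        for t in range(n):
            out[t][s[t] > 0] = s[t][s[t] > 0]
    return out


def lineage_from_rows(rows, frames):
    lin = ct.Lineage()
    for (lab, b, e, par) in rows:
        nodes = [(t, lab) for t in range(b, e + 1) if np.any(frames[t] == lab)]
        lin.add(ct.Track(lab, nodes, parent_id=par or None))
    return lin


# ---------------------------------------------------------------------------
# match_objects / seg_score
# ---------------------------------------------------------------------------


class TestMatchObjects:
    def test_identical_masks_match_one_to_one(self):
        f = np.zeros((20, 20), dtype=np.int32)
        f[2:6, 2:6] = 1
        f[10:15, 10:15] = 2
        m = match_objects(f, f)
        assert m.gt_to_res == {1: 1, 2: 2}
        assert all(j == 1.0 for j in m.jaccard.values())

    def test_exact_half_overlap_is_not_a_match(self):
        gt = np.zeros((10, 20), dtype=np.int32)
        gt[0:10, 0:10] = 1  # 100 px
        res = np.zeros((10, 20), dtype=np.int32)
        res[0:5, 0:10] = 1  # covers exactly 50
        m = match_objects(gt, res)
        assert m.gt_to_res == {}

    def test_one_result_object_capturing_two_gt(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[2:8, 2:8] = 1
        gt[2:8, 12:18] = 2
        res = np.zeros((20, 20), dtype=np.int32)
        res[2:8, 2:18] = 5
        m = match_objects(gt, res)
        assert m.gt_to_res == {1: 5, 2: 5}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            match_objects(np.zeros((5, 5), int), np.zeros((6, 5), int))


class TestSegScore:
    def test_identical_masks_score_one(self):
        f = np.zeros((20, 20), dtype=np.int32)
        f[3:9, 3:9] = 1
        masks = ct.LabeledMasks([f])
        assert ct.seg_score(masks, masks) == 1.0

    def test_partial_overlap_jaccard(self):
        # 100-px GT, 100-px result, 60 shared: J = 60/140
        gt = np.zeros((20, 30), dtype=np.int32)
        gt[0:10, 0:10] = 1
        res = np.zeros((20, 30), dtype=np.int32)
        res[0:10, 4:14] = 1
        seg = ct.seg_score(ct.LabeledMasks([gt]), ct.LabeledMasks([res]))
        assert seg == pytest.approx(60 / 140)

    def test_missed_object_contributes_zero(self):
        gt = np.zeros((20, 30), dtype=np.int32)
        gt[2:6, 2:6] = 1
        gt[10:14, 20:24] = 2
        res = np.zeros((20, 30), dtype=np.int32)
        res[2:6, 2:6] = 1
        seg = ct.seg_score(ct.LabeledMasks([gt]), ct.LabeledMasks([res]))
        assert seg == pytest.approx(0.5)

    def test_empty_ground_truth_rejected(self):
        empty = ct.LabeledMasks([np.zeros((5, 5), dtype=np.int32)])
        with pytest.raises(ValueError, match="SEG undefined"):
            ct.seg_score(empty, empty)


# ---------------------------------------------------------------------------
# AOGM / DET / TRA
# ---------------------------------------------------------------------------


def two_cell_two_frame():
    """2 cells x 2 frames: 4 nodes, 2 link edges; AOGM0 = 43."""
    gt_frames = combine(
        square((2, 20, 20), [0, 1], (2, 2), 4, 1),
        square((2, 20, 20), [0, 1], (12, 12), 4, 2),
    )
    rows = [(1, 0, 1, 0), (2, 0, 1, 0)]
    return gt_frames, rows


class TestAogm:
    def test_identical_graphs_cost_zero(self):
        frames, rows = two_cell_two_frame()
        lin = lineage_from_rows(rows, frames)
        masks = ct.LabeledMasks(frames)
        rep = ct.aogm(lin, masks, lin, masks)
        assert rep.aogm == 0.0
        assert rep.counts == {"NS": 0, "FN": 0, "FP": 0, "ED": 0, "EA": 0, "EC": 0}

    def test_missing_link_edge_costs_w_ea(self):
        frames, rows = two_cell_two_frame()
        gt_lin = lineage_from_rows(rows, frames)
        masks = ct.LabeledMasks(frames)
        # result: same masks, but cell 2's link is broken into two tracks
        res_rows = [(1, 0, 1, 0), (2, 0, 0, 0), (3, 1, 1, 0)]
        res_frames = [frames[0].copy(), frames[1].copy()]
        res_frames[1][res_frames[1] == 2] = 3
        res_lin = lineage_from_rows(res_rows, res_frames)
        rep = ct.aogm(gt_lin, masks, res_lin, ct.LabeledMasks(res_frames))
        assert rep.counts["EA"] == 1
        assert rep.aogm == pytest.approx(1.5)
        assert rep.aogm0 == pytest.approx(43.0)  # 4*10 + 2*1.5
        assert rep.tra == pytest.approx(1 - 1.5 / 43)
        assert rep.det == 1.0

    def test_missing_whole_cell_costs_fn_and_ea(self):
        frames, rows = two_cell_two_frame()
        gt_lin = lineage_from_rows(rows, frames)
        res_frames = [f.copy() for f in frames]
        for f in res_frames:
            f[f == 2] = 0
        res_lin = lineage_from_rows([(1, 0, 1, 0)], res_frames)
        rep = ct.aogm(gt_lin, ct.LabeledMasks(frames), res_lin,
                      ct.LabeledMasks(res_frames))
        assert rep.counts["FN"] == 2 and rep.counts["EA"] == 1
        assert rep.aogm == pytest.approx(21.5)

    def test_det_with_one_false_negative_node(self):
        # 4 GT nodes, result misses one: DET = 1 - 10/40
        frames, rows = two_cell_two_frame()
        gt_lin = lineage_from_rows(rows, frames)
        res_frames = [f.copy() for f in frames]
        res_frames[1][res_frames[1] == 2] = 0
        res_lin = lineage_from_rows([(1, 0, 1, 0), (2, 0, 0, 0)], res_frames)
        rep = ct.aogm(gt_lin, ct.LabeledMasks(frames), res_lin,
                      ct.LabeledMasks(res_frames))
        assert rep.det == pytest.approx(1 - 10 / 40)

    def test_perfect_result_scores_one(self, default_movie):
        _, _, masks, lineage = default_movie
        rep = ct.evaluate(lineage, masks, lineage, masks)
        assert rep.seg == rep.det == rep.tra == 1.0

    def test_empty_result_scores_zero(self):
        frames, rows = two_cell_two_frame()
        gt_lin = lineage_from_rows(rows, frames)
        empty_frames = [np.zeros_like(f) for f in frames]
        rep = ct.aogm(gt_lin, ct.LabeledMasks(frames), ct.Lineage(),
                      ct.LabeledMasks(empty_frames))
        assert rep.det == 0.0 and rep.tra == 0.0

    @pytest.mark.parametrize("error", [
        {"type": "drop_object", "frame": 1, "label": 2},
        {"type": "merge_masks", "frame": 0, "labels": (1, 2)},
        {"type": "drop_link", "track": 1, "frame": 0},
        {"type": "false_division", "child": 2, "parent": 1},
    ])
    def test_any_single_error_strictly_lowers_tra(self, error):
        gt_frames = combine(
            square((3, 30, 30), [0, 1, 2], (2, 2), 4, 1),
            square((3, 30, 30), [0, 1, 2], (12, 12), 4, 2),
            square((3, 30, 30), [0, 1, 2], (22, 22), 4, 3),
        )
        rows = [(1, 0, 2, 0), (2, 0, 2, 0), (3, 0, 2, 0)]
        gt_lin = lineage_from_rows(rows, gt_frames)
        gt_masks = ct.LabeledMasks(gt_frames)
        if error["type"] == "false_division":
            # a spurious parent edge needs a child starting after the parent
            # ends: break both tracks first, then add the bogus edge
            lin, masks, _ = ct.inject_errors(
                gt_lin, gt_masks,
                [{"type": "drop_link", "track": 1, "frame": 0},
                 {"type": "drop_link", "track": 2, "frame": 0}],
            )
            tail2 = max(lin.tracks)
            lin, masks, _ = ct.inject_errors(
                lin, masks, [{"type": "false_division", "child": tail2, "parent": 1}]
            )
        else:
            lin, masks, _ = ct.inject_errors(gt_lin, gt_masks, [error])
        masks = ct.relabel_masks_to_tracks(lin, masks)
        rep = ct.aogm(gt_lin, gt_masks, lin, masks)
        assert rep.tra < 1.0


# ---------------------------------------------------------------------------
# Oracle parity fixtures
# ---------------------------------------------------------------------------


def fixture_perfect():
    frames, rows = two_cell_two_frame()
    return frames, rows, [f.copy() for f in frames], list(rows)


def fixture_broken_link():
    frames, rows = two_cell_two_frame()
    res_frames = [f.copy() for f in frames]
    res_frames[1][res_frames[1] == 2] = 3
    return frames, rows, res_frames, [(1, 0, 1, 0), (2, 0, 0, 0), (3, 1, 1, 0)]


def fixture_missed_and_spurious():
    gt = combine(
        square((3, 25, 25), [0, 1, 2], (2, 2), 4, 1),
        square((3, 25, 25), [0, 1, 2], (12, 12), 4, 2),
    )
    res = combine(
        square((3, 25, 25), [0, 1, 2], (2, 2), 4, 1),
        square((3, 25, 25), [1, 2], (12, 12), 4, 2),      # missed in frame 0
        square((3, 25, 25), [0, 1], (18, 3), 3, 7),       # spurious object
    )
    return gt, [(1, 0, 2, 0), (2, 0, 2, 0)], res, \
        [(1, 0, 2, 0), (2, 1, 2, 0), (7, 0, 1, 0)]


def fixture_division_vs_missed_division():
    gt = combine(
        square((4, 30, 30), [0, 1], (10, 10), 4, 1),
        square((4, 30, 30), [2, 3], (4, 4), 4, 2),
        square((4, 30, 30), [2, 3], (18, 18), 4, 3),
    )
    gt_rows = [(1, 0, 1, 0), (2, 2, 3, 1), (3, 2, 3, 1)]
    # result: daughter 2 correctly parented, daughter 3 left unparented
    res = [f.copy() for f in gt]
    res_rows = [(1, 0, 1, 0), (2, 2, 3, 1), (3, 2, 3, 0)]
    return gt, gt_rows, res, res_rows


def fixture_merge_and_shift():
    gt = combine(
        square((2, 30, 30), [0, 1], (5, 5), 6, 1),
        square((2, 30, 30), [0, 1], (5, 13), 6, 2),
    )
    gt_rows = [(1, 0, 1, 0), (2, 0, 1, 0)]
    # result frame 1 merges both into one wide object (a node split)
    res = [gt[0].copy(), np.zeros_like(gt[1])]
    res[1][5:11, 5:19] = 1
    res_rows = [(1, 0, 1, 0), (2, 0, 0, 0)]
    return gt, gt_rows, res, res_rows


def fixture_wrong_edge_semantics():
    gt = combine(
        square((2, 20, 20), [0], (8, 8), 4, 1),
        square((2, 20, 20), [1], (8, 8), 4, 2),
    )
    gt_rows = [(1, 0, 0, 0), (2, 1, 1, 1)]   # 1 -> 2 is a parent edge
    res = [f.copy() for f in gt]
    res[1][res[1] == 2] = 1
    res_rows = [(1, 0, 1, 0)]                 # same edge as a track link
    return gt, gt_rows, res, res_rows


@pytest.mark.parametrize("fixture", [
    fixture_perfect,
    fixture_broken_link,
    fixture_missed_and_spurious,
    fixture_division_vs_missed_division,
    fixture_merge_and_shift,
    fixture_wrong_edge_semantics,
])
def test_parity_with_reference_scorer(fixture):
    gt_frames, gt_rows, res_frames, res_rows = fixture()
    want = reference_scores(gt_frames, gt_rows, res_frames, res_rows)
    rep = ct.evaluate(
        lineage_from_rows(gt_rows, gt_frames), ct.LabeledMasks(gt_frames),
        lineage_from_rows(res_rows, res_frames), ct.LabeledMasks(res_frames),
    )
    assert rep.seg == pytest.approx(want["seg"], abs=1e-12)
    assert rep.det == pytest.approx(want["det"], abs=1e-12)
    assert rep.tra == pytest.approx(want["tra"], abs=1e-12)
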