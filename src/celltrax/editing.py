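"""Programmatic ROI and trajectory editing.

Every operation is value-producing: it returns an edited copy and leaves
its input untouched, so a failed batch never corrupts state.  All
operations either preserve lineage validity or fail cleanly.

Edit scripts are an ordered, replayable list of commands (the batch
equivalent of interactive mouse edits) with a line-oriented text form:

    add_roi FRAME ROI_ID ROW COL [POLY r0,c0 r1,c1 ...]
    move_roi FRAME ROI_ID ROW COL
    delete_roi FRAME ROI_ID
    cut TRACK_ID FRAME
    link A_ID B_ID [division]
    set_parent CHILD_ID PARENT_ID|none
    delete_track TRACK_ID [cascade]

Lines starting with '#' are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Lineage, Roi, Track, validate_lineage


class EditError(ValueError):
    def __init__(self, message: str, index: int | None = None):
        super().__init__(message if index is None else f"command {index}: {message}")
        self.index = index


def _fresh(lineage: Lineage) -> Lineage:
    return lineage.copy()


def cut_track(lineage: Lineage, track_id: int, frame: int) -> Lineage:
    """Split a track after ``frame``.

    Part A (nodes at or before the cut) keeps the id and the parent; part B
    (later nodes) gets a new id and no parent.  Children re-point to the
    part containing the old last frame — always B — keeping every
    mother-before-daughter relation intact.
    """
    out = _fresh(lineage)
    track = out.tracks.get(track_id)
    if track is None:
        raise EditError(f"no track {track_id}")
    before = [n for n in track.nodes if n[0] <= frame]
    after = [n for n in track.nodes if n[0] > frame]
    if not before or not after:
        raise EditError(
            f"cut at frame {frame} outside track {track_id} span "
            f"[{track.start_frame}, {track.end_frame})"
        )
    new_id = out.next_track_id()
    track.nodes = before
    out.add(Track(track_id=new_id, nodes=after, parent_id=None))
    for t in out.tracks.values():
        if t.track_id not in (track_id, new_id) and t.parent_id == track_id:
            t.parent_id = new_id
    return out


def link_tracks(
    lineage: Lineage, a_id: int, b_id: int, as_division: bool = False,
    max_children: int = 2,
) -> Lineage:
    """Join two tracks: concatenation, or a mother->daughter edge.

    Concatenation absorbs b's nodes into a (b's children re-point to a);
    division makes b a daughter of a.  Both require a to end strictly
    before b begins.
    """
    out = _fresh(lineage)
    a, b = out.tracks.get(a_id), out.tracks.get(b_id)
    if a is None or b is None:
        raise EditError(f"unknown track in link {a_id}->{b_id}")
    if a.end_frame >= b.start_frame:
        raise EditError(
            f"temporal overlap: track {a_id} ends at {a.end_frame}, "
            f"track {b_id} starts at {b.start_frame}"
        )
    if as_division:
        n_children = len(out.children_of(a_id))
        if b.parent_id != a_id:
            n_children += 1
        if n_children > max_children:
            raise EditError(f"track {a_id} would exceed {max_children} children")
        b.parent_id = a_id
    else:
        if b.parent_id is not None:
            raise EditError(f"track {b_id} has a parent; cannot concatenate")
        a.nodes = a.nodes + b.nodes
        del out.tracks[b_id]
        for t in out.tracks.values():
            if t.parent_id == b_id:
                t.parent_id = a_id
    return out


def delete_track(lineage: Lineage, track_id: int, cascade: bool = False) -> Lineage:
    """Remove a track; children are orphaned (or cascaded away)."""
    out = _fresh(lineage)
    if track_id not in out.tracks:
        raise EditError(f"no track {track_id}")
    doomed = {track_id}
    if cascade:
        changed = True
        while changed:
            changed = False
            for t in out.tracks.values():
                if t.parent_id in doomed and t.track_id not in doomed:
                    doomed.add(t.track_id)
                    changed = True
    for tid in doomed:
        del out.tracks[tid]
    for t in out.tracks.values():
        if t.parent_id in doomed:
            t.parent_id = None
    return out


def delete_node(lineage: Lineage, frame: int, roi_id: int) -> Lineage:
    """Remove one (frame, roi_id) node from whichever track holds it.

    Deleting an interior node splits the track at the hole (cut
    semantics) — identity across the hole is never silently invented.
    Deleting a track's sole node removes the track.
    """
    node = (frame, roi_id)
    holder = None
    for t in lineage.tracks.values():
        if node in t.nodes:
            holder = t.track_id
            break
    if holder is None:
        raise EditError(f"no track contains node {node}")
    track = lineage.tracks[holder]
    if len(track.nodes) == 1:
        return delete_track(lineage, holder)
    if node == track.nodes[0] or node == track.nodes[-1]:
        out = _fresh(lineage)
        out.tracks[holder].nodes = [n for n in out.tracks[holder].nodes if n != node]
        return out
    out = cut_track(lineage, holder, frame - 1)  # split before the node
    # the node is now the head of the new part; drop it
    for t in out.tracks.values():
        if t.nodes and t.nodes[0] == node:
            t.nodes = t.nodes[1:]
            break
    return out


def set_parent(lineage: Lineage, child_id: int, parent_id: int | None,
               max_children: int = 2) -> Lineage:
    out = _fresh(lineage)
    child = out.tracks.get(child_id)
    if child is None:
        raise EditError(f"no track {child_id}")
    if parent_id is not None:
        parent = out.tracks.get(parent_id)
        if parent is None:
            raise EditError(f"no track {parent_id}")
        if parent.end_frame >= child.start_frame:
            raise EditError(
                f"parent {parent_id} ends at {parent.end_frame}, child starts "
                f"at {child.start_frame}"
            )
        siblings = [c for c in out.children_of(parent_id) if c != child_id]
        if len(siblings) + 1 > max_children:
            raise EditError(f"track {parent_id} would exceed {max_children} children")
    child.parent_id = parent_id
    return out


# ---------------------------------------------------------------------------
# Edit scripts
# ---------------------------------------------------------------------------


@dataclass
class EditCommand:
    op: str
    args: dict = field(default_factory=dict)


@dataclass
class EditScript:
    commands: list[EditCommand] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.commands)


def _polygon_region(vertices: list[tuple[float, float]]) -> np.ndarray:
    from skimage.draw import polygon

    arr = np.asarray(vertices, dtype=np.float64)
    rr, cc = polygon(arr[:, 0], arr[:, 1])
    if len(rr) == 0:  # degenerate polygon: rasterize the vertices themselves
        pts = np.unique(np.round(arr).astype(np.int64), axis=0)
        return pts
    return np.stack([rr, cc], axis=1).astype(np.int64)


def parse_script(text: str) -> EditScript:
    """Parse the line-oriented edit-script grammar."""
    commands: list[EditCommand] = []
    for ln, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        op, rest = parts[0], parts[1:]
        try:
            if op == "add_roi":
                args = {
                    "frame": int(rest[0]), "roi_id": int(rest[1]),
                    "row": float(rest[2]), "col": float(rest[3]),
                }
                if len(rest) > 4:
                    if rest[4] != "POLY":
                        raise ValueError(f"expected POLY, got {rest[4]}")
                    args["polygon"] = [
                        tuple(map(float, tok.split(","))) for tok in rest[5:]
                    ]
                commands.append(EditCommand("add_roi", args))
            elif op == "move_roi":
                commands.append(EditCommand("move_roi", {
                    "frame": int(rest[0]), "roi_id": int(rest[1]),
                    "row": float(rest[2]), "col": float(rest[3])}))
            elif op == "delete_roi":
                commands.append(EditCommand("delete_roi", {
                    "frame": int(rest[0]), "roi_id": int(rest[1])}))
            elif op == "cut":
                commands.append(EditCommand("cut", {
                    "track_id": int(rest[0]), "frame": int(rest[1])}))
            elif op == "link":
                commands.append(EditCommand("link", {
                    "a_id": int(rest[0]), "b_id": int(rest[1]),
                    "as_division": len(rest) > 2 and rest[2] == "division"}))
            elif op == "set_parent":
                pid = None if rest[1].lower() == "none" else int(rest[1])
                commands.append(EditCommand("set_parent", {
                    "child_id": int(rest[0]), "parent_id": pid}))
            elif op == "delete_track":
                commands.append(EditCommand("delete_track", {
                    "track_id": int(rest[0]),
                    "cascade": len(rest) > 1 and rest[1] == "cascade"}))
            else:
                raise ValueError(f"unknown command {op!r}")
        except (IndexError, ValueError) as exc:
            raise EditError(f"line {ln + 1}: {exc}") from exc
    return EditScript(commands)


def format_script(script: EditScript) -> str:
    lines = []
    for cmd in script.commands:
        a = cmd.args
        if cmd.op == "add_roi":
            line = f"add_roi {a['frame']} {a['roi_id']} {a['row']:g} {a['col']:g}"
            if a.get("polygon"):
                line += " POLY " + " ".join(f"{r:g},{c:g}" for r, c in a["polygon"])
        elif cmd.op == "move_roi":
            line = f"move_roi {a['frame']} {a['roi_id']} {a['row']:g} {a['col']:g}"
        elif cmd.op == "delete_roi":
            line = f"delete_roi {a['frame']} {a['roi_id']}"
        elif cmd.op == "cut":
            line = f"cut {a['track_id']} {a['frame']}"
        elif cmd.op == "link":
            line = f"link {a['a_id']} {a['b_id']}" + (
                " division" if a.get("as_division") else "")
        elif cmd.op == "set_parent":
            pid = a["parent_id"]
            line = f"set_parent {a['child_id']} {'none' if pid is None else pid}"
        elif cmd.op == "delete_track":
            line = f"delete_track {a['track_id']}" + (
                " cascade" if a.get("cascade") else "")
        else:
            raise EditError(f"unknown command {cmd.op!r}")
        lines.append(line)
    return "\n".join(lines) + ("\n" if lines else "")


def _copy_rois(rois: Sequence[Sequence[Roi]]) -> list[list[Roi]]:
    return [[r.copy() for r in frame] for frame in rois]


def apply_script(
    lineage: Lineage,
    rois: Sequence[Sequence[Roi]],
    script: EditScript,
    default_half: int = 5,
) -> tuple[Lineage, list[list[Roi]]]:
    """Apply a script atomically; the inputs are returned edited or not at all.

    ``add_roi`` creates the ROI (optionally with a polygon-rasterized
    region — imported freehand geometry) and a new single-node track for
    it, so subsequent ``link``/``set_parent`` commands can wire it in.
    """
    lin = lineage.copy()
    new_rois = _copy_rois(rois)

    def find_roi(frame: int, roi_id: int) -> tuple[int, Roi]:
        if not 0 <= frame < len(new_rois):
            raise EditError(f"frame {frame} out of range")
        for i, r in enumerate(new_rois[frame]):
            if r.roi_id == roi_id:
                return i, r
        raise EditError(f"no roi {roi_id} in frame {frame}")

    for idx, cmd in enumerate(script.commands):
        a = cmd.args
        try:
            if cmd.op == "add_roi":
                frame, roi_id = a["frame"], a["roi_id"]
                if not 0 <= frame < len(new_rois):
                    raise EditError(f"frame {frame} out of range")
                if any(r.roi_id == roi_id for r in new_rois[frame]):
                    raise EditError(f"roi {roi_id} already exists in frame {frame}")
                row, col = a["row"], a["col"]
                region = None
                if a.get("polygon"):
                    region = _polygon_region(a["polygon"])
                    rmin, cmin = region.min(axis=0)
                    rmax, cmax = region.max(axis=0)
                    cen = region.mean(axis=0)
                    roi = Roi(roi_id, frame, (float(cen[0]), float(cen[1])),
                              (int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
                              region=region)
                elif a.get("region") is not None:
                    region = np.asarray(a["region"], dtype=np.int64)
                    rmin, cmin = region.min(axis=0)
                    rmax, cmax = region.max(axis=0)
                    cen = region.mean(axis=0)
                    roi = Roi(roi_id, frame, (float(cen[0]), float(cen[1])),
                              (int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
                              region=region)
                else:
                    h = default_half
                    r0, c0 = int(round(row)), int(round(col))
                    roi = Roi(roi_id, frame, (row, col),
                              (r0 - h, c0 - h, r0 + h + 1, c0 + h + 1))
                new_rois[frame].append(roi)
                lin.add(Track(track_id=lin.next_track_id(), nodes=[(frame, roi_id)]))
            elif cmd.op == "move_roi":
                _, roi = find_roi(a["frame"], a["roi_id"])
                dr = a["row"] - roi.centroid[0]
                dc = a["col"] - roi.centroid[1]
                roi.centroid = (a["row"], a["col"])
                r0, c0, r1, c1 = roi.bbox
                roi.bbox = (int(round(r0 + dr)), int(round(c0 + dc)),
                            int(round(r1 + dr)), int(round(c1 + dc)))
                if roi.region is not None:
                    roi.region = roi.region + np.array(
                        [int(round(dr)), int(round(dc))], dtype=np.int64)
            elif cmd.op == "delete_roi":
                i, _ = find_roi(a["frame"], a["roi_id"])
                del new_rois[a["frame"]][i]
                node = (a["frame"], a["roi_id"])
                if any(node in t.nodes for t in lin.tracks.values()):
                    lin = delete_node(lin, *node)
            elif cmd.op == "cut":
                lin = cut_track(lin, a["track_id"], a["frame"])
            elif cmd.op == "link":
                lin = link_tracks(lin, a["a_id"], a["b_id"], a.get("as_division", False))
            elif cmd.op == "set_parent":
                lin = set_parent(lin, a["child_id"], a["parent_id"])
            elif cmd.op == "delete_track":
                lin = delete_track(lin, a["track_id"], a.get("cascade", False))
            else:
                raise EditError(f"unknown command {cmd.op!r}")
        except EditError as exc:
            raise EditError(str(exc), index=idx) from exc

    problems = validate_lineage(lin)
    if problems:
        raise EditError(f"script leaves lineage invalid: {problems}")
    return lin, new_rois
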