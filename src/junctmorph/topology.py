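"""Cell segmentation, tricellular-corner detection and interface extraction.

A *corner* is a point where three or more cells meet; an *interface* is the
corner-to-corner skeleton path separating two neighbouring cells.  Cells are
the 4-connected components of the skeleton's complement (the skeleton itself
is 8-connected, so 4-connectivity for cells prevents leaks through diagonal
skeleton steps).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .edge_map import SkeletonMap
from .image_io import BinaryMask

__all__ = [
    "CellLabelMap",
    "Corner",
    "InterfaceRecord",
    "label_cells",
    "detect_corners",
    "adjust_corners",
    "extract_interfaces",
    "classify_junctions",
]

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class CellLabelMap:
    """Cells labelled 1..n_cells; 0 marks the skeleton itself."""

    pixels: np.ndarray
    n_cells: int
    border_labels: frozenset

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Corner:
    """A tricellular meeting point delimiting interfaces."""

    id: int
    position: tuple[int, int]
    adjacent_cells: frozenset
    source: str = "auto"


@dataclass(frozen=True)
class InterfaceRecord:
    """Ordered corner-to-corner skeleton path between two cells."""

    id: int
    corner_a: int
    corner_b: int
    path: tuple[tuple[int, int], ...]
    cell_pair: tuple[int, int]
    junction_class: str = "untyped"
    flags: tuple[str, ...] = ()

    @property
    def canonical_key(self):
        return (
            min(self.corner_a, self.corner_b),
            max(self.corner_a, self.corner_b),
            self.cell_pair,
        )


def label_cells(skeleton: SkeletonMap, border_margin: int = 2) -> CellLabelMap:
    """Label the 4-connected components of the skeleton complement.

    Components with any pixel within ``border_margin`` of the image border
    are flagged so downstream steps can exclude cells that are not fully
    surrounded by neighbours.
    """
    lab, n = ndimage.label(~skeleton.pixels, structure=_STRUCT4)
    border = set()
    m = max(1, int(border_margin))
    for sl in (
        lab[:m, :], lab[-m:, :], lab[:, :m], lab[:, -m:]
    ):
        border.update(np.unique(sl).tolist())
    border.discard(0)
    return CellLabelMap(lab.astype(np.int32), int(n), frozenset(border))


def _distinct_label_stack(labels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel count of distinct nonzero labels within Chebyshev ``radius``."""
    h, w = labels.shape
    pad = np.zeros((h + 2 * radius, w + 2 * radius), dtype=labels.dtype)
    pad[radius : radius + h, radius : radius + w] = labels
    k = 2 * radius + 1
    planes = np.empty((k * k, h, w), dtype=labels.dtype)
    i = 0
    for dr in range(k):
        for dc in range(k):
            planes[i] = pad[dr : dr + h, dc : dc + w]
            i += 1
    planes.sort(axis=0)
    distinct = (planes[0] > 0).astype(np.int32)
    distinct += ((planes[1:] != planes[:-1]) & (planes[1:] > 0)).sum(axis=0)
    return distinct


def _labels_near(labels: np.ndarray, r: int, c: int, radius: int) -> set:
    h, w = labels.shape
    patch = labels[
        max(0, r - radius) : min(h, r + radius + 1),
        max(0, c - radius) : min(w, c + radius + 1),
    ]
    vals = set(np.unique(patch).tolist())
    vals.discard(0)
    return vals


def detect_corners(
    skeleton: SkeletonMap, labels: CellLabelMap, radius: int = 2
) -> list[Corner]:
    """Find skeleton pixels where >= 3 distinct cells meet.

    A skeleton pixel is a candidate when at least three distinct nonzero
    cell labels occur within Chebyshev distance ``radius``.  Candidates
    within ``2 * radius`` of each other merge into one corner placed at
    their centroid snapped to the nearest skeleton pixel (ties to the
    smallest ``(row, col)``); a meeting point of four or more cells is a
    single corner.  Corners are sorted by position and numbered from 1.
    """
    if skeleton.shape != labels.shape:
        raise ValueError("skeleton and label map shapes differ")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    distinct = _distinct_label_stack(labels.pixels, radius)
    cand = skeleton.pixels & (distinct >= 3)
    if not cand.any():
        return []
    fat = ndimage.binary_dilation(cand, np.ones((2 * radius + 1,) * 2, bool))
    groups = skmeasure.label(fat, connectivity=2)
    sk_pts = np.argwhere(skeleton.pixels)
    corners = []
    for gid in range(1, int(groups.max()) + 1):
        pts = np.argwhere(cand & (groups == gid))
        centroid = pts.mean(axis=0)
        d2 = ((sk_pts - centroid) ** 2).sum(axis=1)
        # argmin over lexicographically sorted points -> deterministic ties
        order = np.lexsort((sk_pts[:, 1], sk_pts[:, 0]))
        best = order[int(np.argmin(d2[order]))]
        pos = (int(sk_pts[best, 0]), int(sk_pts[best, 1]))
        adjacent = set()
        for r, c in map(tuple, pts):
            adjacent |= _labels_near(labels.pixels, r, c, radius)
        adjacent |= _labels_near(labels.pixels, pos[0], pos[1], radius)
        corners.append((pos, frozenset(adjacent)))
    corners.sort(key=lambda t: t[0])
    return [
        Corner(i + 1, pos, adj, "auto")
        for i, (pos, adj) in enumerate(corners)
    ]


def adjust_corners(
    corners: list[Corner],
    additions: list[tuple[int, int]],
    removals: list[int],
    skeleton: SkeletonMap,
    labels: CellLabelMap,
    radius: int = 2,
) -> list[Corner]:
    """Apply manual corner corrections.

    Added corners must lie on the skeleton; their adjacent cells are read
    from the label map and may number fewer than three.  Numbering of the
    surviving corners is preserved; additions get fresh ids.
    """
    known = {c.id for c in corners}
    for rid in removals:
        if rid not in known:
            raise ValueError(f"unknown corner id {rid} in removals")
    kept = [c for c in corners if c.id not in set(removals)]
    next_id = max((c.id for c in corners), default=0) + 1
    out = list(kept)
    for r, c in additions:
        r, c = int(r), int(c)
        if not (0 <= r < skeleton.shape[0] and 0 <= c < skeleton.shape[1]):
            raise ValueError(f"manual corner ({r}, {c}) out of bounds")
        if not skeleton.pixels[r, c]:
            raise ValueError(f"manual corner ({r}, {c}) is not on the skeleton")
        adj = frozenset(_labels_near(labels.pixels, r, c, radius))
        out.append(Corner(next_id, (r, c), adj, "manual"))
        next_id += 1
    return out


def _segment_endpoints(seg_pts: set) -> tuple[list, int]:
    """Endpoints (pixels with <= 1 in-segment neighbour) and max degree."""
    endpoints = []
    max_deg = 0
    for r, c in sorted(seg_pts):
        deg = sum((r + dr, c + dc) in seg_pts for dr, dc in _N8)
        max_deg = max(max_deg, deg)
        if deg <= 1:
            endpoints.append((r, c))
    return endpoints, max_deg


def _bfs_path(allowed: set, start, goal):
    if start == goal:
        return [start]
    parent = {start: None}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for dr, dc in _N8:
            nxt = (cur[0] + dr, cur[1] + dc)
            if nxt in allowed and nxt not in parent:
                parent[nxt] = cur
                if nxt == goal:
                    path = [nxt]
                    while parent[path[-1]] is not None:
                        path.append(parent[path[-1]])
                    return path[::-1]
                queue.append(nxt)
    return None


def _flanking_cells(path, labels: np.ndarray):
    """The two cell labels most frequently 4-adjacent to the path.

    An open path floating inside a single cell (e.g. drawn between two
    manual corners) is flanked by that cell on both sides and yields a
    repeated pair.
    """
    h, w = labels.shape
    counts = Counter()
    for r, c in path:
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                counts[int(labels[rr, cc])] += 1
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if not top:
        return None
    if len(top) == 1:
        return (top[0][0], top[0][0])
    pair = sorted((top[0][0], top[1][0]))
    return (pair[0], pair[1])


def extract_interfaces(
    skeleton: SkeletonMap,
    corners: list[Corner],
    labels: CellLabelMap,
    min_length: int = 5,
    exclude_border: bool = True,
    zone_radius: int = 2,
    log: list | None = None,
) -> list[InterfaceRecord]:
    """Split the skeleton into corner-to-corner interface records.

    The skeleton is treated as a graph whose nodes are corners and whose
    edges are corner-free paths.  Each surviving path becomes one
    :class:`InterfaceRecord` with its flanking cell pair.  Duplicates
    (same corner pair and cell pair) are removed; dangling paths, loops,
    paths shorter than ``min_length`` pixels and — by default — interfaces
    touching a border-flagged cell are excluded and reported in ``log``.
    """
    if skeleton.shape != labels.shape:
        raise ValueError("skeleton and label map shapes differ")

    def note(reason, detail):
        if log is not None:
            log.append({"stage": "extract_interfaces", "reason": reason,
                        "detail": detail})

    sk = skeleton.pixels
    pos_of = {c.id: c.position for c in corners}
    # Assign each skeleton pixel near a corner to its nearest corner (zone).
    zone_owner: dict = {}
    for corner in sorted(corners, key=lambda c: c.id):
        cr, cc = corner.position
        for dr in range(-zone_radius, zone_radius + 1):
            for dc in range(-zone_radius, zone_radius + 1):
                r, c = cr + dr, cc + dc
                if not (0 <= r < sk.shape[0] and 0 <= c < sk.shape[1]):
                    continue
                if not sk[r, c]:
                    continue
                d2 = (r - cr) ** 2 + (c - cc) ** 2
                prev = zone_owner.get((r, c))
                if prev is None or (d2, corner.id) < prev:
                    zone_owner[(r, c)] = (d2, corner.id)
    zone_pixels: dict = {}
    for pix, (_, cid) in zone_owner.items():
        zone_pixels.setdefault(cid, set()).add(pix)

    seg_mask = sk.copy()
    for pix in zone_owner:
        seg_mask[pix] = False
    seg_lab = skmeasure.label(seg_mask, connectivity=2)

    found = []
    for sid in range(1, int(seg_lab.max()) + 1):
        pts = set(map(tuple, np.argwhere(seg_lab == sid)))
        endpoints, max_deg = _segment_endpoints(pts)
        if max_deg >= 3 or len(endpoints) > 2:
            note("complex", f"segment of {len(pts)} px has internal branching")
            continue
        if not endpoints:
            note("loop", f"closed loop of {len(pts)} px without corners")
            continue
        if len(endpoints) == 1:
            endpoints = [endpoints[0], endpoints[0]]
        end_corners = []
        for er, ec in endpoints:
            owners = []
            for dr, dc in _N8:
                q = (er + dr, ec + dc)
                if q in zone_owner:
                    owners.append(zone_owner[q])
            if owners:
                end_corners.append(min(owners)[1])
            else:
                end_corners.append(None)
        if endpoints[0] == endpoints[1]:
            # single-pixel segment: collect all adjacent corners
            owners = sorted(
                {zone_owner[(endpoints[0][0] + dr, endpoints[0][1] + dc)][1]
                 for dr, dc in _N8
                 if (endpoints[0][0] + dr, endpoints[0][1] + dc) in zone_owner}
            )
            if len(owners) >= 2:
                end_corners = [owners[0], owners[1]]
        ca, cb = end_corners
        if ca is None or cb is None:
            note("dangling", f"segment of {len(pts)} px ends off any corner")
            continue
        if ca == cb:
            note("self_loop", f"segment returns to corner {ca}")
            continue
        allowed = pts | zone_pixels.get(ca, set()) | zone_pixels.get(cb, set())
        path = _bfs_path(allowed, pos_of[ca], pos_of[cb])
        if path is None:
            note("disconnected", f"no skeleton path between corners {ca}, {cb}")
            continue
        pair = _flanking_cells(path, labels.pixels)
        if pair is None:
            note("no_cell_pair", f"corners {ca}-{cb}: fewer than 2 flanking cells")
            continue
        found.append((min(ca, cb), max(ca, cb), pair, tuple(path)))

    found.sort(key=lambda t: (t[0], t[1], t[2]))
    records = []
    seen = set()
    for ca, cb, pair, path in found:
        key = (ca, cb, pair)
        if key in seen:
            note("duplicate", f"corners {ca}-{cb}, cells {pair}")
            continue
        seen.add(key)
        if len(path) < min_length:
            note("degenerate", f"corners {ca}-{cb}: path of {len(path)} px")
            continue
        if exclude_border and (
            pair[0] in labels.border_labels or pair[1] in labels.border_labels
        ):
            note("border", f"corners {ca}-{cb}, cells {pair}")
            continue
        records.append(
            InterfaceRecord(len(records) + 1, ca, cb, path, pair)
        )
    return records


def classify_junctions(
    interfaces: list[InterfaceRecord],
    labels: CellLabelMap,
    expression_mask: BinaryMask,
    min_fraction: float = 0.5,
) -> list[InterfaceRecord]:
    """Label each junction ee / en / control from an expression mask.

    A cell counts as expressing when at least ``min_fraction`` of its pixels
    are mask-positive (the boundary case classifies as expressing).
    """
    if expression_mask.shape != labels.shape:
        raise ValueError("expression mask shape differs from label map")
    lab = labels.pixels.ravel()
    pos = expression_mask.pixels.ravel().astype(np.float64)
    totals = np.bincount(lab, minlength=labels.n_cells + 1)
    hits = np.bincount(lab, weights=pos, minlength=labels.n_cells + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, hits / np.maximum(totals, 1), 0.0)
    expressing = {
        int(l) for l in range(1, labels.n_cells + 1)
        if frac[l] >= min_fraction
    }
    out = []
    for rec in interfaces:
        a, b = rec.cell_pair
        n = (a in expressing) + (b in expressing)
        cls = ("control", "en", "ee")[n]
        out.append(replace(rec, junction_class=cls))
    return out
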