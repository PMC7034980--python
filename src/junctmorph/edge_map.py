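"""Boundary detection, skeletonization, scripted edits and ridge refinement.

The cell outline is represented as a :class:`SkeletonMap`: a 1-pixel-wide,
8-connected binary network over the junction-marker image.  Manual GUI-style
corrections are replaced by a declarative :class:`EditScript` so that the
semi-automated workflow is reproducible and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .image_io import BinaryMask, RasterImage

__all__ = [
    "SkeletonMap",
    "Edit",
    "EditScript",
    "detect_edges",
    "skeletonize",
    "apply_edits",
    "refine_skeleton",
    "load_edit_script",
    "save_edit_script",
]

PROV_AUTO = 0
PROV_ADDED = 1
PROV_REFINED = 2

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonMap:
    """1-pixel-wide binary boundary network with per-pixel provenance."""

    pixels: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("skeleton must be 2-D")
        if self.provenance is None:
            self.provenance = np.zeros(self.pixels.shape, dtype=np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
            if self.provenance.shape != self.pixels.shape:
                raise ValueError("provenance shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def n_components(self) -> int:
        return int(skmeasure.label(self.pixels, connectivity=2).max())

    def is_one_pixel_wide(self) -> bool:
        """Standard thinning criterion: no 2x2 block is entirely set."""
        s = self.pixels
        full = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        return not bool(full.any())


@dataclass(frozen=True)
class Edit:
    """One scripted correction: draw (``add``) or erase (``remove``)."""

    action: str
    polyline: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.action not in ("add", "remove"):
            raise ValueError(f"unknown edit action {self.action!r}")
        pts = tuple((int(r), int(c)) for r, c in self.polyline)
        minimum = 2 if self.action == "add" else 1
        if len(pts) < minimum:
            raise ValueError(
                f"{self.action} edit needs >= {minimum} polyline points"
            )
        object.__setattr__(self, "polyline", pts)


@dataclass(frozen=True)
class EditScript:
    """Ordered list of edits standing in for interactive skeleton editing."""

    edits: tuple[Edit, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "edits", tuple(self.edits))

    def __iter__(self):
        return iter(self.edits)

    def __len__(self):
        return len(self.edits)

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for i, edit in enumerate(self.edits):
            for r, c in edit.polyline:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(
                        f"edit {i}: coordinate ({r}, {c}) outside {h}x{w}"
                    )


def load_edit_script(path) -> EditScript:
    """Parse the structured-text edit format.

    One edit per line: ``add: r,c r,c ...`` or ``remove: r,c ...``.
    Blank lines and ``#`` comments are ignored.
    """
    edits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            action, _, rest = line.partition(":")
            pts = tuple(
                tuple(int(v) for v in tok.split(","))
                for tok in rest.split()
            )
            edits.append(Edit(action.strip(), pts))
    return EditScript(tuple(edits))


def save_edit_script(path, script: EditScript) -> None:
    with open(path, "w") as fh:
        for edit in script:
            pts = " ".join(f"{r},{c}" for r, c in edit.polyline)
            fh.write(f"{edit.action}: {pts}\n")


def detect_edges(
    image: RasterImage,
    blur_radius: float = 1.0,
    local_window: int = 15,
    binarize_threshold: float = 1.2,
    unsharp_amount: float = 1.0,
    ridge_fraction: float = 0.6,
    min_object_size: int = 8,
) -> BinaryMask:
    """Binary edge map of bright boundary ridges.

    The marker image is blurred (noise suppression), sharpened with an
    unsharp mask (ridge embossing), then binarized by comparing each pixel
    against the mean of its ``local_window`` neighbourhood scaled by
    ``binarize_threshold``.  A uniform image therefore yields an empty map.
    Pixels passing the mean test but falling below ``ridge_fraction`` of
    the local 5x5 maximum (blur shoulders flanking a ridge) are suppressed,
    and speckles smaller than ``min_object_size`` pixels are dropped.
    """
    if blur_radius < 0:
        raise ValueError("blur_radius must be >= 0")
    if local_window < 3 or local_window % 2 == 0:
        raise ValueError("local_window must be odd and >= 3")
    img = image.as_float()
    base = ndimage.gaussian_filter(img, blur_radius) if blur_radius > 0 else img
    wide = ndimage.gaussian_filter(base, max(2.0 * blur_radius, 1.0))
    emboss = base + unsharp_amount * (base - wide)
    # neighbourhood average taken on the blurred image: the unsharp ripple
    # is zero-mean and would otherwise bias the local reference downward
    local_mean = ndimage.uniform_filter(base, size=local_window)
    mask = emboss > local_mean * binarize_threshold
    if ridge_fraction > 0:
        ridge_max = ndimage.maximum_filter(emboss, size=5, mode="nearest")
        mask &= emboss >= ridge_fraction * ridge_max
    if min_object_size > 1:
        mask = skmorph.remove_small_objects(
            mask, max_size=min_object_size - 1, connectivity=2
        )
    return BinaryMask(mask)


def _neighbor_count(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.convolve(
        sk.astype(np.uint8), kernel, mode="constant", cval=0
    )


def _neighbors(sk: np.ndarray, r: int, c: int):
    h, w = sk.shape
    for dr, dc in _N8:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
            yield rr, cc


def _remove_isolated(sk: np.ndarray) -> np.ndarray:
    out = sk.copy()
    out[_neighbor_count(sk) == 0] = False
    return out


def _prune_spurs(sk: np.ndarray, prune_len: int) -> np.ndarray:
    """Delete terminal branches of <= ``prune_len`` pixels hanging off
    branch points.  Free-standing segments (no branch point) are kept."""
    if prune_len <= 0:
        return sk
    sk = sk.copy()
    for _ in range(10):
        nc = _neighbor_count(sk)
        endpoints = np.argwhere(sk & (nc == 1))
        removed = False
        for r, c in map(tuple, endpoints):
            if not sk[r, c]:
                continue
            chain = [(r, c)]
            prev = None
            cur = (r, c)
            while len(chain) <= prune_len:
                nbrs = [q for q in _neighbors(sk, *cur) if q != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if nc[nxt] >= 3:
                    # spur attached to a branch point: delete it, plus the
                    # attachment pixel itself when it became redundant
                    for p in chain:
                        sk[p] = False
                    if _is_locally_removable(sk, *nxt):
                        sk[nxt] = False
                    removed = True
                    break
                chain.append(nxt)
                prev, cur = cur, nxt
        if not removed:
            break
        sk = _remove_isolated(sk)
    return sk


def _enforce_thin(sk: np.ndarray) -> np.ndarray:
    """Remove redundant pixels so that no 2x2 block is fully set, keeping
    local 8-connectivity intact.  Deterministic scan order."""
    sk = sk.copy()
    h, w = sk.shape
    for _ in range(8):
        full = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        blocks = np.argwhere(full)
        if len(blocks) == 0:
            break
        changed = False
        for r, c in map(tuple, blocks):
            block = [(r, c), (r + 1, c), (r, c + 1), (r + 1, c + 1)]
            if not all(sk[p] for p in block):
                continue
            for pr, pc in reversed(block):
                if _is_locally_removable(sk, pr, pc):
                    sk[pr, pc] = False
                    changed = True
                    break
            else:
                # X-crossing: every block pixel carries its own arm, so no
                # pixel is simple.  Remove one and bridge any arm that
                # loses contact with the remaining block pixels.
                p = block[3]
                arms = [q for q in _neighbors(sk, *p) if q not in block]
                sk[p] = False
                rest = [q for q in block if sk[q]]
                for n in arms:
                    if any(
                        max(abs(n[0] - q[0]), abs(n[1] - q[1])) <= 1
                        for q in rest
                    ):
                        continue
                    for q in sorted(
                        (n[0] + dr, n[1] + dc)
                        for dr in (-1, 0, 1)
                        for dc in (-1, 0, 1)
                    ):
                        if (
                            q != p
                            and 0 <= q[0] < h and 0 <= q[1] < w
                            and not sk[q]
                            and any(
                                max(abs(q[0] - b[0]), abs(q[1] - b[1])) <= 1
                                for b in rest
                            )
                        ):
                            sk[q] = True
                            break
                changed = True
        if not changed:
            break
    return sk


def _is_locally_removable(sk: np.ndarray, r: int, c: int) -> bool:
    """True when deleting (r, c) keeps its neighbours 8-connected within the
    surrounding 5x5 patch (a conservative simple-point test)."""
    h, w = sk.shape
    nbrs = [q for q in _neighbors(sk, r, c)]
    if len(nbrs) <= 1:
        return False
    r0, c0 = max(0, r - 2), max(0, c - 2)
    patch = sk[r0 : min(h, r + 3), c0 : min(w, c + 3)].copy()
    patch[r - r0, c - c0] = False
    lab = skmeasure.label(patch, connectivity=2)
    ids = {lab[q[0] - r0, q[1] - c0] for q in nbrs}
    return len(ids) == 1 and 0 not in ids


def skeletonize(edges: BinaryMask, prune_len: int = 5) -> SkeletonMap:
    """Thin a binary edge map to a 1-pixel-wide, 8-connected skeleton.

    Isolated pixels are removed and terminal spurs shorter than
    ``prune_len`` pixels (thinning artifacts) are pruned.
    """
    sk = skmorph.skeletonize(edges.pixels)
    sk = _remove_isolated(sk)
    sk = _prune_spurs(sk, prune_len)
    sk = _enforce_thin(sk)
    return SkeletonMap(sk)


def apply_edits(skeleton: SkeletonMap, edits: EditScript) -> SkeletonMap:
    """Apply scripted corrections and re-thin to 1-pixel width.

    ``add`` edits rasterize the polyline with 8-connected line drawing;
    ``remove`` edits clear skeleton pixels within Chebyshev distance 1 of
    the rasterized polyline.
    """
    edits.validate(skeleton.shape)
    if len(edits) == 0:
        return SkeletonMap(skeleton.pixels.copy(), skeleton.provenance.copy())
    sk = skeleton.pixels.copy()
    prov = skeleton.provenance.copy()
    for edit in edits:
        if edit.action == "add":
            for (r0, c0), (r1, c1) in zip(edit.polyline, edit.polyline[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                sk[rr, cc] = True
                prov[rr, cc] = PROV_ADDED
        else:
            erase = np.zeros(sk.shape, dtype=bool)
            pts = edit.polyline
            if len(pts) == 1:
                erase[pts[0]] = True
            for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                erase[rr, cc] = True
            erase = ndimage.binary_dilation(erase, np.ones((3, 3), bool))
            sk[erase] = False
    sk = _enforce_thin(skmorph.skeletonize(sk))
    return SkeletonMap(sk, prov)


def refine_skeleton(
    skeleton: SkeletonMap, image: RasterImage, search_radius: int = 2
) -> SkeletonMap:
    """Snap the skeleton onto the local intensity ridge.

    Each skeleton pixel moves to the maximum-intensity pixel within its
    ``(2r+1)^2`` neighbourhood; a pixel that already attains the window
    maximum stays put (so a ridge-aligned or constant-intensity skeleton is a
    fixed point), otherwise ties go to the smallest ``(row, col)``.  The
    moved point set is dilated and re-thinned; if that would change the
    connected-component count the original skeleton is returned unchanged.
    """
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    img = image.as_float()
    h, w = img.shape
    size = 2 * search_radius + 1
    window_max = ndimage.maximum_filter(img, size=size, mode="nearest")
    moved = np.zeros_like(skeleton.pixels)
    any_moved = False
    for r, c in map(tuple, np.argwhere(skeleton.pixels)):
        if img[r, c] >= window_max[r, c]:
            moved[r, c] = True
            continue
        r0, c0 = max(0, r - search_radius), max(0, c - search_radius)
        patch = img[r0 : min(h, r + search_radius + 1),
                    c0 : min(w, c + search_radius + 1)]
        pr, pc = np.unravel_index(int(np.argmax(patch)), patch.shape)
        moved[r0 + pr, c0 + pc] = True
        any_moved = True
    if not any_moved:
        return SkeletonMap(skeleton.pixels.copy(), skeleton.provenance.copy())
    target = skeleton.n_components()
    for dil in (3, 5):
        fat = ndimage.binary_dilation(moved, np.ones((dil, dil), bool))
        thin = _enforce_thin(skmorph.skeletonize(fat))
        thin = _prune_spurs(thin, 3)
        if int(skmeasure.label(thin, connectivity=2).max()) == target:
            prov = np.where(
                thin & ~skeleton.pixels, PROV_REFINED, skeleton.provenance
            ).astype(np.uint8)
            return SkeletonMap(thin, prov)
    return SkeletonMap(skeleton.pixels.copy(), skeleton.provenance.copy())
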