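"""Synthetic epithelial-monolayer scenes with exact ground truth.

Monolayers are modelled as the Voronoi tessellation of a jittered hexagonal
lattice of cell centres: this yields exactly the tricellular-corner topology
the measurement pipeline assumes, with analytically known vertices and
edges, while the jitter keeps vertices well separated so corner counts are
recoverable at raster scale.  Each cell-cell edge is rendered as a staining
band of controllable width, intensity, sinusoidal (or triangular)
undulation and fragmentation; cytoplasm is filled at a background level and
Gaussian read-out noise is added last.

Ground truth describes the *rendered* scene exactly: the true boundary of
an interface is the digitized pixel polyline actually painted, and
``contour_px`` is the arc length of that polyline.  The continuous length
of the ideal geometric scaffold (Voronoi segment plus undulation) is kept
alongside as ``scaffold_length``; it differs from the rendered length by
ordinary raster chord quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .image_io import BinaryMask, RasterImage, compute_psnr
from .metrics import SQRT2

__all__ = [
    "SceneSpec",
    "Marker2Spec",
    "TruthInterface",
    "SceneGroundTruth",
    "Scene",
    "preset",
    "generate_monolayer",
    "generate_grid",
    "degrade_scene",
]


@dataclass(frozen=True)
class Marker2Spec:
    """Photometry of an optional second, co-registered marker channel."""

    staining_width: float = 2.0
    staining_intensity: float = 160.0
    coverage_fraction: float = 0.6
    fragment_length: float = 10.0
    seed_offset: int = 101


@dataclass(frozen=True)
class SceneSpec:
    """All controllable properties of a synthetic monolayer scene."""

    height: int = 256
    width: int = 256
    n_cells: int = 12
    seed: int = 0
    staining_width: float = 3.0
    staining_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sigma: float = 0.0
    coverage_fraction: float = 1.0
    fragment_length: float = 30.0
    undulation_amplitude: float = 0.0
    undulation_period: float = 30.0
    undulation_wave: str = "sine"
    jitter: float = 0.15
    bit_depth: int = 8
    expression_fraction: float = 0.0
    marker2: Marker2Spec | None = None

    def __post_init__(self):
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must lie in [0, 1]")
        if self.staining_width < 1:
            raise ValueError("staining_width must be >= 1 pixel")
        max_value = 2**self.bit_depth - 1
        if not (0 <= self.background_intensity <= max_value):
            raise ValueError("background_intensity outside bit depth")
        if not (0 <= self.staining_intensity <= max_value):
            raise ValueError("staining_intensity outside bit depth")
        if self.undulation_wave not in ("sine", "triangle"):
            raise ValueError("undulation_wave must be 'sine' or 'triangle'")


_PRESETS = {
    "linear_epithelial": dict(
        coverage_fraction=1.0, undulation_amplitude=0.0
    ),
    "undulated": dict(undulation_amplitude=2.5, undulation_period=40.0),
    "zigzag_endothelial": dict(
        undulation_amplitude=3.0,
        undulation_period=24.0,
        undulation_wave="triangle",
    ),
    "dotted_disc": dict(
        coverage_fraction=0.4, fragment_length=8.0, staining_width=2.0
    ),
    # Fingerprint presets: a mild control phenotype and two perturbations
    # with programmed effect directions (see docs/methods.md).
    "control_epithelial": dict(
        coverage_fraction=0.9,
        staining_intensity=180.0,
        undulation_amplitude=0.8,
        undulation_period=40.0,
        noise_sigma=6.0,
    ),
    "rac1_like": dict(
        coverage_fraction=0.55,
        staining_intensity=240.0,
        undulation_amplitude=0.8,
        undulation_period=40.0,
        noise_sigma=6.0,
    ),
    "ras_like": dict(
        coverage_fraction=0.55,
        staining_intensity=140.0,
        undulation_amplitude=2.5,
        undulation_period=40.0,
        noise_sigma=6.0,
    ),
}


def preset(name: str, **overrides) -> SceneSpec:
    """A named phenotype preset, optionally overridden field by field."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SceneSpec(**params)


@dataclass(frozen=True)
class TruthInterface:
    """Exact description of one rendered cell-cell interface."""

    id: int
    cells: tuple[int, int]
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    path: tuple[tuple[int, int], ...]
    contour_px: float
    scaffold_length: float
    coverage: float
    covered_intervals: tuple[tuple[float, float], ...]
    covered_runs_px: tuple[tuple[int, int], ...]
    marker_pixel_count: int
    marker_total_intensity: float
    interior: bool


@dataclass(frozen=True)
class SceneGroundTruth:
    seeds: np.ndarray | None
    region_labels: np.ndarray
    interior_cells: frozenset
    interfaces: tuple[TruthInterface, ...]
    skeleton: np.ndarray
    clean: np.ndarray
    expressing: frozenset

    def interior_interfaces(self) -> list[TruthInterface]:
        return [t for t in self.interfaces if t.interior]

    def interior_corner_positions(self) -> list[tuple[float, float]]:
        """Distinct endpoints of interior interfaces (the true vertices)."""
        pts = {}
        for t in self.interior_interfaces():
            for p in t.endpoints:
                key = (round(p[0], 3), round(p[1], 3))
                pts[key] = p
        return sorted(pts.values())


@dataclass(frozen=True)
class Scene:
    image: RasterImage
    truth: SceneGroundTruth
    marker2: RasterImage | None = None
    expression_mask: BinaryMask | None = None


# ---------------------------------------------------------------------------
# geometry helpers


def _hex_seeds(h, w, n_cells, jitter, rng):
    spacing = math.sqrt(h * w / (max(n_cells, 2) * math.sqrt(3) / 2.0))
    dy = spacing * math.sqrt(3) / 2.0
    n_rows = max(2, int(round(h / dy)))
    pts = []
    for row in range(n_rows):
        y = (row + 0.5) * h / n_rows
        n_in_row = max(2, int(round(w / spacing)))
        for k in range(n_in_row):
            x = (k + (0.25 if row % 2 == 0 else 0.75)) * w / n_in_row
            pts.append((y, x))
    pts = np.asarray(pts, dtype=float)
    pts += rng.uniform(-jitter * spacing, jitter * spacing, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 2.0, h - 3.0)
    pts[:, 1] = np.clip(pts[:, 1], 2.0, w - 3.0)
    return pts


def _mirror_seeds(seeds, h, w):
    tops = seeds.copy()
    tops[:, 0] = -1.0 - tops[:, 0]
    bots = seeds.copy()
    bots[:, 0] = 2.0 * h - 1.0 - bots[:, 0]
    lefts = seeds.copy()
    lefts[:, 1] = -1.0 - lefts[:, 1]
    rights = seeds.copy()
    rights[:, 1] = 2.0 * w - 1.0 - rights[:, 1]
    return np.vstack([seeds, tops, bots, lefts, rights])


def _sample_edge(p1, p2, spec: SceneSpec, phase: float):
    """Densely sample the (possibly undulated) curve between two vertices.

    Undulation is a normal displacement with a sine (or triangle) profile
    and a half-sine envelope pinning both endpoints.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    vec = p2 - p1
    length = float(np.hypot(*vec))
    n = max(int(length / 0.25) + 1, 8)
    t = np.linspace(0.0, 1.0, n)
    pts = p1[None, :] + t[:, None] * vec[None, :]
    if spec.undulation_amplitude > 0 and length > 4:
        normal = np.array([-vec[1], vec[0]]) / length
        s = t * length
        arg = 2.0 * math.pi * s / spec.undulation_period + phase
        if spec.undulation_wave == "sine":
            wave = np.sin(arg)
        else:
            wave = 2.0 / math.pi * np.arcsin(np.sin(arg))
        disp = spec.undulation_amplitude * wave * np.sin(math.pi * t)
        pts = pts + disp[:, None] * normal[None, :]
    steps = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return pts, s


def _fragment(total, coverage, frag_len, rng, min_gap=2.0):
    """Covered arc-length intervals for one edge (seeded, gaps >= min_gap
    whenever the budget allows)."""
    if coverage >= 1.0:
        return [(0.0, total)]
    if coverage <= 0.0:
        return []
    covered_total = coverage * total
    gap_total = total - covered_total
    n_frag = max(1, int(round(covered_total / frag_len)))
    n_slots = n_frag + 1
    n_gaps = min(n_slots, max(1, int(gap_total // min_gap)))
    if n_gaps < n_slots:
        slots = set(rng.choice(n_slots, size=n_gaps, replace=False).tolist())
    else:
        slots = set(range(n_slots))
    frag_w = rng.uniform(0.7, 1.3, n_frag)
    frag_lens = frag_w / frag_w.sum() * covered_total
    gap_w = rng.uniform(0.5, 1.5, n_gaps)
    gap_lens = gap_w / gap_w.sum() * gap_total
    intervals = []
    pos = 0.0
    gi = 0
    for slot in range(n_slots):
        if slot in slots:
            pos += gap_lens[gi]
            gi += 1
        if slot < n_frag:
            intervals.append((pos, pos + frag_lens[slot]))
            pos += frag_lens[slot]
    return intervals


def _covered_flags(s, intervals):
    if not intervals:
        return np.zeros(len(s), dtype=bool)
    bounds = np.asarray(intervals, float).ravel()
    idx = np.searchsorted(bounds, s, side="right")
    return idx % 2 == 1


def _digitize(pts, covered, h, w):
    """Round dense samples to an 8-connected pixel path inside the image.

    Returns the pixel path, per-pixel covered flags and a clipped flag.
    """
    ipts = np.rint(pts).astype(int)
    path = []
    flags = []
    clipped = False
    for i, (r, c) in enumerate(map(tuple, ipts)):
        if not (0 <= r < h and 0 <= c < w):
            clipped = True
            continue
        if path and (r, c) == path[-1]:
            flags[-1] = flags[-1] or bool(covered[i])
            continue
        if len(path) >= 2 and (r, c) == path[-2]:
            path.pop()
            flags.pop()
            flags[-1] = flags[-1] or bool(covered[i])
            continue
        if path:
            pr, pc = path[-1]
            if max(abs(r - pr), abs(c - pc)) > 1:
                clipped = True  # path left and re-entered the frame
                break
        path.append((r, c))
        flags.append(bool(covered[i]))
    # Compress to the minimal 8-connected chain: drop a pixel whenever its
    # two chain neighbours are themselves 8-adjacent (L-corner artifacts of
    # dense-sample rounding), merging its covered flag into the predecessor.
    changed = True
    while changed and len(path) >= 3:
        changed = False
        out_p = [path[0]]
        out_f = [flags[0]]
        i = 1
        while i < len(path) - 1:
            pr, pc = out_p[-1]
            nr, nc = path[i + 1]
            if max(abs(pr - nr), abs(pc - nc)) <= 1:
                out_f[-1] = out_f[-1] or flags[i]
                changed = True
            else:
                out_p.append(path[i])
                out_f.append(flags[i])
            i += 1
        out_p.append(path[-1])
        out_f.append(flags[-1])
        path, flags = out_p, out_f
    return path, np.asarray(flags, dtype=bool), clipped


def _polyline_px_length(path):
    if len(path) < 2:
        return 0.0
    d = np.abs(np.diff(np.asarray(path), axis=0))
    n_diag = int((d.min(axis=1) == 1).sum())
    return (len(d) - n_diag) + n_diag * SQRT2


def _runs(flags):
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(flags) - 1))
    return tuple(out)


def _paint(stain, pts, s, intervals, width):
    """Mark pixels within ``width/2`` of the curve whose arc-projection
    falls inside a covered interval.  Fragment ends are cut perpendicular
    to the curve (no protruding caps) so programmed coverage is honoured."""
    if not intervals:
        return np.zeros((0, 2), dtype=int)
    h, w = stain.shape
    r0 = max(0, int(np.floor(pts[:, 0].min() - width)))
    r1 = min(h, int(np.ceil(pts[:, 0].max() + width)) + 1)
    c0 = max(0, int(np.floor(pts[:, 1].min() - width)))
    c1 = min(w, int(np.ceil(pts[:, 1].max() + width)) + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 2), dtype=int)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    dist, idx = cKDTree(pts).query(coords)
    sel = (dist <= width / 2.0) & _covered_flags(s[idx], intervals)
    hit = coords[sel]
    stain[hit[:, 0], hit[:, 1]] = True
    return hit


# ---------------------------------------------------------------------------
# scene assembly


def _assemble(
    spec: SceneSpec,
    edges,
    region_labels: np.ndarray,
    interior_cells: frozenset,
    seeds: np.ndarray | None,
    rng: np.random.Generator,
) -> Scene:
    """Render edge descriptors ``(p1, p2, (cell_a, cell_b), force_cover)``
    into image + ground truth."""
    h, w = spec.height, spec.width
    stain = np.zeros((h, w), dtype=bool)
    stain2 = np.zeros((h, w), dtype=bool) if spec.marker2 else None
    skeleton = np.zeros((h, w), dtype=bool)
    rng2 = (
        np.random.default_rng((spec.seed + spec.marker2.seed_offset) % 2**31)
        if spec.marker2
        else None
    )
    truths = []
    for p1, p2, cells, force_cover in edges:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        pts, s = _sample_edge(p1, p2, spec, phase)
        total = float(s[-1])
        if total < 2.0:
            continue
        cov = 1.0 if force_cover else spec.coverage_fraction
        intervals = _fragment(total, cov, spec.fragment_length, rng)
        covered = _covered_flags(s, intervals)
        hit = _paint(stain, pts, s, intervals, spec.staining_width)
        if spec.marker2 is not None:
            m2 = spec.marker2
            iv2 = _fragment(total, m2.coverage_fraction, m2.fragment_length, rng2)
            _paint(stain2, pts, s, iv2, m2.staining_width)
        path, flags, clipped = _digitize(pts, covered, h, w)
        if len(path) < 2:
            continue
        skeleton[tuple(np.asarray(path).T)] = True
        interior = (
            not clipped
            and cells[0] in interior_cells
            and cells[1] in interior_cells
        )
        truths.append(
            TruthInterface(
                id=len(truths) + 1,
                cells=(min(cells), max(cells)),
                endpoints=(tuple(map(float, p1)), tuple(map(float, p2))),
                path=tuple(path),
                contour_px=_polyline_px_length(path),
                scaffold_length=total,
                coverage=cov,
                covered_intervals=tuple(
                    (float(a), float(b)) for a, b in intervals
                ),
                covered_runs_px=_runs(flags),
                marker_pixel_count=int(len(hit)),
                marker_total_intensity=float(
                    len(hit) * spec.staining_intensity
                ),
                interior=interior,
            )
        )

    clean = np.full((h, w), float(spec.background_intensity))
    clean[stain] = spec.staining_intensity
    max_value = 2**spec.bit_depth - 1
    img = clean.copy()
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, max_value)
    image = RasterImage(img, spec.bit_depth)

    marker2_img = None
    if spec.marker2 is not None:
        c2 = np.full((h, w), float(spec.background_intensity))
        c2[stain2] = spec.marker2.staining_intensity
        if spec.noise_sigma > 0:
            c2 = c2 + rng.normal(0.0, spec.noise_sigma, size=c2.shape)
        marker2_img = RasterImage(np.clip(c2, 0, max_value), spec.bit_depth)

    n_cells = int(region_labels.max())
    expressing = frozenset()
    expr_mask = None
    if spec.expression_fraction > 0:
        draw = rng.random(n_cells) < spec.expression_fraction
        expressing = frozenset(
            int(i + 1) for i in range(n_cells) if draw[i]
        )
        expr_mask = BinaryMask(np.isin(region_labels, sorted(expressing)))

    truth = SceneGroundTruth(
        seeds=seeds,
        region_labels=region_labels,
        interior_cells=interior_cells,
        interfaces=tuple(truths),
        skeleton=skeleton,
        clean=clean,
        expressing=expressing,
    )
    return Scene(image, truth, marker2_img, expr_mask)


def generate_monolayer(spec: SceneSpec) -> Scene:
    """Render a Voronoi monolayer scene with exact ground truth.

    Boundary edges between peripheral cells are rendered only where they
    fall inside the frame; peripheral cells open onto the image border and
    are marked non-interior, as in micrographs where edge cells run
    off-frame.  Deterministic for a fixed ``spec.seed``.
    """
    if spec.n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    seeds = _hex_seeds(h, w, spec.n_cells, spec.jitter, rng)
    n = len(seeds)
    vor = Voronoi(_mirror_seeds(seeds, h, w))

    # nearest-seed raster labels (cells are numbered seed index + 1)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    _, owner = cKDTree(seeds).query(grid)
    region_labels = (owner.reshape(h, w) + 1).astype(np.int32)
    margin = 2
    border_ids = set()
    for sl in (
        region_labels[:margin, :],
        region_labels[-margin:, :],
        region_labels[:, :margin],
        region_labels[:, -margin:],
    ):
        border_ids.update(np.unique(sl).tolist())
    interior_cells = frozenset(
        i + 1 for i in range(n) if (i + 1) not in border_ids
    )

    edges = []
    for (i, j), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if i >= n or j >= n or v1 < 0 or v2 < 0:
            continue
        p1, p2 = vor.vertices[v1], vor.vertices[v2]
        inside = lambda p: -1 < p[0] < h and -1 < p[1] < w
        if not (inside(p1) or inside(p2)):
            continue
        edges.append((p1, p2, (int(i) + 1, int(j) + 1), False))
    return _assemble(spec, edges, region_labels, interior_cells, seeds, rng)


def generate_grid(
    spec: SceneSpec | None = None,
    n_rows: int = 2,
    n_cols: int = 2,
    margin: int = 12,
) -> Scene:
    """Regular rectangular-lattice monolayer inside an inset frame.

    The frame is fully stained; interior interfaces follow the spec's
    coverage.  The region outside the frame touches the image border, so
    frame junctions are border-excluded downstream while the ``n_rows x
    n_cols`` cells inside are interior.  Axis-aligned geometry makes this
    the canonical straight-junction fixture (true linearity exactly 1).
    """
    if spec is None:
        spec = SceneSpec(n_cells=n_rows * n_cols)
    h, w = spec.height, spec.width
    ys = np.linspace(margin, h - 1 - margin, n_rows + 1)
    xs = np.linspace(margin, w - 1 - margin, n_cols + 1)
    ys = np.rint(ys).astype(int)
    xs = np.rint(xs).astype(int)

    def cell(i, j):
        return i * n_cols + j + 1

    exterior = n_rows * n_cols + 1
    edges = []
    # interior vertical interfaces
    for k in range(1, n_cols):
        for i in range(n_rows):
            edges.append((
                (float(ys[i]), float(xs[k])),
                (float(ys[i + 1]), float(xs[k])),
                (cell(i, k - 1), cell(i, k)),
                False,
            ))
    # interior horizontal interfaces
    for k in range(1, n_rows):
        for j in range(n_cols):
            edges.append((
                (float(ys[k]), float(xs[j])),
                (float(ys[k]), float(xs[j + 1])),
                (cell(k - 1, j), cell(k, j)),
                False,
            ))
    # frame (always fully stained; flanked by the exterior region)
    for j in range(n_cols):
        edges.append(((float(ys[0]), float(xs[j])), (float(ys[0]), float(xs[j + 1])),
                      (cell(0, j), exterior), True))
        edges.append(((float(ys[-1]), float(xs[j])), (float(ys[-1]), float(xs[j + 1])),
                      (cell(n_rows - 1, j), exterior), True))
    for i in range(n_rows):
        edges.append(((float(ys[i]), float(xs[0])), (float(ys[i + 1]), float(xs[0])),
                      (cell(i, 0), exterior), True))
        edges.append(((float(ys[i]), float(xs[-1])), (float(ys[i + 1]), float(xs[-1])),
                      (cell(i, n_cols - 1), exterior), True))

    rows_idx = np.clip(np.digitize(np.arange(h), ys[1:-1]), 0, n_rows - 1)
    cols_idx = np.clip(np.digitize(np.arange(w), xs[1:-1]), 0, n_cols - 1)
    region_labels = (
        rows_idx[:, None] * n_cols + cols_idx[None, :] + 1
    ).astype(np.int32)
    outside = np.zeros((h, w), dtype=bool)
    outside[: ys[0], :] = True
    outside[ys[-1] + 1 :, :] = True
    outside[:, : xs[0]] = True
    outside[:, xs[-1] + 1 :] = True
    region_labels[outside] = exterior
    interior_cells = frozenset(range(1, n_rows * n_cols + 1))
    rng = np.random.default_rng(spec.seed)
    return _assemble(spec, edges, region_labels, interior_cells, None, rng)


def degrade_scene(
    image: RasterImage, target_psnr: float, seed: int, tol: float = 0.5
) -> RasterImage:
    """Add Gaussian noise fitted so the degraded PSNR matches ``target_psnr``.

    The noise field is drawn once from ``seed`` and its amplitude
    bisected (PSNR is strictly decreasing in sigma up to clipping), so the
    result is deterministic.  Targets below the clipping-limited floor of
    the bit depth raise a parameter error.
    """
    if target_psnr <= 0:
        raise ValueError("target_psnr must be positive (dB)")
    rng = np.random.default_rng(seed)
    unit = rng.standard_normal(image.shape)
    base = image.as_float()
    max_value = image.max_value

    def degraded(sigma):
        return RasterImage(
            np.clip(base + sigma * unit, 0, max_value), image.bit_depth
        )

    lo, hi = 1e-3, 4.0 * max_value
    floor = compute_psnr(image, degraded(hi))
    if target_psnr < floor:
        raise ValueError(
            f"target {target_psnr:.1f} dB below the achievable floor "
            f"({floor:.1f} dB) for this image"
        )
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        p = compute_psnr(image, degraded(mid))
        if abs(p - target_psnr) <= 0.5 * tol:
            return degraded(mid)
        if p > target_psnr:
            lo = mid
        else:
            hi = mid
    return degraded(math.sqrt(lo * hi))
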