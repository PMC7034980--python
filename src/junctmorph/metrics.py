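"""Per-junction primary and secondary parameters.

Primary parameters are raw lengths (pixels), areas (pixels^2) and summed
intensities (A.U.) measured on the interface path and its dilation band.
Secondary parameters normalise these per junction length or area so that
junctions of different sizes can be compared:

* linearity index — contour / straight-line Euclidean distance (>= 1; 1 is a
  perfectly taut contact, larger values mean undulation);
* coverage index — % of the interface contour covered by staining fragments;
* interface occupancy — % of the band area occupied by above-threshold marker;
* intensity per interface area and cluster density — marker intensity
  normalised to the band area or to the marker's own stained area.

Contours use the weighted 8-connected step metric: 1 per orthogonal step,
sqrt(2) per diagonal step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, RasterImage
from .topology import InterfaceRecord

__all__ = [
    "BandMask",
    "PrimaryMeasures",
    "SecondaryMeasures",
    "path_length",
    "dilate_interface",
    "covered_runs",
    "measure_primary",
    "derive_secondary",
    "measure_second_marker",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class BandMask:
    """Dilation band: all pixels within Chebyshev distance <= dilation of
    some path pixel, clipped to the image bounds."""

    interface_id: int
    pixels: np.ndarray
    dilation: int

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class PrimaryMeasures:
    interface_contour: float
    straight_interface_length: float
    interface_area: int
    junction_contour: float
    straight_junction_length: float
    junction_area: int
    fragmented_junction_contour: float
    marker_area: int
    marker_intensity: float


@dataclass(frozen=True)
class SecondaryMeasures:
    interface_linearity_index: float
    junction_linearity_index: float
    coverage_index: float
    interface_occupancy: float
    intensity_per_interface_area: float
    cluster_density: float


def path_length(path) -> float:
    """Geodesic length of an 8-connected pixel path.

    Orthogonal steps count 1, diagonal steps sqrt(2).  Raises if consecutive
    pixels are not 8-neighbours.
    """
    pts = np.asarray(path, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("path must be a sequence of (row, col) pixels")
    if len(pts) < 2:
        return 0.0
    steps = np.abs(np.diff(pts, axis=0))
    cheb = steps.max(axis=1)
    if (cheb > 1).any() or (cheb == 0).any():
        bad = int(np.argmax((cheb > 1) | (cheb == 0)))
        raise ValueError(
            f"path pixels {bad} and {bad + 1} are not distinct 8-neighbours"
        )
    n_diag = int((steps.min(axis=1) == 1).sum())
    n_orth = len(steps) - n_diag
    return n_orth + n_diag * SQRT2


def _euclid(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _path_array(interface) -> np.ndarray:
    path = interface.path if isinstance(interface, InterfaceRecord) else interface
    return np.asarray(path, dtype=np.int64)


def dilate_interface(
    interface: InterfaceRecord, dilation: int, image_shape: tuple[int, int]
) -> BandMask:
    """Chebyshev dilation band of the interface path (dilation 1..9)."""
    if not (1 <= int(dilation) <= 9):
        raise ValueError("dilation must be between 1 and 9 pixels")
    d = int(dilation)
    h, w = image_shape
    band = np.zeros((h, w), dtype=bool)
    for r, c in _path_array(interface):
        band[max(0, r - d) : min(h, r + d + 1),
             max(0, c - d) : min(w, c + d + 1)] = True
    iid = interface.id if isinstance(interface, InterfaceRecord) else -1
    return BandMask(iid, band, d)


def _nearest_path_index(path: np.ndarray, band: np.ndarray):
    """Band pixel coordinates and, per pixel, the index of its nearest path
    pixel (squared Euclidean distance, ties to the lower path index)."""
    coords = np.argwhere(band)
    if len(coords) == 0:
        return coords, np.zeros(0, dtype=np.int64)
    nearest = np.empty(len(coords), dtype=np.int64)
    chunk = 4096
    for i in range(0, len(coords), chunk):
        block = coords[i : i + chunk]
        d2 = ((block[:, None, :] - path[None, :, :]) ** 2).sum(axis=2)
        nearest[i : i + chunk] = np.argmin(d2, axis=1)
    return coords, nearest


def _runs_from_bool(covered: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, flag in enumerate(covered):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(covered) - 1))
    return runs


def covered_runs(
    interface: InterfaceRecord, band: BandMask, marker_mask: BinaryMask
) -> list[tuple[int, int]]:
    """Maximal runs of path indices covered by the thresholded marker.

    Each path pixel owns the band pixels nearest to it (its perpendicular
    cross-section; distance ties go to the lower path index) and is covered
    iff that cross-section contains at least one above-threshold pixel.
    Gap tolerance is zero: any uncovered pixel splits runs.
    """
    path = _path_array(interface)
    coords, nearest = _nearest_path_index(path, band.pixels)
    covered = np.zeros(len(path), dtype=bool)
    if len(coords):
        hit = marker_mask.pixels[coords[:, 0], coords[:, 1]]
        covered[np.unique(nearest[hit])] = True
    return _runs_from_bool(covered)


def measure_primary(
    interface: InterfaceRecord,
    band: BandMask,
    image: RasterImage,
    threshold: float,
) -> PrimaryMeasures:
    """All primary parameters of one junction for one marker.

    The junction extent runs between the outermost covered path pixels; when
    the marker covers nothing inside the band every junction-related field
    is zero while the interface geometry is reported unchanged.
    """
    if not (0 <= threshold <= image.max_value):
        raise ValueError(
            f"threshold {threshold} outside [0, {image.max_value}]"
        )
    path = _path_array(interface)
    interface_contour = path_length(path)
    straight_interface = _euclid(path[0], path[-1])
    coords, nearest = _nearest_path_index(path, band.pixels)
    interface_area = len(coords)

    intens = image.pixels[coords[:, 0], coords[:, 1]].astype(np.float64)
    above = intens > threshold
    marker_area = int(above.sum())
    marker_intensity = float(intens[above].sum())

    covered = np.zeros(len(path), dtype=bool)
    if marker_area:
        covered[np.unique(nearest[above])] = True
    runs = _runs_from_bool(covered)

    if runs:
        frag = sum(
            path_length(path[s : e + 1]) if e > s else 0.0 for s, e in runs
        )
        first, last = runs[0][0], runs[-1][1]
        junction_contour = (
            path_length(path[first : last + 1]) if last > first else 0.0
        )
        straight_junction = _euclid(path[first], path[last])
        junction_area = int(((nearest >= first) & (nearest <= last)).sum())
    else:
        frag = junction_contour = straight_junction = 0.0
        junction_area = 0

    return PrimaryMeasures(
        interface_contour=float(interface_contour),
        straight_interface_length=float(straight_interface),
        interface_area=int(interface_area),
        junction_contour=float(junction_contour),
        straight_junction_length=float(straight_junction),
        junction_area=int(junction_area),
        fragmented_junction_contour=float(frag),
        marker_area=marker_area,
        marker_intensity=marker_intensity,
    )


def derive_secondary(
    p: PrimaryMeasures, cluster_density_denominator: str = "marker_area"
) -> SecondaryMeasures:
    """Normalised (secondary) parameters from the primary ones.

    Ratios whose denominator is zero (e.g. junction linearity of an
    unstained interface) are reported as NaN, i.e. missing, rather than
    raising.  ``cluster_density_denominator`` selects the stained-area
    convention: ``marker_area`` (above-threshold pixel count; the default,
    making cluster density the mean above-threshold intensity) or
    ``junction_area`` (band pixels spanned by the junction extent).
    """
    if p.interface_contour <= 0 or p.interface_area <= 0:
        raise ValueError("degenerate interface: zero contour or band area")
    if cluster_density_denominator not in ("marker_area", "junction_area"):
        raise ValueError(
            "cluster_density_denominator must be 'marker_area' or "
            "'junction_area'"
        )
    ili = (
        p.interface_contour / p.straight_interface_length
        if p.straight_interface_length > 0
        else math.nan
    )
    jli = (
        p.junction_contour / p.straight_junction_length
        if p.straight_junction_length > 0
        else math.nan
    )
    coverage = 100.0 * p.fragmented_junction_contour / p.interface_contour
    occupancy = 100.0 * p.marker_area / p.interface_area
    ipia = p.marker_intensity / p.interface_area
    denom = (
        p.marker_area
        if cluster_density_denominator == "marker_area"
        else p.junction_area
    )
    density = p.marker_intensity / denom if denom > 0 else math.nan
    return SecondaryMeasures(
        interface_linearity_index=float(ili),
        junction_linearity_index=float(jli),
        coverage_index=float(coverage),
        interface_occupancy=float(occupancy),
        intensity_per_interface_area=float(ipia),
        cluster_density=float(density),
    )


def measure_second_marker(
    interface: InterfaceRecord,
    band: BandMask,
    marker2: RasterImage,
    threshold2: float,
    cluster_density_denominator: str = "marker_area",
) -> tuple[PrimaryMeasures, SecondaryMeasures]:
    """Measure a co-registered second marker inside marker 1's band.

    The interface geometry (contour, Euclidean length, band area) is the
    one defined by marker 1's skeleton; only the staining-dependent fields
    change.
    """
    if marker2.shape != band.pixels.shape:
        raise ValueError("marker2 shape differs from the band mask")
    p = measure_primary(interface, band, marker2, threshold2)
    s = derive_secondary(p, cluster_density_denominator)
    return p, s
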