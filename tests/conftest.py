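"""Shared fixtures and helpers for the junctmorph test suite."""

import numpy as np
import pytest

from junctmorph import (
    AnalysisConfig,
    InterfaceRecord,
    RasterImage,
    analyze_arrays,
    generate_monolayer,
)
from junctmorph.topology import CellLabelMap, label_cells


def neighbor_groups(sk, r, c):
    """Crossing number: 0->1 transitions around the 8-neighbourhood ring;
    >= 3 marks a true branch point (arms of the skeleton)."""
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
            (1, 1), (1, 0), (1, -1), (0, -1)]
    vals = []
    for dr, dc in ring:
        rr, cc = r + dr, c + dc
        vals.append(
            bool(
                0 <= rr < sk.shape[0]
                and 0 <= cc < sk.shape[1]
                and sk[rr, cc]
            )
        )
    return sum(
        (not vals[i]) and vals[(i + 1) % 8] for i in range(8)
    )


def straight_junction(
    length=100,
    runs=((10, 39), (60, 79)),
    stain_width=5,
    intensity=200,
    background=10,
    shape=(41, 141),
    row=20,
    col0=10,
    bit_depth=8,
):
    """An isolated horizontal interface with stain painted over the given
    path-index runs; returns (record, image)."""
    path = tuple((row, col0 + i) for i in range(length + 1))
    img = np.full(shape, background, dtype=float)
    half = stain_width // 2
    for a, b in runs:
        for i in range(a, b + 1):
            r, c = path[i]
            img[r - half : r + half + 1, c] = intensity
    return (
        InterfaceRecord(1, 1, 2, path, (1, 2)),
        RasterImage(img, bit_depth),
    )


def label_to_seed_map(labels: CellLabelMap, region_labels: np.ndarray):
    """Match pipeline cell labels to generator seed cells by majority
    overlap with the nearest-seed region map."""
    mapping = {}
    for lab in range(1, labels.n_cells + 1):
        sel = labels.pixels == lab
        if sel.any():
            mapping[lab] = int(np.bincount(region_labels[sel]).argmax())
    return mapping


def measure_scene(scene, threshold=100.0, dilation=2, **config_kwargs):
    """Run the measurement pipeline on a scene using its ground-truth
    skeleton (the fully user-validated boundary map)."""
    config = AnalysisConfig(
        threshold=threshold, dilation=dilation, **config_kwargs
    )
    return analyze_arrays(
        scene.image,
        config,
        expression_mask=scene.expression_mask,
        skeleton=scene.truth.skeleton,
    )


def match_to_truth(df, scene):
    """Pair each measured row with its ground-truth interface via the
    flanking cell pair; returns list of (row, TruthInterface)."""
    from junctmorph.edge_map import SkeletonMap

    labels = label_cells(SkeletonMap(scene.truth.skeleton))
    mapping = label_to_seed_map(labels, scene.truth.region_labels)
    truth_by_pair = {
        t.cells: t for t in scene.truth.interior_interfaces()
    }
    pairs = []
    for _, row in df.iterrows():
        key = tuple(sorted((mapping[row.cell_a], mapping[row.cell_b])))
        t = truth_by_pair.get(key)
        if t is not None:
            pairs.append((row, t))
    return pairs


@pytest.fixture(scope="session")
def voronoi_scene():
    """A clean mid-size monolayer reused by several read-only tests."""
    from junctmorph import SceneSpec

    return generate_monolayer(
        SceneSpec(n_cells=30, height=256, width=256, seed=1)
    )
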