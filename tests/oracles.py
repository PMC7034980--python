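"""Independent brute-force oracles for the per-junction measurements.

Everything here is computed by direct enumeration over pixels and path
indices, deliberately sharing no code with the library implementation.
"""

import math


def brute_path_length(path):
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        assert max(dr, dc) == 1, "oracle requires an 8-connected path"
        total += math.sqrt(2.0) if (dr == 1 and dc == 1) else 1.0
    return total


def brute_band(path, dilation, shape):
    """Set of pixels within Chebyshev distance <= dilation of the path."""
    h, w = shape
    band = set()
    for r, c in path:
        for rr in range(max(0, r - dilation), min(h, r + dilation + 1)):
            for cc in range(max(0, c - dilation), min(w, c + dilation + 1)):
                band.add((rr, cc))
    return band


def brute_nearest_index(path, pixel):
    best = None
    best_i = None
    for i, (r, c) in enumerate(path):
        d2 = (pixel[0] - r) ** 2 + (pixel[1] - c) ** 2
        if best is None or d2 < best:
            best, best_i = d2, i
    return best_i


def brute_runs(covered):
    runs = []
    start = None
    for i, flag in enumerate(covered):
        if flag and start is None:
            start = i
        if not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(covered) - 1))
    return runs


def brute_primary(path, dilation, shape, image, threshold):
    """All primary measures by exhaustive enumeration.

    ``image`` is indexable as image[r][c] (or a numpy array); marker pixels
    are those strictly above ``threshold``.
    """
    band = brute_band(path, dilation, shape)
    assign = {px: brute_nearest_index(path, px) for px in band}
    marker = {px for px in band if image[px[0]][px[1]] > threshold}

    covered = [False] * len(path)
    for px in marker:
        covered[assign[px]] = True
    runs = brute_runs(covered)

    out = {
        "interface_contour": brute_path_length(path),
        "straight_interface_length": math.dist(path[0], path[-1]),
        "interface_area": len(band),
        "marker_area": len(marker),
        "marker_intensity": float(
            sum(int(image[px[0]][px[1]]) for px in marker)
        ),
        "runs": runs,
    }
    if runs:
        frag = 0.0
        for s, e in runs:
            if e > s:
                frag += brute_path_length(path[s : e + 1])
        first, last = runs[0][0], runs[-1][1]
        out["fragmented_junction_contour"] = frag
        out["junction_contour"] = (
            brute_path_length(path[first : last + 1]) if last > first else 0.0
        )
        out["straight_junction_length"] = math.dist(path[first], path[last])
        out["junction_area"] = sum(
            1 for px in band if first <= assign[px] <= last
        )
    else:
        out["fragmented_junction_contour"] = 0.0
        out["junction_contour"] = 0.0
        out["straight_junction_length"] = 0.0
        out["junction_area"] = 0
    return out


def permutation_pvalue(a, b, n_perm, rng):
    """Two-sided permutation test on the difference of means."""
    import numpy as np

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        stat = abs(pooled[: len(a)].mean() - pooled[len(a) :].mean())
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
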