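"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: persistence
is recomputed by sweeping every threshold and relabelling superlevel /
sublevel pixel sets with ``scipy.ndimage.label``; radial statistics are
recomputed by direct pixel-distance binning; the rank-sum test is
recomputed by exhaustive enumeration of group assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import ndimage

# Freudenthal 6-neighbourhood as a labelling structure (centre row/col 1):
# orthogonal neighbours plus upper-left and lower-right diagonals.
FREUDENTHAL_STRUCTURE = np.array(
    [[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool
)


def sweep_h0(a: np.ndarray) -> list[tuple[float, float, tuple[int, int]]]:
    """Brute-force degree-0 persistence: descending threshold sweep.

    Components of each superlevel set are labelled from scratch; a feature
    is keyed by its argmax pixel, dies when a component first contains an
    older feature's argmax, and the survivor takes death = global min.
    Requires pairwise-distinct values.
    """
    a = np.asarray(a, dtype=float)
    values = np.sort(np.unique(a))[::-1]
    alive: dict[tuple[int, int], float] = {}
    feats = []
    for t in values:
        mask = a >= t
        labels, n = ndimage.label(mask, structure=FREUDENTHAL_STRUCTURE)
        for lab in range(1, n + 1):
            comp = labels == lab
            members = [p for p in alive if comp[p]]
            vals = a.copy()
            vals[~comp] = -np.inf
            argmax = np.unravel_index(np.argmax(vals), a.shape)
            argmax = (int(argmax[0]), int(argmax[1]))
            if argmax not in alive:
                alive[argmax] = float(a[argmax])
            for p in members:
                if p != argmax:
                    feats.append((alive.pop(p), float(t), p))
    gmin = float(a.min())
    for p, b in alive.items():
        feats.append((b, gmin, p))
    return feats


def sweep_h1(a: np.ndarray) -> list[tuple[float, float, tuple[int, int]]]:
    """Brute-force degree-1 persistence via the complement sweep.

    At each threshold the sublevel pixel set is labelled; components not
    touching the image boundary are the holes of the superlevel complex.
    A hole is keyed by its argmin pixel; its birth is the highest
    threshold at which it is interior and its death is its argmin value.
    Requires pairwise-distinct values.
    """
    a = np.asarray(a, dtype=float)
    rows, cols = a.shape
    values = np.sort(np.unique(a))[::-1]
    birth: dict[tuple[int, int], float] = {}
    for t in values:
        mask = a < t
        labels, n = ndimage.label(mask, structure=FREUDENTHAL_STRUCTURE)
        boundary_labels = set(labels[0, :]) | set(labels[-1, :])
        boundary_labels |= set(labels[:, 0]) | set(labels[:, -1])
        for lab in range(1, n + 1):
            if lab in boundary_labels:
                continue
            comp = labels == lab
            vals = a.copy()
            vals[~comp] = np.inf
            argmin = np.unravel_index(np.argmin(vals), a.shape)
            argmin = (int(argmin[0]), int(argmin[1]))
            if argmin not in birth:
                birth[argmin] = float(t)
    return [(b, float(a[p]), p) for p, b in birth.items()]


def radial_bin_means(
    values: np.ndarray,
    pixel_size: float,
    center_xy: tuple[float, float],
    r_edges_um: np.ndarray,
) -> np.ndarray:
    """Mean intensity per annulus by direct pixel-distance binning."""
    rows, cols = values.shape
    cy, cx = center_xy[1], center_xy[0]
    xs = (np.arange(cols) + 0.5) * pixel_size
    ys = (np.arange(rows) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    dist = np.hypot(xx - cx, yy - cy)
    out = np.full(len(r_edges_um) - 1, np.nan)
    for k in range(len(r_edges_um) - 1):
        sel = (dist >= r_edges_um[k]) & (dist < r_edges_um[k + 1])
        if sel.any():
            out[k] = values[sel].mean()
    return out


def line_samples(
    values: np.ndarray,
    pixel_size: float,
    points_xy: np.ndarray,
) -> np.ndarray:
    """Bilinear interpolation at physical points, written out longhand."""
    rows, cols = values.shape
    out = np.full(len(points_xy), np.nan)
    for i, (x, y) in enumerate(points_xy):
        c = x / pixel_size - 0.5
        r = y / pixel_size - 0.5
        r0, c0 = math.floor(r), math.floor(c)
        if r0 < 0 or c0 < 0 or r0 + 1 >= rows or c0 + 1 >= cols:
            if 0 <= r <= rows - 1 and 0 <= c <= cols - 1:
                # on-edge point: clamp the interpolation cell
                r0 = min(max(r0, 0), rows - 2)
                c0 = min(max(c0, 0), cols - 2)
            else:
                continue
        fr, fc = r - r0, c - c0
        out[i] = (
            values[r0, c0] * (1 - fr) * (1 - fc)
            + values[r0, c0 + 1] * (1 - fr) * fc
            + values[r0 + 1, c0] * fr * (1 - fc)
            + values[r0 + 1, c0 + 1] * fr * fc
        )
    return out


def exact_rank_sum_p(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U and p by exhaustive enumeration.

    Enumerates every assignment of the pooled sample into groups of the
    observed sizes, using midranks for ties.  Only feasible for small n.
    """
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, dtype=float)
    n1, n2 = len(a), len(b)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * n2 / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        # two-tailed: arrangements at least as extreme about the midpoint
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


# ---------------------------------------------------------------------------
# Continuum oracle for hourglass-template morphometry: the same feature
# definitions evaluated on near-continuum grids straight from the analytic
# template, with hand-rolled peak finding and flood fill, independent of the
# heatmap pipeline.

def _local_maxima_with_prominence(y: np.ndarray) -> list[tuple[int, float]]:
    """(index, prominence) of every strict-left local maximum of y."""
    idx = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    out = []
    for i in idx:
        left_min = y[: i + 1][::-1]
        right_min = y[i:]
        # walk until terrain exceeds the peak (or the end) on each side
        lm = y[i]
        j = i
        while j > 0 and y[j] <= y[i]:
            lm = min(lm, y[j])
            j -= 1
        lm = min(lm, y[j]) if y[j] <= y[i] else lm
        rm = y[i]
        j = i
        while j < len(y) - 1 and y[j] <= y[i]:
            rm = min(rm, y[j])
            j += 1
        rm = min(rm, y[j]) if y[j] <= y[i] else rm
        out.append((int(i), float(y[i] - max(lm, rm))))
    return out


def _crossings(z: np.ndarray, y: np.ndarray, i: int, level: float):
    lo = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] <= level <= y[j]:
            f = (level - y[j - 1]) / (y[j] - y[j - 1])
            lo = z[j - 1] + f * (z[j] - z[j - 1])
            break
    hi = np.nan
    for j in range(i, len(y) - 1):
        if y[j + 1] <= level <= y[j]:
            f = (y[j] - level) / (y[j] - y[j + 1])
            hi = z[j] + f * (z[j + 1] - z[j])
            break
    return float(lo), float(hi)


def template_profile(template, r_lo: float, r_hi: float, z: np.ndarray) -> np.ndarray:
    """Continuum mean of the template over a radial window, per z."""
    r = np.linspace(r_lo, r_hi, 2001)
    return template.intensity(r[np.newaxis, :], z[:, np.newaxis]).mean(axis=1)


def template_core_network_features(template, prominence_frac: float = 0.1) -> dict:
    """Oracle core/network peak positions and FWHMs on a 1 nm z grid."""
    z = np.arange(0.0, 450.0 + 0.5, 1.0)
    out = {}
    for name, (rlo, rhi) in (("core", (0.0, 100.0)), ("network", (400.0, 600.0))):
        y = template_profile(template, rlo, rhi, z)
        peaks = _local_maxima_with_prominence(y)
        peaks = [p for p in peaks if p[1] >= prominence_frac * y.max()]
        peaks.sort(key=lambda p: p[1], reverse=True)
        peaks = sorted(peaks[:2], key=lambda p: p[0])
        feats = []
        for i, _ in peaks:
            lo, hi = _crossings(z, y, i, y[i] / 2)
            feats.append({"z": float(z[i]), "fwhm": hi - lo, "half_lo": lo})
        out[name] = feats
    return out


def template_half_max_radius(template, peak_z: float) -> float:
    r = np.linspace(0.0, 600.0, 6001)
    prof = template.intensity(r, np.full_like(r, peak_z))
    half = prof[0] / 2
    below = np.flatnonzero(prof <= half)
    if below.size == 0:
        return np.nan
    j = below[0]
    f = (prof[j - 1] - half) / (prof[j - 1] - prof[j])
    return float(r[j - 1] + f * (r[j] - r[j - 1]))


def template_contour_extent(template, cell_nm: float = 5.0) -> tuple[float, float]:
    """Oracle (bottom_z, top_z) of the contour component holding the max.

    Evaluates the template on a fine (r, z) grid, smooths with a Gaussian
    of 10 nm physical sigma, thresholds at the mean within r <= 350 nm,
    and flood-fills (8-neighbour) from the global maximum.
    """
    from scipy.ndimage import gaussian_filter

    r = (np.arange(int(600 / cell_nm)) + 0.5) * cell_nm
    z = np.arange(0.0, 450.0 + cell_nm / 2, cell_nm)
    grid = template.intensity(r[np.newaxis, :], z[:, np.newaxis])
    smoothed = gaussian_filter(grid, sigma=10.0 / cell_nm, mode="nearest")
    thr = smoothed[:, r <= 350.0].mean()
    mask = smoothed > thr
    start = np.unravel_index(np.argmax(smoothed), smoothed.shape)
    seen = np.zeros_like(mask)
    stack = [start]
    seen[start] = True
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < mask.shape[0]
                    and 0 <= nj < mask.shape[1]
                    and mask[ni, nj]
                    and not seen[ni, nj]
                ):
                    seen[ni, nj] = True
                    stack.append((ni, nj))
    rows = np.flatnonzero(seen.any(axis=1))
    return float(z[rows.min()]), float(z[rows.max()])


def template_protrusion(template) -> float:
    feats = template_core_network_features(template)
    nets = feats["network"]
    if not nets:
        return np.nan
    lower_net = nets[0]
    bottom, _ = template_contour_extent(template)
    return max(0.0, lower_net["half_lo"] - bottom)
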