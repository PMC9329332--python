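"""3D podosome morphometry from calibrated z-stacks.

A podosome's axial architecture is summarised by two maps: a perpendicular
line-scan map (intensity along the line through the podosome and the site
centre, at every z) and a radial-averaging heatmap (mean intensity at each
radius from the podosome, at every z).  From the radial heatmap the module
extracts the hourglass features: the two actin cores and their z-FWHM and
half-max radii, the neck between them, the upper/lower actin networks,
the podosome height (z-extent of the mean-intensity contour), and the
ventral protrusion length (how far the podosome base extends below the
lower actin network).

Internal values keep full precision; rounding to the nearest 10 nm (the
axial resolution of the source data) happens only in the reporting layer
(:meth:`PodosomeMorphology.rounded` and the CSV export).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .images import Image2D, ImageStack3D

__all__ = [
    "LineScanMap",
    "RadialHeatmap",
    "PodosomeMorphology",
    "perpendicular_line_scan",
    "radial_average",
    "podosome_contour",
    "axial_profiles",
    "extract_morphology",
    "aggregate_heatmaps",
    "morphology_frame",
    "write_heatmap",
]

CORE_RADIUS_NM = 100.0  # core profile: mean intensity for r <= 100 nm
NETWORK_RADIUS_NM = (400.0, 600.0)  # network profile: 400 <= r <= 600 nm
CONTOUR_RADIUS_NM = 350.0  # contour threshold: mean within r <= 350 nm


@dataclass
class LineScanMap:
    """Intensity over (d, z): d in um along the scan line, z in nm.

    Negative d points inward, toward the phagocytosis-site centre;
    positive d points outward; d = 0 is the podosome.
    """

    values: np.ndarray  # (nz, nd)
    d_positions: np.ndarray  # um, symmetric about 0
    z_positions: np.ndarray  # nm


@dataclass
class RadialHeatmap:
    """Mean intensity over (r bin, z slice); r in nm from 0 outward."""

    values: np.ndarray  # (nz, nr)
    r_centers: np.ndarray  # nm, bin centres, contiguous from 0
    z_positions: np.ndarray  # nm
    r_bin: float  # nm
    normalized: bool = False

    def normalize(self) -> "RadialHeatmap":
        """Divide the whole heatmap by its maximum."""
        peak = float(self.values.max())
        if peak <= 0:
            raise ValueError("cannot normalise a non-positive heatmap")
        return replace(self, values=self.values / peak, normalized=True)


@dataclass
class PodosomeMorphology:
    """Structural features of one podosome, all z/length values in nm.

    Absent features (e.g. an undetectable lower core) carry NaN values
    and a False presence flag.
    """

    height: float = np.nan
    protrusion_length: float = np.nan
    neck_z: float = np.nan
    upper_core_z: float = np.nan
    upper_core_fwhm: float = np.nan
    upper_core_rhm: float = np.nan
    lower_core_z: float = np.nan
    lower_core_fwhm: float = np.nan
    lower_core_rhm: float = np.nan
    upper_network_z: float = np.nan
    upper_network_fwhm: float = np.nan
    lower_network_z: float = np.nan
    lower_network_fwhm: float = np.nan
    has_upper_core: bool = False
    has_lower_core: bool = False
    has_neck: bool = False
    has_upper_network: bool = False
    has_lower_network: bool = False

    def rounded(self, step: float = 10.0) -> "PodosomeMorphology":
        """Reporting convention: round every length to the nearest 10 nm."""
        kwargs = {}
        for name in (
            "height",
            "protrusion_length",
            "neck_z",
            "upper_core_z",
            "upper_core_fwhm",
            "upper_core_rhm",
            "lower_core_z",
            "lower_core_fwhm",
            "lower_core_rhm",
            "upper_network_z",
            "upper_network_fwhm",
            "lower_network_z",
            "lower_network_fwhm",
        ):
            v = getattr(self, name)
            kwargs[name] = v if np.isnan(v) else step * round(v / step)
        return replace(self, **kwargs)


def _sample_physical(values: np.ndarray, pixel_size: float, pts_xy: np.ndarray):
    """Bilinear samples at physical (x, y) um points; NaN out of bounds."""
    col = pts_xy[:, 0] / pixel_size - 0.5
    row = pts_xy[:, 1] / pixel_size - 0.5
    return ndimage.map_coordinates(
        values, np.stack([row, col]), order=1, mode="constant", cval=np.nan
    )


def _as_stack(stack) -> ImageStack3D:
    if isinstance(stack, Image2D):
        return ImageStack3D(stack.values[np.newaxis], stack.pixel_size, np.array([0.0]))
    return stack


def perpendicular_line_scan(
    stack,
    podosome_xy,
    site_center_xy,
    half_length: float = 1.0,
    step: float | None = None,
) -> LineScanMap:
    """Line scan through the podosome, oriented away from the site centre.

    At every z the intensity is sampled by bilinear interpolation at
    uniform steps (default ``pixel_size / 2``) along the line through the
    podosome and the site centre: 1 um inward (d < 0, toward the centre)
    and 1 um outward.  Samples falling outside the image are excluded
    (NaN) with a warning.
    """
    stack = _as_stack(stack)
    pod = np.asarray(podosome_xy, dtype=float)
    ctr = np.asarray(site_center_xy, dtype=float)
    direction = pod - ctr  # points outward from the site
    norm = float(np.hypot(*direction))
    if norm == 0:
        raise ValueError("podosome and site centre coincide: no scan direction")
    u = direction / norm
    if step is None:
        step = stack.pixel_size / 2
    n = int(np.floor(half_length / step + 1e-9))
    d = np.arange(-n, n + 1) * step
    pts = pod[np.newaxis, :] + d[:, np.newaxis] * u[np.newaxis, :]
    rows = np.array(
        [_sample_physical(sl, stack.pixel_size, pts) for sl in stack.slices]
    )
    if np.isnan(rows).any():
        warnings.warn(
            "line scan clipped: some samples fall outside the image",
            stacklevel=2,
        )
    return LineScanMap(values=rows, d_positions=d, z_positions=stack.z_positions)


def radial_average(
    stack,
    podosome_xy,
    r_max: float = 600.0,
    r_bin: float | None = None,
    normalize: bool = False,
) -> RadialHeatmap:
    """Radially averaged intensity around a podosome, per z slice.

    For each radius bin centre the mean of bilinear samples over a dense
    set of angles is taken (this agrees with distance-binned pixel means
    within sampling tolerance).  ``r_max`` and ``r_bin`` are in nm; the
    bin width defaults to the z-step (10 nm for single slices).
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    stack = _as_stack(stack)
    if r_bin is None:
        r_bin = stack.z_step or 10.0
    pod = np.asarray(podosome_xy, dtype=float)
    n_bins = int(round(r_max / r_bin))
    r_centers = (np.arange(n_bins) + 0.5) * r_bin

    ps_nm = stack.pixel_size * 1000.0
    pts = []
    splits = [0]
    for r in r_centers:
        n_ang = max(32, int(np.ceil(2 * np.pi * r / (ps_nm / 2))))
        ang = 2 * np.pi * np.arange(n_ang) / n_ang
        pts.append(
            pod[np.newaxis, :]
            + (r / 1000.0) * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        )
        splits.append(splits[-1] + n_ang)
    pts = np.concatenate(pts, axis=0)

    grid = np.empty((stack.slices.shape[0], n_bins))
    for zi, sl in enumerate(stack.slices):
        samples = _sample_physical(sl, stack.pixel_size, pts)
        for k in range(n_bins):
            chunk = samples[splits[k] : splits[k + 1]]
            grid[zi, k] = np.nanmean(chunk) if np.isfinite(chunk).any() else np.nan
    if np.isnan(grid).any():
        warnings.warn(
            "radial average clipped: some radii fall outside the image",
            stacklevel=2,
        )
    hm = RadialHeatmap(
        values=grid,
        r_centers=r_centers,
        z_positions=stack.z_positions,
        r_bin=float(r_bin),
    )
    return hm.normalize() if normalize else hm


def podosome_contour(heatmap: RadialHeatmap, sigma: float = 1.0):
    """Boolean contour mask of the heatmap.

    The heatmap is smoothed with a Gaussian kernel (sigma in grid cells,
    variance 1 by default) and thresholded at the mean smoothed intensity
    over all cells with r <= 350 nm.  Degenerate (all-equal) heatmaps
    yield an empty mask with a warning.
    """
    if heatmap.r_centers.max() + heatmap.r_bin / 2 < CONTOUR_RADIUS_NM:
        raise ValueError("heatmap must cover r >= 350 nm for contouring")
    smoothed = ndimage.gaussian_filter(heatmap.values, sigma=sigma, mode="nearest")
    inner = heatmap.r_centers <= CONTOUR_RADIUS_NM
    threshold = float(smoothed[:, inner].mean())
    mask = smoothed > threshold
    if mask.all() or not mask.any():
        warnings.warn("degenerate heatmap: contour is empty or full", stacklevel=2)
    return mask


def axial_profiles(heatmap: RadialHeatmap) -> tuple[np.ndarray, np.ndarray]:
    """Core (r <= 100 nm) and network (400-600 nm) mean-intensity vs z."""
    if heatmap.r_centers.max() + heatmap.r_bin / 2 < NETWORK_RADIUS_NM[1]:
        raise ValueError("heatmap must cover r >= 600 nm for network profiles")
    core_sel = heatmap.r_centers <= CORE_RADIUS_NM
    net_sel = (heatmap.r_centers >= NETWORK_RADIUS_NM[0]) & (
        heatmap.r_centers <= NETWORK_RADIUS_NM[1]
    )
    return heatmap.values[:, core_sel].mean(axis=1), heatmap.values[:, net_sel].mean(
        axis=1
    )


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak position by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[1] - x[0]
    return float(x[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def _half_crossings(
    x: np.ndarray, y: np.ndarray, i: int, half: float
) -> tuple[float, float]:
    """z positions where the profile crosses ``half`` on each side of peak
    i, by linear interpolation; NaN where the profile never drops."""
    lo = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] <= half <= y[j]:
            f = (half - y[j - 1]) / (y[j] - y[j - 1])
            lo = x[j - 1] + f * (x[j] - x[j - 1])
            break
    hi = np.nan
    for j in range(i, len(y) - 1):
        if y[j + 1] <= half <= y[j]:
            f = (y[j] - half) / (y[j] - y[j + 1])
            hi = x[j] + f * (x[j + 1] - x[j])
            break
    return float(lo), float(hi)


def _find_profile_peaks(
    z: np.ndarray, profile: np.ndarray, prominence_frac: float
) -> list[dict]:
    """Local maxima with prominence >= prominence_frac * max(profile)."""
    if profile.max() <= 0:
        return []
    idx, props = signal.find_peaks(profile, prominence=prominence_frac * profile.max())
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        zp, vp = _refine_peak(z, profile, int(i))
        lo, hi = _half_crossings(z, profile, int(i), profile[i] / 2)
        peaks.append(
            {
                "index": int(i),
                "z": zp,
                "value": float(vp),
                "prominence": float(prom),
                "fwhm": hi - lo,
                "half_lo": lo,
                "half_hi": hi,
            }
        )
    return peaks


def _half_max_radius(heatmap: RadialHeatmap, peak_z: float) -> float:
    """Interpolated radius where the radial profile at ``peak_z`` falls to
    half its innermost (r -> 0) value."""
    z = heatmap.z_positions
    zi = int(np.clip(np.searchsorted(z, peak_z), 1, len(z) - 1))
    # linear interpolation between the bracketing z rows
    f = (peak_z - z[zi - 1]) / (z[zi] - z[zi - 1]) if len(z) > 1 else 0.0
    f = float(np.clip(f, 0.0, 1.0))
    row = (1 - f) * heatmap.values[zi - 1] + f * heatmap.values[zi]
    half = row[0] / 2
    for k in range(len(row) - 1):
        if row[k] >= half >= row[k + 1]:
            g = (row[k] - half) / (row[k] - row[k + 1])
            return float(
                heatmap.r_centers[k]
                + g * (heatmap.r_centers[k + 1] - heatmap.r_centers[k])
            )
    return np.nan


def extract_morphology(
    heatmap: RadialHeatmap, prominence_frac: float = 0.1
) -> PodosomeMorphology:
    """Extract the hourglass features from a radial-averaging heatmap.

    The two most prominent local maxima of the core profile are the upper
    (larger z) and lower cores; the neck is the core-profile minimum
    between them.  Network peaks are classified below/above the
    inter-network trough.  The podosome height is the z-extent of the
    contour component containing the heatmap maximum, and the protrusion
    length is the distance from the lower network's lower FWHM crossing
    down to the bottom of that contour component (floored at 0).

    Features whose peak cannot be detected at the given prominence are
    reported absent.  The result is invariant under positive scaling of
    the heatmap.
    """
    z = heatmap.z_positions
    core, net = axial_profiles(heatmap)
    morph = PodosomeMorphology()

    core_peaks = _find_profile_peaks(z, core, prominence_frac)
    core_peaks.sort(key=lambda p: p["prominence"], reverse=True)
    core_peaks = sorted(core_peaks[:2], key=lambda p: p["z"])
    if not core_peaks:
        return morph

    if len(core_peaks) == 2:
        lower, upper = core_peaks
        morph.has_upper_core = morph.has_lower_core = True
        morph.upper_core_z, morph.lower_core_z = upper["z"], lower["z"]
        morph.upper_core_fwhm, morph.lower_core_fwhm = upper["fwhm"], lower["fwhm"]
        morph.upper_core_rhm = _half_max_radius(heatmap, upper["z"])
        morph.lower_core_rhm = _half_max_radius(heatmap, lower["z"])
        lo_i, hi_i = lower["index"], upper["index"]
        seg = core[lo_i : hi_i + 1]
        neck_i = lo_i + int(np.argmin(seg))
        neck_z, _ = _refine_peak(z, -core, neck_i)
        morph.neck_z = neck_z
        morph.has_neck = True
    else:
        (upper,) = core_peaks
        morph.has_upper_core = True
        morph.upper_core_z = upper["z"]
        morph.upper_core_fwhm = upper["fwhm"]
        morph.upper_core_rhm = _half_max_radius(heatmap, upper["z"])

    net_peaks = _find_profile_peaks(z, net, prominence_frac)
    net_peaks.sort(key=lambda p: p["prominence"], reverse=True)
    net_peaks = sorted(net_peaks[:2], key=lambda p: p["z"])
    lower_net = upper_net = None
    if len(net_peaks) == 2:
        lower_net, upper_net = net_peaks
    elif len(net_peaks) == 1:
        # classify a lone network peak against the neck (or mid-range)
        split = morph.neck_z if morph.has_neck else float(z.mean())
        if net_peaks[0]["z"] < split:
            lower_net = net_peaks[0]
        else:
            upper_net = net_peaks[0]
    if lower_net is not None:
        morph.has_lower_network = True
        morph.lower_network_z = lower_net["z"]
        morph.lower_network_fwhm = lower_net["fwhm"]
    if upper_net is not None:
        morph.has_upper_network = True
        morph.upper_network_z = upper_net["z"]
        morph.upper_network_fwhm = upper_net["fwhm"]

    mask = podosome_contour(heatmap)
    if mask.any():
        smoothed = ndimage.gaussian_filter(heatmap.values, sigma=1.0, mode="nearest")
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        peak_cell = np.unravel_index(np.argmax(smoothed), smoothed.shape)
        lab = labels[peak_cell]
        if lab > 0:
            rows = np.flatnonzero((labels == lab).any(axis=1))
            top_z, bottom_z = float(z[rows.max()]), float(z[rows.min()])
            morph.height = top_z - bottom_z
            if lower_net is not None and np.isfinite(lower_net["half_lo"]):
                morph.protrusion_length = max(0.0, lower_net["half_lo"] - bottom_z)
    return morph


def aggregate_heatmaps(heatmaps: list[RadialHeatmap]) -> RadialHeatmap:
    """Population-mean heatmap: per-map unit-max normalisation, then the
    cell-wise mean.  All maps must share the same (r, z) grid."""
    if not heatmaps:
        raise ValueError("no heatmaps to aggregate")
    first = heatmaps[0]
    for hm in heatmaps[1:]:
        if not (
            np.array_equal(hm.r_centers, first.r_centers)
            and np.array_equal(hm.z_positions, first.z_positions)
        ):
            raise ValueError("heatmaps must share an identical (r, z) grid")
    stackv = np.stack([hm.normalize().values for hm in heatmaps])
    return RadialHeatmap(
        values=stackv.mean(axis=0),
        r_centers=first.r_centers.copy(),
        z_positions=first.z_positions.copy(),
        r_bin=first.r_bin,
        normalized=True,
    )


def write_heatmap(path, heatmap: RadialHeatmap) -> None:
    """Export a heatmap grid as CSV (``.csv``) or 32-bit TIFF.

    The CSV carries one row per z slice (nm) with radius-bin-centre (nm)
    column headers; the TIFF stores the bare (z, r) grid.
    """
    import pathlib

    import tifffile

    path = pathlib.Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.DataFrame(
            heatmap.values,
            index=pd.Index(heatmap.z_positions, name="z_nm"),
            columns=[f"r_{c:g}" for c in heatmap.r_centers],
        )
        frame.to_csv(path)
    else:
        tifffile.imwrite(path, heatmap.values.astype(np.float32))


def morphology_frame(morphologies: list[PodosomeMorphology]) -> pd.DataFrame:
    """Reporting table (values rounded to the nearest 10 nm)."""
    rows = []
    for i, m in enumerate(morphologies):
        r = m.rounded()
        rows.append(
            {
                "podosome_id": i,
                "height_nm": r.height,
                "protrusion_nm": r.protrusion_length,
                "neck_z_nm": r.neck_z,
                "upper_core_z": r.upper_core_z,
                "upper_core_fwhm": r.upper_core_fwhm,
                "upper_core_rhm": r.upper_core_rhm,
                "lower_core_z": r.lower_core_z,
                "lower_core_fwhm": r.lower_core_fwhm,
                "lower_core_rhm": r.lower_core_rhm,
                "upper_net_z": r.upper_network_z,
                "upper_net_fwhm": r.upper_network_fwhm,
                "lower_net_z": r.lower_network_z,
                "lower_net_fwhm": r.lower_network_fwhm,
                "has_upper_core": m.has_upper_core,
                "has_lower_core": m.has_lower_core,
                "has_neck": m.has_neck,
                "has_upper_network": m.has_upper_network,
                "has_lower_network": m.has_lower_network,
            }
        )
    return pd.DataFrame(rows)
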