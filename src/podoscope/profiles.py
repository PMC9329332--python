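"""Site-level 1D analyses: radial profiles and ring metrics.

Radial profiles average the intensity in annuli around a phagocytosis
site centre (the classic ImageJ "Radial Profile" computation).  Edge-type
channels such as IgG or the Fc-gamma receptor are summarised by the
inflection radius of a four-parameter logistic fit; ring-forming species
(paxillin, talin, myosin) observed in perpendicular line scans are
summarised by the distances of the inner (toward the site centre) and
outer peaks from the podosome, their prominence-based FWHMs, and the
peak-to-peak distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .images import Image2D

__all__ = [
    "RadialProfile",
    "SigmoidFit",
    "RingMetrics",
    "FitError",
    "radial_profile",
    "sigmoid_inflection",
    "ring_metrics",
]


class FitError(RuntimeError):
    """Raised when a model fit cannot be obtained; carries diagnostics."""


@dataclass
class RadialProfile:
    """Mean intensity per annulus around a centre point."""

    radii: np.ndarray  # um, bin centres, increasing from 0
    intensities: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit f(r) = base + amp / (1 + exp((r - r0)/s)).

    ``amp > 0`` describes a falling edge (disk-like channel), ``amp < 0``
    a rising one.  ``inflection_radius`` is r0.
    """

    baseline: float
    amplitude: float
    inflection_radius: float
    slope_scale: float
    residual_ss: float


@dataclass
class RingMetrics:
    """Inner/outer peak geometry of a species line scan (um).

    A side with no qualifying peak carries None in its fields;
    ``peak_to_peak`` is the sum of the two distances when both exist.
    """

    inner_peak_distance: float | None = None
    outer_peak_distance: float | None = None
    inner_fwhm: float | None = None
    outer_fwhm: float | None = None

    @property
    def peak_to_peak(self) -> float | None:
        if self.inner_peak_distance is None or self.outer_peak_distance is None:
            return None
        return self.inner_peak_distance + self.outer_peak_distance


def radial_profile(
    image: Image2D, center_xy, r_max: float, channel: str = ""
) -> RadialProfile:
    """Mean intensity over pixels in each annulus [r, r + dr), dr = pixel size."""
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    cx, cy = float(center_xy[0]), float(center_xy[1])
    rows, cols = image.shape
    if not (0 <= cx <= cols * image.pixel_size and 0 <= cy <= rows * image.pixel_size):
        raise ValueError("centre must lie inside the image")
    dr = image.pixel_size
    xs = (np.arange(cols) + 0.5) * dr
    ys = (np.arange(rows) + 0.5) * dr
    dist = np.hypot(xs[np.newaxis, :] - cx, ys[:, np.newaxis] - cy)
    n_bins = int(np.ceil(r_max / dr))
    which = np.floor(dist / dr).astype(int)
    inside = which < n_bins
    sums = np.bincount(which[inside], weights=image.values[inside], minlength=n_bins)
    counts = np.bincount(which[inside], minlength=n_bins)
    keep = counts > 0
    radii = (np.arange(n_bins)[keep] + 0.5) * dr
    return RadialProfile(radii=radii, intensities=sums[keep] / counts[keep], channel=channel)


def _logistic(r, base, amp, r0, s):
    arg = np.clip((r - r0) / s, -500.0, 500.0)
    return base + amp / (1.0 + np.exp(arg))


def sigmoid_inflection(profile: RadialProfile) -> SigmoidFit:
    """Least-squares logistic fit; the returned inflection is r0.

    Initialisation uses the profile extremes and the radius of the
    half-amplitude crossing; bounds keep r0 inside the data range.
    Flat profiles and non-convergent fits raise :class:`FitError`.
    """
    r = profile.radii
    y = profile.intensities
    span = float(y.max() - y.min())
    if span == 0 or r.size < 4:
        raise FitError("profile is flat or too short for a sigmoid fit")
    falling = y[: max(1, r.size // 4)].mean() >= y[-max(1, r.size // 4) :].mean()
    amp0 = span if falling else -span
    base0 = float(y.min()) if falling else float(y.max())
    half = base0 + amp0 / 2
    crossing = np.argmin(np.abs(y - half))
    r00 = float(r[crossing])
    s0 = float((r[-1] - r[0]) / 10) or 1.0
    r_range = float(r[-1] - r[0])
    try:
        popt, _ = optimize.curve_fit(
            _logistic,
            r,
            y,
            p0=[base0, amp0, r00, s0],
            bounds=(
                [-np.inf, -10 * span, float(r[0]), 1e-6],
                [np.inf, 10 * span, float(r[-1]), 10 * r_range],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"sigmoid fit failed: {exc}") from exc
    residual = float(np.sum((y - _logistic(r, *popt)) ** 2))
    return SigmoidFit(
        baseline=float(popt[0]),
        amplitude=float(popt[1]),
        inflection_radius=float(popt[2]),
        slope_scale=float(popt[3]),
        residual_ss=residual,
    )


def _refine_peak_d(d: np.ndarray, y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(y) - 1:
        return float(d[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(d[i])
    delta = float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))
    return float(d[i] + delta * (d[1] - d[0]))


def ring_metrics(
    d, values, prominence_frac: float = 0.1
) -> RingMetrics:
    """Inner/outer peak metrics of a species scan centred on a podosome.

    ``d`` runs over [-L, +L] um with the reference (actin) podosome peak
    at d = 0; negative d points toward the site centre.  On each side the
    highest local maximum with prominence >= ``prominence_frac`` of the
    scan maximum is taken; widths are FWHMs at half prominence, making
    the metrics invariant to constant baselines and positive scaling.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(values, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("d and values must be matching 1D arrays")
    span = float(y.max() - y.min())
    if span == 0:
        return RingMetrics()
    idx, props = signal.find_peaks(y, prominence=prominence_frac * span)
    widths, _, _, _ = signal.peak_widths(y, idx, rel_height=0.5)
    step = float(d[1] - d[0])
    metrics = RingMetrics()
    for side in ("inner", "outer"):
        on_side = d[idx] < 0 if side == "inner" else d[idx] > 0
        if not on_side.any():
            continue
        cand = np.flatnonzero(on_side)
        best = cand[np.argmax(y[idx[cand]])]
        pos = _refine_peak_d(d, y, int(idx[best]))
        setattr(metrics, f"{side}_peak_distance", abs(pos))
        setattr(metrics, f"{side}_fwhm", float(widths[best] * step))
    return metrics
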