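"""Seeded synthetic frustrated-phagocytosis scenes with known ground truth.

The generator emulates the geometry of frustrated phagocytosis on
micropatterned IgG disks: each phagocytosis site is a ring of
podosome-sized intensity puncta (~0.3 um FWHM) at ~1.8 um radius around
the disk centre, on a smoothed-random cortical-actin background with
additive read noise.  Optional isolated distractor puncta mimic off-site
actin spots.  In 3D mode every podosome carries an hourglass axial
template (two cores joined by a narrow neck, upper/lower actin networks,
a small ventral protrusion knob) rendered over a 0-450 nm z-grid with
10 nm steps.

Template defaults use the population means reported for phagocytic
podosomes (upper core at z = 270 nm with 90 nm axial FWHM and 160 nm
half-max radius; lower core at 70 nm / 80 nm / 140 nm; networks at
260 nm and 80 nm; ~20 nm protrusion).  They serve as generator truths
for recovery tests against the pipeline's measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import Image2D, ImageStack3D
from .quant import RadialHeatmap

__all__ = [
    "FWHM_TO_SIGMA",
    "GaussianLobe",
    "NetworkSlab",
    "PodosomeTemplate",
    "SiteSpec",
    "SceneSpec",
    "GroundTruth",
    "default_template",
    "random_template",
    "render_heatmap_direct",
    "render_scene",
    "benchmark_scene",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM / 2.3548
RHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))  # sigma = r_halfmax / 1.1774


@dataclass(frozen=True)
class GaussianLobe:
    """One core lobe: separable Gaussian in z and in radius (nm)."""

    center_z: float
    sigma_z: float
    sigma_r: float
    amplitude: float


@dataclass(frozen=True)
class NetworkSlab:
    """An actin network sheet: Gaussian in z, rising-then-decaying in r.

    The radial factor (r / decay_r)**3 * exp(3 * (1 - r / decay_r))
    vanishes at the podosome axis and peaks (value 1) at r = decay_r, so
    the slab lives away from the core as the surrounding network does;
    the cubic onset keeps it from bleeding into the core radii.
    """

    center_z: float
    sigma_z: float
    decay_r: float
    amplitude: float


@dataclass(frozen=True)
class PodosomeTemplate:
    """Analytic intensity model I(r, z) of one podosome (units nm).

    The hourglass is two core lobes joined by a narrow axial bridge whose
    amplitude is ``neck_fraction`` of the dimmer lobe, plus two network
    slabs and a ventral protrusion knob extending ``knob_extent_nm``
    below the lower network's half-max boundary.
    """

    upper_lobe: GaussianLobe
    lower_lobe: GaussianLobe
    lower_network: NetworkSlab
    upper_network: NetworkSlab
    neck_fraction: float = 0.5
    neck_center_offset: float = -15.0
    neck_sigma_z: float = 25.0
    neck_sigma_r: float = 60.0
    knob_extent_nm: float = 20.0
    knob_amplitude: float = 0.05
    knob_sigma_z: float = 15.0
    knob_sigma_r: float = 50.0

    def __post_init__(self) -> None:
        if not self.lower_lobe.center_z < self.upper_lobe.center_z:
            raise ValueError("lower lobe must sit below the upper lobe")
        for lobe in (self.upper_lobe, self.lower_lobe):
            if lobe.sigma_z <= 0 or lobe.sigma_r <= 0 or lobe.amplitude < 0:
                raise ValueError("lobe sigmas must be positive, amplitude >= 0")

    @property
    def neck_center_z(self) -> float:
        # the neck is typically narrowest closer to the upper core
        mid = 0.5 * (self.lower_lobe.center_z + self.upper_lobe.center_z)
        return mid + self.neck_center_offset

    @property
    def knob_center_z(self) -> float:
        net = self.lower_network
        lower_half = net.center_z - net.sigma_z * math.sqrt(2 * math.log(2))
        return max(0.0, lower_half - self.knob_extent_nm)

    def intensity(self, r, z) -> np.ndarray:
        """Evaluate the template at radii and heights in nm (broadcast)."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.zeros(np.broadcast_shapes(r.shape, z.shape))
        for lobe in (self.upper_lobe, self.lower_lobe):
            out = out + lobe.amplitude * np.exp(
                -((z - lobe.center_z) ** 2) / (2 * lobe.sigma_z**2)
                - r**2 / (2 * lobe.sigma_r**2)
            )
        bridge_amp = self.neck_fraction * min(
            self.upper_lobe.amplitude, self.lower_lobe.amplitude
        )
        if bridge_amp > 0:
            out = out + bridge_amp * np.exp(
                -((z - self.neck_center_z) ** 2) / (2 * self.neck_sigma_z**2)
                - r**2 / (2 * self.neck_sigma_r**2)
            )
        for net in (self.lower_network, self.upper_network):
            radial = np.where(
                r > 0, (r / net.decay_r) ** 3 * np.exp(3.0 * (1.0 - r / net.decay_r)), 0.0
            )
            out = out + net.amplitude * radial * np.exp(
                -((z - net.center_z) ** 2) / (2 * net.sigma_z**2)
            )
        if self.knob_amplitude > 0:
            out = out + self.knob_amplitude * np.exp(
                -((z - self.knob_center_z) ** 2) / (2 * self.knob_sigma_z**2)
                - r**2 / (2 * self.knob_sigma_r**2)
            )
        return out


def default_template() -> PodosomeTemplate:
    """Template at the reported population-mean geometry."""
    return PodosomeTemplate(
        upper_lobe=GaussianLobe(270.0, 90.0 * FWHM_TO_SIGMA, 160.0 * RHM_TO_SIGMA, 1.0),
        lower_lobe=GaussianLobe(70.0, 80.0 * FWHM_TO_SIGMA, 140.0 * RHM_TO_SIGMA, 0.7),
        lower_network=NetworkSlab(80.0, 100.0 * FWHM_TO_SIGMA, 450.0, 0.25),
        upper_network=NetworkSlab(260.0, 70.0 * FWHM_TO_SIGMA, 450.0, 0.2),
    )


def random_template(rng: np.random.Generator) -> PodosomeTemplate:
    """Draw an hourglass template within physiological parameter ranges."""
    return PodosomeTemplate(
        upper_lobe=GaussianLobe(
            center_z=rng.uniform(240, 300),
            sigma_z=rng.uniform(70, 110) * FWHM_TO_SIGMA,
            sigma_r=rng.uniform(130, 190) * RHM_TO_SIGMA,
            amplitude=1.0,
        ),
        lower_lobe=GaussianLobe(
            center_z=rng.uniform(50, 90),
            sigma_z=rng.uniform(60, 100) * FWHM_TO_SIGMA,
            sigma_r=rng.uniform(110, 170) * RHM_TO_SIGMA,
            amplitude=rng.uniform(0.55, 0.85),
        ),
        lower_network=NetworkSlab(
            center_z=rng.uniform(60, 100),
            sigma_z=rng.uniform(80, 120) * FWHM_TO_SIGMA,
            decay_r=450.0,
            amplitude=rng.uniform(0.15, 0.3),
        ),
        upper_network=NetworkSlab(
            center_z=rng.uniform(240, 280),
            sigma_z=rng.uniform(60, 90) * FWHM_TO_SIGMA,
            decay_r=450.0,
            amplitude=rng.uniform(0.12, 0.28),
        ),
        neck_fraction=rng.uniform(0.35, 0.55),
        knob_extent_nm=rng.uniform(10, 30),
        knob_amplitude=rng.uniform(0.02, 0.08),
    )


def render_heatmap_direct(
    template: PodosomeTemplate,
    r_centers=None,
    z_positions=None,
    r_bin: float = 10.0,
) -> RadialHeatmap:
    """Evaluate a template analytically on an (r, z) grid -- no sampling.

    Defaults to the standard quantification grid: r bins of 10 nm up to
    600 nm, z from 0 to 450 nm in 10 nm steps.
    """
    if r_centers is None:
        r_centers = (np.arange(60) + 0.5) * r_bin
    if z_positions is None:
        z_positions = np.arange(0.0, 451.0, 10.0)
    r_centers = np.asarray(r_centers, dtype=float)
    z_positions = np.asarray(z_positions, dtype=float)
    grid = template.intensity(r_centers[np.newaxis, :], z_positions[:, np.newaxis])
    return RadialHeatmap(
        values=grid,
        r_centers=r_centers,
        z_positions=z_positions,
        r_bin=float(r_bin),
    )


@dataclass(frozen=True)
class SiteSpec:
    """One phagocytosis site: a jittered ring of podosomes."""

    center_xy: tuple[float, float]  # um
    ring_radius_um: float = 1.8
    n_podosomes: int = 8
    position_jitter_um: float = 0.0  # max radial displacement of each punctum
    rotation_rad: float = 0.0  # global phase of the ring


@dataclass
class SceneSpec:
    """Recipe for one synthetic field.

    2D scenes are sums of Gaussian puncta over a smoothed-random
    background with additive zero-mean noise.  Setting ``z_grid =
    (z0_nm, step_nm, count)`` switches to 3D: every punctum is rendered
    through its hourglass template slice by slice.
    """

    field_size_um: float = 20.0
    pixel_size_um: float = 0.05
    sites: list[SiteSpec] = field(default_factory=list)
    n_distractors: int = 0
    distractor_min_distance_um: float = 3.0  # keep-out radius around site centres
    spot_fwhm_um: float = 0.3
    spot_amplitude: float = 1.0
    background_offset: float = 0.35  # cortical actin level
    texture_amplitude: float = 0.1
    texture_correlation_um: float = 1.0
    site_depletion_depth: float = 0.7  # cortical actin deficit over the disk
    site_depletion_radius_um: float = 1.5  # ~3 um IgG disk
    site_depletion_edge_um: float = 0.4
    noise_sd: float = 0.05
    rng_seed: int = 0
    z_grid: tuple[float, float, int] | None = None
    template: PodosomeTemplate | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.field_size_um <= 0:
            raise ValueError("field and pixel sizes must be positive")


@dataclass
class GroundTruth:
    """Planted coordinates of a rendered scene (um)."""

    podosome_positions: np.ndarray  # (n, 2)
    site_ids: np.ndarray  # (n,)
    site_centers: np.ndarray  # (m, 2)
    distractor_positions: np.ndarray  # (k, 2)

    def to_frame(self) -> pd.DataFrame:
        n, k = len(self.podosome_positions), len(self.distractor_positions)
        pos = np.concatenate(
            [
                self.podosome_positions.reshape(-1, 2),
                self.distractor_positions.reshape(-1, 2),
            ]
        )
        return pd.DataFrame(
            {
                "podosome_id": np.arange(n + k),
                "site_id": np.concatenate([self.site_ids, np.full(k, -1)]).astype(int),
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
                "is_distractor": np.concatenate(
                    [np.zeros(n, bool), np.ones(k, bool)]
                ),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        pods = frame[~frame["is_distractor"]]
        dist = frame[frame["is_distractor"]]
        return cls(
            podosome_positions=pods[["x_um", "y_um"]].to_numpy(float),
            site_ids=pods["site_id"].to_numpy(int),
            site_centers=_centers_from_members(pods),
            distractor_positions=dist[["x_um", "y_um"]].to_numpy(float),
        )


def _centers_from_members(pods: pd.DataFrame) -> np.ndarray:
    centers = []
    for _, grp in pods.groupby("site_id"):
        centers.append(grp[["x_um", "y_um"]].to_numpy(float).mean(axis=0))
    return np.array(centers).reshape(-1, 2)


def _sample_truth(spec: SceneSpec, rng: np.random.Generator) -> GroundTruth:
    positions, site_ids = [], []
    for sid, site in enumerate(spec.sites):
        cx, cy = site.center_xy
        for k in range(site.n_podosomes):
            ang = site.rotation_rad + 2 * np.pi * k / site.n_podosomes
            x = cx + site.ring_radius_um * math.cos(ang)
            y = cy + site.ring_radius_um * math.sin(ang)
            if site.position_jitter_um > 0:
                jr = site.position_jitter_um * math.sqrt(rng.uniform())
                ja = rng.uniform(0, 2 * np.pi)
                x += jr * math.cos(ja)
                y += jr * math.sin(ja)
            positions.append((x, y))
            site_ids.append(sid)
    positions = np.array(positions).reshape(-1, 2)
    if positions.size and (
        positions.min() < 0 or positions.max() > spec.field_size_um
    ):
        raise ValueError("a podosome falls outside the field")

    centers = np.array([s.center_xy for s in spec.sites]).reshape(-1, 2)
    distractors = []
    margin = 0.5
    attempts = 0
    while len(distractors) < spec.n_distractors and attempts < 10000:
        attempts += 1
        p = rng.uniform(margin, spec.field_size_um - margin, size=2)
        if centers.size and (
            np.hypot(*(centers - p).T).min() < spec.distractor_min_distance_um
        ):
            continue
        if distractors and np.hypot(*(np.array(distractors) - p).T).min() < 0.6:
            continue
        distractors.append(p)
    if len(distractors) < spec.n_distractors:
        raise ValueError("could not place all distractors; field too crowded")
    return GroundTruth(
        podosome_positions=positions,
        site_ids=np.array(site_ids, dtype=int),
        site_centers=centers,
        distractor_positions=np.array(distractors).reshape(-1, 2),
    )


def _background(spec: SceneSpec, shape, rng: np.random.Generator) -> np.ndarray:
    bg = np.full(shape, float(spec.background_offset))
    if spec.texture_amplitude > 0:
        white = rng.standard_normal(shape)
        sigma = spec.texture_correlation_um / spec.pixel_size_um
        tex = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
        sd = tex.std()
        if sd > 0:
            bg = bg + spec.texture_amplitude * tex / sd
    if spec.site_depletion_depth > 0 and spec.sites:
        # cortical actin is depleted over the IgG disk: the hole the
        # site-scale persistence sweep detects
        ps = spec.pixel_size_um
        xs = (np.arange(shape[1]) + 0.5) * ps
        ys = (np.arange(shape[0]) + 0.5) * ps
        factor = np.ones(shape)
        for site in spec.sites:
            cx, cy = site.center_xy
            r = np.hypot(xs[np.newaxis, :] - cx, ys[:, np.newaxis] - cy)
            edge = max(spec.site_depletion_edge_um, 1e-6)
            t = np.clip((r - spec.site_depletion_radius_um) / edge, 0.0, 1.0)
            ramp = t * t * (3 - 2 * t)  # smoothstep from disk to surround
            factor = factor * (1.0 - spec.site_depletion_depth * (1.0 - ramp))
        bg = bg * factor
    return bg


def _add_spot_2d(
    canvas: np.ndarray, spec: SceneSpec, x: float, y: float, amplitude: float
) -> None:
    """Accumulate one Gaussian punctum, evaluated on a local window."""
    ps = spec.pixel_size_um
    sigma_px = spec.spot_fwhm_um * FWHM_TO_SIGMA / ps
    rows, cols = canvas.shape
    rc, cc = y / ps - 0.5, x / ps - 0.5
    half = int(math.ceil(5 * sigma_px))
    r0, r1 = max(0, int(rc) - half), min(rows, int(rc) + half + 1)
    c0, c1 = max(0, int(cc) - half), min(cols, int(cc) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, np.newaxis] - rc
    cc_ = np.arange(c0, c1)[np.newaxis, :] - cc
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -(rr**2 + cc_**2) / (2 * sigma_px**2)
    )


def render_scene(spec: SceneSpec):
    """Render a scene and return (image-or-stack, ground truth).

    The ground truth (podosome/distractor coordinates, site centres) is
    returned exactly as planted.  The same spec and seed always render
    the identical scene.
    """
    rng = np.random.default_rng(spec.rng_seed)
    truth = _sample_truth(spec, rng)
    n_px = int(round(spec.field_size_um / spec.pixel_size_um))
    shape = (n_px, n_px)
    all_spots = np.concatenate(
        [truth.podosome_positions, truth.distractor_positions]
    ).reshape(-1, 2)

    if spec.z_grid is None:
        canvas = _background(spec, shape, rng)
        for x, y in all_spots:
            _add_spot_2d(canvas, spec, x, y, spec.spot_amplitude)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=shape)
        return Image2D(canvas, spec.pixel_size_um), truth

    z0, dz, nz = spec.z_grid
    z = z0 + dz * np.arange(nz)
    template = spec.template or default_template()
    bg = _background(spec, shape, rng)
    xs = (np.arange(n_px) + 0.5) * spec.pixel_size_um
    slices = np.empty((nz,) + shape)
    # lateral distance of every pixel to every punctum, reused across z
    dists_nm = [
        np.hypot(xs[np.newaxis, :] - x, xs[:, np.newaxis] - y) * 1000.0
        for x, y in all_spots
    ]
    for zi, zval in enumerate(z):
        plane = bg.copy()
        for dist in dists_nm:
            plane += spec.spot_amplitude * template.intensity(dist, zval)
        slices[zi] = plane + rng.normal(0.0, spec.noise_sd, size=shape)
    return ImageStack3D(slices, spec.pixel_size_um, z), truth


def benchmark_scene(
    seed: int,
    field_size_um: float = 20.0,
    pixel_size_um: float = 0.05,
    n_sites_range: tuple[int, int] = (4, 8),
    podosomes_per_site_range: tuple[int, int] = (6, 10),
    ring_radius_um: float = 1.8,
    position_jitter_um: float = 0.1,
    distractor_fraction: float = 0.05,
) -> SceneSpec:
    """Assemble one field of the detection benchmark.

    Sites (4-8 per field) are placed with non-overlapping podosome rings
    of 6-10 puncta at 1.8 um radius with <= 0.1 um positional jitter;
    isolated distractor puncta amount to 5% of the podosome count.  Spot
    amplitude is 20x the additive noise SD.
    """
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(n_sites_range[0], n_sites_range[1] + 1))
    margin = ring_radius_um + 0.7
    min_separation = 2 * ring_radius_um + 0.9
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_sites and attempts < 20000:
        attempts += 1
        p = rng.uniform(margin, field_size_um - margin, size=2)
        if centers and np.hypot(*(np.array(centers) - p).T).min() < min_separation:
            continue
        centers.append(p)
    sites = [
        SiteSpec(
            center_xy=(float(c[0]), float(c[1])),
            ring_radius_um=ring_radius_um,
            n_podosomes=int(
                rng.integers(
                    podosomes_per_site_range[0], podosomes_per_site_range[1] + 1
                )
            ),
            position_jitter_um=position_jitter_um,
            rotation_rad=float(rng.uniform(0, 2 * np.pi)),
        )
        for c in centers
    ]
    n_pods = sum(s.n_podosomes for s in sites)
    return SceneSpec(
        field_size_um=field_size_um,
        pixel_size_um=pixel_size_um,
        sites=sites,
        n_distractors=int(round(distractor_fraction * n_pods)),
        rng_seed=seed,
    )
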