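"""Semi-automatic detection of podosomes and phagocytosis sites.

The detector runs the persistence machinery at two smoothing scales: a
fine scale matched to the podosome footprint (~0.3 um) where degree-0
features (intensity maxima) mark podosome cores, and a coarse scale
matched to the phagocytosis-site footprint (~1.5 um) where degree-1
features (holes of the actin superlevel set) mark the dim disk interior
ringed by podosomes.  Significance of a feature is decided by two-cluster
k-means on the persistence values, and a refinement pass enforces the
biological prior that podosomes come in groups around a site.

Preprocessing: min-max normalisation to [0, 1], a small amount of
zero-mean Gaussian uniqueness noise, then a uniform (box) smoothing
filter sized to the feature of interest.  The smoothing attenuates the
noise to insignificance while the pixel values stay pairwise distinct,
so every persistence feature maps to a unique pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .images import Image2D
from .persistence import compute_persistence

__all__ = [
    "DetectionParams",
    "PodosomeSet",
    "SiteSet",
    "DetectionResult",
    "smoothing_width",
    "preprocess",
    "split_significant",
    "detect_features",
    "refine",
    "run_detection",
]


@dataclass
class DetectionParams:
    """Tunable parameters of the detection pipeline.

    Sizes are physical (um).  ``noise_variance`` is the variance of the
    zero-mean uniqueness noise added to the [0, 1]-normalised image
    before smoothing.  ``significance_floor`` is a guard for featureless
    images: the
    significant k-means cluster is discarded if its mean persistence is
    below this fraction of the preprocessed image's dynamic range.
    """

    podosome_feature_size: float = 0.3
    site_feature_size: float = 1.5
    noise_variance: float = 0.01
    rng_seed: int = 0
    min_podosomes_per_site: int = 3
    max_podosome_site_distance: float = 2.7
    max_refine_iterations: int = 10
    significance_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.podosome_feature_size <= 0 or self.site_feature_size <= 0:
            raise ValueError("feature sizes must be positive")
        if self.podosome_feature_size >= self.site_feature_size:
            raise ValueError("podosome feature size must be below site size")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        if self.min_podosomes_per_site < 1:
            raise ValueError("min_podosomes_per_site must be >= 1")
        if self.max_podosome_site_distance <= 0:
            raise ValueError("max_podosome_site_distance must be positive")


@dataclass
class PodosomeSet:
    """Podosome detections in physical coordinates.

    ``site_id`` is -1 before refinement; afterwards it indexes the
    accompanying :class:`SiteSet`.
    """

    positions: np.ndarray  # (n, 2) [x, y] um
    persistence: np.ndarray  # (n,)
    loci: np.ndarray  # (n, 2) [row, col] source pixels
    site_id: np.ndarray = None  # (n,) int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.persistence = np.asarray(self.persistence, dtype=float)
        self.loci = np.asarray(self.loci, dtype=int).reshape(-1, 2)
        if self.site_id is None:
            self.site_id = np.full(len(self.positions), -1, dtype=int)
        self.site_id = np.asarray(self.site_id, dtype=int)

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "podosome_id": np.arange(len(self)),
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "persistence": self.persistence,
                "site_id": self.site_id,
            }
        )


@dataclass
class SiteSet:
    """Phagocytosis-site centres with member podosome indices."""

    centers: np.ndarray  # (m, 2) [x, y] um
    members: list = field(default_factory=list)  # list of index arrays

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": np.arange(len(self)),
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
                "n_podosomes": [len(m) for m in self.members],
            }
        )


@dataclass
class DetectionResult:
    """Full output of the detect-and-refine chain."""

    podosomes_raw: PodosomeSet
    site_candidates: np.ndarray
    podosomes: PodosomeSet
    sites: SiteSet


def smoothing_width(feature_size: float, pixel_size: float) -> int:
    """Odd box-kernel width (pixels) for a physical feature size."""
    if feature_size < pixel_size:
        raise ValueError(
            f"feature size {feature_size} um is below one pixel ({pixel_size} um)"
        )
    w = int(round(feature_size / pixel_size))
    if w % 2 == 0:
        w += 1  # ties between odd widths resolve toward more smoothing
    return max(w, 1)


def preprocess(
    image: Image2D,
    feature_size: float,
    noise_variance: float = 0.01,
    rng_seed=0,
    max_redraws: int = 100,
) -> Image2D:
    """Normalise, add uniqueness noise, and box-smooth.

    The image is min-max normalised to [0, 1], zero-mean Gaussian noise
    of the given variance is added for pixel uniqueness, and the result
    is smoothed with a square uniform filter of odd width
    ``round(feature_size / pixel_size)`` (reflect padding).  Smoothing
    the noise keeps it insignificant for the downstream persistence
    analysis (the box filter attenuates its standard deviation by the
    kernel width) while the pixel values stay pairwise distinct, so
    every persistence feature localises to one pixel; the noise is
    redrawn on the (measure-zero) chance of a collision.
    """
    v = image.values
    lo, hi = float(v.min()), float(v.max())
    norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    w = smoothing_width(feature_size, image.pixel_size)

    if noise_variance == 0:
        smoothed = ndimage.uniform_filter(norm, size=w, mode="reflect")
        if np.unique(smoothed).size != smoothed.size:
            raise ValueError(
                "zero noise variance requires pairwise-distinct pixel values"
            )
        return Image2D(smoothed, image.pixel_size)

    rng = np.random.default_rng(rng_seed)
    sd = float(np.sqrt(noise_variance))
    for _ in range(max_redraws):
        noisy = norm + rng.normal(0.0, sd, size=norm.shape)
        smoothed = ndimage.uniform_filter(noisy, size=w, mode="reflect")
        if np.unique(smoothed).size == smoothed.size:
            return Image2D(smoothed, image.pixel_size)
    raise RuntimeError("could not obtain pairwise-distinct pixel values")


def split_significant(
    persistences, floor_value: float = 0.0
) -> np.ndarray:
    """Label significantly persistent features by 1D two-cluster k-means.

    The optimal k=2 clustering of scalars is the contiguous split of the
    sorted values minimising the within-cluster sum of squares; it is
    found exhaustively, which makes the labelling deterministic.  The
    cluster with the larger mean is significant unless its mean falls
    below ``floor_value`` (degenerate, featureless input), in which case
    nothing is significant.

    Returns a boolean mask aligned with the input order.
    """
    p = np.asarray(list(persistences), dtype=float)
    if p.size < 2 or np.all(p == p[0]):
        return np.zeros(p.size, dtype=bool)
    s = np.sort(p)
    # prefix sums make every contiguous split O(1)
    c1 = np.concatenate([[0.0], np.cumsum(s)])
    c2 = np.concatenate([[0.0], np.cumsum(s**2)])

    def sse(i, j):  # within-cluster sum of squares of s[i:j]
        n = j - i
        tot = c1[j] - c1[i]
        return (c2[j] - c2[i]) - tot * tot / n

    ks = range(1, p.size)
    best_k = min(ks, key=lambda k: sse(0, k) + sse(k, p.size))
    threshold = s[best_k]
    upper_mean = (c1[p.size] - c1[best_k]) / (p.size - best_k)
    if upper_mean < floor_value:
        return np.zeros(p.size, dtype=bool)
    return p >= threshold


def detect_features(
    image: Image2D, params: DetectionParams, mode: str
):
    """Detect podosome candidates (maxima) or site candidates (holes).

    ``mode='podosome'``: preprocess at the podosome scale, run degree-0
    persistence, keep significant features, and return a
    :class:`PodosomeSet` of their loci at pixel centres in um.

    ``mode='site'``: preprocess at the site scale, run degree-1
    persistence, and return the significant hole loci as an (m, 2) array
    of candidate centres in um.
    """
    if mode not in ("podosome", "site"):
        raise ValueError(f"mode must be 'podosome' or 'site', got {mode!r}")
    if image.values.max() == image.values.min():
        # featureless input: no dynamic range, nothing can be significant
        return (
            np.empty((0, 2))
            if mode == "site"
            else PodosomeSet(
                positions=np.empty((0, 2)),
                persistence=np.empty(0),
                loci=np.empty((0, 2), dtype=int),
            )
        )
    stream = 0 if mode == "podosome" else 1
    feature_size = (
        params.podosome_feature_size if mode == "podosome" else params.site_feature_size
    )
    pre = preprocess(
        image,
        feature_size,
        params.noise_variance,
        rng_seed=[params.rng_seed, stream],
    )
    feats = compute_persistence(pre, degree=0 if mode == "podosome" else 1)
    pvals = np.array([f.persistence for f in feats])
    # the normalised image has unit dynamic range, so the floor is the
    # stated fraction directly; this rejects the noise-only clusters a
    # featureless image would otherwise promote
    mask = split_significant(pvals, floor_value=params.significance_floor)
    kept = [f for f, m in zip(feats, mask) if m]
    loci = np.array([f.locus for f in kept], dtype=int).reshape(-1, 2)
    x, y = pre.pixel_to_physical(loci[:, 0], loci[:, 1])
    positions = np.stack([x, y], axis=1) if len(kept) else np.empty((0, 2))
    if mode == "site":
        return positions
    return PodosomeSet(
        positions=positions,
        persistence=np.array([f.persistence for f in kept]),
        loci=loci,
    )


def refine(
    podosomes: PodosomeSet,
    site_candidates: np.ndarray,
    params: DetectionParams,
) -> tuple[PodosomeSet, SiteSet]:
    """Associate podosomes with sites and prune both sets to a fixed point.

    Iterates until stable (or ``max_refine_iterations``): (1) assign each
    podosome to its nearest site centre (ties to the lowest site index);
    (2) drop podosomes farther than ``max_podosome_site_distance`` from
    their site; (3) drop sites with fewer than
    ``min_podosomes_per_site`` members, orphaning their podosomes; (4)
    re-centre every surviving site at the arithmetic mean of its member
    positions.  Only podosomes with a surviving site are returned.
    """
    centers = np.asarray(site_candidates, dtype=float).reshape(-1, 2)
    pod_idx = np.arange(len(podosomes))
    if len(podosomes) == 0 or len(centers) == 0:
        return _empty_refined(podosomes)

    for _ in range(params.max_refine_iterations):
        pos = podosomes.positions[pod_idx]
        d = cdist(pos, centers)
        nearest = d.argmin(axis=1)  # argmin takes the lowest index on ties
        close = d[np.arange(len(pod_idx)), nearest] <= params.max_podosome_site_distance

        keep_site = np.zeros(len(centers), dtype=bool)
        for s in range(len(centers)):
            members = close & (nearest == s)
            if members.sum() >= params.min_podosomes_per_site:
                keep_site[s] = True
        keep_pod = close & keep_site[nearest]

        new_centers = np.array(
            [
                pos[keep_pod & (nearest == s)].mean(axis=0)
                for s in np.flatnonzero(keep_site)
            ]
        ).reshape(-1, 2)

        stable = (
            keep_pod.all()
            and keep_site.all()
            and len(new_centers) == len(centers)
            and np.allclose(new_centers, centers)
        )
        pod_idx = pod_idx[keep_pod]
        centers = new_centers
        if stable or len(pod_idx) == 0 or len(centers) == 0:
            break

    if len(pod_idx) == 0 or len(centers) == 0:
        return _empty_refined(podosomes)

    pos = podosomes.positions[pod_idx]
    nearest = cdist(pos, centers).argmin(axis=1)
    refined = PodosomeSet(
        positions=pos,
        persistence=podosomes.persistence[pod_idx],
        loci=podosomes.loci[pod_idx],
        site_id=nearest,
    )
    members = [np.flatnonzero(nearest == s) for s in range(len(centers))]
    return refined, SiteSet(centers=centers, members=members)


def _empty_refined(podosomes: PodosomeSet) -> tuple[PodosomeSet, SiteSet]:
    empty_pods = PodosomeSet(
        positions=np.empty((0, 2)),
        persistence=np.empty(0),
        loci=np.empty((0, 2), dtype=int),
        site_id=np.empty(0, dtype=int),
    )
    return empty_pods, SiteSet(centers=np.empty((0, 2)), members=[])


def run_detection(image: Image2D, params: DetectionParams) -> DetectionResult:
    """Full chain: detect podosomes and sites, then refine."""
    pods_raw = detect_features(image, params, mode="podosome")
    candidates = detect_features(image, params, mode="site")
    pods, sites = refine(pods_raw, candidates, params)
    return DetectionResult(
        podosomes_raw=pods_raw,
        site_candidates=candidates,
        podosomes=pods,
        sites=sites,
    )
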