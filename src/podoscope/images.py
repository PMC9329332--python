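"""Calibrated image containers and TIFF I/O.

All lateral geometry is in micrometres (pixel centres at ``(index + 0.5) *
pixel_size``, origin at the top-left corner, row-major 0-based indexing);
axial positions are in nanometres.  Images are plain intensity grids in
arbitrary units -- no photometric interpretation is attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Image2D",
    "ImageStack3D",
    "read_image",
    "read_stack",
    "write_image",
    "write_stack",
]


@dataclass
class Image2D:
    """A single calibrated 2D fluorescence image.

    Parameters
    ----------
    values
        2D array of finite intensities (arbitrary units), row-major.
    pixel_size
        Physical width of one pixel in micrometres.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_to_physical(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel indices to physical (x, y) at pixel centres, in um."""
        x = (np.asarray(cols, dtype=float) + 0.5) * self.pixel_size
        y = (np.asarray(rows, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def physical_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map physical (x, y) in um to fractional (row, col) coordinates."""
        col = np.asarray(x, dtype=float) / self.pixel_size - 0.5
        row = np.asarray(y, dtype=float) / self.pixel_size - 0.5
        return row, col


@dataclass
class ImageStack3D:
    """An ordered z-stack of calibrated slices (e.g. an iPALM rendering).

    ``z_positions`` are in nanometres, strictly increasing with a uniform
    step (typically 0-450 nm in 10 nm steps).
    """

    slices: np.ndarray
    pixel_size: float
    z_positions: np.ndarray

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.slices.ndim != 3 or self.slices.size == 0:
            raise ValueError("stack must be a non-empty (nz, rows, cols) array")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("stack contains non-finite values")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if self.z_positions.shape != (self.slices.shape[0],):
            raise ValueError("z_positions must match the number of slices")
        steps = np.diff(self.z_positions)
        if self.z_positions.size > 1:
            if not np.all(steps > 0):
                raise ValueError("z_positions must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("z-step must be uniform")

    @property
    def z_step(self) -> float:
        """Axial step in nm (0 for a single-slice stack)."""
        if self.z_positions.size < 2:
            return 0.0
        return float(self.z_positions[1] - self.z_positions[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape

    def mean_projection(self) -> Image2D:
        """Mean intensity projection along z, used as the detection input."""
        return Image2D(self.slices.mean(axis=0), self.pixel_size)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_image(path, image: Image2D) -> None:
    """Write a 2D image as single-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size_um": image.pixel_size}, sort_keys=True) + "\n"
    )


def write_stack(path, stack: ImageStack3D) -> None:
    """Write a z-stack as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.slices.astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "z0_nm": float(stack.z_positions[0]),
        "z_step_nm": stack.z_step,
        "n_slices": int(stack.slices.shape[0]),
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True) + "\n")


def _read_meta(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_image(path, pixel_size: float | None = None) -> Image2D:
    """Read a TIFF as a 2D image; stacks are mean z-projected.

    ``pixel_size`` (um) overrides the sidecar value when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    data = tifffile.imread(path)
    meta = _read_meta(path)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValueError(
            f"pixel size for {path} not given and no metadata sidecar found"
        )
    if data.ndim == 3:
        data = data.mean(axis=0)
    return Image2D(np.asarray(data, dtype=float), float(ps))


def read_stack(
    path,
    pixel_size: float | None = None,
    z0_nm: float | None = None,
    z_step_nm: float | None = None,
) -> ImageStack3D:
    """Read a multi-page TIFF z-stack with calibration from the sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    meta = _read_meta(path)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    z0 = z0_nm if z0_nm is not None else meta.get("z0_nm", 0.0)
    dz = z_step_nm if z_step_nm is not None else meta.get("z_step_nm", 10.0)
    if ps is None:
        raise ValueError(f"pixel size for {path} not given and no sidecar found")
    z = z0 + dz * np.arange(data.shape[0])
    return ImageStack3D(np.asarray(data, dtype=float), float(ps), z)
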