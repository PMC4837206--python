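"""In-memory containers for spectra, confocal planes, and Z-stacks.

The atomic object is a :class:`Spectrum` — one wavenumber axis (cm⁻¹,
strictly ascending in memory) plus an intensity vector in counts.  A
:class:`PlaneImage` is a W×H grid of spectra sharing one axis at a single
focal depth, and a :class:`ZStack` is the ordered set of planes of one
confocal measurement, acquired at a constant z-step (here typically
0.5 μm, the axial step used when profiling the vessel wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["Spectrum", "PlaneImage", "ZStack"]

#: absolute tolerance (μm) when checking that z-steps are constant
Z_STEP_TOL = 1e-6


def _ascending_axis(axis: np.ndarray, intensity: np.ndarray):
    """Return (axis, intensity) with the axis strictly ascending.

    On-disk axes may run in either direction; in memory the axis is always
    ascending so that window bounds can be given as [lo, hi] everywhere.
    """
    d = np.diff(axis)
    if np.all(d > 0):
        return axis, intensity
    if np.all(d < 0):
        return axis[::-1].copy(), intensity[..., ::-1].copy()
    raise DataError("non-monotonic wavenumber axis")


@dataclass
class Spectrum:
    """One Raman spectrum: wavenumbers (cm⁻¹) and intensities (counts)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise DataError("Spectrum axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise DataError(
                f"axis length {self.axis.size} != intensity length {self.intensity.size}"
            )
        if self.axis.size < 2:
            raise DataError("Spectrum needs at least 2 channels")
        self.axis, self.intensity = _ascending_axis(self.axis, self.intensity)
        if not np.all(np.isfinite(self.intensity)):
            raise DataError("Spectrum intensities must be finite")

    def __len__(self) -> int:
        return self.axis.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis.copy(), self.intensity.copy())


@dataclass
class PlaneImage:
    """A W×H grid of spectra sharing one axis, at one focal depth.

    ``data`` has shape (H, W, C) with the pixel origin at the top-left and
    row-major pixel order; ``z`` is the focal offset in μm, ``pixel_size``
    the lateral sampling in μm (15 μm / 75 px = 0.2 μm in the reference
    acquisition geometry).
    """

    axis: np.ndarray
    data: np.ndarray
    z: float
    pixel_size: float = 0.2

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError("PlaneImage data must have shape (H, W, C)")
        if self.data.shape[-1] != self.axis.size:
            raise DataError(
                f"plane has {self.data.shape[-1]} channels but axis has {self.axis.size}"
            )
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise DataError("PlaneImage must have at least one pixel")
        if not np.all(np.diff(self.axis) > 0):
            raise DataError("PlaneImage axis must be strictly ascending")
        self.z = float(self.z)
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) pixel grid shape."""
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixels(self) -> np.ndarray:
        """Spectra as a flat (H·W, C) array in row-major pixel order."""
        return self.data.reshape(-1, self.axis.size)

    def total_intensity(self) -> float:
        """Summed intensity over all pixels and channels."""
        return float(self.data.sum())


@dataclass
class ZStack:
    """Planes of one 3D measurement, ordered by increasing z."""

    planes: list[PlaneImage]
    z_step: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise DataError("ZStack needs at least one plane")
        axis0 = self.planes[0].axis
        shape0 = self.planes[0].shape
        for k, p in enumerate(self.planes):
            if p.axis.shape != axis0.shape or not np.array_equal(p.axis, axis0):
                raise DataError(f"plane {k} axis differs from plane 0 axis")
            if p.shape != shape0:
                raise DataError(
                    f"plane {k} grid {p.shape} differs from plane 0 grid {shape0}"
                )
        zs = np.array([p.z for p in self.planes])
        if len(zs) > 1:
            steps = np.diff(zs)
            if np.any(steps <= 0):
                raise DataError("plane z values must be strictly increasing")
            if np.any(np.abs(steps - self.z_step) > Z_STEP_TOL):
                raise DataError(
                    f"plane z spacing {steps} is not the declared z_step {self.z_step}"
                )
        self.z_step = float(self.z_step)

    @property
    def axis(self) -> np.ndarray:
        return self.planes[0].axis

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def z_values(self) -> np.ndarray:
        return np.array([p.z for p in self.planes])

    def data(self) -> np.ndarray:
        """All intensities as one (n_planes, H, W, C) array (copy-free stack)."""
        return np.stack([p.data for p in self.planes])

    def plane_totals(self) -> np.ndarray:
        """Per-plane total intensity — the depth profile of overall signal."""
        return np.array([p.total_intensity() for p in self.planes])

    def with_data(self, data: np.ndarray, metadata: dict[str, Any] | None = None) -> "ZStack":
        """New stack with identical geometry but replaced intensities."""
        if data.shape != (self.n_planes, *self.planes[0].shape, self.axis.size):
            raise ConfigError("replacement data shape mismatch")
        planes = [
            PlaneImage(self.axis, data[k], p.z, p.pixel_size)
            for k, p in enumerate(self.planes)
        ]
        md = dict(self.metadata)
        if metadata:
            md.update(metadata)
        return ZStack(planes, self.z_step, md)
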