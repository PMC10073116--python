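"""Synthetic reflectivity phantoms placed at one or more depth slices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ParameterError, SpectroAngularGrid

__all__ = ["ObjectVolume", "make_phantom"]

PHANTOM_KINDS = ("siemens_star", "bar_target", "point_array", "random_particles", "mirror")


@dataclass
class ObjectVolume:
    """Complex reflectivity maps ``O(r, z)`` on the lateral grid.

    ``slices`` has shape (N, N, N_z); ``depths_um`` is strictly increasing,
    measured from the objective focus (positive into the sample).
    """

    slices: np.ndarray
    depths_um: np.ndarray
    pixel_size_um: float
    max_reflectivity: float = 1.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=complex)
        if self.slices.ndim == 2:
            self.slices = self.slices[:, :, None]
        self.depths_um = np.atleast_1d(np.asarray(self.depths_um, dtype=float))
        if self.slices.shape[2] != self.depths_um.size:
            raise ParameterError("one reflectivity slice per depth required")
        if self.depths_um.size > 1 and not np.all(np.diff(self.depths_um) > 0):
            raise ParameterError("depths must be strictly increasing")
        peak = np.abs(self.slices).max() if self.slices.size else 0.0
        if peak > self.max_reflectivity * (1 + 1e-9):
            raise ParameterError("reflectivity exceeds the stated maximum")

    @property
    def n_depths(self) -> int:
        return self.depths_um.size

    def spectrum(self) -> np.ndarray:
        """Centered object spectra ``O~(K, z)``, orthonormal forward kernel."""
        return np.fft.fftshift(
            np.fft.fft2(self.slices, axes=(0, 1), norm="ortho"), axes=(0, 1)
        )


def _radial_grids(n: int):
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    return y - c, x - c


def _siemens_star(n: int, n_spokes: int) -> np.ndarray:
    y, x = _radial_grids(n)
    phi = np.arctan2(y, x)
    r = np.hypot(y, x)
    star = (np.cos(n_spokes * phi) > 0).astype(float)
    star[r > 0.45 * n] = 0.0
    star[r < 0.04 * n] = 0.0
    return star


def _bar_target(n: int) -> np.ndarray:
    img = np.zeros((n, n))
    groups = (max(n // 16, 1), max(n // 10, 1), max(n // 6, 1))
    y0 = n // 8
    for w in groups:
        for k in range(3):
            x0 = n // 8 + k * 2 * w
            img[y0 : y0 + n // 3, x0 : x0 + w] = 1.0
        y0 += n // 3 + n // 12
        if y0 + n // 3 >= n:
            break
    return img


def make_phantom(
    kind: str,
    grid: SpectroAngularGrid,
    depths_um,
    seed: int = 0,
    *,
    n_spokes: int = 8,
    n_points: int = 5,
    particle_density_per_um2: float = 0.15,
    particle_diameter_um: float = 0.5,
    reflectivity: float = 1.0,
) -> ObjectVolume:
    """Deterministic test phantoms.

    ``siemens_star`` and ``bar_target`` are binary reflectivity charts,
    ``point_array`` places isolated single-pixel reflectors, ``mirror`` is a
    uniform plane, and ``random_particles`` draws a Poisson number of disks at
    uniform positions independently per slice.
    """
    if kind not in PHANTOM_KINDS:
        raise ParameterError(f"unknown phantom kind {kind!r}")
    n = grid.pixels_per_side
    depths = np.atleast_1d(np.asarray(depths_um, dtype=float))
    rng = np.random.default_rng(seed)
    slices = np.zeros((n, n, depths.size), dtype=complex)

    if kind == "mirror":
        slices[:] = reflectivity
    elif kind == "siemens_star":
        slices[:, :, 0] = reflectivity * _siemens_star(n, n_spokes)
        for j in range(1, depths.size):
            slices[:, :, j] = reflectivity * _siemens_star(n, max(n_spokes - 2 * j, 4))
    elif kind == "bar_target":
        base = _bar_target(n)
        for j in range(depths.size):
            slices[:, :, j] = reflectivity * np.rot90(base, k=j % 4)
    elif kind == "point_array":
        for j in range(depths.size):
            if n_points == 1:
                pts = np.array([[n // 2, n // 2]])
            else:
                m = int(np.ceil(np.sqrt(n_points)))
                coords = np.linspace(n // 4, 3 * n // 4, m).astype(int)
                pts = np.array([(a, b) for a in coords for b in coords][:n_points])
            slices[pts[:, 0], pts[:, 1], j] = reflectivity
    else:  # random_particles
        area = grid.field_of_view_um ** 2
        radius_px = 0.5 * particle_diameter_um / grid.pixel_size_um
        if particle_diameter_um < 2 * grid.pixel_size_um:
            warnings.warn(
                "particle diameter is below two grid pixels (sub-resolution)",
                stacklevel=2,
            )
        y, x = np.mgrid[0:n, 0:n]
        for j in range(depths.size):
            count = rng.poisson(particle_density_per_um2 * area)
            for _ in range(count):
                cy, cx = rng.uniform(0, n, size=2)
                disk = (y - cy) ** 2 + (x - cx) ** 2 <= max(radius_px, 0.5) ** 2
                slices[:, :, j][disk] = reflectivity

    return ObjectVolume(
        slices=slices,
        depths_um=depths,
        pixel_size_um=grid.pixel_size_um,
        max_reflectivity=max(reflectivity, 1.0),
    )
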