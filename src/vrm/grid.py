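"""Acquisition geometry: spectral axis, illumination set, spatial-frequency grids.

Conventions used throughout the package:

* wavelengths are stored in nm; wavevectors are in rad/um (``k0 = 2*pi/lambda_um``);
* real-space coordinates are in um, depths ``z`` in um, positive away from the
  objective focus into the sample;
* the spatial-frequency grid is centered (fftshifted order), node ``(N/2, N/2)``
  is ``k = 0`` and the spacing is ``dk = 2*pi / field_of_view``;
* the forward transform E(r) -> E~(k) uses the ``exp(-i k.r)`` kernel and
  orthonormal scaling, image recovery uses the inverse kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SpectralAxis",
    "SpectroAngularGrid",
    "build_spectral_axis",
    "fermat_spiral_angles",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class ParameterError(ValueError):
    """Invalid acquisition parameter."""


@dataclass(frozen=True)
class SpectralAxis:
    """Set of scanned source wavelengths plus the per-line source bandwidth.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths, nm.
    subband_bandwidth_nm
        Bandwidth of the source at each scanned line (``dlambda_S``), nm. The
        full bandwidth is the scanned span plus one sub-band.
    """

    wavelengths_nm: tuple[float, ...]
    subband_bandwidth_nm: float

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ParameterError("spectral axis needs at least one wavelength")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if self.subband_bandwidth_nm <= 0:
            raise ParameterError("sub-band bandwidth must be positive")

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def full_bandwidth_nm(self) -> float:
        w = self.wavelengths_nm
        return (w[-1] - w[0]) + self.subband_bandwidth_nm

    @property
    def center_index(self) -> int:
        """Index of the reference wavelength: the scanned line closest to the
        arithmetic midpoint of the span; ties resolve to the shorter line."""
        w = np.asarray(self.wavelengths_nm)
        mid = 0.5 * (w[0] + w[-1])
        d = np.abs(w - mid)
        # argmin picks the first (shorter-wavelength) entry on exact ties
        return int(np.argmin(d))

    @property
    def center_wavelength_nm(self) -> float:
        return self.wavelengths_nm[self.center_index]

    def subset(self, indices) -> "SpectralAxis":
        w = [self.wavelengths_nm[i] for i in sorted(indices)]
        return SpectralAxis(tuple(w), self.subband_bandwidth_nm)


def build_spectral_axis(
    lambda_min_nm: float,
    lambda_max_nm: float,
    step_nm: float,
    subband_nm: float,
) -> SpectralAxis:
    """Uniformly scanned spectral axis from ``lambda_min`` to ``lambda_max``.

    The number of lines is ``round((max - min)/step) + 1`` and the full
    bandwidth is the scanned span plus one sub-band width.
    """
    if step_nm <= 0:
        raise ParameterError("step must be positive")
    if subband_nm <= 0:
        raise ParameterError("sub-band bandwidth must be positive")
    if not lambda_min_nm < lambda_max_nm and lambda_min_nm != lambda_max_nm:
        raise ParameterError("lambda_min must not exceed lambda_max")
    n = int(round((lambda_max_nm - lambda_min_nm) / step_nm)) + 1
    w = lambda_min_nm + step_nm * np.arange(n)
    return SpectralAxis(tuple(float(x) for x in w), float(subband_nm))


def fermat_spiral_angles(n: int, numerical_aperture: float, center: bool = True) -> np.ndarray:
    """``(n, 2)`` illumination angles (rad) covering the NA disk uniformly.

    Uses a golden-angle (Fermat) spiral in direction-sine space, which gives a
    quasi-uniform disk coverage for any requested channel count. With
    ``center=True`` the first channel is exactly normal incidence.
    """
    if n < 1:
        raise ParameterError("need at least one illumination")
    i = np.arange(n, dtype=float)
    if center:
        r = np.zeros(n)
        if n > 1:
            r[1:] = numerical_aperture * np.sqrt((i[1:] - 0.5) / (n - 1))
    else:
        r = numerical_aperture * np.sqrt((i + 0.5) / n)
    phi = i * _GOLDEN_ANGLE
    s = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)
    # clip: floating error must not push |sin| above the NA
    norm = np.linalg.norm(s, axis=-1)
    over = norm > numerical_aperture
    if np.any(over):
        s[over] *= (numerical_aperture / norm[over, None]) * (1 - 1e-12)
    return np.arcsin(s)


@dataclass(frozen=True)
class SpectroAngularGrid:
    """Acquisition axes: spectral lines, illumination angles, spatial grid.

    ``illumination_angles_rad`` holds per-channel 2-vectors ``(theta_y,
    theta_x)``; the transverse direction-sine vector is the componentwise sine
    and must satisfy ``|sin(theta)| <= NA``.
    """

    spectral: SpectralAxis
    illumination_angles_rad: np.ndarray
    field_of_view_um: float
    pixels_per_side: int
    numerical_aperture: float
    medium_index: float = 1.4

    def __post_init__(self) -> None:
        ang = np.atleast_2d(np.asarray(self.illumination_angles_rad, dtype=float))
        if ang.shape[-1] != 2:
            raise ParameterError("illumination angles must be 2-vectors")
        object.__setattr__(self, "illumination_angles_rad", ang)
        if self.pixels_per_side % 2 != 0 or self.pixels_per_side < 4:
            raise ParameterError("pixels_per_side must be even and >= 4")
        if self.field_of_view_um <= 0:
            raise ParameterError("field of view must be positive")
        if not (0 < self.numerical_aperture <= self.medium_index):
            raise ParameterError("need 0 < NA <= medium index")
        s = np.linalg.norm(np.sin(ang), axis=-1)
        if np.any(s > self.numerical_aperture * (1 + 1e-9)):
            raise ParameterError("illumination direction sine exceeds the NA")

    # -- grid geometry -----------------------------------------------------

    @property
    def n_illuminations(self) -> int:
        return self.illumination_angles_rad.shape[0]

    @property
    def dk(self) -> float:
        """Spatial-frequency spacing, rad/um."""
        return 2.0 * np.pi / self.field_of_view_um

    @property
    def pixel_size_um(self) -> float:
        return self.field_of_view_um / self.pixels_per_side

    @property
    def k_axis(self) -> np.ndarray:
        n = self.pixels_per_side
        return self.dk * (np.arange(n) - n // 2)

    @property
    def k_squared(self) -> np.ndarray:
        """``|k|^2`` on the centered output grid, shape (N, N)."""
        ky = self.k_axis[:, None]
        kx = self.k_axis[None, :]
        return ky * ky + kx * kx

    def pupil_radius(self, lambda_nm: float) -> float:
        """Output pupil radius ``2*pi*NA/lambda`` in rad/um."""
        return 2.0 * np.pi * self.numerical_aperture / (lambda_nm * 1e-3)

    def pupil_mask(self, lambda_nm: float) -> np.ndarray:
        r = self.pupil_radius(lambda_nm)
        return self.k_squared <= r * r * (1 + 1e-12)

    def kz_map(self, lambda_nm: float) -> np.ndarray:
        """Axial wavevector ``sqrt((2 pi n / lambda)^2 - |k|^2)`` on the grid.

        Evanescent nodes (only possible outside the pupil when NA <= n) are
        set to zero.
        """
        k_med = 2.0 * np.pi * self.medium_index / (lambda_nm * 1e-3)
        arg = k_med * k_med - self.k_squared
        return np.sqrt(np.clip(arg, 0.0, None))

    # -- illumination wavevectors -------------------------------------------

    def kin_vectors(self, lambda_nm: float) -> np.ndarray:
        """Exact ``k_in = (2 pi / lambda) sin(theta)`` per channel, (N_ill, 2)."""
        s = np.sin(self.illumination_angles_rad)
        return (2.0 * np.pi / (lambda_nm * 1e-3)) * s

    def kin_nodes(self, lambda_nm: float) -> tuple[np.ndarray, np.ndarray]:
        """Snap each channel's ``k_in`` to the nearest grid node.

        Returns ``(index, inside)`` where ``index`` is (N_ill, 2) integer
        ``(iy, ix)`` into the centered grid and ``inside`` flags nodes whose
        snapped wavevector lies inside the per-wavelength pupil.
        """
        half = self.pixels_per_side // 2
        kin = self.kin_vectors(lambda_nm)
        idx = np.rint(kin / self.dk).astype(int) + half
        idx = np.clip(idx, 0, self.pixels_per_side - 1)
        kv = (idx - half) * self.dk
        r = self.pupil_radius(lambda_nm)
        inside = (kv * kv).sum(axis=-1) <= r * r * (1 + 1e-12)
        return idx, inside

    def kin_index_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Snapped node table over all (channel, wavelength) pairs.

        Returns ``(kin_index, inside)`` with shapes (N_ill, N_lambda, 2) and
        (N_ill, N_lambda).
        """
        nl = self.spectral.n_wavelengths
        idx = np.empty((self.n_illuminations, nl, 2), dtype=int)
        ins = np.empty((self.n_illuminations, nl), dtype=bool)
        for l, lam in enumerate(self.spectral.wavelengths_nm):
            idx[:, l], ins[:, l] = self.kin_nodes(lam)
        return idx, ins

    def kz_in(self, node_index: np.ndarray, lambda_nm: float) -> np.ndarray:
        """Axial wavevector of the snapped illumination node(s)."""
        half = self.pixels_per_side // 2
        kv = (np.asarray(node_index) - half) * self.dk
        k_med = 2.0 * np.pi * self.medium_index / (lambda_nm * 1e-3)
        arg = k_med * k_med - (kv * kv).sum(axis=-1)
        return np.sqrt(np.clip(arg, 0.0, None))
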