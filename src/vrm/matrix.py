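"""The volumetric reflection matrix: data model, basis conversion, storage.

The central object records the complex reflected field for every combination
of illumination channel and wavelength, either as real-space images
``E(r; theta_in, lambda)`` or as spatial-frequency spectra
``E~(k; k_in, lambda)`` on the centered output grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np

from .grid import SpectralAxis, SpectroAngularGrid

__all__ = [
    "VolumetricReflectionMatrix",
    "PupilPairCount",
    "to_kin_basis",
    "from_kin_basis",
    "pair_count",
    "save_matrix",
    "load_matrix",
    "shift2d",
]

REAL_SPACE_THETA = "real_space_theta"
FREQUENCY_KIN = "frequency_kin"

_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent stored matrix container."""


def shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift of the two leading axes; samples leaving the grid are
    dropped (zero-filled), never wrapped."""
    out = np.zeros_like(a)
    ny, nx = a.shape[:2]
    ys = slice(max(dy, 0), min(ny + dy, ny))
    xs = slice(max(dx, 0), min(nx + dx, nx))
    yr = slice(max(-dy, 0), min(ny - dy, ny))
    xr = slice(max(-dx, 0), min(nx - dx, nx))
    out[ys, xs] = a[yr, xr]
    return out


@dataclass
class VolumetricReflectionMatrix:
    """Complex field stack indexed ``(y/k_y, x/k_x, illumination, wavelength)``.

    In the ``frequency_kin`` basis every wavelength slab is supported on its
    pupil ``|k| <= 2*pi*NA/lambda`` and ``kin_index[(i, l)]`` holds the grid
    node ``(iy, ix)`` assigned to ``k_in(theta_i, lambda_l)``.
    """

    data: np.ndarray
    basis: str
    grid: SpectroAngularGrid
    kin_index: np.ndarray | None = None
    kin_inside: np.ndarray | None = None
    excluded_count: int = 0

    def __post_init__(self) -> None:
        n = self.grid.pixels_per_side
        expected = (n, n, self.grid.n_illuminations, self.grid.spectral.n_wavelengths)
        if self.data.shape != expected:
            raise FormatError(
                f"data shape {self.data.shape} inconsistent with grid {expected}"
            )
        if self.basis not in (REAL_SPACE_THETA, FREQUENCY_KIN):
            raise FormatError(f"unknown basis {self.basis!r}")
        if self.basis == FREQUENCY_KIN and self.kin_index is None:
            raise FormatError("frequency_kin basis requires kin_index")

    @property
    def n_wavelengths(self) -> int:
        return self.grid.spectral.n_wavelengths

    @property
    def n_illuminations(self) -> int:
        return self.grid.n_illuminations

    def copy(self) -> "VolumetricReflectionMatrix":
        return replace(
            self,
            data=self.data.copy(),
            kin_index=None if self.kin_index is None else self.kin_index.copy(),
            kin_inside=None if self.kin_inside is None else self.kin_inside.copy(),
        )

    def total_power(self) -> np.ndarray:
        """Total power per (illumination, wavelength)."""
        return np.sum(np.abs(self.data) ** 2, axis=(0, 1))


def to_kin_basis(matrix: VolumetricReflectionMatrix) -> VolumetricReflectionMatrix:
    """Fourier transform each image over r and index illuminations by ``k_in``.

    The forward kernel is ``exp(-i k.r)`` with orthonormal scaling, so the
    conversion is unitary on the retained (pupil) band. Each channel's
    ``k_in`` is snapped to the nearest grid node; channels whose snapped node
    falls outside the pupil are zeroed and counted.
    """
    if matrix.basis != REAL_SPACE_THETA:
        raise ValueError("matrix is not in the real_space_theta basis")
    g = matrix.grid
    spec = np.fft.fftshift(
        np.fft.fft2(matrix.data, axes=(0, 1), norm="ortho"), axes=(0, 1)
    )
    kin_index, inside = g.kin_index_table()
    excluded = 0
    for l, lam in enumerate(g.spectral.wavelengths_nm):
        mask = g.pupil_mask(lam)
        spec[..., l] *= mask[:, :, None]
        bad = ~inside[:, l]
        if np.any(bad):
            spec[:, :, bad, l] = 0.0
            excluded += int(bad.sum())
    if excluded:
        warnings.warn(
            f"{excluded} (illumination, wavelength) channels snapped outside "
            "the pupil and were excluded",
            stacklevel=2,
        )
    return VolumetricReflectionMatrix(
        data=spec,
        basis=FREQUENCY_KIN,
        grid=g,
        kin_index=kin_index,
        kin_inside=inside,
        excluded_count=excluded,
    )


def from_kin_basis(matrix: VolumetricReflectionMatrix) -> VolumetricReflectionMatrix:
    """Inverse of :func:`to_kin_basis` on the retained band."""
    if matrix.basis != FREQUENCY_KIN:
        raise ValueError("matrix is not in the frequency_kin basis")
    imgs = np.fft.ifft2(
        np.fft.ifftshift(matrix.data, axes=(0, 1)), axes=(0, 1), norm="ortho"
    )
    return VolumetricReflectionMatrix(
        data=imgs, basis=REAL_SPACE_THETA, grid=matrix.grid
    )


@dataclass(frozen=True)
class PupilPairCount:
    """Number of admissible ``(k_in, k)`` node pairs per momentum difference.

    ``counts[K]`` is the number of pairs with ``K = k - k_in`` where ``k``
    runs over the output pupil and ``k_in`` over the snapped illumination
    nodes inside the pupil; ``K`` lives on the same centered grid and pairs
    falling outside it are dropped.
    """

    counts: np.ndarray
    lambda_nm: float

    @property
    def n_zero(self) -> int:
        n = self.counts.shape[0]
        return int(self.counts[n // 2, n // 2])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def support(self) -> np.ndarray:
        return self.counts > 0


def pair_count(grid: SpectroAngularGrid, lambda_nm: float) -> PupilPairCount:
    """Discrete autocorrelation of the output pupil with the illumination set.

    Equivalent to counting, for every momentum difference ``K`` on the grid,
    the ``(k_in, k)`` node pairs with both members inside their pupils.
    """
    if not np.any(np.isclose(grid.spectral.wavelengths_nm, lambda_nm)):
        raise ValueError(f"{lambda_nm} nm is not on the spectral axis")
    half = grid.pixels_per_side // 2
    pupil = grid.pupil_mask(lambda_nm).astype(np.int64)
    idx, inside = grid.kin_nodes(lambda_nm)
    counts = np.zeros_like(pupil)
    # distinct occupied nodes each count once per occupying channel
    for (iy, ix) in idx[inside]:
        counts += shift2d(pupil, half - iy, half - ix)
    return PupilPairCount(counts=counts, lambda_nm=float(lambda_nm))


# ---------------------------------------------------------------------------
# storage: one HDF5 group per matrix, chunked along the wavelength axis

_REQUIRED_DATASETS = ("data_re", "data_im", "wavelengths_nm", "theta_in_rad")
_REQUIRED_ATTRS = ("NA", "n", "FOV_um", "basis", "subband_nm", "format_version")


def save_matrix(path, matrix: VolumetricReflectionMatrix, group: str = "matrix") -> None:
    """Write a matrix to an HDF5 container (complex data as re/im pairs)."""
    g = matrix.grid
    n = g.pixels_per_side
    chunk = (n, n, min(g.n_illuminations, 64), 1)
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        grp = f.create_group(group)
        grp.create_dataset("data_re", data=matrix.data.real, chunks=chunk)
        grp.create_dataset("data_im", data=matrix.data.imag, chunks=chunk)
        grp.create_dataset("wavelengths_nm", data=np.asarray(g.spectral.wavelengths_nm))
        grp.create_dataset("theta_in_rad", data=g.illumination_angles_rad)
        if matrix.kin_index is not None:
            grp.create_dataset("kin_index", data=matrix.kin_index)
            grp.create_dataset("kin_inside", data=matrix.kin_inside)
        grp.attrs["NA"] = g.numerical_aperture
        grp.attrs["n"] = g.medium_index
        grp.attrs["FOV_um"] = g.field_of_view_um
        grp.attrs["basis"] = matrix.basis
        grp.attrs["subband_nm"] = g.spectral.subband_bandwidth_nm
        grp.attrs["excluded_count"] = matrix.excluded_count
        grp.attrs["format_version"] = _FORMAT_VERSION
        grp.attrs["axes"] = "ky,kx,illumination,wavelength"
        grp.attrs["units"] = "k: rad/um; r,FOV: um; wavelengths: nm; theta: rad"


def load_matrix(path, group: str = "matrix", wavelength_indices=None) -> VolumetricReflectionMatrix:
    """Read a matrix back; ``wavelength_indices`` selects a spectral slab."""
    with h5py.File(path, "r") as f:
        if group not in f:
            raise FormatError(f"missing group {group!r}")
        grp = f[group]
        for key in _REQUIRED_DATASETS:
            if key not in grp:
                raise FormatError(f"missing dataset {key!r}")
        for key in _REQUIRED_ATTRS:
            if key not in grp.attrs:
                raise FormatError(f"missing attribute {key!r}")
        wav = grp["wavelengths_nm"][()]
        sel = np.arange(len(wav)) if wavelength_indices is None else np.asarray(wavelength_indices)
        data = grp["data_re"][..., sel] + 1j * grp["data_im"][..., sel]
        spectral = SpectralAxis(tuple(float(x) for x in wav[sel]), float(grp.attrs["subband_nm"]))
        grid = SpectroAngularGrid(
            spectral=spectral,
            illumination_angles_rad=grp["theta_in_rad"][()],
            field_of_view_um=float(grp.attrs["FOV_um"]),
            pixels_per_side=int(data.shape[0]),
            numerical_aperture=float(grp.attrs["NA"]),
            medium_index=float(grp.attrs["n"]),
        )
        kin_index = grp["kin_index"][()][:, sel] if "kin_index" in grp else None
        kin_inside = grp["kin_inside"][()][:, sel] if "kin_inside" in grp else None
        n = grid.pixels_per_side
        if data.shape[:3] != (n, n, grid.n_illuminations):
            raise FormatError(
                f"stored data shape {data.shape} does not match the declared grid"
            )
        return VolumetricReflectionMatrix(
            data=data,
            basis=str(grp.attrs["basis"]),
            grid=grid,
            kin_index=kin_index,
            kin_inside=kin_inside,
            excluded_count=int(grp.attrs.get("excluded_count", 0)),
        )
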