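"""Synthesis of volumetric reflection matrices.

The single-scattering channel follows the momentum-conservation forward
model: for every illumination node ``k_in`` and wavelength, the recorded
spectrum is the object spectrum shifted to ``k - k_in``, weighted by the
roundtrip ballistic attenuation and the defocus phases of the in/out axial
wavevectors, and wrapped by the input/output dispersion phases. Multiple
scattering is synthesized as circular Gaussian speckle of prescribed mean
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SpectroAngularGrid
from .matrix import FREQUENCY_KIN, VolumetricReflectionMatrix, shift2d
from .medium import DispersionMap, MediumSpec
from .phantom import ObjectVolume

__all__ = [
    "simulate_single_scattering",
    "simulate_multiple_scattering",
    "simulate_reflection_matrix",
    "SimulationRecord",
]


def _empty_matrix(grid: SpectroAngularGrid) -> VolumetricReflectionMatrix:
    n = grid.pixels_per_side
    kin_index, inside = grid.kin_index_table()
    data = np.zeros((n, n, grid.n_illuminations, grid.spectral.n_wavelengths), complex)
    return VolumetricReflectionMatrix(
        data=data,
        basis=FREQUENCY_KIN,
        grid=grid,
        kin_index=kin_index,
        kin_inside=inside,
    )


def simulate_single_scattering(
    obj: ObjectVolume,
    grid: SpectroAngularGrid,
    medium: MediumSpec | None = None,
    dispersion: DispersionMap | None = None,
) -> VolumetricReflectionMatrix:
    """Dispersion-modified single-scattering matrix.

    For each (illumination, wavelength) the field is

    ``E~_S(k) = e^{i phi_in(k_in)} e^{i phi_o(k)}
    sum_z e^{-2z/l_s} O~(k - k_in, z) e^{i (k_z^in + k_z(k)) z}``

    with the illumination wavevector realized exactly on its snapped grid
    node, so the momentum shift is an integer translation of the object
    spectrum (out-of-grid samples dropped). Output pupils are applied per
    wavelength; with NA <= n every retained node is propagating.
    """
    medium = medium or MediumSpec()
    out = _empty_matrix(grid)
    half = grid.pixels_per_side // 2
    spectra = obj.spectrum()  # (N, N, Nz)
    depths = obj.depths_um
    wav = grid.spectral.wavelengths_nm
    ls = medium.ls_um(np.asarray(wav))

    for l, lam in enumerate(wav):
        pupil = grid.pupil_mask(lam)
        kz = grid.kz_map(lam)
        atten = np.exp(-2.0 * depths / ls[l])  # roundtrip ballistic loss
        # output-side depth kernel, per slice
        kern = atten[None, None, :] * np.exp(1j * kz[:, :, None] * depths[None, None, :])
        kz_in = grid.kz_in(out.kin_index[:, l], lam)
        phi_o = None
        if dispersion is not None:
            phi_o = np.exp(1j * dispersion.phi_o[:, :, l])
        for i in range(grid.n_illuminations):
            if not out.kin_inside[i, l]:
                continue
            iy, ix = out.kin_index[i, l]
            acc = np.zeros((grid.pixels_per_side,) * 2, complex)
            for j in range(obj.n_depths):
                term = shift2d(spectra[:, :, j], iy - half, ix - half)
                acc += term * kern[:, :, j] * np.exp(1j * kz_in[i] * depths[j])
            acc *= pupil
            if dispersion is not None:
                acc *= phi_o
                acc *= np.exp(1j * dispersion.phi_in[iy, ix, l])
            out.data[:, :, i, l] = acc
    return out


def simulate_multiple_scattering(
    grid: SpectroAngularGrid,
    medium: MediumSpec,
    seed: int | None = None,
) -> VolumetricReflectionMatrix:
    """Circular complex Gaussian speckle background.

    With ``rho = 0`` (default) the entries are i.i.d. across output node,
    illumination and wavelength, mean intensity ``M(lambda)`` inside the
    pupils and zero outside; coherence-gated backgrounds at well-separated
    depths are then mutually independent.

    With ``rho > 0`` the speckle is synthesized as a dense comb of
    depth-localized Gaussian components (each carrying the defocus phases of
    its depth, with independent per-element statistics so no
    momentum-conserving structure is introduced). A fraction ``rho`` of each
    component's power comes from one comb-shared Gaussian field, so the
    coherence-gated backgrounds at *any* pair of depths acquire correlation
    ``rho`` — emulating partially correlated depth speckle. The per-element
    mean intensity remains ``M(lambda)`` in expectation.
    """
    out = _empty_matrix(grid)
    rng = np.random.default_rng(medium.seed if seed is None else seed)
    wav = grid.spectral.wavelengths_nm
    m_of_l = medium.ms_power(len(wav))
    rho = medium.ms_depth_correlation
    n = grid.pixels_per_side
    shape = (n, n, grid.n_illuminations)

    def gauss():
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)

    if rho == 0:
        for l, lam in enumerate(wav):
            if m_of_l[l] == 0:
                continue
            out.data[..., l] = gauss() * (
                np.sqrt(m_of_l[l]) * grid.pupil_mask(lam)[:, :, None]
            )
        return out

    n_comb = 33
    z_comb = np.linspace(-0.5, 0.5, n_comb) * medium.ms_depth_span_um
    shared = gauss()
    comps = [
        np.sqrt(1 - rho) * gauss() + np.sqrt(rho) * shared for _ in range(n_comb)
    ]
    for l, lam in enumerate(wav):
        if m_of_l[l] == 0:
            continue
        kz = grid.kz_map(lam)
        kz_in = grid.kz_in(out.kin_index[:, l], lam)
        field = np.zeros(shape, complex)
        for d, zd in enumerate(z_comb):
            field += comps[d] * (
                np.exp(1j * kz * zd)[:, :, None] * np.exp(1j * kz_in * zd)[None, None, :]
            )
        field *= np.sqrt(m_of_l[l] / n_comb) * grid.pupil_mask(lam)[:, :, None]
        out.data[..., l] = field
    return out


@dataclass
class SimulationRecord:
    """Ground-truth sidecar for a synthesized matrix."""

    s_lambda: np.ndarray
    m_lambda: np.ndarray
    dispersion: DispersionMap | None
    obj: ObjectVolume
    medium: MediumSpec
    seed: int

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.s_lambda))

    @property
    def mean_m(self) -> float:
        return float(np.mean(self.m_lambda))


def simulate_reflection_matrix(
    obj: ObjectVolume,
    grid: SpectroAngularGrid,
    medium: MediumSpec | None = None,
    dispersion: DispersionMap | None = None,
    seed: int | None = None,
) -> tuple[VolumetricReflectionMatrix, SimulationRecord]:
    """Full matrix ``E~ = E~_S + E~_M`` plus the ground-truth record.

    ``s_lambda`` / ``m_lambda`` are the mean single/multiple-scattering
    intensities per admissible element at each wavelength, measured from the
    synthesized components (the quantities S and M of the fidelity model).
    """
    medium = medium or MediumSpec()
    single = simulate_single_scattering(obj, grid, medium, dispersion)
    speckle = simulate_multiple_scattering(grid, medium, seed=seed)
    wav = grid.spectral.wavelengths_nm
    s_l = np.zeros(len(wav))
    m_l = np.zeros(len(wav))
    for l, lam in enumerate(wav):
        pupil = grid.pupil_mask(lam)
        count = pupil.sum() * max(int(single.kin_inside[:, l].sum()), 1)
        s_l[l] = np.sum(np.abs(single.data[..., l]) ** 2) / count
        m_l[l] = np.sum(np.abs(speckle.data[..., l]) ** 2) / count
    single.data += speckle.data
    record = SimulationRecord(
        s_lambda=s_l,
        m_lambda=m_l,
        dispersion=dispersion,
        obj=obj,
        medium=medium,
        seed=medium.seed if seed is None else seed,
    )
    return single, record
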