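import numpy as np
import pytest

from vrm import (
    SpectroAngularGrid,
    build_spectral_axis,
    fermat_spiral_angles,
    make_phantom,
    simulate_single_scattering,
)


def make_grid(
    n_pixels=16,
    n_ill=21,
    fov=2.2,
    lam_min=632.5,
    lam_max=662.5,
    step=7.5,
    subband=15.0,
    na=1.0,
    index=1.4,
    ill_na=None,
):
    return SpectroAngularGrid(
        spectral=build_spectral_axis(lam_min, lam_max, step, subband),
        illumination_angles_rad=fermat_spiral_angles(n_ill, ill_na or na),
        field_of_view_um=fov,
        pixels_per_side=n_pixels,
        numerical_aperture=na,
        medium_index=index,
    )


@pytest.fixture(scope="session")
def tiny_grid():
    """16 px, 5 wavelengths, 21 illumination channels."""
    return make_grid()


@pytest.fixture(scope="session")
def narrow_grid():
    """Narrow fractional bandwidth and illumination margin inside the pupil:
    snapped k_in nodes are identical across wavelengths, so discrete gain
    laws are exact."""
    return make_grid(
        n_pixels=16, n_ill=21, fov=2.2, lam_min=645.0, lam_max=650.0, step=2.5,
        ill_na=0.8,
    )


@pytest.fixture(scope="session")
def correction_grid():
    """24 px, 21 wavelengths at 2.5 nm, 64 channels: the dispersion-recovery
    study grid (lambda-stable node sets, adequate gate suppression)."""
    return make_grid(
        n_pixels=24, n_ill=64, fov=3.3, lam_min=622.5, lam_max=672.5, step=2.5
    )


@pytest.fixture(scope="session")
def point_matrix(tiny_grid):
    obj = make_phantom("point_array", tiny_grid, [0.0], n_points=1)
    return simulate_single_scattering(obj, tiny_grid)


def ideal_reconstruction(obj, grid) -> np.ndarray:
    """Analytic noiseless reconstruction oracle: the object spectrum weighted
    by the pair-count transfer function N(K) at the reference wavelength,
    inverse transformed. Independent of the gating code path."""
    from vrm.matrix import pair_count

    spec = obj.spectrum()[:, :, 0]
    nk = pair_count(grid, grid.spectral.center_wavelength_nm).counts
    return np.fft.ifft2(np.fft.ifftshift(spec * nk), norm="ortho")


def lambda_stable_nodes(matrix) -> bool:
    """True when every channel keeps one snapped node across wavelengths."""
    ki = matrix.kin_index
    return bool(np.all(ki == ki[:, :1, :]) and matrix.kin_inside.all())
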