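"""Scattering-medium description and spectro-angular dispersion screens.

The medium enters the single-scattering model only through the roundtrip
ballistic attenuation ``exp(-2 z / l_s(lambda))`` and the input/output phase
screens ``phi_in(k_in, lambda)``, ``phi_o(k, lambda)``; multiple scattering is
a statistical speckle background with mean intensity ``M(lambda)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .grid import ParameterError, SpectroAngularGrid

__all__ = ["MediumSpec", "DispersionMap", "sample_dispersion"]

#: default scattering mean free path endpoints (nm -> um), linearly
#: interpolated in wavelength between them
DEFAULT_LS_TABLE = ((535.0, 56.1), (760.0, 83.1))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to the storage interval (-pi, pi]."""
    out = np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def circular_rms(phi: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Circular spread ``sqrt(-2 ln |<e^{i phi}>|)`` in radians."""
    p = np.asarray(phi)[mask] if mask is not None else np.asarray(phi).ravel()
    if p.size == 0:
        raise ParameterError("empty support")
    r = np.abs(np.exp(1j * p).mean())
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


@dataclass(frozen=True)
class MediumSpec:
    """Scattering medium parameters.

    Parameters
    ----------
    ls_table_nm_um
        ``((lambda_nm, l_s_um), ...)`` tabulated scattering mean free path;
        linear interpolation between entries, flat extrapolation outside.
        ``l_s = inf`` disables attenuation.
    anisotropy_g
        Scattering anisotropy ``g`` in ``[0, 1)``.
    multiple_scatter_power
        Mean speckle intensity ``M`` per matrix element (scalar, or one value
        per wavelength).
    ms_depth_correlation
        ``rho`` in [0, 1]: correlation between coherence-gated speckle
        backgrounds at different depths, realized by routing that fraction of
        the power of every depth-localized speckle component through one
        shared Gaussian field (see the speckle synthesizer).
    ms_depth_span_um
        Depth range covered by the correlated speckle comb when ``rho > 0``.
    """

    ls_table_nm_um: tuple = DEFAULT_LS_TABLE
    anisotropy_g: float = 0.0
    depth_of_focus_plane_um: float = 0.0
    multiple_scatter_power: float | tuple = 0.0
    ms_depth_correlation: float = 0.0
    ms_depth_span_um: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        tab = np.asarray(self.ls_table_nm_um, dtype=float)
        if tab.ndim != 2 or tab.shape[1] != 2 or np.any(tab[:, 1] <= 0):
            raise ParameterError("l_s table must be (lambda_nm, l_s_um>0) rows")
        if not 0 <= self.anisotropy_g < 1:
            raise ParameterError("anisotropy g must lie in [0, 1)")
        if np.any(np.asarray(self.multiple_scatter_power) < 0):
            raise ParameterError("multiple-scatter power must be >= 0")
        if not 0 <= self.ms_depth_correlation <= 1:
            raise ParameterError("depth correlation must lie in [0, 1]")

    def ls_um(self, lambda_nm) -> np.ndarray:
        tab = np.asarray(self.ls_table_nm_um, dtype=float)
        order = np.argsort(tab[:, 0])
        return np.interp(np.asarray(lambda_nm, dtype=float), tab[order, 0], tab[order, 1])

    def ms_power(self, n_wavelengths: int) -> np.ndarray:
        m = np.asarray(self.multiple_scatter_power, dtype=float)
        if m.ndim == 0:
            return np.full(n_wavelengths, float(m))
        if m.size != n_wavelengths:
            raise ParameterError("per-wavelength M has the wrong length")
        return m


@dataclass
class DispersionMap:
    """Input and output phase screens on the output k-grid.

    ``phi_in`` is a function of the illumination wavevector ``k_in`` sampled
    on the same centered grid as the output pupil (it is looked up at each
    channel's snapped node when applied); ``phi_o`` is a function of the
    output wavevector ``k``. Shapes are ``(N, N, N_lambda)``; values are
    wrapped to (-pi, pi] and meaningful only on the support masks.
    """

    phi_in: np.ndarray
    phi_o: np.ndarray
    support_in: np.ndarray
    support_out: np.ndarray
    wavelengths_nm: tuple
    piston_removed: bool = False
    tilt_removed: bool = False

    def __post_init__(self) -> None:
        if self.phi_in.shape != self.phi_o.shape:
            raise ParameterError("phi_in / phi_o shape mismatch")
        if self.phi_in.shape[2] != len(self.wavelengths_nm):
            raise ParameterError("one screen slab per wavelength required")
        self.phi_in = wrap_phase(np.where(self.support_in, self.phi_in, 0.0))
        self.phi_o = wrap_phase(np.where(self.support_out, self.phi_o, 0.0))

    @classmethod
    def zeros(cls, grid: SpectroAngularGrid) -> "DispersionMap":
        n = grid.pixels_per_side
        nl = grid.spectral.n_wavelengths
        support = np.stack(
            [grid.pupil_mask(w) for w in grid.spectral.wavelengths_nm], axis=-1
        )
        z = np.zeros((n, n, nl))
        return cls(
            phi_in=z.copy(),
            phi_o=z.copy(),
            support_in=support.copy(),
            support_out=support.copy(),
            wavelengths_nm=grid.spectral.wavelengths_nm,
        )

    def is_zero(self) -> bool:
        return not (np.any(self.phi_in) or np.any(self.phi_o))

    def sample_in(self, node_index: np.ndarray, l: int) -> np.ndarray:
        """phi_in at snapped illumination nodes, wavelength index ``l``."""
        idx = np.atleast_2d(node_index)
        return self.phi_in[idx[:, 0], idx[:, 1], l]

    def compose(self, other: "DispersionMap") -> "DispersionMap":
        """Elementwise sum of screens (wrapped); supports are intersected for
        phi_in/phi_o where both are defined, united otherwise."""
        if self.phi_in.shape != other.phi_in.shape:
            raise ParameterError("cannot compose maps on different grids")
        return DispersionMap(
            phi_in=wrap_phase(self.phi_in + other.phi_in),
            phi_o=wrap_phase(self.phi_o + other.phi_o),
            support_in=self.support_in | other.support_in,
            support_out=self.support_out | other.support_out,
            wavelengths_nm=self.wavelengths_nm,
        )

    def negate(self) -> "DispersionMap":
        return DispersionMap(
            phi_in=wrap_phase(-self.phi_in),
            phi_o=wrap_phase(-self.phi_o),
            support_in=self.support_in.copy(),
            support_out=self.support_out.copy(),
            wavelengths_nm=self.wavelengths_nm,
        )


def _fit_tilt_once(phi: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    e = np.exp(1j * phi)
    gy_pairs = e[1:, :] * e[:-1, :].conj()
    my = mask[1:, :] & mask[:-1, :]
    gx_pairs = e[:, 1:] * e[:, :-1].conj()
    mx = mask[:, 1:] & mask[:, :-1]
    gy = float(np.angle(gy_pairs[my].mean())) if my.any() else 0.0
    gx = float(np.angle(gx_pairs[mx].mean())) if mx.any() else 0.0
    return gy, gx


def remove_tilt(phi: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Remove the linear (tilt) component of a wrapped phase screen.

    The gradient is estimated from nearest-neighbour phase-difference
    phasors (unwrap-free) and a centered plane is subtracted; the fit is
    iterated to its fixed point so the returned screen has exactly zero
    fitted tilt, making "tilt-free" a well-defined gauge. Returns the
    de-tilted screen and the total fitted gradient per pixel.
    """
    phi = np.asarray(phi, dtype=float)
    n0, n1 = phi.shape
    y, x = np.mgrid[0:n0, 0:n1]
    y = y - n0 // 2
    x = x - n1 // 2
    total = np.array([0.0, 0.0])
    work = phi
    for _ in range(12):
        gy, gx = _fit_tilt_once(work, mask)
        total += (gy, gx)
        work = wrap_phase(phi - total[0] * y - total[1] * x)
        if max(abs(gy), abs(gx)) < 1e-10:
            break
    return work, (total[0], total[1])


def _smooth_screen(rng, n: int, sigma_px: float) -> np.ndarray:
    noise = rng.standard_normal((n, n))
    if sigma_px > 0:
        noise = gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    return noise


def _scale_to_rms(screen: np.ndarray, mask: np.ndarray, target: float) -> np.ndarray:
    """Scale a zero-mean screen so its circular RMS over ``mask`` hits
    ``target`` (the two agree to first order but diverge for strong phases)."""
    base = screen[mask]
    lin = np.std(base)
    if lin == 0 or target == 0:
        return np.zeros_like(screen)

    def f(s):
        return circular_rms(s * base) - target

    hi = target / lin
    while f(hi) < 0 and hi < 1e4 * target / lin:
        hi *= 2.0
    try:
        s = brentq(f, 0.0, hi)
    except ValueError:
        s = target / lin
    return s * screen


def sample_dispersion(
    grid: SpectroAngularGrid,
    strength_rad: float,
    correlation_length: float = 0.25,
    spectral_model: str = "separable",
    seed: int = 0,
) -> DispersionMap:
    """Random smooth spectro-angular dispersion screens.

    The angular parts are filtered Gaussian noise with correlation length
    expressed as a fraction of the pupil radius at the reference wavelength;
    their circular RMS over that pupil equals ``strength_rad``. The spectral
    part is zero at the reference wavelength; with ``spectral_model ==
    'separable'`` it is an independent random offset per wavelength of the
    same RMS scale, with ``'polynomial_in_inv_lambda'`` it is a group-delay +
    group-delay-dispersion polynomial in ``1/lambda - 1/lambda_c``.
    """
    if strength_rad < 0:
        raise ParameterError("dispersion strength must be >= 0")
    if correlation_length <= 0:
        raise ParameterError("correlation length must be positive")
    if spectral_model not in ("separable", "polynomial_in_inv_lambda", "none"):
        raise ParameterError(f"unknown spectral model {spectral_model!r}")

    n = grid.pixels_per_side
    wav = grid.spectral.wavelengths_nm
    nl = len(wav)
    ic = grid.spectral.center_index
    lam_c = wav[ic]
    out = DispersionMap.zeros(grid)
    if strength_rad == 0:
        return out

    rng = np.random.default_rng(seed)
    mask_c = grid.pupil_mask(lam_c)
    sigma_px = correlation_length * grid.pupil_radius(lam_c) / grid.dk

    phi = {}
    for name in ("in", "out"):
        ang = _scale_to_rms(_smooth_screen(rng, n, sigma_px), mask_c, strength_rad)
        if name == "out":
            # a tilt of the output screen is the unobservable joint-gauge
            # mode (it only translates the image); draw it tilt-free so
            # estimates and reconstructions are registered with the phantom
            ang = _scale_to_rms(remove_tilt(ang, mask_c)[0], mask_c, strength_rad)
            ang, _ = remove_tilt(ang, mask_c)
        if spectral_model == "none":
            spec = np.zeros(nl)
        elif spectral_model == "separable":
            spec = strength_rad * rng.standard_normal(nl)
            spec[ic] = 0.0
        else:
            u = 1.0 / np.asarray(wav) - 1.0 / lam_c
            u = u / np.max(np.abs(u)) if np.max(np.abs(u)) > 0 else u
            a1, a2 = strength_rad * rng.standard_normal(2)
            spec = a1 * u + a2 * u * u
        phi[name] = ang[:, :, None] + spec[None, None, :]

    return DispersionMap(
        phi_in=phi["in"],
        phi_o=phi["out"],
        support_in=out.support_in,
        support_out=out.support_out,
        wavelengths_nm=wav,
    )
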