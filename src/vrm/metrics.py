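"""Scalar theory: fidelity, complexity, resolution and signal metrics.

The working condition of correlation-based dispersion estimation is set by
``C_rel = (S/M) * zeta * sqrt(N)`` — the relative weight of single-scattered
waves in the estimation correlations — where ``S`` and ``M`` are the mean
single- and multiple-scattering intensities per detection element, ``N`` is
the effective number of elements entering the cross-correlation of the pupil
functions, and ``zeta`` in (0, 1] quantifies how much the residual input and
output angular dispersions decorrelate the sums (``zeta = 1`` when none
remain).

``zeta`` and the effective optical thickness are main-text-consistent
reconstructions: the package defines them so that every stated property
holds (``zeta = 1`` at zero dispersion; roundtrip attenuation
``eta^2 exp(-2z/l_s)``), with ``N`` defaulting to the number of
momentum-difference bins carrying at least one pupil pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ParameterError
from .medium import DispersionMap, circular_rms, remove_tilt, wrap_phase

__all__ = [
    "coherence_gate_fwhm",
    "transport_mfp",
    "strehl_ratio",
    "zeta_complexity",
    "crel",
    "effective_channel_gain",
    "signal_intensity",
    "effective_optical_thickness",
    "image_correlation",
    "circular_rmse",
    "circular_rms",
    "remove_tilt",
    "FidelityReport",
    "ResolutionReport",
]

#: Gaussian-spectrum coherence-gating FWHM constant, 2 ln 2 / pi
_GATE_CONST = 2.0 * np.log(2.0) / np.pi


def coherence_gate_fwhm(lambda_c_nm: float, delta_lambda_nm: float, n: float) -> float:
    """Axial FWHM of the coherence gate, um: ``(2 ln2/pi) lambda_c^2 / (n dl)``.

    This is the depth resolution set by the full spectral bandwidth, quoted
    at the sample (divide-by-index convention).
    """
    if lambda_c_nm <= 0 or delta_lambda_nm <= 0 or n <= 0:
        raise ParameterError("wavelength, bandwidth and index must be positive")
    return _GATE_CONST * lambda_c_nm**2 / (n * delta_lambda_nm) * 1e-3


def transport_mfp(l_s_um: float, g: float) -> float:
    """Transport mean free path ``l_t = l_s / (1 - g)``, um."""
    if not 0 <= g < 1:
        raise ParameterError("anisotropy g must lie in [0, 1)")
    if l_s_um <= 0:
        raise ParameterError("l_s must be positive")
    return l_s_um / (1.0 - g)


def strehl_ratio(phi: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Peak-PSF attenuation of a phase-only pupil screen:
    ``eta = |<e^{i phi}>|^2`` over the pupil support."""
    vals = np.asarray(phi)[mask] if mask is not None else np.asarray(phi).ravel()
    if vals.size == 0:
        raise ParameterError("empty pupil support")
    return float(np.abs(np.exp(1j * vals).mean()) ** 2)


def zeta_complexity(maps: DispersionMap, lambda_nm: float) -> float:
    """Joint complexity of the input and output angular screens at one
    wavelength: ``|<e^{i phi_in}>| * |<e^{i phi_o}>|`` over their supports.

    Equals 1 iff both screens are constant (piston-only) over their support.
    """
    wav = np.asarray(maps.wavelengths_nm)
    l = int(np.argmin(np.abs(wav - lambda_nm)))
    sin = maps.support_in[:, :, l]
    sout = maps.support_out[:, :, l]
    if not (sin.any() and sout.any()):
        raise ParameterError("maps have empty support at this wavelength")
    zin = np.abs(np.exp(1j * maps.phi_in[:, :, l][sin]).mean())
    zout = np.abs(np.exp(1j * maps.phi_o[:, :, l][sout]).mean())
    return float(zin * zout)


def crel(s: float, m: float, zeta: float, n: float) -> float:
    """Estimation fidelity ``C_rel = (S/M) zeta sqrt(N)``."""
    if m <= 0:
        raise ParameterError("multiple-scattering intensity M must be positive")
    if s < 0 or zeta < 0 or n < 0:
        raise ParameterError("S, zeta and N must be non-negative")
    return (s / m) * zeta * np.sqrt(n)


def effective_channel_gain(n_z: int, background_amp_gain: float) -> float:
    """Fold-increase of effective detection channels from merging ``n_z``
    depths whose coherently added background amplitude grew by the given
    factor: the squared fidelity gain ``(n_z / gain)^2`` read as a channel
    multiplier, ``n_z^2 / gain^2``."""
    if n_z < 1 or background_amp_gain <= 0:
        raise ParameterError("need n_z >= 1 and a positive amplitude gain")
    return float(n_z**2 / background_amp_gain**2)


def signal_intensity(image, target_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean intensity on the target region minus the mean off-target
    intensity (may be negative; reported as-is)."""
    target_mask = np.asarray(target_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if np.any(target_mask & background_mask):
        raise ParameterError("target and background masks overlap")
    if not (target_mask.any() and background_mask.any()):
        raise ParameterError("masks must be non-empty")
    inten = image.intensity if hasattr(image, "intensity") else np.abs(np.asarray(image)) ** 2
    return float(inten[target_mask].mean() - inten[background_mask].mean())


def effective_optical_thickness(z_um: float, l_s_um: float, eta: float) -> float:
    """One-way thickness (in multiples of ``l_s``) whose pure-scattering
    roundtrip attenuation equals the combined ``eta^2 exp(-2z/l_s)``:
    ``l_eff / l_s = z/l_s - ln(eta)``."""
    if z_um <= 0 or l_s_um <= 0:
        raise ParameterError("depth and l_s must be positive")
    if not 0 < eta <= 1:
        raise ParameterError("Strehl ratio must lie in (0, 1]")
    return float(z_um / l_s_um - np.log(eta))


def image_correlation(a, b, register: bool = False) -> float:
    """Pearson correlation of two intensity images (complex inputs are
    converted to intensity).

    With ``register=True`` the first image is aligned to the second by the
    integer shift maximizing their cross-correlation before comparing —
    useful when an unobservable dispersion tilt has translated the
    reconstruction.
    """
    def inten(x):
        arr = x.intensity if hasattr(x, "intensity") else np.asarray(x)
        if np.iscomplexobj(arr):
            arr = np.abs(arr) ** 2
        return arr.astype(float)

    u, v = inten(a), inten(b)
    if register and u.ndim == 2 and u.shape == v.shape:
        xc = np.fft.ifft2(
            np.fft.fft2(u - u.mean()) * np.conj(np.fft.fft2(v - v.mean()))
        )
        sy, sx = np.unravel_index(np.argmax(np.abs(xc)), xc.shape)
        u = np.roll(np.roll(u, -int(sy), axis=0), -int(sx), axis=1)
    u = u.ravel() - u.mean()
    v = v.ravel() - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0:
        return 0.0
    return float((u @ v) / denom)


def circular_rmse(
    estimate: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    remove_piston: bool = True,
) -> float:
    """Circular RMS of the wrapped difference between two phase maps.

    A constant offset (piston) between the screens is unobservable, so it is
    removed by default before computing the RMS.
    """
    d = wrap_phase(np.asarray(estimate) - np.asarray(truth))
    vals = d[mask] if mask is not None else d.ravel()
    if vals.size == 0:
        raise ParameterError("empty support")
    if remove_piston:
        vals = wrap_phase(vals - np.angle(np.exp(1j * vals).mean()))
    return float(np.sqrt(np.mean(vals**2)))


@dataclass
class FidelityReport:
    """Inputs and value of the fidelity parameter ``C_rel``."""

    s: float
    m: float
    n_effective: float
    zeta: float
    s_lambda: np.ndarray | None = None
    m_lambda: np.ndarray | None = None

    @property
    def c_rel(self) -> float:
        return crel(self.s, self.m, self.zeta, self.n_effective)

    def to_dict(self) -> dict:
        def clean(x):
            return float(x) if np.isfinite(x) else None

        return {
            "S": clean(self.s),
            "M": clean(self.m),
            "N_effective": self.n_effective,
            "zeta": self.zeta,
            "C_rel": clean(self.c_rel) if np.isfinite(self.m) and self.m > 0 else None,
            "S_lambda": None if self.s_lambda is None else list(map(float, self.s_lambda)),
            "M_lambda": None if self.m_lambda is None else list(map(float, self.m_lambda)),
        }

    @classmethod
    def from_record(cls, record, grid, maps: DispersionMap | None = None) -> "FidelityReport":
        """Build from a simulation ground-truth record.

        ``N`` defaults to the number of momentum-difference bins with at
        least one admissible pupil pair at the reference wavelength; ``zeta``
        is evaluated on the true screens (1 when none were applied).
        """
        from .matrix import pair_count

        lam_c = grid.spectral.center_wavelength_nm
        n_eff = int(pair_count(grid, lam_c).support.sum())
        maps = maps if maps is not None else record.dispersion
        zeta = 1.0 if maps is None else zeta_complexity(maps, lam_c)
        m = record.mean_m
        return cls(
            s=record.mean_s,
            m=m if m > 0 else np.nan,
            n_effective=n_eff,
            zeta=zeta,
            s_lambda=record.s_lambda,
            m_lambda=record.m_lambda,
        )


@dataclass
class ResolutionReport:
    """Measured and analytic resolution figures."""

    axial_fwhm_um: float
    analytic_axial_um: float
    lateral_fwhm_um: float | None = None
    strehl: float | None = None

    def to_dict(self) -> dict:
        return {
            "axial_fwhm_um": self.axial_fwhm_um,
            "analytic_axial_um": self.analytic_axial_um,
            "lateral_fwhm_um": self.lateral_fwhm_um,
            "strehl": self.strehl,
        }
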