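"""Estimation and correction of spectro-angular dispersion from the matrix.

The medium multiplies the single-scattered wave by ``exp(i phi_in(k_in,
lambda))`` and ``exp(i phi_o(k, lambda))``. Both screens are recovered from
the data alone in two steps:

1. *Spectral step* — for each illumination node, the column at wavelength
   ``lambda`` is correlated against the same column at the reference
   wavelength ``lambda_c``; the correlation angle is the relative input
   dispersion. The symmetric row correlation gives the relative output
   dispersion. Input and output passes alternate until the updates vanish.
2. *Angular step* — after spectral correction and coherence gating to a
   target depth, the per-node angular phases at ``lambda_c`` are found from
   correlations between all pairs of gated columns (and, symmetrically, rows
   in the momentum-difference frame). The all-pairs system is solved by the
   consensus iteration: each column is correlated against the coherent sum of
   all other corrected columns, which converges to the fixed point of the
   pairwise phase-difference equations.

Correlations are unweighted sums of elementwise products; amplitudes act as
natural weights. No phase unwrapping is used anywhere: estimates live on
phasors and maps are stored wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import (
    CoherenceGatedMatrix,
    ReconstructedImage,
    coherence_gate,
    confocal_sum,
    kshift_stack,
    per_lambda_normalize,
)
from .grid import ParameterError
from .matrix import FREQUENCY_KIN, VolumetricReflectionMatrix, shift2d
from .medium import DispersionMap, wrap_phase

__all__ = [
    "SpectralEstimate",
    "AngularEstimate",
    "CorrectionResult",
    "estimate_spectral_dispersion",
    "estimate_angular_dispersion",
    "correct_spectro_angular",
    "apply_dispersion",
    "allpairs_phase_solve",
    "DispersionModel",
    "DispersionCorrectionResults",
]

_FLOOR = 1e-30


def _binned(matrix: VolumetricReflectionMatrix):
    """Node-binned view R(k, k_in node, lambda): channels whose snapped
    ``k_in`` coincide are pooled, which aligns the object spectrum across
    wavelengths within each column."""
    from .gating import _node_table

    nodes, node_of = _node_table(matrix)
    n = matrix.grid.pixels_per_side
    nl = matrix.n_wavelengths
    r = np.zeros((n, n, nodes.shape[0], nl), complex)
    for i in range(matrix.n_illuminations):
        for l in range(nl):
            j = node_of[i, l]
            if j >= 0:
                r[:, :, j, l] += matrix.data[:, :, i, l]
    return r, nodes, node_of


@dataclass
class SpectralEstimate:
    """Relative (to lambda_c) spectral dispersion and the corrected matrix."""

    maps: DispersionMap
    matrix: VolumetricReflectionMatrix
    diagnostics: list
    converged: bool
    iterations: int
    flagged: int


def defocus_mode(grid) -> np.ndarray:
    """The depth-re-referencing mode of the spectral estimation:
    ``k_z(k, lambda) - k_z(k, lambda_c)`` on the grid, per wavelength.

    A spectral phase of this shape (scaled by a depth ``dz``) on both
    screens is indistinguishable from shifting the depth origin by ``dz`` —
    a gauge freedom of the relative-dispersion estimate. The estimator
    removes its fitted component so gated depths keep their meaning; without
    this, light from a dominant out-of-focus plane silently re-references
    the depth axis toward that plane.
    """
    wav = grid.spectral.wavelengths_nm
    ic = grid.spectral.center_index
    ref = grid.kz_map(wav[ic])
    return np.stack([grid.kz_map(w) - ref for w in wav], axis=-1)


def _fit_defocus_gauge(phi_in, phi_o, sup_in, sup_out, grid) -> float:
    """Depth offset maximizing the phasor alignment of both screens with the
    defocus mode (coarse scan plus bounded refinement)."""
    from scipy.optimize import minimize_scalar

    mode = defocus_mode(grid)
    m_in = mode[sup_in]
    m_out = mode[sup_out]
    v_in = phi_in[sup_in]
    v_out = phi_o[sup_out]
    if m_in.size + m_out.size == 0:
        return 0.0

    def score(dz):
        return -(np.cos(v_in - m_in * dz).sum() + np.cos(v_out - m_out * dz).sum())

    wav = grid.spectral.wavelengths_nm
    ic = grid.spectral.center_index
    steps = np.diff(np.asarray(wav))
    if steps.size == 0:
        return 0.0
    # ambiguity (aliasing) period of the on-axis mode
    z_alias = wav[ic] ** 2 * 1e-3 / (grid.medium_index * steps.min())
    grid_dz = np.linspace(-0.5 * z_alias, 0.5 * z_alias, 801)
    vals = [score(d) for d in grid_dz]
    best = grid_dz[int(np.argmin(vals))]
    width = grid_dz[1] - grid_dz[0]
    res = minimize_scalar(
        score, bounds=(best - 2 * width, best + 2 * width), method="bounded"
    )
    return float(res.x)


def estimate_spectral_dispersion(
    matrix: VolumetricReflectionMatrix,
    tol: float = 1e-3,
    max_iter: int = 30,
    remove_defocus_gauge: bool = True,
) -> SpectralEstimate:
    """Recover ``phi(.., lambda) - phi(.., lambda_c)`` for both screens.

    Alternates input (per illumination node) and output (per output node)
    correlation passes against the reference wavelength, each applied
    multiplicatively as ``exp(-i phi_hat)``, until the largest phase update
    falls below ``tol`` or ``max_iter`` is reached. Elements whose
    correlation magnitude is at the machine floor get a zero update and are
    counted as flagged. The fitted depth-re-referencing (defocus) gauge mode
    is removed from the estimate by default (see :func:`defocus_mode`).
    """
    if matrix.basis != FREQUENCY_KIN:
        raise ParameterError("matrix must be in the frequency_kin basis")
    nl = matrix.n_wavelengths
    if nl < 2:
        raise ParameterError("spectral estimation needs at least two wavelengths")
    g = matrix.grid
    ic = g.spectral.center_index
    r, nodes, node_of = _binned(matrix)
    nn = nodes.shape[0]
    n = g.pixels_per_side

    phi_in = np.zeros((nn, nl))
    phi_o = np.zeros((n, n, nl))
    diagnostics = []
    converged = False
    flagged = 0
    it = 0
    for it in range(1, max_iter + 1):
        ref = r[:, :, :, ic]
        c_in = np.einsum("yxnl,yxn->nl", r, ref.conj())
        low = np.abs(c_in) <= _FLOOR
        flagged += int(low[:, np.arange(nl) != ic].sum())
        d_in = np.where(low, 0.0, np.angle(c_in))
        d_in[:, ic] = 0.0
        r *= np.exp(-1j * d_in)[None, None, :, :]
        phi_in += d_in

        c_out = np.einsum("yxnl,yxn->yxl", r, r[:, :, :, ic].conj())
        d_out = np.where(np.abs(c_out) <= _FLOOR, 0.0, np.angle(c_out))
        d_out[:, :, ic] = 0.0
        r *= np.exp(-1j * d_out)[:, :, None, :]
        phi_o += d_out

        step = max(np.abs(d_in).max(), np.abs(d_out).max())
        diagnostics.append(
            {
                "stage": "spectral",
                "iteration": it,
                "max_update_rad": float(step),
                "mean_corr_mag": float(np.abs(c_in).mean()),
            }
        )
        if step < tol:
            converged = True
            break

    # grid-form maps: phi_in scattered onto the occupied nodes per wavelength
    phi_in_grid = np.zeros((n, n, nl))
    sup_in = np.zeros((n, n, nl), dtype=bool)
    for l in range(nl):
        occ = node_of[:, l]
        for i in np.flatnonzero(occ >= 0):
            iy, ix = nodes[occ[i]]
            phi_in_grid[iy, ix, l] = phi_in[occ[i], l]
            sup_in[iy, ix, l] = True
    sup_out = np.stack([g.pupil_mask(w) for w in g.spectral.wavelengths_nm], axis=-1)

    if remove_defocus_gauge:
        dz = _fit_defocus_gauge(phi_in_grid, phi_o, sup_in, sup_out, g)
        if dz != 0.0:
            mode = defocus_mode(g)
            phi_o = wrap_phase(phi_o - mode * dz)
            phi_in_grid = wrap_phase(np.where(sup_in, phi_in_grid - mode * dz, 0.0))
            mode_at_node = mode[nodes[:, 0], nodes[:, 1], :]
            phi_in = wrap_phase(phi_in - mode_at_node * dz)

    # apply the accumulated correction to a copy of the matrix
    out = matrix.copy()
    for l in range(nl):
        out.data[..., l] *= np.exp(-1j * phi_o[:, :, l])[:, :, None]
        sel = node_of[:, l]
        ok = sel >= 0
        fac = np.ones(matrix.n_illuminations, complex)
        fac[ok] = np.exp(-1j * phi_in[sel[ok], l])
        out.data[..., l] *= fac[None, None, :]
    maps = DispersionMap(
        phi_in=phi_in_grid,
        phi_o=np.where(sup_out, phi_o, 0.0),
        support_in=sup_in,
        support_out=sup_out,
        wavelengths_nm=g.spectral.wavelengths_nm,
    )
    return SpectralEstimate(
        maps=maps,
        matrix=out,
        diagnostics=diagnostics,
        converged=converged,
        iterations=it,
        flagged=flagged,
    )


def _consensus_angular(b, nodes, half, tol, max_iter):
    """Consensus-correlation solver for per-node input and per-k output
    phases on a momentum-aligned stack ``b`` of shape (N, N, N_z, N_nodes).

    Multi-depth stacks simply carry ``N_z > 1``: all correlations pool the
    depth axis, which is exactly the merged-depth estimator.
    """
    b = b.copy()
    n = b.shape[0]
    nn = nodes.shape[0]
    phi_in = np.zeros(nn)
    phi_o = np.zeros((n, n))
    diagnostics = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t = b.sum(axis=-1)
        c_in = np.einsum("yxzn,yxz->n", b, t.conj()) - np.einsum(
            "yxzn->n", np.abs(b) ** 2
        )
        d_in = np.where(np.abs(c_in) <= _FLOOR, 0.0, np.angle(c_in))
        b *= np.exp(-1j * d_in)[None, None, None, :]
        phi_in += d_in

        t = b.sum(axis=-1)
        acc = np.zeros((n, n), complex)
        for j, (iy, ix) in enumerate(nodes):
            tmp = (b[:, :, :, j] * (t - b[:, :, :, j]).conj()).sum(axis=2)
            acc += shift2d(tmp, iy - half, ix - half)
        d_out = np.where(np.abs(acc) <= _FLOOR, 0.0, np.angle(acc))
        for j, (iy, ix) in enumerate(nodes):
            b[:, :, :, j] *= np.exp(
                -1j * shift2d(d_out, half - iy, half - ix)
            )[:, :, None]
        phi_o += d_out

        step = max(np.abs(d_in).max(), np.abs(d_out).max())
        diagnostics.append(
            {
                "stage": "angular",
                "iteration": it,
                "max_update_rad": float(step),
                "mean_corr_mag": float(np.abs(c_in).mean()),
            }
        )
        if step < tol:
            converged = True
            break
    return phi_in, phi_o, diagnostics, converged, it


def _remove_piston(phi, mask=None):
    vals = phi[mask] if mask is not None else phi
    if vals.size == 0:
        return phi
    piston = np.angle(np.exp(1j * vals).mean())
    return wrap_phase(phi - piston)


def _gauge_fix(phi_in, phi_o, nodes, grid):
    """Fix the unobservable gauge modes of an angular estimate.

    Pistons are removed from both screens. The joint tilt mode — adding
    ``t.k`` to the output screen and ``-t.k_in`` to the input screen leaves
    everything but a lateral image shift invariant — is fixed by removing
    the fitted tilt from the output screen and compensating the input
    screen, keeping the corrected data self-consistent.
    """
    from .medium import remove_tilt

    half = grid.pixels_per_side // 2
    pupil = grid.pupil_mask(grid.spectral.center_wavelength_nm)
    phi_o = wrap_phase(phi_o)
    phi_o_fix, (gy, gx) = remove_tilt(np.where(pupil, phi_o, 0.0), pupil)
    phi_o_fix = np.where(pupil, phi_o_fix, 0.0)
    # same plane evaluated at the illumination nodes
    comp = gy * (nodes[:, 0] - half) + gx * (nodes[:, 1] - half)
    phi_in_fix = wrap_phase(phi_in + comp)
    phi_in_fix = _remove_piston(phi_in_fix)
    phi_o_fix = np.where(pupil, _remove_piston(phi_o_fix, pupil), 0.0)
    return phi_in_fix, phi_o_fix


@dataclass
class AngularEstimate:
    """Angular dispersion at the reference wavelength, gauge-fixed (piston
    removed from each screen; the joint tilt, which only translates the
    image, is left in place)."""

    phi_in_nodes: np.ndarray
    phi_o: np.ndarray
    nodes: np.ndarray
    gated: CoherenceGatedMatrix
    diagnostics: list
    converged: bool
    iterations: int


def estimate_angular_dispersion(
    cg: CoherenceGatedMatrix,
    tol: float = 1e-3,
    max_iter: int = 30,
) -> AngularEstimate:
    """Recover ``phi_in(k_in, lambda_c)`` and ``phi_o(k, lambda_c)`` from a
    coherence-gated matrix (built from a spectrally corrected stack).

    Non-convergence at ``max_iter`` is reported through the ``converged``
    flag with full diagnostics, not as an exception.
    """
    half = cg.grid.pixels_per_side // 2
    b = kshift_stack(cg)[:, :, None, :]
    phi_in, phi_o, diagnostics, converged, it = _consensus_angular(
        b, cg.nodes, half, tol, max_iter
    )
    phi_in, phi_o = _gauge_fix(wrap_phase(phi_in), phi_o, cg.nodes, cg.grid)

    corrected = cg.copy()
    for j in range(cg.n_nodes):
        corrected.data[:, :, j] *= np.exp(-1j * phi_in[j])
    corrected.data *= np.exp(-1j * phi_o)[:, :, None]
    return AngularEstimate(
        phi_in_nodes=phi_in,
        phi_o=phi_o,
        nodes=cg.nodes,
        gated=corrected,
        diagnostics=diagnostics,
        converged=converged,
        iterations=it,
    )


def allpairs_phase_solve(b, nodes=None):
    """Explicit all-pairs solver used as an independent oracle on small sets.

    Builds the pairwise correlation matrix ``C_ij = sum_K b_i b_j*`` of the
    momentum-aligned columns and returns the per-column phases as the angle
    of the leading eigenvector of ``C`` (the least-squares solution of the
    pairwise phase-difference system), piston-removed.
    """
    cols = b.reshape(-1, b.shape[-1])
    c = cols.T @ cols.conj()
    w, v = np.linalg.eigh(c)
    lead = v[:, np.argmax(w)]
    phases = np.angle(lead)
    return _remove_piston(wrap_phase(phases))


def apply_dispersion(
    matrix: VolumetricReflectionMatrix,
    maps: DispersionMap,
    sign: int = 1,
) -> VolumetricReflectionMatrix:
    """Multiply each element by ``exp(sign * i (phi_in + phi_o))``.

    ``sign=+1`` imprints the screens (as the medium does), ``sign=-1``
    removes them; the two compose to the identity exactly.
    """
    g = matrix.grid
    n = g.pixels_per_side
    nl = matrix.n_wavelengths
    if maps.phi_in.shape != (n, n, nl):
        raise ParameterError("dispersion maps do not match the matrix grid")
    out = matrix.copy()
    ki = matrix.kin_index
    for l in range(nl):
        out.data[..., l] *= np.exp(sign * 1j * maps.phi_o[:, :, l])[:, :, None]
        v = maps.phi_in[ki[:, l, 0], ki[:, l, 1], l]
        out.data[..., l] *= np.exp(sign * 1j * v)[None, None, :]
    return out


@dataclass
class CorrectionResult:
    """Outcome of the iterated two-step correction."""

    maps: DispersionMap
    matrix: VolumetricReflectionMatrix
    diagnostics: list
    converged: bool
    iterations: int
    signal_history: list = field(default_factory=list)


def correct_spectro_angular(
    matrix: VolumetricReflectionMatrix,
    z_t: float,
    outer_iters: int = 3,
    normalize: bool = False,
    reference: np.ndarray | None = None,
    spectral: bool = True,
    tol: float = 1e-3,
    max_iter: int = 30,
    flatten: bool = False,
) -> tuple[CorrectionResult, ReconstructedImage]:
    """Full pipeline: spectral step, coherence gating, angular step, iterated.

    Each outer iteration estimates the relative spectral dispersion on the
    working matrix, gates to ``z_t``, estimates the angular dispersion at the
    reference wavelength, and re-applies the angular correction to the full
    matrix before the next round. ``spectral=False`` disables the spectral
    step (the broadband-matrix baseline, which can only correct angular
    dispersion at the center wavelength). The composed maps are
    ``phi(:, lambda) = relative-spectral + angular-at-lambda_c``.
    """
    from .gating import propagate_to_depth

    g = matrix.grid
    n = g.pixels_per_side
    nl = matrix.n_wavelengths
    # bring the target plane to focus first, so its defocus phases cannot be
    # absorbed into the estimated dispersion screens
    work = propagate_to_depth(matrix, z_t)
    if normalize:
        work, _ = per_lambda_normalize(work, reference=reference)

    spec_in = np.zeros((n, n, nl))
    spec_o = np.zeros((n, n, nl))
    ang_in = np.zeros((n, n))
    ang_o = np.zeros((n, n))
    sup_in = np.zeros((n, n, nl), dtype=bool)
    diagnostics = []
    signal_history = []
    converged = True
    iterations = 0
    last_est = None

    for outer in range(1, outer_iters + 1):
        if spectral and nl >= 2:
            se = estimate_spectral_dispersion(work, tol=tol, max_iter=max_iter)
            work = se.matrix
            spec_in += se.maps.phi_in
            spec_o += se.maps.phi_o
            sup_in |= se.maps.support_in
            for d in se.diagnostics:
                diagnostics.append({"outer": outer, **d})
            iterations += se.iterations
            converged = converged and se.converged
        cg = coherence_gate(work, 0.0)
        ae = estimate_angular_dispersion(cg, tol=tol, max_iter=max_iter)
        last_est = ae
        for d in ae.diagnostics:
            diagnostics.append({"outer": outer, **d})
        iterations += ae.iterations
        converged = converged and ae.converged
        # re-apply the angular correction to the full matrix, every wavelength
        in_grid = np.zeros((n, n))
        for j, (iy, ix) in enumerate(ae.nodes):
            in_grid[iy, ix] = ae.phi_in_nodes[j]
            sup_in[iy, ix, :] = True
        ang_in = wrap_phase(ang_in + in_grid)
        ang_o = wrap_phase(ang_o + ae.phi_o)
        ki = work.kin_index
        for l in range(nl):
            work.data[..., l] *= np.exp(-1j * ae.phi_o)[:, :, None]
            v = in_grid[ki[:, l, 0], ki[:, l, 1]]
            work.data[..., l] *= np.exp(-1j * v)[None, None, :]
        image = confocal_sum(coherence_gate(work, 0.0), flatten=flatten)
        image.depth_um = float(z_t)
        signal_history.append(image.total_intensity)

    sup_out = np.stack([g.pupil_mask(w) for w in g.spectral.wavelengths_nm], axis=-1)
    maps = DispersionMap(
        phi_in=wrap_phase(spec_in + ang_in[:, :, None]),
        phi_o=wrap_phase(spec_o + ang_o[:, :, None]),
        support_in=sup_in,
        support_out=sup_out,
        wavelengths_nm=g.spectral.wavelengths_nm,
        piston_removed=True,
    )
    result = CorrectionResult(
        maps=maps,
        matrix=work,
        diagnostics=diagnostics,
        converged=converged,
        iterations=iterations,
        signal_history=signal_history,
    )
    return result, image


# ---------------------------------------------------------------------------
# model-style front end


class DispersionModel:
    """Dispersion-estimation model for a measured or simulated matrix.

    Follows the model/results pattern: the model holds the data and the
    estimation settings, ``fit`` runs the two-step iterated correction and
    returns a results object with the estimated screens, the corrected
    matrix, the reconstructed image and convergence diagnostics.

    Parameters
    ----------
    matrix
        Volumetric reflection matrix in the frequency basis.
    target_depth_um
        Depth used for coherence gating during the angular step.
    normalize
        Equalize per-wavelength single-scattering intensity first.
    spectral
        Include the spectral step (disable for the broadband baseline).
    """

    def __init__(
        self,
        matrix: VolumetricReflectionMatrix,
        target_depth_um: float = 0.0,
        normalize: bool = False,
        reference: np.ndarray | None = None,
        spectral: bool = True,
    ):
        if matrix.basis != FREQUENCY_KIN:
            raise ParameterError("matrix must be in the frequency_kin basis")
        self.matrix = matrix
        self.target_depth_um = target_depth_um
        self.normalize = normalize
        self.reference = reference
        self.spectral = spectral

    def fit(
        self,
        outer_iters: int = 3,
        tol: float = 1e-3,
        max_iter: int = 30,
    ) -> "DispersionCorrectionResults":
        result, image = correct_spectro_angular(
            self.matrix,
            self.target_depth_um,
            outer_iters=outer_iters,
            normalize=self.normalize,
            reference=self.reference,
            spectral=self.spectral,
            tol=tol,
            max_iter=max_iter,
        )
        return DispersionCorrectionResults(self, result, image)


class DispersionCorrectionResults:
    """Estimates, diagnostics and reconstruction from a fitted model."""

    def __init__(self, model: DispersionModel, result: CorrectionResult, image):
        self.model = model
        self.result = result
        self.image = image

    @property
    def maps(self) -> DispersionMap:
        return self.result.maps

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def iterations(self) -> int:
        return self.result.iterations

    @property
    def signal_history(self):
        return self.result.signal_history

    def summary(self) -> str:
        from .metrics import strehl_ratio, zeta_complexity

        g = self.model.matrix.grid
        ic = g.spectral.center_index
        lam_c = g.spectral.center_wavelength_nm
        pupil = g.pupil_mask(lam_c)
        eta = strehl_ratio(self.maps.phi_o[:, :, ic], pupil)
        zeta = zeta_complexity(self.maps, lam_c)
        lines = [
            "Spectro-angular dispersion correction",
            "=" * 44,
            f"wavelengths            {g.spectral.n_wavelengths:>10d}",
            f"illumination channels  {g.n_illuminations:>10d}",
            f"target depth (um)      {self.image.depth_um:>10.3f}",
            f"outer/total iterations {len(self.signal_history):>4d} /{self.iterations:>4d}",
            f"converged              {str(self.converged):>10s}",
            f"est. Strehl @ lam_c    {eta:>10.4f}",
            f"est. complexity zeta   {zeta:>10.4f}",
            f"final signal intensity {self.signal_history[-1]:>10.4g}",
        ]
        return "\n".join(lines)
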