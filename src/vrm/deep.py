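"""Deep-imaging strategies: progressive depth imaging and multi-depth
(volumetric) dispersion correction.

Progressive imaging solves the dispersion at a shallow depth first, removes
it from the whole matrix, and then solves only the *residual* dispersion at
a deeper plane — trading an unsolvable complexity for a solvable one.
Multi-depth correction concatenates coherence-gated matrices from several
depths so the estimation correlations pool single-scattering signal from a
volume: signal correlations grow with the number of merged depths ``N_z``
while mutually independent backgrounds grow only as ``sqrt(N_z)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correction import (
    CorrectionResult,
    _consensus_angular,
    _gauge_fix,
    apply_dispersion,
    correct_spectro_angular,
    estimate_angular_dispersion,
)
from .gating import (
    CoherenceGatedMatrix,
    ReconstructedImage,
    coherence_gate,
    confocal_sum,
    kshift_stack,
)
from .grid import ParameterError, SpectroAngularGrid
from .matrix import VolumetricReflectionMatrix
from .medium import DispersionMap, wrap_phase

__all__ = [
    "MultiDepthMatrix",
    "LayerDispersion",
    "ProgressiveResult",
    "MultiDepthResult",
    "ProgressiveAbort",
    "build_multidepth",
    "multidepth_correct",
    "background_amplitude_gain",
    "progressive_correct",
    "zeta_gain",
]


class ProgressiveAbort(RuntimeError):
    """Raised when the upper-layer correction of a progressive run fails;
    carries the upper-layer diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class MultiDepthMatrix:
    """Coherence-gated matrices from several depths, stacked block-wise.

    ``blocks[i]`` equals the gated matrix at ``depths_um[i]`` elementwise
    (shape (N_z, N, N, N_nodes)); the momentum alignment used by the
    estimator is applied on demand. The logical output axis of the merged
    matrix is the concatenation of the per-depth output blocks.
    """

    blocks: np.ndarray
    nodes: np.ndarray
    depths_um: np.ndarray
    lambda_c_nm: float
    grid: SpectroAngularGrid

    @property
    def n_depths(self) -> int:
        return self.blocks.shape[0]

    @property
    def output_size(self) -> int:
        """Length of the concatenated output axis."""
        n = self.grid.pixels_per_side
        return self.n_depths * n * n

    def gated(self, i: int) -> CoherenceGatedMatrix:
        return CoherenceGatedMatrix(
            data=self.blocks[i].copy(),
            nodes=self.nodes.copy(),
            target_depth_um=float(self.depths_um[i]),
            lambda_c_nm=self.lambda_c_nm,
            grid=self.grid,
        )


def build_multidepth(matrix: VolumetricReflectionMatrix, z_list) -> MultiDepthMatrix:
    """Gate the (spectrally corrected) matrix at each requested depth and
    append the results along the output axis."""
    z = np.atleast_1d(np.asarray(z_list, dtype=float))
    if z.size < 1:
        raise ParameterError("need at least one depth")
    gates = [coherence_gate(matrix, zt) for zt in z]
    nodes = gates[0].nodes
    blocks = np.stack([gt.data for gt in gates], axis=0)
    return MultiDepthMatrix(
        blocks=blocks,
        nodes=nodes,
        depths_um=z,
        lambda_c_nm=gates[0].lambda_c_nm,
        grid=matrix.grid,
    )


@dataclass
class MultiDepthResult:
    phi_in_nodes: np.ndarray
    phi_o: np.ndarray
    nodes: np.ndarray
    images: list
    diagnostics: list
    converged: bool
    iterations: int


def multidepth_correct(
    md: MultiDepthMatrix,
    tol: float = 1e-3,
    max_iter: int = 30,
    equalize_blocks: bool = False,
    check_isoplanatism: bool = False,
) -> MultiDepthResult:
    """Single angular-dispersion estimate shared by all merged depths.

    The consensus correlations run over the concatenated output axis, i.e.
    they sum over all depth blocks jointly (the axial-isoplanatic
    assumption: one screen is valid across the merged range). With
    ``equalize_blocks`` each depth block is amplitude-normalized first to
    compensate depth-dependent attenuation; default off. With ``N_z = 1``
    the estimate is identical to the single-depth estimator.
    """
    half = md.grid.pixels_per_side // 2
    stack = []
    for i in range(md.n_depths):
        b = kshift_stack(md.gated(i))
        if equalize_blocks:
            rms = np.sqrt(np.mean(np.abs(b) ** 2))
            if rms > 0:
                b = b / rms
        stack.append(b)
    b = np.stack(stack, axis=2)  # (N, N, N_z, N_nodes)
    phi_in, phi_o, diagnostics, converged, it = _consensus_angular(
        b, md.nodes, half, tol, max_iter
    )
    phi_in, phi_o = _gauge_fix(wrap_phase(phi_in), phi_o, md.nodes, md.grid)

    images = []
    for i in range(md.n_depths):
        cg = md.gated(i)
        for j in range(cg.n_nodes):
            cg.data[:, :, j] *= np.exp(-1j * phi_in[j])
        cg.data *= np.exp(-1j * phi_o)[:, :, None]
        images.append(confocal_sum(cg))

    if check_isoplanatism and md.n_depths > 1:
        spread = _isoplanatism_spread(md, tol, max_iter)
        if spread > 0.5:
            warnings.warn(
                f"per-depth angular estimates differ by {spread:.2f} rad RMS; "
                "the merged depths may not share one dispersion",
                stacklevel=2,
            )
    return MultiDepthResult(
        phi_in_nodes=phi_in,
        phi_o=phi_o,
        nodes=md.nodes,
        images=images,
        diagnostics=diagnostics,
        converged=converged,
        iterations=it,
    )


def _isoplanatism_spread(md: MultiDepthMatrix, tol, max_iter) -> float:
    """Circular RMS spread of per-depth output-screen estimates."""
    from .metrics import circular_rmse

    pupil = md.grid.pupil_mask(md.lambda_c_nm)
    maps = []
    for i in range(md.n_depths):
        est = estimate_angular_dispersion(md.gated(i), tol=tol, max_iter=max_iter)
        maps.append(est.phi_o)
    spreads = [circular_rmse(m, maps[0], pupil) for m in maps[1:]]
    return float(np.max(spreads)) if spreads else 0.0


def background_amplitude_gain(md: MultiDepthMatrix) -> float:
    """Amplitude growth of the coherently added gated backgrounds.

    The pairwise correlations between the gated fields of different depths
    are accumulated by magnitude (phase-aligned addition), which is the
    quantity that degrades the merged-depth estimator — the background terms
    of its correlations combine across depth blocks through the squared
    correlation magnitude, independent of its phase. For backgrounds that
    are independent between depths the gain is ``sqrt(N_z)``; full
    correlation pushes it to ``N_z``. Used with speckle-only input to
    quantify the effective channel gain ``N_z^2 / gain^2`` of merging.
    """
    pupil = md.grid.pupil_mask(md.lambda_c_nm)
    x = np.stack(
        [md.blocks[i][pupil, :].ravel() for i in range(md.n_depths)], axis=0
    )
    c = x @ x.conj().T
    power = np.mean(np.real(np.diag(c)))
    if power == 0:
        raise ParameterError("empty gated blocks")
    return float(np.sqrt(np.abs(c).sum() / power))


@dataclass
class LayerDispersion:
    """Upper-layer, residual and composed dispersion screens.

    The composition ``phi^L = phi^U + phi^(L-U)`` holds exactly (mod 2 pi)
    by construction.
    """

    upper: DispersionMap
    residual: DispersionMap
    composed: DispersionMap = field(init=False)

    def __post_init__(self) -> None:
        self.composed = self.upper.compose(self.residual)


@dataclass
class ProgressiveResult:
    layers: LayerDispersion
    image_upper: ReconstructedImage
    image_lower: ReconstructedImage
    upper_result: CorrectionResult
    lower_result: CorrectionResult


def progressive_correct(
    matrix: VolumetricReflectionMatrix,
    z_upper: float,
    z_lower: float,
    outer_iters: int = 3,
    require_upper_convergence: bool = True,
    lower_spectral: bool = False,
    **kwargs,
) -> ProgressiveResult:
    """Use the dispersion solved at a shallow depth to image a deeper one.

    1. run the full correction at ``z_upper`` to obtain the upper-layer
       screens ``phi^U(., lambda)`` (all wavelengths);
    2. pre-correct the whole matrix,
       ``E~_c = e^{-i phi_o^U} E~ e^{-i phi_in^U}``;
    3. run the correction on the pre-corrected matrix at ``z_lower``, which
       now faces only the residual screens ``phi^(L-U)``;
    4. compose the net lower-layer dispersion ``phi^L = phi^U + phi^(L-U)``.

    The lower stage estimates the residual *angular* screens at the
    reference wavelength by default (``lower_spectral=False``): the shared
    medium spectral dispersion was already removed with the upper maps, and
    re-estimating spectral dispersion on a matrix dominated by the
    out-of-gate upper-layer light is ill-posed — two depth planes compete as
    the phase reference of the wavelength correlations.

    Progressive imaging requires a solvable upper layer: if the upper-layer
    estimation has not settled — its final angular phase update exceeds
    ``settle_tol`` (updates settle at the noise level when the solve
    succeeds, but stay large when it fails) — the run aborts with the
    upper-layer diagnostics attached.
    """
    if not z_upper < z_lower:
        raise ParameterError("z_upper must be shallower than z_lower")
    settle_tol = kwargs.pop("settle_tol", 0.1)
    res_u, img_u = correct_spectro_angular(
        matrix, z_upper, outer_iters=outer_iters, **kwargs
    )
    if require_upper_convergence and not res_u.converged:
        last_angular = [
            d["max_update_rad"] for d in res_u.diagnostics if d["stage"] == "angular"
        ]
        if not last_angular or last_angular[-1] > settle_tol:
            raise ProgressiveAbort(
                "upper-layer dispersion correction did not settle",
                res_u.diagnostics,
            )
    pre = apply_dispersion(matrix, res_u.maps, sign=-1)
    res_l, img_l = correct_spectro_angular(
        pre, z_lower, outer_iters=outer_iters, spectral=lower_spectral, **kwargs
    )
    layers = LayerDispersion(upper=res_u.maps, residual=res_l.maps)
    return ProgressiveResult(
        layers=layers,
        image_upper=img_u,
        image_lower=img_l,
        upper_result=res_u,
        lower_result=res_l,
    )


def zeta_gain(zeta_before: float, zeta_after: float) -> float:
    """Fold-change of the estimation fidelity ``C_rel`` when pre-correction
    replaces a complexity ``zeta_before`` by ``zeta_after``.

    Interpreted as the effective single-scattering-intensity gain: removing
    upper-layer dispersion lets correlations use the signal as if it were
    ``1/|zeta|`` times stronger.
    """
    if zeta_before <= 0:
        raise ParameterError("zeta_before must be positive")
    return float(zeta_after / zeta_before)
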