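# vrm — volumetric reflection-matrix microscopy

`vrm` simulates and reconstructs **volumetric reflection matrices**: the set
of complex backscattered fields `E~(k; k_in, λ)` recorded for every
combination of illumination wavevector `k_in` and wavelength `λ` when imaging
an object embedded in a scattering, dispersive medium. It is aimed at
researchers in computational adaptive optics and coherence-gated microscopy
who want a controlled, fully synthetic test bed for matrix-based
reconstruction and dispersion-correction algorithms.

## The model

A target with reflectivity `O(r, z)` behind a scattering medium returns, for
each illumination node and wavelength, a single-scattered spectrum obeying
object momentum conservation,

    E~_S(k; k_in, λ) = e^{i φ_in(k_in, λ)} e^{i φ_o(k, λ)}
                       Σ_z e^{-2z/l_s(λ)} O~(k - k_in, z)
                       e^{i k_z^in(λ) z} e^{i k_z(λ) z},

with `k_z = sqrt((2πn/λ)² − |k|²)`, scattering mean free path `l_s(λ)`, and
input/output **spectro-angular dispersion** screens `φ_in`, `φ_o` imparted by
the medium. Multiple scattering adds a circular-Gaussian speckle background
of mean intensity `M(λ)` per element.

Reconstruction combines two gates:

* **coherence gating** — `E~_cg(k, z_t; k_in) = Σ_λ E~ e^{-i(k_z^in + k_z) z_t}`
  isolates the roundtrip path length of depth `z_t`;
* **confocal gating** — columns are aligned to the momentum difference
  `K = k − k_in` and summed over illumination, so single-scattered waves grow
  by `N_λ N(K)` while speckle adds incoherently (amplitude SNR gain
  `sqrt(N_λ N(K))`).

The dispersion screens are estimated from the matrix itself by a two-step,
iterated correlation procedure (spectral step against the reference
wavelength `λ_c`, then angular step on the gated matrix, realized as a
consensus iteration over all channel pairs). Two deep-imaging strategies
build on it: **progressive depth imaging** (screens solved at a shallow
plane pre-correct the matrix for a deeper one) and **multi-depth correction**
(gated matrices from `N_z` depths are concatenated so the estimator pools
single-scattering signal from a volume, raising the fidelity
`C_rel = (S/M) ζ sqrt(N)` by `sqrt(N_z)`).

## Worked example

Simulate a Siemens-star phantom behind a dispersive, scattering medium and
recover it with the model/results interface:

```python
import numpy as np
from vrm import (SpectroAngularGrid, build_spectral_axis, fermat_spiral_angles,
                 make_phantom, sample_dispersion, simulate_reflection_matrix,
                 DispersionModel, coherence_gate_fwhm)
from vrm.medium import MediumSpec

grid = SpectroAngularGrid(
    spectral=build_spectral_axis(622.5, 672.5, 2.5, 15.0),  # 21 lines
    illumination_angles_rad=fermat_spiral_angles(64, 1.0),
    field_of_view_um=3.3, pixels_per_side=24,
    numerical_aperture=1.0, medium_index=1.4,
)
phantom = make_phantom("siemens_star", grid, depths_um=[0.0], n_spokes=6)
medium = MediumSpec(multiple_scatter_power=0.2, seed=7)
screens = sample_dispersion(grid, strength_rad=1.8, correlation_length=0.2, seed=3)
matrix, record = simulate_reflection_matrix(phantom, grid, medium, screens)
print("S/M =", round(record.mean_s / record.mean_m, 2))

results = DispersionModel(matrix, target_depth_um=0.0).fit(outer_iters=3)
print(results.summary())
```

prints

```
S/M = 7.13
Spectro-angular dispersion correction
============================================
wavelengths                    21
illumination channels          64
target depth (um)           0.000
outer/total iterations    3 /  57
converged                    True
est. Strehl @ lam_c        0.0076
est. complexity zeta       0.0116
final signal intensity  1.399e+08
```

The estimated Strehl ratio 0.0076 says the 1.8-rad screens would have
attenuated the focal peak to below 1% of its ideal value; the recovered
screens (`results.maps`) undo that, and `results.image` holds the corrected
coherence-gated confocal reconstruction. The analytic axial resolution for
this 65-nm bandwidth, `coherence_gate_fwhm(647.5, 65, 1.4)`, is 2.03 µm.

A command-line interface wraps the same operations
(`vrm simulate / reconstruct / correct / progressive / multidepth / metrics /
fixtures`); run `vrm --help`.

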