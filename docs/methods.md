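# Methods

## Forward model and its assumptions

The simulator synthesizes the volumetric reflection matrix
`E~(k; k_in, λ)` of a thin-slice phantom stack behind a scattering,
dispersive medium:

* **Single scattering.** Each depth slice contributes its laterally shifted
  object spectrum `O~(k − k_in, z)` with the roundtrip ballistic factor
  `e^{−2z/l_s(λ)}` and the defocus phases `e^{i(k_z^in + k_z) z}`, where the
  axial wavevectors use the medium index (`k_z = sqrt((2πn/λ)² − |k|²)`).
  The depth integral is a plain sum over the discrete slices (phantoms are
  thin layers; no slice-thickness weighting). Depths are measured from the
  objective focus, positive into the sample, so only attenuation
  *differences* between slices are physically meaningful; the overall scale
  is a free normalization.
* **Dispersion.** The medium multiplies the single-scattered wave by pure
  phase screens `e^{iφ_in(k_in, λ)}`, `e^{iφ_o(k, λ)}`, assumed constant over
  the simulated volume (axially isoplanatic) and position-independent.
* **Multiple scattering.** Modeled statistically, not physically: circular
  complex Gaussian speckle, i.i.d. across output node, illumination and
  wavelength, mean intensity `M(λ)` per element inside the pupils. The
  reconstruction and fidelity theory only depend on `S/M` and on the
  independence structure of the background, which this model reproduces; it
  carries no information about the actual scatterer configuration.

Illumination wavevectors are realized **exactly on their snapped grid
nodes** (`k_in` rounded to the nearest node of the centered frequency grid,
spacing `Δk = 2π/FOV`); the acquisition angles are recorded separately. This
makes `K = k − k_in` an exact integer shift and the coherent gain law
`N_λ N(K)` exact on the grid. Converting externally supplied real-space
stacks snaps with an error bounded by `Δk/2` per component; channels whose
snapped node leaves the pupil are zeroed and counted.

## Numerical conventions

* Forward transform `E(r) → E~(k)` uses the `e^{−ik·r}` kernel with
  orthonormal scaling; image recovery uses the inverse kernel. Frequency
  grids are centered (fftshifted), node `(N/2, N/2)` is `k = 0`.
* `k` in rad/µm, `r` and `z` in µm, wavelengths stored in nm.
* Out-of-grid samples in momentum shifts are dropped, never wrapped
  (wrap-around would alias the object spectrum).
* Phases are stored wrapped to `(−π, π]`; no phase unwrapping is used
  anywhere — all estimation operates on phasors.
* The coherence-gated matrix is indexed by the snapped `k_in` node: channels
  whose nodes coincide are pooled. With more than one wavelength this is
  what makes a single per-column momentum shift well defined, since the same
  acquisition angle maps to a different `k_in` at each wavelength.
* The reference wavelength `λ_c` is the scanned line closest to the
  arithmetic midpoint of the span; exact ties resolve to the shorter line.

## Dispersion estimation

The two-step procedure alternates multiplicative phase updates obtained from
unweighted correlation sums (amplitudes act as natural weights):

1. **Spectral step** (on the full matrix, node-binned): input updates per
   `(k_in, λ)` from `⟨E~(k; k_in, λ) E~*(k; k_in, λ_c)⟩_k`, output updates
   per `(k, λ)` from the sum over nodes; iterated until the largest update
   falls below `tol` (default 1e−3 rad) or 30 iterations.
2. **Angular step** (on the coherence-gated matrix at the target depth):
   the all-pairs correlation system is solved by consensus iteration — each
   column is correlated against the coherent sum of all other corrected
   columns — whose fixed point is the least-squares solution of the pairwise
   phase differences. An explicit all-pairs eigenvector solver is shipped
   for small-set cross-checks.

Outer iterations (default 3) alternate the two steps, re-applying the
angular correction to the full matrix. Non-convergence is reported through
a flag with per-iteration diagnostics, never as an exception. Correlation
magnitudes at the machine floor produce zero updates and are counted.

**Gauge modes.** Three families of solutions are indistinguishable from the
data and are pinned explicitly:

* *Pistons* — a constant exchanged between `φ_in` and `φ_o` (per wavelength
  in the spectral step): both screens are returned piston-free.
* *Joint tilt* — adding `t·k` to the output screen and `−t·k_in` to the
  input screen only translates the image. The estimator removes the fitted
  tilt of the output screen (an unwrap-free nearest-neighbour phasor fit,
  iterated to its fixed point) and compensates the input screen. The screen
  generator draws the true output screen tilt-free in the same gauge, so
  reconstructions are registered with the phantom.
* *Defocus (depth re-referencing)* — a spectral phase of the shape
  `(k_z(λ) − k_z(λ_c))·δz` on both screens is exactly a shift of the depth
  origin. The spectral estimator fits and removes this mode (coarse scan
  over ± half the comb's ambiguity period plus bounded refinement); without
  this, light from a dominant out-of-focus plane silently re-references the
  depth axis toward that plane. In addition, the correction pipeline
  propagates the matrix to the target depth *before* estimating, so the
  target plane's own defocus cannot be absorbed into the screens.

**Reference-wavelength support.** The spectral correlations are taken
against `λ_c` only. Output nodes outside the `λ_c` pupil, and illumination
nodes not occupied at `λ_c` (both exist because pupils and `k_in` scale as
`1/λ`), have no reference column and their relative dispersion is not
estimable by this procedure; they retain their dispersion and contribute
incoherently. Recovery tests therefore compare maps on λ_c-referenced
supports, and quantitative study grids keep the fractional bandwidth small
enough that snapped nodes are wavelength-stable.

**Progressive imaging.** The upper-layer screens (all wavelengths) are
applied to the full matrix; the lower stage then estimates the residual
*angular* screens at `λ_c` by default. Re-running the spectral step on the
pre-corrected bilayer matrix is ill-posed — the shallow and deep planes
compete as the depth reference of the wavelength correlations — and was
observed to destroy an otherwise recoverable lower image; a flag restores
the full pipeline for single-dominant-plane data. A run aborts if the
upper-layer estimation has not settled (final angular update above 0.1 rad:
updates settle at the noise floor when the solve succeeds and stay large
when it fails).

**Multi-depth correction.** Gated matrices from `N_z` depths are stacked
and the consensus correlations pool the depth axis jointly; `N_z = 1`
reduces bit-identically to the single-depth estimator. Depth blocks enter
unweighted by default (optional amplitude equalization compensates
depth-dependent attenuation). A diagnostic flag compares per-depth
single-depth estimates and warns above 0.5 rad RMS spread (the axial
isoplanatism caveat).

## Synthetic-data generator

* **Phantoms:** binary Siemens stars and bar charts, point arrays, uniform
  planes ("mirror"), and Poisson-placed particle disks; deterministic per
  seed. Sub-resolution particle diameters trigger a warning.
* **Medium:** `l_s(λ)` linearly interpolated between tabulated endpoints;
  defaults 56.1 µm at 535 nm and 83.1 µm at 760 nm (polystyrene-bead
  phantom regime). Anisotropy `g` enters only through
  `l_t = l_s/(1 − g)`.
* **Dispersion screens:** filtered Gaussian noise with correlation length a
  fraction of the `λ_c` pupil radius (default 0.25); circular RMS over the
  `λ_c` pupil scaled exactly to the requested strength. Spectral part:
  independent per-line offsets (`separable`), group-delay/GDD polynomial in
  `1/λ − 1/λ_c` (`polynomial_in_inv_lambda`), or none.
* **Depth-correlated speckle:** with `ρ > 0` the background is a dense comb
  of depth-localized Gaussian components (33 over a 16-µm span by default),
  each drawing a fraction `ρ` of its power from one comb-shared field, with
  independent per-element statistics so no momentum-conserving structure is
  introduced. Coherence-gated backgrounds at any two depths then carry
  correlation magnitude ≈ ρ. The correlation's *phase* varies with depth in
  this construction; since the merged-depth estimator is degraded by the
  squared correlation magnitude regardless of phase, the background
  amplitude gain accumulates pairwise correlations by magnitude
  (`gain² = Σ_ij |⟨X_i X_j*⟩| / mean power`), giving `sqrt(N_z)` for
  independent depths and `N_z` for fully correlated ones.
* All randomness flows from one root seed through named substreams
  (phantom, speckle, dispersion, residual).

What passing tests do **not** show about real data: the speckle model has no
physical scatterers, memory effect, or spatially varying statistics; screens
are space-invariant; phantoms are thin discrete slices; and detection noise,
demodulation artifacts and sample motion are absent.

## Scalar theory

* Coherence-gate axial FWHM: `(2 ln 2/π) λ_c²/(n Δλ_F)` (Gaussian-spectrum
  constant; it reproduces both printed depth resolutions from the printed
  bandwidths, and the printed sub-band coherence length to 1%). The
  simulated discrete comb matches it when the sub-band is a small fraction
  of the scanned span.
* `ζ = |⟨e^{iφ_in}⟩| · |⟨e^{iφ_o}⟩|` over the screen supports at one
  wavelength, and `l_eff/l_s = z/l_s − ln η` are **main-text-consistent
  reconstructions**: their exact definitions live in supplementary material
  not reproduced here, and these forms satisfy every property the main text
  states (ζ = 1 iff no dispersion; combined attenuation `η² e^{−2z/l_s}`).
* `C_rel = (S/M) ζ sqrt(N)` with `N` defaulting to the number of
  momentum-difference bins carrying at least one pupil pair. The working
  threshold in `C_rel` is treated as an empirical property of the estimator
  and characterized by threshold-straddling simulations, not asserted.

## Depth-scan profile

`depth_scan` exposes three intensity metrics. `integrated` (default) and
`peak` evaluate the full coherent reconstruction per depth; for a planar
reflector at NA 1.0 their profile measures the *combined* confocal +
coherence gate, which is noticeably sharper (≈ 0.50 µm for the 29-line
axis) than the coherence gate alone because of the angular spread of `k_z`.
The `axial_response` metric — the gated normal-incidence channel — isolates
the coherence gate and is the quantity the bandwidth formula predicts
(0.599 µm for the same axis); the depth-resolution characterization and its
tests use it. In real systems pupil apodization pushes the combined gate
toward the coherence-limited value.

## Study conditions used by the tests

Scaled-down grids chosen as the package's standard study sizes: 16 px / 5
lines / 21 channels (unit tests), 24 px / 21 lines at 2.5 nm / 64 channels
(dispersion-recovery and deep-imaging studies; wavelength-stable node sets),
and 32 px / 29 lines / 49 channels (axial-resolution runs). Two-layer
scenes place the planes 11.4 µm apart — a null of the 21-line gate kernel —
with the deep target at 0.2 relative amplitude and speckle chosen so the
direct deep solve sits below the working point while the shallow solve and
the pre-corrected residual solve sit above it. The multi-depth study merges
eight depths at 3 µm spacing with speckle 20× the single-scattering level.

## Known limitations

* Wide fractional bandwidths leave part of the pupil unreferenced at `λ_c`
  (see above); chaining intermediate reference lines is not implemented.
* Space-variant (position-dependent) screens, amplitude pupil errors, and
  physical multiple-scattering transport are out of scope.
* Only a single progressive step (upper → lower) is automated; chaining is
  user-scriptable.
* The `N(K)`-shaped transfer function is not deconvolved by default
  (optional flattening divides it out); quantitative image comparisons use
  an `N(K)`-weighted reference.
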