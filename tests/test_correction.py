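import numpy as np
import pytest

from vrm.correction import (
    DispersionModel,
    allpairs_phase_solve,
    apply_dispersion,
    correct_spectro_angular,
    estimate_angular_dispersion,
    estimate_spectral_dispersion,
)
from vrm.forward import simulate_multiple_scattering, simulate_single_scattering
from vrm.gating import coherence_gate, confocal_sum, kshift_stack
from vrm.medium import DispersionMap, MediumSpec, circular_rms, sample_dispersion, wrap_phase
from vrm.metrics import circular_rmse, image_correlation
from vrm.phantom import make_phantom

from conftest import make_grid

NO_LOSS = MediumSpec(ls_table_nm_um=((535.0, 1e12), (760.0, 1e12)))


def occupied_at_reference(matrix):
    """Nodes occupied at the reference wavelength (the estimable support)."""
    g = matrix.grid
    ic = g.spectral.center_index
    occ = np.zeros((g.pixels_per_side,) * 2, bool)
    for i in range(g.n_illuminations):
        if matrix.kin_inside[i, ic]:
            iy, ix = matrix.kin_index[i, ic]
            occ[iy, ix] = True
    return occ


def spectral_only_maps(grid, seed, scale=0.8):
    """Separable spectral screens: one random offset per wavelength and
    screen, constant over the pupil, zero at the reference line."""
    rng = np.random.default_rng(seed)
    maps = DispersionMap.zeros(grid)
    ic = grid.spectral.center_index
    nl = grid.spectral.n_wavelengths
    for arr in (maps.phi_in, maps.phi_o):
        offs = scale * rng.standard_normal(nl)
        offs[ic] = 0.0
        arr += offs[None, None, :]
    return DispersionMap(
        phi_in=maps.phi_in, phi_o=maps.phi_o,
        support_in=maps.support_in, support_out=maps.support_out,
        wavelengths_nm=grid.spectral.wavelengths_nm,
    )


class TestSpectralEstimation:
    def test_dispersion_free_matrix_gives_flat_maps(self, correction_grid):
        g = correction_grid
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS)
        est = estimate_spectral_dispersion(m)
        assert circular_rms(est.maps.phi_o[est.maps.support_out]) < 0.05
        assert circular_rms(est.maps.phi_in[est.maps.support_in]) < 0.05

    def test_reference_column_has_zero_update(self, correction_grid):
        g = correction_grid
        maps = sample_dispersion(g, 1.0, seed=11)
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS, maps)
        est = estimate_spectral_dispersion(m)
        ic = g.spectral.center_index
        assert not np.any(est.maps.phi_in[:, :, ic])
        assert not np.any(est.maps.phi_o[:, :, ic])

    def test_separable_spectral_recovery_under_background(self, correction_grid):
        # S/M = 10: the per-line phase curve is recovered to < 0.1 rad
        g = correction_grid
        truth = spectral_only_maps(g, seed=5)
        obj = make_phantom("siemens_star", g, [0.0])
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        s_level = np.mean(np.abs(m.data[g.pupil_mask(g.spectral.center_wavelength_nm)]) ** 2)
        spk = simulate_multiple_scattering(
            g, MediumSpec(multiple_scatter_power=s_level / 10.0, seed=2)
        )
        m.data += spk.data
        # fixed gauge (no defocus-mode projection) so the recovered per-line
        # curve is directly comparable to the imprinted one
        est = estimate_spectral_dispersion(m, remove_defocus_gauge=False)
        assert est.iterations <= 10
        # the in/out split of a per-line offset is gauge (only the sum is
        # observable): compare the summed phase curves over the pupil
        ic = g.spectral.center_index
        nl = g.spectral.n_wavelengths
        err = []
        for l in range(nl):
            if l == ic:
                continue
            sup = est.maps.support_in[:, :, l] & occupied_at_reference(m)
            est_curve = np.angle(
                np.mean(np.exp(1j * est.maps.phi_in[:, :, l][sup]))
            ) + np.angle(
                np.mean(np.exp(1j * est.maps.phi_o[:, :, l][est.maps.support_out[:, :, l]]))
            )
            half = g.pixels_per_side // 2
            true_curve = truth.phi_in[half, half, l] + truth.phi_o[half, half, l]
            err.append(wrap_phase(est_curve - true_curve))
        assert np.sqrt(np.mean(np.asarray(err) ** 2)) < 0.1


class TestAngularEstimation:
    def test_no_dispersion_gives_flat_maps(self, correction_grid):
        g = correction_grid
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS)
        est = estimate_angular_dispersion(coherence_gate(m, 0.0))
        pupil = g.pupil_mask(g.spectral.center_wavelength_nm)
        assert circular_rms(est.phi_o[pupil]) < 0.05
        assert circular_rms(est.phi_in_nodes) < 0.05

    def test_strong_screen_recovery_above_working_point(self, correction_grid):
        g = correction_grid
        truth = sample_dispersion(g, 2.0, 0.2, spectral_model="none", seed=31)
        obj = make_phantom("siemens_star", g, [0.0])
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        s_level = np.mean(np.abs(m.data[g.pupil_mask(g.spectral.center_wavelength_nm)]) ** 2)
        spk = simulate_multiple_scattering(
            g, MediumSpec(multiple_scatter_power=s_level / 10.0, seed=3)
        )
        m.data += spk.data
        res, img = correct_spectro_angular(m, 0.0, outer_iters=3)
        ic = g.spectral.center_index
        pupil = g.pupil_mask(g.spectral.center_wavelength_nm)
        assert circular_rmse(res.maps.phi_o[:, :, ic], truth.phi_o[:, :, ic], pupil) < 0.15
        clean = confocal_sum(coherence_gate(simulate_single_scattering(obj, g, NO_LOSS), 0.0))
        assert image_correlation(img, clean) > 0.9

    def test_far_below_working_point_fails(self, correction_grid):
        g = correction_grid
        truth = sample_dispersion(g, 2.2, 0.15, spectral_model="none", seed=31)
        obj = make_phantom("random_particles", g, [0.0], seed=3,
                           particle_density_per_um2=0.3, particle_diameter_um=0.4)
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        spk = simulate_multiple_scattering(g, MediumSpec(multiple_scatter_power=20.0, seed=17))
        m.data += spk.data
        res, img = correct_spectro_angular(m, 0.0, outer_iters=3)
        clean = confocal_sum(coherence_gate(simulate_single_scattering(obj, g, NO_LOSS), 0.0))
        assert image_correlation(img, clean) < 0.3

    def test_monotone_fidelity_in_signal_to_background(self):
        # recovered-map error is non-increasing in S/M (single line, angular)
        g = make_grid(n_pixels=16, n_ill=21, fov=2.2, lam_min=647.5, lam_max=647.5,
                      step=1.0, ill_na=0.8)
        truth = sample_dispersion(g, 1.5, 0.25, spectral_model="none", seed=4)
        obj = make_phantom("siemens_star", g, [0.0])
        base = simulate_single_scattering(obj, g, NO_LOSS, truth)
        s_level = np.mean(np.abs(base.data[g.pupil_mask(647.5)]) ** 2)
        pupil = g.pupil_mask(647.5)
        means = []
        for sm in (0.1, 0.3, 1.0, 3.0, 10.0):
            errs = []
            for seed in range(10):
                spk = simulate_multiple_scattering(
                    g, MediumSpec(multiple_scatter_power=s_level / sm, seed=seed)
                )
                m = base.copy()
                m.data += spk.data
                est = estimate_angular_dispersion(coherence_gate(m, 0.0))
                errs.append(circular_rmse(est.phi_o, truth.phi_o[:, :, 0], pupil))
            means.append(np.mean(errs))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.02

    def test_consensus_matches_allpairs_least_squares(self):
        # five channels, input phases only: the consensus fixed point equals
        # the eigenvector solution of the explicit all-pairs system
        g = make_grid(n_pixels=16, n_ill=5, fov=2.2, lam_min=647.5, lam_max=647.5,
                      step=1.0, ill_na=0.6)
        rng = np.random.default_rng(8)
        truth_in = rng.uniform(-2, 2, 5)
        obj = make_phantom("siemens_star", g, [0.0])
        m = simulate_single_scattering(obj, g, NO_LOSS)
        for i in range(5):
            m.data[:, :, i, 0] *= np.exp(1j * truth_in[i])
        cg = coherence_gate(m, 0.0)
        est = estimate_angular_dispersion(cg)
        oracle = allpairs_phase_solve(kshift_stack(cg))
        d = wrap_phase(est.phi_in_nodes - oracle)
        d = wrap_phase(d - np.angle(np.exp(1j * d).mean()))
        assert np.abs(d).max() < 0.02
        # and both agree with the imprinted phases (per snapped node)
        node_truth = np.empty(cg.n_nodes)
        for i in range(5):
            j = np.flatnonzero((cg.nodes == m.kin_index[i, 0]).all(axis=1))[0]
            node_truth[j] = truth_in[i]
        e = wrap_phase(est.phi_in_nodes - node_truth)
        e = wrap_phase(e - np.angle(np.exp(1j * e).mean()))
        assert np.abs(e).max() < 0.05


class TestFullCorrection:
    def test_noiseless_dispersed_phantom_restored(self):
        # exact invertibility of pure phase screens requires every channel
        # to keep its reference-line counterpart: restrict to channels whose
        # snapped node is wavelength-stable
        from vrm.grid import SpectroAngularGrid

        g0 = make_grid(n_pixels=24, n_ill=80, fov=3.3, lam_min=637.5,
                       lam_max=657.5, step=2.5, ill_na=0.9)
        ki, inside = g0.kin_index_table()
        stable = np.all(ki == ki[:, :1, :], axis=(1, 2)) & inside.all(axis=1)
        g = SpectroAngularGrid(
            g0.spectral, g0.illumination_angles_rad[stable], 3.3, 24, 1.0, 1.4
        )
        obj = make_phantom("siemens_star", g, [0.0])
        truth = sample_dispersion(g, 1.5, 0.3, seed=3)
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        clean = confocal_sum(coherence_gate(simulate_single_scattering(obj, g, NO_LOSS), 0.0))
        res, img = correct_spectro_angular(m, 0.0, outer_iters=3, tol=1e-4)
        # intensity images agree to 1% RMS (global phase is unobservable)
        diff = img.intensity - clean.intensity
        assert np.sqrt(np.mean(diff**2) / np.mean(clean.intensity**2)) < 0.01
        assert res.converged

    def test_signal_never_decreases_across_outer_iterations(self, correction_grid):
        g = correction_grid
        obj = make_phantom("siemens_star", g, [0.0])
        truth = sample_dispersion(g, 1.8, 0.2, seed=9)
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        s_level = np.mean(np.abs(m.data[g.pupil_mask(g.spectral.center_wavelength_nm)]) ** 2)
        spk = simulate_multiple_scattering(
            g, MediumSpec(multiple_scatter_power=s_level / 20.0, seed=5)
        )
        m.data += spk.data
        res, _ = correct_spectro_angular(m, 0.0, outer_iters=3)
        hist = res.signal_history
        for later, earlier in zip(hist[1:], hist[:-1]):
            assert later >= 0.99 * earlier

    def test_contrast_grows_with_bandwidth(self):
        # wider spectral coverage, after correction, means stronger coherent
        # accumulation relative to the speckle background
        from vrm.metrics import signal_intensity
        from vrm.workflows import _subset_wavelengths

        g = make_grid(n_pixels=16, n_ill=32, fov=2.2, lam_min=617.5, lam_max=677.5,
                      step=7.5, ill_na=0.9)
        obj = make_phantom("siemens_star", g, [0.0])
        truth = sample_dispersion(g, 1.0, 0.3, seed=6)
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        s_level = np.mean(np.abs(m.data[g.pupil_mask(g.spectral.center_wavelength_nm)]) ** 2)
        spk = simulate_multiple_scattering(
            g, MediumSpec(multiple_scatter_power=s_level, seed=1)
        )
        m.data += spk.data
        target = np.abs(obj.slices[:, :, 0]) > 0
        ic = g.spectral.center_index
        sig = []
        for hw in (0, 2, 4):
            sub = _subset_wavelengths(m, list(range(ic - hw, ic + hw + 1)))
            if sub.n_wavelengths == 1:
                img = confocal_sum(coherence_gate(sub, 0.0))
            else:
                _, img = correct_spectro_angular(sub, 0.0, outer_iters=2)
            sig.append(signal_intensity(img, target, ~target))
        assert sig[0] < sig[1] < sig[2]

    def test_spectral_step_matters_for_spectrally_dispersed_data(self):
        # broadband-matrix baseline: only angular dispersion at the center
        # wavelength can be corrected, so the accumulated signal is weaker
        from vrm.metrics import signal_intensity

        g = make_grid(n_pixels=16, n_ill=32, fov=2.2, lam_min=617.5, lam_max=677.5,
                      step=7.5, ill_na=0.9)
        obj = make_phantom("siemens_star", g, [0.0])
        target = np.abs(obj.slices[:, :, 0]) > 0
        wins = 0
        for seed in range(5):
            truth = sample_dispersion(g, 1.2, 0.3, seed=100 + seed)
            m = simulate_single_scattering(obj, g, NO_LOSS, truth)
            _, vrm_img = correct_spectro_angular(m, 0.0, outer_iters=2)
            _, brm_img = correct_spectro_angular(m, 0.0, outer_iters=2, spectral=False)
            if signal_intensity(vrm_img, target, ~target) > signal_intensity(
                brm_img, target, ~target
            ):
                wins += 1
        assert wins == 5


class TestApplyDispersion:
    def test_apply_then_correct_is_identity(self, tiny_grid):
        g = tiny_grid
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS)
        maps = sample_dispersion(g, 2.0, seed=7)
        round_trip = apply_dispersion(apply_dispersion(m, maps, +1), maps, -1)
        assert np.allclose(round_trip.data, m.data, atol=1e-12)

    def test_true_map_correction_equals_clean_simulation(self, tiny_grid):
        g = tiny_grid
        obj = make_phantom("siemens_star", g, [0.0])
        maps = sample_dispersion(g, 1.5, seed=8)
        dispersed = simulate_single_scattering(obj, g, NO_LOSS, maps)
        clean = simulate_single_scattering(obj, g, NO_LOSS)
        corrected = apply_dispersion(dispersed, maps, -1)
        assert np.allclose(corrected.data, clean.data, atol=1e-10)

    def test_speckle_statistics_unchanged_by_phase_screens(self, tiny_grid):
        g = tiny_grid
        spk = simulate_multiple_scattering(
            g, MediumSpec(multiple_scatter_power=1.0, seed=4)
        )
        maps = sample_dispersion(g, 2.5, seed=9)
        out = apply_dispersion(spk, maps, +1)
        assert np.allclose(np.abs(out.data), np.abs(spk.data), atol=1e-12)

    def test_piston_exchange_between_screens_is_invisible(self, tiny_grid):
        g = tiny_grid
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS)
        maps = sample_dispersion(g, 1.0, seed=10)
        shifted = DispersionMap(
            phi_in=maps.phi_in + 0.7,
            phi_o=maps.phi_o - 0.7,
            support_in=maps.support_in,
            support_out=maps.support_out,
            wavelengths_nm=maps.wavelengths_nm,
        )
        a = apply_dispersion(m, maps, +1)
        b = apply_dispersion(m, shifted, +1)
        keep = a.kin_inside.all(axis=1)
        assert np.allclose(a.data[:, :, keep], b.data[:, :, keep], atol=1e-10)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, correction_grid):
        g = correction_grid
        obj = make_phantom("siemens_star", g, [0.0])
        truth = sample_dispersion(g, 1.0, 0.3, seed=12)
        m = simulate_single_scattering(obj, g, NO_LOSS, truth)
        res = DispersionModel(m, target_depth_um=0.0).fit(outer_iters=2)
        text = res.summary()
        assert "Strehl" in text and "converged" in text
        assert res.converged
        assert len(res.signal_history) == 2
        assert res.maps.phi_o.shape == (24, 24, g.spectral.n_wavelengths)
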