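import numpy as np
import pytest

from vrm.forward import simulate_multiple_scattering, simulate_single_scattering
from vrm.gating import (
    coherence_gate,
    confocal_sum,
    depth_scan,
    kshift_stack,
    per_lambda_normalize,
    profile_fwhm,
    propagate_to_depth,
)
from vrm.grid import ParameterError, SpectroAngularGrid
from vrm.matrix import pair_count
from vrm.medium import MediumSpec
from vrm.metrics import coherence_gate_fwhm, signal_intensity
from vrm.phantom import make_phantom

from conftest import lambda_stable_nodes, make_grid

NO_LOSS = MediumSpec(ls_table_nm_um=((535.0, 1e12), (760.0, 1e12)))


class TestCoherenceGate:
    def test_single_wavelength_is_defocus_phase_only(self):
        g = make_grid(n_pixels=16, n_ill=10, fov=2.2, lam_min=650.0, lam_max=650.0, step=1.0)
        obj = make_phantom("siemens_star", g, [0.0])
        m = simulate_single_scattering(obj, g, NO_LOSS)
        z = 0.8
        cg = coherence_gate(m, z)
        lam = g.spectral.wavelengths_nm[0]
        phase = np.exp(-1j * g.kz_map(lam) * z)
        for j, (iy, ix) in enumerate(cg.nodes):
            i = [
                i for i in range(g.n_illuminations)
                if tuple(m.kin_index[i, 0]) == (iy, ix) and m.kin_inside[i, 0]
            ]
            expect = sum(
                m.data[:, :, k, 0] * phase * np.exp(-1j * g.kz_in((iy, ix), lam) * z)
                for k in i
            )
            expect = expect * g.pupil_mask(lam)
            assert np.allclose(cg.data[:, :, j], expect, atol=1e-12)

    def test_mirror_gated_amplitude_counts_wavelengths(self, narrow_grid):
        g = narrow_grid
        z0 = 0.6
        obj = make_phantom("mirror", g, [z0])
        m = simulate_single_scattering(obj, g, NO_LOSS)
        assert lambda_stable_nodes(m)
        nl = g.spectral.n_wavelengths
        single = np.abs(m.data).max()
        cg = coherence_gate(m, z0)
        for j, (iy, ix) in enumerate(cg.nodes):
            # channels pooled on one node add their wavelength sums
            expect = cg.n_contributions[j] * single
            assert cg.n_contributions[j] % nl == 0
            assert np.abs(cg.data[iy, ix, j]) == pytest.approx(expect, rel=1e-9)

    def test_speckle_gated_intensity_adds_incoherently(self, narrow_grid):
        g = narrow_grid
        m_power = 0.5
        vals = []
        for seed in range(10):
            med = MediumSpec(multiple_scatter_power=m_power, seed=seed)
            spk = simulate_multiple_scattering(g, med)
            cg = coherence_gate(spk, 0.3)
            pupil = g.pupil_mask(g.spectral.center_wavelength_nm)
            vals.append(np.mean(np.abs(cg.data[pupil, :]) ** 2))
        nl = g.spectral.n_wavelengths
        assert np.mean(vals) == pytest.approx(nl * m_power, rel=0.05)

    def test_linearity(self, narrow_grid):
        g = narrow_grid
        a = simulate_single_scattering(make_phantom("mirror", g, [0.4]), g, NO_LOSS)
        b = simulate_single_scattering(
            make_phantom("point_array", g, [0.0], n_points=1), g, NO_LOSS
        )
        combo = a.copy()
        combo.data = 0.7 * a.data + 1.3j * b.data
        lhs = coherence_gate(combo, 0.2).data
        rhs = 0.7 * coherence_gate(a, 0.2).data + 1.3j * coherence_gate(b, 0.2).data
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_empty_axis_impossible(self, narrow_grid):
        # the grid type itself refuses an empty spectral axis
        with pytest.raises(ParameterError):
            SpectroAngularGrid(
                narrow_grid.spectral.__class__((), 15.0),
                narrow_grid.illumination_angles_rad,
                2.2, 16, 1.0, 1.4,
            )


class TestConfocalSum:
    def test_single_center_channel_is_widefield_image(self):
        g = make_grid(n_pixels=16, n_ill=1, fov=2.2, lam_min=650.0, lam_max=650.0, step=1.0)
        obj = make_phantom("siemens_star", g, [0.0])
        m = simulate_single_scattering(obj, g, NO_LOSS)
        cg = coherence_gate(m, 0.0)
        assert cg.n_nodes == 1
        img = confocal_sum(cg)
        direct = np.fft.ifft2(np.fft.ifftshift(cg.data[:, :, 0]), norm="ortho")
        assert np.allclose(img.image, direct, atol=1e-12)

    def test_coherent_gain_equals_pair_count_growth(self, narrow_grid):
        # noiseless point reflector: the aligned K-space amplitude grows by
        # exactly N_lambda * N(K)
        g = narrow_grid
        obj = make_phantom("point_array", g, [0.0], n_points=1)
        m = simulate_single_scattering(obj, g, NO_LOSS)
        assert lambda_stable_nodes(m)
        single = np.abs(m.data[m.data != 0])[0]
        eccg = kshift_stack(coherence_gate(m, 0.0)).sum(axis=-1)
        nk = pair_count(g, g.spectral.center_wavelength_nm).counts
        nl = g.spectral.n_wavelengths
        sup = nk > 0
        assert np.allclose(
            np.abs(eccg[sup]), nl * nk[sup] * single, rtol=1e-9
        )

    def test_background_suppression_versus_coherent_gain(self):
        # speckle K-bin intensity ~ N_lambda N(K) M while a coherent plane
        # grows as (N_lambda N(0))^2: their ratio tracks N_lambda N(0)
        ratios, predicted = [], []
        for n_ill, nl_hi in [(8, 647.5), (16, 650.0), (21, 652.5)]:
            g = make_grid(
                n_pixels=16, n_ill=n_ill, fov=2.2, lam_min=645.0, lam_max=nl_hi, step=2.5
            )
            obj = make_phantom("mirror", g, [0.0])
            s = simulate_single_scattering(obj, g, NO_LOSS)
            half = g.pixels_per_side // 2
            sig = np.abs(kshift_stack(coherence_gate(s, 0.0)).sum(-1)[half, half]) ** 2
            bg = []
            for seed in range(40):
                med = MediumSpec(multiple_scatter_power=1.0, seed=seed)
                spk = simulate_multiple_scattering(g, med)
                bg.append(
                    np.abs(kshift_stack(coherence_gate(spk, 0.0)).sum(-1)[half, half]) ** 2
                )
            nl = g.spectral.n_wavelengths
            n0 = pair_count(g, g.spectral.center_wavelength_nm).n_zero
            ratios.append(sig / np.mean(bg))
            predicted.append(nl * n0)
        ratios = np.asarray(ratios) / ratios[0]
        predicted = np.asarray(predicted) / predicted[0]
        assert np.allclose(ratios, predicted, rtol=0.35)


class TestDepthScan:
    def test_mirror_profile_peaks_at_its_depth(self, narrow_grid):
        g = narrow_grid
        z0 = 0.9
        m = simulate_single_scattering(make_phantom("mirror", g, [z0]), g, NO_LOSS)
        for metric in ("integrated", "axial_response"):
            scan = depth_scan(m, np.arange(-2, 2.01, 0.1), metric=metric)
            assert scan.depths_um[np.argmax(scan.profile)] == pytest.approx(z0, abs=0.051)

    @pytest.mark.parametrize(
        "lam_lo, lam_hi, step",
        [(542.5, 752.5, 7.5), (595.0, 700.0, 3.75), (803.0, 878.0, 2.5)],
    )
    def test_axial_fwhm_tracks_analytic_coherence_gate(self, lam_lo, lam_hi, step):
        # dense combs whose sub-band (two scan steps) is a small fraction of
        # the span, where the Gaussian bandwidth formula applies
        g = make_grid(
            n_pixels=32, n_ill=25, fov=4.2, lam_min=lam_lo, lam_max=lam_hi,
            step=step, subband=2 * step,
        )
        m = simulate_single_scattering(make_phantom("mirror", g, [0.0]), g, NO_LOSS)
        scan = depth_scan(m, np.arange(-4, 4.001, 0.02), metric="axial_response")
        spec = g.spectral
        analytic = coherence_gate_fwhm(
            spec.center_wavelength_nm, spec.full_bandwidth_nm, g.medium_index
        )
        assert scan.fwhm_um == pytest.approx(analytic, rel=0.05)

    def test_halving_bandwidth_doubles_fwhm(self):
        zs = np.arange(-3, 3.001, 0.02)
        fwhm = {}
        for lo, hi in [(542.5, 752.5), (595.0, 700.0)]:
            g = make_grid(n_pixels=32, n_ill=9, fov=4.2, lam_min=lo, lam_max=hi, step=7.5)
            m = simulate_single_scattering(make_phantom("mirror", g, [0.0]), g, NO_LOSS)
            fwhm[hi - lo] = depth_scan(m, zs, metric="axial_response").fwhm_um
        assert fwhm[105.0] / fwhm[210.0] == pytest.approx(2.0, rel=0.1)

    def test_profile_fwhm_of_known_gaussian(self):
        z = np.linspace(-3, 3, 601)
        width = 0.9
        p = np.exp(-4 * np.log(2) * z**2 / width**2)
        assert profile_fwhm(z, p) == pytest.approx(width, abs=0.02)


class TestNormalization:
    def test_equal_slabs_untouched(self, narrow_grid):
        g = narrow_grid
        m = simulate_single_scattering(make_phantom("siemens_star", g, [0.0]), g, NO_LOSS)
        normed, scales = per_lambda_normalize(m, reference=np.ones(g.spectral.n_wavelengths))
        assert np.allclose(scales, 1.0, atol=1e-12)
        assert np.allclose(normed.data, m.data, atol=1e-12)

    def test_zero_slab_rejected(self, narrow_grid):
        g = narrow_grid
        m = simulate_single_scattering(make_phantom("mirror", g, [0.0]), g, NO_LOSS)
        m.data[..., 0] = 0.0
        with pytest.raises(ParameterError):
            per_lambda_normalize(m)

    def test_quadratic_signal_scaling_restored_by_normalization(self):
        # strongly wavelength-dependent attenuation at depth: the raw signal
        # grows sub-quadratically with the number of lines, normalization
        # restores the quadratic coherent-addition law
        from vrm.workflows import _subset_wavelengths

        g = make_grid(
            n_pixels=24, n_ill=64, fov=3.3, lam_min=602.5, lam_max=692.5, step=7.5
        )
        med = MediumSpec(ls_table_nm_um=((602.5, 1.2), (692.5, 12.0)))
        obj = make_phantom("point_array", g, [2.0], n_points=5)
        m = simulate_single_scattering(obj, g, med)
        s_lambda = np.array([
            np.mean(np.abs(m.data[g.pupil_mask(lam), :, l]) ** 2)
            for l, lam in enumerate(g.spectral.wavelengths_nm)
        ])
        normed, _ = per_lambda_normalize(m, reference=s_lambda)
        target = np.abs(obj.slices[:, :, 0]) > 0
        background = ~target
        ic = g.spectral.center_index

        def sweep(matrix):
            xs, ys = [], []
            for hw in range(0, 7):
                sel = list(range(ic - hw, ic + hw + 1))
                img = confocal_sum(
                    coherence_gate(propagate_to_depth(_subset_wavelengths(matrix, sel), 2.0), 0.0)
                )
                xs.append(len(sel))
                ys.append(signal_intensity(img, target, background))
            return np.polyfit(np.log(xs), np.log(ys), 1)[0]

        slope_norm = sweep(normed)
        slope_raw = sweep(m)
        assert slope_norm == pytest.approx(2.0, abs=0.1)
        assert slope_raw < slope_norm - 0.05
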