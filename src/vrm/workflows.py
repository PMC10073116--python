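"""End-to-end experiment workflows and fixture generation.

Every workflow is a thin composition of the library operations: build the
grid and sample, synthesize the matrix, run the requested reconstruction or
correction, and write matrices (HDF5), images (32-bit float TIFF, one page
per depth, resolution tags in um) and a JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile

from .config import ExperimentConfig
from .correction import DispersionModel
from .deep import background_amplitude_gain, build_multidepth, multidepth_correct, progressive_correct
from .forward import simulate_reflection_matrix, simulate_single_scattering
from .gating import coherence_gate, confocal_sum, depth_scan, per_lambda_normalize
from .grid import SpectroAngularGrid, build_spectral_axis, fermat_spiral_angles
from .matrix import save_matrix
from .medium import MediumSpec, sample_dispersion
from .metrics import FidelityReport, ResolutionReport, coherence_gate_fwhm, image_correlation
from .phantom import make_phantom

__all__ = ["build_grid", "build_sample", "run_experiment", "make_fixtures", "example_config"]

log = logging.getLogger("vrm")


def build_grid(cfg: ExperimentConfig) -> SpectroAngularGrid:
    g = cfg.grid
    spectral = build_spectral_axis(g.lambda_min_nm, g.lambda_max_nm, g.step_nm, g.subband_nm)
    angles = fermat_spiral_angles(g.n_illuminations, g.numerical_aperture)
    return SpectroAngularGrid(
        spectral=spectral,
        illumination_angles_rad=angles,
        field_of_view_um=g.field_of_view_um,
        pixels_per_side=g.pixels_per_side,
        numerical_aperture=g.numerical_aperture,
        medium_index=g.medium_index,
    )


def build_sample(cfg: ExperimentConfig, grid: SpectroAngularGrid):
    """Phantom, medium and dispersion screens from the config substreams."""
    p = cfg.phantom
    obj = make_phantom(
        p.kind,
        grid,
        p.depths_um,
        seed=cfg.substream_seed("phantom"),
        n_spokes=p.n_spokes,
        n_points=p.n_points,
        particle_density_per_um2=p.particle_density_per_um2,
        particle_diameter_um=p.particle_diameter_um,
        reflectivity=p.reflectivity,
    )
    m = cfg.medium
    medium = MediumSpec(
        ls_table_nm_um=tuple(map(tuple, m.ls_table_nm_um)),
        anisotropy_g=m.anisotropy_g,
        multiple_scatter_power=m.multiple_scatter_power,
        ms_depth_correlation=m.ms_depth_correlation,
        ms_depth_span_um=m.ms_depth_span_um,
        seed=cfg.substream_seed("speckle"),
    )
    d = cfg.dispersion
    dispersion = sample_dispersion(
        grid,
        d.strength_rad,
        correlation_length=d.correlation_length,
        spectral_model=d.spectral_model,
        seed=cfg.substream_seed("dispersion"),
    )
    return obj, medium, dispersion


def _write_tiff(path, images, pixel_size_um):
    stack = np.stack([np.abs(getattr(im, "image", im)) ** 2 for im in images]).astype(
        np.float32
    )
    res = 1.0 / pixel_size_um  # pixels per um
    tifffile.imwrite(
        path,
        stack,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "ZYX"},
    )


def _signal_masks(obj):
    inten = np.abs(obj.slices[:, :, 0]) ** 2
    target = inten > 0.5 * inten.max() if inten.max() > 0 else inten > 0
    return target, ~target


def run_experiment(cfg: ExperimentConfig, output_dir=None) -> Path:
    """Run a configured experiment end to end; returns the output directory.

    The report is deterministic for a given config and seed, except for the
    entries under ``"timings"``. Failures are logged with the stage name and
    re-raised after retaining partial outputs.
    """
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "seed": cfg.seed, "mode": cfg.pipeline.mode}
    timings: dict = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        grid = build_grid(cfg)
        obj, medium, dispersion = build_sample(cfg, grid)
        timings["setup"] = time.perf_counter() - t0

        stage = "simulate"
        log.info("stage=%s seed=%s hash=%s", stage, cfg.seed, chash)
        t0 = time.perf_counter()
        residual = None
        if cfg.pipeline.mode == "progressive" and cfg.dispersion.residual_strength_rad > 0:
            residual = sample_dispersion(
                grid,
                cfg.dispersion.residual_strength_rad,
                correlation_length=cfg.dispersion.residual_correlation_length,
                spectral_model=cfg.dispersion.spectral_model,
                seed=cfg.substream_seed("residual"),
            )
            matrix, record = _simulate_layered(
                obj, grid, medium, dispersion, residual
            )
        else:
            matrix, record = simulate_reflection_matrix(obj, grid, medium, dispersion)
        save_matrix(out / "matrix.h5", matrix)
        timings["simulate"] = time.perf_counter() - t0

        fid = FidelityReport.from_record(record, grid)
        report["fidelity"] = fid.to_dict()

        stage = cfg.pipeline.mode
        log.info("stage=%s seed=%s hash=%s", stage, cfg.seed, chash)
        t0 = time.perf_counter()
        pl = cfg.pipeline
        ref = record.s_lambda if pl.use_truth_reference else None
        if pl.mode == "reconstruct":
            _run_reconstruct(cfg, grid, matrix, obj, report, out)
        elif pl.mode == "correct":
            res = DispersionModel(
                matrix, pl.target_depth_um, normalize=pl.normalize, reference=ref
            ).fit(outer_iters=pl.outer_iters)
            report["correction"] = {
                "converged": res.converged,
                "iterations": res.iterations,
                "signal_history": res.signal_history,
                "image_correlation_with_phantom": image_correlation(
                    res.image, obj.slices[:, :, 0]
                ),
            }
            _write_tiff(out / "image.tif", [res.image], grid.pixel_size_um)
            (out / "summary.txt").write_text(res.summary() + "\n")
        elif pl.mode == "bandwidth_sweep":
            report["bandwidth_sweep"] = _run_bandwidth_sweep(
                cfg, grid, matrix, record, obj
            )
        elif pl.mode == "progressive":
            report["progressive"] = _run_progressive(
                cfg, grid, matrix, obj, out
            )
        elif pl.mode == "multidepth":
            z0 = pl.target_depth_um - 0.5 * (pl.n_depths - 1) * pl.depth_spacing_um
            zs = z0 + pl.depth_spacing_um * np.arange(pl.n_depths)
            md = build_multidepth(matrix, zs)
            res = multidepth_correct(md, max_iter=30)
            report["multidepth"] = {
                "n_depths": int(md.n_depths),
                "background_amplitude_gain": background_amplitude_gain(md),
                "converged": res.converged,
            }
            _write_tiff(out / "images.tif", res.images, grid.pixel_size_um)
        timings[pl.mode] = time.perf_counter() - t0
    except Exception:
        log.exception("stage=%s failed (hash=%s); partial outputs in %s", stage, chash, out)
        report["failed_stage"] = stage
        report["timings"] = timings
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        raise
    report["timings"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return out


def _simulate_layered(obj, grid, medium, dispersion, residual):
    """Two-regime volume: slices in the shallow half see the base screens,
    deeper slices see base + residual (depth-dependent dispersion for
    progressive-imaging studies)."""
    from .forward import SimulationRecord, simulate_multiple_scattering
    from .phantom import ObjectVolume

    lower_maps = dispersion.compose(residual)
    mid = 0.5 * (obj.depths_um[0] + obj.depths_um[-1])
    total = None
    for j in range(obj.n_depths):
        piece = ObjectVolume(
            slices=obj.slices[:, :, j],
            depths_um=[obj.depths_um[j]],
            pixel_size_um=obj.pixel_size_um,
            max_reflectivity=obj.max_reflectivity,
        )
        maps = dispersion if obj.depths_um[j] <= mid else lower_maps
        part = simulate_single_scattering(piece, grid, medium, maps)
        if total is None:
            total = part
        else:
            total.data += part.data
    speckle = simulate_multiple_scattering(grid, medium)
    wav = grid.spectral.wavelengths_nm
    s_l = np.zeros(len(wav))
    m_l = np.zeros(len(wav))
    for l, lam in enumerate(wav):
        pupil = grid.pupil_mask(lam)
        count = pupil.sum() * max(int(total.kin_inside[:, l].sum()), 1)
        s_l[l] = np.sum(np.abs(total.data[..., l]) ** 2) / count
        m_l[l] = np.sum(np.abs(speckle.data[..., l]) ** 2) / count
    total.data += speckle.data
    record = SimulationRecord(
        s_lambda=s_l, m_lambda=m_l, dispersion=dispersion, obj=obj,
        medium=medium, seed=medium.seed,
    )
    return total, record


def _run_progressive(cfg, grid, matrix, obj, out):
    """Direct versus progressive reconstruction of the deeper plane."""
    from .correction import correct_spectro_angular

    pl = cfg.pipeline
    z_u, z_l = pl.z_upper_um, pl.z_lower_um
    # clean references for the correlation figures
    lower_ix = int(np.argmin(np.abs(obj.depths_um - z_l)))
    from .phantom import ObjectVolume

    clean_lower = ObjectVolume(
        slices=obj.slices[:, :, lower_ix],
        depths_um=[obj.depths_um[lower_ix]],
        pixel_size_um=obj.pixel_size_um,
        max_reflectivity=obj.max_reflectivity,
    )
    ref_l = confocal_sum(
        coherence_gate(simulate_single_scattering(clean_lower, grid), z_l)
    )
    _, img_direct = correct_spectro_angular(matrix, z_l, outer_iters=pl.outer_iters)
    prog = progressive_correct(
        matrix, z_u, z_l, outer_iters=pl.outer_iters,
        require_upper_convergence=False,
    )
    payload = {
        "upper_converged": prog.upper_result.converged,
        "direct_correlation": image_correlation(img_direct, ref_l),
        "progressive_correlation": image_correlation(prog.image_lower, ref_l),
    }
    _write_tiff(
        out / "images.tif", [prog.image_upper, prog.image_lower], grid.pixel_size_um
    )
    return payload


def _run_reconstruct(cfg, grid, matrix, obj, report, out):
    pl = cfg.pipeline
    spec = grid.spectral
    if pl.scan_z0_um is not None and pl.scan_z1_um is not None:
        zs = np.arange(pl.scan_z0_um, pl.scan_z1_um + 1e-9, pl.scan_dz_um)
    else:
        zs = np.atleast_1d(obj.depths_um)
    img = confocal_sum(coherence_gate(matrix, pl.target_depth_um))
    _write_tiff(out / "image.tif", [img], grid.pixel_size_um)
    scan = depth_scan(matrix, zs, metric="integrated")
    axial = depth_scan(matrix, zs, metric="axial_response")
    analytic = coherence_gate_fwhm(
        spec.center_wavelength_nm, spec.full_bandwidth_nm, grid.medium_index
    )
    rr = ResolutionReport(
        axial_fwhm_um=axial.fwhm_um,
        analytic_axial_um=analytic,
    )
    report["resolution"] = rr.to_dict()
    report["depth_scan"] = {
        "depths_um": list(map(float, scan.depths_um)),
        "integrated_profile": list(map(float, scan.profile)),
        "axial_response_profile": list(map(float, axial.profile)),
        "integrated_fwhm_um": scan.fwhm_um,
    }


def _run_bandwidth_sweep(cfg, grid, matrix, record, obj):
    """Signal intensity versus used bandwidth, with per-wavelength
    normalization: the quadratic coherent-addition law."""
    from .matrix import VolumetricReflectionMatrix

    pl = cfg.pipeline
    norm, _ = per_lambda_normalize(matrix, reference=record.s_lambda)
    ic = grid.spectral.center_index
    nl = grid.spectral.n_wavelengths
    target, background = _signal_masks(obj)
    rows = []
    for half_width in range(0, min(ic, nl - 1 - ic) + 1):
        sel = list(range(ic - half_width, ic + half_width + 1))
        sub = _subset_wavelengths(norm, sel)
        img = confocal_sum(coherence_gate(sub, pl.target_depth_um))
        from .metrics import signal_intensity

        rows.append((len(sel), signal_intensity(img, target, background)))
    n_l = np.array([r[0] for r in rows], dtype=float)
    sig = np.array([r[1] for r in rows], dtype=float)
    ok = sig > 0
    slope = float(np.polyfit(np.log(n_l[ok]), np.log(sig[ok]), 1)[0]) if ok.sum() > 1 else float("nan")
    return {
        "n_lambda": list(map(int, n_l)),
        "signal_intensity": list(map(float, sig)),
        "loglog_slope": slope,
    }


def _subset_wavelengths(matrix, indices):
    """Matrix restricted to a subset of spectral lines."""
    from dataclasses import replace

    from .matrix import VolumetricReflectionMatrix

    g = matrix.grid
    spectral = g.spectral.subset(indices)
    grid = SpectroAngularGrid(
        spectral=spectral,
        illumination_angles_rad=g.illumination_angles_rad,
        field_of_view_um=g.field_of_view_um,
        pixels_per_side=g.pixels_per_side,
        numerical_aperture=g.numerical_aperture,
        medium_index=g.medium_index,
    )
    sel = np.asarray(sorted(indices))
    return VolumetricReflectionMatrix(
        data=matrix.data[..., sel],
        basis=matrix.basis,
        grid=grid,
        kin_index=matrix.kin_index[:, sel],
        kin_inside=matrix.kin_inside[:, sel],
    )


def example_config(name: str) -> ExperimentConfig:
    """Bundled scaled-down experiment configurations.

    ``bandwidth-mini``: 9-wavelength bandwidth sweep on a point target with
    wavelength-dependent attenuation (the quadratic signal-scaling check).
    ``bilayer-mini``: two-depth phantom for a progressive-correction run.
    """
    if name == "bandwidth-mini":
        return ExperimentConfig(
            grid={
                "lambda_min_nm": 617.5,
                "lambda_max_nm": 677.5,
                "step_nm": 7.5,
                "subband_nm": 15.0,
                "n_illuminations": 64,
                "field_of_view_um": 3.3,
                "pixels_per_side": 24,
                "numerical_aperture": 1.0,
                "medium_index": 1.4,
            },
            phantom={"kind": "point_array", "n_points": 5, "depths_um": [0.0]},
            medium={"multiple_scatter_power": 0.0},
            pipeline={"mode": "bandwidth_sweep", "normalize": True},
            seed=20230404,
        )
    if name == "bilayer-mini":
        # two target layers 11.4 um apart (a null of the 21-line gate
        # kernel); the deeper layer is ballistically attenuated and sits
        # under an additional residual screen
        return ExperimentConfig(
            grid={
                "lambda_min_nm": 622.5,
                "lambda_max_nm": 672.5,
                "step_nm": 2.5,
                "subband_nm": 15.0,
                "n_illuminations": 64,
                "field_of_view_um": 3.3,
                "pixels_per_side": 24,
                "numerical_aperture": 1.0,
                "medium_index": 1.4,
            },
            phantom={"kind": "siemens_star", "n_spokes": 8, "depths_um": [-5.7, 5.7]},
            medium={
                "ls_table_nm_um": [[647.5, 14.2]],
                "multiple_scatter_power": 0.015,
            },
            dispersion={
                "strength_rad": 2.2,
                "correlation_length": 0.15,
                "residual_strength_rad": 0.35,
                "residual_correlation_length": 0.3,
            },
            pipeline={"mode": "progressive", "z_upper_um": -5.7, "z_lower_um": 5.7},
            seed=20230405,
        )
    raise KeyError(f"unknown example config {name!r}")


_FIXTURES = {
    "tiny": dict(pixels=16, n_lambda=5, n_ill=21, fov=2.2, seed=11),
    "small": dict(pixels=64, n_lambda=9, n_ill=89, fov=8.8, seed=12),
}


def make_fixtures(size: str, out_dir) -> dict:
    """Write the version-pinned simulation fixtures used by the test suite.

    ``tiny``: 16x16 px, 5 wavelengths, 21 illuminations; ``small``: 64x64 px,
    9 wavelengths, 89 illuminations. Regeneration from the pinned seeds is
    bit-identical.
    """
    if size not in _FIXTURES:
        raise KeyError(f"unknown fixture size {size!r}")
    p = _FIXTURES[size]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    step = 7.5
    lam_c = 647.5
    span = (p["n_lambda"] - 1) * step
    cfg = ExperimentConfig(
        grid={
            "lambda_min_nm": lam_c - span / 2,
            "lambda_max_nm": lam_c + span / 2,
            "step_nm": step,
            "subband_nm": 15.0,
            "n_illuminations": p["n_ill"],
            "field_of_view_um": p["fov"],
            "pixels_per_side": p["pixels"],
            "numerical_aperture": 1.0,
            "medium_index": 1.4,
        },
        phantom={"kind": "point_array", "n_points": 5, "depths_um": [0.0]},
        seed=p["seed"],
        output_dir=str(out),
    )
    grid = build_grid(cfg)
    obj, medium, dispersion = build_sample(cfg, grid)
    matrix, record = simulate_reflection_matrix(obj, grid, medium, dispersion)
    mpath = out / f"{size}_matrix.h5"
    save_matrix(mpath, matrix)
    cfg.to_yaml(out / f"{size}_config.yaml")
    np.save(out / f"{size}_phantom.npy", obj.slices)
    return {"matrix": mpath, "config": out / f"{size}_config.yaml", "grid": grid,
            "matrix_obj": matrix, "object": obj, "record": record}
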