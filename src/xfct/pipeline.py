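"""End-to-end demo pipeline: simulate -> correct -> reconstruct -> calibrate.

Each stage reads and writes files with fixed names inside the run's output
directory so stages can be re-run individually from the command line; with
``resume`` enabled a stage whose outputs already exist is skipped.

Stage outputs
-------------
* ``sinograms.npz(.json)``      three-bin XFCT sinogram set
* ``transmission.npz(.json)``   transmission log sinogram
* ``truth_*.tif``               ground-truth concentration / attenuation maps
* ``ct_mu.tif``                 FBP attenuation map [1/cm]
* ``corrected.npz``             scatter-corrected fluorescence sinogram
* ``xfct_uncorrected.tif``      PRF-only MLEM pass (image units)
* ``xfct_image.tif``            attenuation-corrected MLEM image (image units)
* ``xfct_calibrated.tif``       calibrated image [mg/mL]
* ``report.json``               calibration fit, CNR table, detectability
* ``manifest.json``             config, seed, digests, timing
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .forward import simulate_transmission, simulate_xfct
from .io import (
    RunManifest,
    load_image,
    load_sinograms,
    load_transmission,
    save_image,
    save_sinograms,
    save_transmission,
)
from .metrics import (
    ROSE_THRESHOLD,
    RoiSet,
    apply_calibration,
    cnr,
    detectability_limit,
    fit_calibration,
    roi_stats,
)
from .phantom import rasterize
from .recon import fbp_slice, reconstruct_quantitative
from .scatter import correct

__all__ = ["run_simulate", "run_recon_ct", "run_recon_xfct", "run_calibrate",
           "run_correct", "run_pipeline", "default_roi_set"]


def _outdir(cfg: RunConfig, out: str | None) -> Path:
    d = Path(out) if out else Path(cfg.output_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_simulate(cfg: RunConfig, out: str | None = None, resume: bool = False) -> Path:
    """Generate the phantom and simulate XFCT + transmission scans."""
    d = _outdir(cfg, out)
    sino_path = d / "sinograms.npz"
    trans_path = d / "transmission.npz"
    if resume and sino_path.exists() and trans_path.exists():
        return d
    grid = cfg.grid.build()
    geom = cfg.geometry.build()
    protocol = cfg.protocol.build()
    spec = cfg.phantom.build(cfg.seed)
    truth = rasterize(spec, grid)
    spectrum = cfg.spectrum.build()
    sinos = simulate_xfct(
        truth, geom, spectrum, protocol,
        seed=cfg.sub_seed("xfct"), noise=cfg.noise,
    )
    save_sinograms(sino_path, sinos)
    ct_spectrum = cfg.ct.spectrum.build()
    trans = simulate_transmission(
        truth, ct_spectrum, n_views=cfg.ct.n_views,
        photons_per_ray=cfg.ct.photons_per_ray,
        seed=cfg.sub_seed("ct"), noise=cfg.noise,
    )
    save_transmission(trans_path, trans)
    save_image(d / "truth_concentration.tif", truth.concentration_map, grid,
               units="mg/mL")
    e_ct = trans.energy_keV
    save_image(d / "truth_mu_ct.tif", truth.mu_map(e_ct), grid,
               units="1/cm", energy_keV=e_ct)
    return d


def run_correct(cfg: RunConfig, out: str | None = None, resume: bool = False) -> Path:
    """Scatter-correct the fluorescence bin of an existing sinogram set."""
    d = _outdir(cfg, out)
    path = d / "corrected.npz"
    if resume and path.exists():
        return d
    sinos = load_sinograms(d / "sinograms.npz")
    corr = correct(sinos, cfg.spectrum.build())
    np.savez_compressed(path, n_xrf=corr.n_xrf, scatter_estimate=corr.scatter_estimate)
    return d


def run_recon_ct(cfg: RunConfig, out: str | None = None, resume: bool = False) -> Path:
    """Filtered backprojection of the transmission sinogram."""
    d = _outdir(cfg, out)
    path = d / "ct_mu.tif"
    if resume and path.exists():
        return d
    trans = load_transmission(d / "transmission.npz")
    mu = fbp_slice(trans)
    save_image(path, mu, trans.grid, units="1/cm", energy_keV=trans.energy_keV)
    return d


def run_recon_xfct(cfg: RunConfig, out: str | None = None, resume: bool = False) -> Path:
    """Scatter- and attenuation-corrected quantitative MLEM reconstruction."""
    d = _outdir(cfg, out)
    path = d / "xfct_image.tif"
    if resume and path.exists():
        return d
    sinos = load_sinograms(d / "sinograms.npz")
    mu_ct, grid = load_image(d / "ct_mu.tif")
    e_ct = json.loads((d / "ct_mu.json").read_text())["energy_keV"]
    rc = cfg.reconstruction
    result = reconstruct_quantitative(
        sinos, mu_ct, e_ct, cfg.spectrum.build(), grid,
        n_outer=rc.n_outer, n_iter=rc.n_iter,
        bone_threshold=rc.bone_threshold,
        max_concentration=rc.max_concentration,
        stop_rel_change=rc.stop_rel_change,
    )
    save_image(d / "xfct_uncorrected.tif", result.uncorrected.values, grid,
               units="image", iterations=result.uncorrected.n_iterations)
    save_image(path, result.image.values, grid,
               units="image", iterations=result.image.n_iterations,
               log_likelihood=list(map(float, result.image.log_likelihood)))
    return d


def default_roi_set(cfg: RunConfig) -> tuple[RoiSet, list[float]]:
    """Target ROIs on each insertion plus a background sampling ring."""
    spec = cfg.phantom.build(cfg.seed)
    m = cfg.metrics
    targets = tuple(
        (ins.center, m.roi_radius_fraction * ins.radius) for ins in spec.insertions
    )
    n = m.background_n_rois
    backgrounds = tuple(
        (
            (
                m.background_ring_radius * np.cos(2 * np.pi * (k + 0.5) / n),
                m.background_ring_radius * np.sin(2 * np.pi * (k + 0.5) / n),
            ),
            m.background_roi_radius,
        )
        for k in range(n)
    )
    concentrations = [ins.concentration for ins in spec.insertions]
    return RoiSet(targets, backgrounds), concentrations


def run_calibrate(cfg: RunConfig, out: str | None = None, resume: bool = False) -> dict:
    """Fit the concentration calibration, compute CNR and detectability."""
    d = _outdir(cfg, out)
    report_path = d / "report.json"
    if resume and report_path.exists():
        return json.loads(report_path.read_text())
    image, grid = load_image(d / "xfct_image.tif")
    ct_mu, _ = load_image(d / "ct_mu.tif")
    rois, concentrations = default_roi_set(cfg)

    means, sds = [], []
    for center, radius in rois.targets:
        mean, sd, _ = roi_stats(image, grid, center, radius)
        means.append(mean)
        sds.append(sd)
    fit = fit_calibration(means, concentrations)
    calibrated = apply_calibration(image, fit)
    save_image(d / "xfct_calibrated.tif", calibrated, grid, units="mg/mL")

    cnr_xfct = [cnr(image, grid, t, rois.backgrounds) for t in rois.targets]
    cnr_ct = [cnr(ct_mu, grid, t, rois.backgrounds) for t in rois.targets]
    limits = {}
    for label, values in (("xfct", cnr_xfct), ("transmission_ct", cnr_ct)):
        try:
            limits[label] = detectability_limit(values, concentrations)
        except ValueError as err:
            limits[label] = None
            limits[f"{label}_note"] = str(err)

    report = {
        "concentrations_mg_per_mL": concentrations,
        "roi_means": means,
        "roi_sds": sds,
        "calibration": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_square": fit.r_square,
        },
        "cnr": {"xfct": cnr_xfct, "transmission_ct": cnr_ct},
        "rose_threshold": ROSE_THRESHOLD,
        "detectability_limit_mg_per_mL": limits,
    }
    report_path.write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(cfg: RunConfig, out: str | None = None, resume: bool = False) -> dict:
    """Run every stage in order and write the manifest; returns the report."""
    d = _outdir(cfg, out)
    manifest = RunManifest(cfg.model_dump(), cfg.seed, __version__)
    stages = [
        ("simulate", run_simulate),
        ("correct", run_correct),
        ("recon-ct", run_recon_ct),
        ("recon-xfct", run_recon_xfct),
        ("calibrate", run_calibrate),
    ]
    report = None
    for name, fn in stages:
        manifest.start_stage(name)
        try:
            result = fn(cfg, str(d), resume)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest.end_stage()
        if name == "calibrate":
            report = result
    for f in sorted(d.glob("*")):
        if f.suffix in (".npz", ".tif", ".json") and f.name != "manifest.json":
            manifest.record(f.name, f)
    manifest.write(d / "manifest.json")
    return report
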