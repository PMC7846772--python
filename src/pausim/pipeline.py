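"""End-to-end orchestration: simulate -> beamform -> track/correct ->
fluence-fit/compensate -> wavelength compounding and component imaging.

All randomness flows from one top-level seed through named substreams
("scene", "noise", "tracking"), so individual stages can be re-run
bit-identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import acoustics, beamform, spectral, tracking
from .beamform import PAImage, SpectroStack
from .core import ImageGrid, ProbeGeometry, ScanSequence, build_probe_geometry, build_scan_sequence
from .io import Dataset, read_spectrum_csv, rng_for, seed_for
from .optics import FluenceParams, total_fluence_map
from .scene import Phantom, chromophore_spectrum, make_phantom
from .spectral import SearchGrid

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult", "PipelineError", "demo_config",
           "geometry_from_config", "grid_from_config", "sequence_from_config",
           "simulate_rf", "reconstruct_stack"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and its input identifiers."""

    def __init__(self, stage: str, inputs: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (inputs: {inputs}): {cause}")
        self.stage = stage


def demo_config() -> dict:
    """Small three-tube demo scene that runs end to end in seconds."""
    return {
        "probe": {
            "n_elements": 64,
            "element_pitch_mm": 0.2,
            "center_frequency_mhz": 15.0,
            "sampling_rate_mhz": 62.5,
            "sound_speed_m_s": 1540.0,
            "bandwidth_fraction": 0.6,
        },
        "fibers": {"n_per_row": 10, "pitch_mm": 1.5, "elevation_mm": 6.0},
        "sequence": {
            "wavelengths_nm": [700.0, 735.0, 775.0, 815.0, 855.0],
            "laser_off_nm": [700.0],
            "pulse_rate_hz": 1000.0,
            "fiber_order": "ascending",
        },
        "grid": {"width_mm": 12.8, "depth_mm": 8.0, "pitch_mm": 0.16, "z0_mm": 2.0},
        "phantom": {
            "background": {"mu_a_scale": 0.08, "mu_s_prime_700": 10.0, "scattering_power": 1.6},
            "inclusions": [
                {"name": "gnr", "chromophore": "gnr", "center_mm": [-3.5, 6.0], "radius_mm": 0.6, "mu_a": 2.0},
                {"name": "water", "chromophore": "flat", "center_mm": [0.0, 6.0], "radius_mm": 0.6, "mu_a": 0.05},
                {"name": "ink", "chromophore": "ink", "center_mm": [3.5, 6.0], "radius_mm": 0.6, "mu_a": 2.0},
            ],
            "scatterer_density_per_mm2": 250.0,
            "grueneisen": 0.2,
            "motion": {"model": "none"},
        },
        "noise": {"rf_sigma_pa": 0.02, "rf_sigma_us": 1.0},
        "tracking": {"patch_half": 5, "n_iterations": 5, "search_radius": 10},
        "spectral": {"mu_eff_max": 5.0, "mu_eff_step": 0.05},
        "references": ["gnr", "ink"],
    }


def geometry_from_config(config: dict) -> ProbeGeometry:
    p = config.get("probe", {})
    f = config.get("fibers", {})
    return build_probe_geometry(
        n_elements=int(p.get("n_elements", 128)),
        element_pitch=float(p.get("element_pitch_mm", 0.1)) * 1e-3,
        n_fibers_per_row=int(f.get("n_per_row", 10)),
        fiber_pitch=float(f.get("pitch_mm", 1.5)) * 1e-3,
        fiber_elevation=float(f.get("elevation_mm", 6.0)) * 1e-3,
        center_frequency=float(p.get("center_frequency_mhz", 15.0)) * 1e6,
        sampling_rate=float(p.get("sampling_rate_mhz", 62.5)) * 1e6,
        sound_speed=float(p.get("sound_speed_m_s", 1540.0)),
        bandwidth_fraction=float(p.get("bandwidth_fraction", 0.6)),
    )


def grid_from_config(config: dict) -> ImageGrid:
    g = config.get("grid", {})
    pz = g.get("pitch_axial_mm", None)
    return ImageGrid.centered(
        width=float(g.get("width_mm", 12.8)) * 1e-3,
        depth=float(g.get("depth_mm", 10.0)) * 1e-3,
        pitch=float(g.get("pitch_mm", 0.1)) * 1e-3,
        z0=float(g.get("z0_mm", 2.0)) * 1e-3,
        pitch_axial=None if pz is None else float(pz) * 1e-3,
    )


def sequence_from_config(config: dict, geometry: ProbeGeometry) -> ScanSequence:
    s = config.get("sequence", {})
    return build_scan_sequence(
        wavelengths=s.get("wavelengths_nm", [700.0, 775.0, 855.0]),
        n_fibers=geometry.n_fibers,
        pulse_rate=float(s.get("pulse_rate_hz", 1000.0)),
        fiber_order=s.get("fiber_order", "ascending"),
        laser_off_wavelengths=s.get("laser_off_nm", []),
    )


def true_fluence_params(phantom: Phantom, wavelength: float) -> FluenceParams:
    """Forward-model diffusion parameters from the phantom's background."""
    return FluenceParams.from_optical(
        mu_a=float(phantom.background_mu_a(wavelength)),
        mu_s_prime=phantom.mu_s_prime(wavelength),
        wavelength=wavelength,
    )


def simulate_rf(config: dict, seed: int, geometry=None, grid=None, sequence=None,
                phantom=None) -> dict:
    """Simulate all RF frames for one spectroscopic cycle.

    Returns ``{"pa": {(frame, fiber): RFFrame}, "us": {frame: RFFrame}}`` with
    one frame per wavelength; the laser-off wavelength is fired at zero
    energy so only noise reaches the channels.
    """
    geometry = geometry or geometry_from_config(config)
    grid = grid or grid_from_config(config)
    sequence = sequence or sequence_from_config(config, geometry)
    phantom = phantom or make_phantom(config.get("phantom", {}), seed, grid)
    noise = config.get("noise", {})
    sigma_pa = float(noise.get("rf_sigma_pa", 0.0))
    sigma_us = float(noise.get("rf_sigma_us", 0.0))
    rng = rng_for(seed, "noise")
    pulse = acoustics.Pulse(geometry.center_frequency, geometry.bandwidth_fraction)
    n_time_pa = acoustics.n_samples_for(grid, geometry, "pa")
    n_time_us = acoustics.n_samples_for(grid, geometry, "us")

    out = {"pa": {}, "us": {}}
    for k, w in enumerate(sequence.wavelengths):
        energy = 0.0 if w in sequence.laser_off_wavelengths else 1.0
        fl = total_fluence_map(geometry, true_fluence_params(phantom, w), grid)
        mu_a = phantom.mu_a_map(w, frame_index=k)
        for f in sequence.fiber_order:
            p0 = phantom.grueneisen * mu_a * fl.per_fiber[f] * energy
            out["pa"][(k, f)] = acoustics.simulate_pa_rf(
                p0, grid, geometry, pulse, noise_sigma=sigma_pa, rng=rng,
                n_time=n_time_pa, wavelength=w, fiber_index=f, laser_energy=energy,
            )
        pos, refl = phantom.scatterers_at_frame(k)
        out["us"][k] = acoustics.simulate_us_rf(
            pos, refl, geometry, pulse, noise_sigma=sigma_us, rng=rng, n_time=n_time_us,
        )
    return out


def reconstruct_stack(rf: dict, config: dict, geometry=None, grid=None,
                      sequence=None) -> SpectroStack:
    """Beamform all firings and compound each wavelength coherently."""
    geometry = geometry or geometry_from_config(config)
    grid = grid or grid_from_config(config)
    sequence = sequence or sequence_from_config(config, geometry)
    f_number = config.get("probe", {}).get("bmode_f_number", 2.5)
    per_wavelength = {}
    bmode = {}
    for k, w in enumerate(sequence.wavelengths):
        subs = [beamform.das_pa(rf["pa"][(k, f)], geometry, grid) for f in sequence.fiber_order]
        per_wavelength[w] = subs
        if k in rf["us"]:
            bmode[w] = beamform.das_us(rf["us"][k], geometry, grid, f_number=f_number)
    return SpectroStack.from_subimages(
        grid, sequence.wavelengths, per_wavelength, bmode=bmode,
        laser_off_wavelengths=sequence.laser_off_wavelengths,
    )


@dataclass
class PipelineResult:
    """Everything produced by one pipeline run (in memory)."""

    config: dict
    seed: int
    geometry: ProbeGeometry
    grid: ImageGrid
    sequence: ScanSequence
    phantom: Phantom
    stack_raw: SpectroStack
    stack_mc: SpectroStack
    motion_fields: dict
    noise_floor: np.ndarray
    fits: dict
    stack_comp: SpectroStack
    sigma_lambda: PAImage
    spectra: spectral.PixelSpectrum
    components: dict
    timings: dict = field(default_factory=dict)


def _stage(name: str, inputs: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t = time.perf_counter()
            log.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t
            timings[name] = dt
            if exc is not None:
                raise PipelineError(name, inputs, exc) from exc
            log.info("stage %s done in %.2f s", name, dt)

    return _Ctx()


def _reference_spectrum(name_or_path: str):
    try:
        return chromophore_spectrum(str(name_or_path), np.arange(650.0, 951.0, 5.0))
    except ValueError:
        return read_spectrum_csv(name_or_path)


def run_pipeline(config: dict, seed: int, out_path=None) -> PipelineResult:
    """Run the full fast-sweep processing chain on a synthetic scene."""
    timings: dict = {}
    geometry = geometry_from_config(config)
    grid = grid_from_config(config)
    sequence = sequence_from_config(config, geometry)

    with _stage("scene", f"seed={seed}", timings):
        phantom = make_phantom(config.get("phantom", {}), seed, grid)

    with _stage("simulate", f"seed={seed}", timings):
        rf = simulate_rf(config, seed, geometry, grid, sequence, phantom)

    with _stage("beamform", "rf", timings):
        stack_raw = reconstruct_stack(rf, config, geometry, grid, sequence)

    with _stage("track", "images", timings):
        tcfg = config.get("tracking", {})
        params = tracking.TrackParams(
            seed=int(np.random.default_rng(seed_for(seed, "tracking")).integers(2**31)),
            patch_half=int(tcfg.get("patch_half", 5)),
            n_iterations=int(tcfg.get("n_iterations", 5)),
            search_radius=int(tcfg.get("search_radius", 16)),
        )
        if stack_raw.bmode:
            stack_mc, motion_fields = tracking.motion_correct_stack(stack_raw, params)
        else:
            stack_mc, motion_fields = stack_raw.copy(), {}
            stack_mc.motion_corrected = True

    with _stage("noise_floor", "images_mc", timings):
        w_off = sequence.laser_off_wavelengths[0] if sequence.laser_off_wavelengths else None
        if w_off is not None:
            off_img = PAImage(stack_mc.compound[w_off], grid, wavelength=w_off,
                              laser_energy=stack_mc.laser_energy.get(w_off, 0.0))
            noise_floor = spectral.estimate_noise_floor(off_img)
        else:
            noise_floor = np.zeros(grid.shape)

    with _stage("fluence_fit", "images_mc", timings):
        scfg = config.get("spectral", {})
        search = SearchGrid.default(
            mu_eff_max=float(scfg.get("mu_eff_max", 5.0)),
            mu_eff_step=float(scfg.get("mu_eff_step", 0.05)),
        )
        fits = {}
        for w in sequence.active_wavelengths:
            mask = None
            if noise_floor.max() <= 0:
                comp = stack_mc.compound_envelope(w)
                mask = comp > 0.5 * comp.max()
            fits[w] = spectral.estimate_mu_eff(
                stack_mc, geometry, w, mask=mask, search=search, noise_floor=noise_floor,
            )

    with _stage("compensate", "fits", timings):
        stack_comp = spectral.compensate_fluence(stack_mc, fits, geometry)

    with _stage("spectral", "images_comp", timings):
        sigma = spectral.sigma_lambda_compound(stack_comp)
        spectra = spectral.pixel_spectra(stack_comp, noise_floor)
        components = {}
        for ref_name in config.get("references", []):
            ref = _reference_spectrum(ref_name)
            components[ref.name] = spectral.component_weighted(spectra, sigma, ref)

    result = PipelineResult(
        config=config, seed=seed, geometry=geometry, grid=grid, sequence=sequence,
        phantom=phantom, stack_raw=stack_raw, stack_mc=stack_mc,
        motion_fields=motion_fields, noise_floor=noise_floor, fits=fits,
        stack_comp=stack_comp, sigma_lambda=sigma, spectra=spectra,
        components=components, timings=timings,
    )

    if out_path is not None:
        with _stage("write", str(out_path), timings):
            with Dataset(out_path, "w") as ds:
                ds.set_provenance(seed, config)
                ds.write_phantom(phantom, sequence.active_wavelengths)
                ds.write_stack(stack_raw, "images")
                ds.write_stack(stack_mc, "images_mc")
                if motion_fields:
                    ds.write_motion(motion_fields, grid)
                fluence = {w: total_fluence_map(geometry, fits[w].params(), grid).total
                           for w in sequence.active_wavelengths}
                ds.write_spectral(fits, sigma.envelope, components, noise_floor,
                                  fluence_maps=fluence)
    return result
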