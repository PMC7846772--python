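"""Shared test utilities: independent oracles and synthetic-stack builders.

Everything here is deliberately independent of the implementation paths it
checks (brute-force searches, closed forms, direct evaluation).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from pausim import core, optics, scene
from pausim.beamform import SpectroStack


def local_ncc_map(a: np.ndarray, b: np.ndarray, patch: int) -> np.ndarray:
    """Patchwise mean-removed NCC between co-located patches of a and b."""
    ma = uniform_filter(a, patch, mode="constant")
    mb = uniform_filter(b, patch, mode="constant")
    maa = uniform_filter(a * a, patch, mode="constant")
    mbb = uniform_filter(b * b, patch, mode="constant")
    mab = uniform_filter(a * b, patch, mode="constant")
    cov = mab - ma * mb
    va = np.maximum(maa - ma * ma, 0)
    vb = np.maximum(mbb - mb * mb, 0)
    denom = np.sqrt(va * vb)
    return np.where(denom > 1e-12, cov / np.maximum(denom, 1e-300), 0.0)


def exhaustive_block_match(a: np.ndarray, b: np.ndarray, radius: int, patch: int):
    """Full integer-displacement search maximizing patch NCC.

    Returns (dz, dx, ncc) maps; pixels where a shift would leave the frame
    keep whatever in-frame shift scores best.
    """
    nz, nx = a.shape
    best = np.full((nz, nx), -2.0)
    dz = np.zeros((nz, nx), dtype=int)
    dx = np.zeros((nz, nx), dtype=int)
    for u in range(-radius, radius + 1):
        for v in range(-radius, radius + 1):
            shifted = np.full_like(b, np.nan)
            src_z = slice(max(u, 0), nz + min(u, 0))
            src_x = slice(max(v, 0), nx + min(v, 0))
            dst_z = slice(max(-u, 0), nz + min(-u, 0))
            dst_x = slice(max(-v, 0), nx + min(-v, 0))
            shifted[dst_z, dst_x] = b[src_z, src_x]
            valid = ~np.isnan(shifted)
            shifted = np.where(valid, shifted, 0.0)
            ncc = local_ncc_map(a, shifted, patch)
            # patches touching invalid pixels are not comparable
            frac = uniform_filter(valid.astype(float), patch, mode="constant")
            ncc = np.where(frac > 0.999, ncc, -2.0)
            better = ncc > best
            best[better] = ncc[better]
            dz[better] = u
            dx[better] = v
    return dz, dx, best


def smooth_speckle(shape, rng, scale=2.0):
    """Non-negative speckle-like field: smoothed white noise envelope."""
    field = uniform_filter(rng.standard_normal(shape), int(2 * scale) + 1)
    return np.abs(field) + 0.05


def model_stack(
    geometry: core.ProbeGeometry,
    grid: core.ImageGrid,
    wavelengths,
    mu_a_fn,
    mu_eff_fn,
    mu_s_prime_fn,
    rng=None,
    amp_noise: float = 0.0,
    laser_off=(),
) -> SpectroStack:
    """Image-domain forward model: sub-image amplitude = mu_a * Phi_fiber.

    Bypasses the acoustic chain so spectral-module behavior can be tested
    against exact expectations; optional multiplicative amplitude noise.
    """
    stack = SpectroStack(grid=grid, wavelengths=tuple(wavelengths),
                         laser_off_wavelengths=tuple(laser_off), motion_corrected=True)
    for w in stack.wavelengths:
        params = optics.FluenceParams(mu_eff_fn(w), 1.0 / (3.0 * mu_s_prime_fn(w)), w)
        fl = optics.total_fluence_map(geometry, params, grid)
        mu_a = mu_a_fn(w)
        sub = mu_a[None, :, :] * fl.per_fiber
        if amp_noise > 0 and rng is not None:
            sub = sub * (1.0 + amp_noise * rng.standard_normal(sub.shape))
        stack.subimages[w] = sub.astype(complex)
        stack.compound[w] = sub.sum(axis=0).astype(complex)
        stack.laser_energy[w] = 0.0 if w in laser_off else 1.0
    return stack


def background_scene(mu_a_scale=0.3):
    """Wavelength-dependent background optics shared by spectral tests."""
    wl_grid = np.arange(650.0, 951.0, 5.0)
    bg = scene.chromophore_spectrum("background", wl_grid)

    def mu_a_bg(w):
        return mu_a_scale * float(bg(w))

    def mu_s(w):
        return float(scene.intralipid_mu_s_prime(w))

    def mu_eff(w):
        return optics.effective_attenuation(mu_a_bg(w), mu_s(w))

    return mu_a_bg, mu_s, mu_eff
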