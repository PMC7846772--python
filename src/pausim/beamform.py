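"""Delay-and-sum reconstruction of PA sub-images and B-mode frames, and
coherent compounding of sub-images into full PA frames.

The analytic signal is formed along time (Hilbert transform) before delay
application, so complex beamformed fields are retained and envelope detection
is deferred to display/measurement time.  Beamformed fields are demodulated
by the axial carrier phase (a per-pixel unit-modulus factor, identical for
every sub-image), which leaves envelopes and coherent sums unchanged but
makes the complex fields spatially smooth enough to interpolate during
motion correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .acoustics import RFFrame
from .core import ImageGrid, ProbeGeometry

__all__ = ["SubImage", "PAImage", "SpectroStack", "das_pa", "das_us", "compound_subimages"]


@dataclass
class SubImage:
    """Complex beamformed PA field from a single laser firing."""

    field: np.ndarray  # complex, (nz, nx)
    grid: ImageGrid
    fiber_index: int | None = None
    wavelength: float | None = None
    laser_energy: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.field)
        if f.shape != self.grid.shape:
            raise ValueError("field shape must match the grid")
        if not np.all(np.isfinite(f)):
            raise ValueError("field must be finite")
        self.field = f.astype(complex)

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.field)


@dataclass
class PAImage:
    """Compounded per-wavelength PA image (complex field + envelope)."""

    field: np.ndarray
    grid: ImageGrid
    wavelength: float | None = None
    laser_energy: float = 1.0

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.field)


def _gather_delayed(analytic: np.ndarray, sample_idx: np.ndarray, apod: np.ndarray | None) -> np.ndarray:
    """Sum per-element analytic samples at fractional delay indices.

    ``sample_idx`` has shape (n_elements, n_pixels); out-of-window indices
    contribute zero.
    """
    n_el, n_t = analytic.shape
    i0 = np.floor(sample_idx).astype(np.int64)
    frac = sample_idx - i0
    valid = (i0 >= 0) & (i0 < n_t - 1)
    i0c = np.clip(i0, 0, n_t - 2)
    rows = np.arange(n_el)[:, None]
    s = analytic[rows, i0c] * (1.0 - frac) + analytic[rows, i0c + 1] * frac
    s = np.where(valid, s, 0.0)
    if apod is not None:
        s = s * apod
    return s.sum(axis=0), valid


def _check_coverage(valid: np.ndarray) -> None:
    if not np.all(valid.any(axis=0)):
        warnings.warn("some grid pixels fall outside the RF time window; zero-filled",
                      stacklevel=3)


def das_pa(
    rf: RFFrame,
    geometry: ProbeGeometry,
    grid: ImageGrid,
    f_number: float | None = None,
) -> SubImage:
    """One-way delay-and-sum of a PA firing onto the image grid.

    Rectangular apodization by default; if ``f_number`` is given, element e
    contributes to pixel p only when |x_e - x_p| <= z_p / (2 f_number).
    """
    if rf.kind != "pa":
        raise ValueError("das_pa expects a PA RF frame")
    analytic = hilbert(rf.samples, axis=1)
    pix = grid.pixel_positions()
    d = np.linalg.norm(pix[None, :, :] - geometry.element_positions[:, None, :], axis=2)
    idx = (d / geometry.sound_speed - rf.t0) * rf.sampling_rate
    apod = _aperture(geometry, pix, f_number)
    summed, valid = _gather_delayed(analytic, idx, apod)
    _check_coverage(valid)
    demod = np.exp(-2j * np.pi * geometry.center_frequency * pix[:, 2] / geometry.sound_speed)
    return SubImage((summed * demod).reshape(grid.shape), grid, fiber_index=rf.fiber_index,
                    wavelength=rf.wavelength, laser_energy=rf.laser_energy)


def das_us(
    rf: RFFrame,
    geometry: ProbeGeometry,
    grid: ImageGrid,
    f_number: float | None = None,
) -> np.ndarray:
    """Two-way (plane-wave transmit, dynamic receive) DAS; returns the
    detected envelope image."""
    if rf.kind != "us":
        raise ValueError("das_us expects a US RF frame")
    analytic = hilbert(rf.samples, axis=1)
    pix = grid.pixel_positions()
    d_rx = np.linalg.norm(pix[None, :, :] - geometry.element_positions[:, None, :], axis=2)
    delays = (pix[:, 2][None, :] + d_rx) / geometry.sound_speed
    idx = (delays - rf.t0) * rf.sampling_rate
    apod = _aperture(geometry, pix, f_number)
    summed, valid = _gather_delayed(analytic, idx, apod)
    _check_coverage(valid)
    return np.abs(summed).reshape(grid.shape)


def _aperture(geometry: ProbeGeometry, pix: np.ndarray, f_number: float | None):
    if f_number is None:
        return None
    half = pix[:, 2][None, :] / (2.0 * f_number)
    return (np.abs(geometry.element_x[:, None] - pix[:, 0][None, :]) <= half).astype(float)


def compound_subimages(subimages: list) -> PAImage:
    """Coherent (complex) sum of one wavelength's sub-images, before envelope.

    Signal common to the sub-images adds linearly while independent noise
    adds in quadrature, which is the source of the fast-sweep SNR trade-off.
    """
    if len(subimages) == 0:
        raise ValueError("need at least one sub-image")
    wavelengths = {s.wavelength for s in subimages}
    if len(wavelengths) > 1:
        raise ValueError("cannot compound sub-images from different wavelengths")
    grid = subimages[0].grid
    if any(s.grid is not grid and s.grid != grid for s in subimages):
        raise ValueError("sub-images must share one grid")
    total = np.zeros(grid.shape, dtype=complex)
    for s in subimages:
        total = total + s.field
    energy = max(s.laser_energy for s in subimages)
    return PAImage(total, grid, wavelength=subimages[0].wavelength, laser_energy=energy)


@dataclass
class SpectroStack:
    """All beamformed products of one spectroscopic cycle on one grid.

    ``subimages[wavelength]`` is the (n_fibers, nz, nx) complex sub-image
    array in fiber order, ``compound[wavelength]`` the coherent sum, and
    ``bmode[wavelength]`` the interleaved B-mode envelope frame.
    """

    grid: ImageGrid
    wavelengths: tuple  # acquisition order, nm
    subimages: dict = field(default_factory=dict)
    compound: dict = field(default_factory=dict)
    bmode: dict = field(default_factory=dict)
    laser_energy: dict = field(default_factory=dict)
    laser_off_wavelengths: tuple = ()
    motion_corrected: bool = False
    fluence_compensated: bool = False

    @property
    def active_wavelengths(self) -> tuple:
        return tuple(w for w in self.wavelengths if w not in self.laser_off_wavelengths)

    def compound_envelope(self, wavelength: float) -> np.ndarray:
        return np.abs(self.compound[wavelength])

    def subimage_envelopes(self, wavelength: float) -> np.ndarray:
        return np.abs(self.subimages[wavelength])

    @classmethod
    def from_subimages(cls, grid, wavelengths, per_wavelength_subimages, bmode=None,
                       laser_off_wavelengths=(), laser_energy=None) -> "SpectroStack":
        """Build a stack from lists of :class:`SubImage` per wavelength and
        compound each wavelength coherently."""
        stack = cls(grid=grid, wavelengths=tuple(wavelengths),
                    laser_off_wavelengths=tuple(laser_off_wavelengths))
        for w in stack.wavelengths:
            subs = per_wavelength_subimages[w]
            stack.subimages[w] = np.stack([s.field for s in subs])
            stack.compound[w] = compound_subimages(subs).field
            stack.laser_energy[w] = (laser_energy or {}).get(w, max(s.laser_energy for s in subs))
        if bmode:
            stack.bmode = dict(bmode)
        return stack

    def copy(self) -> "SpectroStack":
        out = SpectroStack(
            grid=self.grid, wavelengths=self.wavelengths,
            subimages={w: v.copy() for w, v in self.subimages.items()},
            compound={w: v.copy() for w, v in self.compound.items()},
            bmode={w: v.copy() for w, v in self.bmode.items()},
            laser_energy=dict(self.laser_energy),
            laser_off_wavelengths=self.laser_off_wavelengths,
            motion_corrected=self.motion_corrected,
            fluence_compensated=self.fluence_compensated,
        )
        return out
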