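"""Probe geometry, scan scheduling and shared image-grid conventions.

All lengths are metres internally (configs use mm).  The coordinate frame is
x lateral, y elevation, z axial with z >= 0 pointing into tissue; the array
elements sit on the y = 0, z = 0 line and the illumination fibers form two
mirror-symmetric rows at y = +/- elevation offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProbeGeometry",
    "ScanSequence",
    "ImageGrid",
    "build_probe_geometry",
    "build_scan_sequence",
    "interleaved_fiber_order",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Transducer element and fiber-source coordinates plus acoustic constants."""

    element_positions: np.ndarray  # (n_elements, 3), m
    fiber_positions: np.ndarray  # (n_fibers, 3), m
    center_frequency: float  # Hz
    sampling_rate: float  # Hz
    sound_speed: float  # m/s
    bandwidth_fraction: float = 0.6
    element_width: float | None = None  # m; aperture of one element (directivity)

    def __post_init__(self) -> None:
        ep = np.atleast_2d(np.asarray(self.element_positions, dtype=float))
        fp = np.atleast_2d(np.asarray(self.fiber_positions, dtype=float))
        if ep.shape[0] < 1 or ep.shape[1] != 3:
            raise ValueError("element_positions must be a non-empty (n, 3) array")
        if fp.shape[0] < 2 or fp.shape[0] % 2 != 0 or fp.shape[1] != 3:
            raise ValueError("fiber_positions must hold an even number of 3-D points")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.sampling_rate <= 2.0 * self.center_frequency:
            raise ValueError("sampling_rate must exceed twice the center frequency")
        object.__setattr__(self, "element_positions", ep)
        object.__setattr__(self, "fiber_positions", fp)

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    @property
    def n_fibers(self) -> int:
        return self.fiber_positions.shape[0]

    @property
    def element_x(self) -> np.ndarray:
        return self.element_positions[:, 0]


@dataclass(frozen=True)
class ScanSequence:
    """Ordered (wavelength, fiber) firing schedule with derived timing.

    One pulse is fired per fiber per wavelength, so a single-wavelength frame
    lasts ``n_fibers / pulse_rate`` and a full spectroscopic cycle lasts
    ``n_wavelengths`` frames.
    """

    wavelengths: tuple  # nm, acquisition order
    fiber_order: tuple  # permutation of range(n_fibers)
    pulse_rate: float  # Hz
    laser_off_wavelengths: tuple = ()

    def __post_init__(self) -> None:
        if len(self.wavelengths) == 0:
            raise ValueError("wavelengths must be non-empty")
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        order = tuple(int(i) for i in self.fiber_order)
        if sorted(order) != list(range(len(order))):
            raise ValueError("fiber_order must be a permutation of 0..n_fibers-1")
        off = tuple(self.laser_off_wavelengths)
        if not set(off) <= set(self.wavelengths):
            raise ValueError("laser_off_wavelengths must be a subset of wavelengths")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        object.__setattr__(self, "fiber_order", order)
        object.__setattr__(self, "laser_off_wavelengths", tuple(float(w) for w in off))

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_order)

    @property
    def active_wavelengths(self) -> tuple:
        return tuple(w for w in self.wavelengths if w not in self.laser_off_wavelengths)

    @property
    def frame_time_single_wavelength(self) -> float:
        """Duration (s) of one single-wavelength frame (one loop over fibers)."""
        return self.n_fibers / self.pulse_rate

    @property
    def effective_frame_rate(self) -> float:
        return 1.0 / self.frame_time_single_wavelength

    @property
    def spectroscopic_cycle_time(self) -> float:
        return self.n_wavelengths * self.frame_time_single_wavelength

    @property
    def spectroscopic_frame_rate(self) -> float:
        return 1.0 / self.spectroscopic_cycle_time

    def firings(self):
        """Yield (wavelength, fiber_index) in acquisition order."""
        for w in self.wavelengths:
            for f in self.fiber_order:
                yield w, f


def interleaved_fiber_order(n_fibers: int) -> tuple:
    """Alternate-ends firing order (1, n, 2, n-1, ...) that keeps successive
    surface illumination spots far apart to limit local heating."""
    lo, hi = 0, n_fibers - 1
    order = []
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo += 1
        hi -= 1
    return tuple(order)


def build_probe_geometry(
    n_elements: int = 128,
    element_pitch: float = 0.1e-3,
    n_fibers_per_row: int = 10,
    fiber_pitch: float = 1.5e-3,
    fiber_elevation: float = 6.0e-3,
    center_frequency: float = 15e6,
    sampling_rate: float = 62.5e6,
    sound_speed: float = 1540.0,
    bandwidth_fraction: float = 0.6,
) -> ProbeGeometry:
    """Lay out a linear array with two laterally centered fiber rows.

    The elements span the lateral axis at elevation 0; fiber rows sit at
    +/- ``fiber_elevation`` with their beam entry points on the tissue surface
    (z = 0).  A row of ``n`` fibers at pitch ``p`` spans ``(n - 1) * p``.
    """
    if n_elements < 1 or n_fibers_per_row < 1:
        raise ValueError("element and fiber counts must be positive")
    if element_pitch <= 0 or fiber_pitch <= 0:
        raise ValueError("pitches must be positive")

    ex = (np.arange(n_elements) - (n_elements - 1) / 2.0) * element_pitch
    elements = np.column_stack([ex, np.zeros(n_elements), np.zeros(n_elements)])

    fx = (np.arange(n_fibers_per_row) - (n_fibers_per_row - 1) / 2.0) * fiber_pitch
    top = np.column_stack([fx, np.full(n_fibers_per_row, fiber_elevation), np.zeros(n_fibers_per_row)])
    bottom = top.copy()
    bottom[:, 1] *= -1.0
    fibers = np.concatenate([top, bottom], axis=0)

    return ProbeGeometry(
        element_positions=elements,
        fiber_positions=fibers,
        center_frequency=center_frequency,
        sampling_rate=sampling_rate,
        sound_speed=sound_speed,
        bandwidth_fraction=bandwidth_fraction,
        element_width=element_pitch,
    )


def build_scan_sequence(
    wavelengths: Sequence[float],
    n_fibers: int = 20,
    pulse_rate: float = 1000.0,
    fiber_order: Sequence[int] | str = "ascending",
    laser_off_wavelengths: Sequence[float] = (),
) -> ScanSequence:
    """Assemble a :class:`ScanSequence` with the derived timing fields.

    ``fiber_order`` may be ``"ascending"``, ``"interleaved"`` or an explicit
    permutation of fiber indices.
    """
    if isinstance(fiber_order, str):
        if fiber_order == "ascending":
            order = tuple(range(n_fibers))
        elif fiber_order == "interleaved":
            order = interleaved_fiber_order(n_fibers)
        else:
            raise ValueError(f"unknown fiber_order {fiber_order!r}")
    else:
        order = tuple(fiber_order)
        if len(order) != n_fibers:
            raise ValueError("fiber_order length must equal n_fibers")
    return ScanSequence(
        wavelengths=tuple(wavelengths),
        fiber_order=order,
        pulse_rate=float(pulse_rate),
        laser_off_wavelengths=tuple(laser_off_wavelengths),
    )


@dataclass(frozen=True)
class ImageGrid:
    """Regular pixel grid in the imaging plane (y = 0).

    Grid nodes are pixel centers; images are arrays of shape (nz, nx) with
    axial depth along axis 0.
    """

    x0: float  # m, lateral coordinate of first column
    z0: float  # m, axial coordinate of first row
    nx: int
    nz: int
    dx: float  # m
    dz: float  # m

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.nx < 1 or self.nz < 1:
            raise ValueError("grid must contain at least one pixel")

    @classmethod
    def centered(cls, width: float, depth: float, pitch: float,
                 z0: float = 1.0e-3, pitch_axial: float | None = None) -> "ImageGrid":
        """Grid laterally centered on the array, starting ``z0`` below the
        surface.  ``pitch_axial`` allows finer axial sampling (the axial
        speckle cell is much smaller than the lateral one)."""
        dz = pitch if pitch_axial is None else pitch_axial
        nx = int(round(width / pitch)) + 1
        nz = int(round(depth / dz)) + 1
        return cls(x0=-(nx - 1) / 2.0 * pitch, z0=z0, nx=nx, nz=nz, dx=pitch, dz=dz)

    @classmethod
    def unit(cls, shape: tuple) -> "ImageGrid":
        """Pixel-unit grid (dx = dz = 1) used for image-space algorithms."""
        nz, nx = shape
        return cls(x0=0.0, z0=0.0, nx=nx, nz=nz, dx=1.0, dz=1.0)

    @property
    def shape(self) -> tuple:
        return (self.nz, self.nx)

    @property
    def n_pixels(self) -> int:
        return self.nz * self.nx

    @property
    def x(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.dx

    @property
    def z(self) -> np.ndarray:
        return self.z0 + np.arange(self.nz) * self.dz

    def mesh(self):
        """Return (X, Z) coordinate arrays of shape (nz, nx)."""
        return np.meshgrid(self.x, self.z)

    def pixel_positions(self) -> np.ndarray:
        """Flattened (n_pixels, 3) coordinates in the imaging plane."""
        X, Z = self.mesh()
        return np.column_stack([X.ravel(), np.zeros(self.n_pixels), Z.ravel()])
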