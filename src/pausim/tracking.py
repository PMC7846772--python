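"""PatchMatch speckle tracking between B-mode frames, displacement
accumulation to a reference frame, and image warping for motion correction.

Tracking operates on envelope images.  The randomized search alternates
raster-order neighbor propagation with a shrinking random search around the
current best match; the similarity metric is mean-removed normalized
cross-correlation (NCC) over square patches, refined to subpixel precision by
a parabolic fit of the NCC surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import map_coordinates

from .core import ImageGrid
from .scene import MotionField

__all__ = ["TrackParams", "patchmatch_track", "accumulate_displacements",
           "warp_image", "motion_correct_stack"]


@dataclass(frozen=True)
class TrackParams:
    """PatchMatch configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    patch_half: int = 5  # 11 x 11 patch
    n_iterations: int = 5
    search_radius: int = 16
    radius_decay: float = 0.5
    subpixel: bool = True

    def __post_init__(self) -> None:
        if 2 * self.patch_half + 1 < 3:
            raise ValueError("patch must be at least 3 px wide")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@njit(cache=True)
def _patch_ncc(a, b, i, j, di, dj, half):
    """NCC between the patch of `a` centered at (i, j) and the patch of `b`
    centered at (i + di, j + dj); patches are clipped jointly at borders."""
    nz, nx = a.shape
    r0 = i - half
    r1 = i + half
    c0 = j - half
    c1 = j + half
    if r0 < 0:
        r0 = 0
    if r0 + di < 0:
        r0 = -di
    if r1 > nz - 1:
        r1 = nz - 1
    if r1 + di > nz - 1:
        r1 = nz - 1 - di
    if c0 < 0:
        c0 = 0
    if c0 + dj < 0:
        c0 = -dj
    if c1 > nx - 1:
        c1 = nx - 1
    if c1 + dj > nx - 1:
        c1 = nx - 1 - dj
    n = (r1 - r0 + 1) * (c1 - c0 + 1)
    if r1 - r0 < 1 or c1 - c0 < 1 or n < 9:
        return -2.0
    sa = 0.0
    sb = 0.0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            sa += a[r, c]
            sb += b[r + di, c + dj]
    ma = sa / n
    mb = sb / n
    saa = 0.0
    sbb = 0.0
    sab = 0.0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            va = a[r, c] - ma
            vb = b[r + di, c + dj] - mb
            saa += va * va
            sbb += vb * vb
            sab += va * vb
    denom = np.sqrt(saa * sbb)
    if denom <= 1e-12:
        # Flat patches: identical constants correlate perfectly.
        return 1.0 if saa <= 1e-12 and sbb <= 1e-12 else 0.0
    return sab / denom


@njit(cache=True)
def _pm_search(a, b, half, n_iter, radius0, decay, rand):
    nz, nx = a.shape
    dz = np.zeros((nz, nx), dtype=np.int64)
    dx = np.zeros((nz, nx), dtype=np.int64)
    best = np.empty((nz, nx))
    for i in range(nz):
        for j in range(nx):
            dz[i, j] = int(np.round(rand[0, i, j, 0] * radius0))
            dx[i, j] = int(np.round(rand[0, i, j, 1] * radius0))
            c = _patch_ncc(a, b, i, j, dz[i, j], dx[i, j], half)
            c0 = _patch_ncc(a, b, i, j, 0, 0, half)
            if c0 >= c:  # zero displacement is always a candidate
                dz[i, j] = 0
                dx[i, j] = 0
                c = c0
            best[i, j] = c
    for it in range(n_iter):
        radius = radius0 * decay**it
        if radius < 1.0:
            radius = 1.0
        forward = it % 2 == 0
        for ii in range(nz):
            i = ii if forward else nz - 1 - ii
            for jj in range(nx):
                j = jj if forward else nx - 1 - jj
                # neighbor propagation
                for k in range(2):
                    if k == 0:
                        ni, nj = (i - 1, j) if forward else (i + 1, j)
                    else:
                        ni, nj = (i, j - 1) if forward else (i, j + 1)
                    if 0 <= ni < nz and 0 <= nj < nx:
                        cdz = dz[ni, nj]
                        cdx = dx[ni, nj]
                        if cdz != dz[i, j] or cdx != dx[i, j]:
                            c = _patch_ncc(a, b, i, j, cdz, cdx, half)
                            if c > best[i, j]:
                                best[i, j] = c
                                dz[i, j] = cdz
                                dx[i, j] = cdx
                # random search around current best
                rdz = dz[i, j] + int(np.round(rand[it + 1, i, j, 0] * radius))
                rdx = dx[i, j] + int(np.round(rand[it + 1, i, j, 1] * radius))
                if -nz < rdz < nz and -nx < rdx < nx and (rdz != dz[i, j] or rdx != dx[i, j]):
                    c = _patch_ncc(a, b, i, j, rdz, rdx, half)
                    if c > best[i, j]:
                        best[i, j] = c
                        dz[i, j] = rdz
                        dx[i, j] = rdx
    return dz, dx, best


@njit(cache=True)
def _subpixel_refine(a, b, dz, dx, best, half):
    nz, nx = a.shape
    fz = np.empty((nz, nx))
    fx = np.empty((nz, nx))
    for i in range(nz):
        for j in range(nx):
            fz[i, j] = dz[i, j]
            fx[i, j] = dx[i, j]
            c0 = best[i, j]
            cm = _patch_ncc(a, b, i, j, dz[i, j] - 1, dx[i, j], half)
            cp = _patch_ncc(a, b, i, j, dz[i, j] + 1, dx[i, j], half)
            fz[i, j] += _parabolic(cm, c0, cp)
            cm = _patch_ncc(a, b, i, j, dz[i, j], dx[i, j] - 1, half)
            cp = _patch_ncc(a, b, i, j, dz[i, j], dx[i, j] + 1, half)
            fx[i, j] += _parabolic(cm, c0, cp)
    return fz, fx


@njit(cache=True)
def _parabolic(cm, c0, cp):
    """Vertex offset of the parabola through (-1, cm), (0, c0), (1, cp).

    When all three correlations are positive, fitting the logarithm is used
    instead: for a Gaussian-shaped correlation peak this is exact.  A perfect
    integer match (NCC ~ 1) is left unrefined.
    """
    if c0 >= 1.0 - 1e-9:
        return 0.0
    if cm <= c0 and cp <= c0:
        if cm > 0.0 and c0 > 0.0 and cp > 0.0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        else:
            lm, l0, lp = cm, c0, cp
        denom = lm - 2.0 * l0 + lp
        if denom < -1e-12:
            delta = 0.5 * (lm - lp) / denom
            if delta > 0.5:
                delta = 0.5
            if delta < -0.5:
                delta = -0.5
            return delta
    return 0.0


def patchmatch_track(
    env_a: np.ndarray,
    env_b: np.ndarray,
    params: TrackParams,
    grid: ImageGrid | None = None,
):
    """Dense displacement field from ``env_a`` to ``env_b``.

    Returns ``(field, ncc_map)`` where the field d satisfies
    ``env_b(x + d(x)) ~= env_a(x)``, i.e. warping ``env_b`` by d aligns it
    to ``env_a``.  Deterministic given ``params.seed``.
    """
    a = np.ascontiguousarray(env_a, dtype=np.float64)
    b = np.ascontiguousarray(env_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("envelope frames must be non-negative")
    if grid is None:
        grid = ImageGrid.unit(a.shape)
    elif grid.shape != a.shape:
        raise ValueError("grid shape must match the frames")

    rng = np.random.default_rng(params.seed)
    rand = rng.uniform(-1.0, 1.0, size=(params.n_iterations + 1, *a.shape, 2))
    dz, dx, best = _pm_search(
        a, b, params.patch_half, params.n_iterations,
        float(params.search_radius), params.radius_decay, rand,
    )
    if params.subpixel:
        fz, fx = _subpixel_refine(a, b, dz, dx, best, params.patch_half)
    else:
        fz, fx = dz.astype(float), dx.astype(float)
    field = MotionField(fz * grid.dz, fx * grid.dx, grid)
    return field, np.clip(best, -1.0, 1.0)


def accumulate_displacements(fields: list) -> MotionField:
    """Compose sequential pairwise fields into a frame-k -> frame-0 field.

    With pairwise fields d_i mapping frame i back to frame i-1 (in the
    convention of :func:`patchmatch_track`), the cumulative field obeys
    D_k(x) = D_{k-1}(x) + d_k(x + D_{k-1}(x)): each new pairwise field is
    sampled at the positions displaced by the running cumulative field, not
    added naively.
    """
    if len(fields) == 0:
        raise ValueError("need at least one pairwise field")
    grid = fields[0].grid
    Dz = fields[0].d_axial.copy()
    Dx = fields[0].d_lateral.copy()
    zi, xi = np.meshgrid(np.arange(grid.nz), np.arange(grid.nx), indexing="ij")
    for f in fields[1:]:
        if f.grid.shape != grid.shape:
            raise ValueError("fields must share one grid")
        coords = [zi + Dz / grid.dz, xi + Dx / grid.dx]
        Dz = Dz + map_coordinates(f.d_axial, coords, order=1, mode="nearest")
        Dx = Dx + map_coordinates(f.d_lateral, coords, order=1, mode="nearest")
    return MotionField(Dz, Dx, grid)


def warp_image(image: np.ndarray, field: MotionField, return_mask: bool = False):
    """Resample ``image`` at displaced coordinates: out(x) = image(x + d(x)).

    Bilinear interpolation; samples pulled from outside the frame are zero
    (reported in the optional mask).  Complex images are warped per part.
    """
    grid = field.grid
    if image.shape != grid.shape:
        raise ValueError("image must live on the field's grid")
    da, dl = field.in_pixels()
    zi, xi = np.meshgrid(np.arange(grid.nz), np.arange(grid.nx), indexing="ij")
    coords = [zi + da, xi + dl]
    if np.iscomplexobj(image):
        out = (map_coordinates(image.real, coords, order=1, cval=0.0)
               + 1j * map_coordinates(image.imag, coords, order=1, cval=0.0))
    else:
        out = map_coordinates(image, coords, order=1, cval=0.0)
    if return_mask:
        inside = ((coords[0] >= 0) & (coords[0] <= grid.nz - 1)
                  & (coords[1] >= 0) & (coords[1] <= grid.nx - 1))
        return out, inside
    return out


def motion_correct_stack(stack, params: TrackParams):
    """Track successive B-mode frames, accumulate displacements to the first
    frame of the spectroscopic cycle, and warp all PA images.

    Returns ``(corrected_stack, fields)`` where ``fields[wavelength]`` is the
    cumulative frame->reference motion field used for that wavelength.
    """
    wavelengths = stack.wavelengths
    if not stack.bmode:
        raise ValueError("stack carries no B-mode frames to track")
    pairwise = []
    for k in range(1, len(wavelengths)):
        f, _ = patchmatch_track(
            stack.bmode[wavelengths[k - 1]], stack.bmode[wavelengths[k]],
            TrackParams(seed=params.seed + k, patch_half=params.patch_half,
                        n_iterations=params.n_iterations,
                        search_radius=params.search_radius,
                        radius_decay=params.radius_decay,
                        subpixel=params.subpixel),
            stack.grid,
        )
        pairwise.append(f)

    out = stack.copy()
    fields = {wavelengths[0]: MotionField.zero(stack.grid)}
    for k in range(1, len(wavelengths)):
        w = wavelengths[k]
        D = accumulate_displacements(pairwise[:k])
        fields[w] = D
        out.compound[w] = warp_image(stack.compound[w], D)
        out.subimages[w] = np.stack([warp_image(s, D) for s in stack.subimages[w]])
        out.bmode[w] = warp_image(stack.bmode[w], D)
    out.motion_corrected = True
    return out, fields
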