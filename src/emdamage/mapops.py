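"""Map algebra: frame summation, normalization, subtraction, carving,
low-pass filtering, interpolation and rigid transformation of volumes.

These are the primitive operations behind difference-map analysis of
dose-series reconstructions: low-dose and high-dose maps are brought onto
a common grid (:func:`transform_map` after a coordinate superposition),
band-limited to the poorer resolution (:func:`lowpass_filter`), scaled to
a common RMS (:func:`normalize_rms`) and subtracted
(:func:`subtract_maps`); metal density is removed with
:func:`carve_spheres` before light atoms are picked.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import DensityMap, FrameStack

__all__ = [
    "sum_frames",
    "normalize_rms",
    "subtract_maps",
    "carve_spheres",
    "lowpass_filter",
    "interpolate",
    "transform_map",
]


def sum_frames(stack: FrameStack, first: int, last: int) -> DensityMap:
    """Voxelwise sum of frames *first*..*last* (1-based, inclusive).

    The accumulated fluence (e⁻ Å⁻²) of the selection is recorded in the
    result's ``meta["fluence"]`` together with the frame range.
    """
    if not (1 <= first <= last <= stack.n_frames):
        raise ValueError(
            f"frame range {first}-{last} outside stack of {stack.n_frames} frames"
        )
    out = stack.frames[first - 1].copy()
    for f in stack.frames[first:last]:
        out.grid += f.grid
    n = last - first + 1
    out.meta = {
        "fluence": stack.fluence_per_frame * n,
        "frames": (first, last),
        "n_frames": n,
    }
    return out


def normalize_rms(target: DensityMap, reference: DensityMap) -> DensityMap:
    """Scale *target* so its RMS density equals that of *reference*.

    This is the ratio-of-RMS normalization applied before computing a
    difference map.
    """
    rms_t = target.rms
    if rms_t == 0:
        raise ValueError("cannot normalize a map with zero RMS")
    out = target.copy()
    out.grid *= reference.rms / rms_t
    return out


def subtract_maps(a: DensityMap, b: DensityMap) -> DensityMap:
    """Voxelwise ``a - b``; grids must share geometry exactly."""
    bad = a.same_geometry(b)
    if bad is not None:
        raise ValueError(f"map geometry mismatch in field {bad!r}")
    out = a.copy()
    out.grid = a.grid - b.grid
    return out


def carve_spheres(
    dmap: DensityMap, centers: np.ndarray, radius: float
) -> DensityMap:
    """Zero all voxels whose center lies within *radius* Å of any center.

    Used to subtract metal density before assigning the lighter oxygen and
    water atoms around a metal cluster.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    out = dmap.copy()
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return out
    shape = np.array(out.shape)
    for c in centers:
        cidx = out.xyz_to_index(c)
        half = radius / out.voxel_size
        lo = np.maximum(np.ceil(cidx - half).astype(int), 0)
        hi = np.minimum(np.floor(cidx + half).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
        )
        d2 = (
            ((ii - cidx[0]) * out.voxel_size[0]) ** 2
            + ((jj - cidx[1]) * out.voxel_size[1]) ** 2
            + ((kk - cidx[2]) * out.voxel_size[2]) ** 2
        )
        inside = d2 <= radius**2
        out.grid[ii[inside], jj[inside], kk[inside]] = 0.0
    return out


def lowpass_filter(
    dmap: DensityMap, resolution: float, edge_voxels: int = 5
) -> DensityMap:
    """Attenuate Fourier amplitudes beyond ``1/resolution`` Å⁻¹.

    A cosine ramp of width *edge_voxels* Fourier-voxel spacings ends (falls
    to zero) exactly at the cutoff frequency, so content beyond the stated
    resolution is fully removed while the zero-frequency term (the map
    mean) is untouched.  Requests beyond Nyquist are rejected.
    """
    if resolution < 2.0 * float(np.max(dmap.voxel_size)):
        raise ValueError(
            f"resolution {resolution} Å is beyond Nyquist for voxel size "
            f"{dmap.voxel_size}"
        )
    shape = dmap.shape
    freqs = [
        np.fft.fftfreq(n, d=v) for n, v in zip(shape[:2], dmap.voxel_size[:2])
    ] + [np.fft.rfftfreq(shape[2], d=dmap.voxel_size[2])]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    fmag = np.sqrt(fx**2 + fy**2 + fz**2)
    fcut = 1.0 / resolution
    # one Fourier voxel = spacing along the longest box edge
    df = 1.0 / (np.max(np.array(shape) * dmap.voxel_size))
    width = edge_voxels * df
    ramp_start = max(fcut - width, 0.0)
    mask = np.ones_like(fmag)
    in_ramp = (fmag > ramp_start) & (fmag < fcut)
    mask[in_ramp] = 0.5 * (
        1.0 + np.cos(np.pi * (fmag[in_ramp] - ramp_start) / (fcut - ramp_start))
    )
    mask[fmag >= fcut] = 0.0
    mask[0, 0, 0] = 1.0
    out = dmap.copy()
    out.grid = np.fft.irfftn(np.fft.rfftn(dmap.grid) * mask, s=shape, axes=(0, 1, 2))
    return out


def interpolate(dmap: DensityMap, points: np.ndarray) -> np.ndarray | float:
    """Trilinear interpolation of the map at physical coordinate(s).

    *points* may be a single xyz triple or an ``(N, 3)`` array; values are
    returned with matching shape.  Out-of-bounds points raise ``ValueError``
    (no implicit wrapping).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx = dmap.xyz_to_index(pts)
    upper = np.array(dmap.shape) - 1
    if np.any(idx < -1e-9) or np.any(idx > upper + 1e-9):
        bad = pts[np.any((idx < -1e-9) | (idx > upper + 1e-9), axis=1)][0]
        raise ValueError(f"point {bad} outside map bounds")
    idx = np.clip(idx, 0, upper)
    i0 = np.minimum(np.floor(idx).astype(int), upper - 1)
    frac = idx - i0
    g = dmap.grid
    vals = np.zeros(len(pts))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (frac[:, 0] if di else 1 - frac[:, 0])
                    * (frac[:, 1] if dj else 1 - frac[:, 1])
                    * (frac[:, 2] if dk else 1 - frac[:, 2])
                )
                vals += w * g[i0[:, 0] + di, i0[:, 1] + dj, i0[:, 2] + dk]
    return float(vals[0]) if single else vals


def transform_map(
    dmap: DensityMap, rotation: np.ndarray, translation: np.ndarray
) -> DensityMap:
    """Resample *dmap* under the rigid motion ``x -> R x + t``.

    The output voxel at physical coordinate ``p`` takes the trilinearly
    interpolated input value at ``R⁻¹ (p - t)``; source points outside the
    input grid contribute zero.  *rotation* must be a proper orthonormal
    matrix.
    """
    R = np.asarray(rotation, dtype=float).reshape(3, 3)
    t = np.asarray(translation, dtype=float).reshape(3)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or abs(
        np.linalg.det(R) - 1.0
    ) > 1e-6:
        raise ValueError("rotation must be orthonormal with determinant +1")
    shape = dmap.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * dmap.voxel_size
    pts += dmap.origin
    src = (pts - t) @ R  # (R^-1 (p - t)) with R^-1 = R^T
    src_idx = ((src - dmap.origin) / dmap.voxel_size).T
    out = dmap.copy()
    out.grid = ndimage.map_coordinates(
        dmap.grid, src_idx, order=1, mode="constant", cval=0.0
    ).reshape(shape)
    return out
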