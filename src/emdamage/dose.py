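"""Dose bookkeeping, FSC resolution estimation, Rosenthal-Henderson
B-factor fitting, and damage-metric trajectories versus accumulated dose.

Fluence (e⁻ Å⁻²) is converted to absorbed dose with the standard 300 kV
factor of 3.7 MGy per e⁻ Å⁻², and compared against the ~20 MGy Henderson
limit familiar from X-ray crystallography.  Resolution is estimated from
the Fourier shell correlation of two half-maps at the gold-standard
0.143 cutoff.  The Rosenthal-Henderson B-factor is twice the inverse
slope of 1/d² against ln(particle count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mapops import interpolate, sum_frames
from .model import DensityMap, FrameStack
from .peaks import bond_integrity, find_peaks

__all__ = [
    "MGY_PER_FLUENCE",
    "HENDERSON_LIMIT_MGY",
    "FSC_CUTOFF",
    "dose_to_gray",
    "frames_for_dose",
    "fsc",
    "resolution_at_threshold",
    "rosenthal_henderson_fit",
    "damage_trajectory",
    "FSCCurve",
    "RHFitResult",
    "ResolutionEstimate",
    "DamageProbes",
]

#: MGy absorbed per e⁻ Å⁻² of fluence at 300 kV (configurable per call).
MGY_PER_FLUENCE = 3.7
#: Absorbed dose at which cryo-cooled crystal diffraction halves.
HENDERSON_LIMIT_MGY = 20.0
#: Gold-standard half-map FSC resolution cutoff.
FSC_CUTOFF = 0.143


def dose_to_gray(
    fluence: float, factor: float = MGY_PER_FLUENCE
) -> dict[str, float]:
    """Convert fluence (e⁻ Å⁻²) to absorbed dose (MGy).

    Returns the dose together with its ratio to the Henderson limit.
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    mgy = fluence * factor
    return {
        "fluence": float(fluence),
        "dose_mgy": float(mgy),
        "henderson_ratio": float(mgy / HENDERSON_LIMIT_MGY),
        "exceeds_henderson_limit": mgy > HENDERSON_LIMIT_MGY,
    }


def frames_for_dose(
    total_fluence: float, n_frames: int, target_fluence: float
) -> tuple[int, float]:
    """Number of initial frames delivering approximately *target_fluence*.

    Rounds ``target/total * n_frames`` to the nearest frame (half away
    from zero), minimum 1.  Returns ``(k, realized_fluence)`` where the
    realized fluence is ``k/n_frames * total``.
    """
    if target_fluence <= 0:
        raise ValueError("target fluence must be positive")
    if target_fluence > total_fluence:
        raise ValueError(
            f"target fluence {target_fluence} exceeds total {total_fluence}"
        )
    k = int(np.floor(target_fluence / total_fluence * n_frames + 0.5))
    k = max(k, 1)
    return k, k / n_frames * total_fluence


@dataclass
class FSCCurve:
    """Per-shell Fourier correlation between two half-maps."""

    frequencies: np.ndarray  # shell centers, Å⁻¹, strictly increasing
    correlations: np.ndarray  # in [-1, 1]
    counts: np.ndarray  # Fourier voxels per shell

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")


def fsc(half1: DensityMap, half2: DensityMap, n_shells: int | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps of identical geometry.

    Per radial shell: ``Re(sum F1 conj(F2)) / sqrt(sum|F1|^2 sum|F2|^2)``.
    Shells are uniform in spatial frequency up to the Nyquist frequency of
    the coarsest axis; *n_shells* defaults to half the smallest grid
    dimension.
    """
    bad = half1.same_geometry(half2)
    if bad is not None:
        raise ValueError(f"half-map geometry mismatch in field {bad!r}")
    if n_shells is None:
        n_shells = min(half1.shape) // 2
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    F1 = np.fft.rfftn(half1.grid)
    F2 = np.fft.rfftn(half2.grid)
    shape = half1.shape
    freqs = [
        np.fft.fftfreq(shape[0], d=half1.voxel_size[0]),
        np.fft.fftfreq(shape[1], d=half1.voxel_size[1]),
        np.fft.rfftfreq(shape[2], d=half1.voxel_size[2]),
    ]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    fmag = np.sqrt(fx**2 + fy**2 + fz**2)
    nyquist = float(np.min(0.5 / half1.voxel_size))
    edges = np.linspace(0.0, nyquist, n_shells + 1)
    which = np.digitize(fmag.ravel(), edges) - 1
    valid = (which >= 0) & (which < n_shells)
    num = np.bincount(
        which[valid], weights=(F1 * np.conj(F2)).real.ravel()[valid],
        minlength=n_shells,
    )
    p1 = np.bincount(
        which[valid], weights=(np.abs(F1) ** 2).ravel()[valid], minlength=n_shells
    )
    p2 = np.bincount(
        which[valid], weights=(np.abs(F2) ** 2).ravel()[valid], minlength=n_shells
    )
    counts = np.bincount(which[valid], minlength=n_shells)
    denom = np.sqrt(p1 * p2)
    corr = np.divide(num, denom, out=np.zeros(n_shells), where=denom > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return FSCCurve(centers[keep], np.clip(corr[keep], -1.0, 1.0), counts[keep])


@dataclass
class ResolutionEstimate:
    """Resolution at an FSC threshold, with crossing diagnostics."""

    resolution: float  # Å
    crossed: bool
    flag: str = ""  # "", "no_crossing", or "below_at_first_shell"


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = FSC_CUTOFF
) -> ResolutionEstimate:
    """First low-to-high-frequency crossing of the FSC below *threshold*.

    Linear interpolation between the bracketing shells; if the curve never
    drops below the threshold the Nyquist resolution is returned with a
    ``no_crossing`` flag, and if it is already below at the first shell a
    flagged sentinel (infinite resolution) is returned rather than an
    exception.
    """
    f = curve.frequencies
    c = curve.correlations
    if c[0] < threshold:
        return ResolutionEstimate(float("inf"), False, "below_at_first_shell")
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(1.0 / f[-1], False, "no_crossing")
    j = int(below[0])
    f_cross = f[j - 1] + (threshold - c[j - 1]) * (f[j] - f[j - 1]) / (
        c[j] - c[j - 1]
    )
    return ResolutionEstimate(1.0 / f_cross, True, "")


@dataclass
class RHFitResult:
    """Rosenthal-Henderson fit: 1/d² = (2/B) ln N + intercept."""

    B: float  # Å²
    intercept: float  # Å⁻²
    residual_se: float
    ln_n: np.ndarray
    inv_d2: np.ndarray
    physical: bool  # False when the fitted slope is <= 0


def rosenthal_henderson_fit(
    points: list[tuple[int, float]]
) -> RHFitResult:
    """Fit the B-factor from (particle count, resolution Å) pairs.

    Least-squares line of 1/d² on ln N; ``B = 2/slope``.  A non-positive
    slope yields a result flagged unphysical rather than an exception.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    ns = np.array([p[0] for p in points], dtype=float)
    ds = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(ns)) < 2:
        raise ValueError("particle counts must not all coincide")
    if np.any(ns <= 0) or np.any(ds <= 0):
        raise ValueError("counts and resolutions must be positive")
    x = np.log(ns)
    y = 1.0 / ds**2
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(len(points) - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof))
    physical = fit.slope > 0
    B = 2.0 / fit.slope if physical else float("nan")
    return RHFitResult(B, float(fit.intercept), se, x, y, physical)


@dataclass
class DamageProbes:
    """What to measure per dose: bond segments, metal sites, distances.

    * ``bonds``: label -> (xyz_a, xyz_b) segments for integrity checks;
    * ``metal_sites``: label -> xyz for peak-height occupancy proxies;
    * ``distance_pairs``: (label_a, label_b) pairs measured between local
      density maxima near the corresponding metal sites.
    """

    bonds: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    metal_sites: dict[str, np.ndarray] = field(default_factory=dict)
    distance_pairs: list[tuple[str, str]] = field(default_factory=list)
    bond_contour_sigma: float = 4.0


def _local_peak_position(
    dmap: DensityMap, near: np.ndarray, radius: float = 1.0
) -> np.ndarray:
    """Subvoxel position of the highest local maximum within *radius* Å
    of *near*; falls back to *near* if none is found."""
    candidates = [
        p for p in find_peaks(dmap, threshold_sigma=1.0)
        if np.linalg.norm(p.position - near) <= radius
    ]
    if not candidates:
        return np.asarray(near, dtype=float)
    return candidates[0].position


def damage_trajectory(
    stack: FrameStack,
    dose_list: list[float],
    probes: DamageProbes,
    factor: float = MGY_PER_FLUENCE,
) -> pd.DataFrame:
    """Damage metrics versus accumulated dose.

    For each target fluence in *dose_list* the initial frames delivering
    it are summed and scaled to a per-frame average (so that, absent
    damage and noise, metrics are dose-independent), then sigma, bond
    integrity, metal peak heights (occupancy proxy = height ratio against
    the lowest-dose row) and listed inter-peak distances are measured.
    Returns one row per dose, ordered as given.
    """
    rows = []
    for fluence in dose_list:
        k, realized = frames_for_dose(stack.total_fluence, stack.n_frames, fluence)
        summed = sum_frames(stack, 1, k)
        avg = summed.copy()
        avg.grid /= k
        row: dict = {
            "target_fluence": fluence,
            "realized_fluence": realized,
            "dose_mgy": realized * factor,
            "frames": k,
            "sigma": avg.sigma,
        }
        for name, (a, b) in probes.bonds.items():
            chk = bond_integrity(avg, a, b, probes.bond_contour_sigma)
            row[f"bond_{name}_intact"] = chk.intact
            row[f"bond_{name}_min_sigma"] = chk.min_sigma
        site_positions = {}
        for label, xyz in probes.metal_sites.items():
            pos = _local_peak_position(avg, xyz)
            site_positions[label] = pos
            row[f"height_{label}"] = float(interpolate(avg, pos))
        for a, b in probes.distance_pairs:
            row[f"dist_{a}-{b}"] = float(
                np.linalg.norm(site_positions[a] - site_positions[b])
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if probes.metal_sites and len(df) > 0:
        ref_row = df["realized_fluence"].idxmin()
        for label in probes.metal_sites:
            ref = df.loc[ref_row, f"height_{label}"]
            df[f"occupancy_proxy_{label}"] = df[f"height_{label}"] / ref
    return df
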