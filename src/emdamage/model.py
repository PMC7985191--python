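"""Core in-memory containers: density maps, atomic models, frame stacks.

Conventions used throughout the package:

* Maps are stored as C-ordered ``(nx, ny, nz)`` arrays; the physical
  coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``
  (0-based indexing, orthogonal axes only).
* Atomic coordinates, voxel sizes and origins are in Å; atomic displacement
  parameters (ADP, a.k.a. B-factor) in Å²; occupancies dimensionless in
  [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DensityMap",
    "Atom",
    "AtomicModel",
    "FrameStack",
    "SCATTERING_WEIGHTS",
    "METAL_ELEMENTS",
    "scattering_weight",
]

# Per-element density weights for the Gaussian-atom forward model, roughly
# proportional to atomic number. Stand-ins for electron form factors, which
# are deliberately out of scope: the pipeline only relies on relative peak
# heights (metal ≫ oxygen ≫ hydrogen).
SCATTERING_WEIGHTS: dict[str, float] = {
    "H": 1.0,
    "C": 6.0,
    "N": 7.0,
    "O": 8.0,
    "NA": 11.0,
    "MG": 12.0,
    "P": 15.0,
    "S": 16.0,
    "CL": 17.0,
    "K": 19.0,
    "CA": 20.0,
    "MN": 25.0,
    "FE": 26.0,
    "CO": 27.0,
    "NI": 28.0,
    "CU": 29.0,
    "ZN": 30.0,
}

#: Elements treated as metals when building the "metals" selection.
METAL_ELEMENTS = frozenset(
    {"NA", "MG", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN"}
)


def scattering_weight(element: str) -> float:
    """Density weight for *element* (case-insensitive symbol)."""
    try:
        return SCATTERING_WEIGHTS[element.upper()]
    except KeyError:
        raise KeyError(f"no scattering weight for element {element!r}") from None


@dataclass
class DensityMap:
    """A 3D scalar density grid on an orthogonal lattice.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Density values.
    voxel_size : array-like of 3 floats
        Å per voxel along each axis; must be positive.
    origin : array-like of 3 floats
        Physical coordinate (Å) of voxel ``(0, 0, 0)``.
    meta : dict
        Free-form provenance (e.g. accumulated fluence of a frame sum).
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if any(n < 2 for n in self.grid.shape):
            raise ValueError(f"grid needs >= 2 voxels per axis, got {self.grid.shape}")
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    # Statistics are computed on demand so they can never go stale after a
    # mutation of ``grid``.
    @property
    def mean(self) -> float:
        return float(self.grid.mean())

    @property
    def sigma(self) -> float:
        """Standard deviation over all voxels (the paper's contour unit)."""
        return float(self.grid.std())

    @property
    def rms(self) -> float:
        """Root mean square density (used for difference-map scaling)."""
        return float(np.sqrt(np.mean(self.grid**2)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    def index_to_xyz(self, ijk: np.ndarray) -> np.ndarray:
        """Physical coordinate(s) of fractional voxel index/indices *ijk*."""
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index/indices of physical coordinate(s) *xyz*."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.grid.copy(), self.voxel_size, self.origin, dict(self.meta)
        )

    def same_geometry(self, other: "DensityMap") -> str | None:
        """Return the name of the first mismatching geometry field, or None."""
        if self.shape != other.shape:
            return "shape"
        if not np.allclose(self.voxel_size, other.voxel_size, atol=1e-6):
            return "voxel_size"
        if not np.allclose(self.origin, other.origin, atol=1e-6):
            return "origin"
        return None


@dataclass
class Atom:
    """One atom record of a coordinate model."""

    element: str
    label: str  # pipeline label, e.g. "Mn1", "O5", "W3", "SG1"
    name: str  # PDB atom name, e.g. "MN1", "CA", "O"
    resname: str
    chain: str
    resseq: int
    xyz: np.ndarray
    occ: float = 1.0
    adp: float = 0.0
    altloc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(3).copy()
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1] for {self.label}")
        if self.adp < 0:
            raise ValueError(f"negative ADP {self.adp} for {self.label}")

    def copy(self) -> "Atom":
        return replace(self, xyz=self.xyz.copy())


class AtomicModel:
    """Ordered atom list with named selections.

    Built-in selections (computed lazily):

    * ``"metals"`` — atoms whose element is in :data:`METAL_ELEMENTS`;
    * ``"waters"`` — atoms of residues named ``HOH``;
    * ``"CA"`` — Cα atoms (atom name ``CA`` of a non-metal element);
    * ``"cluster_oxygens"`` — oxygens of non-water hetero residues
      (the bridging oxo ligands of a metal cluster).
    """

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms: list[Atom] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    def positions(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in atoms])

    def selection(self, name: str) -> list[int]:
        """Indices of the named selection (see class docstring)."""
        if name == "metals":
            return [i for i, a in enumerate(self.atoms) if a.element in METAL_ELEMENTS]
        if name == "waters":
            return [i for i, a in enumerate(self.atoms) if a.resname == "HOH"]
        if name == "CA":
            return [
                i
                for i, a in enumerate(self.atoms)
                if a.name == "CA" and a.element not in METAL_ELEMENTS
            ]
        if name == "cluster_oxygens":
            return [
                i
                for i, a in enumerate(self.atoms)
                if a.element == "O" and a.resname not in ("HOH",) and a.name != "O"
            ]
        raise KeyError(f"unknown selection {name!r}")

    def by_label(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(f"no atom labelled {label!r}")

    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def subset(self, indices: Sequence[int]) -> "AtomicModel":
        return AtomicModel(self.atoms[i].copy() for i in indices)

    def copy(self) -> "AtomicModel":
        return AtomicModel(a.copy() for a in self.atoms)


@dataclass
class FrameStack:
    """Dose-fractionated series of per-frame density maps.

    Fractionation is uniform: ``total_fluence`` (e⁻ Å⁻²) is delivered in
    ``len(frames)`` equal increments of ``fluence_per_frame``.
    """

    frames: list[DensityMap]
    fluence_per_frame: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameStack needs at least one frame")
        if self.fluence_per_frame <= 0:
            raise ValueError("fluence_per_frame must be positive")
        geom0 = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=2):
            bad = geom0.same_geometry(f)
            if bad is not None:
                raise ValueError(f"frame {i} differs from frame 1 in {bad}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_fluence(self) -> float:
        return self.fluence_per_frame * len(self.frames)
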