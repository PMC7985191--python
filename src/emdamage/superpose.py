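"""Least-squares rigid superposition (Kabsch) and RMSD of atom sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AtomicModel

__all__ = ["RigidTransform", "kabsch_fit", "rmsd", "pair_atoms", "match_labels"]


@dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(
            self.rotation @ self.rotation.T, np.eye(3), atol=1e-9
        ) or abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be orthonormal with det +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Proper rotation + translation minimizing RMSD of *moving* onto *fixed*.

    SVD-based with the usual determinant sign correction, so a reflection
    is never returned even for reflection-related point sets.  Requires at
    least 3 non-collinear point pairs.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point set length mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of centered moving set
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray, superpose_first: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets (Å).

    With ``superpose_first`` the optimal rigid superposition of *a* onto
    *b* is applied before measuring.
    """
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape != B.shape:
        raise ValueError(f"point set length mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 1:
        raise ValueError("need >= 1 point")
    if superpose_first:
        A = kabsch_fit(A, B).apply(A)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def pair_atoms(
    a: AtomicModel, b: AtomicModel, selection: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Match atoms of a named selection across two models.

    Atoms are keyed by ``(chain, resseq, insertion code, atom name)``;
    only the blank altloc or conformer "A" is considered, so alternative
    conformations never double-count.  Unmatched atoms are dropped.
    Returns ``(coords_a, coords_b, n_pairs)``.
    """

    def keyed(model: AtomicModel) -> dict:
        out = {}
        for i in model.selection(selection):
            at = model[i]
            if at.altloc not in ("", "A"):
                continue
            key = (at.chain, at.resseq, at.icode, at.name)
            out.setdefault(key, at.xyz)
        return out

    ka, kb = keyed(a), keyed(b)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValueError(f"no paired atoms for selection {selection!r}")
    pa = np.array([ka[k] for k in common])
    pb = np.array([kb[k] for k in common])
    return pa, pb, len(common)


def match_labels(fragment: AtomicModel, reference: AtomicModel) -> AtomicModel:
    """Transfer labels from *reference* onto *fragment* by geometry.

    Assumes the two sets live in the same coordinate frame (superpose
    first if not).  Within each element group, fragment atoms are assigned
    to reference atoms by minimum-total-distance matching (Hungarian
    algorithm), so e.g. four unlabelled Mn peaks acquire the reference's
    Mn1..Mn4 identities.  Returns a relabelled copy of *fragment* ordered
    like *reference*.
    """
    from scipy.optimize import linear_sum_assignment

    frag_by_el: dict[str, list[int]] = {}
    ref_by_el: dict[str, list[int]] = {}
    for i, at in enumerate(fragment):
        frag_by_el.setdefault(at.element, []).append(i)
    for i, at in enumerate(reference):
        ref_by_el.setdefault(at.element, []).append(i)
    if {e: len(v) for e, v in frag_by_el.items()} != {
        e: len(v) for e, v in ref_by_el.items()
    }:
        raise ValueError("fragment and reference element compositions differ")

    mapping: dict[int, int] = {}  # reference index -> fragment index
    for el, ref_idx in ref_by_el.items():
        frag_idx = frag_by_el[el]
        cost = np.linalg.norm(
            fragment.positions(frag_idx)[None, :, :]
            - reference.positions(ref_idx)[:, None, :],
            axis=-1,
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            mapping[ref_idx[r]] = frag_idx[c]
    out = []
    for i in range(len(reference)):
        at = fragment[mapping[i]].copy()
        at.label = reference[i].label
        at.name = reference[i].name
        out.append(at)
    return AtomicModel(out)
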