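"""Rigid-body superposition, RMSD and cutoff neighbor search.

These are the kernels every trajectory observable uses: least-squares
(Kabsch) superposition with the proper-rotation correction, plain unfitted
RMSD, applying a fit computed on one atom subset to a whole frame, and an
exact minimum-image pair search under orthorhombic periodic boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "PairList",
    "DegenerateGeometryError",
    "kabsch",
    "rmsd",
    "superpose_frame",
    "neighbor_pairs",
]


class DegenerateGeometryError(ValueError):
    """Input too degenerate for a unique rigid fit (too few / collinear points)."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R @ x + t."""

    rotation: np.ndarray  # 3×3, det = +1
    translation: np.ndarray  # 3-vector, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PairList:
    """Pairs (i into A, j into B) with minimum-image distance ≤ cutoff."""

    pairs: frozenset[tuple[int, int]]
    cutoff: float


def _check_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name}: expected M×3 array, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: non-finite coordinates")
    return x


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the minimizing :class:`RigidTransform` and the RMSD after
    applying it.  The reflection branch of the SVD solution is corrected
    by sign-flipping the smallest singular vector, so the returned rotation
    is always proper (chirality preserved).

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    collinear reference, for which the rotation is not unique.
    """
    mob = _check_points(mobile, "mobile")
    ref = _check_points(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError(f"shape mismatch: {mob.shape} vs {ref.shape}")
    if mob.shape[0] < 3:
        raise DegenerateGeometryError("kabsch requires at least 3 points")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - mc, ref - rc
    # collinearity check on the reference: second singular value ~ 0
    sv = np.linalg.svd(q, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = rc - rot @ mc
    transform = RigidTransform(rot, t)
    fitted = transform.apply(mob)
    return transform, rmsd(fitted, ref)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Unfitted root-mean-square deviation between two equal point sets (Å)."""
    a = _check_points(a, "a")
    b = _check_points(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_frame(frame: np.ndarray, align, reference: np.ndarray) -> np.ndarray:
    """Fit ``frame`` onto ``reference`` using only the ``align`` atom subset,
    then apply the transform to every atom of the frame.

    ``align`` is an AtomIndexSet (or index array) into both coordinate sets.
    """
    frame = _check_points(frame, "frame")
    reference = _check_points(reference, "reference")
    idx = align.as_array() if hasattr(align, "as_array") else np.asarray(align, dtype=int)
    if idx.size == 0:
        raise DegenerateGeometryError("empty alignment selection")
    transform, _ = kabsch(frame[idx], reference[idx])
    return transform.apply(frame)


def _wrap(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(x, box)


def neighbor_pairs(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
    box: tuple[float, float, float] | None = None,
) -> PairList:
    """Exact pair list: all (i, j) with distance(A_i, B_j) ≤ cutoff.

    With ``box`` given, distances use the orthorhombic minimum-image
    convention and the cutoff must not exceed half the shortest box length
    (beyond which minimum image is ambiguous).  Closed boundary: a pair at
    exactly the cutoff distance is included.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = _check_points(coords_a, "coords_a")
    b = _check_points(coords_b, "coords_b")
    if box is not None:
        boxv = np.asarray(box, dtype=float)
        if np.any(boxv <= 0):
            raise ValueError("box lengths must be positive")
        if cutoff > boxv.min() / 2:
            raise ValueError(
                f"cutoff {cutoff} Å exceeds half the shortest box length "
                f"({boxv.min() / 2} Å); minimum image invalid"
            )
        ta = cKDTree(_wrap(a, boxv), boxsize=boxv)
        tb = cKDTree(_wrap(b, boxv), boxsize=boxv)
    else:
        ta, tb = cKDTree(a), cKDTree(b)
    hits = ta.query_ball_tree(tb, r=cutoff)
    pairs = frozenset((i, j) for i, js in enumerate(hits) for j in js)
    return PairList(pairs, cutoff)
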