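"""Solvent-accessible surface area (Shrake–Rupley) and contact areas.

SASA is computed by placing a deterministic quasi-uniform point set (a
golden-spiral lattice, fixed orientation) on each atom's probe-inflated
sphere and counting the points that fall outside every neighbouring
atom's inflated sphere:

    SASA_i = (exposed points / total points) × 4π (r_i + probe)²

The contact area between two disjoint atom groups is half the surface
buried on bringing them together,

    A_contact = (SASA(A) + SASA(B) − SASA(A ∪ B)) / 2,

which may come out slightly negative for adjacent but non-touching groups
— a quadrature artefact of the SASA difference, reported as-is rather
than clipped.

No periodic images are used: groups are assumed compact (made whole), the
typical use of SASA on clustered molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomIndexSet, Structure

__all__ = [
    "RadiusTable",
    "SasaResult",
    "BONDI_RADII",
    "DEFAULT_RADIUS",
    "sphere_points",
    "sasa",
    "contact_area",
]

# Bondi van der Waals radii (Å), keyed by element symbol.  Elements not
# listed resolve to DEFAULT_RADIUS; synthetic bead structures declare
# their radii explicitly through a custom table instead.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "SE": 1.90,
}
DEFAULT_RADIUS = 1.5


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii by element (falling back to a default) or by
    atom name for bead models."""

    by_element: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    by_name: dict[str, float] = field(default_factory=dict)
    default: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        for table in (self.by_element, self.by_name):
            for key, r in table.items():
                if not (0.5 < r < 3.0):
                    raise ValueError(f"radius for {key!r} out of range (0.5, 3.0): {r}")
        if not (0.5 < self.default < 3.0):
            raise ValueError(f"default radius out of range: {self.default}")

    def radius(self, name: str, element: str) -> float:
        if name.upper() in self.by_name:
            return self.by_name[name.upper()]
        return self.by_element.get(element.upper(), self.default)

    def radii_for(self, structure: Structure, indices: np.ndarray) -> np.ndarray:
        return np.asarray(
            [self.radius(structure.atoms[i].name, structure.atoms[i].element)
             for i in indices],
            dtype=float,
        )


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total accessible area (Å²) for one atom subset."""

    per_atom: np.ndarray  # Å², aligned with the subset's index order
    total: float
    probe: float
    n_points: int


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    structure: Structure,
    coords: np.ndarray,
    subset: AtomIndexSet,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiusTable | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of ``subset`` treated as an isolated molecule.

    Only atoms inside the subset occlude each other; everything outside it
    is ignored (that is what makes the SASA-difference contact area work).
    """
    if len(subset) == 0:
        raise ValueError("sasa: empty subset")
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    radii = radii or RadiusTable()
    idx = subset.as_array()
    coords = np.asarray(coords, dtype=float)
    xyz = coords[idx]
    if not np.all(np.isfinite(xyz)):
        raise ValueError("sasa: non-finite coordinates in subset")
    r = radii.radii_for(structure, idx) + probe
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = r.max()
    per_atom = np.empty(len(idx), dtype=float)
    for k in range(len(idx)):
        # any neighbour whose inflated sphere can reach this atom's surface
        neigh = tree.query_ball_point(xyz[k], r[k] + max_r)
        neigh = [j for j in neigh if j != k]
        pts = xyz[k] + r[k] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > r[j] ** 2
            if not exposed.any():
                break
        frac = exposed.sum() / n_points
        per_atom[k] = frac * 4.0 * math.pi * r[k] ** 2
    return SasaResult(per_atom, float(per_atom.sum()), probe, n_points)


def contact_area(
    structure: Structure,
    coords: np.ndarray,
    group_a: AtomIndexSet,
    group_b: AtomIndexSet,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiusTable | None = None,
) -> float:
    """Contact area (Å²) between two disjoint groups:
    (SASA(A) + SASA(B) − SASA(A ∪ B)) / 2.

    The half keeps a single interface from being double-counted, so the
    value is the area of one face of the contact.
    """
    sa_idx, sb_idx = set(group_a.indices), set(group_b.indices)
    if sa_idx & sb_idx:
        raise ValueError("contact_area: groups overlap")
    union = AtomIndexSet(tuple(sorted(sa_idx | sb_idx)), label="A+B")
    kw = dict(probe=probe, n_points=n_points, radii=radii)
    a = sasa(structure, coords, group_a, **kw).total
    b = sasa(structure, coords, group_b, **kw).total
    ab = sasa(structure, coords, union, **kw).total
    return (a + b - ab) / 2.0
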