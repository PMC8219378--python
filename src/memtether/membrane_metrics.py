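"""Protein–membrane observables.

Implements the per-residue lipid-contact metric (how many lipid molecules
have any atom within a cutoff of any atom of a protein residue, averaged
over frames after a burn-in), the membrane contact-area time series, the
count of membrane-contacting residues per frame, lipid-type enrichment in
the contact shell, and the full residue × time contact map.

A lipid *molecule* is identified by ``(chain, residue_id, residue_name)``
— the PDB convention of one residue per lipid.  Contact distances use the
minimum-image convention whenever the frame has a box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import surface
from .geometry import neighbor_pairs
from .structio import AtomIndexSet, Structure, Trajectory

__all__ = [
    "ResidueContactProfile",
    "MetricSeries",
    "EnrichmentSeries",
    "residue_lipid_contacts",
    "membrane_contact_area_series",
    "contact_residue_count_series",
    "lipid_enrichment",
    "contact_map",
    "burn_in_slice",
]

ResidueKey = tuple[str, int]
LipidKey = tuple[str, int, str]


@dataclass(frozen=True)
class MetricSeries:
    """A (time, value) observable stream with a label and units."""

    times: np.ndarray
    values: np.ndarray
    label: str
    units: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, self.label or "value": self.values})


@dataclass(frozen=True)
class ResidueContactProfile:
    """Mean lipid-molecule contact count per protein residue."""

    counts: dict[ResidueKey, float]
    burn_in_fraction: float
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain": c, "resid": r, "mean_count": v}
            for (c, r), v in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["chain", "resid", "mean_count"])


@dataclass(frozen=True)
class EnrichmentSeries:
    """Per-frame fraction of contacting lipids of one type vs its leaflet
    baseline.  Frames with zero contacting lipids carry NaN (undefined),
    not zero."""

    times: np.ndarray
    fraction_in_contact: np.ndarray  # NaN where no lipid in contact
    baseline_fraction: float
    label: str

    @property
    def enrichment(self) -> np.ndarray:
        if self.baseline_fraction <= 0:
            return np.full_like(self.fraction_in_contact, np.nan)
        return self.fraction_in_contact / self.baseline_fraction

    def mean_enrichment(self) -> float:
        """Mean over frames where the fraction is defined."""
        e = self.enrichment
        valid = ~np.isnan(e)
        if not valid.any():
            return float("nan")
        return float(e[valid].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "fraction_in_contact": self.fraction_in_contact,
                "enrichment": self.enrichment,
            }
        )


def burn_in_slice(n_frames: int, burn_in_fraction: float) -> slice:
    """Frames retained after discarding the first ⌈f·n⌉ frames."""
    if not (0 <= burn_in_fraction < 1):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    discard = math.ceil(burn_in_fraction * n_frames)
    if discard >= n_frames:
        raise ValueError(
            f"burn-in discards all {n_frames} frames (fraction {burn_in_fraction})"
        )
    return slice(discard, n_frames)


def _residue_keys(topology: Structure, sel: AtomIndexSet) -> tuple[list[ResidueKey], np.ndarray]:
    """Residue keys in selection order and per-atom residue index."""
    keys: list[ResidueKey] = []
    seen: dict[ResidueKey, int] = {}
    atom_res = np.empty(len(sel), dtype=int)
    for k, i in enumerate(sel.indices):
        a = topology.atoms[i]
        key = (a.chain_id, a.residue_id)
        if key not in seen:
            seen[key] = len(keys)
            keys.append(key)
        atom_res[k] = seen[key]
    return keys, atom_res


def _lipid_keys(topology: Structure, sel: AtomIndexSet) -> tuple[list[LipidKey], np.ndarray]:
    keys: list[LipidKey] = []
    seen: dict[LipidKey, int] = {}
    atom_mol = np.empty(len(sel), dtype=int)
    for k, i in enumerate(sel.indices):
        a = topology.atoms[i]
        key = (a.chain_id, a.residue_id, a.residue_name)
        if key not in seen:
            seen[key] = len(keys)
            keys.append(key)
        atom_mol[k] = seen[key]
    return keys, atom_mol


def _frame_contacts(
    coords: np.ndarray,
    box,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    atom_res: np.ndarray,
    atom_mol: np.ndarray,
    cutoff: float,
) -> set[tuple[int, int]]:
    """(residue index, lipid-molecule index) pairs in contact in one frame."""
    pa = coords[protein_sel.as_array()]
    la = coords[lipid_sel.as_array()]
    pl = neighbor_pairs(pa, la, cutoff, box=box)
    return {(int(atom_res[i]), int(atom_mol[j])) for i, j in pl.pairs}


def contact_map(
    traj: Trajectory,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    cutoff: float = 5.0,
) -> pd.DataFrame:
    """Residue × time table of lipid-molecule contact counts.

    Rows are indexed by (chain, resid); columns are frame times (ns).
    Summing rows over post-burn-in columns and dividing by the retained
    frame count reproduces :func:`residue_lipid_contacts` exactly.
    """
    res_keys, atom_res = _residue_keys(traj.topology, protein_sel)
    _mol_keys, atom_mol = _lipid_keys(traj.topology, lipid_sel)
    counts = np.zeros((len(res_keys), traj.n_frames), dtype=int)
    for f in range(traj.n_frames):
        contacts = _frame_contacts(
            traj.coords(f), traj.box(f), protein_sel, lipid_sel,
            atom_res, atom_mol, cutoff,
        )
        for ri, _mi in contacts:
            counts[ri, f] += 1
    index = pd.MultiIndex.from_tuples(res_keys, names=["chain", "resid"])
    return pd.DataFrame(counts, index=index, columns=traj.times)


def residue_lipid_contacts(
    traj: Trajectory,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    cutoff: float = 5.0,
    burn_in_fraction: float = 0.3,
) -> ResidueContactProfile:
    """Per-residue mean count of lipid molecules within ``cutoff`` Å.

    A lipid molecule counts once for a residue in a frame if *any* of its
    atoms is within the cutoff of *any* atom of the residue; the profile
    is the mean over frames retained after burn-in.
    """
    keep = burn_in_slice(traj.n_frames, burn_in_fraction)
    cmap = contact_map(traj, protein_sel, lipid_sel, cutoff=cutoff)
    retained = cmap.iloc[:, keep]
    means = retained.mean(axis=1)
    counts = {key: float(means.loc[key]) for key in means.index}
    return ResidueContactProfile(counts, burn_in_fraction, cutoff)


def membrane_contact_area_series(
    traj: Trajectory,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    probe: float = 1.4,
    n_points: int = 960,
    radii: surface.RadiusTable | None = None,
) -> MetricSeries:
    """Per-frame SASA-difference contact area between protein and membrane.

    Negative values (adjacent but non-touching groups) are retained, not
    clipped.
    """
    if set(protein_sel.indices) & set(lipid_sel.indices):
        raise ValueError("protein and lipid selections overlap")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = surface.contact_area(
            traj.topology, traj.coords(f), protein_sel, lipid_sel,
            probe=probe, n_points=n_points, radii=radii,
        )
    return MetricSeries(traj.times, values, label="membrane_contact_area", units="A^2")


def contact_residue_count_series(
    traj: Trajectory,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    cutoff: float = 5.0,
) -> MetricSeries:
    """Per-frame number of protein residues with ≥1 lipid molecule in contact."""
    res_keys, atom_res = _residue_keys(traj.topology, protein_sel)
    _mk, atom_mol = _lipid_keys(traj.topology, lipid_sel)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        contacts = _frame_contacts(
            traj.coords(f), traj.box(f), protein_sel, lipid_sel,
            atom_res, atom_mol, cutoff,
        )
        values[f] = len({ri for ri, _ in contacts})
    return MetricSeries(traj.times, values, label="contact_residue_count", units="residues")


def lipid_enrichment(
    traj: Trajectory,
    protein_sel: AtomIndexSet,
    lipid_sel: AtomIndexSet,
    lipid_type: str | tuple[str, ...],
    cutoff: float = 5.0,
) -> EnrichmentSeries:
    """Enrichment of one lipid type (or a set of types) among the lipids
    in contact with the protein.

    baseline = fraction of the type among all lipid molecules in the
    selection; per frame, fraction = fraction of the type among contacting
    molecules; enrichment = fraction / baseline.  Frames without any
    contacting lipid are recorded as NaN (undefined), never as zero.
    """
    types = (lipid_type,) if isinstance(lipid_type, str) else tuple(lipid_type)
    types = tuple(t.upper() for t in types)
    mol_keys, atom_mol = _lipid_keys(traj.topology, lipid_sel)
    is_type = np.asarray([key[2].upper() in types for key in mol_keys])
    if not is_type.any():
        raise ValueError(f"lipid type(s) {types} not present in lipid selection")
    baseline = float(is_type.mean())
    _rk, atom_res = _residue_keys(traj.topology, protein_sel)
    frac = np.full(traj.n_frames, np.nan)
    for f in range(traj.n_frames):
        contacts = _frame_contacts(
            traj.coords(f), traj.box(f), protein_sel, lipid_sel,
            atom_res, atom_mol, cutoff,
        )
        mols = {mi for _, mi in contacts}
        if mols:
            frac[f] = sum(1 for m in mols if is_type[m]) / len(mols)
    return EnrichmentSeries(traj.times, frac, baseline, label="+".join(types))
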