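"""Coarse-grained Monte Carlo generator of membrane-tethered domain
trajectories, plus membrane-composition and ion planners.

The generator stands in for microsecond all-atom MD of a GTPase tethered
to the inner membrane leaflet.  The model is deliberately minimal so that
its stationary distribution can be cross-checked by direct sampling:

* the lower leaflet is a square lattice of immobile one-bead lipids at
  z = 0, with types (POPC 0 e, POPS −1 e, PIP2 −4 e) assigned by the
  composition planner and shuffled by the seeded generator;
* the protein is a rigid spherical shell of beads with an optional
  positively charged polar cap (the membrane-binding patch), tethered to
  a fixed membrane anchor bead through a freely jointed tail of harmonic
  bonds — short tail + charged patch emulates a RhoD-like GTPase, long
  tail + neutral surface an RND1-like one;
* the energy is screened Coulomb (Debye–Hückel) between all charged bead
  pairs, a purely repulsive soft-core between protein beads and lipid
  beads and the half-space z < 0, and harmonic bonds along the tether.

Energies are in units of kT at 300 K: the Coulomb prefactor is the
Bjerrum length 560.74/ε_r Å (7.0 Å in water), and the default Debye
length 7.9 Å corresponds to 150 mM monovalent salt.  Sampling is
Metropolis Monte Carlo — rigid-body domain translations and rotations
plus per-bead tail displacement and crankshaft moves — so the stationary
distribution is exactly Boltzmann and can be validated against a naive
rejection sampler.  Time labels on saved frames are nominal (1 ns per
sweep).  All randomness flows through one seeded generator in documented
order: lipid-type shuffle first, then per-sweep move proposals and
acceptance draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structio import Atom, Structure, Trajectory

__all__ = [
    "SynthConfig",
    "EnergyBreakdown",
    "IonPlan",
    "System",
    "MoveRecord",
    "RunManifest",
    "LIPID_CHARGES",
    "plan_membrane",
    "audit_membrane",
    "plan_ions",
    "build_system",
    "energy",
    "simulate",
    "rhod_like_config",
    "rnd1_like_config",
]

LIPID_CHARGES = {"POPC": 0.0, "POPS": -1.0, "PIP2": -4.0}
LIPID_ORDER = ("POPC", "POPS", "PIP2")  # fixed tie-break precedence
WATER_MOLARITY = 55.345  # mol/L, pure water
BJERRUM_VACUUM = 560.74  # Å·kT·e⁻² at 300 K; divide by dielectric


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic membrane-tether system.

    Identical configs (same seed) produce bit-identical trajectories.
    """

    n_lipids_lower: int = 225
    lipid_fractions: dict = field(
        default_factory=lambda: {"POPC": 0.70, "POPS": 0.25, "PIP2": 0.05}
    )
    lipid_spacing: float = 8.0        # Å; ~64 Å² per lipid
    domain_radius: float = 12.0       # Å, rigid shell radius
    n_domain_beads: int = 48
    patch_charge_per_bead: float = 1.0  # e
    n_patch_beads: int = 12
    tail_beads: int = 4
    bond_length: float = 5.0          # Å, harmonic rest length
    debye_length: float = 7.9         # Å; 150 mM monovalent salt
    dielectric: float = 80.0
    temperature_kT: float = 1.0       # energies are in kT units
    n_sweeps: int = 2000
    save_stride: int = 40             # sweeps between saved frames
    seed: int = 0
    # soft-core / bead geometry
    bead_radius: float = 2.5          # Å, domain and tail beads
    lipid_radius: float = 2.9         # Å
    ev_strength: float = 10.0         # kT at full overlap
    bond_k: float = 2.0               # kT/Å²
    # finite-size regularization: screened Coulomb is evaluated at
    # max(r, elec_min_distance) so opposite charges on finite beads
    # plateau at their contact value instead of diverging
    elec_min_distance: float = 5.4    # Å = bead_radius + lipid_radius
    # move sizes
    translation_step: float = 1.0     # Å (max)
    rotation_step_deg: float = 5.0    # degrees (max); 0 disables rotations
    tail_step: float = 1.0            # Å (max)
    crank_step_deg: float = 60.0      # degrees (max)
    box_height: float = 150.0         # Å

    def __post_init__(self) -> None:
        total = sum(self.lipid_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"lipid fractions sum to {total}, expected 1")
        if self.tail_beads < 0:
            raise ValueError("tail_beads must be ≥ 0")
        if self.n_lipids_lower <= 0:
            raise ValueError("n_lipids_lower must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    electrostatic: float
    excluded_volume: float
    bonds: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.excluded_volume + self.bonds


@dataclass(frozen=True)
class IonPlan:
    n_na: int
    n_cl: int
    n_neutralizing: int  # counter-ions added beyond the salt pairs


@dataclass(frozen=True)
class MoveRecord:
    """One attempted MC move, for detailed-balance auditing."""

    kind: str
    delta_e: float
    accept_prob: float
    accepted: bool
    coords_before: np.ndarray
    coords_after: np.ndarray


@dataclass
class RunManifest:
    seed: int
    acceptance_rates: dict[str, float]
    energy_trace: list[float]
    n_sweeps: int
    save_stride: int


def plan_membrane(n_lipids: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer lipid counts by largest-remainder rounding.

    Counts sum exactly to ``n_lipids``; remainder ties are broken by the
    fixed precedence POPC > POPS > PIP2 (then alphabetical).
    """
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    for name, f in fractions.items():
        if f < 0:
            raise ValueError(f"negative fraction for {name}: {f}")
    total = sum(fractions.values())
    if total <= 0:
        raise ValueError("fractions sum to zero")
    names = sorted(
        fractions,
        key=lambda n: (LIPID_ORDER.index(n) if n in LIPID_ORDER else len(LIPID_ORDER), n),
    )
    exact = {n: n_lipids * fractions[n] / total for n in names}
    counts = {n: math.floor(exact[n]) for n in names}
    remaining = n_lipids - sum(counts.values())
    by_remainder = sorted(names, key=lambda n: -(exact[n] - counts[n]))
    for n in by_remainder[:remaining]:
        counts[n] += 1
    return counts


def audit_membrane(
    structure: Structure,
    lipid_names: tuple[str, ...] = tuple(LIPID_CHARGES),
) -> dict[str, dict[str, float]]:
    """Molecule counts and fractions per lipid type in a structure.

    Lipids are identified by residue name; one residue per lipid molecule.
    """
    mols: set[tuple[str, int, str]] = set()
    for a in structure.atoms:
        if a.residue_name.upper() in lipid_names:
            mols.add((a.chain_id, a.residue_id, a.residue_name.upper()))
    if not mols:
        raise ValueError("structure contains no lipid residues")
    counts: dict[str, int] = {}
    for _, _, name in mols:
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    return {
        name: {"count": c, "fraction": c / total} for name, c in sorted(counts.items())
    }


def plan_ions(
    n_waters: int, concentration: float, solute_charge: int = 0
) -> IonPlan:
    """Na+/Cl− counts for a target molarity plus charge neutralization.

    Salt pairs = round(concentration × n_waters / 55.345) — the mole
    ratio of ions to water at the given molarity.  The net solute charge
    is neutralized by extra counter-ions (Na+ for a negative solute, Cl−
    for a positive one).
    """
    if concentration < 0:
        raise ValueError("concentration must be ≥ 0")
    if n_waters < 0:
        raise ValueError("n_waters must be ≥ 0")
    if solute_charge != int(solute_charge):
        raise ValueError("solute_charge must be an integer")
    pairs = round(concentration * n_waters / WATER_MOLARITY)
    q = int(solute_charge)
    n_na = pairs + max(-q, 0)
    n_cl = pairs + max(q, 0)
    if n_na < 0 or n_cl < 0:
        raise ValueError("neutralization would require a negative ion count")
    return IonPlan(n_na, n_cl, abs(q))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class System:
    """A built synthetic system: topology, state arrays and energy model.

    Atom order: lipids, anchor, tail beads, domain beads.  The domain is
    rigid: its bead coordinates are ``center + offsets`` with the offsets
    rotated as a block by rotation moves.
    """

    config: SynthConfig
    structure: Structure
    charges: np.ndarray         # per atom, e
    lipid_slice: slice
    anchor_index: int
    tail_slice: slice
    domain_slice: slice
    tether_bead: int            # absolute atom index of the tethered domain bead
    coords: np.ndarray          # current N×3, Å
    domain_center: np.ndarray
    domain_offsets: np.ndarray  # n_domain_beads × 3, rotated in place
    box: np.ndarray             # 3 lengths, Å

    # -- derived index caches -------------------------------------------------
    def __post_init__(self) -> None:
        self._charged = np.flatnonzero(self.charges != 0.0)
        lip = np.arange(self.lipid_slice.start, self.lipid_slice.stop)
        self._charged_lipids = lip[self.charges[lip] != 0.0]
        dom = np.arange(self.domain_slice.start, self.domain_slice.stop)
        self._charged_domain = dom[self.charges[dom] != 0.0]
        self._protein = np.concatenate(
            [np.arange(self.tail_slice.start, self.tail_slice.stop), dom]
        )
        self._lipid_xyz = self.coords[self.lipid_slice].copy()

    # -- chain topology -------------------------------------------------------
    def chain_indices(self) -> list[int]:
        """Bonded chain: anchor, tail beads, tethered domain bead."""
        tail = list(range(self.tail_slice.start, self.tail_slice.stop))
        return [self.anchor_index] + tail + [self.tether_bead]

    # -- energy terms ---------------------------------------------------------
    def _min_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.box * np.round(d / self.box)

    def _screened_coulomb(self, xi: np.ndarray, qi: np.ndarray,
                          xj: np.ndarray, qj: np.ndarray) -> float:
        """Sum over all i, j pairs (cross terms only)."""
        if len(xi) == 0 or len(xj) == 0:
            return 0.0
        d = self._min_image(xi[:, None, :] - xj[None, :, :])
        r = np.sqrt(np.sum(d * d, axis=-1))
        r = np.maximum(r, self.config.elec_min_distance)
        lb = BJERRUM_VACUUM / self.config.dielectric
        lam = self.config.debye_length
        screen = np.exp(-r / lam) if np.isfinite(lam) else 1.0
        return float(np.sum(lb * np.outer(qi, qj) * screen / r))

    def _elec_within(self, coords: np.ndarray) -> float:
        """All charged pairs (i < j), minimum image."""
        idx = self._charged
        if len(idx) < 2:
            return 0.0
        x = coords[idx]
        q = self.charges[idx]
        d = self._min_image(x[:, None, :] - x[None, :, :])
        r = np.sqrt(np.sum(d * d, axis=-1))
        iu = np.triu_indices(len(idx), k=1)
        rij = np.maximum(r[iu], self.config.elec_min_distance)
        lb = BJERRUM_VACUUM / self.config.dielectric
        lam = self.config.debye_length
        screen = np.exp(-rij / lam) if np.isfinite(lam) else 1.0
        return float(np.sum(lb * np.outer(q, q)[iu] * screen / rij))

    def _ev_beads(self, bead_xyz: np.ndarray) -> float:
        """Soft-core repulsion of protein beads vs lipids and the z<0 wall."""
        cfg = self.config
        e = 0.0
        # wall
        z = bead_xyz[:, 2]
        below = z < 0
        if below.any():
            e += cfg.ev_strength * float(np.sum((z[below] / cfg.bead_radius) ** 2))
        sigma = cfg.bead_radius + cfg.lipid_radius
        # lipids sit at z = 0: only beads within sigma in z can overlap
        near = np.abs(z) < sigma
        if near.any():
            d = self._min_image(bead_xyz[near][:, None, :] - self._lipid_xyz[None, :, :])
            r = np.sqrt(np.sum(d * d, axis=-1))
            overlap = r < sigma
            if overlap.any():
                e += cfg.ev_strength * float(np.sum((1.0 - r[overlap] / sigma) ** 2))
        return e

    def _bond_energy_chain(self, coords: np.ndarray, which: list[int] | None = None) -> float:
        cfg = self.config
        chain = self.chain_indices()
        pairs = list(zip(chain[:-1], chain[1:]))
        if which is not None:
            wanted = set(which)
            pairs = [p for p in pairs if p[0] in wanted or p[1] in wanted]
        e = 0.0
        for i, j in pairs:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            e += 0.5 * cfg.bond_k * (r - cfg.bond_length) ** 2
        return e

    def energy(self, coords: np.ndarray | None = None) -> EnergyBreakdown:
        """Full energy breakdown of a frame (kT units)."""
        coords = self.coords if coords is None else np.asarray(coords, dtype=float)
        elec = self._elec_within(coords)
        ev = self._ev_beads(coords[self._protein])
        bonds = self._bond_energy_chain(coords)
        return EnergyBreakdown(elec, ev, bonds)


def build_system(config: SynthConfig, rng: np.random.Generator | None = None) -> System:
    """Construct the lattice membrane, tethered rigid domain and tail.

    The lipid-type shuffle is the first consumer of the seeded generator,
    so two builds with equal seeds are bit-identical.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    counts = plan_membrane(cfg.n_lipids_lower, cfg.lipid_fractions)
    n_side = math.ceil(math.sqrt(cfg.n_lipids_lower))
    box = np.array(
        [n_side * cfg.lipid_spacing, n_side * cfg.lipid_spacing, cfg.box_height]
    )
    types: list[str] = []
    for name in sorted(counts, key=lambda n: (LIPID_ORDER.index(n)
                                              if n in LIPID_ORDER else 99, n)):
        types.extend([name] * counts[name])
    types = [types[i] for i in rng.permutation(len(types))]

    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    charges: list[float] = []
    serial = 1
    k = 0
    for i in range(n_side):
        for j in range(n_side):
            if k >= cfg.n_lipids_lower:
                break
            name = types[k]
            pos = ((i + 0.5) * cfg.lipid_spacing, (j + 0.5) * cfg.lipid_spacing, 0.0)
            atoms.append(Atom(serial, "P", "P", name, k + 1, "L", pos))
            coords.append(pos)
            charges.append(LIPID_CHARGES[name])
            serial += 1
            k += 1
    n_lip = k
    lipid_slice = slice(0, n_lip)

    cx, cy = box[0] / 2.0 + cfg.lipid_spacing / 2.0, box[1] / 2.0 + cfg.lipid_spacing / 2.0

    # fixed membrane anchor (the lipidated/amphipathic tail anchor)
    anchor_index = len(atoms)
    anchor_pos = (cx, cy, 0.0)
    atoms.append(Atom(serial, "CA", "C", "ANC", 1, "A", anchor_pos))
    coords.append(anchor_pos)
    charges.append(0.0)
    serial += 1

    # rigid domain: shell beads; patch = cap of beads nearest the -z pole
    unit = _fibonacci_sphere(cfg.n_domain_beads)
    offsets = unit * cfg.domain_radius
    order_by_z = np.argsort(offsets[:, 2])
    patch = set(order_by_z[: cfg.n_patch_beads].tolist())
    tether_local = int(order_by_z[0])  # bottom bead carries the tether
    center0 = np.array([cx, cy, cfg.domain_radius + cfg.bond_length])
    if center0[2] - cfg.domain_radius < 0:
        raise ValueError("domain overlaps the membrane plane at start")

    # tail: freely jointed chain between the anchor and the tethered bead,
    # laid out as a planar zig-zag with every bond at its rest length
    tether_pos0 = center0 + offsets[tether_local]
    tail_slice = slice(len(atoms), len(atoms) + cfg.tail_beads)
    if cfg.tail_beads > 0:
        a0 = np.asarray(anchor_pos)
        gap = tether_pos0 - a0
        nb = cfg.tail_beads + 1
        glen = float(np.linalg.norm(gap))
        axis = gap / glen if glen > 0 else np.array([0.0, 0.0, 1.0])
        step = glen / nb
        lat = math.sqrt(max(cfg.bond_length**2 - step**2, 0.0))
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        # zig-zag pattern 0, h, 0, h … keeps almost every bond at its rest
        # length; any residual strain relaxes within the first few sweeps
        for t in range(cfg.tail_beads):
            frac = (t + 1) / nb
            amp = lat if t % 2 == 0 else 0.0
            pos = a0 + axis * (glen * frac) + perp * amp
            atoms.append(Atom(serial, "CA", "C", "TAI", t + 1, "T", tuple(pos)))
            coords.append(tuple(pos))
            charges.append(0.0)
            serial += 1

    domain_slice = slice(len(atoms), len(atoms) + cfg.n_domain_beads)
    for b in range(cfg.n_domain_beads):
        pos = center0 + offsets[b]
        q = cfg.patch_charge_per_bead if b in patch else 0.0
        atoms.append(Atom(serial, "CA", "C", "DOM", b + 1, "P", tuple(pos)))
        coords.append(tuple(pos))
        charges.append(q)
        serial += 1

    structure = Structure(atoms, box=tuple(box))
    return System(
        config=cfg,
        structure=structure,
        charges=np.asarray(charges),
        lipid_slice=lipid_slice,
        anchor_index=anchor_index,
        tail_slice=tail_slice,
        domain_slice=domain_slice,
        tether_bead=domain_slice.start + tether_local,
        coords=np.asarray(coords, dtype=float),
        domain_center=center0.copy(),
        domain_offsets=offsets.copy(),
        box=box,
    )


def energy(system: System, coords: np.ndarray | None = None) -> EnergyBreakdown:
    """Module-level alias for :meth:`System.energy`."""
    return system.energy(coords)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


class _MC:
    """Metropolis sampler over the tethered-domain degrees of freedom."""

    def __init__(self, system: System, rng: np.random.Generator,
                 log_moves: bool = False):
        self.s = system
        self.rng = rng
        self.cfg = system.config
        self.log: list[MoveRecord] = []
        self.log_moves = log_moves
        self.attempts: dict[str, int] = {}
        self.accepts: dict[str, int] = {}

    # local energy of the subset of terms a move can change
    def _local_domain(self, coords: np.ndarray) -> float:
        s = self.s
        dom = np.arange(s.domain_slice.start, s.domain_slice.stop)
        e = s._screened_coulomb(
            coords[s._charged_domain], s.charges[s._charged_domain],
            coords[s._charged_lipids], s.charges[s._charged_lipids],
        )
        e += s._ev_beads(coords[dom])
        e += s._bond_energy_chain(coords, which=[s.tether_bead])
        return e

    def _local_tail_bead(self, coords: np.ndarray, idx: int) -> float:
        s = self.s
        e = s._ev_beads(coords[idx : idx + 1])
        e += s._bond_energy_chain(coords, which=[idx])
        return e

    def _metropolis(self, kind: str, delta_e: float,
                    before: np.ndarray, after: np.ndarray) -> bool:
        kT = self.cfg.temperature_kT
        if kT <= 0:
            prob = 1.0 if delta_e <= 0 else 0.0
            accepted = delta_e <= 0
            self.rng.uniform()  # keep the draw order fixed
        else:
            prob = min(1.0, math.exp(-delta_e / kT)) if delta_e > 0 else 1.0
            accepted = self.rng.uniform() < prob
        self.attempts[kind] = self.attempts.get(kind, 0) + 1
        if accepted:
            self.accepts[kind] = self.accepts.get(kind, 0) + 1
        if self.log_moves:
            self.log.append(
                MoveRecord(kind, delta_e, prob, accepted, before.copy(), after.copy())
            )
        return accepted

    def sweep(self) -> None:
        s, cfg, rng = self.s, self.cfg, self.rng
        dom = np.arange(s.domain_slice.start, s.domain_slice.stop)

        # rigid translation
        delta = rng.uniform(-cfg.translation_step, cfg.translation_step, 3)
        trial = s.coords.copy()
        trial[dom] += delta
        de = self._local_domain(trial) - self._local_domain(s.coords)
        if self._metropolis("translate", de, s.coords, trial):
            s.coords = trial
            s.domain_center = s.domain_center + delta

        # rigid rotation about the domain center
        if cfg.rotation_step_deg > 0:
            axis = rng.normal(size=3)
            while np.linalg.norm(axis) < 1e-12:
                axis = rng.normal(size=3)
            angle = math.radians(rng.uniform(-cfg.rotation_step_deg, cfg.rotation_step_deg))
            rot = _rotation_matrix(axis, angle)
            new_offsets = s.domain_offsets @ rot.T
            trial = s.coords.copy()
            trial[dom] = s.domain_center + new_offsets
            de = self._local_domain(trial) - self._local_domain(s.coords)
            if self._metropolis("rotate", de, s.coords, trial):
                s.coords = trial
                s.domain_offsets = new_offsets

        chain = s.chain_indices()
        # tail displacement moves
        for idx in range(s.tail_slice.start, s.tail_slice.stop):
            delta = rng.uniform(-cfg.tail_step, cfg.tail_step, 3)
            trial = s.coords.copy()
            trial[idx] += delta
            de = self._local_tail_bead(trial, idx) - self._local_tail_bead(s.coords, idx)
            if self._metropolis("tail_move", de, s.coords, trial):
                s.coords = trial

        # tail crankshaft moves: rotate a bead about its neighbour axis
        for pos, idx in enumerate(chain[1:-1], start=1):
            prev_i, next_i = chain[pos - 1], chain[pos + 1]
            axis = s.coords[next_i] - s.coords[prev_i]
            angle = math.radians(rng.uniform(-cfg.crank_step_deg, cfg.crank_step_deg))
            if np.linalg.norm(axis) < 1e-9:
                continue  # degenerate axis; skip (no acceptance draw)
            rot = _rotation_matrix(axis, angle)
            trial = s.coords.copy()
            trial[idx] = s.coords[prev_i] + rot @ (s.coords[idx] - s.coords[prev_i])
            de = self._local_tail_bead(trial, idx) - self._local_tail_bead(s.coords, idx)
            if self._metropolis("crankshaft", de, s.coords, trial):
                s.coords = trial


def simulate(
    config: SynthConfig,
    return_details: bool = False,
    log_moves: bool = False,
):
    """Run Metropolis MC and return the saved-frame :class:`Trajectory`.

    Frames (including the initial configuration at t = 0) are saved every
    ``save_stride`` sweeps with nominal times of 1 ns per sweep, over the
    topology produced by :func:`build_system`, so every analysis module
    runs on the output unchanged.  With ``return_details=True`` a
    ``(trajectory, system, manifest)`` triple is returned; ``log_moves``
    additionally records every attempted move in ``manifest`` space via
    the returned sampler log (for detailed-balance audits).
    """
    if config.n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    if config.save_stride <= 0:
        raise ValueError("save_stride must be positive")
    rng = np.random.default_rng(config.seed)
    system = build_system(config, rng)
    mc = _MC(system, rng, log_moves=log_moves)

    frames = [(0.0, system.coords.copy(), tuple(system.box))]
    e_trace = [system.energy().total]
    for sweep in range(1, config.n_sweeps + 1):
        mc.sweep()
        if sweep % config.save_stride == 0:
            frames.append((float(sweep), system.coords.copy(), tuple(system.box)))
            e_trace.append(system.energy().total)
    traj = Trajectory(system.structure, frames)
    if not return_details:
        return traj
    rates = {
        kind: mc.accepts.get(kind, 0) / n for kind, n in mc.attempts.items()
    }
    manifest = RunManifest(
        seed=config.seed,
        acceptance_rates=rates,
        energy_trace=e_trace,
        n_sweeps=config.n_sweeps,
        save_stride=config.save_stride,
    )
    manifest.move_log = mc.log  # type: ignore[attr-defined]
    return traj, system, manifest


def rhod_like_config(seed: int = 0, **overrides) -> SynthConfig:
    """Charged-patch, short-tail study condition (RhoD-like)."""
    cfg = SynthConfig(
        patch_charge_per_bead=1.0, n_patch_beads=12, tail_beads=4, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg


def rnd1_like_config(seed: int = 0, **overrides) -> SynthConfig:
    """Neutral-surface, long-tail study condition (RND1-like)."""
    cfg = SynthConfig(
        patch_charge_per_bead=0.0, n_patch_beads=12, tail_beads=14, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg
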