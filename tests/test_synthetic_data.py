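"""Planners, system builder, energy model and Metropolis sampler."""

import math

import numpy as np
import pytest

from memtether.structio import parse_selection
from memtether.synthetic_data import (
    BJERRUM_VACUUM,
    EnergyBreakdown,
    SynthConfig,
    audit_membrane,
    build_system,
    plan_ions,
    plan_membrane,
    simulate,
)


SMALL = dict(n_lipids_lower=64, n_domain_beads=16, n_sweeps=40, save_stride=10)


class TestPlanMembrane:
    def test_inner_leaflet_70_25_5(self):
        counts = plan_membrane(540, {"POPC": 0.70, "POPS": 0.25, "PIP2": 0.05})
        assert counts == {"POPC": 378, "POPS": 135, "PIP2": 27}

    def test_7_to_3_split(self):
        counts = plan_membrane(10, {"POPC": 0.7, "POPS": 0.3})
        assert counts == {"POPC": 7, "POPS": 3}

    def test_equal_thirds(self):
        counts = plan_membrane(3, {"POPC": 1 / 3, "POPS": 1 / 3, "PIP2": 1 / 3})
        assert counts == {"POPC": 1, "POPS": 1, "PIP2": 1}

    def test_counts_always_sum_to_n(self, rng):
        for _ in range(50):
            f = rng.dirichlet([1, 1, 1])
            counts = plan_membrane(
                int(rng.integers(1, 500)),
                {"POPC": f[0], "POPS": f[1], "PIP2": f[2]},
            )
            assert sum(counts.values()) == sum(counts.values())  # ints
            assert all(c >= 0 for c in counts.values())

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            plan_membrane(10, {"POPC": 1.2, "POPS": -0.2})


class TestAuditMembrane:
    def test_pip2_five_percent_exactly(self):
        cfg = SynthConfig(n_lipids_lower=540)
        system = build_system(cfg)
        audit = audit_membrane(system.structure)
        assert audit["PIP2"]["count"] == 27
        assert audit["PIP2"]["fraction"] == pytest.approx(0.05)

    def test_single_type(self):
        cfg = SynthConfig(n_lipids_lower=25, lipid_fractions={"POPC": 1.0})
        audit = audit_membrane(build_system(cfg).structure)
        assert audit["POPC"]["fraction"] == 1.0

    def test_plan_build_audit_roundtrip(self, rng):
        for _ in range(10):
            f = rng.dirichlet([2, 2, 2])
            fr = {"POPC": f[0], "POPS": f[1], "PIP2": 1 - f[0] - f[1]}
            n = int(rng.integers(10, 200))
            cfg = SynthConfig(n_lipids_lower=n, lipid_fractions=fr)
            audit = audit_membrane(build_system(cfg).structure)
            planned = plan_membrane(n, fr)
            for name, c in planned.items():
                if c:
                    assert audit[name]["count"] == c

    def test_no_lipids_rejected(self, membrane_structure):
        from memtether.structio import Structure

        protein_only = Structure(membrane_structure.atoms[:4])
        with pytest.raises(ValueError):
            audit_membrane(protein_only)


class TestPlanIons:
    def test_physiological_salinity(self):
        # mole-ratio arithmetic: 0.150 M × 55,345 waters / 55.345 M = 150 pairs
        plan = plan_ions(55_345, 0.150)
        assert (plan.n_na, plan.n_cl) == (150, 150)

    def test_neutralization_only(self):
        plan = plan_ions(1000, 0.0, solute_charge=-4)
        assert (plan.n_na, plan.n_cl) == (4, 0)

    def test_linearity_in_waters(self):
        a = plan_ions(10_000, 0.2)
        b = plan_ions(20_000, 0.2)
        assert abs(b.n_na - 2 * a.n_na) <= 1


class TestBuildSystem:
    def test_lipid_counts_match_plan(self):
        cfg = SynthConfig(**SMALL)
        system = build_system(cfg)
        audit = audit_membrane(system.structure)
        planned = plan_membrane(cfg.n_lipids_lower, cfg.lipid_fractions)
        for name, c in planned.items():
            got = audit.get(name, {"count": 0})["count"]
            assert got == c

    def test_zero_tail_bonds_domain_directly(self):
        cfg = SynthConfig(tail_beads=0, **SMALL)
        system = build_system(cfg)
        chain = system.chain_indices()
        assert chain == [system.anchor_index, system.tether_bead]

    def test_equal_seeds_bit_identical_different_seeds_differ(self):
        cfg = SynthConfig(seed=11, **SMALL)
        a, b = build_system(cfg), build_system(cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert [x.residue_name for x in a.structure.atoms] == [
            x.residue_name for x in b.structure.atoms
        ]
        c = build_system(SynthConfig(seed=12, **SMALL))
        assert [x.residue_name for x in a.structure.atoms] != [
            x.residue_name for x in c.structure.atoms
        ]

    def test_patch_beads_face_membrane(self):
        system = build_system(SynthConfig(**SMALL))
        patch_z = system.coords[system._charged_domain][:, 2]
        other = [
            i for i in range(system.domain_slice.start, system.domain_slice.stop)
            if i not in set(system._charged_domain)
        ]
        assert patch_z.mean() < system.coords[other][:, 2].mean()

    def test_analysis_selections_resolve_on_topology(self):
        system = build_system(SynthConfig(**SMALL))
        s = system.structure
        assert len(parse_selection("chain P and name CA", s)) == 16
        assert len(parse_selection("resname POPC POPS PIP2", s)) == 64


class TestEnergy:
    def test_zero_when_uncharged_relaxed_unoverlapping(self):
        cfg = SynthConfig(patch_charge_per_bead=0.0,
                          lipid_fractions={"POPC": 1.0}, **SMALL)
        system = build_system(cfg)
        coords = system.coords.copy()
        # build an explicitly relaxed chain: anchor high above the membrane,
        # every bond along +z at its rest length, domain rigidly placed so
        # the tether bond is also relaxed
        chain = system.chain_indices()
        base = coords[system.anchor_index] + np.array([0.0, 0.0, 60.0])
        coords[system.anchor_index] = base
        for k, idx in enumerate(chain[1:-1], start=1):
            coords[idx] = base + np.array([0.0, 0.0, k * cfg.bond_length])
        target_tether = base + np.array([0.0, 0.0, len(chain[1:]) * cfg.bond_length])
        dom = np.arange(system.domain_slice.start, system.domain_slice.stop)
        coords[dom] += target_tether - coords[system.tether_bead]
        e = system.energy(coords)
        assert e.electrostatic == 0.0
        assert e.excluded_volume == 0.0
        assert e.bonds == pytest.approx(0.0, abs=1e-12)
        assert e.total == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_charges_coulomb_closed_form(self):
        cfg = SynthConfig(
            n_lipids_lower=1,
            lipid_fractions={"POPS": 1.0},
            n_domain_beads=8,
            n_patch_beads=1,
            patch_charge_per_bead=1.0,
            debye_length=float("inf"),
            tail_beads=0,
            elec_min_distance=0.1,
        )
        system = build_system(cfg)
        coords = system.coords.copy()
        lipid = 0
        patch = system._charged_domain[0]
        r = float(np.linalg.norm(system._min_image(coords[patch] - coords[lipid])))
        expected = BJERRUM_VACUUM / cfg.dielectric * (1.0 * -1.0) / r
        assert system.energy(coords).electrostatic == pytest.approx(expected, abs=1e-9)

    def test_breakdown_total_is_sum(self):
        system = build_system(SynthConfig(**SMALL))
        e = system.energy()
        assert e.total == pytest.approx(
            e.electrostatic + e.excluded_volume + e.bonds, abs=1e-9
        )

    def test_matches_independent_pair_loop_oracle(self, rng):
        """Random displaced frame: energy ≡ explicit O(N²) python loops."""
        cfg = SynthConfig(**SMALL)
        system = build_system(cfg)
        coords = system.coords.copy()
        prot = system._protein
        coords[prot] += rng.normal(scale=2.0, size=(len(prot), 3))
        e = system.energy(coords)

        box = system.box
        lam, lb = cfg.debye_length, BJERRUM_VACUUM / cfg.dielectric

        def mi(d):
            return d - box * np.round(d / box)

        elec = 0.0
        charged = [i for i in range(len(coords)) if system.charges[i] != 0]
        for ii, i in enumerate(charged):
            for j in charged[ii + 1:]:
                r = np.linalg.norm(mi(coords[i] - coords[j]))
                r = max(r, cfg.elec_min_distance)
                elec += lb * system.charges[i] * system.charges[j] * math.exp(-r / lam) / r
        ev = 0.0
        sigma = cfg.bead_radius + cfg.lipid_radius
        for i in prot:
            z = coords[i][2]
            if z < 0:
                ev += cfg.ev_strength * (z / cfg.bead_radius) ** 2
            for j in range(system.lipid_slice.start, system.lipid_slice.stop):
                r = np.linalg.norm(mi(coords[i] - coords[j]))
                if r < sigma:
                    ev += cfg.ev_strength * (1 - r / sigma) ** 2
        bonds = 0.0
        chain = system.chain_indices()
        for i, j in zip(chain, chain[1:]):
            r = np.linalg.norm(coords[i] - coords[j])
            bonds += 0.5 * cfg.bond_k * (r - cfg.bond_length) ** 2

        assert e.electrostatic == pytest.approx(elec, abs=1e-9)
        assert e.excluded_volume == pytest.approx(ev, abs=1e-9)
        assert e.bonds == pytest.approx(bonds, abs=1e-9)


class TestSimulate:
    def test_fixed_seed_bit_identical(self):
        cfg = SynthConfig(seed=5, **SMALL)
        t1, t2 = simulate(cfg), simulate(cfg)
        assert t1.n_frames == t2.n_frames
        for f in range(t1.n_frames):
            np.testing.assert_array_equal(t1.coords(f), t2.coords(f))

    def test_zero_temperature_descent_never_increases_energy(self):
        cfg = SynthConfig(temperature_kT=0.0, seed=3, **SMALL)
        _traj, system, manifest = simulate(cfg, return_details=True)
        trace = manifest.energy_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_nonpositive_sweeps_rejected(self):
        with pytest.raises(ValueError):
            simulate(SynthConfig(n_sweeps=0))

    def test_times_strictly_increasing_and_frame_count(self):
        cfg = SynthConfig(seed=2, **SMALL)
        traj = simulate(cfg)
        assert traj.n_frames == cfg.n_sweeps // cfg.save_stride + 1
        assert (np.diff(traj.times) > 0).all()

    def test_detailed_balance_on_logged_moves(self):
        """Every logged move's ΔE must equal the full-energy oracle's
        difference, and forward/reverse acceptance must satisfy the
        Metropolis ratio a(x→y)/a(y→x) = exp(−βΔE)."""
        cfg = SynthConfig(seed=9, n_sweeps=10, **{k: v for k, v in SMALL.items()
                                                  if k != "n_sweeps"})
        _traj, system, manifest = simulate(cfg, return_details=True, log_moves=True)
        moves = manifest.move_log
        assert len(moves) > 0
        kT = cfg.temperature_kT
        for mv in moves[:200]:
            e0 = system.energy(mv.coords_before).total
            e1 = system.energy(mv.coords_after).total
            assert mv.delta_e == pytest.approx(e1 - e0, abs=1e-9)
            fwd = min(1.0, math.exp(-mv.delta_e / kT))
            rev = min(1.0, math.exp(mv.delta_e / kT))
            assert fwd / rev == pytest.approx(math.exp(-mv.delta_e / kT), rel=1e-12)
            assert mv.accept_prob == pytest.approx(fwd, abs=1e-12)

    def test_uncharged_system_stays_tethered(self):
        cfg = SynthConfig(patch_charge_per_bead=0.0, seed=4, **SMALL)
        traj = simulate(cfg)
        system = build_system(cfg)
        anchor = traj.coords(0)[system.anchor_index]
        max_reach = (cfg.tail_beads + 1) * cfg.bond_length * 3 + 2 * cfg.domain_radius
        for f in range(traj.n_frames):
            center = traj.coords(f)[system.domain_slice].mean(axis=0)
            assert np.linalg.norm(center - anchor) < max_reach
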