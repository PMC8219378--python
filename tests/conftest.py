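"""Shared fixtures: tiny hand-built structures, trajectories and alignments.

Everything is generated programmatically; nothing is read from disk
except what a test itself writes to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from memtether.structio import Atom, Structure, Trajectory


def make_atom(serial, name="CA", resname="ALA", resid=1, chain="A",
              coords=(0.0, 0.0, 0.0), element=None):
    return Atom(serial, name, element or name[0], resname, resid, chain, tuple(coords))


@pytest.fixture
def three_atom_pdb(tmp_path):
    text = (
        "CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1\n"
        "ATOM      1  N   ALA A   1      11.000  12.000  13.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      12.500  12.000  13.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      14.000  12.500  13.500  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "three.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def membrane_structure():
    """20 atoms: 4 protein residues (one atom each) + 8 lipids of 2 atoms."""
    atoms = []
    serial = 1
    for i in range(4):
        atoms.append(make_atom(serial, "CA", "ALA", i + 1, "A", (i * 3.0, 0, 10)))
        serial += 1
    names = ["POPC", "POPC", "POPC", "POPS", "POPS", "PIP2", "TIP3", "TIP3"]
    for j, rn in enumerate(names):
        for k in range(2):
            atoms.append(
                make_atom(serial, f"C{k+1}", rn, j + 1, "L", (j * 4.0, k * 1.5, 0.0), "C")
            )
            serial += 1
    return Structure(atoms, box=(100.0, 100.0, 100.0))


def build_trajectory(structure: Structure, coord_list, times=None) -> Trajectory:
    times = times if times is not None else list(range(len(coord_list)))
    frames = [
        (float(t), np.asarray(c, dtype=float), structure.box)
        for t, c in zip(times, coord_list)
    ]
    return Trajectory(structure, frames)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
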