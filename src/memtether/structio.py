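"""Structure, trajectory and selection I/O.

Single source of truth for coordinates and atom metadata.  Reads and
writes multi-model PDB (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``CRYST1``
records) and the package's own plain-text frame format, parses the small
selection language used to name atom groups (chains, residue-id ranges,
residue-name and atom-name lists, ``and``/``or``/``not``), and emits TSV
tables.

Conventions: residue numbering follows PDB author numbering (1-based,
ranges inclusive on both ends); internal atom indexing is 0-based; all
file-facing output is 1-based.  Alternate locations keep the first altloc;
insertion codes are rejected explicitly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomIndexSet",
    "StructureParseError",
    "StructuralMismatchError",
    "SelectionSyntaxError",
    "EmptyInputError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "parse_selection",
    "write_table",
]


class StructureParseError(ValueError):
    """A coordinate file could not be parsed; message names the line."""


class StructuralMismatchError(ValueError):
    """A trajectory model does not match its topology."""


class SelectionSyntaxError(ValueError):
    """Selection expression failed to parse; message carries a caret."""


class EmptyInputError(ValueError):
    """A file or selection contained no atoms where some were required."""


@dataclass(frozen=True)
class Atom:
    """One atom: PDB-style metadata plus coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom serial {self.serial}: non-finite coordinates")


@dataclass
class Structure:
    """An ordered list of atoms with an optional orthorhombic box (Å)."""

    atoms: list[Atom]
    box: tuple[float, float, float] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N×3 float array of coordinates, Å."""
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain_id, residue_id, residue_name) in file order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_id, a.residue_name))
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected {(len(self.atoms), 3)} coords, got {coords.shape}")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                 a.chain_id, tuple(c))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.box)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` is a list of ``(time_ns, coords, box)`` triples; every frame
    has exactly ``len(topology)`` coordinate rows and times are strictly
    increasing.
    """

    topology: Structure
    frames: list[tuple[float, np.ndarray, tuple[float, float, float] | None]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        n = len(self.topology)
        times = []
        for i, (t, xyz, _box) in enumerate(self.frames):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise StructuralMismatchError(
                    f"frame {i}: expected {n} atoms, got {xyz.shape[0]}"
                )
            times.append(t)
        if any(b >= a for a, b in zip(times[1:], times)):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([t for t, _, _ in self.frames], dtype=float)

    def coords(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i][1], dtype=float)

    def box(self, i: int) -> tuple[float, float, float] | None:
        return self.frames[i][2]


@dataclass(frozen=True)
class AtomIndexSet:
    """Sorted, duplicate-free 0-based indices into a Structure's atoms."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if list(idx) != sorted(set(idx)):
            raise ValueError("indices must be sorted and unique")
        if idx and idx[0] < 0:
            raise ValueError("negative atom index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB parsing

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _parse_pdb_atom(line: str, lineno: int) -> Atom:
    if len(line) < 54:
        raise StructureParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    if len(line) > 26 and line[26] not in (" ", ""):
        raise StructureParseError(
            f"line {lineno}: insertion code {line[26]!r} not supported"
        )
    try:
        serial = int(line[6:11])
    except ValueError:
        raise StructureParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from None
    coords = []
    for lo, hi in _COORD_SLICES:
        fieldtxt = line[lo:hi]
        try:
            coords.append(float(fieldtxt))
        except ValueError:
            raise StructureParseError(
                f"line {lineno}: malformed coordinate field {fieldtxt!r}"
            ) from None
    name = line[12:16].strip()
    resname = line[17:21].strip() or line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resid = int(line[22:26])
    except ValueError:
        raise StructureParseError(f"line {lineno}: bad residue id {line[22:26]!r}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    return Atom(serial, name, element, resname, resid, chain, tuple(coords))


def _read_pdb(path: Path) -> tuple[list[list[Atom]], tuple[float, float, float] | None, list[float]]:
    """Return (models, box, remark_times)."""
    models: list[list[Atom]] = []
    current: list[Atom] = []
    box = None
    times: list[float] = []
    in_model = False
    altloc_seen: set[tuple[str, int, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "CRYST1":
                try:
                    box = (float(raw[6:15]), float(raw[15:24]), float(raw[24:33]))
                except ValueError:
                    raise StructureParseError(
                        f"line {lineno}: malformed CRYST1 record"
                    ) from None
            elif rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                altloc_seen = set()
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                altloc_seen = set()
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                altloc = raw[16] if len(raw) > 16 else " "
                if altloc not in (" ", "A"):
                    continue  # keep first altloc only
                atom = _parse_pdb_atom(raw.rstrip("\n"), lineno)
                key = (atom.chain_id, atom.residue_id, atom.name)
                if altloc == "A" and key in altloc_seen:
                    continue
                if altloc == "A":
                    altloc_seen.add(key)
                current.append(atom)
            elif rec == "REMARK" and "time" in raw.lower() and "=" in raw:
                try:
                    times.append(float(raw.split("=")[-1].split()[0]))
                except (ValueError, IndexError):
                    pass
    if current:
        models.append(current)
    if in_model and models and not models[-1]:
        models.pop()
    models = [m for m in models if m]
    return models, box, times


def _looks_like_frame_format(path: Path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().split()
    if len(first) != 2:
        return False
    try:
        int(first[0]), int(first[1])
    except ValueError:
        return False
    return True


def _read_frame_file(path: Path) -> tuple[int, list[tuple[float, np.ndarray]]]:
    """Plain-text frame format: header ``natoms nframes``, then per frame a
    line ``t`` followed by ``natoms`` lines of ``x y z``."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty file")
    head = lines[0].split()
    try:
        natoms, nframes = int(head[0]), int(head[1])
    except (ValueError, IndexError):
        raise StructureParseError(f"line 1: bad frame-format header {lines[0]!r}") from None
    frames = []
    pos = 1
    for k in range(nframes):
        if pos >= len(lines):
            raise StructureParseError(f"frame {k}: truncated file")
        try:
            t = float(lines[pos])
        except ValueError:
            raise StructureParseError(
                f"line {pos + 1}: expected frame time, got {lines[pos]!r}"
            ) from None
        block = lines[pos + 1 : pos + 1 + natoms]
        if len(block) < natoms:
            raise StructureParseError(f"frame {k}: expected {natoms} coordinate lines")
        try:
            xyz = np.asarray([[float(v) for v in ln.split()[:3]] for ln in block])
        except ValueError:
            raise StructureParseError(f"frame {k}: malformed coordinate line") from None
        frames.append((t, xyz))
        pos += 1 + natoms
    return natoms, frames


def read_structure(path: str | Path) -> Structure:
    """Read a structure from a PDB file or plain-text frame file.

    For multi-model PDB the first model is the topology.  Frame-format
    files produce placeholder atoms (one residue per atom, name ``X``).
    """
    path = Path(path)
    if _looks_like_frame_format(path):
        natoms, frames = _read_frame_file(path)
        if natoms == 0 or not frames:
            raise EmptyInputError(f"{path}: zero atoms")
        atoms = [
            Atom(i + 1, "X", "X", "UNK", i + 1, " ", tuple(frames[0][1][i]))
            for i in range(natoms)
        ]
        return Structure(atoms)
    models, box, _times = _read_pdb(path)
    if not models or not models[0]:
        raise EmptyInputError(f"{path}: zero atoms")
    return Structure(models[0], box)


def read_trajectory(
    path: str | Path,
    topology: Structure | None = None,
    stride_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory: one frame per PDB MODEL, or plain-text frames.

    Times come from embedded ``REMARK ... time=`` records when present,
    otherwise frame index × ``stride_ns``.
    """
    path = Path(path)
    if _looks_like_frame_format(path):
        if topology is None:
            topology = read_structure(path)
        natoms, raw = _read_frame_file(path)
        if natoms != len(topology):
            raise StructuralMismatchError(
                f"frame file has {natoms} atoms, topology has {len(topology)}"
            )
        frames = [(t, xyz, topology.box) for t, xyz in raw]
        return Trajectory(topology, frames)

    models, box, times = _read_pdb(path)
    if not models:
        raise EmptyInputError(f"{path}: no models")
    if topology is None:
        topology = Structure(models[0], box)
    n = len(topology)
    frames = []
    for i, model in enumerate(models, start=1):
        if len(model) != n:
            raise StructuralMismatchError(
                f"model {i}: has {len(model)} atoms, topology expects {n}"
            )
        xyz = np.asarray([a.coords for a in model], dtype=float)
        t = times[i - 1] if len(times) >= len(models) else (i - 1) * stride_ns
        frames.append((t, xyz, box))
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# PDB / frame-format writing

def _format_pdb_atom(a: Atom, coords: Sequence[float]) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial % 100000:5d} {name:<4.4s} {a.residue_name:<4.4s}"
        f"{a.chain_id:1.1s}{a.residue_id % 10000:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"  1.00  0.00          {a.element:>2.2s}"
    )


def write_structure(s: Structure, path: str | Path) -> None:
    lines = []
    if s.box is not None:
        lines.append(
            f"CRYST1{s.box[0]:9.3f}{s.box[1]:9.3f}{s.box[2]:9.3f}"
            "  90.00  90.00  90.00 P 1           1"
        )
    for a in s.atoms:
        lines.append(_format_pdb_atom(a, a.coords))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB with per-frame ``REMARK`` time records."""
    lines = []
    box = traj.topology.box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            "  90.00  90.00  90.00 P 1           1"
        )
    for i, (t, xyz, _b) in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.append(f"REMARK     time= {t:.6g}")
        for a, c in zip(traj.topology.atoms, xyz):
            lines.append(_format_pdb_atom(a, c))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Selection language
#
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := not_expr ("and" not_expr)*
#   not_expr := "not" not_expr | primary
#   primary  := "(" expr ")" | "all" | "chain" IDS | "name" IDS
#             | "resname" IDS | "resid" RANGES
#
# Residue-id ranges are inclusive on both ends (PDB author numbering).

_KEYWORDS = {"and", "or", "not", "chain", "name", "resname", "resid", "all", "(", ")"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


def _caret_error(expr: str, pos: int, msg: str) -> SelectionSyntaxError:
    return SelectionSyntaxError(f"{msg}\n  {expr}\n  {' ' * pos}^")


class _SelParser:
    def __init__(self, expr: str, structure: Structure):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.s = structure

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise _caret_error(self.expr, len(self.expr), "unexpected end of selection")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise _caret_error(self.expr, 0, "empty selection")
        mask = self.or_expr()
        if self.peek() is not None:
            tok, p = self.peek()
            raise _caret_error(self.expr, p, f"unexpected token {tok!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek()[0].lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() is not None and self.peek()[0].lower() == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        if self.peek() is not None and self.peek()[0].lower() == "not":
            self.next()
            return ~self.not_expr()
        return self.primary()

    def _values(self) -> list[tuple[str, int]]:
        vals = []
        while self.peek() is not None:
            tok, p = self.peek()
            if tok.lower() in _KEYWORDS:
                break
            vals.append((tok, p))
            self.next()
        return vals

    def primary(self) -> np.ndarray:
        tok, p = self.next()
        word = tok.lower()
        n = len(self.s)
        if word == "(":
            mask = self.or_expr()
            closing = self.next()
            if closing[0] != ")":
                raise _caret_error(self.expr, closing[1], "expected ')'")
            return mask
        if word == "all":
            return np.ones(n, dtype=bool)
        if word == "chain":
            vals = self._values()
            if not vals:
                raise _caret_error(self.expr, p, "chain requires at least one value")
            chains = {v for v, _ in vals}
            return np.asarray([a.chain_id in chains for a in self.s.atoms])
        if word == "name":
            vals = self._values()
            if not vals:
                raise _caret_error(self.expr, p, "name requires at least one value")
            names = {v.upper() for v, _ in vals}
            return np.asarray([a.name.upper() in names for a in self.s.atoms])
        if word == "resname":
            vals = self._values()
            if not vals:
                raise _caret_error(self.expr, p, "resname requires at least one value")
            rn = {v.upper() for v, _ in vals}
            return np.asarray([a.residue_name.upper() in rn for a in self.s.atoms])
        if word == "resid":
            vals = self._values()
            if not vals:
                raise _caret_error(self.expr, p, "resid requires at least one value")
            wanted: set[int] = set()
            for v, vp in vals:
                m = re.fullmatch(r"(-?\d+)-(\d+)", v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    if hi < lo:
                        raise _caret_error(self.expr, vp, f"descending resid range {v!r}")
                    wanted.update(range(lo, hi + 1))
                    continue
                try:
                    wanted.add(int(v))
                except ValueError:
                    raise _caret_error(self.expr, vp, f"bad resid {v!r}") from None
            return np.asarray([a.residue_id in wanted for a in self.s.atoms])
        raise _caret_error(self.expr, p, f"unknown selection keyword {tok!r}")


def parse_selection(expr: str, s: Structure) -> AtomIndexSet:
    """Evaluate a selection expression against a structure.

    Returns a deterministic, sorted :class:`AtomIndexSet`.  An empty result
    is allowed but flagged in the returned label.
    """
    mask = _SelParser(expr, s).parse()
    idx = tuple(int(i) for i in np.flatnonzero(mask))
    label = expr if idx else f"{expr} [EMPTY]"
    return AtomIndexSet(idx, label)


# ---------------------------------------------------------------------------
# Tables

def write_table(rows: Iterable[Mapping[str, object]] | pd.DataFrame,
                path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as TSV with a header; floats at 6 sig figs."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
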