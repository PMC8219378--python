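"""Charged-residue census over a Rho-family multiple sequence alignment.

Given an MSA of Rho-family GTPase catalytic domains, count positively
(K/R/H) and negatively (D/E) charged residues inside a putative
membrane-interface window defined in one reference sequence's ungapped
numbering, and measure each sequence's C-terminal tail length (residues
after the alignment column where the reference's catalytic domain ends).
Histidine is counted positive: at a negatively charged inner leaflet it
contributes to membrane binding alongside Lys/Arg.

The window ranges and the long/short tail threshold are configuration:
the library refuses to guess a tail cutoff.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

__all__ = [
    "Msa",
    "InterfaceWindow",
    "ChargeCensusRecord",
    "AlignmentFormatError",
    "POSITIVE_RESIDUES",
    "NEGATIVE_RESIDUES",
    "read_alignment",
    "map_window",
    "charge_census",
    "tail_length",
    "census_table",
]

POSITIVE_RESIDUES = frozenset("KRH")
NEGATIVE_RESIDUES = frozenset("DE")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


class AlignmentFormatError(ValueError):
    """Input is not a well-formed alignment."""


@dataclass(frozen=True)
class Msa:
    """Ordered (id, gapped sequence) pairs of equal length."""

    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("empty alignment")
        width = len(self.sequences[0][1])
        ids = [sid for sid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate sequence ids")
        for sid, seq in self.sequences:
            if len(seq) != width:
                raise AlignmentFormatError(
                    f"sequence {sid!r} has length {len(seq)}, expected {width}"
                )
    @property
    def width(self) -> int:
        return len(self.sequences[0][1])

    def get(self, sid: str) -> str:
        for s, seq in self.sequences:
            if s == sid:
                return seq
        raise KeyError(f"sequence id {sid!r} not in alignment")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.sequences)


@dataclass(frozen=True)
class InterfaceWindow:
    """Inclusive residue-number ranges in the reference's ungapped numbering."""

    ref_id: str
    ref_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        spans = sorted(self.ref_ranges)
        for (lo, hi) in spans:
            if lo < 1 or hi < lo:
                raise ValueError(f"bad range ({lo}, {hi})")
        for (_, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("window ranges overlap")
        object.__setattr__(self, "ref_ranges", tuple(tuple(r) for r in spans))


@dataclass(frozen=True)
class ChargeCensusRecord:
    id: str
    n_pos: int
    n_neg: int
    tail_len: int
    tail_class: str  # "long" | "short"


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an aligned FASTA or Clustal file.

    The format is sniffed from the first non-blank line when not given.
    Sequences are upper-cased and '.' gaps normalized to '-'.  Ragged
    (unaligned) input raises :class:`AlignmentFormatError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if fmt is None:
        first = next((ln for ln in text.splitlines() if ln.strip()), "")
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    return Msa(tuple((rec.id, _normalize(str(rec.seq))) for rec in aln))


def _ref_column_of(ref_gapped: str, residue_number: int) -> int:
    """0-based alignment column of the reference's Nth ungapped residue."""
    count = 0
    for col, c in enumerate(ref_gapped):
        if c != GAP:
            count += 1
            if count == residue_number:
                return col
    raise ValueError(
        f"residue number {residue_number} exceeds reference length {count}"
    )


def map_window(msa: Msa, window: InterfaceWindow) -> dict[str, str]:
    """Extract each sequence's residues at the window's alignment columns.

    The reference's ungapped residue-number ranges are converted to
    alignment columns; every sequence's characters in those columns are
    returned with gaps preserved.
    """
    ref = msa.get(window.ref_id)
    cols: list[int] = []
    for lo, hi in window.ref_ranges:
        start = _ref_column_of(ref, lo)
        end = _ref_column_of(ref, hi)
        cols.extend(range(start, end + 1))
    return {sid: "".join(seq[c] for c in cols) for sid, seq in msa.sequences}


def charge_census(window_residues: dict[str, str] | str) -> dict[str, tuple[int, int]] | tuple[int, int]:
    """Count (positive, negative) charged residues in window strings.

    Positive = K, R, H; negative = D, E; gaps contribute nothing.  A bare
    string returns one (n_pos, n_neg) pair; a mapping returns a mapping.
    """
    def count_one(s: str) -> tuple[int, int]:
        s = _normalize(s)
        bad = set(s) - AMINO_ACIDS - {GAP}
        if bad:
            raise ValueError(f"non-amino characters in window: {sorted(bad)}")
        n_pos = sum(1 for c in s if c in POSITIVE_RESIDUES)
        n_neg = sum(1 for c in s if c in NEGATIVE_RESIDUES)
        return n_pos, n_neg

    if isinstance(window_residues, str):
        return count_one(window_residues)
    return {sid: count_one(s) for sid, s in window_residues.items()}


def tail_length(msa: Msa, ref_id: str, ref_catalytic_end: int) -> dict[str, int]:
    """Per-sequence C-terminal tail length.

    The alignment column holding the reference's catalytic-domain end is
    located; each sequence's tail is its count of non-gap residues
    strictly C-terminal to that column.
    """
    ref = msa.get(ref_id)
    end_col = _ref_column_of(ref, ref_catalytic_end)
    return {
        sid: sum(1 for c in seq[end_col + 1:] if c != GAP)
        for sid, seq in msa.sequences
    }


DEFAULT_EXCLUDED_IDS = ("RHBT1", "RHBT2", "RHBT3")


def census_table(
    msa: Msa,
    window: InterfaceWindow,
    ref_catalytic_end: int,
    tail_threshold: int,
    excluded_ids: tuple[str, ...] = DEFAULT_EXCLUDED_IDS,
) -> list[ChargeCensusRecord]:
    """One :class:`ChargeCensusRecord` per (non-excluded) sequence.

    ``tail_class`` is ``short`` iff ``tail_len <= tail_threshold``.  The
    threshold is a required argument: there is no universally agreed
    long/short cutoff, so the caller must state one.  The default
    exclusions drop the Rhotekin-domain-bearing family members whose
    C-terminal architecture makes the tail length incomparable.
    """
    if tail_threshold is None:
        raise ValueError("tail_threshold is required (no library default)")
    windows = map_window(msa, window)
    tails = tail_length(msa, window.ref_id, ref_catalytic_end)
    records = []
    excluded = set(excluded_ids or ())
    for sid in msa.ids:
        if sid in excluded:
            continue
        n_pos, n_neg = charge_census(windows[sid])
        tl = tails[sid]
        records.append(
            ChargeCensusRecord(
                id=sid,
                n_pos=n_pos,
                n_neg=n_neg,
                tail_len=tl,
                tail_class="short" if tl <= tail_threshold else "long",
            )
        )
    return records
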