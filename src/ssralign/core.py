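"""Repeat-unit partitioning and slippage-aware realignment of SSR regions.

A microsatellite (SSR) locus inside a multiple sequence alignment is described
by an ordered list of repeat units (e.g. ``TA CA``) and a 1-based inclusive
column window ``[first, last]``.  Generic aligners place the alleles of such a
locus so that copies of *different* units share columns ("overlaps"), turning
pure replication-slippage variation — which only changes tandem copy numbers —
into spurious substitutions.

The realignment here removes those overlaps.  Each sequence's window content
is degapped and decomposed left-to-right into

    prefix | unit_1 run | unmatched_1 | unit_2 run | unmatched_2 | ...

by a greedy single-pass scan: the prefix absorbs residues until the first unit
matches, each run is the maximal tandem repetition of its unit, and residues
that continue neither the current unit nor start the next one accumulate as
"unmatched" interrupting residues.  The decomposed sequences are then
reassembled into non-overlapping per-unit column blocks: within block *i*
every row holds whole copies of unit *i* padded on the right with gaps to the
longest run, and interrupting residues sit right-aligned against the next
block — i.e. after the slippage gap and before the next repeated unit, the
natural position for the imperfection under a slippage model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .io import GAP, Alignment

MAX_UNIT_LENGTH = 6
_UNIT_ALPHABET = frozenset("ACGT")
_WINDOW_ALPHABET = frozenset("ACGTN")


class WindowError(ValueError):
    """The SSR window falls outside the alignment columns."""


class NoRepeatFoundWarning(UserWarning):
    """The first repeat unit never matches inside a window; the whole window
    is preserved as prefix."""


def _validate_units(units: Sequence[str]) -> tuple[str, ...]:
    units = tuple(u.upper() for u in units)
    if not units:
        raise ValueError("at least one repeat unit is required")
    for u in units:
        if not 1 <= len(u) <= MAX_UNIT_LENGTH:
            raise ValueError(
                f"repeat unit {u!r} must be 1-{MAX_UNIT_LENGTH} bp long"
            )
        if not set(u) <= _UNIT_ALPHABET:
            raise ValueError(f"repeat unit {u!r} contains non-ACGT characters")
    for a, b in zip(units, units[1:]):
        if a == b:
            raise ValueError(
                f"adjacent duplicate repeat unit {a!r}: two identical "
                "consecutive units are one unit"
            )
    return units


@dataclass(frozen=True)
class SSRSpec:
    """An SSR locus: ordered repeat units plus a 1-based inclusive column window."""

    units: tuple[str, ...]
    first: int
    last: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", _validate_units(self.units))
        if self.first < 1 or self.last < self.first:
            raise WindowError(
                f"window [{self.first}, {self.last}] is not a valid 1-based "
                "inclusive range"
            )


@dataclass(frozen=True)
class UnitBlock:
    """One repeat unit's share of a partitioned window.

    ``copies`` tandem copies of ``unit`` were matched, followed by
    ``unmatched`` interrupting residues that continue neither this unit nor
    start the next block's unit.
    """

    unit: str
    copies: int
    unmatched: str

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be non-negative")
        if GAP in self.unmatched:
            raise ValueError("unmatched residues may not contain gaps")

    @property
    def matched(self) -> str:
        return self.unit * self.copies


@dataclass(frozen=True)
class PartitionedSSR:
    """Per-sequence decomposition of a degapped SSR window."""

    prefix: str
    blocks: tuple[UnitBlock, ...]

    def reconstruct(self) -> str:
        """The original (degapped) window content; no residue created or lost."""
        return self.prefix + "".join(b.matched + b.unmatched for b in self.blocks)


def degap(seq: str) -> str:
    """Remove all gap characters, preserving residue order."""
    return seq.replace(GAP, "")


def _run_length(seq: str, start: int, unit: str) -> int:
    """Maximal k such that ``seq[start:]`` begins with ``unit`` repeated k times."""
    k = 0
    i = start
    step = len(unit)
    while seq.startswith(unit, i) and i + step <= len(seq):
        i += step
        k += 1
    return k


def match_run(seq: str, pos: int, unit: str) -> int:
    """Maximal number of tandem ``unit`` copies starting at 1-based ``pos``.

    Greedy with no lookahead beyond the run; 0 when the unit does not match
    or ``pos`` is past the end of the sequence.
    """
    if not 1 <= pos <= len(seq) + 1:
        raise ValueError(f"pos {pos} outside 1..{len(seq) + 1}")
    return _run_length(seq, pos - 1, unit)


def partition_sequence(window: str, units: Sequence[str]) -> PartitionedSSR:
    """Decompose an ungapped SSR window into per-unit blocks, left to right.

    The scan is greedy and non-resuming: the prefix absorbs residues until the
    first unit matches; each block takes the maximal tandem run of its unit,
    then accumulates unmatched residues one at a time until the next block's
    unit matches (the final block absorbs everything remaining).  ``N`` never
    matches a unit.  A window in which the first unit never matches becomes
    pure prefix (with a warning); the content-preservation invariant
    ``PartitionedSSR.reconstruct() == window`` always holds.
    """
    units = _validate_units(units)
    window = window.upper()
    if not set(window) <= _WINDOW_ALPHABET:
        bad = sorted(set(window) - _WINDOW_ALPHABET)
        raise ValueError(f"window contains illegal characters {bad} (degap first?)")

    L = len(window)
    u1 = units[0]
    i = 0
    while i < L and not window.startswith(u1, i):
        i += 1
    prefix = window[:i]
    if i == L and L > 0:
        warnings.warn(
            f"first repeat unit {u1!r} never matches in window; the whole "
            "window is kept as unaligned prefix",
            NoRepeatFoundWarning,
            stacklevel=2,
        )

    blocks: list[UnitBlock] = []
    pos = i
    n = len(units)
    for bi, unit in enumerate(units):
        copies = _run_length(window, pos, unit)
        pos += copies * len(unit)
        if bi + 1 < n:
            nxt = units[bi + 1]
            j = pos
            while j < L and not window.startswith(nxt, j):
                j += 1
            unmatched = window[pos:j]
            pos = j
        else:
            unmatched = window[pos:]
            pos = L
        blocks.append(UnitBlock(unit, copies, unmatched))
    return PartitionedSSR(prefix, tuple(blocks))


def assemble_blocks(
    parts: Sequence[PartitionedSSR], units: Sequence[str]
) -> list[str]:
    """Reassemble partitioned windows into equal-length, overlap-free rows.

    Field widths are the per-column maxima over all sequences: the prefix is
    right-aligned (gaps on the left) in a field of the longest prefix; each
    unit's run is left-aligned and gap-padded on the right to the longest run;
    each unmatched stretch is right-aligned against the next block.  Degapping
    any output row recovers that sequence's window content.
    """
    units = _validate_units(units)
    if not parts:
        raise ValueError("assemble_blocks requires at least one partitioned window")
    for p in parts:
        if tuple(b.unit for b in p.blocks) != units:
            raise ValueError("all partitions must use the same ordered unit list")

    n_blocks = len(units)
    prefix_w = max(len(p.prefix) for p in parts)
    copies_w = [
        max(p.blocks[i].copies for p in parts) * len(units[i])
        for i in range(n_blocks)
    ]
    unmatched_w = [
        max(len(p.blocks[i].unmatched) for p in parts) for i in range(n_blocks)
    ]

    rows: list[str] = []
    for p in parts:
        pieces = [p.prefix.rjust(prefix_w, GAP)]
        for i, block in enumerate(p.blocks):
            pieces.append(block.matched.ljust(copies_w[i], GAP))
            pieces.append(block.unmatched.rjust(unmatched_w[i], GAP))
        rows.append("".join(pieces))
    return rows


def realign(aln: Alignment, spec: SSRSpec) -> Alignment:
    """Replace the SSR window of ``aln`` with its slippage-aware realignment.

    Columns before ``spec.first`` and after ``spec.last`` are copied verbatim;
    the window columns are degapped per sequence, partitioned by repeat unit
    and reassembled into non-overlapping per-unit blocks.  The result is a
    valid rectangular alignment whose degapped rows are identical to the
    input's (no residue is created or lost); its length may differ from the
    input's because block widths are recomputed.
    """
    if not 1 <= spec.first <= spec.last <= aln.length:
        raise WindowError(
            f"window [{spec.first}, {spec.last}] outside alignment columns "
            f"1..{aln.length}"
        )
    a, b = spec.first - 1, spec.last
    parts = [partition_sequence(degap(row[a:b]), spec.units) for row in aln.rows]
    windows = assemble_blocks(parts, spec.units)
    rows = tuple(row[:a] + w + row[b:] for row, w in zip(aln.rows, windows))
    return Alignment(aln.names, rows)


def ssr_fraction(ssr_len: int, total_len: int) -> float:
    """Percentage of a sequence occupied by its SSR region, one decimal place."""
    if ssr_len <= 0 or total_len <= 0:
        raise ValueError("lengths must be positive")
    if ssr_len > total_len:
        raise ValueError("SSR length cannot exceed total length")
    return round(100.0 * ssr_len / total_len, 1)
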