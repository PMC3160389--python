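"""Alignment container and readers/writers for FASTA and the SALT table format.

The SALT table format is a minimal aligned-sequence exchange format used by
microsatellite genotyping workflows: the first line carries the number of
samples and the number of alignment columns, separated by any run of
whitespace; every following non-blank line carries an allele name, whitespace,
and the (gapped) sequence. Because whitespace is the separator, names may not
contain spaces or tabs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

from Bio import SeqIO

ALPHABET = frozenset("ACGTN-")
GAP = "-"
FASTA_WRAP = 70

AlignmentFormat = Literal["fasta", "salt_table"]


class AlignmentShapeError(ValueError):
    """Rows of an alignment differ in length (ragged alignment)."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N, -}."""


class FormatError(ValueError):
    """A file does not conform to the requested alignment format."""


def _normalize(seq: str) -> str:
    # uppercase on read; '.' is an alternative gap glyph some editors emit
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment over {A,C,G,T,N,-}.

    ``names`` and ``rows`` are parallel tuples; every row has the same number
    of columns.  Sequences are uppercased on construction and ``.`` gaps are
    normalized to ``-``, so two alignments that differ only in case or gap
    glyph compare equal.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        rows = tuple(_normalize(r) for r in self.rows)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "rows", rows)
        if not names:
            raise AlignmentShapeError("alignment must contain at least one sequence")
        if len(names) != len(rows):
            raise AlignmentShapeError(
                f"{len(names)} names but {len(rows)} sequences"
            )
        seen: set[str] = set()
        for name in names:
            if not name:
                raise ValueError("sequence names must be non-empty")
            if name in seen:
                raise ValueError(f"duplicate sequence name {name!r}")
            seen.add(name)
        width = len(rows[0])
        for name, row in zip(names, rows):
            if len(row) != width:
                raise AlignmentShapeError(
                    f"sequence {name!r} has length {len(row)}, expected {width}"
                )
            for col, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"illegal character {ch!r} in sequence {name!r} at column {col + 1}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.names, self.rows))

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


def _detect_format(text: str) -> AlignmentFormat:
    stripped = text.lstrip()
    return "fasta" if stripped.startswith(">") else "salt_table"


def _parse_fasta(text: str) -> Alignment:
    from io import StringIO

    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise FormatError("no FASTA records found")
    names = tuple(rec.id for rec in records)
    rows = tuple(str(rec.seq) for rec in records)
    return Alignment(names, rows)


def _parse_salt_table(text: str) -> Alignment:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty salt_table file")
    header = lines[0].split()
    if len(header) != 2:
        raise FormatError(
            f"salt_table header must hold two integers, got {lines[0]!r}"
        )
    try:
        n_samples, n_cols = int(header[0]), int(header[1])
    except ValueError as exc:
        raise FormatError(
            f"salt_table header must hold two integers, got {lines[0]!r}"
        ) from exc
    names: list[str] = []
    rows: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise FormatError(
                f"salt_table record must be '<name> <sequence>', got {ln!r}"
            )
        names.append(parts[0])
        rows.append(parts[1])
    if len(names) != n_samples:
        raise FormatError(
            f"salt_table header declares {n_samples} samples, found {len(names)}"
        )
    aln = Alignment(tuple(names), tuple(rows))
    if aln.length != n_cols:
        raise FormatError(
            f"salt_table header declares {n_cols} nucleotides, rows have {aln.length}"
        )
    return aln


def read_alignment(
    path: str | Path, format: Literal["fasta", "salt_table", "auto"] = "auto"
) -> Alignment:
    """Read an alignment from ``path``.

    ``format='auto'`` sniffs FASTA by a leading ``>``; anything else is parsed
    as a SALT table.  Sequences are validated (rectangular, legal alphabet)
    and uppercased.
    """
    text = Path(path).read_text()
    fmt = _detect_format(text) if format == "auto" else format
    if fmt == "fasta":
        return _parse_fasta(text)
    if fmt == "salt_table":
        return _parse_salt_table(text)
    raise ValueError(f"unknown alignment format {format!r}")


def format_alignment(aln: Alignment, format: AlignmentFormat) -> str:
    """Render ``aln`` as FASTA (wrapped at 70 columns) or SALT table text."""
    if format == "fasta":
        chunks: list[str] = []
        for name, row in aln:
            chunks.append(f">{name}\n")
            for start in range(0, len(row), FASTA_WRAP):
                chunks.append(row[start : start + FASTA_WRAP] + "\n")
        return "".join(chunks)
    if format == "salt_table":
        lines = [f"{len(aln)} {aln.length}"]
        lines.extend(f"{name} {row}" for name, row in aln)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path: str | Path, format: AlignmentFormat) -> None:
    """Write ``aln`` to ``path`` such that reading it back yields an equal alignment."""
    Path(path).write_text(format_alignment(aln, format))
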