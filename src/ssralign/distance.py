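"""Pairwise p-distances and the overall pairwise value (PV) of an alignment.

The distance used throughout is the uncorrected p-distance with pairwise
deletion: for each pair of rows, sites where either sequence carries a gap
(or an ``N``, treated as missing data) are skipped, and the distance is the
fraction of mismatches among the remaining comparable sites.  The PV of an
alignment is the arithmetic mean of all pairwise distances; comparing PV
before and after SSR realignment quantifies how many spurious substitutions
the overlapped alignment contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GAP, Alignment

_MISSING = frozenset({GAP, "N"})


class NoComparableSitesWarning(UserWarning):
    """Two sequences share no gap-free site; their distance is reported as 0."""


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching sites among sites comparable in both sequences.

    Sites where either sequence has a gap or an ``N`` are excluded (pairwise
    deletion).  Returns 0.0, with a warning, when no comparable site exists.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    comparable = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _MISSING or y in _MISSING:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        warnings.warn(
            "no comparable (gap-free in both) sites; distance reported as 0.0",
            NoComparableSitesWarning,
            stacklevel=2,
        )
        return 0.0
    return diffs / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "d", d)
        n = len(labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if n and not np.allclose(np.diag(d), 0.0, atol=1e-12, equal_nan=False):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("distances must be non-negative")
        d.flags.writeable = False

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All pairwise p-distances of an alignment (requires >= 2 sequences)."""
    n = len(aln)
    if n < 2:
        raise ValueError("distance matrix requires at least 2 sequences")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(aln.rows[i], aln.rows[j])
    return DistanceMatrix(tuple(aln.names), d)


def overall_mean_distance(dm: DistanceMatrix) -> float:
    """Overall pairwise value (PV): mean of the strict upper triangle."""
    n = len(dm)
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(dm.d[iu].mean())


def format_distance_matrix(dm: DistanceMatrix) -> str:
    """Tab-separated export: label header row, then one labelled row per taxon."""
    lines = ["\t".join(("",) + dm.labels)]
    for label, row in zip(dm.labels, dm.d):
        lines.append(label + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"
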