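"""Synthetic SSR allele panels with known ground truth.

Alleles at a microsatellite locus share conserved flanking sequence and differ
mainly in per-unit tandem copy numbers (replication slippage changes copy
number without substitutions).  The generator draws copy numbers per unit from
configured ranges, optionally injects a single interrupting residue inside a
repeat run (an "imperfect" SSR) and point substitutions in the flanks, and
records everything it did so that each emitted sequence can be rebuilt exactly
from its truth record.

``naive_overlap_alignment`` produces the flawed baseline a generic aligner
tends to emit for such panels: every SSR region left-justified and padded with
gaps on the right, so that copies of different units share columns.  Those
"overlap" columns are the artifact that slippage-aware realignment removes.

Five preset designs (``case_config``) emulate panels of 26 alleles at loci of
increasing complexity: a simple (TA)10 locus; compound (TA)10(CA)16,
(TA)10(CA)16(CG)14 and (TA)10(CA)16(CG)14(TG)18 loci; and a compound-imperfect
(GAA)4(GAT)6(GAGGAT)3 locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import _validate_units
from .io import Alignment

BASES = "ACGT"

#: units and reference copy numbers of the five preset locus designs
CASE_DESIGNS: dict[str, tuple[tuple[str, ...], tuple[int, ...]]] = {
    "A": (("TA",), (10,)),
    "B": (("TA", "CA"), (10, 16)),
    "C": (("TA", "CA", "CG"), (10, 16, 14)),
    "D": (("TA", "CA", "CG", "TG"), (10, 16, 14, 18)),
    "E": (("GAA", "GAT", "GAGGAT"), (4, 6, 3)),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic allele panel.

    ``copy_ranges[i]`` is the inclusive [min, max] range the i-th unit's copy
    number is drawn from.  ``flank_snp_rate`` is a per-site substitution
    probability applied independently to both flanks; ``imperfect_rate`` is
    the per-allele probability of carrying one interrupting residue inside a
    repeat run.  Generation is deterministic for a fixed ``seed``.
    """

    units: tuple[str, ...]
    copy_ranges: tuple[tuple[int, int], ...]
    n_alleles: int
    flank5: str
    flank3: str
    flank_snp_rate: float = 0.0
    imperfect_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", _validate_units(self.units))
        ranges = tuple((int(lo), int(hi)) for lo, hi in self.copy_ranges)
        object.__setattr__(self, "copy_ranges", ranges)
        if len(ranges) != len(self.units):
            raise ValueError("one copy range per unit is required")
        for lo, hi in ranges:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid copy range [{lo}, {hi}]")
        if self.n_alleles < 2:
            raise ValueError("a panel needs at least 2 alleles")
        for rate in (self.flank_snp_rate, self.imperfect_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        for flank in (self.flank5, self.flank3):
            if not set(flank) <= set(BASES):
                raise ValueError("flanks must be ungapped ACGT sequences")


@dataclass(frozen=True)
class AlleleTruth:
    """Everything needed to rebuild one allele from the panel config.

    ``imperfection`` is ``(unit_index, boundary, base)``: ``base`` was
    inserted between tandem copy ``boundary`` and ``boundary + 1`` of unit
    ``unit_index`` (or ``None``).  SNP tuples are ``(0-based position,
    substituted base)`` within the respective flank.
    """

    copies: tuple[int, ...]
    imperfection: tuple[int, int, str] | None
    flank5_snps: tuple[tuple[int, str], ...]
    flank3_snps: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class AlleleSet:
    """A generated panel: sequences plus per-allele ground truth."""

    config: SimConfig
    names: tuple[str, ...]
    sequences: tuple[str, ...]
    truths: tuple[AlleleTruth, ...]

    def ssr_region(self, index: int) -> str:
        seq = self.sequences[index]
        return seq[len(self.config.flank5) : len(seq) - len(self.config.flank3)]


def _apply_snps(flank: str, snps: Sequence[tuple[int, str]]) -> str:
    out = list(flank)
    for pos, base in snps:
        out[pos] = base
    return "".join(out)


def reconstruct_allele(cfg: SimConfig, truth: AlleleTruth) -> str:
    """Rebuild a sequence from its truth record (the AlleleSet invariant)."""
    pieces: list[str] = []
    for i, (unit, copies) in enumerate(zip(cfg.units, truth.copies)):
        run = unit * copies
        if truth.imperfection is not None and truth.imperfection[0] == i:
            _, boundary, base = truth.imperfection
            cut = boundary * len(unit)
            run = run[:cut] + base + run[cut:]
        pieces.append(run)
    return (
        _apply_snps(cfg.flank5, truth.flank5_snps)
        + "".join(pieces)
        + _apply_snps(cfg.flank3, truth.flank3_snps)
    )


def _draw_snps(
    rng: np.random.Generator, flank: str, rate: float
) -> tuple[tuple[int, str], ...]:
    snps: list[tuple[int, str]] = []
    if rate > 0.0:
        for pos, ref in enumerate(flank):
            if rng.random() < rate:
                alt = str(rng.choice([b for b in BASES if b != ref]))
                snps.append((pos, alt))
    return tuple(snps)


def generate_alleles(cfg: SimConfig) -> AlleleSet:
    """Generate a panel deterministically from ``cfg.seed``.

    Each allele draws one copy number per unit uniformly from its range.  With
    probability ``imperfect_rate`` one interrupting residue — a base that does
    not occur in the affected unit (so it always breaks the tandem match) — is
    inserted at a random boundary strictly inside a run with >= 2 copies.
    """
    rng = np.random.default_rng(cfg.seed)
    names: list[str] = []
    sequences: list[str] = []
    truths: list[AlleleTruth] = []
    width = len(str(cfg.n_alleles))
    for k in range(cfg.n_alleles):
        copies = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in cfg.copy_ranges
        )
        imperfection: tuple[int, int, str] | None = None
        if cfg.imperfect_rate > 0.0 and rng.random() < cfg.imperfect_rate:
            eligible = [i for i, c in enumerate(copies) if c >= 2]
            if eligible:
                ui = int(rng.choice(eligible))
                boundary = int(rng.integers(1, copies[ui]))
                unit = cfg.units[ui]
                pool = [b for b in BASES if b not in unit] or [
                    b for b in BASES if b != unit[0]
                ]
                imperfection = (ui, boundary, str(rng.choice(pool)))
        truth = AlleleTruth(
            copies=copies,
            imperfection=imperfection,
            flank5_snps=_draw_snps(rng, cfg.flank5, cfg.flank_snp_rate),
            flank3_snps=_draw_snps(rng, cfg.flank3, cfg.flank_snp_rate),
        )
        names.append(f"allele_{k + 1:0{width}d}")
        sequences.append(reconstruct_allele(cfg, truth))
        truths.append(truth)
    return AlleleSet(cfg, tuple(names), tuple(sequences), tuple(truths))


def naive_overlap_alignment(alleles: AlleleSet) -> Alignment:
    """Left-justify every SSR region and pad right with gaps to the longest.

    This deliberately lets different units share columns, as generic aligners
    do for compound SSRs; degapping any row recovers the original allele.
    """
    f5 = len(alleles.config.flank5)
    f3 = len(alleles.config.flank3)
    ssrs = [alleles.ssr_region(i) for i in range(len(alleles.sequences))]
    width = max(len(s) for s in ssrs)
    rows = tuple(
        seq[:f5] + ssr + "-" * (width - len(ssr)) + (seq[len(seq) - f3 :] if f3 else "")
        for seq, ssr in zip(alleles.sequences, ssrs)
    )
    return Alignment(alleles.names, rows)


def ssr_window(alleles: AlleleSet) -> tuple[int, int]:
    """1-based inclusive column window of the SSR in the naive alignment."""
    f5 = len(alleles.config.flank5)
    width = max(
        len(alleles.ssr_region(i)) for i in range(len(alleles.sequences))
    )
    return f5 + 1, f5 + width


def random_flank(length: int, seed: int) -> str:
    """A fixed pseudo-random ACGT flank of the given length."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def case_config(
    case: str,
    *,
    n_alleles: int = 26,
    seed: int = 0,
    flank_len: int = 150,
    copy_spread: int = 5,
    flank_snp_rate: float = 0.0,
    imperfect_rate: float = 0.0,
) -> SimConfig:
    """A SimConfig emulating one of the five preset locus designs (A-E).

    Copy ranges span the design's reference counts +/- ``copy_spread``
    (floored at 1 so every unit is present in every allele); flanks are fixed
    150 bp pseudo-random sequences shared by all alleles, reflecting the
    conserved flanking regions real SSR markers rely on.
    """
    try:
        units, refs = CASE_DESIGNS[case.upper()]
    except KeyError:
        raise ValueError(f"unknown case {case!r}; choose one of A-E") from None
    rng = np.random.default_rng(seed)
    flank5 = "".join(rng.choice(list(BASES), size=flank_len))
    flank3 = "".join(rng.choice(list(BASES), size=flank_len))
    return SimConfig(
        units=units,
        copy_ranges=tuple((max(1, c - copy_spread), c + copy_spread) for c in refs),
        n_alleles=n_alleles,
        flank5=flank5,
        flank3=flank3,
        flank_snp_rate=flank_snp_rate,
        imperfect_rate=imperfect_rate,
        seed=int(rng.integers(0, 2**31)),
    )


def format_truth(alleles: AlleleSet) -> str:
    """Tab-separated truth sidecar: name, per-unit copies, imperfection, SNPs."""
    cfg = alleles.config
    header = (
        ["name"]
        + [f"copies_{u}" for u in cfg.units]
        + ["imperfection", "flank5_snps", "flank3_snps"]
    )
    lines = ["\t".join(header)]
    for name, truth in zip(alleles.names, alleles.truths):
        imp = (
            "."
            if truth.imperfection is None
            else "{}:{}:{}".format(*truth.imperfection)
        )
        f5 = ";".join(f"{p}:{b}" for p, b in truth.flank5_snps) or "."
        f3 = ";".join(f"{p}:{b}" for p, b in truth.flank3_snps) or "."
        lines.append(
            "\t".join([name, *map(str, truth.copies), imp, f5, f3])
        )
    return "\n".join(lines) + "\n"


def write_truth(alleles: AlleleSet, path: str | Path) -> None:
    Path(path).write_text(format_truth(alleles))
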