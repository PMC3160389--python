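"""Independent oracles for the greedy SSR partitioner.

Two pieces, deliberately separate from the implementation:

* ``all_decompositions`` enumerates every content-preserving split of a window
  into prefix + per-unit (run, unmatched) blocks, with no greediness built in.
* ``satisfies_greedy_constraints`` is a declarative statement of the greedy
  left-to-right scan: the prefix ends at the first match of unit 1, each run
  is maximal, and unmatched stretches contain no start of the next unit and
  end exactly where the next unit begins (or at the window end).

``brute_force_partition`` filters the enumeration through the constraints and
asserts the survivor is unique.  It is exponential in the window length, so it
is used exhaustively only on short windows; the constraint checker alone is
linear and scales to the full window-length-12 sweep.
"""

from __future__ import annotations

from typing import Iterator, Sequence

Blocks = tuple[tuple[str, int, str], ...]  # (unit, copies, unmatched) per block


def _block_splits(s: str, units: Sequence[str], i: int) -> Iterator[Blocks]:
    if i == len(units):
        if s == "":
            yield ()
        return
    unit = units[i]
    copies = 0
    while True:
        body = unit * copies
        if not s.startswith(body):
            break
        rest = s[len(body):]
        if i == len(units) - 1:
            yield ((unit, copies, rest),)
        else:
            for cut in range(len(rest) + 1):
                for tail in _block_splits(rest[cut:], units, i + 1):
                    yield ((unit, copies, rest[:cut]),) + tail
        copies += 1


def all_decompositions(
    window: str, units: Sequence[str]
) -> list[tuple[str, Blocks]]:
    """Every (prefix, blocks) whose concatenation reproduces the window."""
    out: list[tuple[str, Blocks]] = []
    for p in range(len(window) + 1):
        for blocks in _block_splits(window[p:], units, 0):
            out.append((window[:p], blocks))
    return out


def satisfies_greedy_constraints(
    window: str, units: Sequence[str], prefix: str, blocks: Blocks
) -> bool:
    """Declarative characterization of the greedy non-resuming partition."""
    if prefix + "".join(u * c + um for u, c, um in blocks) != window:
        return False
    if tuple(u for u, _, _ in blocks) != tuple(units):
        return False
    L = len(window)
    u1 = units[0]
    # prefix stops at the first occurrence of unit 1
    for q in range(len(prefix)):
        if window.startswith(u1, q):
            return False
    pos = len(prefix)
    if pos < L and not window.startswith(u1, pos):
        return False
    for i, (unit, copies, unmatched) in enumerate(blocks):
        if not window.startswith(unit * copies, pos):
            return False
        pos += copies * len(unit)
        if window.startswith(unit, pos):  # run must be maximal
            return False
        if i + 1 < len(blocks):
            nxt = units[i + 1]
            for q in range(pos, pos + len(unmatched)):
                if window.startswith(nxt, q):  # next unit may not start inside
                    return False
            pos += len(unmatched)
            if pos < L and not window.startswith(nxt, pos):
                return False
        else:
            if window[pos:] != unmatched:
                return False
            pos = L
    return True


def brute_force_partition(
    window: str, units: Sequence[str]
) -> tuple[str, Blocks]:
    """The unique decomposition satisfying the greedy constraints."""
    hits = [
        (prefix, blocks)
        for prefix, blocks in all_decompositions(window, units)
        if satisfies_greedy_constraints(window, units, prefix, blocks)
    ]
    assert len(hits) == 1, f"{window!r}: {len(hits)} greedy decompositions"
    return hits[0]
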