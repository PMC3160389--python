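import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssralign import (
    Alignment,
    PartitionedSSR,
    SSRSpec,
    UnitBlock,
    WindowError,
    assemble_blocks,
    degap,
    match_run,
    partition_sequence,
    realign,
    ssr_fraction,
)
from ssralign.core import NoRepeatFoundWarning

from _oracles import brute_force_partition, satisfies_greedy_constraints


@pytest.mark.parametrize(
    "gapped,clean",
    [("TA--TA", "TATA"), ("----", ""), ("ACGT", "ACGT")],
)
def test_degap(gapped, clean):
    assert degap(gapped) == clean


class TestMatchRun:
    @pytest.mark.parametrize(
        "seq,pos,unit,expected",
        [
            ("TATATACA", 1, "TA", 3),
            ("TATATACA", 7, "CA", 1),
            ("GGGG", 1, "TA", 0),
            ("TATA", 5, "TA", 0),  # pos one past the end is legal, matches nothing
        ],
    )
    def test_examples(self, seq, pos, unit, expected):
        assert match_run(seq, pos, unit) == expected

    def test_agrees_with_exhaustive_definition(self):
        # maximal k with seq[pos-1 : pos-1+k*|u|] == u*k, checked for every pos
        for seq in ("TATATACA", "TATAT", "CACACACG", "AAAA"):
            for unit in ("TA", "CA", "A"):
                for pos in range(1, len(seq) + 2):
                    best = max(
                        k
                        for k in range(len(seq) + 1)
                        if seq[pos - 1 : pos - 1 + k * len(unit)] == unit * k
                        and pos - 1 + k * len(unit) <= len(seq)
                    )
                    assert match_run(seq, pos, unit) == best

    def test_pos_out_of_range(self):
        with pytest.raises(ValueError):
            match_run("TATA", 0, "TA")
        with pytest.raises(ValueError):
            match_run("TATA", 6, "TA")


class TestPartition:
    @pytest.mark.parametrize(
        "window,units,prefix,blocks",
        [
            ("TATACACACA", ("TA", "CA"), "", (("TA", 2, ""), ("CA", 3, ""))),
            ("TATAGCACA", ("TA", "CA"), "", (("TA", 2, "G"), ("CA", 2, ""))),
            ("GGTATA", ("TA",), "GG", (("TA", 2, ""),)),
            ("", ("TA", "CA"), "", (("TA", 0, ""), ("CA", 0, ""))),
            # interrupted run does not resume: trailing TA copies stay unmatched
            ("TACTATA", ("TA", "CA"), "", (("TA", 1, "CTATA"), ("CA", 0, ""))),
            # N matches no unit
            ("TANTACA", ("TA", "CA"), "", (("TA", 1, "NTA"), ("CA", 1, ""))),
        ],
    )
    def test_examples(self, window, units, prefix, blocks):
        part = partition_sequence(window, units)
        assert part.prefix == prefix
        assert tuple((b.unit, b.copies, b.unmatched) for b in part.blocks) == blocks

    def test_no_match_yields_pure_prefix_with_warning(self):
        with pytest.warns(NoRepeatFoundWarning):
            part = partition_sequence("GGGG", ("TA", "CA"))
        assert part.prefix == "GGGG"
        assert all(b.copies == 0 and b.unmatched == "" for b in part.blocks)

    def test_gap_in_window_rejected(self):
        with pytest.raises(ValueError, match="degap"):
            partition_sequence("TA-TA", ("TA",))

    @pytest.mark.parametrize(
        "units", [(), ("TATATAG",), ("TA", "TA"), ("T-",), ("ta", "TA")]
    )
    def test_invalid_units_rejected(self, units):
        with pytest.raises(ValueError):
            partition_sequence("TATA", units)

    @given(window=st.text("TACGN", max_size=40))
    def test_content_preservation(self, window):
        part = partition_sequence(window, ("TA", "CA"))
        assert part.reconstruct() == window

    def test_matches_enumeration_oracle_exhaustively(self):
        # every window up to 7 bp over {T,A,C}: enumerate all decompositions,
        # keep the unique greedy one, compare
        units = ("TA", "CA")
        for length in range(8):
            for tup in itertools.product("TAC", repeat=length):
                window = "".join(tup)
                part = partition_sequence(window, units)
                got = (
                    part.prefix,
                    tuple((b.unit, b.copies, b.unmatched) for b in part.blocks),
                )
                assert got == brute_force_partition(window, units)

    def test_phase_overlapping_units_resolved_by_block_order(self):
        # TA consumes greedily before AT gets a chance
        part = partition_sequence("TATAT", ("TA", "AT"))
        assert [(b.unit, b.copies, b.unmatched) for b in part.blocks] == [
            ("TA", 2, "T"),
            ("AT", 0, ""),
        ]


class TestAssemble:
    def test_two_sequence_example(self):
        units = ("TA", "CA")
        parts = [
            partition_sequence("TATACACACA", units),
            partition_sequence("TATATACACA", units),
        ]
        assert assemble_blocks(parts, units) == ["TATA--CACACA", "TATATACACA--"]

    def test_unmatched_right_aligned_against_next_block(self):
        units = ("TA",)
        parts = [partition_sequence(w, units) for w in ("TATAG", "TATA")]
        assert assemble_blocks(parts, units) == ["TATAG", "TATA-"]

    def test_single_sequence_is_unchanged(self):
        units = ("TA", "CA")
        part = partition_sequence("GGTATAGCACA", units)
        assert assemble_blocks([part], units) == ["GGTATAGCACA"]

    def test_empty_parts_rejected(self):
        with pytest.raises(ValueError):
            assemble_blocks([], ("TA",))

    def test_mismatched_units_rejected(self):
        part = PartitionedSSR("", (UnitBlock("TA", 1, ""),))
        with pytest.raises(ValueError):
            assemble_blocks([part], ("CA",))


UNIT_POOL = ("TA", "CA", "CG", "TG", "GAA", "GAT")


@st.composite
def window_panels(draw):
    """A unit list plus several ungapped windows to partition against it."""
    k = draw(st.integers(1, 3))
    units = tuple(draw(st.permutations(UNIT_POOL)))[:k]
    n = draw(st.integers(1, 6))
    windows = [draw(st.text("ACGTN", max_size=30)) for _ in range(n)]
    return units, windows


class TestRealign:
    def test_micro_example(self, micro_alignment):
        out = realign(micro_alignment, SSRSpec(("TA", "CA"), 3, 10))
        assert out.rows == ("GGTATA--CACAGG", "GGTATATACA--GG")
        assert out.names == micro_alignment.names

    def test_window_out_of_range(self, micro_alignment):
        with pytest.raises(WindowError):
            realign(micro_alignment, SSRSpec(("TA",), 3, 99))

    def test_idempotent_on_own_output(self, micro_alignment):
        spec = SSRSpec(("TA", "CA"), 3, 10)
        once = realign(micro_alignment, spec)
        # output window spans the same block region, now 2 columns wider
        spec2 = SSRSpec(("TA", "CA"), 3, once.length - 2)
        assert realign(once, spec2) == once

    def test_gapped_input_window_is_degapped_first(self):
        aln = Alignment(("a", "b"), ("GGTA--TACAGG", "GGTATATACAGG"))
        out = realign(aln, SSRSpec(("TA", "CA"), 3, 10))
        assert out.rows == ("GGTATA--CAGG", "GGTATATACAGG")

    @given(panel=window_panels())
    def test_shape_content_and_non_overlap(self, panel):
        units, windows = panel
        flank5, flank3 = "GGG", "CCC"
        parts = [partition_sequence(w, units) for w in windows]
        rows = tuple(
            flank5 + assembled + flank3
            for assembled in assemble_blocks(parts, units)
        )
        assert len(set(map(len, rows))) == 1  # assemble guarantees equal lengths
        aln = Alignment(tuple(f"s{i}" for i in range(len(rows))), rows)

        # shape formula: flanks + P + sum_i (C_i |u_i| + U_i)
        P = max(len(p.prefix) for p in parts)
        widths = [
            max(p.blocks[i].copies for p in parts) * len(units[i])
            + max(len(p.blocks[i].unmatched) for p in parts)
            for i in range(len(units))
        ]
        assert aln.length == len(flank5) + P + sum(widths) + len(flank3)

        if P + sum(widths) == 0:
            return  # all windows empty: nothing to realign

        # content preservation through the full realign pipeline
        spec = SSRSpec(units, len(flank5) + 1, aln.length - len(flank3))
        out = realign(aln, spec)
        for before, after in zip(aln.rows, out.rows):
            assert degap(after) == degap(before)

        # non-overlap: inside unit i's repeat field every row holds whole
        # copies of unit i followed by gaps only
        col = len(flank5) + P
        for i, unit in enumerate(units):
            c_width = max(p.blocks[i].copies for p in parts) * len(unit)
            for row in out.rows:
                field = row[col : col + c_width]
                stripped = field.rstrip("-")
                assert set(field[len(stripped):]) <= {"-"}
                assert len(stripped) % len(unit) == 0
                assert stripped == unit * (len(stripped) // len(unit))
            col += c_width + max(len(p.blocks[i].unmatched) for p in parts)

    @given(panel=window_panels())
    def test_realigned_windows_satisfy_greedy_constraints(self, panel):
        units, windows = panel
        for w in windows:
            part = partition_sequence(w, units)
            assert satisfies_greedy_constraints(
                w,
                units,
                part.prefix,
                tuple((b.unit, b.copies, b.unmatched) for b in part.blocks),
            )


class TestSsrFraction:
    @pytest.mark.parametrize(
        "ssr,total,expected",
        [(54, 351, 15.4), (100, 397, 25.2), (160, 457, 35.0),
         (182, 479, 38.0), (72, 769, 9.4), (100, 100, 100.0)],
    )
    def test_values(self, ssr, total, expected):
        assert ssr_fraction(ssr, total) == expected

    @pytest.mark.parametrize("ssr,total", [(0, 10), (10, 0), (-1, 10), (11, 10)])
    def test_invalid_lengths(self, ssr, total):
        with pytest.raises(ValueError):
            ssr_fraction(ssr, total)
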