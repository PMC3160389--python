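# Methods

## The realignment model

An SSR locus is specified by an ordered list of repeat units
`u₁, u₂, …, u_k` (each 1–6 bp over ACGT; two identical consecutive units are
one unit) and a 1-based inclusive column window `[first, last]` of the input
alignment. The model assumption is that variation inside the window is
dominated by replication slippage: alleles differ in per-unit tandem copy
numbers, so the biologically faithful alignment of the window pairs repeat
copies only with copies of the *same* unit, and expresses copy-number
differences as gaps. Substitution-like signal belongs to the conserved flanks,
which are left untouched.

### Partitioning (per sequence)

The window content is degapped (the input arrives from a generic aligner and
may contain gaps that would corrupt unit matching) and scanned once, left to
right:

1. **Prefix** — residues are consumed until the first position where `u₁`
   matches. If `u₁` never matches, the entire window becomes prefix and a
   `NoRepeatFoundWarning` is emitted; content is preserved regardless.
2. **Run of block i** — the maximal number of consecutive copies of `uᵢ`
   starting at the cursor (`copies ≥ 0`; a single copy counts as a run).
3. **Unmatched of block i** — residues are appended one at a time until the
   cursor starts a match of `u_{i+1}` (then block *i+1* begins) or, for the
   final block, until the window is exhausted.

The scan is greedy and **non-resuming**: once a run is interrupted, later
copies of the same unit that occur before the next unit begins stay in the
unmatched stretch. For imperfect SSRs this is a genuine modelling choice, not
a forced one — an interrupted run could alternatively resume after the
interruption. Non-resuming matches the single-pass, temporary-array structure
of the procedure and keeps the decomposition unique; the trade-off is that a
long run with an early interruption is rendered as one short run plus a long
unmatched stretch. `N` matches no unit and flows into prefix/unmatched.
Matching is case-insensitive (sequences are uppercased on read). When units
overlap in phase (e.g. `TA` followed by `AT` on `TATAT…`), earlier blocks
consume greedily first, which makes the result deterministic by construction.

The decomposition satisfies a content-preservation invariant — prefix +
Σ(unitᵢ × copiesᵢ + unmatchedᵢ) equals the degapped window exactly — and is
the unique decomposition satisfying a declarative set of greedy constraints
(prefix minimal, runs maximal, unmatched stretches free of the next unit's
start). The test suite verifies uniqueness by exhaustive enumeration on all
windows ≤ 7 bp over {T,A,C} and checks the constraints on all ~800 000
windows ≤ 12 bp.

### Reassembly

Let `P` be the longest prefix, `Cᵢ` the largest copy number and `Uᵢ` the
longest unmatched stretch of block *i* over all sequences. Each output row is

```
prefix right-aligned to width P
│ (uᵢ)^copies left-aligned to width Cᵢ·|uᵢ| │ unmatched right-aligned to width Uᵢ │ …
```

so every realigned row has length `P + Σᵢ (Cᵢ·|uᵢ| + Uᵢ)`. Left-aligning runs
puts the slippage gap at the run's 3′ end; right-aligning the unmatched
residues places interruptions after that gap and immediately before the next
repeated unit (or the 3′ flank), the natural position under a slippage model
in which imperfections suppress further slippage. The prefix is right-aligned
against block 1 for the symmetric reason. Realignment is idempotent: running
it again on its own output (with the window updated to the new block extent)
is a fixed point.

## Distances and trees

* **p-distance, pairwise deletion.** The evaluation distance is the
  uncorrected proportion of mismatches among sites where neither sequence has
  a gap; `N` is treated as missing data and excluded the same way. This is
  the simplest distance consistent with "overall pairwise distance" reporting
  and makes the before/after comparison transparent: every overlap column
  contributes mismatches before realignment and a gap (excluded site) after.
  A pair with no comparable site gets distance 0 with a warning.
* **PV (overall pairwise value)** is the arithmetic mean of the strict upper
  triangle of the distance matrix.
* **UPGMA** joins the closest pair, places the new node at half the joined
  distance and averages cluster distances weighted by cluster size. Ties are
  broken deterministically toward the pair with the lowest cluster-creation
  indices (the order any given software resolves ties in is arbitrary; this
  one makes runs byte-reproducible). Output trees are ultrametric to 1e-9 and
  serialized as standard Newick with branch lengths; labels containing
  Newick-special characters are single-quoted.

The distance-matrix type enforces symmetry, zero diagonal and non-negativity
but not an upper bound of 1, so UPGMA can also be used on distances other
than p-distances.

## Synthetic panels

The generator emulates allele panels at a single SSR locus: fixed conserved
flanks, per-unit copy numbers drawn uniformly from configured ranges,
optionally one interrupting residue per allele (probability `imperfect_rate`)
inserted at a random boundary strictly inside a run of ≥ 2 copies — the
inserted base never occurs in the affected unit, so it always breaks the
tandem match — and optional flank SNPs at a per-site rate. Every draw is
recorded in a truth sidecar from which each emitted sequence can be rebuilt
exactly; generation is deterministic per seed.

Five preset designs (A–E) emulate 26-allele panels at loci of increasing
complexity: (TA)₁₀; (TA)₁₀(CA)₁₆; (TA)₁₀(CA)₁₆(CG)₁₄;
(TA)₁₀(CA)₁₆(CG)₁₄(TG)₁₈; and (GAA)₄(GAT)₆(GAGGAT)₃. Copy ranges span the
design's reference counts ± 5 (floored at 1 so every unit is present in every
allele, which keeps the ground truth recoverable); flanks are fixed 150 bp
pseudo-random sequences per config seed. These values were chosen once as
typical of dinucleotide SSR marker panels and are defaults, not fitted
quantities.

`naive_overlap_alignment` builds the flawed baseline the realigner is
measured against: each SSR region left-justified and right-padded with gaps.
This reproduces the qualitative artifact of generic aligners — different
units sharing columns — but not their full behaviour (no gap-penalty-driven
gap placement, no flank misalignment). Consequently, passing pipeline tests
demonstrate the overlap-removal mechanism, not performance on arbitrary
real-world aligner output; with slippage-only panels the post-realignment PV
is exactly 0, whereas on real data residual flank polymorphism keeps it
positive.

## Numerical and interface choices

* Window coordinates are 1-based inclusive columns, matching how SSR loci are
  reported; they are converted internally to 0-based half-open.
* `ssr_fraction` returns `100·ssr/total` rounded to one decimal, the
  convention used in locus summary tables.
* FASTA is written wrapped at 70 columns; readers accept any wrapping. The
  SALT table header is validated against the actual row count and (gapped)
  row length — mismatches are errors, not warnings. `.` gaps are normalized
  to `-`; `U` (RNA) is rejected.
* Degenerate inputs: an empty window partitions to an empty prefix and
  all-zero blocks; a window where the first unit never matches becomes pure
  prefix (warning); `assemble_blocks` on a single sequence returns the window
  unchanged.
* Problem sizes: tests and the acceptance script use 26-allele panels (the
  size of the reference panels the presets emulate), 150 bp flanks, and the
  exhaustive partition sweeps described above.

## Known limitations

* One SSR window per call; disjoint loci are realigned by running the tool
  once per window.
* The non-resuming rule can fragment heavily imperfect SSRs (see above).
* p-distance carries no multiple-hit correction; for the short, closely
  related alleles this tooling targets that is adequate, but deep divergences
  would need corrected distances.
* UPGMA assumes a clock (ultrametricity); it is provided because it is the
  standard companion analysis for SSR allele panels, not because it is the
  best tree method available.
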