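# ssralign

Slippage-aware realignment of microsatellite (SSR) regions in multiple
sequence alignments.

## The problem

Microsatellites — simple sequence repeats (SSRs) — are tandem repeats with a
unit of 1–6 bp. Their dominant mutational process is replication slippage,
which changes the tandem *copy number* of a unit without substituting bases,
so allelic variation at an SSR locus is insertion/deletion-like. General
purpose aligners are tuned for substitution-dominated sequence and, inside a
compound SSR such as (TA)ₙ(CA)ₘ, happily place copies of *different* units in
the same column. Every such "overlap" column is scored as a substitution that
never happened, inflating pairwise distances and distorting the trees built
from them.

`ssralign` post-processes an existing alignment. Given the ordered repeat
units and the 1-based column window `[first, last]` of the SSR locus, it
degaps each sequence's window, decomposes it greedily into

```
prefix | (unit₁)^c₁ | unmatched₁ | (unit₂)^c₂ | unmatched₂ | …
```

and reassembles the window into non-overlapping per-unit blocks: within block
*i* every row holds whole copies of unitᵢ, left-aligned and gap-padded to the
longest run, so alleles that differ only by slippage align with gaps instead
of substitutions. Interrupting ("imperfect") residues are placed right-aligned
against the next block — after the slippage gap and before the next repeated
unit. Flanking columns are copied verbatim and no residue is ever created or
lost.

The package also ships the evaluation machinery used to measure the effect —
uncorrected p-distances with pairwise deletion, the overall pairwise value
(PV, the mean of all pairwise distances), and UPGMA trees with Newick export —
plus a synthetic allele generator with ground truth, so the whole pipeline is
testable without any external data.

## Worked example

Simulate a 6-allele panel at a compound (TA)₈₋₁₂(CA)₁₄₋₁₈ locus with 12 bp
conserved flanks, emitting the naive left-justified baseline alignment a
generic aligner would produce:

```sh
$ ssr-realign simulate --units "TA CA" --copies "8:12 14:18" --n 6 --seed 7 \
      --flank-len 12 --out panel.fasta --truth panel.truth.tsv
$ ssr-realign compare --in panel.fasta --units "TA CA" --first 13 --last 70
pv_before	pv_after	pv_delta	length_before	length_after
0.026967	0.000000	0.026967	82	84
```

The baseline alignment has a mean pairwise distance (PV) of 0.026967 even
though the six alleles differ *only* in TA/CA copy numbers: columns where one
allele's CA run starts under another allele's TA run are counted as
substitutions. After realignment the PV is exactly 0 — the variation collapses
into gap columns — at the cost of two extra alignment columns (82 → 84).
`compare` also writes `panel.before.nwk` / `panel.after.nwk` UPGMA trees.
Looking at two of the rows makes the mechanism visible:

```
naive      ...TATATATATATATATATATATATATACACACACA...   allele_1
           ...TATATATATATATATACACACACACACACACACA...   allele_5  (CA under TA)

realigned  ...TATATATATATATATATATATATATACACACACA...   allele_1
           ...TATATATATATATATA----------CACACACA...   allele_5  (gap, no mismatch)
```

The realignment itself is available as `ssr-realign realign --in … --out …
--units "TA CA" --first 13 --last 70`, and as the library call
`realign(alignment, SSRSpec(("TA", "CA"), 13, 70))`. Input alignments may be
FASTA or the two-line-header "SALT table" text format (`<n_samples>
<n_columns>` header, then `<name> <sequence>` per line).

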