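# Methods

## Model and procedure

`bildcut` decides, for each query read, which prefix of its ranked
BLAST hit list is phylogenetically inseparable from it. The decision is
cast as model comparison on a query-anchored multiple alignment: for a
horizontal cut after the *i*-th ranked hit, each alignment column is
scored by the log-odds of two independent Dirichlet-multinomial columns
(top group vs bottom group) against a single column, with the column's
nucleotide-frequency vector integrated out under a Dirichlet prior.
Writing **c** for a column's nucleotide counts and α for the prior,

L(**c**) = ln[Γ(α\*)/Γ(α\*+c\*) · ∏ₖ Γ(αₖ+cₖ)/Γ(αₖ)],
V = L(**x**) + L(**y**) − L(**x**+**y**),

and the cut score V_i sums V over columns weighted by (e_j)^a, where
e_j is the base-4 entropy of the full column. Positive V_i means the
two-group model explains the column data better. The first index whose
score is non-negative and strictly dominates both neighbours ends the
outlier set; the query receives the lowest common ancestor (longest
common prefix) of the outliers' six-rank lineages, and a query with no
qualifying peak stays unclassified by design — the method is meant as a
high-precision filter in front of slower phylogenetic placement, so
declining is cheap and guessing is expensive.

Assumptions worth stating: the BLAST pairwise alignments are taken as
given (no realignment); columns are treated independently; the alphabet
is strictly A/C/G/T, with ambiguity codes contributing nothing to any
count; and the ranked order of hits by bit-score is a sensible
one-dimensional proxy for phylogenetic proximity, which is exactly the
assumption the cut-score series is designed to interrogate rather than
trust blindly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (prior) | (½, ½, ½, ½) | Jeffreys' Dirichlet prior; α\* = 2. Uninformative yet proper; any positive 4-vector is accepted. |
| a | 2.7 | exponent on the column entropy weight. Larger values concentrate the score on diverse columns; 0 would weight all non-conserved columns equally (weight e_j⁰ at e_j>0), and the value 2.7 is the published operating point of the method. |
| coverage_min | 0.90 | hits whose local alignment covers ≤ 90 % of the query are discarded (strict inequality: exactly 90 % is out). Coverage is computed from query coordinates, not alignment length, so gaps do not inflate it. |
| max_hits | 100 | size cap of the ranked set, matching the BLAST `-max_target_seqs` the format targets. |
| min_edge_weight | 20 | co-occurrence edges below this count are removed before component analysis. |

Natural logarithms are used throughout. The classification decision
depends only on signs and the ordering of scores, both invariant under
change of log base; a property test pins this down.

## Numerical choices

Γ is never evaluated directly: all column scores go through `gammaln`,
and the vectorised cut-series path replaces per-element `gammaln` calls
with lookup tables over integer counts (every argument is αₖ + k for
small integer k), which makes a 100-hit × 1500-column query score in
milliseconds. Columns whose visible count total is zero are skipped:
their entropy is defined as 0 and their split score is identically 0,
so they cannot influence any decision. Ties in bit-score keep BLAST's
output order (stable sort); ties in the cut-score series are not peaks
(strict inequalities).

Two boundary cases of the first-peak scan were genuinely open and were
resolved as follows. At i = 0 the cut puts the query alone above the
line; a peak there yields an empty outlier set and hence an
unclassified query (there are no labels to aggregate). At the far end,
the cut with an empty bottom group scores identically zero — it *is*
the unsplit model — so the final index is never a peak candidate and
serves only as right-neighbour context. The alternative (letting the
final index qualify whenever its left neighbour is lower) would turn
every all-negative series into a spurious "all hits are outliers" call,
contradicting the rule that negative scores favour a single alignment.

Lineages are compared by exact, case-sensitive string match per rank;
lineages that skip ranks are rejected at parse time rather than
patched, because silently repairing them would mask exactly the
database curation errors the co-occurrence analysis is meant to
surface.

## Synthetic data generator

The generator grows a six-rank taxonomy from a single random root
sequence by point substitution. `n_genera` is factorised into per-rank
branching factors with the fan-out pushed toward the leaves (20 → 2
orders × 2 families × 5 genera), mirroring how real taxonomies widen
near the genus level; every genus emits `seqs_per_genus` leaves. The
divergence vector gives the substitution fraction on branches leaving
each rank, with the Genus entry governing the leaf branches, so
"genus-level divergence 2 %" means members of a genus each differ from
their genus ancestor by 2 % (≈ 4 % pairwise, ≈ 96 % identity) and
"family-level 10 %" puts sibling genera ≈ 78 % identity apart. Defaults
are full-length sequences (1500 nt) with divergences
(0.13, 0.12, 0.11, 0.10, 0.10, 0.02) from Kingdom down to Genus: 16S is
globally conserved, so upper ranks sit just above the family stratum —
pushing them much higher would create within-order identities below
anything BLAST could align end-to-end, which real 16S data never shows.
Divergences may not increase from Kingdom toward Genus and are capped
at 0.75, the expected distance between unrelated sequences.

The BLAST emulator compares the query to every reference as an
ungapped, end-to-end alignment and emits 14-column tabular rows with a
bit-score surrogate 2·matches − 3·mismatches (megablast's default
reward/penalty). Only positive-scoring references produce rows, just as
BLAST reports no alignment without a positive score; under this scoring
that excludes references below ~60 % identity, which megablast could
not seed a full-length alignment on anyway. One integer seed drives
every draw; identical seeds give byte-identical FASTA, taxonomy, and
hit tables.

What the generator deliberately does not model: insertions and
deletions (substitution-only evolution keeps the emulated rows exact,
so the alignment-imposition path with insertion dropping is exercised
by hand-built alignments in the tests instead), rate heterogeneity
across sites, hypervariable-region structure, chimeras, and non-uniform
genus sizes. Passing the synthetic benchmarks therefore demonstrates
that the scoring, peak detection and LCA machinery behave as designed
on cleanly separated clades — not that real 16S accuracy figures carry
over, since real reference databases add alignment noise, ragged
coverage, uneven taxon sampling and annotation errors.

## Evaluation protocols

The harness reproduces two standard protocols on the synthetic
reference. Leave-one-sequence-out removes only the query's own
sequence; leave-one-genus-out removes its whole genus. Per rank, a
query counts as correctly classified when its assigned label matches
the truth, or when it is unassigned and no other database sequence
carries its true label; as misclassified when the assigned label is
wrong; and as falsely unclassified when it is unassigned although the
true label survives in the database. The "label exists independently"
check removes, per query, one copy of its own lineage or its genus's
lineages according to the protocol.

At the default study conditions (20 genera × 5 sequences, 1500 nt,
seed 0) the leave-one-sequence-out run recovers the exact six-rank
lineage for 100/100 queries and the leave-one-genus-out run assigns
100/100 queries their correct family with zero genus-level labels.
Across other seeds the genus-out protocol occasionally (a few per cent
of queries) assigns the single nearest sibling genus when sampling
noise makes one genus block clearly closest — the same rare
failure mode the underlying evaluation methodology reports on real
data — while sequence-out full-lineage recovery stays at 94–100 %.

## Known limitations

The first-peak rule is local: a marginal early peak (a noise wiggle
that clears zero) preempts a far stronger split later in the series.
The co-occurrence graph uses binary per-query membership, so one
promiscuous reference appearing in many small outlier sets can bridge
genera. The emulator's identity floor means synthetic hit lists never
contain the deeply diverged tail that real megablast output can carry
for short highly conserved regions. And the method is tied to the
six-rank lineage model; finer taxonomies (species, strain) are out of
scope.
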