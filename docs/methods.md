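# Methods

## Genome signatures

A sequence's tetranucleotide usage profile (TUP) is the 256-vector of
Z-scores of observed tetranucleotide counts against the maximal-order
Markov expectation, i.e. the count expected given the sequence's own
trinucleotide and dinucleotide composition. Counting conventions:

* Every sequence is extended by its reverse complement. Extension is
  implemented by counting the two strands independently and summing —
  no window spans the junction a literal string concatenation would
  create, since such windows are artifacts of the concatenation order.
  This makes signatures exactly strand-invariant:
  `signature(s) == signature(revcomp(s))` entrywise.
* Any window containing a non-ACGT symbol contributes nothing, at every k.
* Degenerate cases map to Z = 0 rather than missing: if the central
  dinucleotide count N(n₂n₃) is zero, or the variance estimate is ≤ 0.
  This keeps every signature a finite fixed-length vector so that Pearson
  correlation between any two signatures is defined (an all-constant
  signature — possible only for pathological inputs like homopolymers —
  raises an undefined-correlation error, which the screen treats as
  no-hit).
* All 256-entry vectors are serialized in lexicographic order AAAA…TTTT.

## Screening and binning

Contigs shorter than 10 kb are excluded before signatures are computed
(shorter fragments give unstable profiles). A contig is retained when its
TUP correlates at `r_min = 0.6` or over with *any* driver signature —
best-of over drivers, with ties broken by driver id for determinism. All
thresholds in the package are inclusive ("0.6 or over" sets the pattern).

Binning is a pure function of the ORF annotation set:

* `phage` — ≥ 1 ORF whose function label matches the phage lexicon
  (case-insensitive substring: capsid, terminase, tail, portal, integrase,
  holin, lysin, baseplate, "phage", …) **or** ≥ 1 ORF with driver-homology
  evidence. Both lexicons ship as editable text resources
  (`src/pgsr/data/*.txt`) because no closed vocabulary exists for either
  class.
* `non_phage` — no phage-related ORF and ≥ 1 ORF with a chromosomal
  (housekeeping) label. "Dominated by chromosomal functions" is
  operationalized as *any* chromosomal label in the absence of phage
  labels; this is a documented choice, not the only defensible one.
* `unclassified` — anything else, including zero ORFs.

Host affiliation tries the nucleotide level first (top valid hit by bit
score, ≥ 75% identity over ≥ 1 kb at e ≤ 1e−5); only when that fails does
the ORF level apply, requiring ≥ 2 ORFs whose best valid hits agree at the
bacterial order level (the genus is affiliated only if those ORFs also
agree on it). Hit-table ties break by bit score, then e-value, then id.

`find_orfs` is a deliberately naive six-frame ATG→stop caller (standard
genetic code, ATG-only starts) that exists so fixtures are self-contained;
it is not a gene predictor.

## Phylograms

Distances are Pearson dissimilarities d = 1 − r between TUPs (range
[0, 2]; anticorrelated pairs keep d > 1). Neighbor joining follows the
classical Saitou–Nei agglomeration with two deterministic conventions:
equal-Q ties select the pair whose subtrees contain the lexicographically
smallest leaf labels, and a negative branch-length estimate is clamped to
zero with the deficit moved to the sibling branch so the pair's mutual
distance is preserved (the PHYLIP convention). On additive matrices the
algorithm is an exact inverse of tree-to-distance simulation, which the
tests exploit as an oracle (with an independent neighbor-joining
implementation as a cross-check).

Bootstrap supports resample the 256 tetranucleotide **columns** with
replacement, reusing the already-computed Z columns rather than re-deriving
Markov expectations on resampled sequence — the resampling unit is the
feature, not the sequence, and whether the original procedure recomputed
Z-scores per replicate is unknowable from the description; the
column-resampling reading is implemented and documented as such. The
full-data NJ tree is returned with each internal edge annotated by the
percentage of replicates containing the same bipartition; no consensus
topology is built, since supports are displayed on a single phylogram.
A replicate that happens to draw an all-constant signature row is redrawn.

Newick output formats branch lengths and supports with Python's shortest
round-tripping float representation, so write→read→write is byte-identical.

## Profiles

Read-mapping stringency policies (all thresholds inclusive):

| policy | min identity | min read fraction | max mismatch | max gaps |
|--------|--------------|-------------------|--------------|----------|
| high   | 90%          | 0.90              | 0.10         | 0.00     |
| low    | 70%          | 0.25              | 0.10         | 0.10     |
| low75  | 75%          | 0.25              | 0.10         | 0.10     |

`low75` exists because the operational description of the low-stringency
screen and its summary disagree on the identity floor (70 vs 75); the
operational value is the default and the other is selectable. Each read
maps to at most one reference per data set (best identity wins).

Relative abundance is valid hits per Mb of the searched data set
(ORF-level validity: ≥ 35% identity over ≥ 30 aa at e ≤ 1e−5); read
recruitment is reads mapped per Mb of reference. Habitat categories are a
total, single-valued decision table on normalized gut/non-gut hit rates:
GT (gut only), NG (non-gut only), GAH (both, gut majority), GAL (both,
non-gut majority — ties fall here, as "majority" is strict), UNCLASS (no
hits). The χ² utility is the classical Pearson statistic with
df = (r−1)(k−1) and an upper-tail p; zero expected cells are an error.

## Viral-enterotypes

The phage × sample matrix holds hits/Mb (validity: ≥ 80% identity over
≥ 50% of the subject at e ≤ 1e−5; inclusive); scaffold co-members merge
into single rows by summing. The two-pass heuristic grouping:

* Rows with incidence ≥ 40% of samples are noise for the heuristic only
  (they stay in Bray–Curtis and the ordination).
* Profile similarity is Spearman rank correlation ≥ τ (default 0.6).
  The original procedure specifies neither metric nor threshold — only
  that grouping ignores absolute abundance levels — and rank correlation
  is the natural level-free choice; τ is exposed as a parameter.
* Pass 1 founds up to four lettered groups (A–D) greedily from a seeded
  random start; pass 2 re-assigns every sample to its best pass-1 founder
  (refinement, not re-founding). Samples are processed in sorted-id order
  so the outcome is invariant to input order, up to the identity of the
  random start.

Bray–Curtis is computed over all rows, with d = 0 for a pair of all-zero
columns. NMDS minimizes Kruskal stress-1 with monotone regression of
configuration distances on dissimilarities, taking the best of 20 random
SMACOF starts; stress-1 is computed in-package by isotonic regression on
the final configuration and coordinates are centered. ANOSIM uses Clarke's
R = (r̄_between − r̄_within) / (M/2) on mid-ranked dissimilarities, samples
labelled UC excluded (a heterogeneous leftover set is not a hypothesis
group). When the number of distinct relabelings does not exceed the
requested permutation count, the permutation distribution is enumerated
exhaustively and p is exact; otherwise p = (1 + #{R* ≥ R}) / (1 + N) under
random relabeling. R is invariant to any strictly monotone transform of
the dissimilarities because only ranks enter.

## Synthetic data

Genus composition is an order-3 Markov model (64 trinucleotide contexts ×
4 emissions). This order is chosen deliberately: the TUP Z-score measures
exactly the third-order structure remaining after the maximal-order Markov
expectation is removed, so an order-3 model plants signal that the
statistic can see without being trivially separable. Genus models are
per-context mixtures (1 − δ)·base + δ·own-Dirichlet-draw; δ = 0 gives
identical genera and divergence grows monotonically with δ. The shipped
default δ = 0.75 was calibrated once so that 50 kb samples give
within-genus signature correlations ≈ 0.99 and between-genus ≈ 0.1–0.3,
bracketing the 0.6 screening threshold from both sides
(`calibration_report` re-derives this at run time).

The default community has 3 genera, 120 kb chromosomes each carrying one
30 kb prophage drawn from the *same* genus model (the compositional-
amelioration premise under test), an independent 30 kb driver per genus,
and fragmentation into ≥ 10 kb contigs (mean 15 kb) with cuts forced at
prophage boundaries so each contig's truth label is unambiguous. Fixture
annotation and hit tables are generated consistent with truth, and every
numeric filter receives one decoy record exactly at its threshold and one
a single unit-in-the-last-decimal below, pinning the inclusive-boundary
convention.

The enterotype cohort (40 samples, 4 groups, 60 phage, log-normal
multiplicative noise with CV 0.5) plants per-group template profiles with
log-uniform abundances on [0.1, 10]: 8 phage of each group's own, 4 shared
with each adjacent group on a ring, plus 10 noise phage present in every
sample. The ring overlap reflects the observation that real enterotype-like
groupings overlap rather than separating cleanly, and gives the
between-group Bray–Curtis geometry a low intrinsic dimension so a 2-D
ordination can represent it faithfully.

What the generators do **not** emulate: sequencing error, assembly
artifacts and chimerism, strain-level mosaicism, horizontal transfer,
taxonomically real genomes, or compositional heterogeneity along a
chromosome. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal under the stated
compositional model — not expected field performance on real gut
metagenomes, where signature overlap between unrelated taxa and
boundary-spanning contigs will degrade all rates.

## Problem sizes and numerics

Default test/validation scales: 28-contig community (3 genera), 8-taxon
bootstrap phylograms with 200 replicates, 100 random 4–8-taxon additive
matrices for NJ validation, 40-sample cohort with 999 ANOSIM permutations,
and 1,000 random sequences for the brute-force signature cross-check.
Signature oracle agreement is asserted at 1e−9 entrywise; NJ recovery at
1e−9; correlation-matrix symmetry/PSD at 1e−8 on eigenvalues. All
stochastic stages require an explicit seed and are pure functions of it;
omitting the seed is an error, not a silent default.

## Known limitations

* The screen cannot separate a prophage from its host chromosome by
  composition alone — that is the point of the functional-binning stage —
  so chromosome–prophage junction contigs are binned by whichever evidence
  they carry; no boundary (attL/attR) detection is attempted.
* `heuristic_group` depends on the random starting sample; different seeds
  can found groups from different templates (labels permute, membership is
  stable on well-separated cohorts).
* NMDS is a local optimizer; the restart count bounds but does not
  eliminate the risk of a suboptimal embedding.
* BLAST/CDD/RAST-style searches are consumed as tables, never executed.
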