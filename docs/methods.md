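# Methods

## Ortholog clustering

Proteins from all genomes are pooled and clustered greedily: sequences are
sorted by decreasing length (ties: lexicographically smaller gene id, then
genome id) and each is compared against the representatives of existing
families in creation order, joining the first family it matches; otherwise
it founds a new family with itself as representative. This is the
CD-HIT-style incremental scheme — membership is always judged against the
representative, never against all members.

The membership rule has two parts, both computed from the best local
alignment of the pair (match +1, mismatch −1, gap open −2, gap extend −1
by default; a substitution matrix can be supplied):

- identity = matches / aligned columns (gap columns count in the
  denominator) ≥ 0.5, and
- the aligned region covers ≥ 0.5 of the **shorter** sequence
  (`coverage_mode="both"` switches to requiring it of both sequences).

Two consequences of using the *best-scoring* local alignment are worth
knowing. First, a trailing mismatch is trimmed when dropping it scores
higher, so identity is measured on the optimal local block. Second,
unrelated sequences typically align over a short, nearly exact block:
their *identity* can be high while their *coverage* is tiny, so the joint
rule — not identity alone — is what separates families. The test suite
asserts exactly this joint separation on planted collections.

Paralog removal keeps, per family and genome, the longest member (ties:
smallest gene id) and records the rest; the family count never changes.

An optional 4-mer prescreen skips alignments against representatives that
share no 4-mer with the query. It applies only when both sequences have
≥ 100 residues: at that length related proteins (≥ 50% identity) share
exact 4-mers with overwhelming probability while unrelated ones rarely do;
below it the filter is unsafe and every pair is aligned. Tests verify the
prescreen never changes results on protein-scale instances.

## Pan-matrix and occupancy classes

The binary matrix has one row per family and one column per genome
(1 = the genome has a retained member). Classes come purely from row sums:
all genomes → core, exactly one → singleton, otherwise accessory. In a
single-genome collection every row satisfies both rules; the "all
genomes" condition takes precedence and the summary flags the collection
as degenerate. Reported percentages round half away from zero to match
published table style; exact values are kept in machine-readable output.

## Accumulation curves and openness

For a genome order, pan(k) counts families present in ≥ 1 of the first k
genomes and core(k) families present in all of them. Medians and standard
deviations are taken across orders: all n! orders are enumerated for
n ≤ 7, otherwise 1000 (configurable) seeded uniform random permutations
are sampled — a reproducible, statistically equivalent stand-in for
tool-specific order-selection heuristics. Explicit orders can be supplied
for niche-ordered plots. The mean number of new gene families per added
genome averages pan(k) − pan(k−1) over all orders and steps k ≥ 2.

Median pan points are fitted with the power law `y = A·x^B + C` and core
points with `y = A·e^(B·x) + C`, by least squares (`scipy`'s trust-region
reflective solver, tolerances 1e-10) with the documented starts — power
law: C₀ = y(1), A₀ = y(n) − y(1), B₀ = 0.5; exponential: C₀ = y(n),
A₀ = y(1) − y(n), B₀ = −1 — plus up to 20 jittered restarts, keeping the
best sum of squares; restarting stops early once converged solutions stop
improving (restarts exist to rescue non-convergence, not to re-find the
same optimum). The exponent is bounded to a numerically sane window
(|B| ≤ 10 for the power law, ≤ 50 for the exponential; data exponents in
this problem are O(1)). r² = 1 − SS_res/SS_tot on the fitted median
points.
Flat input (SS_tot = 0) is a degenerate fit: returned with r² = 1 and
`identifiable=False`, since A ≈ 0 and B are not jointly constrained.

Openness follows the Heaps-law reading of the pan exponent: open when
0 < B < 1, closed when B < 0, otherwise undetermined. Extrapolation
evaluates the power law at a chosen x; the core prediction is the
asymptote C, defined only for a decaying exponential (B < 0).

## Niche-exclusive set logic

For a niche N with ≥ 1 genome:

- exclusively present(N): families in ≥ 1 genome of N and in 0 genomes
  outside N (singletons of N's genomes qualify). Requiring presence in
  *all* of N's genomes would be strictly stronger than the niche core,
  which is not how niche-specific counts behave in practice — the ≥ 1
  reading is used.
- exclusively absent(N): families absent from all of N and present in
  *every* genome outside N (undefined for single-niche collections).
- niche pan / niche core: families in ≥ 1 / in all of N's genomes; the
  core is reported as null for single-genome niches, where it would
  trivially equal the pan.

These definitions force the invariants the suite checks: exclusive sets
are pairwise disjoint across niches, exclusive-present ⊆ niche pan, and
exclusive-absent(N) ⊆ niche core(M) for every other niche M. Labels are
free strings compared case-insensitively after trimming.

## Distances, neighbor joining, bootstraps

Binary genome distances on pan-matrix columns: Jaccard
(1 − |∩|/|∪| of family sets, default) or simple matching (fraction of
rows that differ). Core-genome distance: per-family pairwise p-distance
(mismatches / compared positions, gap columns excluded on both sides) from
a global alignment of the two protein sequences (BLOSUM62, gap −11/−1),
aggregated over families weighted by compared positions — with pre-aligned
input this equals the concatenated-alignment p-distance, so externally
aligned marker genes (a 16S-style alignment) drop straight in.

Neighbor joining is the standard Saitou–Nei agglomeration: join the pair
minimizing Q = (m−2)·d(i,j) − r_i − r_j (ties: lowest index pair, for
determinism), NJ branch-length formulas, matrix reduction, final
three-way join solved by the three path equations. Negative branch
lengths are clamped to zero with the deficit moved to the sibling so the
path length through the join is preserved. On additive matrices the
output tree reproduces the input path lengths exactly (tested to 1e-9
against randomly generated trees, and cross-checked topologically against
scikit-bio's NJ).

Bootstrap supports resample characters with replacement — pan-matrix rows,
or alignment columns — rebuild the tree per replicate, and report for each
internal bipartition of the original tree the percentage of replicates
containing it. With < 4 leaves supports are undefined and omitted. Trees
are unrooted (the root shown in Newick is the arbitrary trifurcation);
`root_at` provides outgroup-rooted display. The pan-matrix tree defaults
to 100 replicates; the sequence-tree replicate count is a flag (published
captions differ between 100 and 1000 for such trees — the count here is
deliberately configurable, default 100).

## Codon usage and GC

A genome's codon profile counts frame-1 codons across the concatenated
CDSs of its core gene set (any class subset can be selected). "All coding
triplets" is read as the 61 sense codons: stop codons and codons with
non-ACGT characters are excluded from numerator and denominator; a
64-codon mode exists behind a flag. The distance is the plain sum of
squared frequency differences — bounded by 2 (disjoint point masses),
zero iff the profiles are equal. GC content is (G+C)/(A+C+G+T) with
ambiguity codes ignored.

## Functional profiles and enrichment

Annotations are an input table (family id → set of COG letters or class
names); families without codes are "unannotated", counted separately and
excluded from percentages. A multi-code family contributes one count per
code (an option restricts to single-code families). Enrichment of a
category in a target set versus a disjoint background uses the two-sided
Fisher exact test — computed as the sum of hypergeometric probabilities no
larger than the observed table's (the standard convention, with 1e-7
relative tie slack), verified in tests against exact rational enumeration
for every table with n ≤ 40 and against `scipy.stats.fisher_exact`. A
two-proportion z-test is available as an option; p-values are reported
raw, with Benjamini–Hochberg adjustment behind a flag. Profile vectors
(percentages) are clustered with average linkage on Euclidean distance;
the same routine on the transposed matrix clusters the category axis.

## dN/dS screening

CDS pairs are aligned via their translated proteins (global, BLOSUM62);
gaps map back to codon triplets, and gapped or ambiguous codon columns are
excluded. Unweighted Nei–Gojobori counting then gives:

- synonymous sites per codon: at each position, the fraction of the three
  single-base changes that are synonymous, with changes to stop codons
  removed and the fraction renormalized over the rest; site totals are
  averaged between the two sequences, so N + S = 3 × retained codons holds
  exactly.
- differences per codon pair: equal-weight average over all minimal
  substitution pathways; pathways through a stop codon are discarded (if
  none survive, all pathways are used with stop steps counted as
  nonsynonymous — a documented, rarely reached fallback).
- pN = Nd/N and pS = Sd/S with the Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3), undefined for p ≥ 3/4 (saturation).

dN/dS > 1 (strict) flags positive selection. The ratio is undefined when
dS = 0 or either distance is saturated; such pairs are listed separately
and never flagged. Because a handful of codons can produce spurious
ratios, flagging is additionally gated on ≥ 100 retained codons (the gate
is a parameter; shorter would-be hits are reported in their own list).
Identical sequences give dN = dS = 0: the ratio is undefined but the pair
is reported as not positive. Both the corrected distances and the raw
proportions are emitted, so either convention can be inspected downstream.

## Synthetic collections

The generator plants, in a fixed order: core families (all genomes),
shared accessory (each genome carries the family with probability
p_acc = 0.5, patterns resampled until 1 < carriers < n), exclusive-present
families (each genome of the niche carries with probability 0.7, ≥ 1
forced), exclusive-absent families (pattern fully forced: everyone outside
the niche), and per-genome singletons. One ancestral protein per family is
drawn i.i.d. uniform over the 20-letter alphabet — which makes
between-family similarity as low as random sequences allow, so the
clustering ground truth is unambiguous — and every carrier receives a
substitution-only mutant at the configured within-family identity
(default 0.8, safely above the 0.5 clustering threshold; exactly
`round((1−identity)·L)` positions change, so realized identity is within
0.5/L of the target). Optional paralogs are extra within-genome mutants of
the same ancestor. Protein lengths are normal (mean 250, sd 60) clipped to
[50, 600] — bacterial CDS scale; tests use shorter means purely for speed.

CDSs are back-translations with codon probabilities biased toward the
genome's GC target: codon weight ∝ product over bases of g/2 (G/C) or
(1−g)/2 (A/T), raised to the power 3 and renormalized per amino acid.
The exponent matters: most codon positions are pinned by the amino acid,
so the unsharpened product moves realized genomic GC only a few points;
cubing the weights lets targets of 0.30/0.60 realize clearly separated
genomic GC while keeping all synonymous codons in play. Every CDS
translates back to its protein exactly (standard code, frame 1).

All randomness flows from one seed through a single generator in a fixed
iteration order, so identical config + seed gives byte-identical FASTA
and truth tables.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: phylogenetically correlated divergence
(mutants are independent draws around one ancestor, not a tree),
insertions/deletions and domain shuffling, gene prediction and assembly
artifacts, horizontal transfer signatures beyond the planted GC classes,
and realistic functional-category composition. Recovery being exact on
synthetic collections shows the pipeline implements its definitions
correctly at the planted divergence, not that 50%/50% thresholds are
optimal for any particular real genus.

## Pipeline and problem sizes

`run_pipeline` executes the stages in dependency order from one sectioned
key-value config, logs every stage's parameters and seeds, and writes a
`report.json` serialized with sorted keys so identical config + seeds give
byte-identical bytes. A config-hash manifest makes completed runs
idempotent (the output directory itself is excluded from the hash: the
same config pointed at two directories produces identical reports). The
dN/dS stage defaults to the two genomes sharing the most families — the
closest thing a collection has to the two-strains-of-one-species
comparison — unless a pair is configured.

Default study sizes in the examples and tests — 6–10 genomes, tens of
planted families per class, 500–1000 permutations, 100 bootstrap
replicates — were chosen as the smallest collections on which every
planted structure (all occupancy classes, ≥ 2 niches including a
single-genome niche, exclusive-absent patterns) is realized and
recoverable; all counts scale up via `SimConfig` without code changes.

## Known limitations

- Greedy clustering is order-dependent by design (longest-first,
  representative-only comparisons); it reproduces that scheme's behavior,
  including its sensitivity to representative choice near thresholds.
- The identity denominator is the aligned-column count of one optimal
  local alignment; co-optimal alignments with different column counts are
  resolved by the aligner's traversal order.
- p-distances on proteins are not model-corrected; the NJ trees are
  distance summaries, not likelihood estimates.
- The dN/dS screen is the bare pairwise ratio with a codon-count gate —
  no statistical test on the ratio is performed.
- Multiple sequence alignment is out of scope: the core-genome distance
  aggregates pairwise alignments unless pre-aligned input is given.
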