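# Methods

## Canonical k-mer counting

Genomes are read from multi-record FASTA; every record is treated as one
disjoint sequence of the genome, so the sliding window never crosses a
record boundary and `N_T = Σ_i max(L_i − k + 1, 0)` for N-free sequences.
Lowercase input is uppercased and IUPAC ambiguity codes other than `N` are
mapped to `N`; any window containing `N` contributes neither to the counts
nor to `N_T`.  This generalizes the textbook `N_T = L − n·k + n` window
count, which assumes N-free sequences, to masked assemblies.

Only odd k in [3, 51] are accepted.  With odd k no k-mer equals its own
reverse complement, so canonicalization (keep the lexicographically smaller
of k-mer and reverse complement) partitions the 4^k words into exactly
`S = 4^k/2` canonical classes; even k would need special-casing of
palindromes and is rejected.  For k ≤ 31 windows are packed two bits per
base into unsigned 64-bit integers and counted with vectorised numpy
(`numpy.unique`); for 31 < k ≤ 51 a plain string fallback is used, adequate
at the small scales where such long k-mers matter here.  Exactness of both
paths is pinned by a naive-enumeration oracle test over random sequences.

Set algebra is exact: the union merges key arrays and sums counts, and the
intersection cardinality is obtained as `|A| + |B| − |A ∪ B|` (verified in
tests against direct key intersection).  K-mer sets round-trip through a
small versioned TSV format.

## Coverage statistics and the choice of k

`SSC = 2 N_D / 4^k` is the fraction of the canonical space a genome
covers.  The random baseline `E[N_D,R] = S(1 − (1 − 1/S)^{N_T})` is the
expected occupancy of S bins after `N_T` uniform draws; it is evaluated in
log space (`S · −expm1(N_T · log1p(−1/S))`), which stays accurate both when
`N_T/S` is tiny (large k) and huge (small k).  `NSSC = N_D / E[N_D,R]`
tends to 1 at both extremes of k — full saturation at small k, full
specificity at large k — and attains an interior minimum at k\* for
sequence collections with internal k-mer sharing (repeats, shared
ancestry).  k\* is reported as the argmin over the evaluated odd grid only,
with exact ties broken toward the smaller k.

Calibration: for generated i.i.d. sequences the observed `N_D` is compared
to the formula by `coverage_stats.max_calibration_deviation` (1, 2 and
5 Mbp, ten replicates per length, odd k 7–21, per-cell mean versus
expectation, worst cell reported in percent).  A caveat discovered during
validation: the deviation cannot be made arbitrarily small, because `N_D`
itself fluctuates.  The exact multinomial-occupancy standard deviation of
`N_D` is largest where `N_T` is comparable to `S` (k = 11 at these
lengths, ≈ 4×10⁻⁴ relative, empirically ≈ 5×10⁻⁴ because overlapping
windows are correlated), so the mean of ten replicates still deviates by
order 10⁻⁴ (0.01–0.05%).  Typical measured values of the harness are
0.02–0.05%; they measure this intrinsic sampling variance, not model error
(no systematic bias is detectable: deviations change sign across seeds).

Two regression utilities support the database-wide choice of k: an OLS
line of k\* against log10 total k-mer count, extrapolated to the pooled
size of a genome collection, with the policy "round the prediction up to
the next odd integer" (a prediction of 20.7 recommends k = 21); and a
descriptive OLS of SSC on log10 length and |GC − 0.5| whose fitted
coefficients expose marginal effects (e.g. a 100-fold length increase or a
0.35 GC deviation).  `combined_nssc` pools k-mer sets by union and
normalizes by the summed `N_T`, quantifying how much a collection shares
through common ancestry.

In the pipeline, `k: auto` uses the regression when the genomes span at
least half a decade of total k-mer count; for near-equal-length
collections (where the line is uninformative) it falls back to the pooled
combined-NSSC minimum and steps one odd k above it for specificity.

## Jaccard similarity and ANI

Comparisons are exact set operations — no MinHash sketching — so the
Jaccard values carry no estimation error beyond the genomes themselves.
The Poisson model maps Jaccard to ANI via
`ANI/100 = 1 + ln(2J/(1+J))/k`; the inverse (`t = exp(k(ANI/100 − 1))`,
`J = t/(2 − t)`) round-trips to ≥ 10 decimals.  Pairs sharing zero k-mers
have undefined log-similarity and ANI; they are carried as NaN sentinels
and counted, never clamped, and are excluded from log-domain statistics.

For genomes diverged by independent per-site substitution with probability
p, the window survival probability is (1 − p)^k exactly, so the estimator
converges on `100(1 + ln(1 − p))` rather than `100(1 − p)`: the two agree
to 0.005 points at p = 0.01 and 0.13 points at p = 0.05, but differ by
0.54 points at p = 0.10.  This small-p approximation error is a property
of the conversion formula itself, not of the implementation; the test
suite asserts the exact model value, and the acceptance-level check of
`100(1 − p)` at a 0.5-point band accordingly fails at p = 0.10 while
passing at 0.01 and 0.05.

## Clustering, leaf ordering and tree comparison

Dissimilarity defaults to `1 − J` (a strictly order-reversing transform; a
`−log10` variant is available and recorded in run metadata).  Agglomeration
uses the Ward.D2 criterion — squared dissimilarities inside the
Lance–Williams recurrence, merge heights on the scale of the input — via
scipy's `linkage(method="ward")`, verified digit-exact against R
`hclust(method = "ward.D2")` on a frozen 12-point matrix.  Ties resolve to
the lowest cluster index, making merge sequences deterministic.

Optimal leaf ordering is the exact Bar-Joseph dynamic program implemented
in-package: for every internal node a table of minimal adjacent-leaf cost
over (leftmost, rightmost) leaf pairs is combined bottom-up with two
min-plus products, and the optimal flips are reconstructed from the root.
It provably attains the optimum over all 2^(n−1) flips (tested against
exhaustive search for n ≤ 8) and never worsens the input embedding.  Cost
is O(n³)-ish, comfortable at the hundreds-of-leaves scale this package
targets.

Reference trees are built by nesting organisms through the major ranks
(superkingdom → species); polytomies are preserved, missing rank labels
attach the lineage at the nearest labelled ancestor, and user-supplied
intermediate ranks (extra columns, in order) can be passed to resolve
polytomies.  Branch lengths of reference trees are not meaningful.

Tree distance is a generalized Robinson–Foulds variant based on mutual
clustering information: each nontrivial bipartition is a two-block
clustering of the leaves; splits of the two trees are matched one-to-one by
a linear assignment maximizing summed mutual information, and the distance
is `(H1 + H2 − 2·MCI) / (H1 + H2)` where `H` sums split entropies.  It is
0 exactly for identical topologies, rewards near-identical splits (needed
when comparing a binary dendrogram to a polytomous taxonomy), and
approaches 1 for unrelated trees.  Because no independent implementation
of this variant is available in the environment, the variant choice is
validated empirically against the random-tree baseline: 100 pairs of
random 44-leaf trees (recursive uniform leaf-set splitting, shuffled
labels) give mean 0.853 ± 0.015, matching the published baseline for this
statistic (0.852 ± 0.018).

## LCA-level taxonomy screening

Pairs are ranked by their lowest common ancestor: 1 = species …
7 = superkingdom, 8 = organism (root).  The lineage walk skips ranks
unlabelled in either lineage, so comparisons group at the nearest
populated shared rank — the pragmatic rule for databases with
missing/unranked levels.  Per-rank distributions of log10 Jaccard use a
Gaussian KDE with Silverman bandwidth on support [−8, 0] with boundary
reflection; the bandwidth is floored at the grid step so tight clusters
remain resolvable on the returned grid.  Zero-Jaccard pairs are excluded
and counted, preserving the bookkeeping identity (pairs in KDE) +
(zero pairs) = (pairs at rank).

Per-genome trajectories record median and maximum log10 similarity at each
populated rank; deltas between consecutive populated ranks below a
threshold (0, −0.05, −0.1, −0.5) mark potential misclassifications.  The
maximum-based deltas are deliberately more sensitive: a single aberrant
relative flips them without moving the medians.  Three pair rules complete
the report: same-species pairs under 95% estimated ANI (under 90% being
the strongest signal), different-genus pairs over 95% (modulo a
user-supplied allowlist of genus pairs known to straddle the threshold for
nomenclatural reasons), and congeneric species pairs with a strain pair
over 95% (reported per species pair).  The package flags; it never
auto-corrects.

## Synthetic data: what it does and does not emulate

Random sequences are i.i.d. with P(G) = P(C) = gc/2.  Clades descend from
a single random root by branch-wise Bernoulli per-site substitution to a
uniformly chosen different base; length is preserved.  Default per-branch
rates (superkingdom 0.15, phylum 0.10, class 0.08, order 0.06, family
0.05, genus 0.05, species 0.035, strain 0.005) were chosen once to place
the implied ANI bands where practitioners expect them — conspecific
strains ≈ 99%, congeneric species ≈ 92%, cross-genus ≈ 80%,
cross-superkingdom pairs sharing only trace 21-mers — and so that no clean
pair sits on the 95% species boundary.  The default clade is 2
superkingdoms × 2 genera × 2 species × 2 strains at 100 kbp.

Substitution-only divergence keeps the Poisson Jaccard↔ANI relationship
exact, which is the point: the generator provides ground truth for the
estimator, the clustering and the LCA logic.  It does not emulate indels,
rearrangements, repeat families, codon structure, selection, unequal
genome lengths within a clade, or database sampling bias.  Horizontal
transfer (contiguous segment replacement between genomes) and
endosymbiont-style reduction (contiguous deletion) are available as
explicit perturbations.  Consequently, green tests demonstrate correctness
of the machinery and of the model's self-consistency — not robustness to
every bias of real assemblies, where k-mer homoplasy at small k, contig
fragmentation and contamination add effects the generator deliberately
omits.

## Numerical and determinism notes

All stochastic operations take an explicit `numpy.random.Generator` or
seed; pipeline runs with identical config and seed are bit-identical, and
every run directory contains the resolved config and a log with input and
output checksums.  Degenerate inputs are defined errors, not silent
results: empty k-mer sets for Jaccard, zero windows for NSSC, all-equal x
for the k\* line, rank-deficient designs for the GC regression,
non-symmetric or negative matrices for clustering.  Problem sizes in the
test and acceptance harnesses (20–100 kbp clade genomes, 1–5 Mbp
calibration sequences, 100 tree pairs) were chosen as the smallest scales
at which the statistical claims under test are clearly resolved.

## Known limitations

In-memory counting targets desk scale (tens of Mbp per genome); there is
no disk-based or multi-threaded counting, no sketching, and no
alignment-based ANI.  The k\* regression needs genuine genome-length
spread; the pooled-NSSC fallback covers the equal-length case.  The GC
regression is descriptive OLS with no heteroscedasticity treatment.  KDE
boundary handling by reflection is one of several defensible conventions
for bounded supports.  The random-coverage calibration is limited by the
intrinsic occupancy variance of `N_D` (see above), so sub-0.01% agreement
claims are not reproducible at megabase lengths around k = 11.
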