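# Methods

## Distance model

All analyses run on a reference-anchored, trimmed, gap-free character
matrix. The distance is SNP%: for rows *x*, *y* of equal length,
`SNP%(x, y) = 100 · #{i : x_i ≠ y_i, both comparable} / #{i : both
comparable}`, a comparable position holding an unambiguous A/C/G/T in both
rows. This is the raw *p*-distance on a percentage scale; no
multiple-hit correction (K2P or similar) is applied, because the loci this
package targets diverge by a few percent at most, where corrections are
negligible and would obscure the directly counted quantity. Pairs with no
comparable site are *missing*, never zero, and propagate as errors into
stages that need complete matrices.

## Alignment and trimming

Barcode sets within a genus are near-identical, so instead of a progressive
MSA every record is globally aligned to a designated reference accession
(Gotoh three-state affine dynamic programming, default scoring match +2,
mismatch −1, gap open −4, gap extend −1; a gap of length *k* costs
`open + (k−1)·extend`). Rows are projected onto reference coordinates:
record bases falling between reference positions (insertions) are dropped
and logged — the subsequent de-gapping would remove those columns anyway —
and uncovered reference positions hold `-`. Traceback ties are broken
substitution > gap-in-second-sequence > gap-in-first, making output
deterministic; any sane scheme recovers the same homology at these
divergences, the fixed one just pins tests.

Trimming keeps the interval between the first and last column covered by a
real base (non-gap, non-N) in **every** row — complete coverage, the
conservative reading of head/tail cutting — then removes interior columns
containing a gap in any row. Interior `N` columns stay: `N` is missing
data and handled per-pair downstream, whereas a gapped column is not a
homologous site for all rows. The `column_map` carries every kept column's
original 1-based reference position, so results can be reported in either
frame. Trimming is idempotent and, on indel-free clean input, the whole
load → align → trim path is the identity.

## Barcode-gap evaluation

The intraspecific sample pools all conspecific pairs of every species with
≥ 2 records (per-species samples are also reported). The interspecific
sample follows a resampling scheme: `k_species` (default 6) species drawn
without replacement, then `k_draws` (default 6) rounds in which one
sequence per selected species is drawn **with replacement** and every
cross-species pair among the round's representatives contributes one SNP%
value — sample size `k_draws · C(k_species, 2)` (90 at the defaults). The
pooled reading (distances pooled across the whole draw rather than kept per
species pair) is one of two defensible interpretations of the protocol;
both the species count and the draw count are exposed as parameters.

The verdict uses a **Welch** unequal-variance *t*-test (intra and inter
samples have grossly unequal variances by construction), two-sided, plus an
explicit direction gate: `suitable ⇔ p < α and mean(inter) > mean(intra)`,
α defaulting to 0.05. The statistic and Welch–Satterthwaite degrees of
freedom are computed explicitly (p from the Student-*t* tail); degenerate
inputs follow the convention: both variances zero with equal means → p = 1,
with unequal means → p = 0. Note the samples are not independent draws —
pairs share sequences — so the nominal test is anticonservative for its
stated α; under the simulator's exchangeable null the realized suitable
rate is ≈ 0.03–0.05 (direction gate halves the two-sided rate, correlation
pushes it back up), which the calibration test pins within ±0.02 of α.

## Region scoring

A partition splits the trimmed locus into contiguous labeled regions;
without explicit breakpoints the default is 1/6, 4/6, 1/6 of the trimmed
length, labeled `a`, `b`, `c` (unreliable primer-adjacent ends around a
core). Every non-reference sequence gets a per-region SNP count against
the reference row (N excluded) and a density (count / region length);
totals additionally count columns polymorphic in at least one row, so both
the per-sequence and the column-wise summary are available. Regions are
compared by a paired two-sided *t*-test on per-sequence **densities**
(pairing on sequences controls each sequence's overall divergence;
normalizing by length removes the length confound that raw counts carry).

## Diagnostic sites

A site is diagnostic for a query when its unambiguous base is absent from
all conspecific references at that column. Requirements: at least
`min_conspecific` (default 3) conspecific references overall, and at least
one unambiguous conspecific observation at the column (otherwise absence is
vacuous); an ambiguous query base is never diagnostic since it cannot
exclude a shared allele. "Homozygous" is treated at sequence level — a
single unambiguous call — as chromatogram evidence is out of scope. Each
call lists the species whose strict-majority consensus equals the query
state (ties disqualify); a call with no sharing species is private. Sites
are reported in both the trimmed-alignment and original reference frames.

Under the mutation model, a query individual carries `L · intra/2` private
substitutions in expectation (≈ 3 per 1.2 kb at 0.5% divergence), and
essentially all of them are called alongside a planted variant; users
separate the planted signal by its genus-wide sharing pattern or by
comparing multiple conspecific queries.

## Trees and networks

Neighbor joining is the classic agglomerative algorithm: join the pair
minimizing `Q(i,j) = (r−2)·d(i,j) − R_i − R_j`, assign limb lengths
`l_i = d(i,j)/2 + (R_i − R_j)/(2(r−2))`, reduce, and close the 3-taxon case
exactly. Equal Q values are resolved toward the lexicographically smallest
node pair, so results are deterministic. NJ is consistent on additive
matrices, which the test suite exploits as an oracle. It replaces
likelihood-based tree search deliberately: a distance-based tree on the
pipeline's own SNP% matrix is implementable, deterministic and testable,
whereas ML inference belongs to external tools. Negative branch lengths on
non-additive input are kept in the tree object and floored at zero only in
Newick output (logged); Newick uses fixed 6-decimal lengths and canonical
child order (by smallest descendant leaf), so write → parse → write is
byte-stable.

Haplotype collapsing merges rows identical at every comparable site with
`N` matching anything. The wildcard rule is not transitive in general, so
merging is greedy in input order and N-mediated merges are logged; a
property test guards that no two output representatives remain mergeable.
The network is a minimum-spanning network over representative mismatch
counts: edges processed in increasing weight, and at each weight level
every edge joining two components *as they stood before the level* is
included before merging — a minimum spanning forest plus all tie edges at
the merge weights. An optional `step_limit` truncates connections (a
simple stand-in for a statistical-parsimony connection limit); haplotypes
unreachable under the limit form their own components.

## Synthetic data

The simulator draws a uniform random genus root, derives one root per
species, and individuals from their species root, by independent per-site
substitution to a uniformly chosen different base. Divergence parameters
are *pairwise* expected substitution loads: `intra_divergence` between two
conspecific individuals (each individual steps at `intra/2`) and
`inter_divergence` between two heterospecific individuals (each species
root steps at `(inter − intra)/2`, hence `inter ≥ intra` is required).
This parameterization is what makes *equal* divergences a genuine null —
every sequence becomes an i.i.d. derivative of the genus root, so species
labels are exchangeable — while `inter > intra` plants a barcode gap of
known size. Composing steps stays in the same substitution-kernel family,
giving the closed form used by the oracle tests: the expected observed
Hamming fraction across steps `p_1..p_k` is
`D = (3/4)·(1 − Π(1 − 4p_i/3))`.

Defaults (6 species × 4 individuals, 1.2 kb, intra 0.5%, inter 3%) are the
test-design conditions for a *matK*-like locus in a species-rich genus;
real divergence magnitudes for such genera are not pinned by public data,
so these are stated working values, not estimates. `simulate_clade_genus`
adds one extra ancestor node (a clade root at a chosen extra divergence,
default studies use 8%) to produce a genus with one divergent clade — still
i.i.d. per-site substitution, not a tree-process simulator.

What the simulator does **not** emulate: indels (the analyses run
gap-stripped, so indel realism buys nothing — terminal degradation is
available separately), rate heterogeneity across sites, transition bias,
recombination-free coalescent genealogies, and chromatogram-level artifacts.
Passing tests therefore demonstrate correctness of the algorithms and
calibration under this model, not robustness to every property of real
sequence collections.

## Problem sizes and numerical choices

Monte-Carlo studies use 2000 replicates for null calibration (±0.02
tolerance on a rate near 0.05), 500 for power, 200 for diagnostic recovery
and NJ-consistency checks, and 100 for clade-recovery and network-weight
cross-checks; `scripts/acceptance.py` uses the same designs at 60–1000
replicates, sizes chosen so the whole script re-runs in well under a
minute on one CPU while keeping Monte-Carlo error a few times smaller than
each tolerance. All randomness flows through explicit integer seeds
(numpy PCG64); identical configuration and seed give byte-identical
artifacts, which the checksum manifest of the CLI makes checkable. Exact
float equality is only ever asserted where the computation is exact
(integer counts, identical arithmetic paths); statistical comparisons carry
explicit tolerances stated with each test.

## Known limitations

- Reference-anchored alignment discards insertions relative to the
  reference; variation inside such insertions is invisible.
- The Welch test's independence assumption is violated by shared-sequence
  correlation between distance pairs; the verdict is calibrated empirically
  under the simulator's null but is not an exact level-α test.
- Strict-majority consensus makes sharing-species annotation conservative
  for species with deep internal splits.
- The step-limited network approximates, but does not implement,
  statistical parsimony's 95% connection limit.
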