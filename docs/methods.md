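# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paralog calling

Each proteome is searched against itself with pairwise local alignment
(BLOSUM62, gap open −11 / extend −1). Every unordered pair is aligned
once and reported in both directions. Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with the published gapped
BLOSUM62 constants (λ = 0.267, K = 0.041), query length m and database
size n = the proteome's total residue count — the search is
within-proteome, so the proteome *is* the database. Defaults: E ≤ 10⁻⁵,
≤ 1000 hits per query.

Percent identity is computed over the aligned columns of the local
alignment (identities / alignment length × 100, gaps counted in the
length, as in BLAST tabular output). No length-coverage requirement is
imposed by default (`min_coverage = 0`); the identity threshold
(default 75 %) applies per hit. A protein with at least one non-self hit
at or above the threshold is a paralog; the number of copies is never
counted, so the paralog fraction is a fraction of *proteins*. The strict
75 % cut targets recent or strongly conserved duplications; it is not
comparable with the common 30 %-identity/60 %-coverage paralog
definition.

The genome-size trend is ordinary least squares of paralog-gene count on
genome size (Mb) with Pearson r. Outliers are flagged at
|internally studentized residual| > 3 and a second fit excluding them is
attached; an exact fit (zero residual variance) flags nothing. Genome
size means the main chromosome only, so plasmid-rich organisms do not
distort the fit.

## COG profiles

A protein contributes one count to each of its COG category letters and
one count to `-` when unclassified, so fractions are over assignments,
not proteins. ptt-style cells such as `COG0583K` or `KL` are parsed by
stripping an optional leading `COG<digits>` token. Because the
paralog/singleton ratio is sensitive to choices such as ribosomal-protein
inclusion, group comparisons are anchored on near-zero categories: a
category is "dominated" when one group's fraction is below ε = 0.005
(configurable) while the other's is ≥ 5ε. Cluster-level consensus is the
plurality category over the cluster's paralogs (ties broken by the
lexicographically smallest letter and flagged); the same plurality rule
applied per term may legitimately disagree with the cluster consensus,
and both labels are reported unchanged. Persistent singletons are
consumed as a provided ID list; the pipeline does not re-derive
persistence.

## Term overrepresentation

Annotations are closed under the true-path rule over `is_a` and
`part_of` (configurable to `is_a` only) before any counting; each
protein counts at most once per term. For organism o with paranome of
size n inside a background of size N, a term with k study hits and K
background hits gets the one-sided Fisher exact p-value

p = Σ_{i=k}^{min(n,K)} C(K,i)·C(N−K,n−i) / C(N,n),

evaluated as the hypergeometric survival function. Bonferroni correction
multiplies by m = the number of terms with ≥ 1 study hit in that
organism (the populated-terms choice; m is recorded in every record for
audit). The EASE-style variant (k−1 in the tail) is available behind a
flag but is not the default, since the classical 2×2 Fisher procedure is
the defined contract. Records pass at corrected p < α (default 0.01,
strict); α = 1 is treated as the "keep everything tested" sanity path.
Three background models are supported — all paralogs pooled over
organisms, all proteins of all proteomes, or the organism's own
proteome — and the cross-organism filter then keeps only terms
significant in ≥ 3 organisms.

## Species graph

Pairwise organism similarity is the number of shared overrepresented
terms; the relative overlap divides by min(|A|,|B|), the only reading of
"maximum possible overlap" that is computable per pair. An edge needs
count ≥ 10 and relative overlap ≥ 0.30 (both configurable); its weight
is the count. Only organisms incident to a retained edge become nodes.
Layout and visual cluster picking are out of scope; the weighted edge
list loads into any viewer.

## Biclustering

A bicluster is an inclusion-maximal all-ones submatrix of the binary
species × term incidence matrix. These coincide exactly with the formal
concepts of the relation, and are enumerated with a Close-by-One
depth-first search over columns on bitset row masks with
canonical-generation pruning, so each concept is produced once;
min_rows = min_cols = 2 by default (the smallest non-trivial module).
Enumeration is exponential in the worst case, so a budget guard
(100 000 concepts) aborts with advice to decompose the matrix.
Overlapping clusters are deliberately retained — they are alternative
groupings of the same associations. Organisms with fewer than two
filtered terms cannot join any cluster and are reported as
unclusterable. Clusters whose organisms all map to one species label are
dropped (many sequenced strains of one species otherwise produce large,
artificially uniform clusters), and (organism, term) co-occurrence is
counted over the surviving clusters, optionally excluding listed
species.

## Semantic similarity

A term's semantic value assigns contribution 1 to the term itself and,
to each ancestor, the maximum over upward paths of the product of edge
weights (0.8 per `is_a`, 0.6 per `part_of` — the standard constants of
the Wang graph-based measure; configurable). The similarity of terms a,
b is Σ_{t shared} (S_a(t) + S_b(t)) / (SV(a) + SV(b)) ∈ [0,1]; identical
terms score exactly 1. Cross-namespace pairs score 0 rather than being
dropped so that mixed-namespace clusters are penalised while every
cluster score stays well defined. A cluster's homogeneity is the mean
over unordered distinct term pairs (self-pairs excluded by default,
available behind a flag); a single-term cluster scores 1.0 and callers
should treat such singletons separately. Background models are compared
with Welch's unequal-variance two-sided t-test on the per-cluster score
lists, with box-plot statistics per model; models with fewer than two
clusters are excluded with a warning.

## Alignment-free distance

For each query position the *shulen* is the length of the shortest
prefix of the suffix starting there that does not occur in the subject
(remaining length + 1 when the whole suffix occurs). Profiles are exact,
via a suffix automaton of the reversed subject streamed with the
reversed query in O(n + m); a naive substring-search oracle guards the
implementation in the tests.

The distance estimator inverts an explicit model of the expected mean
shulen. With per-site mismatch probability π, the longest match from a
position is max(homologous match, background match): the homologous
match length exceeds x with probability (1−π)^(x+1), the background
match is the longest common prefix against ≈ m random subject suffixes,
P(b ≤ x) ≈ (1 − 4^−(x+1))^m for uniform DNA, and truncation at the query
end weights the tail sum by (1 − x/L):

E[mean shulen] = 1 + Σ_{x=0}^{L−1} (1 − x/L) · [1 − (1 − (1−π)^(x+1)) · (1 − 4^−(x+1))^m].

π is found by Brent root finding on this expectation against the
observed mean, converted by the Jukes–Cantor correction
d = −¾ ln(1 − 4π/3), and the two directed estimates are averaged. The
background model assumes approximately uniform base composition, which
the simulations satisfy; strongly skewed genomes would bias the
background term.

Near the JC bound the expectation curve flattens, so a threshold on π
alone cannot reliably flag unrelated sequences. Instead a direction is
*saturated* when its observed mean shulen lies within 4 block-bootstrap
standard errors (block 200) of the unrelated-sequence expectation; the
mismatch estimate is then capped at π = 0.74 so downstream thresholding
keeps finite values, and the pair is flagged. Sequences under 1 kb get a
wide-uncertainty flag. Useful resolution depends on length: at 10 kb
distances up to ≈ 0.3 substitutions/site are resolvable, at 50 kb the
estimator's error is well under 0.01 across d = 0.02–0.2 (the test suite
measures this).

Cluster-level distance is the mean over unordered organism pairs
(maximum available via a flag; the choice between mean and max was open
and the mean is the less outlier-sensitive default). The convergence
screen selects clusters with similarity > 0.7 and distance > 0.1, both
strict; among selected clusters with overlapping organism sets only the
one with fewest organisms is kept (ties: fewest terms, then
lexicographic), since overlapping biclusters restate one signal.

## Synthetic data

Generators are pure functions of (parameters, seed) and every one
returns a planted-truth record sufficient to score downstream detectors.

* **Proteomes** — paralog families are built by independently mutating a
  random ancestor; substitutions only, uniform over the 19 alternative
  residues, with the per-site rate q solved from
  (1−q)² + q²/19 = target pairwise identity. No indels, no domain
  structure, no composition bias: identity is analytically controllable,
  and indel robustness of the aligner is deliberately untested here.
  Singletons are uniform random sequences (pairwise identity ≈ 5 %), far
  below the 75 % calling threshold.
* **Ontologies** — parents are drawn only from earlier-created terms, so
  the DAG is acyclic by construction; each root founds a namespace and
  extra parents stay within it.
* **Annotations** — background terms are assigned independently at a
  base rate (default 0.05); a planted (term, fold) assigns the term to
  the organism's paranome at base rate × fold. Real annotation is far
  more structured (correlated terms, depth-dependent specificity), so
  passing the power and null tests shows correct statistics under
  exchangeability, not robustness to annotation bias.
* **Incidence matrices** — all-ones blocks plus Bernoulli noise.
* **rDNA sequences** — Jukes–Cantor evolution along a given tree from a
  uniform root; no rate heterogeneity, indels, or GC skew, matching the
  assumptions of the distance estimator. Validation therefore speaks to
  the estimator's statistical correctness, not to model misspecification
  on real 16S data.

The bundled demo world (12 organisms) plants one convergent
configuration: two clades of six, 0.27 substitutions/site apart (0.02
within), with three organisms per clade carrying a pair of sibling terms
five `is_a` levels deep across their whole paranome. The depth fixes the
pair's similarity at 0.729 (> 0.7); the clade mixture puts the cluster's
mean distance near 0.17 (> 0.1). The planted terms' ancestors are masked
by annotating the immediate parent directly on 80 % of background
proteins, so propagation does not drag the whole ancestor chain through
the enrichment filter — the closed-form hypergeometric calculations
behind these rates put the planted terms' corrected p-values orders of
magnitude below 0.01 and the ancestors' well above it. Demo 16S
sequences are 5 kb (longer than real 16S) so clade distances are
estimated with comfortable margin.

## Problem sizes and determinism

The test suite and the acceptance script use deliberately small problem
sizes chosen to make the statistical contracts sharp rather than to
mimic dataset scale: 50 kb sequence pairs for the distance-accuracy
grid, 10–20 kb for tree correlations, proteomes of ~20–45 proteins for
alignment-based recovery, 500-protein proteomes for enrichment power,
and exhaustive enumeration oracles up to N = 60 (Fisher) and 10×10
matrices (biclustering). Every random draw is seeded; pipeline runs with
the same config and seed are byte-identical, and all outputs are written
in sorted order to keep runs diffable.

## Known limitations

* E-values rely on fixed Karlin–Altschul constants for BLOSUM62 11/1;
  other matrices or gap costs would need their own λ, K.
* The enrichment test assumes exchangeable annotation under the null;
  annotation propagation makes tests across nested terms correlated,
  which Bonferroni handles conservatively but not optimally.
* Bicluster enumeration is exponential in adversarial dense matrices;
  the budget guard refuses rather than degrades.
* The distance estimator assumes roughly uniform composition and no
  indels; it estimates substitutions only (Jukes–Cantor scale).
* Cluster selection with strict cuts at (0.7, 0.1) inherits those
  constants' arbitrariness; both are exposed in the config.
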