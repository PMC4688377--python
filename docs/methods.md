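# Methods

## Model

A tumor sample is represented by the set of its distinct somatically
altered genes — point mutations (from MAF, silent variants excluded by
default), copy-number gains (GISTIC call ≥ +2) and losses (≤ −2) — pooled
into one set of size *M* and restricted to the nodes of an undirected,
simple, symbol-level PPI network of *N* genes. Alterations of all types
are treated interchangeably: the null "mutates the network" at gene level,
and *M* counts distinct genes, not events, so a gene mutated twice or both
mutated and amplified contributes once.

For a candidate gene *g* of degree *k*, the observed statistic is
*x*, the number of altered genes among the *k* immediate neighbors of *g*.
The gene's own alteration is excluded from *x* (it is reported separately
as `self_altered`) but *g* remains part of the permutation pool. The null
hypothesis places the sample's *M* distinct alterations uniformly at
random on the *N* network genes; the p-value is the upper tail
P(X ≥ x). Because drawing *M* distinct genes from *N* and counting hits
among a fixed set of *k* neighbors is a hypergeometric experiment, the
permutation null has the closed form

    p = hypergeom.sf(x − 1, N, k, M),

which `mode="exact"` (the default) evaluates directly. `mode="perm"` runs
the procedure literally: `n_perm` (default 10 000) uniform *M*-subsets are
drawn and p is the plain proportion of permutations reaching *x* or more —
so p = 0 is possible; an optional add-one correction (r+1)/(n_perm+1) is
available. Null count vectors are cached per (k, M) within a run — node
labels are exchangeable under the null, so one cache entry serves every
gene of equal degree, and sharing realized counts makes p monotone in *x*
by construction. An alternative event-level null (placing *M* mutation
events with replacement) was considered and rejected as the default
because *M* is defined from distinct genes; the distinct-gene null is the
one with a verifiable closed form.

Candidate genes come from seed-set expansion: a curated oncogene list is
grown by every network gene with at least `min_connections` (default 2)
interactions into the seed set. Calls use raw α = 0.05 with no
multiple-testing adjustment by default — surrogate neighborhoods are
nested and dependent, and standard corrections for that dependency
structure are not well posed here; Benjamini–Hochberg is available as an
option with that caveat. Per (sample, gene) the result is one of four
states: none, surrogate only (significant, gene unaltered), altered only,
or both; the binary "significant surrogate" view of this matrix is the
feature source for all downstream analyses.

## Downstream analyses

**Drug sensitivity.** GI50 values are discretized per drug by equiprobable
(median) binning into equal-occupancy classes, ties at the median broken
by stable input order toward the lower bin, missing values propagated.
Low GI50 = sensitive by pharmacological convention (a flag flips the
orientation). A random forest (500 trees, √p features per split, fixed
seed) is fit on the binary surrogate features; features are ranked by mean
Gini importance; the forest is refit on the top 10% (at least one
feature); both out-of-bag error estimates are reported. OOB error is the
internal cross-validation estimate from samples outside each bootstrap.

**Subtype association.** For each surrogate gene significant in at least
one sample and each subtype label, a one-vs-rest 2×2 table of
{significant surrogate vs not} × {in subtype vs not} is tested with the
two-sided Fisher exact test; genes never significant anywhere are skipped
(no contrast exists).

**Survival.** Surrogate presence/absence (binary, α = 0.05) enters a
survival tree grown by greedy best-first binary partitioning: at each
step, among all current leaves and features, the present/absent split with
the largest two-sample log-rank statistic is applied, subject to a
complexity threshold (statistic ≥ 3.84, the χ²(1) critical value at 0.05),
a minimum leaf size (default 10) and a terminal-group cap (default 4
leaves; "four nodes" is read as four terminal groups, and the cap covers
either reading). The tree is hand-rolled rather than wrapped from a
recursive-partitioning package so its behavior is fully specified and
testable; leaf groups are compared with the k-group log-rank test
(lifelines), χ² with k−1 degrees of freedom.

## Synthetic cohorts

The generator stands in for real cohort inputs and writes the exact
formats the parsers read (edge list, MAF, GISTIC matrix, seed list, GI50 /
subtype / clinical CSVs); fixtures round-trip bit-exactly and regeneration
with the same seed is byte-identical.

The network is Barabási–Albert preferential attachment (default N = 500,
m = 3), giving the heavy-tailed degree distribution of curated
interactomes; Erdős–Rényi is available for contrast. Cohorts alter each
gene independently at `background_rate` (default 0.02, giving M ≈ 10 on
500 genes — sparse profiles of the kind seen in exome cohorts); neighbors
of each planted target are altered at min(1, enrichment × background)
instead. The planted signal is *neighbor* enrichment, not target
self-mutation, because that is exactly what the statistic detects; targets
default to the best-connected genes (degree ≥ 20), matching the
observation that oncogenes sit among network hubs. Alterations are typed
30% copy-number (gains and losses equally) and 70% mutations, mirroring
the CNA share of cell-line cohorts. An `exposed_fraction` parameter
(default 1.0) restricts the planted enrichment to a random subset of
samples when between-sample contrast is needed for phenotype linkage.

Phenotypes condition on the deterministic latent label
`surrogate_positive` (any planted target significant under the exact
test): GI50 = 1.0 + effect × 1[negative] + N(0, 0.5) so positives are the
sensitive class; subtype defaults to "basal" for positives and "luminal"
otherwise with 10% label noise; survival times are exponential with
baseline hazard 0.1 and hazard ratio 4 for positives, with a seeded 20% of
subjects censored uniformly before their event time.

**What the generator does not emulate:** mutational signatures, gene
length and replication-timing effects, chromosome-level CNA segments,
subclonality, network ascertainment bias, or inter-gene correlation beyond
the planted neighborhoods. Passing tests therefore demonstrate
correctness and calibration of the statistic under its own null and power
against its intended alternative — not performance on real tumor data.

## Statistical behavior worth knowing

**Conservatism under discreteness.** The null statistic is a count on a
small neighborhood, so attainable p-values are discrete; the realized
false-positive rate at α = 0.05 on null cohorts is ~0.02, below the
nominal level. Calibration is therefore assessed one-sided (rate ≤ α +
tolerance). The same applies to Fisher's exact test on small 2×2 tables.

**Power under M-inflation.** Planting neighbor enrichment also raises the
sample's total alteration count *M*, and the null conditions on *M*. With
enrichment 8 on background 0.02 (neighbor alteration rate 0.16) the
enriched neighborhoods push M from ~10 to ~40 of 500 genes, raising the
null mean k·M/N roughly fourfold. The resulting per-target power is
~0.85 for hub targets (degree ≳ 60) but only ~0.4–0.6 for targets of
degree 20–40 — substantially below what a naive comparison of 0.16·k
against the background-only null mean suggests. Detection rates in tests
are checked against an exact-power oracle that samples (x, M) directly
from the generative model and applies the hypergeometric tail.

## Numerical and design choices

- p-values are clipped to [0, 1]; x = 0 returns exactly 1, x > min(k, M)
  exactly 0.
- Significance is strict: p < α, so α = 0 yields no calls and reported
  p = 0 (possible in permutation mode) is always significant for α > 0.
- Permutation draws use a vectorized order-statistics trick (per-row
  argpartition of uniform keys), chunked to bound memory; a single seeded
  generator per run gives bit-reproducible p-values.
- Survival-tree ties in split statistics break toward the
  lexicographically smaller feature name; samples tied at the median GI50
  are assigned by stable input order — both make reruns deterministic.
- Gene symbols are uppercased and whitespace-trimmed at every ingest
  point; no alias/ID mapping is attempted (symbol-level analysis).
- Problem sizes in the test suite (N = 500 networks, 40–60 samples,
  ≥ 2000-test calibrations, n_perm = 10⁵ for oracle comparisons) were
  chosen as the smallest at which the binomial error bars are tight enough
  to make the contracts meaningful.

## Known limitations

- The statistic tests each (sample, gene) marginally; surrogate sets
  overlap, and no dependency-aware multiplicity control is offered beyond
  optional BH.
- Degree-1 gene "neighborhoods" are single genes; their p-values are
  extremely discrete and rarely significant.
- The exact mode assumes the distinct-gene null exactly; if alterations
  cluster for reasons other than neighborhood structure (e.g. regional
  CNAs), the null is misspecified and p-values optimistic.
- The drug-response model ties sensitivity to a single latent indicator;
  per-drug heterogeneity of mechanism is not simulated.
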