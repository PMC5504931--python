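# Methods

## Unit of analysis

A *prescription* is the set of distinct CHM codes dispensed at one
retained ambulatory visit; it is the transaction over which support is
defined, and the denominator of every prevalence in the package.  Claims
rows that split one dispense of the same item across several lines are
merged at read time (doses summed, maximum duration kept) so an item is
counted at most once per prescription.

## Cohort cascade

Filtering proceeds in a fixed order, each step counted in the attrition
report: (1) visit by an index-eligible patient — a patient with at least
one gynecology visit whose diagnosis list matches a configured ICD-9-CM
prefix; (2) patient age at the visit within [20, 50] *completed years*,
bounds inclusive (the common claims convention; the endpoints are not
otherwise specified); (3) first-listed diagnosis matches a configured
prefix (the first code is the visit's primary reason); (4) no excluded
therapy type (acupuncture, moxibustion, manual therapy) on the visit;
(5) at least one CHM item.  Because the steps nest, attrition counts are
monotone non-increasing by construction, and re-filtering the retained
set is the identity.

The disease code is configurable rather than hard-wired, defaulting to
prefix `"617"` (the endometriosis rubric; 671.x codes venous
complications of pregnancy, so a hard-coded value would be wrong for
some upstream code lists).  Matching is by textual prefix because claims
codes carry sub-digits that enumerating exhaustively would not survive.

## Rule mining

Frequent itemsets are mined with a level-wise Apriori written in full in
`chmnet.mining`: frequent *k*-itemsets sharing a (*k*−1)-prefix are
joined, candidates with any infrequent subset are pruned (support is
anti-monotone), and candidates are counted by enumerating each
transaction's combinations.  Default thresholds are the published
screen: support ≥ 1%, confidence ≥ 30%, lift > 1.  The lift threshold is
*strict*: lift = 1 is exact independence, which cannot indicate a
combination.  Maximum itemset size defaults to 3 because pairs and
triples are what the combination tables report.

Combination tables collapse rule directions: each unordered itemset is
reported once, with the itemset (union) support as its prevalence and
the metrics of the higher-confidence direction (tie: lexicographically
smaller antecedent).  Reported percentages are rounded half-up to one
decimal, the precision of the published tables.  Mining emits exactly
the thresholded subset of the unfiltered metrics — the screens never
modify a metric — and this, along with exact agreement with exhaustive
subset enumeration, is asserted by the test suite rather than assumed.

A known quirk of the source tables this workflow mirrors: a few printed
lifts are not exactly confidence ÷ printed consequent prevalence.  The
package follows the standard definitions and makes no attempt to
reverse-engineer the discrepancy.

## Network stage

The top-30 two-CHM combinations (by prevalence, ties by lift then
lexicographic) form a simple undirected graph.  Community detection is
Clauset–Newman–Moore greedy modularity maximization as implemented in
networkx, with combination support as the default edge weight
(frequency is what edge thickness encodes; mapping edge *strength* to
lift rather than confidence is a configurable choice).  Nodes and edges
are inserted in sorted order, so identical inputs yield identical
partitions; cluster ids are assigned 1..C by decreasing community size,
ties by smallest member code.  Triples are reported as a table only —
the graph stays pairwise, matching the figure it emulates.

Cores maximize (prevalence, support-weighted degree, lexicographically
smallest code), per cluster and globally.  Modularity of the returned
partition is stored and checked against the all-singletons baseline.

## Synthetic cohort generator

The generator's defaults are the study conditions of the emulated
analysis: target mean 6.2 items per prescription, a hub formula at
28.1% marginal prevalence, six disjoint planted clusters, within-cluster
odds boost 8, item marginals spanning ~1–30%, HF doses ~4.2 g/day and SH
doses ~1.25 g/day (lognormal), durations ~11.5 days, and a default
cohort of 1,736 patients averaging 7.5 visits (tests and the acceptance
script set exact visit totals of 10,000–50,000).

**Sampling model.**  For each prescription one cluster is seeded with
probability proportional to its seed weight (default 0.20 for the hub
cluster, 0.15–0.155 for the others, 0.03 unseeded); each catalog item is
then included independently with probability q = b·o/(1+b·o), where o is
the item's base odds and b its cluster's boost when that cluster is
seeded (else 1).  Empty prescriptions are redrawn.  An earlier design
drew a prescription size first and filled it by sequential weighted
sampling without replacement; it was abandoned because fixed-size
competition induces systematic negative association between
high-prevalence items (pairwise lifts down to ~0.72 with all boosts at
1), violating the independence limit the generator must satisfy.  Under
the mixture-Bernoulli model, boost = 1 makes items exactly independent,
so every pairwise lift converges to 1 and deviations at finite n are
pure counting noise.

**Calibration.**  Base odds solve p_target = Σ_c P(c)·q(b_c·o) per item
by bisection — deterministic, no simulation — so realized marginals
track their targets under any boost configuration.  Because a
prescription's size is the sum of its inclusion indicators, the expected
size equals the sum of the marginal targets; specs whose targets do not
sum to the configured mean (6.2 by default) are rejected as infeasible
before sampling.  Sampling is additionally *balanced*: seeding-class
counts and each item's inclusion count within a class are
floor(n·p)-plus-randomized-remainder, assigned to uniformly random rows.
Items remain independent given the class (co-occurrence is
hypergeometric with the product mean), while realized marginals sit
within O(1/n) of target — tight enough that every item passes a
3-standard-error calibration check at 10,000 visits with a wide margin.

**Catalog design.**  21 named items form the six clusters: one anchor
per cluster at 20–28% prevalence and satellites at 14–17%, plus 150
unclustered filler herbs decaying geometrically from ~3% to ~1%.  Three
constraints set these numbers.  (i) With boost 8, the seeded/unseeded
odds ratio caps rule confidence near 1.7–2.5 × the anchor's prevalence,
so anchors need ≥ ~18% for satellite→anchor rules to clear the 30%
confidence screen with several-sigma margin; clusters therefore surface
as anchor-centred stars, which is also how the emulated networks look.
(ii) At 50,000 visits the smallest ≥5% pair must carry ~1,000 joint
counts for its lift estimate to stay inside the ±0.1 independence band,
hence the 14% satellite floor and the clean gap between cluster items
and fillers.  (iii) Fillers stay below 3% so that no filler pair — in
particular no filler–hub pair, whose expected confidence equals the
hub's 28.1% prevalence, adjacent to the 30% screen — can reach 1% pair
support and leak into the combination tables.  The items-per-
prescription distribution is the emergent Poisson-binomial mixture
(mean 6.2, SD ≈ 2.4, mode 6); its published counterpart has mode 7 with
mean 6.2, a left skew no independent-inclusion model reproduces, and the
generator targets the mean only.

**Decoys.**  `decoy_fraction` adds, per violation type, that fraction of
the core visit count as extra visits each breaking exactly one cascade
rule (age 17 at the visit, disease code in second position, or
acupuncture co-therapy), attached to otherwise-eligible patients.
Single-cause violations make every attrition count analytically exact:
with n core visits and d decoys per type, the cascade reads
n+3d, n+3d, n+2d, n+d, n, n.

**What the generator does not emulate.**  Calendar trends, demographic
covariates, per-patient disease progression, dose–duration correlation,
and the long 500-item tail of rarely-used products.  Passing recovery
tests therefore shows that the mining and network stages faithfully
extract structure of the planted kind — not that any particular clinical
co-prescription pattern is real.

## Numerical and degenerate-input conventions

Supports are exact ratios of integer counts; oracle comparisons are made
at 1e-12.  An empty transaction list is an error (support undefined);
an empty mined rule set yields empty combination tables and no network,
but the pipeline still writes its full report bundle.  Percentages in
written tables use half-up rounding at one decimal.  All randomness in a
pipeline run flows from one seed; reruns are byte-identical and the run
report lists SHA-256 checksums of every artifact.

## Problem sizes used by the test and acceptance suites

Worked lift examples are closed-form; the Apriori cross-check uses 100–
200 random transaction sets (≤ 12 items, ≤ 500 transactions); planted
recovery and the independence limit use 50,000-visit cohorts; generator
calibration uses 10,000 visits; attrition accounting uses 4,000 core
visits with 5% decoys per type.  These sizes give the recovery and
calibration statistics comfortable margins (ARI is typically 1.0, max
unboosted |lift−1| ≈ 0.06–0.09 against the 0.1 band) while keeping a
full run in tens of seconds.
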