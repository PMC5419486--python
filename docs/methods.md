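# Methods

## Topology weighting

Given a genealogy whose tips belong to n predefined taxa (groups), the
weighting of an unrooted bifurcating taxon topology τ is

    w_τ = K / N,        N = ∏_j s_j,        K = Σ_i [x_i = τ],

where s_j is the number of samples in taxon j, the product runs over all
one-sample-per-taxon transversals, and x_i is the topology of the subtree
induced by transversal i. Weightings are proportions: with no unresolved
subtrees they sum to 1 over the (2n−5)!! possible taxon topologies.

Topology identity is purely unrooted: two trees match iff their canonical
nontrivial bipartition sets agree after relabeling tips by taxon. Rooting
and branch lengths never affect identity. Zero-length internal branches are
retained as bifurcations by default (they still resolve topology);
`collapse_zero_branches` optionally contracts them to polytomies first.
Polytomous subtrees are counted in a separate `unresolved` tally and
excluded from the normalized weights — distributing that mass over
topologies would fabricate resolution the tree does not contain.

### Exact counting and the monophyly collapse

`weight_exact` first collapses every maximal same-taxon clade (in the
unrooted sense) to a single tip carrying a multiplicity. A transversal over
the collapsed tree stands for the product of its tip multiplicities'
worth of original transversals, so collapsed counting is exactly equivalent
to enumerating all N transversals; the test suite holds the two equal
integer-for-integer on hundreds of random trees. Exact mode refuses N above
a configurable ceiling (default 10^7) and directs the caller to sampling.

Internally a transversal's topology is read from integer (edge-count)
tip-to-tip path lengths via the four-point condition: for four taxa the
winning pairing of the quartet sums is the topology (a three-way tie is a
polytomy), and the four-taxon path is fully vectorized; for five taxa a
taxon pair is a cherry-side split iff it wins every quartet containing it,
and the cherry-pair set determines the topology. For six or more taxa the
cherry set is no longer identifying, so a generic split-signature route
(accumulating taxon bits over each chosen tip's root path) is used. The
public `match_topology` is an independent bipartition-based route kept in
agreement with these by tests.

### Approximate weighting

`weight_fixed_sample` draws transversals uniformly with replacement
(sampling with replacement keeps each topology count binomial), so each
weight carries a binomial confidence interval. We use the Wilson score
interval: unlike the Wald interval it behaves at K = 0 and K = evaluated,
which the threshold rule probes constantly. The interval method is a
package choice; the CI level (default 0.95) and the iteration count are
caller-set. `weight_threshold` samples in batches (default 100) until every
topology's interval is narrower than `max_ci_width` or `max_iterations` is
reached, recording which rule fired — highly sorted trees stop early,
star-like trees run to the cap.

### Branch-length diagnostics

`topology_branch_distances` averages, per matched topology, the patristic
distance between every taxon pair over transversals. Taxa joined by recent
introgression sit at shallower distances than taxa joined by the deeper
species branching, so these means help distinguish an introgression
topology from the species topology when weights alone are ambiguous.

## Window trees from SNP data

Windows contain a fixed number of SNPs (default 50), nonoverlapping, per
chromosome; the trailing partial window is dropped so all rows are
comparable. A window is rejected when any haplotype is genotyped at fewer
than `min_calls` sites (the study protocol: ≥40 of 50); rejected windows
propagate as missing rows, keeping trees, index and weights row-aligned.
Coordinates are 1-based inclusive, interval = [first SNP, last SNP].

Distances are raw p-distances (mismatches over jointly called sites; a
zero-overlap pair is an error naming the pair). A Jukes–Cantor correction
is available behind a flag and off by default — the weighting depends only
on topology and JC is monotone in p. Trees come from classical
Saitou–Nei neighbor joining (scikit-bio's implementation; negative branch
estimates clamped to zero). This deliberately substitutes classical NJ for
BIONJ: the two share the O(k³) agglomeration skeleton and differ only in
the variance model used to average distances, and topology agreement is
what weighting consumes.

Unphased heterozygotes (`X/Y`) become missing by default rather than being
randomly phased: phase errors mimic introgression signal, the costlier
failure mode. `phase_policy="random"` opts into random phasing.

Taxon-informative sites (TIS) are defined as having at least two alleles
each present in at least two taxa (the strict reading; it excludes fixed
inter-taxon differences, which separate two taxa but resolve no topology).
A laxer reading — two alleles whose carriers jointly span two taxa — is
available via `mode="lax"`.

The SNP bootstrap resamples window columns with replacement, rebuilds the
tree and reweights; 5%/95% empirical quantiles are reported per topology.
Bootstrap means are slightly conservative (bootstrap trees are less
resolved, pulling weights toward intermediate values), which the acceptance
suite asserts as a tendency over ≥100 windows, not per window.

## The coalescent simulator

The generator is a backward-time structured coalescent with constant deme
sizes and time in units of 4N generations: within a deme of k lineages,
coalescence at total rate k(k−1) (a pair's mean time is 0.5); backward
per-lineage migration from the forward-migration recipient into the source
at rate 4Nm; at a split time, all lineages of the derived deme move into
the ancestral deme. Because simulators differ by factors of two in
migration conventions, the scale sits in one named constant
(`MIGRATION_RATE_SCALE = 1.0`) and is validated two ways: the
zero-migration quartet reproduces the analytic concordance probability
1 − (2/3)e^{−T} for internode T (in 2N-pair units), and the full
four-taxon neutral demography matches an independent msprime run of the
identical model in the cross-check test.

Preset demographies:

* `neutral4` — taxa A,B,C,D, 10 samples each, splitting {[(A,B),C],D} at
  0.5/1.0/1.5 × 4N, forward migration C→B at 4Nm = 0.1.
* `neutral5` — {[(A,B),(C,D)],E}, six samples per taxon; the A/B and C/D
  splits at 0.5, the AB/CD split at 1.0, E at 1.5; same migration.
* `power-{4,5}pop-{4,5,6,10}seq-t1_{0.5,1}` — the power-analysis designs:
  populations split [(1,2),(3,4)] (plus outgroup population 5), terminal
  splits at t2 = 0.1, five-population intermediate split at t1b = 0.2, no
  migration. The sequence count is per population — the sampling-strategy
  grid is stated as counts of sequences drawn from each of four or five
  populations, and this is the reading adopted here.

Recombination is deliberately not simulated. Chromosome-wide mean
weightings are expectations over the marginal genealogy distribution, which
is identical for independent loci; all chromosome-average results are
therefore reproduced as means over independent replicates, and the
population recombination-rate settings of chromosome-scale runs are out of
scope, as are selection scenarios (they require frequency-trajectory-
conditioned coalescents). One consequence worth noting: a single simulated
chromosome is a highly autocorrelated sample, so its printed averages carry
much larger sampling variance than a same-size independent-locus mean.

Mutation uses the infinite-sites model conditioned on an exact variant
count: each of `n_snps` sites falls on a branch with probability
proportional to branch length, carriers follow descent, and ancestral/
derived bases are drawn uniformly without replacement from {A,C,G,T}.
Conditioning on the SNP count (rather than a θ-driven Poisson number)
mirrors the truncation protocol used when comparing tree inference at
fixed SNP counts. Positions are assigned consecutively, so simulated
windows carry no recombination structure or realistic spacing — passing
window tests shows tree inference and weighting behave correctly given the
SNP matrix, not that real linkage patterns are captured.

## Evaluation

Two weighting vectors are compared with the scaled Euclidean distance

    d = sqrt( Σ_i (w_i − x_i)² / m_i² / (n − 1) ),    m_i = max(w_i, 1 − w_i),

where w is the reference vector and m_i its per-coordinate maximum
possible deviation (never below 0.5, so no division by zero). d = 0 means
identical weightings. The statistic is asymmetric (m depends on the
reference only) — the tests assert this deliberately. In contrived corners
the raw formula can exceed 1 by a few percent (several coordinates near
maximal deviation at once); the implementation clamps at 1.0 to honor the
advertised 0–1 scale. Accuracy is reported as 1 − mean(d).

Track aggregation offers plain and span-weighted means (span weighting is
needed when rows are true-genealogy blocks of unequal length) and a
center-weighted moving average for visual smoothing — a moving average
replaces loess here because smoothing is presentational and does not merit
a fitting stack.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` simulates 2000 independent `neutral4` loci for the
chromosome means and 100 replicates of the four-population,
four-sequences-per-population, t1 = 0.5 design at 50 SNPs for the accuracy
figure. Both sizes give Monte-Carlo standard errors well under the
tolerances of interest (≈0.5 percentage points on the means) while keeping
the whole script in the seconds range.

## Known limitations

* Exact weighting is exponential in the number of taxa with many unsorted
  samples; beyond the ceiling only sampled weightings are practical.
* Topology enumeration refuses more than 8 taxa unless overridden —
  (2n−5)!! grows too fast for the catalog to be useful much beyond that.
* The simulator has no recombination, selection, growth or gene
  conversion; it is a test harness for the weighting machinery, not a
  general-purpose coalescent.
* Windows are defined in SNP counts only; base-pair windows are not
  implemented.
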