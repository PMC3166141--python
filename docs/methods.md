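# Methods

`slocus` quantifies the evidence that putative stylar S-allele sequences in
Papaveraceae function in gametophytic self-incompatibility (GSI), and probes
one specific artefact that could mislead sequence-based inference: apparent
recombination introduced by sampling a duplicated, non-functional paralog
alongside genuine S-alleles.  This note records the models, parameter
choices, numerical decisions and limitations.

## Crossing concordance

Under single-locus GSI, haploid pollen is rejected when its S-allele matches
either pistil allele.  Among full sibs of two heterozygous parents this
predicts three phenotype classes from genotype alone: *incompatible*
(identical two-allele genotypes), *semi-compatible* (exactly one shared
allele; the non-matching pollen class suffices for fruit set) and
*compatible* (no shared allele).  Plants from which only one S-like product
amplified are classed *ambiguous*; by design they are excluded from
concordance tables when their recorded class is ambiguous, since most
unexpected fruit set in the source crossing data traces to such plants.
Co-amplified products that never separate in offspring (e.g. the pairs
encoded here as `S3ab` and `S2de`) are collapsed into single haplotype
units before any prediction, and the tetraploid *Argemone munita* is
modelled with its two amplified products as a diploid-like genotype, since
its crossing data show no more than four mating types per sibship.

Concordance is tested on the 2x2 table (cross class x fruit/no-fruit)
with the Pearson chi-square statistic *without* Yates continuity
correction -- the convention that reproduces the published statistics
(93.02 for the *A. munita* table, 113.74 for *Platystemon californicus*)
-- and with Fisher's exact test (two-sided, summing all tables no more
probable than the observed one).  Both are computed via scipy behind the
module surface; the test suite checks them against first-principles
oracles (the Sum (O-E)^2/E formula; full hypergeometric enumeration).

One row of the *P. californicus* table (10/23 fruit among crosses of
plants with only the single recorded product `S1b`) is tabulated as
predicted-incompatible, exactly as published, because the published
totals and chi-square include it; the record additionally carries an
`ambiguous_genotype` flag so analyses can exclude it explicitly.

Diallel analysis: among five full sibs of a one-locus GSI cross there are
only four mating types, so some pair must share a type and be reciprocally
incompatible (pigeonhole; the probability of *no* such pair is exactly
`perm(m, k) / m^k` for k sibs over m equally likely classes -- 0 for
k=5, m=4, and ~0.4999 for the 16-class two-heterozygous-locus
alternative, which is why observing incompatible pairs in all ten
published 5x5 arrays argues for a single locus).

## Coalescent model of pseudogene contamination

The allelic genealogy of S-alleles under long-term balancing selection is
approximated by a neutral coalescent with effective size inflated by a
factor `f`; time is measured in units of `4 N_e f` generations so that a
pair of S-lineages coalesces at rate 1, and the per-site mutation
parameter is `theta_s = 4 f N_e mu`.  A pseudogene created by duplication
`t_d` time units ago escapes balancing selection (per-site parameter
`theta_p = theta_s / f`, hence pair-coalescence rate `f`) and escapes
recombination suppression: between adjacent sites it recombines at scaled
rate `rho_site = theta_s * (r/mu)` per interval (derived from
`4 f N_e r = (4 f N_e mu)(r/mu)`), but only at times more recent than the
duplication.  Breakpoints fall on the `L - 1` inter-site boundaries and
are drawn uniformly over the interval spanned by a lineage's ancestral
material.  Immediately ancestral to `t_d` the pseudogene passes through a
severe bottleneck of duration `t_b` with pair-coalescence rate
`theta_s / theta_b` (relative size `theta_b / theta_s`), representing the
single duplication origin; any lineages surviving it simply rejoin the
S-allele class rather than being forced to one lineage -- with the
default severity `theta_b = theta_s / 2,000,000` collapse to a single
lineage is certain to within e^-10000.  Above `t_d + t_b` a single
panmictic S-class coalescent with no recombination runs to the grand MRCA
of every site.  A sample of `n` sequences contains
`round(c * n)` pseudogene contaminants (exact integers for the design
values c in {0.25, 0.5, 0.75} with n = 24).

Defaults mirror the published simulation design: `f = 20`, `n = 24`,
`L = 327` bp, `t_b = 0.005`, `theta_b = theta_s / 2e6`, with factorial
grids over `theta_s`, `t_d`, `r/mu` and `c`.  The published `t_d` list
prints a duplicated value ("0.01, 0.1, 0.1, 1, 2, 3"); the default grid
uses the five distinct values.  Whether the original implementation
allowed recombination up to `t_d` or to `t_d + t_b` is not stated; here
recombination stops at `t_d`.

### Implementation

The backward-in-time event loop (numba-compiled) tracks, per lineage, the
tree-node id carried at each site.  Every coalescence that merges
ancestral material records one `(site, parent, child1, child2)` triple,
exactly `n - 1` per site, from which all marginal trees are rebuilt; a
site is pruned from the surviving lineage the moment its marginal MRCA is
reached.  Two exact optimisations keep the high-`rho` regime tractable:
(i) recombination proposals are restricted to breakpoints strictly inside
a lineage's ancestral span (splits that leave one side empty are
identity operations on the ancestral process); (ii) when the bottleneck
guarantees pairwise coalescence (rate x duration > 40), any site left
with a single pseudogene-class carrier is parked in a frozen reservoir
lineage -- from that moment no pseudogene-internal event can record a
merge for it, and all pseudogene material provably ends in one lineage at
the duplication time, so the event churn skipped this way has no effect
on the distribution of marginal trees.

Sequences evolve under Jukes-Cantor along each site's marginal tree:
branch lengths convert to expected substitutions per site as
`t * theta_s / 2` (so a pair of S-lineages accumulates `theta_s`
differences per site in expectation), mutation counts are Poisson per
edge, each mutation replaces the current base of the affected subtree
with one of the other three uniformly, and root states are uniform.
This is a finite-sites model: at moderate `theta_s` multiple hits make
the count of polymorphic columns fall below the infinite-sites
(Watterson) expectation `theta L a_{n-1}` -- about 2% at
`theta_s = 0.01` -- while the number of mutation *events* matches it
exactly.  The validation suite therefore checks mutation counts against
the Watterson expectation at `theta_s = 0.1` and polymorphic-column
counts at low `theta_s` (3 Monte Carlo SE plus a stated 2% finite-site
allowance), and compares whole distributions (TMRCA; polymorphic columns
under matched finite-site JC) against msprime as an independent
reference.

## LD-distance permutation test

Sites are reduced to biallelic polymorphic columns (columns with gaps,
ambiguity codes or more than two states are dropped entirely; singletons
are retained by default, with an optional minor-allele-count filter).
For every column pair, `r^2 = D^2 / (p_A q_A p_B q_B)`; the statistic is
the Pearson correlation of `r^2` with inter-site distance, one-tailed
toward negative correlation (LD decay).  The null distribution permutes
the assignment of columns to positions; since both marginal multisets are
invariant, only the cross-sum `sum r^2_ij d_ij` varies, which the
implementation exploits (numba kernel over permutations).  The
Monte-Carlo p-value is `(1 + #{corr_perm <= corr_obs}) / (n_perm + 1)`;
for `S! <= n_perm` columns the permutation set is enumerated and the
p-value is exact.  Alignments with fewer than three usable columns score
"not detected" (p = 1) so that low-diversity grid combinations still
contribute to detection proportions.  Defaults: 1000 permutations,
alpha = 0.05.

Power is maximal at *moderate* per-interval `rho`, where nearby sites
retain LD while distant pairs equilibrate; at very large
`rho = theta_s * (r/mu)` all pairs are equally unlinked, the distance
gradient vanishes, and power collapses back toward alpha.  This is also
the mechanistic reason contaminated samples rarely trigger detection:
the recently duplicated pseudogene contributes little diversity of its
own, so its internal recombination barely shapes the pooled r^2-distance
relationship.  The packaged power check therefore uses a freely
recombining neutral sample at `r/mu = 5` (`rho_site = 0.5`), where decay
across 327 bp is clearly expressed.

## Diversity statistics

`pairwise_pi` is the mean over unordered pairs of the proportion of
differing sites among comparable sites (pairwise deletion of gap or
ambiguous positions).  The Nei-Gojobori pathway method classifies codon
differences by averaging over all orderings of the changed positions;
synonymous site counts per codon are the per-position fractions of
synonymous single-nucleotide changes, averaged between the two sequences.
Conventions the source analysis left unstated were fixed as follows:
changes *to* stop codons count as non-synonymous, so synonymous plus
non-synonymous sites always sum to three per codon; pathways passing
*through* a stop codon are excluded, falling back to including them only
when every pathway is blocked; codons containing gaps, ambiguity codes
or a stop in either sequence are skipped pairwise, not alignment-wide.
The Jukes-Cantor correction `d = -(3/4) ln(1 - 4p/3)` is applied to
pS/pN by default (consistent with published synonymous divergences as
large as 0.70, which exceed the uncorrected ceiling of 3/4 only barely
but are implausible as raw proportions); pairs at `p >= 3/4` are flagged
saturated and dropped from the dS/dN means with a count, never clipped.
A flag yields uncorrected proportions instead.

Sliding-window pi uses window 50 and step 10 by default (the published
figure's parameters are unstated; both are configurable) with 1-based
inclusive coordinates.  The divergence-time helper computes
`T = ds / rate` verbatim from the source's stated formula; the
conventional pairwise halving `T = ds / (2 rate)` is available behind an
explicit option because the stated formula omits it.

## Synthetic data

The generator reproduces the study conditions rather than idealised ones:
full-sib families transmit one haplotype unit per parent uniformly and
independently (1:1:1:1 genotype ratio; linked product groups transmit as
units); fruit counts are binomial with class probabilities
`p_fruit_semi`, `p_fruit_compat`, a baseline for incompatible crosses,
and per-allele "weak SI" leak rates (the published weak allele `S25b`
corresponds to `leak = {"S25b": 0.59}`, matching its observed 59% fruit
set in matching-genotype crosses).  GSI pollen selection is *not* applied
inside family generation -- parents in the encoded designs carry disjoint
genotypes, for which uniform independent transmission is the exact
single-locus GSI expectation -- and tetrasomic inheritance is not
modelled.  Planted-diversity alignments draw each column independently as
monomorphic or biallelic with minor-allele count chosen so expected
column heterozygosity hits the target inside and outside a declared hot
region; realised global pi concentrates within ~10% of target for
`L >= 300`, `n >= 10`.

The two published crossing tables are encoded cell by cell as data (not
re-derived), so concordance statistics can be recomputed without network
access; the family 1-2 unamplified paternal allele is an explicit
`"S2?"` haplotype so ambiguity handling is exercised.

## Problem sizes and reproduction

The packaged reproduction of the detection-ceiling claim
(`scripts/acceptance.py`, and the corresponding acceptance test) uses a
reduced factorial grid -- `theta_s` in {0.1, 1}, `t_d` in {0.1, 1},
`r/mu` in {20, 200}, `c` in {0.25, 0.75}, 500 replicates and 500
permutations per combination -- chosen as the package's desk-scale
design: it brackets the published grid's interior while keeping a full
run in the minutes range on one core.  The maximum detection proportion
over combinations, allowing two binomial standard errors, is compared
with the published ceiling of 0.075.  The full published grid (six
`theta_s` values, five `t_d`, six `r/mu`, three `c`, 1000 replicates) is
available through `run_grid` for larger budgets.

All stochastic operations draw from a single numpy `Generator`; grid
combinations use subseeds spawned deterministically from the master seed,
so results are reproducible and independent of combination order.  The
compiled kernel uses a subseed drawn from the caller's generator (numba's
own RNG state), preserving end-to-end determinism.

## Limitations

* Balancing selection enters only through the `f` rescaling; no explicit
  frequency-dependent selection, gene conversion, or demography beyond
  the single bottleneck.
* The finite-sites JC model means column-count summaries undershoot
  infinite-sites formulas at high `theta_s`; comparisons should use the
  matched finite-site expectation or low mutation rates.
* Passing the synthetic-data tests shows the statistics behave correctly
  under the stated models; real stigmatic sequence data add alignment
  error, PCR/amplification bias among alleles and possible multi-locus
  structure that the generator deliberately does not emulate.
* Published genus-level diversity values depend on the exact GenBank
  sequence sets and DNASP settings used by the original analysis and are
  therefore documentation-level validation only, not unit tests.
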