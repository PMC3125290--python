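# Methods

## The problem and the model

Under neutral clock-like evolution, the number of synonymous substitutions
separating an extant mtDNA haplotype from the most recent common ancestor
(MRCA) of its super-lineage is a Poisson count with mean `rate x age`.
Three consequences drive everything in this package:

1. the distribution of per-haplotype distances within a homogeneous set of
   lineages should fit Poisson(mean);
2. the mean distance of a clade's tips to the clade MRCA (the rho
   statistic) divided by the per-lineage rate estimates the clade's age;
3. the synonymous/non-synonymous split should follow the mutational site
   content, because selection acts on replacements, not silent changes.

Departures are informative: a clade whose tips sit too close to the
super-MRCA either mutates slowly (both mutation classes depleted) or is
under selection (replacements enriched, silent changes depleted). The two
cases demand different treatment — a slow clade can be re-dated with its
own recalibrated rate; a selection-distorted clade cannot be dated from
synonymous counts at all.

## Distances and mutation classes

Trees are rooted, with explicit substitution lists on branches (topologies
are inputs — from curated phylogeny databases or the simulator — never
inferred here). A tip's distance to an ancestor is the number of branch
events on the connecting path that pass a class filter: synonymous only,
all coding (synonymous + non-synonymous + nonsense), an HVS1 position
window (16090–16383, 1-based inclusive), or everything. Distances are
event counts, not Hamming distances: recurrent and back mutations each
count once per event.

Classification uses the vertebrate mitochondrial genetic code (NCBI table
2; Biopython's code tables) with 1-based inclusive reference coordinates.
Light-strand genes are classified after complementing the codon context
into reading orientation. Codon context is taken from the root reference
sequence; at the divergences handled here (a few events per 10 kb
lineage) the reference context is the ancestral context in effectively all
cases. Indels inside coding spans are flagged frame-disrupting and
excluded from synonymous/non-synonymous counts, as are events at
ambiguous bases or on a user-supplied exclusion list (e.g. known
pathogenic positions; empty by default). Site content is the Nei–Gojobori
fractional count: each codon's nine single-base neighbours contribute 1/3
synonymous site per silent neighbour, with stop-creating changes counted
on the non-synonymous side, so S + N = 3 x codons always.

## The Poisson accumulation test

The default test is the classical one-sample Kolmogorov–Smirnov recipe
applied to the integer counts against Poisson(sample mean): because both
the empirical and the Poisson CDF are step functions on the integers, the
sup-gap d is evaluated on the integer support, and p comes from the
asymptotic Kolmogorov distribution. Estimating the rate from the same
sample makes this conservative (true type-I rate well below nominal; the
test suite verifies <= 2 % rejections at the 1 % level under a true
Poisson null). A parametric-bootstrap variant (`method="bootstrap"`)
re-estimates the rate per resample and gives an exact discrete reference
distribution; the asymptotic recipe remains the default for comparability
with the literature that uses it.

The histogram chi-square test bins distances at unit width from zero,
pooling the right tail until every expected cell count reaches a
configurable floor (default 1). Published degrees of freedom for such
tests are data-dependent; the binning rule, not a fixed df, is the
specification.

## Rho dating

`rho` is the arithmetic mean tip-to-MRCA synonymous count. Published
per-site literature rates for mtDNA are stated in mutually incompatible
units, so the canonical calibration here is **anchoring**: a reference
clade with known rho and age fixes the per-genome synonymous rate
(`anchor_rate(8.26, 54 500 y)` gives 1.5156e-4 syn/genome/yr in the worked
example) and every other clade's age is `rho / rate`. Literature per-site
rates are accepted only together with an explicit synonymous-site count.

**Recalibration** for a slow clade divides the clade tips' mean distance
to the *super-lineage* MRCA by the super-lineage age, giving the clade's
own long-run rate (per-site form available given a site count; the
worked-example recalibration implies ~4 200 effective synonymous sites if
expressed at 1.70e-8 /site/yr — larger than the Nei–Gojobori fractional
count of a 11 kb coding region, because the effective count depends on
which annotation release defined "coding"; both numbers are reported, not
reconciled). The simulator's rate-multiplier semantics mirror this
reading: a clade's multiplier applies along its whole history from the
super-root down, which is exactly the situation in which recalibration
recovers the multiplier (verified in the acceptance suite: a 0.5x clade
recalibrates to ~half the baseline rate within 15 % at 500 tips).

Clades with an inverted synonymous/non-synonymous ratio
(`selection_flag`, default threshold: replacements > 50 % of coding
events) are reported `ND` — their synonymous counts understate the events
that occurred.

**Intervals.** The default interval is the star-phylogeny heuristic
`sqrt(rho/n)/rate` (tips treated as independent Poisson draws). When the
branch structure is available, the exact estimator variance
`var(rho) = sum_b l_b (n_b/n)^2` over branches (l_b events, n_b subtended
tips) is used instead; it reduces to rho/n on a star. Neither reproduces
intervals published from other tree topologies, and they are labelled
heuristic in output.

## Ancestral sequences

An internal node is an "ancestral sequence" (AS) when at least one
descendant tip has accumulated zero derived coding mutations below it (the
carrier) and at least one descendant has diverged. Detection uses the
all-coding filter (a carrier is sequence-identical, silent and replacement
alike); the distances Da (mean AS-to-diverged-relative) and Db
(AS-to-super-MRCA) are synonymous counts, matching how such tables are
published. The lifespan statistic is `Da/(Da+Db)`: 1.0 for an ancestor
sitting on the super-MRCA itself (Db = 0), 0.5 when relatives have
diverged exactly as far as the ancestor is deep. When nested nodes share
the same carrier set only the closest-to-root node is reported (the oldest
ancestor). Note the orientation: the ratio that reproduces published
per-clade percentages puts Da in the numerator, even though the quantity
is sometimes described with the roles swapped; this package standardises
on the orientation that reproduces the tables.

## Branch dN/dS by counting

Maximum-likelihood codon models are out of scope; the contrasts here are
counting-based. Ancestral sequences come from Fitch parsimony
(intersection/union up-pass; down-pass ties resolved toward the parent
state, the root taking the alphabetically first base of its set — a
deterministic tie-break). Each branch's differing codons are decomposed
into single-base steps averaged over all minimal substitution orders with
uniform weights; counts are normalised by the ancestral sequence's
fractional site content. Class omega is `(N/Nsites)/(S/Ssites)` pooled
over the class's branches; a class with zero observed synonymous changes
has undefined omega, printed `*`. The meaningful surface of this stand-in
is the ordering and the zero/undefined structure across classes (stems of
a selected clade > slow lineage > background), not absolute ML omegas.
Fitch reconstruction at low divergence recovers >= 95 % of true ancestral
sites (verified against simulator ground truth), but parallel changes and
multiple hits bias counting omega slightly below 1 for neutral data
(~0.85–1.0 at the simulated scale); the neutral-bracketing check in the
acceptance suite uses the band [0.8, 1.2] accordingly.

## HVS1 quality

HVS1 transitions are split by a speedy/weighty site-class table —
published filters are shipped by the user as a two-column TSV; the
packaged `synthetic_site_class_table` (every 4th position weighty, ~25 %)
is a labelled synthetic stand-in for tests only. Transversions and indels
are pooled regardless of class. The WTTI ratio (weighty transitions /
transversions+indels) sits in [2.3, 4.8] for curated good-quality sets and
near 49 for a known bad set; zero denominators yield an infinite-quality
sentinel. Counting is per-occurrence by default (each haplotype's variant
counts once per carrier); `per_occurrence=False` collapses repeated
variants, since published totals do not always state which convention was
used.

## The simulator

The generator emulates the study conditions end to end and its defaults
are those conditions: 500 haploid sequences of 3 000 nt, mutation rate
1.0e-4 /site/generation, omega 1, exponential growth 1.0e-3, effective
population size 1 000. Genealogies are msprime coalescents (haploid
samples, single exponentially growing population). Sequence evolution is
an acceptance/rejection sampler: candidate substitutions arrive as
Poisson(mu x L x branch-length x rate-multiplier) with uniform site and
uniform alternative base (Jukes–Cantor-like exchangeability, uniform
non-stop codon usage at the root); stop-creating candidates are redrawn;
a candidate is accepted with probability min(1, omega) if non-synonymous
and min(1, 1/omega) if synonymous under its branch's lineage class. The
true event log is retained, and the emitted tree carries the events on its
branches, so tree-path distances, the event log and sequence differences
are three mutually checkable routes.

The ascertainment protocol ranks segregating sites by expected
heterozygosity (a 50/50 split is maximal), splits the population by joint
alleles at successive top-variance sites until at least 5 pseudo-
haplogroups of at least 20 members exist (an unreachable criterion returns
the best achieved partition with an explicit warning flag, never
silently), then draws either a uniform random sample or a
haplogroup-proportional sample (largest-remainder rounding; undersized
groups contribute everything and the shortfall reallocates). Sample tree
omega is measured on the true induced subtree by Fitch + counting. Ten
replicate sets with ~40-sequence samples reproduce the negative result:
the paired bias-vs-random omega difference is indistinguishable from zero
(|mean| < 0.1).

What the simulator does **not** model: recombination (none in mtDNA),
migration/population structure, indels, rate variation among sites,
transition/transversion bias, and realistic codon usage. Passing tests on
simulated data therefore demonstrate the correctness of the statistical
machinery under the stated model, not robustness to these real-data
features. Generations convert to years at 25 y/generation where dating of
simulated clades is needed.

## Problem sizes and numerical choices

The test and acceptance batteries use: 1 000 cohorts of n=100 for the KS
type-I check; 10 replicate populations at the full study scale (500 x
3 000 nt) for neutral omega bracketing and the ascertainment experiment;
12 replicates for the rate-multiplier recovery. The whole suite runs in
well under a minute on one core. Degenerate inputs are errors, not
silent results: all-zero count vectors (Poisson rate 0), empty clades,
Da+Db = 0 lifespans, unrooted trees for root-to-tip distances, and
unclassified HVS1 transition positions all raise with a named cause.
Singleton groups report NaN standard deviations. Ages print in ky to two
decimals; underlying values are kept in years unrounded.
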