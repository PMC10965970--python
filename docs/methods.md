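# Methods

This note documents the models implemented in `bridgehead`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Demographic model

Four populations along an invasion chain: a native source (Japan) and three
invasive populations (USA, Azores, Italy) founded at fixed times of 112, 52
and 12 generations before sampling, at one generation per year. Two scenario
topologies differ only in the source of the most recent introduction:
`single_introduction` takes Italy from the Azores, `double_introduction`
takes Italy directly from the USA.

Genealogies follow the haploid continuous-time Kingman coalescent: within a
population of haploid effective size Nₑ, k lineages coalesce at rate
k(k−1)/(2Nₑ), so a pair has expected coalescence time Nₑ. mtDNA is maternal
and effectively clonal, so Nₑ throughout is the haploid mitochondrial
effective number. Founding times are treated as exact event times at which
the daughter population's surviving lineages are injected into the source;
each population has a single constant Nₑ from its founding (no separate
bottleneck parameter — a two-phase Nₑ is over-parameterised for a single
non-recombining locus, and the constant-Nₑ model already produces the
founder-effect diversity ladder). There is no migration after founding and no
recombination.

Sampling consistency of the Kingman coalescent is verified in the tests
against closed forms (E[T₂] = Nₑ, E[TMRCA] = 2Nₑ(1−1/n)) and against an
independent implementation of the same demography in msprime
(Kolmogorov–Smirnov on the TMRCA distribution, both topologies).

## Sequence evolution

TN93 with empirical-style base frequencies, two transition-class rate ratios
(C↔T and A↔G against transversions, defaults 25 and 41), a proportion of
invariant sites (default 0.85) and gamma rate heterogeneity (shape 1.17,
continuous by default; equal-probability discrete categories are available
for cross-checks against likelihood-software conventions). The ratios are
interpreted as instantaneous-rate ratios; this choice is isolated in
`MutationModel.rate_matrix`, which is the single place to change if the
expected-substitution-ratio reading is preferred.

The generator matrix is normalised to one expected substitution per site per
unit time at stationarity, so a branch of b generations at mutation rate μ
(substitutions/site/generation) and site-rate multiplier r has length μ·b·r
in expected substitutions. Invariant sites have r = 0 and variable sites a
mean-1 gamma multiplier, hence the realised genome-wide mean rate is
μ(1−p_inv); estimates of μ are on the model scale, not the realised mean.

Branch endpoint states are sampled from the exact finite-time transition
probabilities P(t) = exp(Qt), obtained from the spectral decomposition of the
reversible generator (symmetrised with √π). Exact Bernoulli thinning keeps
this fast at low rates: a site can only have changed if its uniform draw u
satisfies u < q_max·t (because 1 − P_ii(t) ≤ q_max·t, with q_max the largest
exit rate), so the exponentials are evaluated only at those candidate sites
and the same u decides acceptance against the exact change probability. This
is exact in distribution — no event-time approximation is involved — and its
cost scales with the expected number of substitutions. Degenerate
numerically-zero transition rows (branch length ≈ 0) fall back to a uniform
choice over the three non-parent states; negative round-off probabilities are
clipped at 0.

## Default study conditions of the generator

Sample sizes default to 21/23/20/22 (Japan/USA/Azores/Italy), alignment
length L = 16,031, and μ = 1.14×10⁻⁶ s/s/g. Default effective sizes are
Nₑ = 30,000 (Japan), 850 (USA), 130 (Azores), 5 (Italy). These were set once
by moment matching to the observed regional diversity ladder of the
motivating dataset: Japan's π ≈ 0.0104 fixes Nₑ(Japan) ≈ π/(2μ(1−p_inv));
the invasive Nₑ's are chosen so that the expected number of founding lineages
surviving each founding interval (k → k′ takes ≈ 2Nₑ(1/k′ − 1/k)
generations) reproduces the observed haplotype counts (≈14 in the USA after
112 generations, ≈5 in the Azores after 52, 1 in Italy after 12). They are
study conditions, not fitted parameters.

What the generator emulates: the founder-effect decay of diversity along the
chain, haplotype sharing between source and daughter populations, TN93+I+Γ
site-pattern structure, and the two competing introduction topologies. What
it does not emulate: sequencing error and N-masking, indels and alignment
error, selection on the mitogenome, post-founding migration or admixture,
population growth, and calendar sampling spread (all tips are sampled at one
time). Tests passing on synthetic data therefore validate the estimators
under the model, not robustness to these real-data artefacts.

## Diversity statistics

Haplotype identity is exact string equality (including N and gaps); the
intended input is a complete, fully resolved alignment, where this matches
the behaviour of standard haplotype-collapsing tools. Hd uses the n/(n−1)
correction — on integral haplotype configurations this exactly reproduces
the published regional values the implementation is checked against
(0.98571, 0.91304, 0.63158). π uses pairwise-complete deletion: columns
where either member of a pair holds N or a gap are dropped for that pair
only, and each pair's denominator is its own compared-site count; on a clean
alignment this equals complete deletion. Mean pairwise differences are
absolute counts (not per site), the convention of ABC summary statistics.
The 20-statistic vector order is fixed: (Japan, USA, Azores, Italy)
one-sample pairs of (haplotype count, mean pairwise differences), then the
six population pairs in lexicographic order with (pooled haplotype count,
between-population mean differences). The pooled definition of the
two-sample haplotype count is used.

## Selection tests

Original Nei–Gojobori counting under NCBI translation table 5 (invertebrate
mitochondrial): potential sites per codon position are the fraction of the
three possible changes that are synonymous, with changes to stop codons
removed from the denominator (S + N = 3 per codon); a position whose three
changes all create stops counts as one nonsynonymous site. Multi-substitution
codons are averaged over all orderings of single steps with equal weight;
pathways through stop codons are excluded, and codon pairs with no stop-free
pathway are skipped and logged. Ka = N_d/N and Ks = S_d/S as p-distances,
with optional Jukes–Cantor correction (error above p = 3/4). The Fisher test
rounds the fractional table entries to the nearest integer and reports the
one-tailed hypergeometric tail; degenerate tables return p = 1 with a
warning. Pairwise p-values are reported uncorrected, as the analysis asks a
global question (is any pair significant) rather than per-pair inference.

## ABC engine

Reference tables draw μ and the four Nₑ independently from flat priors
(μ ∈ [1.115×10⁻⁸, 1.5×10⁻⁵] s/s/g; Nₑ ∈ [10, 10⁵], a declared assumption —
project-style defaults rather than published bounds). Statistics are
standardised by their median absolute deviation over the table; columns whose
MAD degenerates to zero (counts pinned at their maximum over most of the
prior) fall back to the standard deviation, then to 1 if truly constant.

Scenario choice: the direct estimate is the scenario frequency among the 500
closest rows (ties at the cutoff broken by simulation index), with a
nonparametric bootstrap (10,000 resamples) for its 95% interval — the
interval construction for this binomial proportion is a package choice and is
labelled as such. The logistic estimate fits a binomial GLM of the scenario
label on statistic deviations over the closest 1% and evaluates it at
deviation zero, with a delta-method interval on the linear predictor;
complete separation falls back to the direct estimate with a warning.

Parameter estimation: local-linear regression adjustment over the closest 1%
with Epanechnikov weights; μ and Nₑ are adjusted on the log scale (they span
orders of magnitude) and back-transformed draws are clipped to the sampled
prior support with a logged count; a singular weighted design is solved with
a small ridge. Point estimate: weighted median. Interval: weighted 95% HPD
(shortest contiguous window of the sorted sample). "Summarised over both
scenarios" means the mixture of per-scenario adjusted samples weighted by the
scenario posterior probabilities.

Desk-scale defaults: 4,000 simulations per scenario in the acceptance script
and 6,000 in the test suite's self-consistency study (the module accepts any
size upward; the DIYABC-style defaults of 500 closest / 1% fractions were
designed for much larger tables, which is worth remembering when
interpreting small-table runs). All analyses are seeded and bit-for-bit
reproducible.

### Known limitation: scenario resolution

The two topologies are nested in distribution: a single-introduction
simulation in which the Azores Nₑ is large enough that no coalescence happens
during the 12–52-generation stopover generates data indistinguishable from a
double introduction. Over most of the flat Nₑ prior (and in particular over
its central half, where Nₑ ≈ 25,000–75,000 and essentially no coalescence
occurs between any of the splits) the scenarios are therefore statistically
equivalent, and modal-scenario recovery on synthetic data sits near chance
(measured ≈ 0.55–0.60 at a 40,000-row reference table) rather than the ≥ 0.7
one might hope for; recovery is asymmetric (single-introduction truths are
recognised, double-introduction truths are ambiguous) exactly because of the
nesting. This is a property of single-locus data under these priors, not of
the estimator: the corresponding self-consistency test is left failing as an
honest statement of that resolution limit. Mutation-rate estimation is
unaffected (95% HPD coverage ≥ 0.9 and posterior medians within a factor ~1.3
of truth in the same studies).

## Lineage counting on dated trees

Ages are years before the youngest tip; input trees carry BEAST-style node
comments (`age`/`height`, `age_95%_HPD`/`height_95%_HPD`). An "introduced
lineage" at threshold T is an edge spanning T (parent age > T ≥ child age,
under either point ages or HPD lower bounds) whose descendants include
focal-region tips; the root is treated as having an infinitely old stem so a
tree entirely younger than T counts one lineage. Using HPD lower bounds
("minimal ages") gives the conservative minimum count. A clade listed in
`collapse_nodes` contributes at most one lineage regardless of its internal
structure, encoding the reading that it diversified after its introduction.
Boundary equality (crown age = T) counts as compatible with local
differentiation. Counts are monotonically non-increasing in T and never
increased by collapsing — both properties are tested against a brute-force
edge enumeration.

## Tandem-repeat annotation

`find_tandem_repeats` targets mitochondrial control regions (a few kb): an
exhaustive scan over unit lengths and phases grows maximal arrays of ≥ 2
copies, each copy within a per-copy substitution budget (default 2) of the
array's majority consensus; overlapping candidates are resolved by more
copies, then longer unit, then leftmost start. A trailing partial copy is the
longest consensus prefix whose mismatches stay within the budget pro-rated by
its length. The implementation is checked against an exhaustive
(start × unit × copies) oracle on short sequences.
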