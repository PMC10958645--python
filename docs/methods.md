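# Methods

`kinlegacy` implements an end-to-end identity-by-descent (IBD) analysis
connecting a small set of *historical* genomes (imputed, low-coverage,
phased) to a large *cohort* of living genotyped participants: IBD segment
detection, relationship-degree estimation, genetic-family reconstruction,
cohort/geographic enrichment testing, IBD-network community analysis, and
pedigree attachment-point inference.  Because the cohort data such a study
runs on is private, the package ships a first-class synthetic study
generator whose planted structure makes every stage testable against
exact ground truth.

## The synthetic genome and study

**Genetic map.** The default genome has 22 autosomes whose genetic
lengths are scaled human autosome lengths summing to a haploid total of
L_hap = 3,500 cM, so the diploid total is D = 7,000 cM.  This puts degree
arithmetic on the human scale: 280 cM of sharing is 4% of the diploid
autosomal genome.  Recombination is uniform at 1 cM per 10 kb on the
synthetic bp scale (a supplied map file overrides this).  The demo study
uses 20,000 sites (~5.7 sites/cM); this density matters — see
"Chance matches" below.

**Populations.** Allele frequencies follow the Balding–Nichols model:
ancestral frequencies uniform on (0.2, 0.8) and per-population draws
Beta(p(1−F)/F, (1−p)(1−F)/F) with drift F = 0.1 by default, so F is the
expected Fst between populations (validated against a Hudson moment
estimator in the tests).  Three populations stand in for West African,
European and Indigenous American ancestry sources.  The ancestral
frequency range deliberately avoids near-fixed sites, which would
otherwise create long chance haplotype matches between unrelated
individuals.

**Admixture.** An admixed haplotype is a Markov mosaic along the map:
ancestry switches arrive at rate g per Morgan (g ≈ generations since
admixture, default 6–8), each tract's population is drawn from the
mixture weights.  Two variants exist: `simulate_admixed` copies alleles
tract-wise from a donor panel (creating real IBD with the donors — useful
for targeted tests), while `simulate_admixed_fresh` draws alleles
site-wise from the tract population's frequencies.  The study generator
uses the frequency-level variant for everyone not genealogically planted:
at study scale, donor-copying from any panel of realistic size would
create pervasive artifactual IBD between "unrelated" cohort members,
which is precisely what the generator must not contain.

**Gene dropping.** Pedigree founders receive labelled haplotypes; every
meiosis draws a Poisson(len/100 cM) crossover count with uniform
positions in cM and no interference.  Descent labels are carried along,
so the true IBD between any two pedigree members is recoverable exactly,
as maximal intervals where two haplotypes carry the same founder-haplotype
label (contiguous shared intervals are merged, matching what a detector
observes).  Meiosis conserves total genetic length: a parent-child pair
totals exactly 3,500 cM when summed over the four haplotype pairings —
the "% of diploid genome" scale used throughout.

**The planted study.**  27 historical individuals: five genetic families
(a mother, two sons who died in childhood, and a 2nd–3rd-degree relative;
plus four mother/children groups; 15 individuals in all) and 12 unrelated
singletons.  Every family's mother has an un-genotyped father who descends
from a fully European founder couple, and Family A's un-sampled father
carries substantial Indigenous-American-like ancestry.  The ~2,000-member
cohort spans 11 regions (five US, three African, three European) with
region-appropriate ancestry mixes and birth/grandparent metadata.  Planted
relatives descend from un-genotyped ancestors of the families through
lineages of 4–9 meioses: close relatives concentrated in one US region
(the Maryland analog), distant connections concentrated in two African and
two European regions, and a set of collaterals of Family A's father who
inherit his Indigenous-American ancestry.  Lineage lengths were chosen so
expected totals (a·D·2^−d for a collateral pair with a common-ancestor
couple at path degree d) straddle the relevant thresholds: ≥30 cM for the
close group, ~10–30 cM for the distant groups.

**Degradation.** The historical panel is degraded with per-allele flips
(rate 0.001) and per-site diploid masking (rate 0.02); masked sites are
refilled with the per-site major allele before matching.  This emulates
matching against *imputed* complete genomes, with the flip channel
standing in for residual imputation error.  Five singletons are labelled
with a low pseudo-coverage and excluded from cohort summaries, mirroring
a coverage-quality cut (22 of 27 analyzed).  What the generator does
*not* emulate: linkage disequilibrium within populations, realistic
site-frequency spectra, phasing error, and coverage-dependent imputation
bias — so passing tests demonstrate the pipeline's correctness on its own
model assumptions, not robustness to all real-data pathologies.

## IBD detection

Detection is a positional Burrows–Wheeler transform (PBWT) long-match
sweep: one left-to-right pass per chromosome maintains the positional
prefix array and divergence array, and reports every maximal interval
over which two haplotypes are allele-identical for at least L sites,
exactly once, in O(sites × haplotypes) plus output.  The cM floor is
converted to L per chromosome as the smallest site count any window
spanning the floor can have, and candidates are re-filtered on their
actual genetic span, so the output is exactly "all maximal matches ≥
min_cM" — verified against a brute-force all-pairs maximal-run scan on
hundreds of random panels.

Error tolerance is obtained by stitching rather than by templating:
segments are called down to min_cM/2 (with a `min_sites` floor, default
16), same-pair fragments separated by gaps ≤ 1 cM are merged (gap
included in the length), and the full min_cM floor (default 7 cM) is
re-applied.  A single allele flip inside a long true segment therefore
splits and re-merges instead of being lost.  The halved pre-stitch floor
is essential — stitching would otherwise be vacuous.

**Chance matches.** For unrelated haplotypes the probability that one
site matches is q = 1 − 2·E[f(1−f)] ≈ 0.6–0.7, so a spurious k-site run
has probability ~q^k.  At the demo density a 7 cM segment spans ~40
sites (q⁴⁰ ≈ 10⁻⁹ per position — negligible), but the pre-stitch floor
spans only ~20, which is why both the cM floor *and* the site floor are
applied before stitching and the full floor after.  Reducing site count
without reducing map length collapses these floors and floods the output
with chance matches; scaled-down tests therefore shrink the *cohort*, not
the site density.

Per-pair IBD is condensed to individual level by summing across all four
haplotype pairings (regions IBD on both pairings count twice), making
parent-child ≈ 3,500 cM on the diploid-percent scale.

## Relatedness and families

Degree uses the expected-sharing convention E[T | d] = D·2^−d
(parent-offspring and full siblings both degree 1).  The estimate is
round(log₂(D/T)) clamped to [1, 12], with half-integer values rounded
toward the *closer* degree; totals below 10 cM get no degree (a single
short segment carries no degree information), only "IBD-connected"
status.  Totals ≥ 30 cM flag a close relative (estimated 9th degree or
closer under this model).  This deliberately uncorrected estimator is
biased toward more-distant calls at small totals because detection misses
short segments; the ±1-degree recovery criterion absorbs this.

Genetic families are connected components of the graph over historical
individuals whose edges are pairs of estimated degree ≤ 3; edge labels
become ranges ("2–3") when the continuous estimate sits near a boundary
(> 0.25 log₂ units from the nearest integer).

## Ancestry stand-ins and cohort filters

Global ancestry is simplex-constrained least squares of genotype dosage/2
on reference allele frequencies, solved exactly by enumerating the faces
of the simplex (K is small); degenerate (near-identical) references warn
and yield an arbitrary but deterministic split.  Local ancestry assigns
each ~1 cM haplotype window to the population with the highest allele
log-likelihood, unassigned when the margin is < 2 log-units or the window
has < 10 sites; unassigned windows are excluded from the denominator when
converting to fractions.  Both are transparent stand-ins for the
production estimators whose role they play; the tests verify internal
consistency (window fractions vs global fit within 5 points) and ≥90%
window accuracy on simulated mosaics at F = 0.15.

Cohort filters implement the study's membership rules exactly: African =
≥95% Sub-Saharan African ancestry and self or all four grandparents born
in Africa; European = ≥99% European ancestry and self or all four
grandparents born in Europe; US = all four grandparents born in the US,
or born in the US with grandparent information unavailable or split
across countries; plus the ≥5% SSA and ≥99% European sub-filters of the
US cohort.  All cutoffs are config constants.

## Enrichment and privacy

The randomization test asks whether a focal subset of a cohort carries
more IBD connections (or close relatives) than identically sized random
subsets: the null draws |focal| members without replacement from the
reference cohort; p = (1 + #{null ≥ observed}) / (R + 1).  The add-one
estimator is a valid Monte-Carlo p-value that can never be zero
(resolution-limited at 1/(R+1), matching "p < 0.001" style reporting at
R = 1000).  Because the null is exactly hypergeometric, the exact upper
tail is computed alongside as an oracle; calibration tests require
agreement within 3 Monte-Carlo standard errors and a type-I error rate at
α = 0.05 inside its 95% binomial interval.

Geographic aggregation rounds coordinates to the nearest integer,
retains each participant independently with probability 0.8 (a config
switch selects exact thinning), masks cells with fewer than 25 retained
participants, and suppresses any surviving count of 1–4 so no reported
individual is distinguishable from fewer than four others (k = 5
anonymity).  The privacy rules are asserted over all emitted outputs.

## IBD networks

Pairs sharing ≥ 700 cM (close kin/duplicates) are removed at the *node*
level: while any such pair exists, the endpoint with the larger total
degree weight (ties: lexicographically larger id) is removed.  The
remaining total-cM-weighted graph is clustered by greedy modularity
maximization over a canonical (sorted) node order, making the result
deterministic and order-invariant; the resolution parameter is exposed.
Historical individuals are projected onto clusters by their mean total
sharing with cluster members.  Familial groups take the close relatives
(≥ 30 cM to a historical individual) plus cohort members sharing
≥ 100 cM with a close relative, and cluster that subgraph the same way.
The choice of greedy modularity (rather than any particular production
algorithm) is a design decision; any modularity maximizer satisfying the
determinism and planted-partition recovery properties would do.

## Pedigree attachment

A candidate attachment point is a pedigree node v plus a lineage degree
g: the external descends from v through g meioses of an un-modeled
lineage ("down" candidates; excluded for individuals who died in
childhood), or through an un-modeled ancestor of a node whose parents are
absent from the pedigree ("up" candidates).  The path degree from the
external to genotyped member m is d = g + d(v, m), with the number of
common ancestors a (1 or 2) read off the pedigree.

The likelihood is a composite over genotyped members in the style of
pairwise-IBD pedigree-inference tools,
treated as conditionally independent: expected segment count
ν = a·(r·d + c)·2^(1−d) (r = map length in Morgans, c = chromosome
count), observed count Poisson with mean ν·e^(−d·min_cM/100) under the
detection floor, and segment lengths Exponential with mean 100/d cM
truncated at the floor.  The posterior is the softmax of candidate
log-likelihoods under a flat prior (no demographic prior, deliberately).
Zero observations are handled by the Poisson mass at zero, which makes
distant candidates preferred for externals with no sharing — flagged
"unattachable".  The exponential-length model is an approximation (true
mean lengths are somewhat shorter at small d), but the count term
dominates ranking; recovery tests require the true attachment as MAP in
≥ 70% and in the top two in ≥ 90% of simulated grandchild externals.

Attachment direction is "downward" when the anchor is genotyped or has a
genotyped ancestor (direct descent from a historical person), otherwise
"upward" (collateral through an un-genotyped ancestor).  In simulations
where externals are collaterals, upward MAP attachments dominate, as they
must.  The ancestry-association permutation test permutes a binary rule
label (e.g. Indigenous-American fraction ≥ 2× Sub-Saharan African
fraction) across externals and counts rule-positives attaching at the
focal lineage; the permutation null is evaluated as the equivalent
hypergeometric draw, p = (b+1)/(R+1).

## Pipeline, determinism and problem sizes

Every threshold lives in `RunConfig` (JSON round-trip): min_cM = 7,
stitch gap = 1 cM, close = 30 cM, expansion = 100 cM, prune = 700 cM,
ancestry cutoffs 95/99/5/99, geographic downsampling 0.8 with a 25
participant floor, coverage cut 0.5×.  Display rounding follows the
magnitude-dependent rule (>100 cM → nearest ten; 30–100 → nearest five;
10–30 → integer; <10 → one decimal), halves away from zero with a
banker's-rounding switch.  All randomness derives from one seed through
labelled `SeedSequence` streams, so reruns are byte-identical.

Problem sizes: the demo pipeline runs 27 historical + ~2,000 cohort
members over 20,000 sites in ~3 minutes on one CPU.  The test suite uses
the same site density with a ~390-member cohort for integration tests,
2,000-site 4-chromosome panels for oracle comparisons, and a 44-site
22-chromosome map wherever only segment bookkeeping (not alleles) is
exercised.  These sizes are the package's validation design; the
generator's defaults define the study conditions.

## Known limitations

- No crossover interference; Poisson counts only.
- The degree estimator does not correct for detection false negatives;
  very distant relationships are systematically called distant-or-missed.
- The attachment likelihood ignores correlation between members'
  observations induced by shared transmission paths (composite
  likelihood), and its length model is approximate.
- Sex chromosomes, mtDNA/Y haplogroups, phasing error and LD are out of
  scope; the matcher assumes phased, complete (imputed) input.
- Modularity clustering can merge weakly separated planted groups at
  small cohort sizes; the familial-group count is scale-dependent.
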