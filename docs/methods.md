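# Methods

`karyoevol` implements a desk-scale analysis of karyotype evolution in a
plant genus: morphometric karyotype statistics, flow-cytometric genome-size
arithmetic, a continuous-time Markov model of haploid chromosome-number
change on a fixed phylogram, and Brownian-motion ancestral reconstruction of
continuous karyotype traits.  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Karyotype morphometry

Arm lengths (µm) of all chromosomes of each mitotic metaphase cell are the
primary data.  Within a cell, chromosomes are ranked by decreasing total
length; rank-wise means across cells define the karyotype, and homologues
are paired as consecutive ranks (only lengths are available, so no
image-based homologue matching is attempted).  Each chromosome is classified
from its arm ratio r = long/short using Levan's nomenclature with the
conventional thresholds r ≤ 1.7 (m), ≤ 3 (sm), ≤ 7 (st), > 7 (t); boundary
values go to the more symmetric class so ties are deterministic.  The
karyotype formula (`2n = 2x = 10 = 4m + 4sm + 2st`) censuses these classes;
its class counts always sum to 2n and the string parses back to the counts.

Karyotype asymmetry is the CV-product index

    AI = CV_CL × CV_CI / 100,

with CV_CL the percent coefficient of variation of the 2n chromosome
lengths and CV_CI that of the centromeric indices (CI = 100·short/total).
Statistics run over all 2n chromosomes of the karyotype, not per haploid
set, and use the sample (n−1) standard deviation; the population convention
is available via `ddof=0`.  AI is zero for a perfectly uniform karyotype and
invariant under rescaling all lengths, which the tests check as properties.

Fewer than 10 measured cells triggers a warning rather than an error: ten
good metaphase spreads is the conventional minimum, but the estimator is
well defined for any positive number of complete cells.

## Genome size

Flow-cytometry peak means enter pre-extracted (no FCS parsing or gating);
the sample 2C value is the internal standard's 2C times the sample/standard
peak ratio.  Runs are accepted only when the peak CV is strictly below the
threshold (default 5%, overridable per sample to accommodate difficult
tissues measured at < 6%).  Replicates aggregate as mean ± sample SD; a
taxon whose runs all fail QC is reported with a failed-QC flag rather than
dropped silently.  Monoploid genome size is 1Cx = 2C/ploidy, displayed at
two decimals with half-up rounding to match printed-table conventions
(an intermediate rounding eight places out absorbs binary-float noise so
that a mean stored as 2.4349999999999996 still prints 2.44).  Group
summaries (per-clade min/max/mean and fold-range) are computed on 1C for
diploids; polyploids are compared through 1Cx.

The bundled study table (`karyoevol/data/crepis_table2.tsv`) carries one
row per analysed accession of the *Crepis* s.l. dataset — 2n, base number
x, ploidy, karyotype formula, AI, and measured 1C with SD and internal
standard.  Subclade labels are included only where the source text places a
species; unplaced accessions carry the generic clade label `IV`.  The
octoploid *C. biennis* enters with its literature base number x = 5.

## Chromosome-number model

The haploid number evolves on states 1..Nmax under four Poisson event
channels with constant rates: gain i→i+1 (ascending dysploidy), loss i→i−1
(descending dysploidy), duplication i→2i (polyploidization), and
demiduplication i→1.5i (triploid bridge), the last splitting its rate
equally between ⌊1.5i⌋ and ⌈1.5i⌉ for odd i.  Targets beyond Nmax truncate
to Nmax; self-targets produced by truncation or by i = 1 are dropped.  The
four model flavours are CONST_RATE (demi = 0), CONST_RATE_DEMI (demi rate
tied to the duplication rate), CONST_RATE_DEMI_EST (free demi rate), and
CONST_RATE_NO_DUPL (dysploidy only).

Nmax defaults to the largest observed count plus 10.  The tests check that
widening the pad to +30 changes the data log-likelihood by < 0.01 (after
removing the log Nmax shift contributed by the uniform root prior).

The likelihood of tip counts is computed by Felsenstein pruning with
per-branch transition matrices P(t) = exp(Qt).  The truncated Q is small
and dense, so P(t) comes from one eigendecomposition reused across branch
lengths when the eigenbasis is well conditioned (condition number < 1e8),
with scipy's scaling-and-squaring `expm` as the fallback; tiny negative
entries from round-off are clipped.  Partials are rescaled by their maximum
at each internal node, so likelihoods of large trees do not underflow.
Missing tips carry all-ones partials; a zero-length branch is the identity
map.  The root prior is uniform over 1..Nmax by default; a fixed
probability vector may be supplied instead (the empirical study does not
state its convention, so both are exposed and neither is guessed).

Rates are fitted by bounded multi-start maximum likelihood: L-BFGS-B on
log-rates in [1e-8, 100], first start at two expected events per channel
over the total tree length, remaining starts log-uniform from the seeded
generator.  AIC = 2k − 2logL with k the number of free rates (the root
prior contributes no parameters); exact AIC ties break toward fewer
parameters.

Marginal ancestral states use the standard up-down (outside) pass: the
"above" partial of a node combines the parent's above partial with the
sibling subtrees, and the posterior is the normalized product of above and
below partials.  On trees small enough to enumerate, the posteriors match
brute-force summation over all internal-state assignments to 1e-10.

Expected per-branch event counts come from stochastic mapping: joint node
states are sampled exactly (root from its posterior, children conditionally
given the sampled parent and the below-partials), then each branch history
is simulated conditional on its endpoints — rejection sampling (forward
Gillespie until the endpoint matches, capped at 1000 attempts per draw)
with conditioned uniformization as the guaranteed-termination fallback.
Realized jumps that more than one channel could produce (e.g. 2→3 by gain
or demiduplication) are attributed proportionally to the channel rates.
Events with expectation above the reporting threshold (default 0.5) are
flagged; descending-dysploidy tallies are reported both as the number of
flagged loss branches and as the summed expectation, since a single branch
can carry more than one expected event.

## Brownian-motion trait reconstruction

A continuous trait x on the tips is modelled as multivariate normal with
mean root·1 and covariance σ²C, C[i,j] being the root-to-MRCA path length.
Maximum likelihood (matching the ancestral-ML convention of the R tools
this mirrors) gives the GLS closed forms root = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and
σ² = eᵀC⁻¹e/n; REML (n−1) is a one-flag switch.  Ancestral states are the
conditional expectations of the Gaussian process given the tips, which for
a Gaussian coincide with the joint ML estimates; consequently every
internal estimate lies within the range of the tip values, a property the
tests assert.  Estimates are also cross-checked against an independent R
implementation (phytools `fastAnc`) on a fixed 4-tip tree.

Missing-trait taxa are pruned (with path compression) before fitting.
Traits are analysed on their raw scale by default with an optional log
transform; constant traits floor σ² at 1e-12, and duplicate zero-length
tips raise unless a terminal-branch floor (fraction of tree height) is
requested, which is logged loudly when applied.

## Synthetic data and calibration experiments

All generators are pure functions of (parameters, seed), with per-generator
substreams derived from the run seed and a generator name, so adding one
simulation to a pipeline never perturbs another's draws.

* **Yule trees**: with k lineages the next split waits Exp(k·birth); the
  process stops when the (n+1)-th split would occur, making the expected
  root height Σ_{k=2..n} 1/k at rate 1 (checked against 100 replicates at
  n = 200 within 3 SE).
* **Chromosome counts**: forward Gillespie under the same CTMC the
  inference fits, returning tip counts plus the true per-branch event log,
  which serves as the oracle for stochastic mapping (empirical one-branch
  transition frequencies over 10,000 draws match exp(Qt) within 3 SE).
* **BM traits**: recursive normal increments; sister-tip covariance matches
  σ² times the shared path length over 1000 replicates.
* **Karyotype measurements**: each homologue pair gets an arm-ratio
  template mid-interval of its Levan class (m 1.3, sm 2.2, st 4.5, t 8.5)
  and a total length on a decreasing 12→6 µm ramp; per-cell multiplicative
  noise at a given CV.  Noise-free rebuilds recover the formula exactly;
  at 2% CV and 10 cells the formula is recovered in ≥ 95% of 100 seeds.
* **Flow peaks**: peak ratios perturbed with the stated CV; the mean
  estimate recovers the simulated truth within Monte-Carlo error.

Calibration experiments (in `karyoevol.experiments`) state the problem
sizes used:

* CTMC rate recovery: 20 replicates of 200-tip Yule trees (birth rate 5,
  height ≈ 1 — a few dozen events per tree), gain 0.5 / loss 1.0 from root
  state 10; both rates within 50% relative error in ≥ 90% of replicates.
* Model selection: data simulated with no demiduplication (duplication rate
  0.15, clear but unsaturated signal); AIC prefers CONST_RATE over the
  tied-demi model in the majority of 10 replicates of 100-tip trees.  At
  much higher duplication rates single realizations regularly mimic
  demiduplication (tips at exactly 1.5× a sibling clade), and the
  preference genuinely weakens — a feature of the models, not the fitter.
* BM recovery: 200-tip Yule trees at birth rate 25 (height ≈ 0.2, the
  depth scale of empirical plastid phylograms in substitutions/site);
  root within ±0.5 and σ² within 30% in ≥ 90% of 20 replicates.  On much
  deeper trees the root estimate is intrinsically ill-determined (its GLS
  variance grows with basal branch lengths), so this tolerance is a
  statement about shallow phylogram scales.
* Stochastic mapping: per-branch expected loss counts rank-correlate with
  the true simulated event log (mean Spearman ρ > 0.7 over 3 seeds) in an
  event-rich regime (30 tips, birth rate 0.5) where the single true
  realization per branch carries enough signal.

What passing these tests shows — and does not.  The generators reproduce
the distributional assumptions of the estimators exactly (correct model
class, no rate heterogeneity across branches, no measurement error in
counts, exchangeable cells in morphometry).  Success therefore validates
the implementations, not the biological adequacy of constant-rate CTMC or
BM models for any real dataset; empirical phylograms with near-zero
branches, non-ultrametric depth variation, or lineage-specific rates can
degrade both root inference and event-count calibration in ways these
simulations do not probe.

## Reproducibility

Every stochastic step (optimizer restarts, stochastic mapping, all
simulators) consumes an explicit seed; the CLI logs its seed (default
1436) on every run, and identical seeds give byte-identical outputs.
`scripts/acceptance.py --seed N --out FILE` re-derives the headline
quantities from scratch: study-table summaries, the worked asymmetry-index
example, pruning-vs-enumeration agreement, the two recovery success rates,
and a 50-tip end-to-end pipeline demonstration (simulate → fit → AIC →
ancestral states → expected events).
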