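# Methods

`telesim` simulates single-cell RNA-seq count matrices from mechanistic
first principles, in three layers: stationary transcription kinetics,
tree-structured cell states, and an explicit library-preparation and
sequencing pipeline. Companion modules invert the first layer (MCMC
estimation of kinetics from counts), match simulation parameters to a
target dataset, derive ground-truth differential-expression labels, and
answer experimental-design questions about rare-population detection.

## Transcription: the two-state promoter at stationarity

Each gene's promoter switches on at rate `k_on` and off at rate `k_off`;
while on, transcripts appear at rate `s` and every transcript decays at
rate `d`. All rates are expressed relative to `d`, which is fixed at 1 and
never exposed. At steady state the transcript count follows the
Beta-Poisson mixture

    p ~ Beta(k_on, k_off),   X ~ Poisson(s * p),

which we sample directly by the two-stage construction rather than by
solving the master equation — the two coincide at stationarity. Closed
forms used throughout:

* mean `E[X] = s * k_on / (k_on + k_off)` (the burst frequency
  `k_on/(k_on+k_off)` times the synthesis rate);
* variance `Var[X] = E[X] + s^2 k_on k_off / ((k_on+k_off)^2 (k_on+k_off+1))`.

**bimod knob.** Dividing both switching rates by `10^bimod` (`bimod` in
[0, 1]) slows the promoter while preserving burst frequency, hence the
mean; the variance and the number of bimodal genes rise. This is the one
place where intrinsic noise can be turned up without touching anything
else.

**High-expression outliers.** A fraction `prop_hge` of genes is flagged as
constitutively on: their counts are Poisson(s) with no Beta mixing, and
their synthesis rate is inflated by `2^(mean_hge - 1 + rank/n)`, where
`rank` orders the flagged genes by mean `s` (ties broken by gene index).

**Modality diagnostic.** A triple (k_on, k_off, s) is labelled
zero-unimodal / nonzero-unimodal / bimodal from a fixed-sub-seed sample of
10,000 draws, histogrammed on the integer grid and smoothed with a
Gaussian kernel of deterministic bandwidth `max(1, range/30)` bins; the
label comes from whether the smoothed density has a boundary mode at
zero, an interior mode, or both. The region boundaries shift slightly
with bandwidth; the rule above is fixed so labels are reproducible.

## Cell states: EVFs on a tree

Each cell carries three independent low-dimensional vectors of extrinsic
variability factors (EVFs), one per kinetic parameter (default 20 per
parameter). Most coordinates are iid N(1, sigma) for every cell; the
first `n_diff_evf` coordinates (default 4, i.e. 20%) are Diff-EVFs whose
expected value follows Brownian motion over a user-supplied Newick tree:
value 1 at the root, one Gaussian step per branch with variance equal to
the branch length, internal-node values shared by all descendants. Two
cells at tree distance D therefore differ in a Diff-EVF by N(0, D), and
E|difference| = sqrt(2D/pi). Branch lengths are in squared-EVF units, so
the ratio sqrt(branch length)/sigma sets between- vs within-population
separability.

* **Discrete mode**: cells sit at the leaves; a leaf is a population.
* **Continuous mode**: cells are allocated to branches by a multinomial
  with probabilities proportional to branch length, placed uniformly
  within the branch and sorted; the Brownian path is sampled at the cell
  positions, and each node's value continues from the end of its edge's
  path so lineages share history. Pseudotime is root distance.
* **Impulse mode**: like continuous, but each Diff-EVF follows a
  two-sigmoid-product impulse curve (onset level, peak level, offset
  level, onset/offset times as fractions of path length, slope) along one
  root-to-tip path; cells off that path take the curve's value at their
  most recent common ancestor with it. With all three levels equal the
  curve is constant and the mode reduces to fixed-mean sampling.

## From EVFs to kinetic parameters

Each gene has three sparse effect vectors (one per parameter): entries
N(0, gene_effects_sd), independently zeroed with probability `eta`
(default 0.7). The raw value of a parameter for gene g in cell c is the
dot product of the gene's effect vector and the cell's EVF vector. Raw
values live on an arbitrary scale, so the whole genes-by-cells matrix is
quantile-mapped onto a reference sample of plausible values: all m*n raw
values are ranked jointly (stable sort; ties keep (gene, cell) order),
m*n values are drawn from the reference with replacement, sorted, and
substituted rank for rank. Mapping is joint over the full matrix, not
per gene. The mapped `s` is then multiplied by the cell-size factor
`scale_s`, `bimod` is applied, outliers are inflated, and counts are
drawn from the Beta-Poisson law (Poisson for outlier genes).

The packaged reference distributions are synthetic log-normal samples
spanning ranges consistent with published mammalian kinetics (k_on and
k_off roughly 0.05–5 relative to degradation, s roughly 10–400); any
user table (TSV with columns k_on, k_off, s) or the output of the
inference module overrides them.

## Technical pipeline: true molecules to observed counts

Per cell, per molecule:

1. **Capture** with per-cell efficiency alpha_hat ~ N(alpha_mean,
   alpha_sd) truncated to (0, 1]; molecules are thinned binomially.
2. **Pre-amplification**: `nPCR1` PCR cycles; in each cycle every copy
   duplicates with its gene's amplification rate, so expected copies grow
   as (1+rate)^nPCR1. A linear (IVT) option replaces this with a single
   deterministic-mean scaling `round(rate * rounds)` — an approximation,
   flagged as such, since no stochastic IVT model is specified.
3. **Fragmentation**: each copy yields `max(1, Poisson(length/400))`
   fragments with uniform random breakpoints; this is calibrated so that
   total length over total fragments is 400 bp for realistic transcript
   length distributions (the `max(1, ·)` floor only matters below ~400
   bp). Full-length (non-UMI) protocols keep every fragment inside the
   size-selection window (default 100–1000 bp); 3'-tag (UMI) protocols
   keep at most the 3'-end fragment of each copy, and only if it is in
   the window. Per-copy retained-fragment distributions are pre-computed
   per gene by a small Monte Carlo (256 draws) and summed over copies by
   exact multinomial decomposition.
4. **Fragment amplification**: `nPCR2` further PCR cycles.
5. **Sequencing**: per-cell read totals ~ N(depth_mean, depth_sd),
   truncated at zero and rounded; reads are drawn from the cell's
   fragment pool without replacement (multivariate hypergeometric).
   For pools above 1e9 fragments exact sampling is infeasible and a
   multinomial approximation is used (the sampling fraction there is
   ~1e-4, where the two laws agree); the approximation can also be
   forced via `sequencing_approx` for speed.
6. **Counting**: reads per gene (non-UMI) or distinct original molecules
   with at least one read (UMI). Optional batch effects multiply counts
   by gene-and-batch factors `2^N(0, batch_factor_sd)`.

**Amplification bias.** Genes are ranked by transcript length into
`nbins` equal-occupancy bins; bin i (1-based) receives systematic bias
`lenslope * (median_rank - i)` added to the basal per-cycle rate
`rate_2PCR`, so longer transcripts amplify worse. A per-gene random bias
N(0, MaxAmpBias - max|length bias|) is added and the rate clamped to
[0, 1]. The constraint `lenslope < 2*MaxAmpBias/(nbins-1)` keeps the
systematic part within the total bias budget. The bias term is defined
on bin rank, not bp: a bp-scaled definition would be dimensionally
incompatible with that constraint.

Two regimes worth knowing about:

* With no amplification, no size selection and saturating depth, UMI
  counts are exactly Binomial(true count, alpha_hat) per gene. With a
  restrictive size window the 3'-fragment retention probability q < 1
  multiplies in (Binomial(true, alpha_hat * q)).
* UMI counts are free of gene-length bias only when sequencing saturates
  molecule detection. At finite depth, length-biased amplification means
  molecules of long genes present few fragments and can be missed
  entirely, which re-introduces a negative length trend. The packaged
  defaults and the tests use a saturated-detection configuration for the
  UMI protocol (depth 5e5, two post-fragmentation cycles at the default
  panel sizes); length bias for full-length protocols is assessed on
  length-normalised read counts, while UMI counts are molecule counts
  and are deliberately not length-normalised.

Sequencing errors, read mis-assignment, reverse transcription and
library clean-up are not modelled.

## Kinetic inference

For one gene over cells: `p_c ~ Beta(k_on, k_off)`, `X_c ~ Poisson(s p_c)`,
observed `Y_c ~ Binomial(X_c, f)` with known downsampling probability f.
Binomial thinning of a Poisson leaves a Poisson, so Y is Beta-Poisson
with effective rate `f*s`, and the per-cell latents are marginalised in
closed form through Kummer's function:

    P(Y=y) = (f s)^y / y! * B(k_on+y, k_off)/B(k_on, k_off)
             * 1F1(k_on+y; k_on+k_off+y; -f s).

The sampler is Metropolis-within-Gibbs on the marginal posterior:
log-scale random walks on each parameter under log-normal priors
(median 1, log-sd 2 — there is no canonical prior for these rates; the
defaults are a package choice, exposed in the model-spec object), plus
two directed moves along the posterior's flat directions: a joint scale
move on (k_on, k_off) (burst frequency invariant) and a mean-preserving
ridge move scaling k_on with a compensating change in s. The ridge move
matters: in the always-on limit the likelihood is flat along
`s * k_on/(k_on+k_off) = const`, and without it chains stall at inflated
s. Proposal scales adapt toward ~30% acceptance during burn-in only
(first 50% of each chain, discarded); 2000 iterations and 3 chains by
default. A latent-variable variant (sampling p_c and X_c explicitly) was
evaluated and mixes far worse for k_off; the marginal form is the
implementation.

Diagnostics report lag autocorrelation (which must decay) and cross-chain
log-median agreement; chains within 1.5 log units of the cross-chain
consensus are "acceptable" and pooled — per gene and across genes — into
reference distributions for the quantile-mapping step.

**Identifiability.** Genes whose mean count is well below 1 carry almost
no information about k_off (and little about k_on): their posteriors
revert to the prior. Parameter-recovery rank correlations on panels that
include such genes plateau around 0.6 for k_off regardless of chain
length, while k_on and s recover at ~0.85–0.95. This is a property of
the data, not of the sampler; recovery should be interpreted per
expression stratum.

## Calibration to a target dataset

Three per-gene statistics summarise any count matrix: mean, percent
non-zero, and sample standard deviation over cells. A database is built
by simulating a user-supplied grid of parameter configurations (the
shipped examples reduce each axis to 3–4 values; full grids are
accepted), persisting JSON configuration + TSV statistics per entry and
resuming interrupted builds. A target is matched to the grid point
minimising the sum, over the three statistics, of the mean absolute
difference between 100 evenly spaced quantiles of the per-gene
distributions — scale-robust, indifferent to gene count, and a metric on
quantile profiles. Ties resolve to the earliest grid entry.

One structural caveat: capture efficiency and cell size act on captured
molecules only through their product (thinning a Poisson(s*p*scale) by
alpha equals thinning by alpha*scale), so grids containing two points
with equal `alpha_mean * scale_s` are near-degenerate and matching
between them is decided by second-order features (depth saturation,
alpha_sd). Grid designs should avoid exact product collisions when both
axes are varied.

## DE ground truth and experimental design

A gene is differentially expressed between two populations by
construction iff (a) it has at least one Diff-EVF with a non-zero effect
entry, counted across all three parameters' effect matrices
(`n_diff_evf > 0`), and (b) the absolute log2 fold change of its
cell-averaged theoretical mean `s*k_on/(k_on+k_off)` exceeds a threshold
(0.8 by default; 0.6–1 is the sensible range). Zero means produce signed
infinities, never NaN. An empirical true-count LFC is available as an
alternative criterion. On simulated true counts, Wilcoxon p-values of
`n_diff_evf = 0` genes are uniform, and skew increasingly with
`n_diff_evf`; sibling populations in the tree share fewer DE genes than
either has against an outgroup.

The design calculators are exact: the probability of drawing at least x
cells of a population of proportion r among N sequenced cells is the
binomial upper tail (evaluated via the survival function), and the
minimum N for a target probability is found by bisection on that
monotone function. The empirical success criterion for rare-population
detection — some cluster holds ≥ x rare cells making up ≥ 70% of the
cluster — takes any clustering's labels; clustering itself is outside
the package.

## Synthetic fixtures and what the tests do not show

The packaged tree (5 populations; two siblings and an outgroup with
illustrative branch lengths), gene-length table (log-normal, median
~1.6 kb, clipped to 0.2–20 kb) and reference kinetic distributions
(log-normal) are synthetic stand-ins generated by
`scripts/generate_fixtures.py`. They emulate the shapes of real
quantities but none is derived from an organism or a dataset, so
passing tests demonstrate internal consistency of the mechanistic model
— moment identities, thinning laws, tree-distance laws, recovery of
parameters the simulator itself generated — not agreement with any
particular tissue or protocol. Calibration to real data requires the
user's own count matrix; kinetic inference from it requires counts that
are reasonably homogeneous per population and, ideally, imputed or
deeply sampled.

## Problem sizes and numerical choices

Default test and example sizes (hundreds of genes, hundreds of cells,
10–14 PCR cycles) were chosen as the smallest scales at which the
statistical claims above are comfortably measurable; all are plain
function arguments and scale up linearly in molecules processed.
Degenerate inputs are handled explicitly: all-zero genes yield flagged
degenerate fits rather than errors; empty outlier masks at small
`prop_hge * n_genes` are silent; zero-length branches are legal (zero
step variance); depth draws below zero truncate to zero reads.
Determinism is hierarchical: one top-level seed derives named substreams
per pipeline stage, so re-running any stage with the same configuration
reproduces its output byte for byte while leaving other stages'
draws untouched.
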