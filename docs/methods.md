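# Methods

## Scope and data model

The pipeline operates on 0-based half-open genomic coordinates throughout
(BED and bedGraph native); 1-based dialects are rejected rather than
guessed. Peaks, genes and transcribed units share one interval record with
an optional absolute summit; peaks without summits fall back to the
interval midpoint. Count matrices are feature-by-sample nonnegative
integers with optional per-sample size factors.

Upstream steps that belong to standard short-read processing — alignment,
deduplication, peak calling, and negative-binomial differential testing of
peaks and transcripts — are out of scope; the pipeline consumes their
outputs (peak/gene tables, count matrices, differential flags) or the
synthetic generator's ground truth.

## Library-size normalization

Counts are normalized by median-of-ratios size factors: per sample, the
median over features (with a positive geometric mean across samples) of
count / geometric mean. This is the convention of count-based differential
testing and makes the factors comparable to what upstream tools would have
used. Factors are returned unscaled (the geometric-mean gauge); only ratios
between samples matter downstream, and a total-count fallback is provided
for matrices where no feature is positive everywhere.

## Accessibility kinetics

Per dynamic peak, normalized counts are rescaled to [0, 1]. The rescaling
anchors are the minimum and maximum of the per-timepoint replicate means,
not of individual samples, so replicate noise does not set the anchors.
Series are oriented so that losses and gains are fitted by the same
decreasing template; the direction is recorded separately.

The model family is f(t) = A + (K − A)/(1 + (t/T50)^B)^f. This form is
algebraically the exponential-in-log-time parameterization but is finite at
t = 0 (value K for B > 0), which lets the untreated sample participate in
the fit. Four variants are fitted: B and T50 always free, plus
fixed(A=0, K=1, f=1), free A, free (A, K), and free (A, K, f). The
free-lower-asymptote variant matters because rescaling by the observed
series extremes shifts the true lower asymptote below zero whenever the
slowest sites have not plateaued by the last timepoint; without it the
fixed variant wins the parsimony race and biases T50 low for slow sites.

Optimization is bounded trust-region least squares seeded from a coarse
vectorized (B, T50) grid (B in [0.25, 8], T50 log-spaced over
[0.05, 48] h); richer variants warm-start from the simpler ones. AIC uses
the Gaussian profile likelihood, n·log(rss/n) + 2(p + 1) with the error
variance counted as a parameter; the additive constant is shared by all
candidates and omitted, so only differences matter. Model competition:
among log-logistic variants the fewest-parameter variant within 2 AIC of
the best is retained; then the asymmetric rule against polynomial nulls is
applied — a 0th- or 1st-degree polynomial is chosen when its AIC is below
the log-logistic AIC + 2, and otherwise the log-logistic is kept unless the
2nd-degree polynomial beats it by at least 2. T50 is reported only for
log-logistic winners; summary densities are computed on asinh-transformed
T50 with the curve area scaled to the number of contributing peaks.

## Transcribed-unit calling

Fragments are pooled per strand; midpoints (floor((start + end − 1)/2)) are
counted in 200 bp bins. The 2-state HMM has Poisson-lognormal emissions:
conditional on a lognormal rate exp(mu + sigma·Z), counts are Poisson. The
marginal emission probability is evaluated by 20-node Gauss–Hermite
quadrature (configurable). EM: standard forward–backward E-step in log
space; closed-form M-step for initial/transition probabilities; numerical
M-step (Nelder–Mead over mu, log sigma) for the emission parameters, with a
candidate update accepted only when it does not decrease the expected
objective (generalized EM), so the data log-likelihood is non-decreasing up
to quadrature error. Initialization is a 2-means-style split of log1p
counts; states are relabeled so state 1 has the higher log-rate mean;
convergence at Δlog L < 1e-6 or 200 iterations. The HMM is fitted once per
strand on pooled genome-wide bins and decoded per chromosome; per-bin
states are posterior-marginal argmax (ties to the low state), with Viterbi
available behind a flag — marginal decoding matches the per-bin
discretization framing, and the two agree on ≥ 99% of bins in the regimes
tested.

Post-processing thresholds (all defaults, all configurable): putative TUs
are maximal high runs with isolated single low bins absorbed; TUs with
≤ 25 overlapping fragments are dropped (strictly more than 25 survive).
Boundary refinement searches a 400 bp window centered on each bin-level
boundary for per-bp coverage steps: the start moves to one past the first
position whose forward difference exceeds 1; the end, mirrored, to one past
the last position whose decrease exceeds 1 (the published rule names only
the rising case; mirroring the falling edge is our interpretation).
Gene association is same-strand overlap; a TU overlapping several genes
with every interval Jaccard < 0.02 is flagged as a many-small-genes TU.
Multi-gene TUs are split at internal TSSs followed by a transcription wave.
The wave rule compares the median per-bp coverage over the downstream half
of a 2 kb window centered at the TSS with the median over the upstream
half, requiring an increase of ≥ 5: stated as a centered-window rule, the
half-window comparison is the reading under which a clean +6 step at the
TSS splits and a +4 step does not, which we take as the intended contract.
Finally TUs are kept when more than 10 fragments overlap in at least two
samples.

## Peak-to-gene association and kernels

Distances are summit minus TSS, sign oriented by gene strand (upstream
negative) for density profiles; kernels use absolute distance (symmetric).
Rules: distance threshold (default 25 kb); basal + extension with a 5 kb
upstream / 1 kb downstream basal domain extended up to a cap but stopping
at the nearest neighboring basal domain; k nearest genes per peak and k
nearest peaks per gene (default k = 6). Kernels: uniform (indicator),
Laplace, Cauchy (default, scale 20 kb) and Gaussian densities, all exactly
zero beyond a 5 Mb truncation inside a 10 Mb candidate window. Weights are
used unnormalized — only relative weights matter to the downstream linear
model — and summing uniform-kernel weights reproduces the
distance-threshold count exactly. Parameter sweeps select the grid point
minimizing k-fold cross-validated binomial deviance, ties to the smaller
parameter.

## Matched controls

Expression matching draws |cases| controls from the stable-gene pool
without replacement, with weights proportional to the case-to-pool density
ratio on case-expression quantile bins, and accepts a draw when a
two-sample KS test fails to reject distributional equality (default
alpha = 0.05, retry cap 1,000). One hundred accepted resamples propagate
control-set variability into every downstream metric. Stratified peak
matching cuts the joint covariate space into per-covariate quantile strata
(10 per covariate, total cells capped at 100), samples controls to mirror
focal occupancy per cell, and borrows from the nearest cells (Manhattan
distance on stratum coordinates) when a cell's pool is exhausted; borrowed
draws are reported, operationalizing "partially matched" without claiming
equivalence.

## Prediction

The predictor matrix holds per-gene kernel-weighted sums by peak category.
The L1-penalized logistic regression standardizes features internally and
reports coefficients on the input scale, making the selected penalty
invariant to feature scaling. The penalty path is log-spaced downward from
the smallest value nulling all coefficients; selection is minimum k-fold
cross-validated binomial deviance (the 1-SE rule is not used). Fits use
scikit-learn's saga solver with an unpenalized intercept, the convention of
the standard lasso-GLM tools. ROC curves enumerate all thresholds with tied
scores grouped; AUC is the trapezoidal area (identical to the Mann–Whitney
U statistic normalized by n1·n0); the operating point maximizes accuracy
with ties resolved toward specificity (higher threshold). Scores are
out-of-fold by default — in-sample scoring is available behind a flag —
because out-of-fold ROC is the honest default when train/test separation is
otherwise unspecified. Under the no-signal null the out-of-fold mean AUC
sits slightly below 0.5 (the usual pessimistic bias of cross-validated
scores at modest n), well within the ±0.05 band we test.

## Motif enrichment

JASPAR-format position frequency matrices are converted to log2-odds
against a uniform background (empirical background behind a flag) with a
pseudocount of 0.8 times the background. The presence threshold is
calibrated from the exact null score distribution, computed by dynamic
programming over discretized scores, at a per-position match probability of
5e-5 — the default of the standard matching tools. Motifs too short or too
sharp to attain that tail probability fall back to consensus-only matching.
Scanning covers all windows on both strands; N scores as background (zero
log-odds contribution). Enrichment is the membership coefficient of
presence ~ membership + GC + total motif content with a Wald test;
constant covariates are dropped (they are collinear with the intercept);
perfect separation falls back to a ridge-penalized fit and is flagged.
P-values are BH-corrected across the motif set. With a small bundled PWM
set the total-motif covariate excludes the tested motif's own hits —
including them lets one motif dominate the total and induces an
explaining-away bias; with hundreds of PWMs the distinction vanishes.
Running summaries along the T50 ranking are centered moving averages
(windows of 400 peaks for motif fractions relative to the stable-peak
baseline, 1,000 peaks for reference-set overlap fractions) with identical
truncation at both edges.

## Synthetic study conditions

The generator emulates an acute pioneer-factor depletion time course:
untreated plus 0.5, 1, 2, 6 and 24 h, two replicates per timepoint, on
4 chromosomes of 5 Mb with 400 genes (TSSs ≥ 2 kb apart, the spacing drawn
by stick-breaking so it holds exactly) and 2,000 peaks of 200 bp. Peak
categories: 30% down-DARs, 10% up-DARs, the rest stable. Down-DAR truth
kinetics: T50 log-uniform on [0.25, 12] h (straddling the sampled
timepoints: most losses fast, some slow), B uniform on [1, 4], A = 0,
K = 1, f = 1; up-DARs rise from 0.2 toward 1 with the same family; stable
peaks are constant. Counts are negative binomial with variance
mu + alpha·mu^2 (alpha = 0.05, a typical ATAC peak-level overdispersion at
~100-fragment depth) around depth 100 times per-sample library factors
drawn uniformly from [0.8, 1.25].

Down-DARs are placed at Cauchy-distributed offsets (scale 20 kb) from
random gene TSSs; the generative expression link is then
P(down) = logistic(−3.5 + 6e4 · S) where S is the truncated-Cauchy-weighted
sum of down-DAR peaks near the TSS. The intercept and slope were calibrated
once so that the oracle AUC of the true probabilities is ≈ 0.8 with ≈ 28%
of genes downregulated (controls must outnumber cases for matching); they
are modeling choices, not measured constants. The no-signal null scenario
sets the slope to zero with intercept −1 so the case count stays large
enough for stable ROC estimation.

Nascent-RNA fragments have Poisson-lognormal bin rates inside gene bodies
(mean 5 fragments per 200 bp bin, lognormal sigma 0.5; down-DEG genes decay
toward 15% over time) and Poisson background at 0.1 per bin on both
strands; fragment lengths are ~N(150, 15) bp, clipped to the transcript —
nascent fragments cannot extend past the unit that produced them, and this
clipping is what creates the sharp coverage steps the bp-refinement rule
keys on. Peak sequences are iid with per-peak GC drawn from [0.3, 0.7]
(recorded as the regression covariate); the planted motif instance is the
PWM consensus, at odds `motif_odds` (default 3) in down-DARs relative to a
15% base rate elsewhere, on a random strand at a random offset. Planting
the consensus rather than a PWM sample makes presence a faithful readout of
planting, so the enrichment regression estimates the planting odds rather
than planting odds attenuated by scanner sensitivity.

All generators are pure functions of the configuration: one global seed
feeds a named, order-fixed substream per generator, so stages rerun
independently and byte-identically.

What the generator does not emulate: read-level artifacts (no FASTQ,
mapping error or duplication), GC bias beyond the recorded covariate,
chromatin-state spatial autocorrelation beyond gene bodies, replicate
batch effects, and 3D-contact structure. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to the full messiness of real sequencing data.

## Problem sizes and numerical choices

Recovery analyses use 500 down-DAR trajectories for kinetics, one
5,000-bin chromosome with 20 genes for TU calling, 100 matched-control
resamples for prediction, and 50–100 seeded replicates for coverage-style
calibrations — sizes chosen so the full study reruns in a few minutes on
one CPU while keeping Monte-Carlo error well below the decision margins.
Tolerances: exact-arithmetic oracles (brute-force association sums, ROC
rank identity, forward-likelihood enumeration) are checked at 1e-9–1e-12;
stochastic recovery criteria use the margins stated in the tests.
Degenerate inputs are handled explicitly: constant series route to the
0th-degree polynomial; all-zero HMM input yields a degenerate single-state
fit with a warning; empty peak windows give zero feature sums; zero
baseline fractions for running enrichment raise with a pseudo-fraction
suggestion.

## Known limitations

- T50 for the slowest sites remains slightly compressed toward the
  observed time range even with the free-asymptote variant, because the
  rescaling anchors are sample extremes; the bias is visible in the
  recovery tables (≈ −0.2 median log error in the slowest tercile) and is
  inherent to the rescale-then-fit procedure.
- The Poisson-lognormal M-step is a two-parameter numerical optimization
  per state and dominates HMM runtime; node count and iteration caps trade
  accuracy for speed.
- Stratified matching guarantees set size, not covariate balance, when the
  pool is structurally misaligned; the borrowed-strata count is the honest
  diagnostic and should be inspected.
- The bundled PWM fixture is synthetic (two 10-mers); it exercises the
  scanner and regression contracts but does not represent any real
  transcription factor's binding preference.
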