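# pioneerdyn

Statistical pipeline linking pioneer-factor-maintained chromatin
accessibility to nascent transcription, for acute-depletion time-course
experiments (dTAG-style degron + ATAC-seq + TT-seq designs). It is aimed at
regulatory-genomics analysts who want to (i) quantify how fast individual
open-chromatin sites collapse after a pioneer factor is degraded, (ii) call
transcribed units directly from stranded nascent-RNA coverage, and (iii)
test how well accessibility losses predict which genes shut down.

Everything runs end-to-end on a bundled synthetic-data generator with known
ground truth, so every estimator in the pipeline is scored against the
parameters that generated its input.

## What it computes

**Accessibility kinetics (T50).** For each dynamic peak, library-size
normalized counts (median-of-ratios size factors) are rescaled to [0, 1]
and fitted with the log-logistic family

    f(t) = A + (K − A) / (1 + (t / T50)^B)^f

where A and K are the lower/upper asymptotes, B the slope at the inflection
time T50, and f the Hill exponent. Several parameterizations (A, K, f free
or fixed at 0, 1, 1) compete with 0th–2nd degree polynomial nulls by AIC:
the simpler log-logistic variant wins when ΔAIC < 2, low-order polynomials
are preferred over the log-logistic when ΔAIC < 2, and the log-logistic is
preferred over the quadratic when ΔAIC < 2. T50 — the time of half-maximal
accessibility change — is reported only when a log-logistic variant wins.

**Transcribed units (TUs).** Pooled stranded fragment midpoints are counted
in 200 bp bins and discretized into low/high transcription states by a
2-state hidden Markov model with Poisson-lognormal emissions (Baum–Welch
EM, Gauss–Hermite quadrature). High-state runs (single-bin gaps absorbed)
become putative TUs, which are filtered (> 25 overlapping fragments),
refined to basepair precision from coverage steps (> 1 within a 400 bp
window), associated with same-strand genes (Jaccard < 0.02 flags
many-small-gene TUs), split at internal TSSs followed by a transcription
wave (median increase ≥ 5 over 2 kb), and count-filtered (> 10 fragments in
≥ 2 samples).

**Peak-to-gene association and prediction.** Peaks are associated to gene
TSSs by four rules (distance threshold, GREAT-style basal + extension, and
two k-nearest-neighbor rules) or weighted by distance-decaying kernels
(uniform / Laplace / Cauchy / Gaussian; default truncated Cauchy,
scale 20 kb). Per-gene weighted sums by peak category feed an L1-penalized
logistic regression (penalty by minimum cross-validated deviance) that
predicts downregulated vs expression-matched stable genes over 100
Kolmogorov–Smirnov-accepted control resamples; performance is summarized by
ROC/AUC and the maximum-accuracy operating point.

**Controls and motifs.** Expression-matched control genes are drawn by
density-weighted sampling with a KS acceptance test; covariate-matched
control peaks by stratified quantile matching with a borrowed-strata
diagnostic. Motif presence is called by log-odds PWM scanning (threshold
from the exact null score distribution at 5e-5 per position, both strands)
and enrichment is the peak-set-membership coefficient of a logistic model
adjusting for GC content and total motif content, with BH correction.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1 --out results/sim
python analysis/02_fit_dynamics.py --seed 1
python analysis/03_call_tus.py --seed 1
python analysis/04_associate_features.py --seed 1
python analysis/05_predict_degs.py --seed 1
python analysis/06_motif_enrichment.py --seed 1
```

At seed 1 this prints (abridged):

```
simulated 400 genes / 2000 peaks on 4 chromosomes; 113 down-DEGs (28%); ...
T50 assigned to 663/800 dynamic peaks; median |log error| 0.220, Spearman rho 0.918
called 20 TUs; 19/20 planted gene bodies recovered with both boundaries within 50 bp
peak_set  down_dar   ndar
down_deg     0.819  0.659
stable       0.361  0.618
DAR features: AUC 0.792 +/- 0.015; binding-only: 0.712 +/- 0.015 (DAR better in 100/100 resamples)
max-accuracy operating point (DARs): TPR 0.70, FPR 0.24
SYN0001: log OR +1.02 (SE 0.11, FDR 8.6e-19)
SYN0002: log OR -0.15 (SE 0.46, FDR 0.74)
```

Reading these numbers: the kinetics stage recovers the planted
half-change times (rank correlation 0.92 against truth); the TU caller
reconstructs planted gene bodies to basepair precision; down-DARs pile up
near the TSSs of downregulated genes (0.82 vs 0.36 peaks per gene in the
central 10 kb bin) while stable peaks do not discriminate; accessibility-loss
features predict downregulation better than binding occupancy alone in
every control resample; and the motif planted at odds 3 in down-DARs is
recovered at log OR ≈ 1.0 ≈ log 3 while the unplanted motif is null.

## Layout

- `src/pioneerdyn/` — the library: `io_core` (intervals, coverage, counts,
  BED/bedGraph/TSV/FASTA I/O), `synthetic` (ground-truth generators),
  `dynamics`, `tu_caller`, `association`, `matching`, `prediction`,
  `motifs`.
- `analysis/` — numbered narrative drivers (the pipeline stages).
- `tests/` — unit, property and end-to-end recovery tests.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices, and limitations.
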