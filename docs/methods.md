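# Methods

Statistical model, parameter choices, and numerical conventions of the
tolerograph pipeline.

## Study design being modeled

A cross-sectional three-group comparison: operationally tolerant
transplant recipients (TOL, default n = 15), non-tolerant recipients
still on immunosuppression (NONTOL, n = 17), and healthy controls (CTRL,
n = 10), each contributing one log2-scale expression profile over
thousands of probe sets. The central confounder is structural: NONTOL
status and immunosuppressant exposure are perfectly collinear, so
drug-responsive genes mimic tolerance genes in a naive two-group
comparison. The pipeline's answer is (a) the three-group filter and (b)
per-agent exposed-vs-unexposed checks within the NONTOL group.

## Synthetic data generator

`generate_dataset(SimConfig)` draws, per probe, a baseline ~ U(4, 12)
(log2 scale) and a noise sd ~ U(0.2, 0.6) (heteroscedastic, echoing array
data), then adds group-mean shifts of exactly `effect_log2` to disjoint
planted categories: TOL-specific up/down, NONTOL-specific up/down,
confounded (identical shift in both patient groups vs controls), and
agent-linked (shifted only in exposed NONTOL samples). Noise is
independent Gaussian. Defaults (2000 probes; 50/50/25/25 specific, 100
confounded; effect 1.0 = two-fold) give effects comfortably above the
1.5-fold filter but small enough that calibration is non-trivial.

What it deliberately does **not** model: probe-level cross-hybridization,
array batch effects, correlated gene modules, non-Gaussian heavy tails,
or missing values. Recovery results on this generator are therefore
best-case calibration checks, not clinical performance estimates.
`generate_probe_level` additionally emits probe-level intensities
`2^(signal + probe affinity + noise)` for exercising the preprocessing
chain; with zero noise and affinities the median-polish summary recovers
the planted signal exactly.

## Preprocessing (RMA-style)

Background adjustment subtracts a per-array intensity quantile (flooring
at ε = 1 to keep intensities positive); quantile normalization replaces
each column's sorted values with the row means of the column-sorted
matrix (ties receive the mean of their tied targets), making all array
distributions identical; median polish fits the additive model
`log2(I) = mu + probe + array` by alternating row/column median sweeps,
and the probe-set summary is `mu + array effect`. Median polish is
hand-rolled (few-line algorithm, and the summary convention matters);
it matches R's `stats::medpolish` exactly on odd-sized matrices — on
even-sized matrices the additive fit is not unique and implementations
may differ by a constant reallocation between row and column effects,
which cancels in group contrasts.

## SAM differential expression

Per probe, `d = (mean_A − mean_B) / (s + s0)` with pooled standard error
`s = sqrt(a · (SS_A + SS_B))`, `a = (1/n_A + 1/n_B)/(n_A + n_B − 2)`.
The fudge factor s0 is chosen among the percentiles {0, 5, …, 100} of s
to minimize the coefficient of variation of windowed median absolute
deviations of d (100 s-quantile windows) — the classic automatic tuning
that stabilizes d at low variance. The null distribution comes from
relabeling: all label assignments are enumerated when there are at most
`n_perm` of them, otherwise `n_perm` (default 100) distinct assignments
are sampled without replacement. Observed order statistics are compared
to the permutation-mean expected order statistics; for each delta on a
200-point grid the cut points are found by scanning outward from where
the expected curve crosses zero, and the estimated FDR is the median
(optionally 90th percentile) permutation exceedance count divided by the
number of calls, capped at 1. The FDR curve is monotonized (running
minimum in delta, the q-value convention) and the smallest delta meeting
the target (default 0.10) is selected; if none does, the call list is
empty and the best estimate attained is reported. Surviving calls must
also pass `2^|mean log2 difference| ≥ 1.5`. `estimate_power` wraps this
in a plant-and-recover simulation for design calculations.

## Three-group filter and secondary analyses

From the two vs-control call lists, *shared* probes (present in both
with the same direction) are removed as treatment/transplant artifacts;
the *final* phenotype lists are the intersections of the remaining
group-unique probes with the direct two-group list, with directions taken
from the vs-control comparison (disagreements with the two-group
direction are kept but flagged). The agent check runs SAM within the
NONTOL group for each immunosuppressant (exposed vs unexposed, skipping
agents with < 2 samples on either side) and reports the overlap with the
phenotype list. The matched-pair analysis tests per-pair log2 ratios by
the Wilcoxon signed-rank test (scipy, zero differences dropped) plus a
geometric-mean ≥ 1.5-fold filter.

## Enrichment

Genes are ranked by signal-to-noise `(μ_A − μ_B)/(σ_A + σ_B)` with each
σ floored at `max(0.2·|μ|, 0.04)` (the classic GSEA floor preventing
near-constant genes from dominating). The enrichment score is the signed
maximal deviation of a weighted running sum (hits weighted by
|score|^1, misses by −1/(N − N_H)). Null distributions come from
phenotype permutation (re-rank under shuffled labels; requires ≥ 7
samples, else the code auto-switches with a warning) or gene-set
permutation (random same-size sets). NES divides ES by the mean |ES| of
same-sign permutations; p-values use the same-sign tail with the +1
correction; FDR uses the standard NES-ratio estimator clipped to [0, 1].
ORA uses the scipy hypergeometric upper tail `P(X ≥ k)` with
Benjamini–Hochberg q-values (statsmodels) across sets.

## Classifier

Patients (controls excluded) are partitioned into 10 stratified folds
whose sizes differ by at most one. Within each fold's training samples
only: the top-20 probes by |SAM d| (s0 re-chosen per fold; `snr`
selector available) are selected, features are standardized, and a
scikit-learn MLP (one hidden layer of 3 logistic units, lbfgs, ≤ 500
iterations, fixed seed) is fitted — selection, scaling and fitting never
see held-out data. A failed fit is retried once with a perturbed seed,
then fails loudly. Held-out predictions are pooled into a confusion
matrix; *weighted accuracy* is total correct / total classified (so
e.g. 29 of 32 = 90.6%), with balanced (macro) accuracy also reported.
AUC is computed from the pooled continuous scores (trapezoid over the
empirical ROC, equal to the tie-corrected concordant-pair fraction) with
a stratified percentile-bootstrap 95% CI (resampling positives and
negatives separately, 2000 replicates). Feature-stability counts tally
how often each probe was selected across folds.

## Reproducibility and numerics

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from the global one (offsets, reduced mod 2^31) and
records all parameters, seeds, and cardinalities in a sorted-keys JSON
manifest, so identical configs yield byte-identical manifests. Floats
are serialized at full precision (`repr`) in all text formats. The
problem sizes used in tests and the acceptance script (hundreds to a few
thousand probes, tens of samples) are this package's own choice: large
enough for the asymptotics that matter (permutation nulls, FDR
estimation) and small enough that the full battery runs in minutes on
one CPU.

## Limitations

- Simulation-backed validation only; no patient dataset ships with the
  package, so absolute clinical performance claims are out of scope.
- SAM's FDR is an estimate with known conservativeness/variance
  trade-offs at small permutation counts; n_perm = 100 is a speed
  default, not an endorsement for publication-grade analyses.
- The ANN is intentionally minimal; the model contract
  (`fit` / `score_samples` / `classify`) accepts any replacement.
- Phenotype-permutation GSEA is weakly powered below ~7 samples per
  group; the gene-set fallback tests a different null.
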