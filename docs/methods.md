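# Methods

`wt1sig` re-implements, as deterministic library code, a workflow for
deriving a prognostic gene signature from expression cohorts stratified by a
driver gene, and for collapsing that signature into a signed cumulative
expression score validated by survival analysis. This note records the
model, the defaults, and the design choices made where the workflow left
room for them.

## The procedure

1. **Driver-quartile stratification.** Samples are sorted by the expression
   of a single driver probe (WT1, Affymetrix probe-set `206067_s_at`, in the
   motivating AML application). With `q = floor(n/4)`, the lowest-`q`
   samples form Q1 and the highest-`q` Q4; the middle quartiles absorb any
   remainder, so |Q1| and |Q4| are always within 1 of n/4. Ties in driver
   expression are broken by sample-ID lexicographic order, which makes the
   split deterministic and invariant to input ordering (a tie warning is
   logged).

2. **High-driver gene set.** Every probe is tested Q4 vs Q1 with a
   two-sided Welch t-test. We use the unequal-variance form deliberately:
   extreme-quartile groups have no reason to share a variance, and Welch is
   never worse than the pooled test here. Benjamini–Hochberg step-up
   adjustment (via `statsmodels`) controls FDR at 0.05 by default. Fold
   differences are reported as `2^(mean_Q4 − mean_Q1)` because inputs are
   log2-scale.

3. **KNN-LOOCV signature selection.** Class labels follow event-free
   survival: event-free samples are "favourable", all others "adverse". In
   each leave-one-out fold, probes are ranked by the absolute *median*
   t-statistic — `(med(x) − med(y)) / sqrt(s²x/nx + s²y/ny)` with ordinary
   sample variances — computed on the n−1 training samples only; the top-m
   features are z-scored on training statistics and the held-out sample is
   classified by k-nearest-neighbours (k = 3, Euclidean distance, majority
   vote by default; 1 − Pearson and distance weighting are options). The
   per-fold lists are trimmed to probes recurring in ≥ 90% of folds
   ("permutations" is read as LOOCV folds: the tool being emulated is a
   cross-validation tool, and one feature list per fold is what it
   produces). Candidate sizes 10–50 are scanned; for each size the trimmed
   list induces a 2-way cluster partition whose log-rank p and Cox HR on
   EFS and OS are ranked, and the rank-sum winner becomes the signature.
   The per-size table is always returned so a user can override the choice.
   The KNN classifier itself is hand-rolled (vectorised all-pairs
   distances) so that the tie policy — neighbour ties by training-sample
   order, vote ties by class prior then label order — is fully specified;
   tests check exact agreement with a brute-force oracle and with
   scikit-learn on tie-free data.

4. **Cluster partition.** Signature rows are z-scored; samples are
   clustered by average-linkage hierarchical clustering on 1 − Pearson
   correlation and the tree is cut into two clusters. The cluster with the
   larger mean signed signature expression (Σ direction·z) is labelled
   "high". Using the signed signature mean rather than the driver probe
   makes the assignment platform-portable when the driver probe is absent.
   This fixed recipe replaces an interactive GUI clustering step; the
   linkage/distance choice is the package's own and is deliberately
   conventional.

5. **Cumulative expression score.** Each signature probe gets the ROC AUC
   of its expression against the adverse-EFS outcome (Mann–Whitney
   identity, midrank ties); direction is + when AUC > 0.5. Probes are
   ranked by |AUC − 0.5| (ties by probe ID); DeLong p-values are reported
   but not used for ordering. The k-probe score of a sample is
   Σ direction·expression over the top-k probes (k = 4 by default, the W4
   analogue), optionally with per-probe z-scoring frozen on training
   statistics for cross-platform transfer. The training-median score
   dichotomises samples; ties go to the low-risk group, a deterministic
   choice that is conservative for the high-risk claim. On validation
   cohorts the median can be re-computed per cohort (default) or
   transferred from training.

6. **Survival validation.** Kaplan–Meier curves, median survival with
   Brookmeyer–Crowley log-log CIs, Mantel–Cox log-rank tests, and Cox
   proportional-hazards fits all go through `lifelines`. Cox fits use the
   Efron tie approximation — the only one lifelines implements, and the
   better one for month-resolution data with heavy ties; a Breslow option
   was considered and dropped because no installed backend exposes it with
   standard errors. The univariate→multivariate rule fits each candidate
   alone and enters those with p < 0.1 into one joint model. PPV/NPV of the
   binary risk marker are computed against "adverse OS" defined as an
   observed death event within follow-up (no fixed horizon is imposed).

## Synthetic cohorts

The generator plants the exact statistical structure the analysis assumes:
one latent factor `w ~ N(0,1)` per sample drives the driver probe
(`8 + b·w`), a block of signal probes (`μ_g + l_g·w`, `l_g ~ ±U(0.5,1)·λ`,
baselines `μ_g ~ N(7,1)`), the hazard (`h0·exp(γ·w)`, exponential event
times), and binary covariates (`Bernoulli(logistic(slope·w))`), against
i.i.d. Gaussian probe noise of SD σ and uniform administrative censoring on
(0, `censor_time_max`). EFS is `min(death, independent extra-failure)` with
the extra-failure hazard at half the baseline, so EFS ≤ OS per sample.
Exponential times keep the proportional-hazards assumption exactly true,
which is what the Cox validation layer presumes.

Defaults are the planted-effect study conditions used throughout the tests:
n = 500 samples, 1000 probes, 50 signal probes, b = λ = 2 (log2 units per
unit latent factor), σ = 1, γ = 0.8 (HR ≈ 2.23 per unit factor),
h0 = 0.02/month (median ~35 months at w = 0, AML-trial-like), censoring cap
120 months. Two-series designs share loadings and γ but draw independent
latent factors, noise, events and censoring.

What the generator does **not** emulate: probe-level array noise models,
probe–probe correlation beyond the single factor, batch/platform effects,
competing risks, or informative censoring. Passing recovery tests therefore
show the pipeline is correct under its own assumptions, not that it would
reproduce any particular clinical cohort's numbers.

## Problem sizes in the test and acceptance runs

Replicate-based checks use the sizes their conditions state where stated
(n = 500 for recovery and the 50-replicate Cox coverage, n = 400 for
two-series concordance, n = 300 for feature-ranking recovery); null
specificity and transfer checks use n = 150–300 samples with 300–400
probes, sizes at which every individual check has comfortable statistical
resolution. The full discovery at n = 500 with the default 10–50 size grid
runs in well under a minute on one CPU because per-fold feature rankings
are computed once and shared across grid sizes.

## Numerical and degenerate-input policy

- Zero-variance groups: Welch t is (0, 1) when means also agree, ±∞ → p = 0
  otherwise; the median t-statistic is capped at ±1e12 with a warning.
- A constant probe has ROC AUC exactly 0.5 and ranks last.
- Degenerate sample profiles in clustering (undefined correlations) get
  distance 1 with a warning; a constant signature matrix is an error.
- 2×2 odds ratios apply the Haldane 0.5 correction only when a cell is
  zero; the Fisher exact p always uses the uncorrected table.
- All randomness flows from explicit integer seeds; re-running a file-level
  discovery writes byte-identical bundles (manifests contain no
  timestamps).

## Known limitations

- The LOOCV reading of the stability rule prunes little on its own:
  leave-one-out folds differ by a single sample, so per-fold rankings are
  highly correlated and most top-m lists repeat in ≥ 90% of folds.
  Specificity under the global null is instead guaranteed upstream, by the
  FDR-controlled high-driver set that the KNN stage is restricted to — on
  null data that set is empty or tiny and the pipeline reports "no
  prognostic signature". Running the size scan directly on a large
  unfiltered null matrix *will* find nominally significant partitions by
  multiplicity of the size grid; the per-size report exists so users can
  see that structure.
- The optimal-size rule (rank-sum over log-rank p ascending and HR
  descending across EFS and OS) is one reasonable formalisation of "best in
  terms of both significance and hazard ratio"; other monotone
  combinations can pick a different size on near-ties.
- Cox ties: Efron only (see above).
- Cross-platform batch correction is out of scope; the normalized score
  variant only removes per-probe location/scale.
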