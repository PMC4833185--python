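# wt1sig

Prognostic gene-signature discovery and scoring for expression cohorts
stratified by a driver gene, with survival-based validation — plus a
synthetic-cohort generator with planted ground truth so every stage is
testable without downloading any data.

The package is aimed at translational transcriptomics: given a normalized
log-scale expression matrix (probes × samples; microarray or RNA-seq) and a
clinical table with survival endpoints, it re-implements the workflow used
to derive a high-WT1 prognostic signature in acute myeloid leukaemia (AML)
and the signed 4-gene cumulative expression score built from it.

## The method

1. **Quartile contrast.** Samples are sorted by a driver probe (WT1,
   probe-set `206067_s_at`); the top quartile Q4 is contrasted against the
   bottom quartile Q1 with a two-sided Welch *t*-test per probe and
   Benjamini–Hochberg FDR < 0.05. The significant probes form the
   *high-driver gene set*.
2. **KNN-LOOCV signature selection.** With event-free survival (EFS)
   labels (event-free = favourable, all else = adverse), a k-nearest-
   neighbour classifier is cross-validated leave-one-out over the
   high-driver set, re-selecting in every fold the top-*m* probes by the
   median *t*-statistic `(med(x)−med(y)) / √(s²x/nx + s²y/ny)`. Lists that
   recur in ≥ 90% of folds are kept; candidate sizes *m* = 10..50 are
   compared by the log-rank *p* and Cox hazard ratio of the 2-way cluster
   partition each list induces, and the rank-sum winner becomes the
   signature (the S17 analogue).
3. **Cumulative score.** Signature probes are ranked by ROC AUC against
   the adverse-EFS outcome; the *k*-probe score of a sample is
   Σᵢ dᵢ·xᵢ over the top-*k* probes with dᵢ = ±1 the AUC direction
   (*k* = 4: the W4 analogue). The median score dichotomises patients into
   risk groups, validated by Kaplan–Meier/log-rank, Cox regression (with a
   univariate *p* < 0.1 screen before the multivariate model), and PPV/NPV.

See `docs/methods.md` for the full model, defaults and design choices.

## Worked example

Discover a signature on one synthetic series and validate it on an
independent series sharing the same planted truth:

```python
import wt1sig as w

cfg = w.SimulationConfig(n_samples=300, n_probes=400, n_signal_probes=30, seed=42)
(expr, clin, _), (expr_b, clin_b, _), truth = w.simulate_pair(cfg, seed2=43)

res = w.discover(expr, clin, w.DRIVER_PROBE,
                 knn_config=w.KnnConfig(n_features_grid=tuple(range(10, 41, 5))))
print(f"high-driver set: {int(res.de_table.significant.sum())} probes at FDR<0.05")
print(f"signature: {len(res.signature.probes)} probes, "
      f"{len(set(res.signature.probes) & set(truth.signal_probe_ids))} planted")
for s in res.score_survival:
    print(f"score split, {s.endpoint.upper()}: log-rank p={s.logrank_p:.2g}, "
          f"HR={s.hr:.2f} ({s.hr_ci[0]:.2f}-{s.hr_ci[1]:.2f}), "
          f"median {s.median_high:.1f} vs {s.median_other:.1f} months")

val = w.validate_series(res.signature, res.score_model, expr_b, clin_b)
sv = {s.endpoint: s for s in val.score_survival}["os"]
ppv, npv = val.ppv_npv_os
print(f"validation OS: HR={sv.hr:.2f} ({sv.hr_ci[0]:.2f}-{sv.hr_ci[1]:.2f}), "
      f"PPV={100*ppv:.1f}%, NPV={100*npv:.1f}%")
```

Output:

```
high-driver set: 36 probes at FDR<0.05
signature: 22 probes, 21 planted
score split, OS: log-rank p=5.6e-17, HR=3.64 (2.64-5.02), median 17.4 vs 77.5 months
score split, EFS: log-rank p=5.4e-18, HR=3.44 (2.56-4.62), median 12.6 vs 52.5 months
validation OS: HR=3.44 (2.50-4.73), PPV=75.3%, NPV=57.3%
```

Reading this: of 400 probes, 36 separate the extreme WT1 quartiles; the
size scan settles on a 22-probe signature of which 21 are truly planted;
the median split of the 4-probe score carves out a high-risk group whose
death hazard is ~3.6× the low-risk group's on the training series, and the
frozen signature + score transfer to the independent series with a similar
hazard ratio — the structure of a discovery-plus-validation study, on data
where the answer is known.

The same flow is available from the shell:

```sh
wt1sig simulate --n-samples 300 --seed 42 --outdir sim/
wt1sig de --expression sim/expression.tsv --driver-probe 206067_s_at --out de.tsv
wt1sig discover --config run.yaml
wt1sig validate --signature out/signature.tsv --score-model out/score_model.json \
    --expression sim2/expression.tsv --clinical sim2/clinical.csv --outdir valout/
```

Real cohorts enter through `load_expression` (GCT 1.2 or TSV; `log2=True`
for raw RSEM-like input) and `load_clinical` (CSV/TSV with
`{os,efs,rfs}_{time,event}` columns in months; extra columns become
covariates).

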