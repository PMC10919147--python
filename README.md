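# cfsurv

Counterfactual survival modelling and treatment recommendation for
observational cohorts, exercised end-to-end on a synthetic registry-like
glioblastoma cohort with known ground truth.

The package fits per-arm survival models — classical T-learners (Cox PH,
survival tree, random survival forest, Cox-loss neural network) and a
balanced twin-head network (shared representation trunk, an integral
probability metric penalty aligning the two arms' latent distributions,
and two Cox-loss risk heads trained end-to-end) — then:

* infers each patient's **individual treatment effect** as the difference
  in predicted median survival between chemoradiotherapy (CRT) and
  radiotherapy (RT), capped at a 60-month horizon;
* recommends an arm per patient and splits the cohort into
  consistent/inconsistent groups (actual treatment vs recommendation);
* evaluates recommendations with the hazard ratio, IPTW-adjusted hazard
  ratio (robust sandwich variance), 5-year restricted-mean-survival-time
  difference, number needed to treat, per-arm Harrell C-index and IPCW
  integrated Brier score, and within-recommendation-group Kaplan–Meier
  comparisons;
* explains predictions with time-dependent Shapley attributions of the
  survival function, rank aggregation across patients, and
  recommendation-behavior odds ratios.

The neural components are implemented in NumPy (dense layers, SELU,
dropout, analytic Cox partial-likelihood and MMD gradients, Adam with
decoupled weight decay) — no GPU or deep-learning framework required.

## Layout

| module | contents |
| --- | --- |
| `cfsurv.synthetic` | seeded cohort generator (Table-style marginals, logistic treatment selection, per-arm Weibull PH laws with effect heterogeneity, closed-form true ITE), oracle model |
| `cfsurv.encoding` | shared covariate schema and design-matrix encoder |
| `cfsurv.stats` | Kaplan–Meier, log-rank, Cox PH (Newton–Raphson, Breslow ties/baseline, robust sandwich), logistic regression, chi-square, RMST |
| `cfsurv.metrics` | Harrell C, Graf IPCW (integrated) Brier score, IPTW weights with SMD balance diagnostics |
| `cfsurv.learners` | T-learner counterfactual models (cph / tree / rsf / deepsurv) |
| `cfsurv.balanced` | balanced twin-head network, IPM distances, 3-fold CV selection |
| `cfsurv.ite` | median extraction, ITE, recommendations, consistency labels |
| `cfsurv.evaluation` | HR / HRa / dRMST / NNT battery, per-arm metrics, cohort summaries |
| `cfsurv.interpret` | time-dependent Shapley attributions, rank matrices, behavior odds ratios |
| `cfsurv.pipeline`, `cfsurv.cli` | orchestration, config, CLI |

## CLI

```bash
# synthetic cohort CSV (+ ground-truth CSV)
cfsurv generate --n 5000 --seed 0 --out runs/cohort.csv --ground-truth-out runs/gt.csv

# whole pipeline: generate -> split -> fit -> recommend -> evaluate (-> interpret)
cfsurv run-all --seed 0 --out-dir runs/demo --models cph bites --interpret

# from a YAML config (flags override config values)
cfsurv run-all --config config.yaml
```

A run directory contains the cohort and split CSVs, per-model per-patient
ITE tables (`ite_<model>.csv`), a one-row-per-model report
(`report.csv` / `report.json` with HR, HRa, dRMST, NNT, per-arm C-index
and IBS), KM exports, attribution/rank/odds-ratio CSVs, and a JSON-lines
log. Rerunning an identical config reproduces every CSV byte-for-byte.
Exit codes: 0 success, 2 configuration error, 3 stage failure.

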