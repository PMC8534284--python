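# metabosig

Case–control metabolomics analysis with network-derived metabolic
signatures: pooled-QC feature filtering, log/Pareto preprocessing,
covariate-adjusted moderated differential analysis, correlation/PCA
exploration, a graphical-lasso network-pruning procedure that extracts
patient-specific and consensus signatures, and an exhaustive-subset
random-forest biomarker screen. It is aimed at small clinical cohorts —
the motivating setting is glioblastoma plasma/tissue profiling (about 60
controls vs 22 patients over a 188-metabolite targeted panel) — and at
methodologists who want the whole pipeline testable against planted
ground truth, which the built-in synthetic-cohort generator provides.

## The core procedure

Metabolite networks are conditional-dependence graphs: the graphical
lasso estimates a sparse precision matrix Θ̂ by maximising the penalised
Gaussian log-likelihood

    log det Θ − tr(SΘ) − λ‖Θ‖₁,off

on standardised log/Pareto-scaled data; an edge (i, j) exists iff
Θ̂ᵢⱼ ≠ 0, weighted by the partial correlation −Θ̂ᵢⱼ/√(Θ̂ᵢᵢΘ̂ⱼⱼ).
Pruning removes from a general network every edge also present in a more
specific one. The signature battery is then

* disease-specific network = prune(fit(control + disease), fit(control))
* patient signature(p) = nodes of
  prune(prune(fit(disease ∖ {p}), fit(control)), disease-specific)
* consensus = metabolites in more than 50% of patient signatures,

and every subset of the consensus is screened as a random-forest
classifier (class-balanced subsampling, 50 repeats, held-out ROC AUC
with a 95% CI).

## Worked example

```python
from metabosig import differential, network, predict, qc
from metabosig.containers import SampleMetadata
from metabosig.synthetic import SimulationConfig, simulate_cohort

plasma, tissue, metadata, qc_series, truth = simulate_cohort(SimulationConfig(seed=1))
pmeta = SampleMetadata(metadata.table.loc[plasma.sample_ids])

logged = qc.knn_impute(qc.log_transform(plasma))
pareto = qc.pareto_scale(logged)

de = differential.moderated_fit(logged, differential.build_design(pmeta))
print(int(de["significant"].sum()), "significant metabolites")

battery = network.run_signature_battery(pareto, pmeta)
print(sorted(battery.consensus.selected))

screen = predict.screen_signature(
    logged, pmeta, sorted(battery.consensus.selected),
    predict.ScreenConfig(n_repeats=50, n_trees=500, seed=1),
)
best = predict.rank_models(screen)[0]
print(f"best model {'+'.join(best.subset)}: AUC={best.auc:.3f} "
      f"({best.ci_low:.3f}-{best.ci_high:.3f})")
```

Output:

```
8 significant metabolites
['PC_004', 'PC_013', 'PC_041', 'PC_045', 'PC_066', 'PC_084', 'SM_005', 'SM_006']
best model PC_004+PC_013+PC_084: AUC=0.956 (0.943-0.968)
```

The 8 significant metabolites are exactly the planted differential set
(log2 shift 2.0 in cases), the consensus recovers the planted case-only
dependence module, and the screen's best subset reaches a held-out AUC
of 0.96 — the planted module members are individually and jointly
discriminative because their case distribution differs in dependence
and variance.

A command-line umbrella mirrors the library:

```bash
metabosig simulate --outdir sim --seed 1
metabosig run --outdir run --seed 1          # full pipeline on a synthetic cohort
metabosig network --matrix sim/plasma_raw.tsv --meta sim/metadata.tsv --outdir net
```

## Layout

| module                  | contents                                                     |
|-------------------------|--------------------------------------------------------------|
| `metabosig.synthetic`   | cohort generator with planted truth (GGM draws, effects, case-only module, cfDNA copula, pooled QC) |
| `metabosig.qc`          | QC filters, log2/Pareto, kNN imputation, CCS calibration     |
| `metabosig.differential`| moderated empirical-Bayes fit, univariate tests, BH/BY FDR   |
| `metabosig.correlate`   | Spearman matrices, Ward clustering, PCA, CV profiling, cfDNA network |
| `metabosig.network`     | graphical lasso, pruning, patient signatures, consensus      |
| `metabosig.predict`     | exhaustive subset screen, random forest, AUC ranking         |
| `metabosig.pipeline`    | end-to-end orchestration and run reports                     |
| `metabosig.cli`         | `metabosig` command-line interface                           |

See `docs/methods.md` for the models, defaults, and design decisions.
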