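# Methods

`metabosig` implements a complete case–control metabolomics analysis of
the kind used in small clinical cohorts (here: glioblastoma plasma and
tissue versus controls): pooled-QC feature filtering, log/Pareto
normalisation with k-nearest-neighbour imputation, covariate-adjusted
moderated differential analysis, unsupervised exploration, a
graphical-lasso network-pruning procedure that extracts patient-specific
and consensus metabolic signatures, and an exhaustive-subset
random-forest biomarker screen. A synthetic-cohort generator with fully
known planted truth makes every stage testable without any external
data. This note records the models, the defaults and why they were
chosen, and the places where the design was genuinely open.

## Quality control and normalisation

Features from an untargeted or targeted run are kept only if they behave
like analytes rather than artefacts in a pooled-QC experiment:

* **Dilution-series response** — Pearson correlation of intensity
  against the dilution fraction of a pooled-QC series (defaults
  1, 1/2, 1/4, 1/8, 1/16). A feature is removed iff r < 0.70 (strict:
  r = 0.70 exactly is kept) or r is undefined (flat response). The
  correlation is computed against the dilution fraction; for a linear
  response the choice of fraction versus concentration factor changes
  only the sign convention, not |r|.
* **Replicate precision** — RSD = 100·sd/mean over repeated pooled-QC
  injections; kept iff RSD < 25% (strict: exactly 25% fails). A
  non-positive mean makes the RSD undefined and fails the feature.

Both filters are per-feature predicates, so they commute and are
idempotent; a feature passes overall iff it passes both.

Normalisation is log2 (base 2 makes "log fold change > 1.5" thresholds
interpretable and matches moderated-statistics convention; no base is
canonical in the field), then k-nearest-neighbour imputation on the log
scale (k = 10, NaN-aware Euclidean distances across samples, mean of the
k nearest observed values; imputing after the log keeps distances
meaningful), then Pareto scaling (centre, divide by the square root of
the standard deviation — intermediate between no scaling and
autoscaling, the usual compromise for intensity data). Fold changes are
reported from log2 data *before* Pareto scaling, which would otherwise
distort their units.

The travelling-wave ion-mobility CCS calibration is the standard
power-law fit ln(CCS′) = x·ln(dt′) + ln(A), by ordinary least squares in
log–log space on calibrant ions of known cross section; predictions
follow CCS′ = A·dt′^x, and CCS error is the signed percent deviation
from a theoretical value.

## Differential analysis

The primary path is a moderated linear model per feature: ordinary least
squares on (intercept, group, sex, centred age), with the group
coefficient as the log2 fold change. Residual variances are shrunk
toward a common prior by empirical Bayes: a scaled inverse chi-square
prior is fitted by moment matching on log-variances (digamma/trigamma
inversion), giving prior degrees of freedom d0 and prior variance s0²;
the posterior variance is s̃² = (d0·s0² + d·s²)/(d0 + d) and the
moderated t is referred to d0 + d degrees of freedom. Setting the prior
degrees of freedom to zero recovers ordinary per-feature t-tests; the
implementation is verified against Bioconductor limma in the test suite.
A univariate path (Welch-free two-sample t or Mann–Whitney U, gated per
feature by Shapiro–Wilk at α = 0.05 in each group) is available since
the study protocol describes both without linking either to specific
tables.

Multiple testing uses step-up FDR control; the default is
Benjamini–Yekutieli (with the c(m) = Σ 1/i inflation), with
Benjamini–Hochberg selectable per analysis — the cfDNA correlation
network uses BH. Significance is adjusted p < 0.05; the "top metabolite"
subset additionally requires |log2 fold change| > 1.5 and adjusted
p < 0.01.

## Unsupervised exploration

Spearman correlation matrices (average ranks for ties, t-approximation
p-values, FDR-adjusted over the upper triangle), Ward agglomerative
clustering on Euclidean distances (the distance is the protocol's
choice; Ward is the common heatmap default), PCA by SVD of the
column-centred log-Pareto matrix, and coefficient-of-variation profiling
on the raw scale (CV is meaningless after a log transform). The
cfDNA–metabolite network keeps edges with BH-adjusted p < 0.05 and
|Spearman rho| > 0.25, both strict.

## Network signatures

Networks are conditional-dependence graphs of an L1-penalised Gaussian
precision estimate (graphical lasso) on standardised columns; an edge is
a nonzero off-diagonal entry, weighted by its partial correlation.
Columns are re-standardised within every sample subset because the
penalised likelihood is not scale invariant. Solving uses exact
connected-component screening (components of the |S| > λ graph), which
leaves the estimate unchanged while making sparse fits fast. Edge
identity for pruning is presence-only; nodes without incident edges are
dropped (a network is its edge-supported subgraph).

The battery:

1. control network = fit(control samples)
2. pooled network = fit(control + disease)
3. disease-specific network = prune(pooled, control)
4. for each patient p: patient-specific network =
   prune(prune(fit(disease minus p), control), disease-specific);
   the patient's **signature** is its node set (signatures are reported
   as metabolite lists, not edge lists).
5. consensus = metabolites in strictly more than 50% of signatures
   (denominator: all signatures, empty ones included).

The leave-one-out networks are fitted on the **disease samples only**
(`loo_cohort="case-only"`). The source protocol is ambiguous here — its
methods text pools controls into the minus-one fits, while its results
describe networks "built using control, disease, or both samples" — and
the two readings behave very differently. With a large control group
pooled in, one patient is ~1% of the fit; leave-one-out then perturbs
the penalised estimate by at most an edge or two, signatures collapse to
estimation noise, and no metabolite can recur in a majority of them (the
average of the leave-one-out statistics equals the full-cohort
statistic, so majority-consistent edge reveals are essentially
impossible). Fitted on cases only, one patient is ~5% of the fit, the
case-specific dependence structure is seen undiluted, signature sizes
land in the realistic 8–16 range, and the consensus concentrates on the
genuinely case-specific module. The pooled variant is retained behind
`loo_cohort="pooled"` for comparison.

λ selection: the protocol gives no value or rule. Extended BIC
(γ = 0.5) over a log grid is available (`lam="auto"`), but at n = 82,
p = 188 it selects the empty network (its known conservatism when
p ≫ n), so the battery ships a fixed tuned default
(`DEFAULT_BATTERY_LAMBDA = 0.82`, calibrated once against
planted-consensus recovery on the default synthetic cohort). One λ
governs every network in a battery so pruning compares like with like.

Positive/negative Spearman views of the consensus are reported with
|rho| as width weight and a floor of 0.1.

## Subset screen

Every non-empty subset of the consensus (capped at 16 metabolites; 2^k−1
subsets, deterministic size-then-lexicographic order) is evaluated as a
random-forest classifier over repeated class-balanced splits: per repeat
the train set draws ⌊0.8 × minority class size⌋ samples from each class,
the forest (500 trees, √p features per split, majority leaf vote) scores
the held-out remainder by the fraction of trees voting case, and the ROC
AUC is recorded. Held-out (not resubstitution) scoring was chosen
because resubstitution AUCs for forests saturate at 1. The summary is
the mean AUC with a normal-approximation 95% CI over repeats, clipped to
[0, 1] (consistent with printed upper bounds of 1.000). Ranking is by
mean AUC, ties to smaller then lexicographically earlier subsets.

The forest itself is a compact numba-compiled CART/bagging
implementation (`metabosig._forest`): the screen fits ~13,000 forests on
a few dozen samples each, a regime where a general-purpose library
spends more time on per-fit bookkeeping than on tree building. It is
cross-checked statistically against scikit-learn's RandomForestClassifier
in the test suite.

## Synthetic cohorts

The generator draws multivariate log-normal data — Gaussian on the log2
scale — so the conditional-independence graph of the log data is known
exactly. Defaults reproduce the study design: plasma 60 control / 22
case, tissue 6 control / 22 case, 188 features in the classic
targeted-panel classes (40 acylcarnitines, 21 amino acids, 21 biogenic
amines, 1 hexose, 90 phosphatidylcholines, 15 sphingomyelins).

* **Control dependence structure** — block-sparse within metabolite
  classes: unit-diagonal precision with off-diagonal −0.3 entries placed
  under a per-node diagonal-dominance budget, so planted partial
  correlations are exact and positive definiteness is guaranteed.
* **Differential signal** — 8 features (outside the consensus module)
  shifted by +2.0 log2 units in cases. Feature log2 standard deviations
  are 0.5 (plasma) and 1.4 (tissue), chosen so raw-scale median CVs land
  near 36% and 127% — the plasma/tissue heterogeneity contrast — giving
  a ~4σ standardised shift.
* **Case-only module** — the 8 consensus metabolites (6
  phosphatidylcholines + 2 sphingomyelins by default) load on a shared
  per-tumor latent factor (loadings ~2.5, activity standard normal,
  cases only), creating within-case pairwise correlations of ~0.85 and
  no control-group dependence. Mean shifts and dependence signal are
  deliberately disjoint by default so the differential and network paths
  have independent oracles.
* **Covariates** — ages with control median ~34 vs case ~62, ~82% male
  cases; cfDNA coupled to chosen metabolites by a Gaussian copula on
  rank-based normal scores (Spearman targets converted to Pearson via
  2·sin(πρ/6); a monotone log-normal map to ng/mL preserves rank
  correlations exactly). Default targets: +0.50 (amino acid), +0.45
  (acylcarnitine), −0.60 (biogenic amine), on conditionally independent
  features so the joint solve is always feasible.
* **Missingness** — completely at random at 2% (the protocol never
  characterises its missingness).
* **Pooled QC** — per-feature replicate injections (n = 8, CV 10%) and
  dilution intensities; features can be labelled well-behaved, flat
  (fails the dilution filter), or noisy (CV 0.5, fails the RSD filter).

What the generator does **not** emulate: instrument drift and batch
effects, detection-limit (intensity-dependent) missingness, heavy-tailed
or skewed abundance distributions beyond log-normality, annotation
ambiguity, and any spatial structure in the tissue data (tissue is
simulated as per-specimen feature tables with higher variance, not as
images). Passing tests therefore demonstrate correctness of the
procedures under the stated statistical model, not robustness to every
artefact of real acquisitions.

## Numerical and protocol choices

* Glasso: sklearn coordinate-descent backend, tol 1e-6 (1e-12 for
  oracle-equivalence checks), edge threshold |ω| > 1e-8.
* Moderated fit: variance-prior fit guards s² ≥ 1e-300; infinite d0
  (no excess spread) falls back to the prior variance with normal
  reference distribution.
* Spearman p-values use the t approximation (adequate for n ≥ 10);
  constant vectors give undefined rho, recorded as missing.
* Degenerate inputs: constant features Pareto-scale to zero columns;
  QC features with non-positive means fail with a reason code;
  self-loops and weightless edge sets are rejected at construction.
* Seeds: every stochastic stage is a pure function of (config, seed);
  the pipeline derives per-stage seeds from one global seed by stable
  FNV hashing of stage names, so stages can be rerun in isolation.
* Problem sizes in the shipped checks: recovery and calibration
  properties average 20 cohort replicates at the study scale (n = 82,
  p = 188); oracle equivalence uses 200 problems of ≤ 4 variables; the
  exhaustive screen evaluates all 255 subsets of an 8-metabolite
  signature at 50 repeats; single-model evaluations default to 500
  trees and the full 255-model screens run at 200 trees (forest
  rankings are stable well below that).

## Known limitations

* The consensus procedure inherits the finite-cohort artefact floor:
  with 22 patients and ~17,600 candidate pairs, a handful of spurious
  case-only correlations survive any penalty and can enter the
  consensus; the default λ keeps the expected count near 2–4.
* EBIC-based λ selection is effectively unusable at p ≫ n (empty
  networks); the fixed default is tuned for the study scale and should
  be re-tuned for very different cohort shapes.
* The moderated model assumes a common design across features and no
  feature-specific covariates; the univariate path drops covariate
  adjustment entirely.
* CCS calibration is unweighted OLS in log space; heteroscedastic
  calibrant errors are not modelled.
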