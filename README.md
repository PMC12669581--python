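# protlca

Latent-class stratification of heart-failure patients from plasma-proteomic
profiles — a reusable implementation of the unsupervised workflow that
derives prognostic patient clusters from a high-dimensional protein panel
and carries a single frozen model to external cohorts.

## The problem

Patients with heart failure with reduced ejection fraction (HFrEF) progress
at very different rates, and clinical variables alone separate them poorly.
Plasma proteomics (thousands of proteins measured per patient, e.g. on
aptamer panels) captures that heterogeneity, but needs an unsupervised model
with a *closed-form assignment rule* so that a cluster model derived in one
cohort can classify new patients elsewhere. Latent class analysis (LCA)
provides exactly that.

## The method

Given an `n × p` protein matrix the derivation chain is:

1. **Standardize** each protein to mean 0, SD 1 (sample SD); the training
   means/SDs are frozen.
2. **PCA** to the first `C = 20` components (30 as a sensitivity setting),
   with a deterministic sign convention.
3. **Categorize** each PC score at percentile cutpoints under four competing
   schemes — quartiles, deciles, 10th/90th, 20th/80th — cutpoints frozen.
4. **Select the scheme** whose fitted latent class model has the highest
   relative entropy `E = 1 − Σᵢₖ (−τᵢₖ ln τᵢₖ) / (n ln K)`.
5. **Latent class analysis**: a K-class mixture over the categorical items
   with mixing proportions `π` and item-response probabilities `ρ_jrk`,
   fitted by multistart EM. The number of classes is chosen by the lowest
   BIC followed by the bootstrap likelihood-ratio test (BLRT, 999 parametric
   bootstraps by default, step up while `p ≤ 0.05`).
6. **Assign** each patient to the class with the highest posterior
   probability `τᵢₖ ∝ π_k Π_j ρ_{j,y_ij,k}`.

The frozen model (means/SDs + loadings + cutpoints + `π`, `ρ`) serializes to
JSON and applies unchanged to an external cohort through the intersection of
protein identifiers. Downstream stages quantify what the clusters mean:
Kaplan–Meier/log-rank and Cox proportional-hazards association with
time-to-event endpoints (follow-up truncated at 3 years, Harrell's
c-statistic), empirical-Bayes moderated differential expression
(BH-adjusted p < 0.05 and |log2FC| ≥ 1.0), and a genetic algorithm that
searches clinical-variable subsets for the best-supported clinical
clustering. A latent profile analysis (Gaussian mixture on the continuous
scores) is included as a sensitivity variant.

Because the cohorts this workflow was designed around are not publicly
deposited, the package ships a seeded synthetic-cohort generator with known
three-class structure (driver-protein mean shifts over a correlated factor
background, class-dependent hazards) so every stage is testable against
ground truth.

## Worked example

```python
import protlca as pl
from sklearn.metrics import adjusted_rand_score

cohort = pl.generate_cohort(pl.SimConfig(seed=13))          # 379 x 300
model = pl.ProteomicStratifier(n_components=20, k_max=4,
                               n_bootstrap=99, n_starts=10,
                               random_state=13).fit(cohort.proteins)
print(model.n_classes_, model.scheme_.name, round(model.lca_.entropy_, 3))
print(round(adjusted_rand_score(cohort.true_labels, model.labels_), 3))

external = pl.generate_cohort(pl.SimConfig(seed=1013))
labels, tau, report = pl.apply_model(model, external.proteins)
print(round(adjusted_rand_score(external.true_labels, labels), 3))
```

prints

```
3 deciles 0.996
0.986
1.0
```

— the selection chain recovers the three simulated classes (BIC table plus
BLRT trace are in `model.report_`), assigns the training cohort at adjusted
Rand index 0.986 against the generating labels, and classifies the external
cohort at 0.975 with the frozen model. `pl.run_association(labels, outcomes)`
then yields per-endpoint hazard ratios against the slowest-progressing
cluster and Harrell's C, and `pl.moderated_stats` / `pl.flag_and_assign`
return the per-protein differential-expression table.

The same chain is scriptable from the shell:

```bash
protlca simulate --config configs/cohort.yaml --out cohort/
protlca derive   --proteins cohort/proteins.csv --config configs/derive.yaml --out model.json
protlca apply    --model model.json --proteins cohort/proteins.csv --out assign.csv
protlca associate --assignments assign.csv --outcomes cohort/outcomes.csv --out assoc/
protlca de       --proteins cohort/proteins.csv --assignments assign.csv --out de.csv
```

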