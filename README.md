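# sfelip

Predicting the **full lipid profile of supercritical CO2–ethanol extraction**
of a microalga from molecular structure, process conditions, and
thermodynamics.

Supercritical fluid extraction (SFE) with CO2 and an ethanol cosolvent
recovers different lipids with different efficiency depending on temperature
*T*, pressure *P* and cosolvent flow *Q*<sub>EtOH</sub>. Finding conditions
that maximise the recovery of a target lipid class normally requires a costly
experimental design. `sfelip` implements a pipeline that learns the mapping

> (29 molecular descriptors, *T*, *P*, *Q*<sub>EtOH</sub> [, ln γ<sup>∞</sup>]) → log₁₀ (relative recovery)

for ~90 annotated lipids over a 2×3×2 factorial design of extraction
conditions, and validates it by holding out an entire unseen condition
(leave-one-condition-out). It is aimed at researchers modelling SFE of
biological matrices who have a lipidomic characterisation of their extracts
and want a cheap *in silico* screen of operating conditions.

## What the pipeline does

1. **Representative-isomer selection** (`sfelip.representative`). LC-MS
   annotation often resolves a lipid only to a shorthand (e.g. "PC
   16:0_18:1") matching several positional isomers. One structure per
   annotation is chosen by K-Medoids (PAM) clustering in standardized
   descriptor space (the candidate nearest the cluster centroid), and
   cross-checked against mean pairwise Tanimoto similarity on Morgan
   fingerprints and against the squared error of each candidate's
   infinite-dilution activity-coefficient (IDAC) curve versus the family
   mean.
2. **Descriptor engineering** (`sfelip.descriptors`). The full RDKit 2D
   descriptor catalogue (~210) is computed per representative structure, then
   reduced by removing degenerate columns and greedy Pearson pruning at
   |r| > 0.75.
3. **COSMO-SAC IDAC** (`sfelip.cosmo_idac`). ln γ<sup>∞</sup> of each lipid
   in the CO2–ethanol mixture at each condition's temperature and ethanol
   mole fraction (lipid pinned at x = 10⁻⁵), from sigma profiles via
   misfit + hydrogen-bonding segment interactions and a
   Staverman–Guggenheim combinatorial term. Pressure does not enter the
   model.
4. **Regression protocol** (`sfelip.profile_model`). One row per
   (lipid, condition); zero-recovery cells are imputed at log₁₀ x = −7 and
   flagged. All rows of one condition (default SC5: 60 °C, 150 bar,
   0.6 mL/min ethanol) form the validation split; the rest splits 80:20 into
   train/test. Six models — lasso, Gaussian-process, SVR, random forest,
   XGBoost, and a small feed-forward ANN — are tuned by grid search with
   5-fold CV and evaluated (MSE/RMSE/MAE/R²) with and without the IDAC
   feature.
5. **Synthetic data** (`sfelip.synthetic_data`). Seeded generators emulate
   the statistical shape of the study inputs (isomer families, recovery
   surfaces with detection-limit censoring, sigma profiles) with full ground
   truth, so every stage is testable without the original measurements.

## Worked example

```python
from sfelip import synthetic_data as sd, descriptors as dm, profile_model as pm

config = sd.GeneratorConfig(seed=1)                      # 89 lipids, 12 conditions
records, families = sd.generate_lipid_library(config)
smiles = {r.lipid_id: families[r.shorthand][0] for r in records}
desc, _ = dm.clean_descriptors(dm.compute_descriptors(smiles))
table, truth = sd.generate_recovery_surface(records, config)

features = pm.assemble_dataset(table, desc, config.resolved_design())
train, test, validation = pm.split_dataset(features, pm.SplitSpec(seed=1))
model, chosen = pm.tune_and_train("xgboost", train, seed=1)
report = pm.evaluate(model, {"train": train, "test": test, "validation": validation})
print(report.metrics.round(3))
```

prints

```
              MSE   RMSE    MAE     R2      n
train       0.017  0.130  0.102  0.987  783.0
test        0.036  0.189  0.154  0.975  196.0
validation  0.040  0.201  0.159  0.959   89.0
```

Train/test rows are random (lipid, condition) cells; the `validation` row is
the entire held-out condition SC5 — R² ≈ 0.96 means the model predicts a
full 89-lipid profile at an operating point it never saw. The same run
through the CLI (`sfelip all --config ...`) also writes the model × (±IDAC)
metrics table, a per-condition class-composition summary, and the
selection-concordance report.

A complete run from one YAML config:

```bash
sfelip all --config src/sfelip/data/default_run.yaml
```

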