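# Methods

This note documents the models and procedures implemented in `sfelip`, the
assumptions behind them, the defaults that matter, and what the synthetic
data generator does and does not emulate.

## Problem setting

Supercritical CO2 with an ethanol cosolvent extracts a lipid mixture whose
composition depends on temperature (40–60 °C), pressure (150–250 bar) and
ethanol flow (0.6–0.9 mL/min at a fixed 5 mL/min CO2 flow). The quantity
modelled is the relative abundance of each annotated lipid in the extract at
each operating point, on a log₁₀ scale. The pipeline's supervised problem
has one row per (lipid, condition) cell; features are molecular descriptors
of the lipid, the three condition variables, and optionally the lipid's
infinite-dilution activity coefficient (IDAC) in the solvent mixture.

## Representative-isomer selection

A shorthand annotation such as "PC 16:0_18:1" can denote several positional
isomers. Three selectors are implemented:

* **K-Medoids + centroid** (default). PAM on Euclidean distances in
  standardized descriptor space, with deterministic BUILD initialisation and
  SWAP refinement, so k = 1 selection needs no random seed. Within the
  target cluster (the largest; ties resolve to the earliest candidate) the
  *mean* descriptor vector is computed and the candidate nearest it is
  chosen. A pure-medoid variant (`pure_medoid=True`) is exposed because
  "nearest the centroid" and "the medoid" can differ; the centroid-nearest
  rule is the default.
* **Tanimoto**: the candidate with the highest mean pairwise Tanimoto
  similarity (Morgan fingerprints, radius 2, 2048 bits — the community
  default; no specific fingerprint is canonical for lipids) to the rest of
  its family.
* **IDAC**: the candidate whose ln γ∞ curve over the (T, x_ethanol) grid has
  the smallest summed squared deviation from the family's pointwise mean
  curve.

All ties break by candidate file order, which is therefore part of the
interface contract. Clustering is per-family by default; nothing prevents
running PAM across a pooled candidate set, but per-family selection is what
the annotation problem requires. In practice large glycerophospholipid
isomers are nearly indistinguishable (pairwise Tanimoto > 0.8, often
> 0.95), so the choice of selector matters little for downstream features —
small free fatty acids are the exception, since moving one double bond
changes a larger fraction of a small molecule's atom environments.

## Descriptor engineering

The full RDKit 2D descriptor catalogue (~210 descriptors) is computed per
molecule; per-descriptor failures become missing values rather than errors.
Cleaning is two deterministic passes in catalogue order:

1. **Degeneracy**: drop columns with any missing value (threshold
   configurable) or fewer than 2 distinct values.
2. **Correlation pruning**: scanning left to right, drop a column whose
   |Pearson r| with any already-retained column exceeds 0.75 (absolute
   value; the earlier column wins). The survivor set has all pairwise
   |r| ≤ 0.75.

The surviving count depends on the molecule set and the RDKit version (on
the synthetic libraries it is typically 15–20), so no fixed survivor count
is asserted anywhere; an explicit descriptor-name preset can bypass
data-driven pruning for users who want to reuse a published selection.
Correctness of the whole cleaning path is established against a brute-force
enumerate-and-test oracle on random matrices.

## COSMO-SAC activity coefficients

The IDAC of a lipid in the CO2–ethanol mixture is computed with the standard
segment-activity-coefficient formulation operating on sigma profiles
(51 uniform bins on [−0.025, 0.025] e/Å²):

* **Exchange energy** ΔW(σₘ, σₙ) = (α′/2)(σₘ+σₙ)² + c_hb·max(0, σ_acc −
  σ_hb)·min(0, σ_don + σ_hb): an electrostatic misfit term plus a
  hydrogen-bonding term active only for strongly polar opposite-sign pairs.
  Universal parameters sit in one frozen config block at the published
  literature values (a_eff = 7.50 Å², α′ = 16466.72, c_hb = 85580 kcal Å⁴
  mol⁻¹ e⁻², σ_hb = 0.0084 e/Å², q₀ = 79.53 Å², r₀ = 66.69 Å³, z = 10,
  r_av = 0.81764 Å).
* **Segment self-consistency** ln Γ(σₘ) = −ln Σₙ p(σₙ) Γ(σₙ)
  exp(−ΔW/RT), solved by successive substitution with log-space mixing
  factor 0.5. The undamped iteration provably oscillates (on a symmetric
  two-bin profile it alternates around the fixed point with eigenvalue −1),
  and 0.5 damping is optimal there; convergence is checked to an ∞-norm
  residual of 1e-10 (1e-12 inside activity-coefficient calls) within 5000
  iterations, and non-convergence raises with the last residual.
* **Activity coefficient**: residual part (A_i/a_eff)·Σ p̂_i(σ)(ln Γ_mix −
  ln Γ_pure) plus the Staverman–Guggenheim combinatorial term from the
  cavity area and volume. Temperatures are Kelvin internally; °C is
  converted at the boundaries.

Correctness is asserted through identities rather than by matching any
external solver: the pure-component limit (ln γ = 0 to 1e-10),
indistinguishability of identical components, a two-bin brute-force grid
search oracle (1e-8), and the Gibbs–Duhem relation Σ xᵢ d ln γᵢ = 0, whose
trapezoid residual over a 97-point composition scan converges O(h²) and is
required below 1e-3. The hydrogen-bonding treatment is the single-profile
form; splitting sigma profiles into bonding/non-bonding parts is left as a
documented hook (`split_hb_profiles`) and not implemented — no equivalence
with any particular external implementation is claimed.

The model has no pressure dependence; the IDAC feature varies only with
temperature and ethanol mole fraction. Feed composition is derived from
pump flows as molar flows Q·ρ/M with pump-side densities (ethanol
0.789 g/mL, liquid CO2 0.90 g/mL) and molar masses (46.07, 44.01 g/mol) —
for 0.6 mL/min ethanol against 5 mL/min CO2 this gives x_EtOH ≈ 0.091. For
IDAC the lipid is pinned at mole fraction 1e-5 with solvents renormalised to
1 − 1e-5; halving that fraction changes ln γ∞ by ~1e-5–1e-4 (the residual
sensitivity of γ to a trace component is O(1–10) per unit mole fraction), so
1e-5 is effectively infinite dilution at the precision that matters for the
regression feature.

## Regression protocol

* **Imputation**: zero-abundance (below-detection) cells get y = −7 exactly,
  one to two decades below the smallest detected abundance, and a censoring
  flag. The count of −7 targets always equals the count of zero cells.
* **Splits**: all rows of one held-out condition (default SC5) are the
  validation set — generalisation to an unseen operating point; remaining
  rows split 80:20 uniformly at random (unstratified; a grouped-by-lipid
  split would be stricter against memorisation but is not the protocol
  implemented here).
* **Models**: lasso, Gaussian-process (RBF + white noise, length-scale
  bounded in [0.1, 1000] to keep the marginal-likelihood optimum away from
  degenerate interpolation), SVR (RBF), random forest, XGBoost
  (single-thread, exact tree method, for bit-reproducibility), and a small
  feed-forward ANN (MLP with early stopping). Features are standardized
  (train-fitted scaler inside the pipeline) for lasso/SVR/GP/ANN and passed
  raw to the tree ensembles.
* **Tuning**: exhaustive grid search scored by 5-fold CV RMSE, refit on the
  full training split; a singleton grid short-circuits to a direct fit.
  Default grids are small and documented in `profile_model.DEFAULT_GRIDS`.
* **Ablation**: the full protocol runs twice, with and without the IDAC
  column, same seeds, yielding the model × (±IDAC) metrics table.
* Everything is seeded; two runs of the same config produce byte-identical
  metrics CSVs.

## Synthetic data generator

The generator emulates the *statistical shape* of the study inputs, with
every planted parameter exposed so tests assert recovery of known structure.

* **Library**: 89 annotated lipids across five classes weighted 0.38/0.32/
  0.14/0.09/0.07 (glycerophospholipids/glycerolipids/sphingolipids/prenols/
  fatty acyls), each family carrying 1–6 candidate SMILES that differ only
  in double-bond position (isoprene count for prenols) — the ambiguity mode
  of shorthand annotation. Chains are built from class templates
  (phosphatidylcholine-, diacylglycerol-, ceramide-, isoprenoid-, free-
  fatty-acid-like) with independent chain lengths (12–24 C) and 0–5
  methylene-interrupted double bonds.
* **Recovery surface**: latent log₁₀ abundance = class baseline (−1.5 to
  −4.3 across classes, matching the multi-decade dynamic range of measured
  lipidomic abundances) + structure effects (−0.09 per carbon from the
  class-typical size, +0.15 per double bond) + a residual lipid intercept
  (sd 0.5) + linear condition effects (+0.12 per 10 °C, +0.15 per 50 bar)
  + non-additive terms (class- and polarity-dependent ethanol-flow response;
  pressure × flow and pressure threshold terms for fatty acyls) + Gaussian
  noise (sd 0.15). Abundances below the detection floor (1e-5) are recorded
  as exact 0.0. The floor sits just above the −7 imputation value by
  design: the imputed value is meant to be "just below the smallest
  detectable abundance", and a large artificial gap between floor and
  imputation would make borderline lipids unpredictable in a way real data
  is not. Condition effects are deliberately small relative to
  lipid-to-lipid spread, as in real extracts where composition shifts by
  tens of percent while abundances span decades.
* **Sigma profiles**: Gaussian mixtures on the standard grid — a dominant
  apolar peak near σ = 0 plus class-dependent donor/acceptor lobes at
  ±0.013 e/Å²; cavity area/volume scale with chain length. The bundled CO2
  and ethanol profiles are synthetic stand-ins with the qualitative shapes
  of the real ones (quadrupolar twin lobes; apolar peak plus hydroxyl
  lobes), not quantum-chemistry outputs.

What passing tests on this data do **not** show: performance on real LC-MS
measurements (no retention-time/adduct/mass-spectral realism, no
inter-batch effects, lognormal-only noise), chemical accuracy of the
synthetic sigma profiles, or that the specific descriptor survivors match
any published selection. What they do show: the pipeline's operations are
individually correct against oracles and identities, and the protocol
reproduces the expected qualitative behaviour — tree ensembles beat the
linear baseline on held-out conditions, a pure-noise IDAC column does not
improve tree models, and held-out-condition R² ≈ 0.9 is reachable when
recovery is largely structure-determined.

## Numerical choices and degenerate inputs

* Pearson pruning keeps the earlier column; |r| is compared, not signed r.
* Standardization uses population (ddof = 0) deviations and refuses n = 1 or
  constant columns.
* PAM tie-breaks: target cluster by size then earliest member; candidate
  ties by order; all documented as part of the contract.
* Segment averaging deposits each raw segment's area on the two neighbouring
  grid bins proportionally (first-moment preserving); densities outside the
  grid are clipped with a warning.
* Sigma-profile validation requires Σp = area to 1e-6 relative, a strictly
  increasing uniform grid, and non-negative p.
* Empty evaluation splits, unknown models, degenerate grids, missing
  holdout conditions, and mismatched family sets all raise typed,
  message-bearing validation errors at the boundary, not downstream.

## Known limitations

* The IDAC model ignores pressure entirely; a pressure-dependent variant
  would need saturation data unavailable for lipids of this size.
* The −7 imputation treats censoring as a point value; a censored-likelihood
  (Tobit-style) treatment would be statistically cleaner but is not what the
  protocol specifies.
* Grid-search spaces are small by design; the Gaussian process in particular
  is sensitive to kernel bounds and is not tuned aggressively.
* K-Medoids with k = 1 reduces to medoid selection before the
  centroid-nearest step; the distinction only matters for k > 1 or the
  pure-medoid option.
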