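# Methods

## Problem and model

`liabprof` estimates off-target liability for small molecules with per-target
QSAR regressors. The dependent variable is pACTIVITY, the negative log10
molar activity pooled over IC50/EC50/Ki/Kd measurements (functional and
binding assays are pooled by default — the usual first-tier screening
compromise that maximises training-set size; a config switch restricts to
binding-only or functional-only). Predictions are thresholded into
concern/not-concern flags and aggregated over a fixed target→liability-group
mapping into seven scores `Ls_i = C_i/(C_i + nC_i)`.

The packaged mapping follows its printed reference lists verbatim. Those
lists are internally inconsistent with their own header counts (the
cardiovascular group is labelled 25 but lists 24 symbols; the union of all
lists is 41 unique targets against a stated panel of 46). We ship the lists
as printed rather than invent entries; the mapping file documents this.

## Curation

Sequential rules, each attributed in the provenance log (first failing rule
wins): species ∈ {"homo sapiens", "human"} case-insensitively; censored
records (> or <) excluded; activity type in the configured set; value > 0 in
a known unit (nM/µM/mM/M). Structures: the largest fragment by heavy-atom
count containing at least one carbon is kept (canonical-SMILES lexicographic
tie-break), charge-separated functional groups are normalized with RDKit's
standard rule set (nitro, N-oxide, azide and kin), charges neutralized, and
the result canonicalized. No 3D geometry is ever generated — all descriptors
are conformer-independent. De-duplication is keyed on exact standardized
SMILES; the representative value is the median, which makes the result
invariant to record order and robust to censoring-adjacent outliers.
Medians pool across activity types by default (configurable).

## Featurization

11 descriptors (MolWt, cLogP, TPSA, HBD, HBA, rotatable bonds, aromatic and
aliphatic ring counts, stereocenters incl. unassigned, fraction Csp3, heavy
atoms) — the properties most informative for chemical-space maps — plus
Morgan fingerprints of radius 6 (radius, not diameter) folded to 1024 bits,
once with standard connectivity invariants (EC) and once with pharmacophoric
feature invariants (FC): 2059 features total. The EC‖FC concatenation (2048
bits) is the Tanimoto similarity vector for the applicability domain and
diversity splitting. Tree ensembles are scale-invariant, so descriptors are
not scaled for modelling; autoscaling happens only inside the chemical-space
analysis. The pre-PCA filter drops columns with sample SD < 0.01, then scans
columns in order and drops any column correlating |R| > 0.95 with an
already-retained one — deterministic and idempotent.

## Splitting

Default: 80/20 stratified on pACTIVITY with equal-width 1.0-log-unit bins
(bins under 2 members merge into their nearest neighbour). Train counts are
allocated by largest remainder, so the train size is exactly
round(0.8·n) and every bin's share is within one compound of 80%.
Alternatives: seeded random; Murcko-scaffold-grouped (no scaffold straddles
the partition; acyclic compounds form one group); max-min diversity (test
set picked first by farthest-point Tanimoto distance). Equal-width rather
than equal-frequency stratification was chosen because activity
distributions pile up at assay thresholds (5 and 6 log units), where
equal-frequency bins would split ties arbitrarily.

## Models and tuning

* MLR baseline: ordinary least squares; with a rank-deficient design (always,
  at 2059 features and desk-scale n) a ridge-stabilised solution
  (α = 0.01) is used and flagged on the model.
* RF: `sklearn.ensemble.RandomForestRegressor`.
* GB: LightGBM, chosen because its parameter set covers every tuned
  hyperparameter — trees [50, 1000], depth [2, 12], learning rate
  [0.01, 0.3] (log scale), leaf size [1, 30], L1/L2 [0, 10], histogram bins
  [20, 100]; RF space: trees [100, 1000], depth [4, 20], leaf size [1, 10],
  feature fraction [0.2, 1.0].

Tuning: a Latin-hypercube design (scipy `qmc`, one sample per equal stratum
per parameter) seeds a genetic algorithm — population 20, tournament size 3,
uniform crossover p = 0.8, per-gene mutation p = 0.1, single elite, ≤ 30
generations — minimising 5-fold CV RMSE computed on folds fixed once per
run, so all candidates are scored on identical resamples. Early stopping:
five stagnant generations or a wall-clock budget (default 300 s per target
at desk scale; a 100-minute preset mirrors the full-scale protocol).
Duplicate configurations are cached, and the returned configuration is the
argmin over every evaluation, so the result can never be worse than the
best LHS seed.

Champion selection: the RF or GB model with the highest external Pearson R,
ties to GB. R rather than RMSE is the selection metric because activity
values cluster at assay cutoffs, which distorts error-based metrics more
than a covariance-based one.

## Validation

R, R², RMSE follow the direct formulas (sample covariance and SDs with
n−1). Internal protocols, each iterated (default 20 iterations; 100 as the
full-scale preset): 5-fold CV on pooled out-of-fold predictions; 90/10
resampling ("bootstrap": random 90% trains, held-out 10% scores);
y-scrambling (the response permuted before refitting, scored by CV — CV
rather than the training fit, so the reported null is an honest ≈ 0 and not
an inflated resubstitution value). External validation requires train/test
index disjointness and hard-fails on overlap.

Enrichment: true actives are the top ⌈0.02·M⌉ compounds by observed
pACTIVITY (stable tie-break by activity then compound key, so the active
set is deterministic); the selection is the top ⌈χ·M⌉ by prediction,
χ ∈ {1%, 5%, 10%}; `EF = (A_χ/M_χ)/(A/M)`; ceiling rounding guarantees a
non-empty selection at 1%. AUC uses the Mann–Whitney rank statistic with
midrank tie correction.

## Applicability domain and profiling

A model's AD is fulfilled when the query's maximum Tanimoto coefficient to
the model's stored training fingerprints strictly exceeds 0.7; the overall
AD score is the fulfilled fraction over the registry. The concern cutoff is
pACTIVITY ≥ 6.5 (10^−6.5 M ≈ 316 nM, conventionally rounded to 300 nM);
the boundary itself maps to concern. An optional per-target variable
threshold (train mean + 2 SD) and an optional per-target weight map for the
liability score are provided; both default off/uniform.

## Chemical space

Basic frameworks: Murcko scaffold first (rings + linkers; exocyclic
double-bonded atoms are part of the scaffold), then every atom becomes
carbon while bond orders and aromaticity are preserved and charges,
isotopes and stereo are dropped. Rings that cannot re-aromatise after
abstraction (e.g. aromaticity depended on a heteroatom) fall back to their
single-bond skeleton with a warning. Acyclic molecules have no framework
and are tallied separately. Frameworks group the space; member-averaged
descriptors are autoscaled and projected by PCA after the variance/
correlation filter. Pairwise dataset matrices: two-sample KS statistic and
p-value on pACTIVITY (both emitted — which one a heatmap should show is a
presentation choice), and mean cross-set Tanimoto similarity, with sets
capped at 200 seeded-subsampled compounds to keep the pairwise cost
desk-scale (an exact mode is the cap set high).

## Synthetic data: what it emulates, and what it does not

`generate_library` assembles SMILES from an in-package fragment grammar
(14 single-site and 6 two-site ring cores, 11 linkers, 25 substituents),
guaranteeing validity, standardization-stability and post-canonicalization
uniqueness; 500 compounds span well over 20 Murcko scaffolds.

`simulate_activities` draws pACTIVITY = signal + N(0, noise_sd) with the
signal scaled to variance (activity_sd² − noise_sd²), so the realized
sample mean/SD match the emulated corpus statistics (defaults 6.6/0.6 log
units) while the residual SD equals the configured noise. Forms: `linear`
(weighted z-scored descriptors — exactly identifiable by MLR when
noiseless), `fingerprint` (weights on a seeded 64-bit subset of bits with
5–95% prevalence, so tree models have recoverable signal), and the default
`mixed` — threshold "activity-cliff" effects on MolWt/LogP/TPSA/rotatable
bonds plus weaker additive descriptor and bit trends (relative SDs
1 : 0.4 : 0.3). The mixed form is what gives the realistic qualitative
pattern: tree ensembles clearly beat the linear baseline, GB edges RF on
panel average, and y-scrambling collapses everything to R ≈ 0.

Signal-to-noise design note: with total SD fixed at 0.6, the population
ceiling for any model is R = √(1 − noise_sd²/0.36) — about 0.87 at
noise_sd 0.3 and 0.94 at 0.2. End-to-end recovery checks that demand
external R ≥ 0.8 on ~100-compound test sets are therefore run at
noise_sd 0.2, where the margin is statistical rather than aspirational;
null (y-scrambling) checks run at 0.3.

`inject_artifacts` appends censored, non-human and jittered replicate
records on top of the clean ones and salts a fraction of structures in
place, so curation must recover the clean compound set exactly and each
replicate group's median exactly — both are checked against brute-force
oracles. The generator does not attempt realistic medicinal-chemistry
series, activity cliffs tied to real pharmacophores, matched molecular
pairs, or inter-laboratory bias structure; passing tests demonstrate the
pipeline's correctness and statistical sanity, not predictive performance
on real assay corpora.

## Problem sizes and numerical choices

Test and acceptance runs use 100–1000 compounds per dataset, 2–3 targets,
20 validation iterations and small tuning budgets (LHS 6–8, population 6–8,
3–5 generations) — the package's desk-scale defaults; the full-scale presets
(100 iterations, 100-minute tuning) are one config switch away. Seeds are
threaded explicitly through every stochastic step; identical configs and
seeds reproduce all numeric outputs bit-for-bit. Degenerate inputs are
defined errors: empty datasets, all-dropped descriptor sets, zero-variance
metric vectors (R reported as NaN with a flag), empty fingerprint stores,
and registries that leave a liability group without any modelled target.

## Known limitations

* The packaged mapping's printed-list inconsistencies (above) are shipped
  as-is.
* "Number of bins" is a LightGBM `max_bin`; other GB implementations would
  need a mapping or a warning.
* The AD is a max-similarity criterion; density- or leverage-based domains
  are out of scope.
* Framework abstraction can produce non-aromatisable rings; the single-bond
  fallback slightly coarsens those frameworks.
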