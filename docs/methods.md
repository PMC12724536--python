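# Methods

## Scope and data model

The package has two halves. The first is exact graph combinatorics:
molecular graphs (finite, simple, connected, hydrogen-suppressed by
caller convention), their degree-pair edge partitions, the M-polynomial,
and nine degree-based topological indices. The second is a statistical
pipeline: preprocessing, three regressors, seven evaluation statistics,
feature selection and ablation, applied either to user tables or to
synthetic study-shaped data.

Property tables are pandas DataFrames indexed by compound id; feature
and target column lists are always passed explicitly rather than
inferred, so the same table can serve different target/feature splits
(the study itself uses properties as features for one another).

## Index computation

The edge partition is the single source of truth: every index is the sum
`Σ m_ij · f(i,j)` over degree pairs. The operator route
(`Dx = x ∂/∂x`, `Dy`, and their inverses `Sx`, `Sy`) exists for the four
integer-order indices (M1, M2, F, HM) and is kept exact — integer
coefficients stay integers under `Dx`/`Dy` — so the equivalence between
the two routes is asserted with `==`, not a tolerance. The fractional
operators that would express Randić-type indices through the polynomial
are deliberately not implemented: kernel summation is exact and
unambiguous, and the polynomial route would add only rounding error.

Degenerate case: the ABC kernel at degree pair (1,1) (the single-edge
graph K₂) returns 0 instead of raising, so batch runs over arbitrary
valid graphs cannot crash on the one pair whose radicand vanishes.

## Preprocessing

Order is fixed: median imputation → IQR outlier filtering → min–max
scaling. Choices that matter:

* Quantiles everywhere use the linear-interpolation convention (rank
  `(n−1)q`). This is load-bearing: it is the only common convention that
  regenerates the published residual IQR of 1.4527288 for the tuned SVR
  on COM; nearest-rank and Tukey-hinge variants do not.
* Scaling statistics are fit on training rows only and applied to test
  rows without clipping. The published test predictions for compounds far
  outside the training range (e.g. actual COM 2110 predicted 2095.1)
  are only possible without clipping or test leakage.
* Constant columns scale to 0 everywhere (they carry no information and
  a 0/0 would otherwise propagate).
* Outlier filtering applies to feature columns only, never targets, and
  defaults off for reproduction runs: all 19 published training
  compounds appear in the published results, so no row can have been
  dropped there.
* Targets are never scaled; published predictions are on natural scales.
* Train size under a random split is `round(f·n)` clamped to
  `[1, n−1]`, drawn by a seeded permutation (`numpy default_rng`).

## Models

* `svr_basic`: RBF-kernel SVR with mainstream defaults (C = 1,
  ε = 0.1, γ = "scale"). With features in [0,1] and raw targets spanning
  hundreds of units, this model collapses to a narrow prediction band —
  visible in the published training predictions (all ≈ 811–822 for COM)
  and asserted as a regression test of the documented failure mode, not
  "fixed".
* `svr_tuned`: grid search over C ∈ {10⁰…10⁶}, γ ∈ {10⁻⁴…10¹},
  ε ∈ {10⁻³…10¹} (log steps), 3-fold shuffled CV (training sets of
  15–23 rows are too small for 5 folds), scoring negative MSE. The grid
  must reach large C and small ε to permit near-interpolating fits;
  ties break toward the first grid point in enumeration order.
* `rf`: 200 trees, unlimited depth, min 2 samples per split, seeded.
* `linear_baseline`: ordinary least squares (minimum-norm when
  underdetermined), available as a context model.

Exact reproduction of the study's fitted predictions is out of reach on
principle — its hyperparameters, seeds and split are unpublished — so
reproduction targets run through the embedded prediction fixtures
instead, and model behaviour is validated on synthetic data.

## Evaluation conventions

Residuals are `r = actual − predicted`; the sample standard deviation
uses the n−1 denominator; IQR uses linear-interpolation quantiles. Two
sample conventions coexist in the published record and are both exposed,
explicitly labelled: fit metrics (MSE, RMSE, MAE, R²) over the 19
training pairs, and residual metrics (mean, Std, IQR) over the 29
pooled train+test pairs. The pooled convention is not stated in the
source; it was recovered by matching the printed numbers and is enforced
by regression tests.

Known inconsistency: the published MR (molar refractivity) residual
cells do not regenerate from the published MR predictions under any of
the conventions above (recomputed tuned Std ≈ 0.095 vs printed 3.039),
while every COM cell regenerates to print rounding. The
`reproduce-tables` report marks exactly those cells
`paper-inconsistent` instead of `pass`/`fail`, so the discrepancy stays
visible without masking real regressions.

## Synthetic data

`random_molecular_graph` builds a uniform random spanning tree by random
attachment under a degree cap (default 4, the organic heavy-atom valence
ceiling) and then adds ring-closing edges only where both endpoints stay
under the cap (~0.25 per atom). `simulate_property_table` computes the
nine indices per graph, generates auxiliary descriptors (BP, DE, IR
analogues) as noisy monotone functions of molecular size, builds each
target as a declared linear/power combination of index columns plus
Gaussian noise (noise sd specified as a fraction of the signal spread,
default 3%), and can inject missing cells, gross outliers (×12
corruption) and pure-noise decoy features.

Defaults mirror the study conditions: 29 compounds (the study's 19
train + 10 test), 8–30 heavy atoms, five targets with magnitudes shaped
like COM/MR/MV/MW/PO. What the generator reproduces about real data is
the *statistical regime* — small n, strongly collinear descriptors,
smooth monotone structure–property relationships. What it does not
reproduce: real chemistry (valence rules beyond the cap, rings
statistics, aromaticity) or the study's actual descriptor values, which
are not published in the main text. Passing synthetic tests therefore
demonstrates pipeline correctness under the study's regime, not
predictive validity on real antibiotics.

## Identifiability and the recovery studies

Across random graphs all nine indices scale with molecular size and are
pairwise correlated at 0.94–0.999. Consequently "which index generated
the target" is not identifiable within the index family: M2, HM and F
are near-perfect proxies for M1. The recovery studies are therefore
posed where the question is well-defined:

* model ordering and tuned-SVR fit quality use the full collinear
  feature set (the regime the study operates in), with the planted
  target y = 2·M1 + 0.05·M1² and noise at 10⁻⁶ of the signal spread;
* RFE recovery asks whether the planted index survives selection
  against the auxiliary descriptors and six independent N(0,1) decoys
  (ten candidates, five kept);
* the ablation strictness check removes the *sole informative* feature
  from a set of M1 plus four noise decoys, where a strict RMSE increase
  is the correct expectation for both models.

These constructions were fixed after a design-stage identifiability
analysis and are frozen in `mpolyqspr.studies`.

## Problem sizes and numerical choices

Studies run 20 replicates (3 for the ablation study, whose tuned-SVR
grid searches dominate cost) at 29 compounds each — the package's own
choice of a study-shaped size that keeps the full suite in well under
two minutes on one CPU. Index values are kept at full float precision;
rounding happens only at serialization (6 decimals in CSV). Metric
implementations are vectorised numpy; the test suite checks them against
a pure-Python loop oracle at 1e−12 relative tolerance and against
scikit-learn where an equivalent exists.

## Known limitations

* The 29 study compounds are published only as molecular formulas; their
  graphs, and hence their true index values, cannot be reconstructed
  from the main text and are not guessed.
* Published ablation RMSE magnitudes are not reproducible (unknown
  split/seed); the package reproduces the qualitative behaviour only.
* SMILES ingestion (rdkit extra) produces the heavy-atom skeleton only;
  bond orders and aromaticity are ignored by design, since the indices
  are purely degree-based.
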