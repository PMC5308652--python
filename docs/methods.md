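# Methods

This document records the models, parameter choices and numerical conventions
implemented in `apoptopredict`, and the limitations of each.

## 1. Input model

A `ProteinPanel` is a long-format table (cell line × protein × replicate →
concentration) over a fixed 19-protein apoptosis panel: Bcl-2, Bcl-xL, Mcl-1,
Bax, Bak, Bid, Bim, Puma, Noxa, SMAC, Apaf-1, caspase-9, caspase-8, cFLIP,
caspase-3, XIAP, DR4, DR5, FADD. Protein names are matched case- and
punctuation-insensitively against an alias table; negative concentrations and
unknown proteins are validation errors. Replicates are aggregated by
arithmetic mean before feature computation. A `ResponseTable` holds surviving
fractions per cell line and treatment arm (TMZ, TRAIL, TMZ+TRAIL, plus
ABT-737 variants); viability given as percent of control is divided by 100 at
read time.

## 2. Functional groups

Eleven features, each of the 19 proteins used exactly once:

| group | combinator | members |
|---|---|---|
| anti_apoptotic_bcl2 | SUM | Bcl-2, Bcl-xL, Mcl-1 |
| momp_pore | SUM | Bax, Bak |
| bid / bim / puma / noxa / smac | SINGLE | one protein each |
| apoptosome | PRODUCT | Apaf-1 × caspase-9 |
| disc | PRODUCT | (DR4 + DR5) × FADD |
| initiator_ratio | RATIO | caspase-8 / cFLIP |
| executioner_ratio | RATIO | caspase-3 / XIAP |

Rationale: SUM for functionally redundant proteins, PRODUCT for obligate
complex formation (zero expression of either partner abolishes the complex),
RATIO for inhibitor stoichiometry. The DISC default treats DR4 and DR5 as
redundant receptors summed before multiplication by FADD; a strict
`triple_product` variant (DR4 × DR5 × FADD) and an 8-group variant pooling
the BH3-only proteins are provided as alternatives. PRODUCT definitions are
stored as tuples of factors, each factor a sum of proteins, which expresses
both product forms in one representation.

Zero denominators in RATIO groups are an error under the default `strict`
policy; a `floor` policy substitutes `ratio_floor_scale` × the column median
(default scale 1e-6) for analyses that must tolerate undetected inhibitors.

## 3. PC space

FG units are heterogeneous (nM, nM², dimensionless), so principal components
are computed on the correlation scale: each FG is z-scored (mean, SD with
ddof = 1) over the training lines and the z-matrix's correlation matrix is
eigendecomposed (`numpy.linalg.eigh`). Conventions:

- Eigenvalues are clipped at 0 (they sum to 11, the FG count) and sorted
  descending.
- Sign convention: the largest-magnitude coefficient of each component is
  made positive, so loadings are deterministic.
- Retention: Kaiser criterion (eigenvalues > 1) with a floor of one
  component; an explicit `n_components` overrides it.
- The standardization is frozen in the model; projection of new or perturbed
  lines never refits. Constant FG columns (SD below 1e-12 of the mean
  magnitude) are a fit error.
- Internally the FG matrix is copied to a C-contiguous array before
  reductions and matrix products, so identical values give bit-identical
  models regardless of how the dataframe was assembled.

## 4. Response classes and discriminant model

Surviving fraction s maps to an ordinal class with upper-inclusive
boundaries: HIGH responder s ≤ 0.30, LOW responder 0.30 < s ≤ 0.80,
RESISTANT s > 0.80. The thresholds are configuration; these defaults are
used throughout the synthetic study.

Linear discriminant analysis is implemented directly: class means, pooled
within-class covariance Σ = Σ_c S_c / (n − C), a ridge of
1e-6 · trace(Σ)/k on the diagonal for numerical stability, and uniform
class priors by default (empirical priors optional). Classification is the
arg-max discriminant score with ties broken toward the less responsive
class. Every class must have at least two members; classes with a single
member are first pooled into the adjacent less-responsive class (the
least-responsive singleton merges upward), repeating until no singletons
remain. An all-singleton labeling is an error (use coarser thresholds).

## 5. LOOCV and treatment recommendation

Each fold drops one line, re-pools singleton classes among the training
labels, refits standardization + PCA (per-fold Kaiser retention by default,
`fixed_k` optional) + LDA on the remaining lines only, and predicts the
held-out line. The held-out observed label is mapped through the fold's
pooling map; an observed class absent from the fold's pooled set maps to the
nearest pooled class (ties toward the more responsive one). Folds whose
training labels collapse to a single class are degenerate and counted
incorrect unless `skip_degenerate` is set. Leakage is tested bit-exactly:
mutating the held-out line must not change the fold's fitted models.

A per-line recommendation prefers the arm with the more responsive predicted
class ("either" on ties, "unavailable" if a prediction is missing). A
recommendation is scored correct when the two arms' observed survivals are
within `similar_tol` = 0.10 of each other (any recommendation acceptable
except that "either" is only correct in this case), or when the recommended
arm's observed survival is at most the other arm's.

## 6. Synergy

Webb's fractional product: CI = s_combo / (s_TMZ × s_TRAIL); CI < 1 means
the combination kills more than independence predicts. Survivals above 1
(assay noise above control) are clipped to 1 with a warning for CI
computation only; a monotherapy survival of 0 leaves CI undefined and is an
error. Synergy classes use upper-inclusive CI bins with a shipped default of
(0.5, 0.9): high synergy CI ≤ 0.5, moderate 0.5 < CI ≤ 0.9, non-synergistic
above. A combination survival of exactly 0 (complete kill) is assigned high
synergy directly. Synergy classes feed the same LOOCV machinery as response
classes.

Noise floor: with viability noise of SD 0.05 on each arm, the CI estimate
degrades sharply when monotherapy survivals are small (the denominator
s_a · s_b amplifies noise); the synthetic-data tests quantify this and the
estimator should not be trusted at monotherapy survival below ~0.2.

## 7. Sensitization (in-silico ABT-737)

ABT-737 neutralizes Bcl-2 and Bcl-xL. The prediction sets both proteins to
zero (a configurable `fraction` allows partial depletion), recomputes the
FGs — only `anti_apoptotic_bcl2` changes, to the remaining Mcl-1 — and
reprojects the line with the frozen model. Verdict: SENSITIZED iff the
post-depletion position falls in a strictly more responsive LDA region. A
continuous readout (reduction of Mahalanobis distance to the most responsive
class mean) accompanies the discrete verdict.

Because projection is linear in the z-scored FGs, the displacement equals
`movement_vector(model, fg, Δz) = −Δz × loading_row[:k]` with
Δz = (Bcl-2 + Bcl-xL)/SD(anti_apoptotic_bcl2). The implementation computes
displacement by direct reprojection; the movement-vector identity is held to
1e-10 in the tests. A line expressing zero Bcl-2 and Bcl-xL cannot move and
is never predicted sensitized.

## 8. Synthetic data generator

Scope: the generator emulates the *shape* of quantitative apoptosis panels,
not any measured dataset. Choices, fixed once as study conditions:

- Protein abundances are log-normal around per-protein medians spanning
  0.1–500 nM with log-scale SD 0.8; replicates add a 15% CV log-normal
  factor; default cohort 11 lines × 19 proteins × 3 replicates = 627
  measurements.
- A latent pro-survival score per arm is a linear combination of z-scored
  FGs (intrinsic-weighted for TMZ, extrinsic-weighted for TRAIL), rescaled
  so its sample SD equals `class_separation` (default 3.0) plus an
  intercept of 0.3; survival = sigmoid(latent) + N(0, 0.05), clipped to
  [0.01, 1.1]. The 0.01 floor models assay detection limits and keeps the
  Webb CI defined.
- Combination survival = true_CI × s_TMZ × s_TRAIL + noise, clipped to
  [0, 1.1]. True CI is either configured or FG-driven:
  0.15 + 1.05 · sigmoid(latent), so synergy classes are a deterministic
  function of the protein profile. The stored ground-truth CI is the
  *realized* noiseless value (the requested CI quantized to the float grid
  of the generated survivals, within 1 ulp), so the Webb estimator recovers
  it bit-exactly when noise is zero.
- Streams are seeded as `default_rng([seed, stage])` with one stage per
  data product, so e.g. the panel is unchanged when only the viability
  noise is re-drawn.
- `generate_gaussian_fg_cohort` draws class-conditional Gaussian FG values
  directly (unit within-class SD, class means `separation` apart along a
  random direction). This is the surface used for parameter-recovery and
  permutation-null studies, where the question is whether the
  PCA + LDA + LOOCV machinery recovers a known class geometry.

Limitation: the protein-level generator produces heavy-tailed FG marginals
(sums and products of log-normals), which violate LDA's Gaussian
assumption. At 11 lines this dominates: LOOCV accuracy on such cohorts is
low and seed-dependent even when the latent separation is large, and raising
`class_separation` does not fix the distributional mismatch. The
Gaussian-FG cohort isolates the estimator from this generator property;
both surfaces are reported.

## 9. Numerical conventions (summary)

- Correlation-scale PCA; Kaiser retention floor 1; deterministic loading
  signs; frozen standardization.
- LDA ridge 1e-6 · trace(Σ)/k; uniform priors; ties toward less responsive.
- Upper-inclusive class boundaries everywhere (response thresholds 0.30 /
  0.80; CI bins 0.5 / 0.9).
- Singleton pooling toward less responsive, least-responsive singleton
  merges upward.
- Survival > 1 clipped to 1 for CI only, with a warning.
- C-contiguous canonical array layout before reductions, for bit-stable
  refits.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`.

No empirical claim in this document goes beyond what the test suite and
`scripts/acceptance.py` compute.
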