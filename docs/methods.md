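# Methods

This note documents the models, procedures, numerical choices, and known
limitations of `cpmnet`, in the order a user meets them.

## Connectivity construction and inclusion rules

Edges are Fisher-z transformed Pearson correlations between node mean time
courses. Because synthetic or degenerate data can produce |r| = 1 (where
arctanh diverges), |r| is clamped to 1 − 1e−7 before the transform. The
diagonal is stored as 0 and excluded everywhere; the edge universe is the
strict upper triangle, in `numpy.triu_indices` order, shared by every
module. A node whose time course has zero variance cannot be correlated
and is flagged uncovered (NaN row/column); we treat exact zero variance as
a coverage failure rather than inventing a correlation for it.

Subjects are excluded when mean frame-to-frame displacement reaches
0.1 mm or maximum displacement reaches 0.15 mm in any analyzed condition
(strict inequalities: a subject at exactly 0.1 mm is excluded). Nodes
uncovered for *any* subject of *any* supplied stack are dropped for all
subjects — conservative, and the reason cross-dataset analyses run on the
node subset common to both datasets. Matrix files are verified symmetric
on read to 1e−8, and subject alignment is always by explicit subject id,
never file order.

## The CPM estimator

Edge selection correlates each edge with the trait in training subjects;
p-values use the t transform t = r·√(df/(1−r²)) with df = n − 2 − k for k
covariates. Two threshold families are supported: p-value (CN = {r > 0,
p < level}, AN = {r < 0, p < level}) and sparsity (top round(level·e)
edges by r in each direction, ties broken by ascending edge index).
Parametric edge p-values are standard for CPM and fast; permutation
inference operates at the model level, not the edge level.

Network strength sums each undirected edge once. The literature's double
sum over (i, j) is ambiguous between counting symmetric entries once or
twice; the choice is invisible to predictions (the fitted slope rescales)
and counting once keeps strengths interpretable as sums over unique edges.
Strength-to-trait models are ordinary least squares first-degree
polynomials; covariates (e.g. sex, motion) can enter at edge selection
(partial correlation), at model fitting (additional regressors), both, or
neither — four explicit modes, because the first two answer different
questions and are evaluated separately.

Cross-validation is leave-one-out by default; k-fold (default k = 10)
assigns subjects by a seeded uniform permutation into folds whose sizes
differ by at most one. Subjects missing the trait are dropped before CV.
If a training fold yields an empty or constant-strength network, that
fold's prediction falls back to the training-trait mean (a defensible
"no information" prediction that keeps the CV loop total). Performance is
Spearman with midranks; percent variance explained is clamped to 0 for
negative correlations, since an anti-predicting model explains nothing.

### Batched permutation kernel

Permutation inference re-runs the full CV loop per permuted trait. The
batched kernel (`batched_cpm_combined`) evaluates the combined-network arm
for hundreds of trait columns at once by expressing per-fold edge-trait
correlations and strength sums as matrix products, and applying p-value
thresholds as the equivalent critical |r| bound. A regression test pins
the kernel column-for-column to the plain CV loop; the generic
`model_runner` path remains available for models the kernel does not
cover (covariates, CN/AN arms).

## Permutation inference with family structure

Heritable traits make siblings non-exchangeable with strangers.
`build_blocks` groups subjects into families, labels each family by the
sorted multiset of sibling types (its *signature*), and groups families
with identical signatures. Size-1 families are relabeled `singleton`
regardless of recorded sibling type, so all singletons form one exchange
group; subjects missing family information become singletons. Each
permutation draw composes two stages: whole-family blocks permute within a
signature group (member slots matched by sibling type), then values
permute within each family among same-type members. Published accounts of
restricted exchangeability do not fix an algorithm at this granularity;
the two-stage scheme is validated by exhaustive enumeration on small
cohorts (`enumerate_reachable`), where the empirical support of 10,000
draws equals the enumerated reachable set.

The permutation p is the plain fraction of iterations whose statistic
strictly exceeds the observed one (no +1 correction, ties favor the
observed side); p = 0 is reportable as p < 1/B. With B = 200 this yields a
type-I error of 10/201 ≈ 0.0498 at the nominal 0.05 level, which the
calibration suite verifies empirically. FDR correction is
Benjamini-Hochberg step-up (via statsmodels), applied across the
conditions of one dataset analog.

The exact Mann-Whitney test enumerates the null distribution of the
smaller group's rank sum by dynamic programming over doubled midranks
(ties handled by enumeration of the observed midrank multiset); the
two-sided p is min(1, 2·min(P(R ≤ r), P(R ≥ r))). Enumeration applies up
to pooled n = 25; beyond that the normal approximation is used and
flagged. Steiger's z compares two dependent correlations sharing one
variable (two models' predictions against the same trait), using the
pooled mean correlation r̄ = (r₁+r₂)/2 in the covariance term, as in the
Lee-Preacher calculator; the one-tailed p comes from the normal upper
tail. Split-half stability retrains on random halves and records held-out
r_s and trained-mask degree vectors per iteration.

## Generalization

Cross-condition validation keeps the CV loop but computes held-out
strengths from the test condition's matrices; with train = test it is
bitwise identical to ordinary CPM (regression-tested). Cross-dataset
transfer intersects the per-fold masks (an edge survives only if selected
in every fold) and scores the intersection network on the external data
as the Spearman correlation between strength and trait — no coefficients
cross datasets, so trait scales need not match. Generalization analyses
default to the less conservative P < 0.01 threshold to limit overfitting;
anatomy uses P < 0.01 for degree/overlap and P < 0.001 for contribution
matrices, where sparser networks aid interpretation.

## Anatomy

Degree, overlap, and contribution are defined in the README. Homolog
assignment reflects opposite-hemisphere centroids across the midline by
negating the first coordinate (the atlas convention puts left-right on
the first axis with midline 0; the axis is configurable) and takes the
nearest reflected centroid; the mapping is nearest-neighbor and not
forced bijective. Network pairs with no possible edges get contribution 0
by convention, which preserves the exact weighted identity
Σ Contribution_{A,B}·(E_{A,B}/E_tot) = 1 for every nonempty mask. The
CN-AN degree relation of a single model needs no separate operation — it
is `degree_similarity` applied to the model's D⁺ and D⁻.

## The synthetic generator

The generator is the package's study population, not a tuning knob. Its
defaults: two task conditions with amplification alpha = 1.0 and one rest
condition with alpha = 0.5 (the task > rest structure under test); trait
effect beta = 0.1 and edge noise sigma = 0.25 (beta/sigma = 0.4, chosen so
planted single-edge correlations are realistic-to-detectable at n ≈ 200:
r = alpha·beta/√(alpha²beta² + sigma²) ≈ 0.37 under full amplification);
family variance share rho_fam = 0.4 with a family mix of 40% singletons
and 20% each non-twin, DZ, and MZ pairs; edge baseline mu ~ N(0.3, 0.1²)
on the Fisher-z scale; motion log-normal around 0.06 mm, kept under the
exclusion thresholds unless excluded subjects are requested; planted sets
default to 1% of the edge universe each. Sex-specific circuits are
disjoint planted sets whose coupling is nonzero only within one sex, with
their own per-condition amplification. A single trait-coupling parameter
serves all sibling types; MZ/DZ-specific heritability is not modeled.

What the generator does *not* emulate: spatial autocorrelation of edges,
realistic network topology, temporal structure (the AR(1) time-course
mode exists only to exercise connectivity construction and truncation),
age or site effects, and trait-motion confounding beyond a linear loading.
Passing recovery tests therefore demonstrates correctness of the
estimator and inference machinery under the assumed generative model, not
performance on real connectomes.

## Problem sizes and numerical choices

Calibration and recovery suites run at desk scale, chosen as the package's
own benchmark conditions: null calibration uses 100 cohorts of n = 100
subjects on 60-node connectomes with B = 200 permutations under k-fold
(k = 10) CV; amplification recovery uses 50 replicates at n = 200, 60
nodes, 30 planted edges per direction; sex-circuit recovery uses 50
replicates at n = 240, 40 nodes, sex_beta = 0.15 with amplification 1.0
vs 0.2 for matched vs mismatched conditions. Tolerances: matrix symmetry
1e−8 on read; correlation clamp 1e−7; sparsity ties broken by edge index;
k-fold fold sizes differ by at most one; all randomness flows through
`numpy.random.default_rng` seeds and identical seeds give bit-identical
outputs.

## Known limitations

Only linear strength models (no regularization, no edgewise models); no
voxel-level I/O or parcellation construction (matrices arrive
preprocessed); degree is the only graph metric; the exact Mann-Whitney
enumeration is limited to pooled n ≤ 25; and the permutation p without +1
correction is slightly anti-conservative at small B (quantified above).
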